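"""Delimited-matrix I/O, model serialisation and report export.

Matrices are TSV/CSV with a header row of feature ids and a first column
of sample ids; empty cells or ``NA`` are missing values. Models serialise
to a single JSON document that round-trips every field needed to predict
new samples and to recompute the plot backends.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FittedModel, OmicsBlock

__all__ = ["read_matrix", "write_matrix", "read_column", "write_column",
           "save_model", "load_model", "export_gml", "export_report"]


def _sep(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_matrix(path) -> OmicsBlock:
    """Read a samples x features matrix (TSV, or CSV by extension)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep(path), index_col=0,
                         na_values=["NA", ""], keep_default_na=True,
                         float_precision="round_trip")
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed table — {e}") from e
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dup[:5]}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dup[:5]}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()].tolist()
            lines = [int(df.index.get_loc(b)) + 2 for b in bad[:5]]
            raise ValueError(
                f"{path}: non-numeric cells in column {col!r} at line(s) {lines}")
    return OmicsBlock(df.to_numpy(dtype=float),
                      sample_ids=[str(i) for i in df.index],
                      feature_ids=[str(c) for c in df.columns],
                      name=path.stem)


def write_matrix(block: OmicsBlock, path) -> None:
    df = pd.DataFrame(block.values, index=block.sample_ids,
                      columns=block.feature_ids)
    df.to_csv(path, sep=_sep(path), na_rep="NA", float_format="%.17g")


def read_column(path, column: str | None = None) -> tuple[list[str], np.ndarray]:
    """Read a per-sample annotation (outcome or study) table.

    First column: sample ids; ``column`` selects the value column
    (default: the first data column). Returns (sample_ids, values).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: expected at least one value column")
    col = column if column is not None else df.columns[0]
    if col not in df.columns:
        raise ValueError(f"{path}: no column {col!r}; have {list(df.columns)}")
    return [str(i) for i in df.index], df[col].astype(str).to_numpy()


def write_column(sample_ids, values, path, column: str = "label") -> None:
    pd.DataFrame({column: values}, index=sample_ids).rename_axis("sample") \
        .to_csv(path, sep=_sep(path))


# ---------------------------------------------------------------------------
# model serialisation
# ---------------------------------------------------------------------------

def _enc(x):
    if isinstance(x, np.ndarray):
        return {"__nd__": True, "data": x.tolist(), "dtype": str(x.dtype)}
    if isinstance(x, (np.floating, np.integer, np.bool_)):
        return x.item()
    if isinstance(x, dict):
        return {k: _enc(v) for k, v in x.items()}
    if isinstance(x, tuple):
        return {"__tuple__": True, "items": [_enc(v) for v in x]}
    if isinstance(x, list):
        return [_enc(v) for v in x]
    return x


def _dec(x):
    if isinstance(x, dict):
        if x.get("__nd__"):
            return np.asarray(x["data"], dtype=x.get("dtype", "float64"))
        if x.get("__tuple__"):
            return tuple(_dec(v) for v in x["items"])
        return {k: _dec(v) for k, v in x.items()}
    if isinstance(x, list):
        return [_dec(v) for v in x]
    return x


_MODEL_FIELDS = [
    "method", "loadings", "scores", "y_loadings", "projection", "keepX",
    "ncomp", "mode", "block_names", "feature_ids", "sample_ids", "col_means",
    "col_sds", "scaled", "class_labels", "y", "y_indicator", "y_coefs",
    "study_labels", "study_params", "design", "convergence",
    "explained_variance", "X_std", "y_scores",
]


def save_model(model: FittedModel, path) -> None:
    """Serialise a fitted model to JSON (loss-free for prediction)."""
    doc = {f: _enc(getattr(model, f)) for f in _MODEL_FIELDS}
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> FittedModel:
    doc = json.loads(Path(path).read_text())
    kwargs = {f: _dec(doc[f]) for f in _MODEL_FIELDS if f in doc}
    return FittedModel(**kwargs)


# ---------------------------------------------------------------------------
# report / graph export
# ---------------------------------------------------------------------------

def export_gml(edges, path) -> None:
    """Write a relevance-network edge list as GML (via networkx)."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        # block-qualified names: feature ids may repeat across blocks
        ni, nj = f"{e.block_i}:{e.feature_i}", f"{e.block_j}:{e.feature_j}"
        g.add_node(ni, block=e.block_i, feature=e.feature_i)
        g.add_node(nj, block=e.block_j, feature=e.feature_j)
        g.add_edge(ni, nj, weight=float(e.similarity),
                   sign="positive" if e.similarity > 0 else "negative")
    nx.write_gml(g, path)


def export_report(obj, path) -> None:
    """Dump a TuneResult / PerfReport / plain dict to JSON."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = {k: getattr(obj, k) for k in obj.__dataclass_fields__}
    Path(path).write_text(json.dumps(_enc(obj), indent=2, default=str))
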