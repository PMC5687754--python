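"""Seeded generators of synthetic omics data with planted structure.

The generators emulate the three situations the supervised methods are
built for:

* :func:`gen_single` — one block with class-specific mean shifts on a
  known subset of features (a plantable molecular signature);
* :func:`gen_multiblock` — several blocks on the same samples whose
  informative features load on shared, class-discriminant latent factors,
  so the signature is correlated across blocks;
* :func:`gen_multistudy` — one block measured in several independent
  studies with additive offsets and multiplicative scale factors per
  study (batch effects) on top of a study-invariant class signal.

Everything is driven by :class:`SimConfig` and a seed; identical
configuration and seed give bitwise-identical output, and the returned
truth metadata records the informative features so recovery experiments
can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import OmicsBlock

__all__ = ["SimConfig", "gen_single", "gen_multiblock", "gen_multistudy",
           "inject_missing", "PRESETS", "preset"]


@dataclass
class SimConfig:
    """Configuration of the synthetic generators.

    Parameters
    ----------
    n_per_class
        Samples per class (int, or one entry per class for unbalanced
        designs).
    p
        Features per block (int, or one entry per block for
        :func:`gen_multiblock`).
    k
        Number of outcome classes.
    n_informative
        Planted discriminative features per block.
    effect
        Class mean shift in units of the noise sd (1.5 is a clearly
        detectable but overlapping signal at typical omics sample sizes).
    n_factors
        Shared latent factors for multi-block data; defaults to k-1, one
        discriminant contrast per factor.
    factor_strength
        gamma in [0, 1]: informative features are
        gamma*factor + sqrt(1-gamma^2)*noise, so two features on the same
        factor correlate at gamma^2 (conditional on class).
    n_studies, study_offset, study_scale
        Study count and batch-effect magnitudes for multi-study data:
        additive per-study/feature offsets ~ N(0, study_offset^2) and
        multiplicative factors exp(N(0, study_scale^2)).
    missing_rate
        Fraction of cells masked by :func:`inject_missing`.
    noise
        "gaussian" or "t3" (Student t with 3 df, heavy-tailed robustness
        probe).
    """

    n_per_class: int | tuple = 20
    p: int | tuple = 100
    k: int = 3
    n_informative: int | tuple = 20
    effect: float = 1.5
    n_factors: int | None = None
    factor_strength: float = 0.8
    n_studies: int = 4
    study_offset: float = 2.0
    study_scale: float = 0.2
    missing_rate: float = 0.05
    noise: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("need at least 2 classes")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        if self.noise not in ("gaussian", "t3"):
            raise ValueError("noise must be 'gaussian' or 't3'")

    def class_sizes(self) -> list[int]:
        if isinstance(self.n_per_class, (int, np.integer)):
            return [int(self.n_per_class)] * self.k
        sizes = [int(v) for v in self.n_per_class]
        if len(sizes) != self.k:
            raise ValueError("n_per_class must have one entry per class")
        return sizes

    def block_sizes(self) -> list[int]:
        return ([int(self.p)] if isinstance(self.p, (int, np.integer))
                else [int(v) for v in self.p])

    def informative_sizes(self, n_blocks: int) -> list[int]:
        if isinstance(self.n_informative, (int, np.integer)):
            return [int(self.n_informative)] * n_blocks
        return [int(v) for v in self.n_informative]


def _noise(rng: np.random.Generator, shape, kind: str) -> np.ndarray:
    if kind == "t3":
        return rng.standard_t(3, size=shape) / np.sqrt(3.0)  # unit variance
    return rng.standard_normal(shape)


def _labels(cfg: SimConfig) -> np.ndarray:
    return np.repeat([f"C{k + 1}" for k in range(cfg.k)], cfg.class_sizes())


def _marker_allocation(n_inf: int, k: int) -> list[int]:
    """Assign informative features to marker classes.

    Each planted feature is a marker "up" in exactly one class. With
    three or more classes the last class carries no markers of its own
    and is characterised by being low on every signature (a
    marker-negative reference group, the common situation for e.g. a
    control or triple-negative subtype); markers are split evenly, in
    contiguous runs, over the remaining classes.
    """
    marker_classes = list(range(k - 1)) if k >= 3 else list(range(k))
    splits = np.array_split(np.arange(n_inf), len(marker_classes))
    alloc = np.empty(n_inf, dtype=int)
    for cls, idx in zip(marker_classes, splits):
        alloc[idx] = cls
    return alloc.tolist()


def _plant_markers(x, y, cfg: SimConfig, n_inf: int):
    classes = [f"C{k + 1}" for k in range(cfg.k)]
    alloc = _marker_allocation(n_inf, cfg.k)
    feature_class = {}
    for j in range(n_inf):
        cls = classes[alloc[j]]
        x[y == cls, j] += cfg.effect
        feature_class[int(j)] = cls
    return feature_class


def gen_single(cfg: SimConfig):
    """One block with class-specific mean shifts on informative features.

    Each informative feature is a marker of one class (shift ``effect``
    noise-sds for that class's samples); see :func:`_marker_allocation`
    for how markers are distributed over classes. Returns
    ``(OmicsBlock, y, truth)`` with ``truth["support"]`` the informative
    feature indices and ``truth["feature_class"]`` their class assignment.
    """
    p = cfg.block_sizes()[0]
    n_inf = cfg.informative_sizes(1)[0]
    if n_inf > p:
        raise ValueError("n_informative exceeds p")
    rng = np.random.default_rng(cfg.seed)
    y = _labels(cfg)
    x = _noise(rng, (len(y), p), cfg.noise)
    feature_class = _plant_markers(x, y, cfg, n_inf)
    block = OmicsBlock(x, name="X")
    truth = {"support": np.arange(n_inf), "feature_class": feature_class,
             "effect": cfg.effect}
    return block, y, truth


def gen_multiblock(cfg: SimConfig):
    """Several blocks whose signatures share class-discriminant factors.

    Factor l is a per-sample latent value ``effect * m_l(class) + N(0,1)``
    where m_l contrasts class l against the rest; informative feature j of
    every block mixes its factor with fresh noise at ``factor_strength``.
    With strength 0 there is neither class signal nor cross-block
    correlation; with strength 1 paired informative features are copies of
    the factor.
    """
    ps = cfg.block_sizes()
    n_infs = cfg.informative_sizes(len(ps))
    rng = np.random.default_rng(cfg.seed)
    y = _labels(cfg)
    n = len(y)
    L = cfg.n_factors if cfg.n_factors is not None else max(1, cfg.k - 1)
    classes = [f"C{k + 1}" for k in range(cfg.k)]
    contrasts = np.zeros((L, cfg.k))
    for l in range(L):
        contrasts[l] = -1.0 / (cfg.k - 1)
        contrasts[l, l % cfg.k] = 1.0
    class_idx = np.array([classes.index(c) for c in y])
    factors = (cfg.effect * contrasts[:, class_idx].T
               + _noise(rng, (n, L), cfg.noise))

    gamma = float(cfg.factor_strength)
    blocks, truth_blocks = [], []
    for b, (p, n_inf) in enumerate(zip(ps, n_infs)):
        if n_inf > p:
            raise ValueError(f"block {b}: n_informative exceeds p")
        x = _noise(rng, (n, p), cfg.noise)
        support = np.arange(n_inf)
        feature_factor = {}
        for j in support:
            l = j % L
            x[:, j] = (gamma * factors[:, l]
                       + np.sqrt(max(0.0, 1 - gamma ** 2)) * x[:, j])
            feature_factor[int(j)] = int(l)
        blocks.append(OmicsBlock(x, name=f"block{b + 1}"))
        truth_blocks.append({"support": support,
                             "feature_factor": feature_factor})
    truth = {"blocks": truth_blocks, "factors": factors,
             "factor_strength": gamma, "effect": cfg.effect}
    return blocks, y, truth


def gen_multistudy(cfg: SimConfig):
    """One block across independent studies with planted batch effects.

    Class composition is (near-)balanced within every study; the class
    signal (as in :func:`gen_single`) is identical across studies, while
    each study adds per-feature offsets and multiplicative scale factors.
    Returns ``(OmicsBlock, y, study, truth)``.
    """
    p = cfg.block_sizes()[0]
    n_inf = cfg.informative_sizes(1)[0]
    rng = np.random.default_rng(cfg.seed)
    y = _labels(cfg)
    n = len(y)
    # deal samples of each class round-robin across studies
    study = np.empty(n, dtype=object)
    for cls in [f"C{k + 1}" for k in range(cfg.k)]:
        idx = np.where(y == cls)[0]
        for i, s in enumerate(idx):
            study[s] = f"study{i % cfg.n_studies + 1}"
    study = study.astype(str)

    x = _noise(rng, (n, p), cfg.noise)
    feature_class = _plant_markers(x, y, cfg, min(n_inf, p))

    for s in sorted(set(study)):
        rows = study == s
        offset = cfg.study_offset * rng.standard_normal(p)
        scale = np.exp(cfg.study_scale * rng.standard_normal(p))
        x[rows] = x[rows] * scale + offset

    block = OmicsBlock(x, name="X")
    truth = {"support": np.arange(min(n_inf, p)),
             "feature_class": feature_class, "effect": cfg.effect}
    return block, y, study, truth


def inject_missing(block: OmicsBlock, rate: float, seed: int = 0) -> OmicsBlock:
    """Mask a random ``rate`` fraction of cells as missing (NaN).

    Guarded so no row or column ends up entirely missing.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    out = block.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.values.shape) < rate
    for j in np.where(mask.all(axis=0))[0]:
        mask[rng.integers(out.n_samples), j] = False
    for i in np.where(mask.all(axis=1))[0]:
        mask[i, rng.integers(out.n_features)] = False
    out.values[mask] = np.nan
    return out


# Shapes mirroring the three case-study data sets commonly used to
# illustrate these methods: a 63x2308 4-class microarray panel, a
# 150-sample 3-block cancer multi-omics set, and a 125x400 4-study
# stem-cell compendium.
PRESETS = {
    "srbct-like": SimConfig(n_per_class=(8, 23, 12, 20), p=2308, k=4,
                            n_informative=60, effect=1.5),
    "tcga-like": SimConfig(n_per_class=(45, 30, 75), p=(200, 184, 142), k=3,
                           n_informative=(20, 20, 15), effect=1.5,
                           factor_strength=0.8),
    "stemcells-like": SimConfig(n_per_class=(30, 37, 58), p=400, k=3,
                                n_informative=30, effect=1.5, n_studies=4,
                                study_offset=2.0, study_scale=0.2),
}


def preset(name: str, seed: int = 0, **overrides) -> SimConfig:
    """A named preset configuration with an optional seed/field override."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed, **overrides)
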