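"""The full parameter-tuning workflow for a sparse discriminant model.

Cross-validation folds, a keepX grid tuned one component at a time with
the balanced error rate, the t-test-based choice of the number of
components, and the final performance/stability report.
"""

import warnings

import numpy as np

from omicspls import SimConfig, gen_single, make_folds, perf, tune_keepx

# sparse refits on tiny CV folds occasionally stop at the iteration cap;
# harmless here, so keep the output readable
warnings.filterwarnings("ignore", message="component did not converge")

block, y, truth = gen_single(SimConfig(
    n_per_class=20, p=500, k=3, n_informative=20, effect=1.5, seed=6))
plan = make_folds(y, nfolds=5, nrepeats=10, seed=6)
print(f"tuning on {block.n_samples} x {block.n_features}, "
      f"5-fold CV x {plan.nrepeats} repeats")

result = tune_keepx("splsda", block.values, y, [10, 20, 30, 40, 50],
                    plan, ncomp=2, measure="ber", distance="centroid")
for h, surf in result.error_surface.items():
    errs = ", ".join(f"{c[0]}:{e:.3f}"
                     for c, e in zip(surf["candidates"], surf["mean"]))
    print(f"  component {h} BER by keepX -> {errs}")
print("chosen keepX per component:", result.chosen_keepX[0])
print("chosen number of components (paired t-tests):", result.chosen_ncomp)

rep = perf("splsda", block.values, y,
           make_folds(y, nfolds=5, nrepeats=5, seed=7),
           ncomp=2, keepX=result.chosen_keepX[0])
print(f"final model BER (centroid distance): "
      f"{rep.error('centroid', 'ber'):.3f}")
freqs = rep.stability[0][1]
info = np.mean([freqs.get(block.feature_ids[j], 0.0)
                for j in truth["support"]])
noise = np.mean([freqs.get(f, 0.0)
                 for i, f in enumerate(block.feature_ids) if i >= 20])
print(f"mean selection frequency: planted markers {info:.2f} "
      f"vs noise features {noise:.3f}")
# stable markers (frequency near 1) are the reproducible signature
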