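"""Predicting LV length from mask shape features with the voting ensemble.

Rasterises 300 ellipses of varying size and orientation, extracts the
shape features (area, principal-axis height, five-level width profile),
and fits the four-member voting ensemble (Extra Trees, AdaBoost, Lasso,
Ridge/KNN/GBDT stack).  Cross-validated R^2 and a one-way ANOVA against
a plain linear fit and a mean-only baseline show what the ensemble adds.
"""

import numpy as np

from echolvef import LVShapeSpec, render_masks
from echolvef.geometry import extract_features
from echolvef.length import EnsembleSpec, LengthTrainingSet, compare_models, crossval_r2

rng = np.random.default_rng(0)
rows = []
for _ in range(300):
    L = rng.uniform(50, 90)
    D = rng.uniform(0.4, 0.6) * L
    spec = LVShapeSpec(long_axis_ed=L, short_axis_ed=D, per_cycle_ef=(55.0,),
                       orientation=rng.uniform(0, np.pi))
    mask, _ = render_masks(np.array([L]), np.array([D]), spec)
    feats = extract_features(mask[0])
    rows.append((feats, feats.height + rng.normal(0, 1.0)))  # 1 px label noise
data = LengthTrainingSet(rows=rows, provenance="synthetic ellipses")

scores = crossval_r2(data, EnsembleSpec(seed=0), k=5, seed=0)
print("ensemble 5-fold R^2 :", [f"{s:.3f}" for s in scores])

from sklearn.dummy import DummyRegressor
from sklearn.linear_model import LinearRegression

cmp = compare_models(
    data,
    {"voting_ensemble": EnsembleSpec(seed=0),
     "linear": LinearRegression,
     "mean_baseline": DummyRegressor},
    k=5, seed=0,
)
for name, s in cmp["scores"].items():
    print(f"{name:16s} mean R^2 {np.mean(s):+.3f}")
print(f"ANOVA across models: F = {cmp['anova_f']:.1f}, p = {cmp['anova_p']:.3g}")
# A small p confirms the per-fold scores differ systematically between models.
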