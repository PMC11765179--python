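"""Train and compare the three ln-viscosity surrogates.

Features are (shear rate, A, G, T); targets are ln of viscosity in
mPa.s.  The comparison uses repeated random 80/20 holdout (reduced to 20
iterations here for speed; the full protocol uses 100).
"""

from bioinkflow import datasets
from bioinkflow.surrogates import (
    fit_forest,
    log_target,
    make_surrogate_factory,
    repeated_holdout,
    select_depth_cv,
    select_order_aic,
)

dataset = datasets.generate_dataset(noise_sigma=0.05, seed=42)
X, y = log_target(dataset)

# model-selection helpers
degree, aic = select_order_aic(X, y, (1, 2, 3, 4))
print(f"AIC-selected polynomial degree: {degree}")
depth, _ = select_depth_cv(X, y, depths=range(1, 16), seed=0)
print(f"CV-selected tree depth: {depth}")

# repeated-holdout comparison
for kind, kwargs in (("poly", {"degree": 4}), ("tree", {}), ("forest", {"n_trees": 200})):
    rep = repeated_holdout(
        X, y, make_surrogate_factory(kind, **kwargs), iterations=20, seed=0
    )
    print(f"{kind:<8} mean R2 = {rep.r2:.4f}  mean MAE = {rep.mae:.4f} "
          f"({rep.n_train}/{rep.n_test} split)")

# feature importances from a forest trained on everything
forest = fit_forest(X, y, seed=7)
print("forest importance ranking:", forest.importance_ranking())
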