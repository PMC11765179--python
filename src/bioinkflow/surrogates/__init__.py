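"""Viscosity surrogates: polynomial response surface, regression tree, random forest.

All three predict ln-viscosity (mPa·s) from (shear rate, alginate,
gelatin, TO-NFC) through a uniform ``model.predict(X)`` contract.
"""

from .evaluation import EvalReport, evaluate, make_surrogate_factory, repeated_holdout
from .features import FEATURE_NAMES, N_FEATURES, log_target, multi_indices, poly_expand
from .forest import RandomForestModel, fit_forest
from .polynomial import (
    PolynomialModel,
    RankDeficientDesignError,
    fit_polynomial,
    select_order_aic,
)
from .tree import RegressionTree, fit_tree, select_depth_cv

__all__ = [
    "EvalReport",
    "FEATURE_NAMES",
    "N_FEATURES",
    "PolynomialModel",
    "RandomForestModel",
    "RankDeficientDesignError",
    "RegressionTree",
    "evaluate",
    "fit_forest",
    "fit_polynomial",
    "fit_tree",
    "log_target",
    "make_surrogate_factory",
    "multi_indices",
    "poly_expand",
    "repeated_holdout",
    "select_depth_cv",
    "select_order_aic",
]


def model_from_dict(d: dict):
    """Deserialize any surrogate model from its JSON dictionary."""
    kind = d.get("kind")
    if kind == "poly":
        return PolynomialModel.from_dict(d)
    if kind == "tree":
        return RegressionTree.from_dict(d)
    if kind == "forest":
        return RandomForestModel.from_dict(d)
    raise ValueError(f"unknown model kind {kind!r}")
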