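"""Time-to-event regressors behind one risk-orientation contract.

All four kinds produce a risk score that is *higher for earlier predicted
progression*, and all four are affine in the input features, so exact
linear SHAP attributions apply. Solvers come from scikit-survival; the
contract (orientation, per-feature weights, convergence errors) is this
module's.

Implementation notes pinned by inspection of scikit-survival:
``FastSurvivalSVM.coef_`` is sign-flipped relative to its risk
predictions (``predict == -X @ coef_``), and the componentwise gradient
boosting ``coef_`` carries the intercept in position 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sksurv.ensemble import ComponentwiseGradientBoostingSurvivalAnalysis
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.svm import FastSurvivalSVM

from .cohort import as_structured

__all__ = ["RegressorKind", "FittedRegressor", "fit_regressor",
           "ConvergenceError", "DEFAULT_HYPERPARAMS", "SEARCH_SPACES"]


class RegressorKind(str, enum.Enum):
    COXPH = "coxph"
    COXNET = "coxnet"
    SVM = "svm"
    GB_LINEAR = "gb_linear"


#: fixed default hyperparameters (config defaults, overridable)
DEFAULT_HYPERPARAMS: dict[RegressorKind, dict] = {
    RegressorKind.COXPH: {"alpha": 1e-5},
    RegressorKind.COXNET: {"l1_ratio": 0.5},
    RegressorKind.SVM: {"alpha": 1.0},
    RegressorKind.GB_LINEAR: {"n_estimators": 100, "learning_rate": 0.1},
}

#: Bayesian-search spaces per regressor: name -> (low, high, scale) or a list
SEARCH_SPACES: dict[RegressorKind, dict] = {
    RegressorKind.COXPH: {"alpha": (1e-6, 1.0, "log")},
    RegressorKind.COXNET: {"l1_ratio": (0.05, 0.95, "linear"), "alpha": (1e-3, 1.0, "log")},
    RegressorKind.SVM: {"alpha": (1e-3, 100.0, "log")},
    RegressorKind.GB_LINEAR: {
        "n_estimators": (25, 300, "int"),
        "learning_rate": (0.01, 0.5, "log"),
    },
}


class ConvergenceError(RuntimeError):
    """A regressor failed to converge; carries the model identifier."""

    def __init__(self, model_id: str, cause: Exception):
        super().__init__(f"{model_id}: {cause}")
        self.model_id = model_id


@dataclass
class FittedRegressor:
    """A fitted survival regressor with its risk-oriented linear weights."""

    kind: RegressorKind
    estimator: object
    feature_names: list[str]
    weights: np.ndarray  # risk = weights @ x + const

    def predict_risk(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = table[self.feature_names].to_numpy(float) if isinstance(table, pd.DataFrame) \
            else np.asarray(table, float)
        if not np.isfinite(x).all():
            raise ValueError("risk prediction requires complete, finite inputs")
        return np.asarray(self.estimator.predict(x), dtype=float)


def fit_regressor(kind: RegressorKind | str, table: pd.DataFrame, outcomes: pd.DataFrame,
                  hyperparams: dict | None = None, seed: int = 0) -> FittedRegressor:
    """Fit one regressor kind on a (selected, standardized) training table."""
    kind = RegressorKind(kind)
    hp = dict(DEFAULT_HYPERPARAMS[kind])
    if hyperparams:
        hp.update(hyperparams)
    x = table.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("training table contains missing or non-finite values")
    y = as_structured(outcomes)
    if int(outcomes["event"].sum()) < 2:
        raise ValueError("need at least two events to fit a survival regressor")

    import contextlib
    import warnings

    @contextlib.contextmanager
    def _quiet_overflow():
        # near-separable small folds legitimately push the Cox linear
        # predictor into exp overflow; the fit itself remains usable
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="overflow encountered in exp")
            warnings.filterwarnings("ignore", message="divide by zero encountered in divide")
            yield

    model_id = f"{kind.value}({', '.join(f'{k}={v}' for k, v in sorted(hp.items()))})"
    try:
        if kind is RegressorKind.COXPH:
            with _quiet_overflow():
                est = CoxPHSurvivalAnalysis(alpha=hp["alpha"]).fit(x, y)
            weights = est.coef_.copy()
        elif kind is RegressorKind.COXNET:
            alpha = hp.get("alpha")
            if alpha is None:
                path = CoxnetSurvivalAnalysis(l1_ratio=hp["l1_ratio"]).fit(x, y)
                alpha = float(path.alphas_[len(path.alphas_) // 2])
            est = CoxnetSurvivalAnalysis(
                l1_ratio=hp["l1_ratio"], alphas=[alpha], fit_baseline_model=False
            ).fit(x, y)
            weights = est.coef_.ravel().copy()
        elif kind is RegressorKind.SVM:
            import warnings

            from sklearn.exceptions import ConvergenceWarning
            with warnings.catch_warnings():
                # at very small n the ranking objective can stop on precision
                # loss after reaching a usable optimum; the weights are still valid
                warnings.simplefilter("ignore", ConvergenceWarning)
                est = FastSurvivalSVM(alpha=hp["alpha"], max_iter=100,
                                      random_state=seed).fit(x, y)
            weights = -est.coef_.copy()  # predict == -X @ coef_
        elif kind is RegressorKind.GB_LINEAR:
            est = ComponentwiseGradientBoostingSurvivalAnalysis(
                n_estimators=int(hp["n_estimators"]),
                learning_rate=hp["learning_rate"],
                random_state=seed,
            ).fit(x, y)
            weights = np.asarray(est.coef_)[1:].copy()  # coef_[0] is the intercept
        else:  # pragma: no cover
            raise ValueError(kind)
    except (np.linalg.LinAlgError, ArithmeticError, ValueError) as exc:
        raise ConvergenceError(model_id, exc) from exc
    return FittedRegressor(kind, est, list(table.columns), weights)
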