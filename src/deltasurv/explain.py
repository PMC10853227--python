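"""Exact SHAP attributions for linear risk models.

All four regressor kinds in this package produce risk scores that are
affine in the (standardized, selected) features, for which the Shapley
values have the closed form

.. math:: \\phi_{ij} = w_j \\, (x_{ij} - \\bar{x}_j^{\\mathrm{bg}})

with the training fold as background. Local accuracy holds exactly:
per-row attributions sum to the prediction minus the mean background
prediction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import FittedPipeline

__all__ = ["linear_shap", "shap_for_pipeline", "aggregate_shap_importance"]


def linear_shap(weights, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """phi[i, j] = w_j * (x[i, j] - mean_j(background))."""
    w = np.asarray(weights, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    if x.shape[1] != len(w) or bg.shape[1] != len(w):
        raise ValueError("weights, rows and background must share the feature axis")
    return w[None, :] * (x - bg.mean(axis=0, keepdims=True))


def shap_for_pipeline(fitted: FittedPipeline, table: pd.DataFrame,
                      background: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-patient SHAP values of a fitted pipeline on (transformed) inputs.

    ``background`` defaults to ``table`` itself (the training fold in the
    intended use). Returned frame is patients x selected features.
    """
    medoids_only = fitted.spec.clustering is not None
    z = fitted.preprocess.transform(table, medoids_only=medoids_only)[fitted.selected_features]
    if background is None:
        zbg = z
    else:
        zbg = fitted.preprocess.transform(background, medoids_only=medoids_only)[fitted.selected_features]
    phi = linear_shap(fitted.regressor.weights, z.to_numpy(), zbg.to_numpy())
    return pd.DataFrame(phi, index=table.index, columns=fitted.selected_features)


def aggregate_shap_importance(shap_frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean |SHAP| per feature across folds/models -> ranked importance table."""
    if not shap_frames:
        raise ValueError("no SHAP frames to aggregate")
    totals: dict[str, list[float]] = {}
    for frame in shap_frames:
        for col in frame.columns:
            totals.setdefault(col, []).extend(np.abs(frame[col].to_numpy()))
    rows = [{"feature": f, "mean_abs_shap": float(np.mean(v)), "n_values": len(v)}
            for f, v in totals.items()]
    out = pd.DataFrame(rows).sort_values(["mean_abs_shap", "feature"],
                                         ascending=[False, True], ignore_index=True)
    return out
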