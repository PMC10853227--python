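"""Model/Results interface for one delta-radiomics survival pipeline.

:class:`DeltaSurvivalModel` is constructed from a feature table and
outcomes (or straight from a paired cohort via :meth:`from_cohort`) plus a
pipeline specification — preprocessing, feature selection, regressor.
``fit()`` returns a :class:`DeltaSurvivalResults` with the fitted chain
and in-sample diagnostics; ``fit_cv()`` returns
:class:`CrossValidationResults` with per-fold scores, bootstrap summaries
and the per-fold fitted transforms needed for robustness reporting.

Everything fitted — scaling statistics, consensus partition, medoids,
selected features, regressor weights — depends only on the training rows
handed to it; test rows are transformed with stored statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import PairedFeatureTable, validate_outcomes
from .evaluation import CVRun, CVScheme, bootstrap_summary, concordance_index, run_repeated_cv
from .feature_sets import FeatureSetKind, build_feature_set, split_sources
from .preprocessing import ClusteringConfig, PreprocessModel, fit_preprocessing, fit_scaling
from .regressors import FittedRegressor, RegressorKind, fit_regressor
from .selection import SelectorKind, select_features

__all__ = ["PipelineSpec", "FittedPipeline", "fit_pipeline", "DeltaSurvivalModel",
           "DeltaSurvivalResults", "CrossValidationResults"]


@dataclass(frozen=True)
class PipelineSpec:
    """What one pipeline does, independent of the data it meets.

    ``clustering=None`` skips consensus clustering (scale-only
    preprocessing); ``selector=None`` uses every available feature.
    """

    selector: SelectorKind | None = SelectorKind.RFE
    regressor: RegressorKind = RegressorKind.SVM
    k: int = 1
    clustering: ClusteringConfig | None = ClusteringConfig()
    selector_n_boot: int = 500
    hyperparams: dict | None = None

    @property
    def label(self) -> str:
        sel = self.selector.value if self.selector else "all"
        return f"{self.regressor.value}+{sel}(k={self.k})"


@dataclass
class FittedPipeline:
    """Train-fold-fitted chain: transforms -> selected features -> regressor."""

    spec: PipelineSpec
    preprocess: PreprocessModel
    selected_features: list[str]
    regressor: FittedRegressor

    def predict_risk(self, table: pd.DataFrame) -> np.ndarray:
        """Risk scores (higher = earlier predicted progression) for any table."""
        z = self.preprocess.transform(table, medoids_only=self.spec.clustering is not None)
        return self.regressor.predict_risk(z[self.selected_features])


def fit_pipeline(spec: PipelineSpec, features: pd.DataFrame, outcomes: pd.DataFrame,
                 seed: int = 0) -> FittedPipeline:
    """Fit the full chain on a training table."""
    rng = np.random.default_rng(seed)
    s_cluster, s_select, s_fit = (int(rng.integers(0, 2**31 - 1)) for _ in range(3))
    if spec.clustering is not None:
        pre = fit_preprocessing(features, spec.clustering, seed=s_cluster)
        z = pre.transform(features)
    else:
        pre = fit_scaling(features)
        z = pre.transform(features, medoids_only=False)
    if spec.selector is not None:
        selected = select_features(
            spec.selector, z, outcomes, spec.k, regressor=spec.regressor,
            n_boot=spec.selector_n_boot, seed=s_select, hyperparams=spec.hyperparams,
        )
    else:
        selected = list(z.columns)
    reg = fit_regressor(spec.regressor, z[selected], outcomes,
                        hyperparams=spec.hyperparams, seed=s_fit)
    return FittedPipeline(spec, pre, selected, reg)


class DeltaSurvivalModel:
    """A delta-radiomics survival pipeline bound to a cohort.

    Parameters
    ----------
    features : DataFrame
        One row per patient (any of the five feature-set kinds).
    outcomes : DataFrame
        ``pfs_months`` / ``event`` per patient, same index.
    spec : PipelineSpec, optional
        The pipeline definition; keyword shortcuts override its fields.
    """

    def __init__(self, features: pd.DataFrame, outcomes: pd.DataFrame,
                 spec: PipelineSpec | None = None, *, seed: int = 0, **overrides):
        outcomes = validate_outcomes(outcomes)
        if not features.index.equals(outcomes.index):
            outcomes = outcomes.loc[features.index]
        self.features = features
        self.outcomes = outcomes
        spec = spec or PipelineSpec()
        if overrides:
            if "selector" in overrides and overrides["selector"] is not None:
                overrides["selector"] = SelectorKind(overrides["selector"])
            if "regressor" in overrides:
                overrides["regressor"] = RegressorKind(overrides["regressor"])
            spec = replace(spec, **overrides)
        self.spec = spec
        self.seed = seed

    @classmethod
    def from_cohort(cls, paired: PairedFeatureTable, outcomes: pd.DataFrame,
                    kind: FeatureSetKind | str = FeatureSetKind.DELTA_ABS,
                    source: str = "radiomics", **kwargs) -> "DeltaSurvivalModel":
        """Build the model from a paired table, a feature-set kind and a source."""
        table = build_feature_set(paired, kind)
        radiomics, conventional = split_sources(table)
        if source == "radiomics":
            table = radiomics
        elif source == "conventional":
            table = conventional
        elif source != "all":
            raise ValueError("source must be 'radiomics', 'conventional' or 'all'")
        return cls(table, outcomes, **kwargs)

    def fit(self) -> "DeltaSurvivalResults":
        fitted = fit_pipeline(self.spec, self.features, self.outcomes, seed=self.seed)
        return DeltaSurvivalResults(self, fitted)

    def fit_cv(self, scheme: CVScheme | None = None, compute_iauc: bool = True,
               keep_models: bool = True) -> "CrossValidationResults":
        scheme = scheme or CVScheme(seed=self.seed)

        def fit_fn(xtr, otr, seed):
            return fit_pipeline(self.spec, xtr, otr, seed=seed)

        run = run_repeated_cv(fit_fn, self.features, self.outcomes, scheme,
                              compute_iauc=compute_iauc, keep_models=keep_models)
        return CrossValidationResults(self, scheme, run)


class DeltaSurvivalResults:
    """Results of fitting one pipeline on the full cohort."""

    def __init__(self, model: DeltaSurvivalModel, fitted: FittedPipeline):
        self.model = model
        self.fitted = fitted

    @property
    def selected_features(self) -> list[str]:
        return self.fitted.selected_features

    @property
    def params(self) -> pd.Series:
        """Risk-oriented linear weights of the fitted regressor."""
        return pd.Series(self.fitted.regressor.weights, index=self.selected_features,
                         name="risk_weight")

    def predict_risk(self, table: pd.DataFrame | None = None) -> np.ndarray:
        return self.fitted.predict_risk(self.model.features if table is None else table)

    @property
    def cindex_train(self) -> float:
        out = self.model.outcomes
        return concordance_index(out["pfs_months"], out["event"], self.predict_risk())

    def summary(self) -> str:
        lines = [
            "Delta-radiomics survival pipeline",
            f"  pipeline:          {self.fitted.spec.label}",
            f"  patients / events: {len(self.model.outcomes)} / {int(self.model.outcomes['event'].sum())}",
            f"  input features:    {self.model.features.shape[1]}",
        ]
        if self.fitted.spec.clustering is not None:
            pre = self.fitted.preprocess
            lines.append(f"  clusters (medoids): {len(pre.medoids)}")
        lines.append(f"  selected features: {', '.join(self.selected_features)}")
        lines.append(f"  training C-index:  {self.cindex_train:.3f}")
        lines.append("  risk weights:")
        for name, w in self.params.items():
            lines.append(f"    {name:<40s} {w:+.4f}")
        return "\n".join(lines)


class CrossValidationResults:
    """Per-fold scores of a repeated-CV evaluation plus bootstrap summaries."""

    def __init__(self, model: DeltaSurvivalModel, scheme: CVScheme, run: CVRun):
        self.model = model
        self.scheme = scheme
        self.run = run

    @property
    def scores(self) -> pd.DataFrame:
        return self.run.scores

    @property
    def models(self) -> list:
        return self.run.models

    def summarize(self, metric: str = "cindex_test", n_boot: int = 1000, seed: int = 0):
        return bootstrap_summary(self.scores[metric], n_boot=n_boot, seed=seed)

    def summary(self, n_boot: int = 1000, seed: int = 0) -> str:
        parts = [
            "Repeated cross-validation",
            f"  pipeline:  {self.model.spec.label}",
            f"  scheme:    {self.scheme.n_folds}-fold x {self.scheme.n_repeats} repeats"
            f" ({len(self.scores)} evaluated folds)",
        ]
        for metric in [c for c in ("cindex_train", "cindex_test", "iauc_train", "iauc_test")
                       if c in self.scores.columns]:
            s = bootstrap_summary(self.scores[metric], n_boot=n_boot, seed=seed)
            parts.append(f"  {metric:<13s} {s}")
        return "\n".join(parts)
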