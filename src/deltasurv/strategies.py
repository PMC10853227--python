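"""Study orchestration: default and fine-tuned strategies, baselines, SHAP.

The *default* strategy applies the full pipeline directly to the paired
cohort: every combination of feature-set kind, source, selection method,
regressor and number of selected features (k in {1,2,3}) is evaluated
under repeated stratified cross-validation with fixed hyperparameters,
and delta-vs-single-time-point and radiomics-vs-conventional one-sided
comparisons are Benjamini–Hochberg corrected across the family.

The *fine-tuned* strategy is two-staged: hyperparameters and informative
single-time-point features are learned on the larger single-scan cohort
(Gaussian-process Bayesian search; SHAP feature ranking across folds) and
transferred to the paired cohort, where the delta feature sets of the
top-1/2/3 named features are evaluated.

Within one training fold the expensive pieces are shared: preprocessing
(consensus clustering) is fitted once per feature table, and the filter
selections once per selector, across all regressors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .cohort import PairedFeatureTable, validate_outcomes
from .evaluation import (CVScheme, ComparisonResult, bh_adjust, bootstrap_summary,
                         compare_models, concordance_index, integrated_auc,
                         split_quietly)
from .explain import aggregate_shap_importance, shap_for_pipeline
from .feature_sets import FEATURE_SET_LABELS, FeatureSetKind, build_feature_set, split_sources
from .model import DeltaSurvivalModel, FittedPipeline, PipelineSpec
from .optimize import OptimizationResult, bayesian_optimize
from .preprocessing import ClusteringConfig, fit_preprocessing
from .regressors import DEFAULT_HYPERPARAMS, SEARCH_SPACES, RegressorKind, fit_regressor
from .robustness import RobustnessReport, robustness_report
from .selection import (SelectorKind, rank_by_mutual_info, rank_by_univariate_cindex,
                        rfe_elimination_order, select_by_lasso_cox)

__all__ = [
    "StrategyConfig",
    "DefaultStrategyResults",
    "run_default_strategy",
    "run_baseline",
    "FineTunedConfig",
    "FineTunedResults",
    "run_fine_tuned_strategy",
    "shap_rank",
]

log = logging.getLogger(__name__)

ALL_SELECTORS = (SelectorKind.UNIVARIATE_CINDEX, SelectorKind.MUTUAL_INFO,
                 SelectorKind.LASSO_COX, SelectorKind.RFE)
ALL_REGRESSORS = (RegressorKind.COXPH, RegressorKind.COXNET,
                  RegressorKind.SVM, RegressorKind.GB_LINEAR)
ALL_KINDS = tuple(FeatureSetKind)


@dataclass(frozen=True)
class StrategyConfig:
    """Grid and evaluation settings for the default strategy."""

    kinds: tuple = ALL_KINDS
    sources: tuple = ("radiomics", "conventional")
    selectors: tuple = ALL_SELECTORS
    regressors: tuple = ALL_REGRESSORS
    k_values: tuple = (1, 2, 3)
    scheme: CVScheme = CVScheme(n_folds=4, n_repeats=25)
    clustering: ClusteringConfig = ClusteringConfig()
    selector_n_boot: int = 500
    n_boot_summary: int = 1000
    compute_iauc: bool = True
    keep_preprocess_models: bool = True
    seed: int = 0

    def cells(self):
        """The full model grid, enumerated deterministically."""
        for kind in self.kinds:
            for source in self.sources:
                for sel in self.selectors:
                    for reg in self.regressors:
                        for k in self.k_values:
                            yield (FeatureSetKind(kind), source, SelectorKind(sel),
                                   RegressorKind(reg), k)


def _fold_splits(features: pd.DataFrame, events: np.ndarray, scheme: CVScheme):
    """Deterministic (repeat, fold, train_idx, test_idx) tuples."""
    rng = np.random.default_rng(scheme.seed)
    for repeat in range(scheme.n_repeats):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        if scheme.stratify_by_event:
            splitter = StratifiedKFold(scheme.n_folds, shuffle=True, random_state=fold_seed)
            splits = split_quietly(splitter, features, events)
        else:
            splitter = KFold(scheme.n_folds, shuffle=True, random_state=fold_seed)
            splits = split_quietly(splitter, features)
        for fold, (tr, te) in enumerate(splits):
            yield repeat, fold, tr, te


@dataclass
class DefaultStrategyResults:
    """Tidy per-fold scores, summaries, comparisons, robustness inputs."""

    scores: pd.DataFrame
    comparisons: pd.DataFrame
    preprocess_models: dict = field(default_factory=dict)  # (kind, source) -> [PreprocessModel]
    selected_features: pd.DataFrame | None = None
    fold_errors: list = field(default_factory=list)
    config: StrategyConfig | None = None

    _CELL = ["kind", "source", "selector", "regressor", "k"]

    def cell_scores(self, kind, source, selector, regressor, k) -> pd.DataFrame:
        s = self.scores
        return s[(s["kind"] == FeatureSetKind(kind).value) & (s["source"] == source)
                 & (s["selector"] == SelectorKind(selector).value)
                 & (s["regressor"] == RegressorKind(regressor).value) & (s["k"] == k)]

    def summaries(self, metric: str = "cindex_test", n_boot: int = 1000,
                  seed: int = 0) -> pd.DataFrame:
        rows = []
        for cell, grp in self.scores.groupby(self._CELL, sort=True):
            s = bootstrap_summary(grp[metric], n_boot=n_boot, seed=seed)
            rows.append(dict(zip(self._CELL, cell),
                             mean=s.mean, se=s.se, ci_low=s.ci_low, ci_high=s.ci_high,
                             n_folds=s.n_scores))
        return pd.DataFrame(rows)

    def heatmap_frame(self, kind, source="radiomics", k=1,
                      metric: str = "cindex_test") -> pd.DataFrame:
        """Selector x regressor grid of mean test performance (one kind, one k)."""
        s = self.scores
        sub = s[(s["kind"] == FeatureSetKind(kind).value) & (s["source"] == source)
                & (s["k"] == k)]
        return sub.pivot_table(index="regressor", columns="selector", values=metric,
                               aggfunc="mean")

    def robustness(self, kind, source="radiomics") -> RobustnessReport:
        key = (FeatureSetKind(kind).value, source)
        if key not in self.preprocess_models:
            raise KeyError(f"no stored preprocessing fits for {key}")
        return robustness_report(self.preprocess_models[key])


def run_default_strategy(paired: PairedFeatureTable, outcomes: pd.DataFrame,
                         config: StrategyConfig = StrategyConfig()) -> DefaultStrategyResults:
    """Evaluate the full model grid on the paired cohort with fixed HPs.

    Per training fold, preprocessing is fitted once per feature table and
    filter/LASSO selections once per selector; RFE is refitted per
    regressor. Fold-level errors are recorded, never silently dropped.
    """
    outcomes = validate_outcomes(outcomes).loc[paired.patients]
    events = outcomes["event"].to_numpy()
    scheme = replace(config.scheme, seed=config.seed)

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for kind in config.kinds:
        kind = FeatureSetKind(kind)
        full = build_feature_set(paired, kind)
        radiomics, conventional = split_sources(full)
        for source in config.sources:
            tab = radiomics if source == "radiomics" else conventional
            if tab.shape[1] == 0:
                log.warning("skipping empty table %s/%s", kind.value, source)
                continue
            tables[(kind.value, source)] = tab

    rows: list[dict] = []
    errors: list[dict] = []
    selected_rows: list[dict] = []
    pre_models: dict[tuple[str, str], list] = {k: [] for k in tables}

    any_table = next(iter(tables.values()))
    for repeat, fold, tr, te in _fold_splits(any_table, events, scheme):
        if events[te].sum() == 0:
            errors.append({"repeat": repeat, "fold": fold, "error": "no test events"})
            continue
        otr, ote = outcomes.iloc[tr], outcomes.iloc[te]
        for t_idx, ((kind, source), table) in enumerate(tables.items()):
            xtr, xte = table.iloc[tr], table.iloc[te]
            seed_seq = [config.seed, t_idx, repeat, fold]
            rng = np.random.default_rng(seed_seq)
            try:
                pre = fit_preprocessing(xtr, config.clustering,
                                        seed=int(rng.integers(0, 2**31 - 1)))
            except ValueError as exc:
                errors.append({"repeat": repeat, "fold": fold, "kind": kind,
                               "source": source, "error": str(exc)})
                continue
            if config.keep_preprocess_models:
                pre_models[(kind, source)].append(pre)
            ztr = pre.transform(xtr)
            zte = pre.transform(xte)
            sel_seed = int(rng.integers(0, 2**31 - 1))
            fit_seed = int(rng.integers(0, 2**31 - 1))

            # selections shared across regressors where possible
            rankings: dict[SelectorKind, pd.DataFrame] = {}
            for sel in config.selectors:
                sel = SelectorKind(sel)
                if sel is SelectorKind.UNIVARIATE_CINDEX:
                    rankings[sel] = rank_by_univariate_cindex(
                        ztr, otr, n_boot=config.selector_n_boot, seed=sel_seed)
                elif sel is SelectorKind.MUTUAL_INFO:
                    rankings[sel] = rank_by_mutual_info(
                        ztr, otr, n_boot=config.selector_n_boot, seed=sel_seed)

            for sel in config.selectors:
                sel = SelectorKind(sel)
                for reg in config.regressors:
                    reg = RegressorKind(reg)
                    try:
                        if sel in rankings:
                            ordered = rankings[sel]["feature"].tolist()
                            feats_by_k = {k: ordered[:k] for k in config.k_values}
                        elif sel is SelectorKind.LASSO_COX:
                            feats_by_k = {k: select_by_lasso_cox(ztr, otr, k)
                                          for k in config.k_values}
                        else:  # RFE: one elimination order per regressor
                            order = rfe_elimination_order(ztr, otr, reg, seed=fit_seed)
                            feats_by_k = {
                                k: [f for f in ztr.columns if f in set(order[-k:])]
                                if k < len(order) else list(ztr.columns)
                                for k in config.k_values
                            }
                        for k in config.k_values:
                            feats = feats_by_k[k]
                            if not feats:
                                raise ValueError("selection returned no features")
                            fitted = fit_regressor(reg, ztr[feats], otr, seed=fit_seed)
                            risk_tr = fitted.predict_risk(ztr[feats])
                            risk_te = fitted.predict_risk(zte[feats])
                            row = {
                                "kind": kind, "source": source, "selector": sel.value,
                                "regressor": reg.value, "k": k,
                                "repeat": repeat, "fold": fold,
                                "cindex_train": concordance_index(
                                    otr["pfs_months"], otr["event"], risk_tr),
                                "cindex_test": concordance_index(
                                    ote["pfs_months"], ote["event"], risk_te),
                            }
                            if config.compute_iauc:
                                import warnings as _w
                                with _w.catch_warnings():
                                    _w.simplefilter("ignore")
                                    row["iauc_test"] = integrated_auc(otr, ote, risk_te)
                            rows.append(row)
                            selected_rows.append({
                                "kind": kind, "source": source, "selector": sel.value,
                                "regressor": reg.value, "k": k, "repeat": repeat,
                                "fold": fold, "features": tuple(feats),
                            })
                    except Exception as exc:  # recorded per cell, never dropped
                        errors.append({"repeat": repeat, "fold": fold, "kind": kind,
                                       "source": source, "selector": sel.value,
                                       "regressor": reg.value, "error": str(exc)})

    scores = pd.DataFrame(rows)
    comparisons = _default_comparisons(scores, config)
    return DefaultStrategyResults(
        scores=scores,
        comparisons=comparisons,
        preprocess_models=pre_models,
        selected_features=pd.DataFrame(selected_rows),
        fold_errors=errors,
        config=config,
    )


def _scores_of(scores: pd.DataFrame, kind: FeatureSetKind, source, sel, reg, k):
    s = scores[(scores["kind"] == kind.value) & (scores["source"] == source)
               & (scores["selector"] == sel.value) & (scores["regressor"] == reg.value)
               & (scores["k"] == k)]
    return s["cindex_test"].to_numpy()


def _default_comparisons(scores: pd.DataFrame, config: StrategyConfig) -> pd.DataFrame:
    """Delta-vs-STP and radiomics-vs-conventional one-sided tests, BH-corrected."""
    if scores.empty:
        return pd.DataFrame(columns=["label", "u_statistic", "p_value", "p_adjusted"])
    results: list[ComparisonResult] = []
    kinds = [FeatureSetKind(k) for k in config.kinds]
    delta_kinds = [k for k in kinds if k.is_delta]
    has_stp = FeatureSetKind.STP in kinds
    for sel in config.selectors:
        sel = SelectorKind(sel)
        for reg in config.regressors:
            reg = RegressorKind(reg)
            for k in config.k_values:
                for dk in delta_kinds:
                    a = _scores_of(scores, dk, "radiomics", sel, reg, k)
                    if len(a) == 0:
                        continue
                    lbl = f"{FEATURE_SET_LABELS[dk]}R>{{}} [{reg.value}+{sel.value}, k={k}]"
                    if has_stp:
                        b = _scores_of(scores, FeatureSetKind.STP, "radiomics", sel, reg, k)
                        if len(b):
                            results.append(compare_models(a, b, lbl.format("STPR")))
                    if "conventional" in config.sources:
                        b = _scores_of(scores, dk, "conventional", sel, reg, k)
                        if len(b):
                            results.append(compare_models(
                                a, b, lbl.format(FEATURE_SET_LABELS[dk] + "C")))
    if not results:
        return pd.DataFrame(columns=["label", "u_statistic", "p_value", "p_adjusted"])
    frame = pd.DataFrame({
        "label": [r.label for r in results],
        "u_statistic": [r.u_statistic for r in results],
        "p_value": [r.p_value for r in results],
        "degenerate": [r.degenerate for r in results],
    })
    frame["p_adjusted"] = bh_adjust(frame["p_value"].to_numpy())
    return frame


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def run_baseline(paired: PairedFeatureTable, outcomes: pd.DataFrame,
                 scheme: CVScheme = CVScheme(n_folds=4, n_repeats=25),
                 kind: FeatureSetKind | str = FeatureSetKind.STP,
                 seed: int = 0) -> dict:
    """Baseline CoxPH models: all conventional features, and univariate deltas.

    Returns CV results for the multivariable conventional-feature CoxPH of
    ``kind`` plus the four univariate models (delta-absolute and relative
    changes of TBR_max and TBR_mean).
    """
    full = build_feature_set(paired, FeatureSetKind(kind))
    _, conventional = split_sources(full)
    if conventional.shape[1] == 0:
        raise ValueError("paired table has no conventional (conv_*) columns")
    spec = PipelineSpec(selector=None, clustering=None, regressor=RegressorKind.COXPH)
    out = {
        "baseline_conventional": DeltaSurvivalModel(
            conventional, outcomes, spec, seed=seed).fit_cv(replace(scheme, seed=seed))
    }
    for dkind, dlabel in ((FeatureSetKind.DELTA_ABS, "ΔA"), (FeatureSetKind.DELTA_REL, "ΔR")):
        table = build_feature_set(paired, dkind)
        for col, clabel in (("conv_TBR_max", "TBR_max"), ("conv_TBR_mean", "TBR_mean")):
            if col not in table.columns:
                raise ValueError(f"paired table lacks the {col} conventional feature")
            out[f"{dlabel}{clabel}"] = DeltaSurvivalModel(
                table[[col]], outcomes, spec, seed=seed).fit_cv(replace(scheme, seed=seed))
    return out


# ---------------------------------------------------------------------------
# SHAP ranking and the fine-tuned strategy
# ---------------------------------------------------------------------------


def shap_rank(fold_models: list[FittedPipeline], table: pd.DataFrame) -> pd.DataFrame:
    """Mean-|SHAP| feature ranking across fold-fitted pipelines.

    Each fold's pipeline attributes the risk of every cohort row; values
    are pooled per original feature name across folds.
    """
    frames = [shap_for_pipeline(m, table) for m in fold_models]
    return aggregate_shap_importance(frames)


@dataclass(frozen=True)
class FineTunedConfig:
    """Two-stage transfer setup."""

    selectors: tuple = ALL_SELECTORS
    regressors: tuple = ALL_REGRESSORS
    k_values: tuple = (1, 2, 3)
    kinds: tuple = ALL_KINDS
    stage1_scheme: CVScheme = CVScheme(n_folds=7, n_repeats=20)
    stage2_scheme: CVScheme = CVScheme(n_folds=4, n_repeats=25)
    stage1_k: int = 3           # selectors limited to at most 3 features
    n_bayes_iter: int = 100
    bayes_scheme: CVScheme | None = None  # objective CV; defaults to stage1_scheme
    clustering: ClusteringConfig = ClusteringConfig()
    selector_n_boot: int = 500
    compute_iauc: bool = True
    seed: int = 0


@dataclass
class FineTunedResults:
    stage1: dict          # (selector, regressor) -> {"hyperparams", "ranking", "cv", "optimization"}
    scores: pd.DataFrame  # stage-2 tidy per-fold scores
    comparisons: pd.DataFrame
    config: FineTunedConfig | None = None

    def summaries(self, metric: str = "cindex_test", n_boot: int = 1000,
                  seed: int = 0) -> pd.DataFrame:
        rows = []
        keys = ["kind", "selector", "regressor", "n_features"]
        for cell, grp in self.scores.groupby(keys, sort=True):
            s = bootstrap_summary(grp[metric], n_boot=n_boot, seed=seed)
            rows.append(dict(zip(keys, cell), mean=s.mean, se=s.se,
                             ci_low=s.ci_low, ci_high=s.ci_high))
        return pd.DataFrame(rows)


def _optimize_hyperparams(spec: PipelineSpec, features: pd.DataFrame,
                          outcomes: pd.DataFrame, scheme: CVScheme,
                          n_iter: int, seed: int) -> OptimizationResult:
    space = SEARCH_SPACES[spec.regressor]

    def objective(params: dict) -> float:
        model = DeltaSurvivalModel(features, outcomes, replace(spec, hyperparams=params),
                                   seed=seed)
        cv = model.fit_cv(replace(scheme, seed=seed), compute_iauc=False, keep_models=False)
        return float(cv.scores["cindex_test"].mean())

    return bayesian_optimize(objective, space, n_iter=n_iter, seed=seed)


def run_fine_tuned_strategy(single_features: pd.DataFrame, single_outcomes: pd.DataFrame,
                            paired: PairedFeatureTable, paired_outcomes: pd.DataFrame,
                            config: FineTunedConfig = FineTunedConfig()) -> FineTunedResults:
    """Stage 1 on the single-scan cohort, stage 2 transfer to the paired cohort.

    Stage 1 optimizes hyperparameters (GP Bayesian search maximizing the
    mean CV test C-index) and SHAP-ranks single-time-point features per
    model; stage 2 rebuilds every feature-set kind restricted to the
    top-1/2/3 stage-1 features and evaluates with the stage-1
    hyperparameters under repeated CV on the paired cohort.
    """
    shared = set(single_features.columns) & set(paired.features)
    if not shared:
        raise ValueError("single-scan and paired cohorts share no feature names")

    stage1: dict = {}
    rows: list[dict] = []
    for sel in config.selectors:
        sel = SelectorKind(sel)
        for reg in config.regressors:
            reg = RegressorKind(reg)
            spec = PipelineSpec(selector=sel, regressor=reg, k=config.stage1_k,
                                clustering=config.clustering,
                                selector_n_boot=config.selector_n_boot)
            if config.n_bayes_iter > 0:
                opt = _optimize_hyperparams(
                    spec, single_features, single_outcomes,
                    config.bayes_scheme or config.stage1_scheme,
                    config.n_bayes_iter, config.seed)
                hp = opt.best_params
            else:
                opt = None
                hp = dict(DEFAULT_HYPERPARAMS[reg])
            spec = replace(spec, hyperparams=hp)
            model = DeltaSurvivalModel(single_features, single_outcomes, spec,
                                       seed=config.seed)
            cv = model.fit_cv(replace(config.stage1_scheme, seed=config.seed),
                              compute_iauc=False)
            ranking = shap_rank(cv.models, single_features)
            stage1[(sel.value, reg.value)] = {
                "hyperparams": hp, "ranking": ranking, "cv": cv, "optimization": opt,
            }

            top = ranking["feature"].head(max(config.k_values)).tolist()
            missing = [f for f in top if f not in set(paired.features)]
            if missing:
                raise ValueError(
                    f"stage-1 top features absent from the paired cohort: {missing}")
            for kind in config.kinds:
                kind = FeatureSetKind(kind)
                table = build_feature_set(paired, kind)
                for m in config.k_values:
                    feats = [f for f in top[:m] if f in table.columns]
                    if not feats:
                        continue
                    spec2 = PipelineSpec(selector=None, clustering=None, regressor=reg,
                                         hyperparams=hp)
                    cv2 = DeltaSurvivalModel(table[feats], paired_outcomes, spec2,
                                             seed=config.seed).fit_cv(
                        replace(config.stage2_scheme, seed=config.seed),
                        compute_iauc=config.compute_iauc, keep_models=False)
                    for _, r in cv2.scores.iterrows():
                        rows.append({
                            "kind": kind.value, "selector": sel.value,
                            "regressor": reg.value, "n_features": m,
                            "repeat": int(r["repeat"]), "fold": int(r["fold"]),
                            "cindex_train": r["cindex_train"],
                            "cindex_test": r["cindex_test"],
                            **({"iauc_test": r["iauc_test"]} if "iauc_test" in r else {}),
                        })
    scores = pd.DataFrame(rows)
    comparisons = _fine_tuned_comparisons(scores, config)
    return FineTunedResults(stage1=stage1, scores=scores, comparisons=comparisons,
                            config=config)


def _fine_tuned_comparisons(scores: pd.DataFrame, config: FineTunedConfig) -> pd.DataFrame:
    if scores.empty:
        return pd.DataFrame(columns=["label", "u_statistic", "p_value", "p_adjusted"])
    results = []
    kinds = [FeatureSetKind(k) for k in config.kinds]
    delta_kinds = [k for k in kinds if k.is_delta]
    if FeatureSetKind.STP not in kinds:
        return pd.DataFrame(columns=["label", "u_statistic", "p_value", "p_adjusted"])
    for (sel, reg, m), grp in scores.groupby(["selector", "regressor", "n_features"]):
        stp = grp[grp["kind"] == FeatureSetKind.STP.value]["cindex_test"].to_numpy()
        if len(stp) == 0:
            continue
        for dk in delta_kinds:
            a = grp[grp["kind"] == dk.value]["cindex_test"].to_numpy()
            if len(a):
                results.append(compare_models(
                    a, stp, f"{FEATURE_SET_LABELS[dk]}R>STPR [{reg}+{sel}, m={m}]"))
    if not results:
        return pd.DataFrame(columns=["label", "u_statistic", "p_value", "p_adjusted"])
    frame = pd.DataFrame({
        "label": [r.label for r in results],
        "u_statistic": [r.u_statistic for r in results],
        "p_value": [r.p_value for r in results],
    })
    frame["p_adjusted"] = bh_adjust(frame["p_value"].to_numpy())
    return frame
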