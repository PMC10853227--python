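"""Feature-selection methods on the post-clustering (medoid) table.

The two filter methods (univariate C-index and mutual information) are
stabilized over 500 patient bootstraps of the training fold: features are
ranked within each bootstrap and aggregated with a mean-reciprocal-rank
importance score. LASSO-Cox reads the L1 regularization path, and RFE
recursively drops the weakest-|weight| feature of the paired regressor.
"""

from __future__ import annotations

import enum
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.feature_selection import mutual_info_regression
from sksurv.linear_model import CoxnetSurvivalAnalysis

from .cohort import as_structured
from .regressors import RegressorKind, fit_regressor

__all__ = [
    "SelectorKind",
    "rank_by_univariate_cindex",
    "rank_by_mutual_info",
    "select_by_lasso_cox",
    "rfe_elimination_order",
    "select_by_rfe",
    "select_features",
]

log = logging.getLogger(__name__)


class SelectorKind(str, enum.Enum):
    UNIVARIATE_CINDEX = "cindex"
    MUTUAL_INFO = "mi"
    LASSO_COX = "lasso"
    RFE = "rfe"


def _aggregate_bootstrap_ranks(score_fn, table: pd.DataFrame, n_boot: int,
                               seed: int) -> pd.DataFrame:
    """Mean-reciprocal-rank importance over patient bootstraps.

    ``score_fn(x, rows)`` returns one score per feature (higher = better)
    for the bootstrap row index, or None to skip that bootstrap.
    """
    rng = np.random.default_rng(seed)
    x = table.to_numpy(float)
    n = len(table)
    importance = np.zeros(table.shape[1])
    used = 0
    for _ in range(n_boot):
        rows = rng.integers(0, n, size=n)
        scores = score_fn(x, rows)
        if scores is None:
            continue
        ranks = rankdata(-np.asarray(scores), method="average")
        importance += 1.0 / ranks
        used += 1
    if used == 0:
        raise ValueError("every bootstrap sample was degenerate; cannot rank features")
    importance /= used
    out = pd.DataFrame({"feature": table.columns, "importance": importance})
    return out.sort_values(["importance", "feature"], ascending=[False, True],
                           ignore_index=True)


def rank_by_univariate_cindex(table: pd.DataFrame, outcomes: pd.DataFrame,
                              n_boot: int = 500, seed: int = 0) -> pd.DataFrame:
    """Rank features by direction-invariant univariate concordance.

    Per bootstrap each feature is scored by ``max(C, 1-C)`` of the feature
    used as the sole risk score; bootstraps with fewer than two events or
    no comparable pair are skipped and logged.
    """
    t = outcomes["pfs_months"].to_numpy(float)
    e = outcomes["event"].to_numpy(int)

    def score(x, rows):
        tb, eb = t[rows], e[rows]
        if eb.sum() < 2:
            log.debug("bootstrap skipped: fewer than two events")
            return None
        comparable = (tb[:, None] < tb[None, :]) & (eb[:, None] == 1)
        n_comp = comparable.sum()
        if n_comp == 0:
            log.debug("bootstrap skipped: no comparable pair")
            return None
        xb = x[rows]
        scores = np.empty(x.shape[1])
        for j in range(x.shape[1]):
            r = xb[:, j]
            conc = comparable & (r[:, None] > r[None, :])
            tied = comparable & (r[:, None] == r[None, :])
            c = (conc.sum() + 0.5 * tied.sum()) / n_comp
            scores[j] = max(c, 1.0 - c)
        return scores

    return _aggregate_bootstrap_ranks(score, table, n_boot, seed)


def rank_by_mutual_info(table: pd.DataFrame, outcomes: pd.DataFrame,
                        n_boot: int = 500, seed: int = 0) -> pd.DataFrame:
    """Rank features by k-nearest-neighbour mutual information with event times.

    MI is estimated on the event cases of each bootstrap (k=3 neighbours);
    bootstraps with fewer than five events fall back to all cases with a
    warning.
    """
    t = outcomes["pfs_months"].to_numpy(float)
    e = outcomes["event"].to_numpy(int)
    rng = np.random.default_rng(seed ^ 0x5F5F5F)
    warned = [False]

    def score(x, rows):
        tb, eb, xb = t[rows], e[rows], x[rows]
        sel = eb == 1
        if sel.sum() < 5:
            if not warned[0]:
                warnings.warn("fewer than 5 events in bootstrap; MI computed on all cases",
                              stacklevel=4)
                warned[0] = True
            sel = np.ones(len(rows), dtype=bool)
        if sel.sum() < 4:  # kNN estimator needs n > k
            return None
        mi_seed = int(rng.integers(0, 2**31 - 1))
        return mutual_info_regression(xb[sel], tb[sel], n_neighbors=3,
                                      random_state=mi_seed)

    return _aggregate_bootstrap_ranks(score, table, n_boot, seed)


def select_by_lasso_cox(table: pd.DataFrame, outcomes: pd.DataFrame, k: int) -> list[str]:
    """Top-k features from the L1-penalized Cox regularization path.

    Uses the largest penalty yielding at least ``k`` nonzero coefficients;
    if the path never reaches ``k``, all nonzero features at the smallest
    penalty are returned (logged).
    """
    y = as_structured(outcomes)
    x = table.to_numpy(float)
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01).fit(x, y)
    coefs = path.coef_  # (p, n_alphas), alphas decreasing
    if k >= table.shape[1]:
        ever = (coefs != 0).any(axis=1)
        return [c for c, keep in zip(table.columns, ever) if keep]
    nnz = (coefs != 0).sum(axis=0)
    reach = np.flatnonzero(nnz >= k)
    col = reach[0] if len(reach) else coefs.shape[1] - 1
    if not len(reach):
        log.warning("LASSO path never reached %d nonzero coefficients; "
                    "returning the %d nonzero at the smallest penalty", k, nnz[col])
    w = np.abs(coefs[:, col])
    order = sorted(range(len(w)), key=lambda j: (-w[j], table.columns[j]))
    chosen = [table.columns[j] for j in order[:k] if w[j] > 0]
    return chosen


def rfe_elimination_order(table: pd.DataFrame, outcomes: pd.DataFrame,
                          regressor: RegressorKind | str,
                          hyperparams: dict | None = None, seed: int = 0) -> list[str]:
    """Full recursive-elimination order, weakest feature first.

    Refits the regressor on the surviving set and drops the
    smallest-|weight| feature (step 1) down to a single survivor. Selecting
    the last ``k`` entries therefore nests across ``k``.
    """
    current = list(table.columns)
    order: list[str] = []
    while len(current) > 1:
        fitted = fit_regressor(regressor, table[current], outcomes,
                               hyperparams=hyperparams, seed=seed)
        w = np.abs(fitted.weights)
        # ties: drop the lexicographically largest so small names survive
        drop_idx = min(range(len(current)), key=lambda j: (w[j], _neg_name(current[j])))
        order.append(current.pop(drop_idx))
    order.extend(current)
    return order


def select_by_rfe(table: pd.DataFrame, outcomes: pd.DataFrame,
                  regressor: RegressorKind | str, k: int,
                  hyperparams: dict | None = None, seed: int = 0) -> list[str]:
    """Recursive feature elimination with the paired linear regressor."""
    order = rfe_elimination_order(table, outcomes, regressor,
                                  hyperparams=hyperparams, seed=seed)
    if k >= len(order):
        return list(table.columns)
    keep = set(order[-k:])
    return [f for f in table.columns if f in keep]


class _neg_name(str):
    """Reverse lexicographic ordering helper for tie-breaking."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)


def select_features(kind: SelectorKind | str, table: pd.DataFrame, outcomes: pd.DataFrame,
                    k: int, regressor: RegressorKind | str | None = None,
                    n_boot: int = 500, seed: int = 0,
                    hyperparams: dict | None = None) -> list[str]:
    """Dispatch to one of the four selection methods; returns <= k feature names."""
    kind = SelectorKind(kind)
    if k < 1:
        raise ValueError("k must be at least 1")
    if k >= table.shape[1] and kind is not SelectorKind.LASSO_COX:
        return list(table.columns)
    if kind is SelectorKind.UNIVARIATE_CINDEX:
        ranking = rank_by_univariate_cindex(table, outcomes, n_boot=n_boot, seed=seed)
        return ranking["feature"].head(k).tolist()
    if kind is SelectorKind.MUTUAL_INFO:
        ranking = rank_by_mutual_info(table, outcomes, n_boot=n_boot, seed=seed)
        return ranking["feature"].head(k).tolist()
    if kind is SelectorKind.LASSO_COX:
        return select_by_lasso_cox(table, outcomes, k)
    if kind is SelectorKind.RFE:
        if regressor is None:
            raise ValueError("RFE requires the paired regressor kind")
        return select_by_rfe(table, outcomes, regressor, k,
                             hyperparams=hyperparams, seed=seed)
    raise ValueError(kind)  # pragma: no cover
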