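"""Train-fold-only transforms: scaling and bootstrap consensus clustering.

The preprocessing chain fitted on each training fold is

1. remove zero-variance features,
2. Z-score the rest (unbiased n-1 standard deviation),
3. cluster highly correlated features by agglomerative clustering on
   ``1 - |Spearman rho|`` (complete linkage, dendrogram cut so every
   within-cluster pair has ``|rho| >= 0.9``), stabilized by consensus over
   500 patient bootstraps through a co-association matrix thresholded at
   0.5 (average-linkage evidence accumulation),
4. keep one representative per cluster: the medoid, i.e. the member
   maximizing the summed absolute Spearman correlation to the other
   members on the full training fold.

Test rows never influence any fitted statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

__all__ = [
    "ClusteringConfig",
    "PreprocessModel",
    "spearman_abs_corr",
    "spearman_cluster",
    "consensus_cluster",
    "select_medoids",
    "fit_preprocessing",
]


@dataclass(frozen=True)
class ClusteringConfig:
    threshold: float = 0.9       # |Spearman| similarity cut for a cluster
    n_boot: int = 500            # patient bootstraps per training fold
    co_threshold: float = 0.5    # co-association cut for the final partition
    linkage: str = "complete"    # per-bootstrap linkage
    consensus_linkage: str = "average"


def spearman_abs_corr(x: np.ndarray) -> np.ndarray:
    """Absolute Spearman correlation matrix; constant columns correlate with nothing."""
    x = np.asarray(x, dtype=float)
    ranks = rankdata(x, axis=0)
    sd = ranks.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    if constant.any():
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.abs(corr)


def _cut(dist: np.ndarray, method: str, height: float) -> np.ndarray:
    """Agglomerate a square distance matrix and cut at ``height`` -> 0-based labels."""
    p = dist.shape[0]
    if p == 1:
        return np.zeros(1, dtype=int)
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    tree = linkage(condensed, method=method)
    return fcluster(tree, t=height, criterion="distance") - 1


def spearman_cluster(x: np.ndarray | pd.DataFrame, threshold: float = 0.9,
                     method: str = "complete") -> np.ndarray:
    """Cluster features at ``|Spearman| >= threshold``; returns 0-based labels.

    With complete linkage the cut guarantees every within-cluster pair
    meets the threshold.
    """
    arr = x.to_numpy() if isinstance(x, pd.DataFrame) else np.asarray(x)
    dist = 1.0 - spearman_abs_corr(arr)
    return _cut(dist, method, 1.0 - threshold)


def consensus_cluster(x: np.ndarray | pd.DataFrame, config: ClusteringConfig = ClusteringConfig(),
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap consensus partition and its co-association matrix.

    Each bootstrap resamples patients with replacement (same n), clusters
    the features, and votes into the co-association matrix; the final
    partition cuts the evidence-accumulation dendrogram at the
    co-association threshold. Deterministic per seed.
    """
    arr = x.to_numpy() if isinstance(x, pd.DataFrame) else np.asarray(x)
    n, p = arr.shape
    rng = np.random.default_rng(seed)
    coassoc = np.zeros((p, p), dtype=float)
    for _ in range(config.n_boot):
        idx = rng.integers(0, n, size=n)
        labels = spearman_cluster(arr[idx], config.threshold, config.linkage)
        coassoc += labels[:, None] == labels[None, :]
    coassoc /= config.n_boot
    np.fill_diagonal(coassoc, 1.0)
    final = _cut(1.0 - coassoc, config.consensus_linkage, 1.0 - config.co_threshold)
    return final, coassoc


def select_medoids(labels: np.ndarray, table: pd.DataFrame) -> list[str]:
    """Per-cluster medoid features, computed on the full training fold.

    The medoid maximizes the summed ``|Spearman|`` to the other cluster
    members; singletons are their own medoid; exact ties break to the
    lexicographically smallest feature name.
    """
    labels = np.asarray(labels)
    if len(labels) != table.shape[1]:
        raise ValueError("partition must cover exactly the table's features")
    corr = spearman_abs_corr(table.to_numpy())
    names = np.asarray(table.columns)
    medoids = []
    for cid in np.unique(labels):
        members = np.flatnonzero(labels == cid)
        if len(members) == 1:
            medoids.append(str(names[members[0]]))
            continue
        sub = corr[np.ix_(members, members)]
        scores = sub.sum(axis=1) - 1.0  # exclude self-correlation
        best = np.max(scores)
        tied = members[np.isclose(scores, best)]
        medoids.append(str(min(names[tied])))
    return sorted(medoids)


@dataclass
class PreprocessModel:
    """Fitted train-fold preprocessing: scaling statistics + consensus partition."""

    kept_features: list[str]
    means: pd.Series
    sds: pd.Series
    labels: np.ndarray = field(default=None)        # cluster id per kept feature
    medoids: list[str] = field(default_factory=list)
    coassoc: pd.DataFrame | None = None

    @property
    def partition(self) -> pd.Series:
        return pd.Series(self.labels, index=self.kept_features, name="cluster")

    def transform(self, table: pd.DataFrame, medoids_only: bool = True) -> pd.DataFrame:
        """Apply the stored train statistics to any table (train or test)."""
        cols = self.medoids if medoids_only else self.kept_features
        missing = set(cols) - set(table.columns)
        if missing:
            raise KeyError(f"table lacks fitted features: {sorted(missing)}")
        z = (table[cols] - self.means[cols]) / self.sds[cols]
        return z


def fit_scaling(train: pd.DataFrame) -> PreprocessModel:
    """Zero-variance removal + Z-score statistics from the training fold only.

    Statistics are computed from a contiguous copy of the training values,
    so bit-identical training rows give bit-identical statistics
    regardless of the parent frame's memory layout.
    """
    if train.shape[0] < 2:
        raise ValueError("need at least two training rows to fit scaling")
    arr = np.ascontiguousarray(train.to_numpy(dtype=float))
    sds = pd.Series(arr.std(axis=0, ddof=1), index=train.columns)
    kept = list(train.columns[sds > 0])
    if not kept:
        raise ValueError("all features have zero variance on this training fold")
    means = pd.Series(arr.mean(axis=0), index=train.columns)
    return PreprocessModel(
        kept_features=kept,
        means=means[kept],
        sds=sds[kept],
    )


def fit_preprocessing(train: pd.DataFrame, config: ClusteringConfig = ClusteringConfig(),
                      seed: int = 0) -> PreprocessModel:
    """Full preprocessing fit: scaling, consensus clustering, medoid extraction."""
    model = fit_scaling(train)
    kept = train[model.kept_features]
    labels, coassoc = consensus_cluster(kept, config, seed=seed)
    model.labels = labels
    model.coassoc = pd.DataFrame(coassoc, index=model.kept_features, columns=model.kept_features)
    model.medoids = select_medoids(labels, kept)
    return model
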