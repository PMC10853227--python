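"""Cluster-stability diagnostics across cross-validation folds.

The consensus partition is refitted on every training fold; stability is
summarized by (a) the mean adjusted Rand index (ARI) over all fold pairs
and (b) per-cluster medoid consistency: with the first fold as reference,
each reference cluster is matched to its maximum-Jaccard cluster in every
other fold, and we report the percentage of folds in which the reference
medoid is that cluster's medoid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .preprocessing import PreprocessModel

__all__ = ["adjusted_rand_index", "RobustnessReport", "robustness_report"]


def adjusted_rand_index(partition_a: pd.Series, partition_b: pd.Series) -> float:
    """Chance-corrected agreement of two feature partitions (1 = identical).

    Both partitions must cover exactly the same feature set.
    """
    if set(partition_a.index) != set(partition_b.index):
        raise ValueError("partitions are over different feature sets")
    b = partition_b.loc[partition_a.index]
    return float(adjusted_rand_score(partition_a.to_numpy(), b.to_numpy()))


@dataclass
class RobustnessReport:
    mean_pairwise_ari: float
    medoid_consistency: pd.DataFrame  # reference cluster, medoid, consistency %
    n_folds: int
    feature_sets_differ: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"Cluster robustness over {self.n_folds} training folds",
                 f"  mean pairwise ARI: {self.mean_pairwise_ari:.3f}"]
        for _, row in self.medoid_consistency.iterrows():
            lines.append(f"  cluster {row['cluster']:>3} medoid {row['medoid']:<40s}"
                         f" consistent in {row['consistency_pct']:5.1f}% of folds")
        return "\n".join(lines)


def _clusters_of(model: PreprocessModel) -> dict[int, set[str]]:
    part = model.partition
    return {cid: set(part.index[part == cid]) for cid in np.unique(part.to_numpy())}


def _medoid_of_cluster(model: PreprocessModel, members: set[str]) -> str | None:
    for m in model.medoids:
        if m in members:
            return m
    return None


def robustness_report(models: list[PreprocessModel]) -> RobustnessReport:
    """ARI and medoid-consistency summary from per-fold preprocessing fits.

    Folds whose surviving features differ are compared on the intersection
    and the report is flagged.
    """
    if len(models) < 2:
        raise ValueError("need at least two folds for a robustness report")
    feature_sets = [set(m.kept_features) for m in models]
    common = set.intersection(*feature_sets)
    differ = any(fs != common for fs in feature_sets)
    if not common:
        raise ValueError("training folds share no surviving features")
    order = sorted(common)

    aris = []
    for a, b in combinations(models, 2):
        pa = a.partition.loc[order]
        pb = b.partition.loc[order]
        aris.append(adjusted_rand_score(pa.to_numpy(), pb.to_numpy()))
    mean_ari = float(np.mean(aris))

    reference = models[0]
    rows = []
    for cid, members in sorted(_clusters_of(reference).items()):
        ref_medoid = _medoid_of_cluster(reference, members)
        matches = 0
        for other in models[1:]:
            best_cluster, best_j = None, -1.0
            for omembers in _clusters_of(other).values():
                union = members | omembers
                j = len(members & omembers) / len(union) if union else 0.0
                if j > best_j:
                    best_j, best_cluster = j, omembers
            if best_cluster is not None and _medoid_of_cluster(other, best_cluster) == ref_medoid:
                matches += 1
        rows.append({
            "cluster": int(cid),
            "medoid": ref_medoid,
            "size": len(members),
            "consistency_pct": 100.0 * matches / (len(models) - 1),
        })
    return RobustnessReport(
        mean_pairwise_ari=mean_ari,
        medoid_consistency=pd.DataFrame(rows),
        n_folds=len(models),
        feature_sets_differ=differ,
    )
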