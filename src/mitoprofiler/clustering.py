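"""Phenotypic clustering of targets and siRNA replicate concordance.

Targets are clustered on a five-dimensional probability profile — the
aggregated scores for mitotic phenotypes (nuclear morphology + mitotic
cells), 53BP1, gamma-H2AX, p53 and EdU — by k-means with restarts.  No
feature scaling is applied: the profiles already live on the common [0, 1]
probability scale.  Cluster labels are reported in descending order of
centroid norm so that the highest label corresponds to the strongest
combined phenotype (a presentation convention).  Pearson correlation with
a Fisher-z confidence interval quantifies concordance between the two
independent siRNAs per target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import FittingError, InputError, ParameterError

PROFILE_COLUMNS = ["mitotic", "53bp1", "gh2ax", "p53", "edu"]


@dataclass
class ClusterResult:
    k: int
    labels: pd.Series            # per-target label in {1..k}
    centroids: np.ndarray        # (k, 5), row i = cluster i+1
    wcss: float                  # within-cluster sum of squares (best restart)
    n_restarts: int
    seed: int

    def members(self, cluster: int) -> list:
        return list(self.labels.index[self.labels == cluster])


def _profile_matrix(profiles: pd.DataFrame) -> np.ndarray:
    missing = [c for c in PROFILE_COLUMNS if c not in profiles.columns]
    if missing:
        raise InputError(f"profile columns missing: {missing}")
    X = profiles[PROFILE_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise InputError("profiles must be finite")
    return X


def kmeans_cluster(
    profiles: pd.DataFrame,
    k: int = 4,
    n_restarts: int = 50,
    seed: int = 42,
) -> ClusterResult:
    """k-means (k-means++ init, Euclidean, best of ``n_restarts`` by WCSS).

    ``profiles`` is indexed by target with the five probability columns.
    Labels are renumbered so cluster k has the largest centroid norm.
    """
    X = _profile_matrix(profiles)
    if k > len(X):
        raise ParameterError(f"k={k} exceeds number of profiles ({len(X)})")
    if k < 1:
        raise ParameterError("k must be >= 1")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    # order clusters by ascending centroid norm -> label k = strongest
    norms = np.linalg.norm(km.cluster_centers_, axis=1)
    order = np.argsort(norms)
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = pd.Series([relabel[int(r)] for r in raw], index=profiles.index, name="cluster")
    centroids = km.cluster_centers_[order]
    return ClusterResult(
        k=k,
        labels=labels,
        centroids=centroids,
        wcss=float(km.inertia_),
        n_restarts=n_restarts,
        seed=seed,
    )


def choose_k(
    profiles: pd.DataFrame,
    k_range: Sequence[int] = range(2, 8),
    n_restarts: int = 50,
    seed: int = 42,
) -> Tuple[int, Dict[int, float]]:
    """Select k by the mean silhouette score over ``k_range``."""
    X = _profile_matrix(profiles)
    if np.allclose(X, X[0]):
        raise FittingError("identical profiles: silhouette undefined")
    scores: Dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= len(X) - 1:
            raise ParameterError(f"k={k} outside [2, n-1]")
        res = kmeans_cluster(profiles, k=k, n_restarts=n_restarts, seed=seed)
        scores[k] = float(silhouette_score(X, res.labels.to_numpy()))
    best = max(scores, key=lambda k: scores[k])
    return best, scores


@dataclass
class ReplicateConcordance:
    r: float
    ci_lower: float
    ci_upper: float
    p: float
    n: int


def replicate_correlation(
    scores_sirna1: Sequence[float], scores_sirna2: Sequence[float]
) -> ReplicateConcordance:
    """Pearson product-moment correlation between paired per-target scores
    of the two independent siRNAs, with Fisher-z 95% CI and the two-sided
    p-value for no correlation."""
    a = np.asarray(scores_sirna1, dtype=float).ravel()
    b = np.asarray(scores_sirna2, dtype=float).ravel()
    if a.size != b.size:
        raise InputError("paired vectors must have equal length")
    if a.size < 3:
        raise InputError("need at least 3 pairs")
    if a.std() == 0 or b.std() == 0:
        raise FittingError("zero variance: correlation undefined")
    res = stats.pearsonr(a, b)
    ci = res.confidence_interval(confidence_level=0.95)
    return ReplicateConcordance(
        r=float(res.statistic),
        ci_lower=float(ci.low),
        ci_upper=float(ci.high),
        p=float(res.pvalue),
        n=int(a.size),
    )


def build_profiles(
    reports: Dict[str, pd.DataFrame],
    sirna_rank: int = 1,
) -> pd.DataFrame:
    """Assemble per-target phenotype profiles from per-readout score
    reports.

    ``reports`` maps readout name to the :func:`~.profiling.screen_report`
    table.  The clustering variable for mitotic phenotypes is the
    morphology readout score; one profile row per target using siRNA
    number ``sirna_rank`` (by convention the primary siRNA, #1).
    """
    readout_to_col = {
        "morphology": "mitotic",
        "53bp1": "53bp1",
        "gh2ax": "gh2ax",
        "p53": "p53",
        "edu": "edu",
    }
    frames = {}
    for readout, col in readout_to_col.items():
        if readout not in reports:
            raise InputError(f"missing report for readout {readout!r}")
        rep = reports[readout]
        sel = rep[rep["sirna"].str.endswith(f"_si{sirna_rank}")]
        if sel.empty:
            sel = rep
        frames[col] = sel.set_index("target")["score"]
    profiles = pd.DataFrame(frames)
    if profiles.isna().any().any():
        raise InputError("incomplete profiles: a target is missing a readout score")
    return profiles[PROFILE_COLUMNS]
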