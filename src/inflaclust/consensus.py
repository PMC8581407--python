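"""Consensus K-means clustering of the five-score matrix and semantic labeling.

Stability-based clustering in the Monti style: repeatedly subsample the
cohort, K-means-partition each subsample (Euclidean distance), and record for
every sample pair the fraction of co-samplings in which the pair co-clustered.
The per-K consensus matrices feed three diagnostics — cluster-consensus, the
relative change in area under the consensus-value CDF (delta area), and the
average silhouette width of the per-K labels on the score matrix — from which
the cluster count is chosen. Final per-K labels come from average-linkage
hierarchical clustering of (1 - consensus).

With six clusters the centroids are given the semantic names of the
inflammasome classification: the two lowest-IC clusters split on IL1B, the two
middle ones on CASP1-versus-IL18 dominance, and the two highest on IL18.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .scoring import ScoreMatrix

logger = logging.getLogger(__name__)

SEMANTIC_NAMES = (
    "IC^Low IL1B^Low",
    "IC^Low IL1B^High",
    "IC^Mid CASP1^High",
    "IC^Mid IL18^High",
    "IC^High IL18^Low",
    "IC^High IL18^High",
)


@dataclass
class ConsensusResult:
    """Per-K consensus matrices, diagnostics, labels, and the chosen K."""

    k_range: tuple[int, ...]
    samples: tuple[str, ...]
    consensus: dict[int, np.ndarray]
    cluster_consensus: dict[int, dict[int, float]]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    silhouette_avg: dict[int, float]
    labels: dict[int, np.ndarray]
    chosen_k: Optional[int]
    seed: int
    subsample_log: list[np.ndarray] = field(repr=False, default_factory=list)
    cosample_counts: Optional[np.ndarray] = field(repr=False, default=None)
    selection_trace: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ClusterLabeling:
    """One cluster's canonical number, semantic name, and score centroid."""

    numeric: int
    original_label: int
    semantic: Optional[str]
    centroid: pd.Series


def consensus_cluster(
    scores: ScoreMatrix,
    k_range: Sequence[int] = tuple(range(2, 9)),
    resamples: int = 500,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_init: int = 20,
) -> ConsensusResult:
    """Resampled K-means consensus clustering over ``k_range``.

    Each resample draws ceil(frac * n) samples without replacement (the same
    draw is reused across K); consensus(i, j) = co-clusterings / co-samplings.
    Fully reproducible from ``seed``; the subsample draws are retained on the
    result so an independent replay can verify the consensus matrices.
    """
    X = scores.values()
    n = X.shape[0]
    k_range = tuple(int(k) for k in k_range)
    if min(k_range) < 2:
        raise ValueError("k_range must start at 2 or above")
    if max(k_range) > n / 3:
        raise ValueError(f"largest K {max(k_range)} exceeds n_samples/3 = {n / 3:.1f}")
    if not (0 < subsample_frac <= 1):
        raise ValueError("subsample_frac must be in (0, 1]")
    n_distinct = np.unique(X, axis=0).shape[0]
    if max(k_range) > n_distinct:
        raise ValueError(
            f"K={max(k_range)} exceeds the {n_distinct} distinct score vectors"
        )

    rng = np.random.default_rng(seed)
    m = int(np.ceil(subsample_frac * n))
    draws = [np.sort(rng.choice(n, size=m, replace=False)) for _ in range(resamples)]
    km_seeds = rng.integers(0, 2**31 - 1, size=(len(k_range), resamples))

    cosample = np.zeros((n, n))
    for idx in draws:
        cosample[np.ix_(idx, idx)] += 1.0

    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, np.ndarray] = {}
    cluster_cons: dict[int, dict[int, float]] = {}
    sil_avg: dict[int, float] = {}
    cdf_area: dict[int, float] = {}

    n_missing = int((cosample == 0)[np.triu_indices(n, 1)].sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} sample pairs were never co-sampled; their consensus "
            "entries are flagged missing and excluded from the CDF",
            stacklevel=2,
        )

    for ki, k in enumerate(k_range):
        cocluster = np.zeros((n, n))
        for b, idx in enumerate(draws):
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=n_init,
                random_state=int(km_seeds[ki, b]),
            )
            part = km.fit_predict(X[idx])
            for c in range(k):
                members = idx[part == c]
                cocluster[np.ix_(members, members)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(cosample > 0, cocluster / np.where(cosample > 0, cosample, 1), np.nan)
        sampled = cosample.diagonal() > 0
        M[np.diag_indices(n)] = np.where(sampled, 1.0, np.nan)
        consensus[k] = M

        # final labels: average linkage on consensus dissimilarity
        D = 1.0 - np.nan_to_num(M, nan=0.0)
        np.fill_diagonal(D, 0.0)
        D = (D + D.T) / 2.0
        Z = linkage(squareform(D, checks=False), method="average")
        lab = fcluster(Z, t=k, criterion="maxclust")
        labels[k] = lab

        cc: dict[int, float] = {}
        iu = np.triu_indices(n, 1)
        for c in np.unique(lab):
            members = np.where(lab == c)[0]
            if len(members) < 2:
                cc[int(c)] = 1.0
                continue
            sub = M[np.ix_(members, members)]
            vals = sub[np.triu_indices(len(members), 1)]
            cc[int(c)] = float(np.nanmean(vals))
        cluster_cons[k] = cc

        vals = M[iu]
        vals = vals[np.isfinite(vals)]
        cdf_area[k] = _cdf_area(vals)
        sil_avg[k] = (
            float(np.mean(silhouette_width(scores, lab)[0]))
            if len(np.unique(lab)) > 1
            else float("nan")
        )

    delta_area: dict[int, float] = {}
    ks = sorted(k_range)
    for i, k in enumerate(ks):
        if i == 0:
            delta_area[k] = cdf_area[k]
        else:
            prev = cdf_area[ks[i - 1]]
            delta_area[k] = (cdf_area[k] - prev) / prev if prev > 0 else float("inf")

    return ConsensusResult(
        k_range=k_range,
        samples=tuple(str(s) for s in scores.samples),
        consensus=consensus,
        cluster_consensus=cluster_cons,
        cdf_area=cdf_area,
        delta_area=delta_area,
        silhouette_avg=sil_avg,
        labels=labels,
        chosen_k=None,
        seed=seed,
        subsample_log=draws,
        cosample_counts=cosample,
    )


def _cdf_area(values: np.ndarray) -> float:
    """Exact area under the empirical CDF of consensus values over [0, 1]."""
    if values.size == 0:
        return 0.0
    uniq, counts = np.unique(values, return_counts=True)
    cdf = np.cumsum(counts) / values.size
    right_edges = np.concatenate([uniq[1:], [1.0]])
    return float(np.sum((right_edges - uniq) * cdf))


def select_k(
    result: ConsensusResult,
    min_silhouette: float = 0.25,
    elbow_floor: float = 0.05,
) -> int:
    """Pick the cluster count.

    Candidate K are those passing both stability gates: consensus-CDF delta
    area above ``elbow_floor`` (the gain in consensus structure when moving
    from K-1 to K is still material) and average silhouette width at least
    ``min_silhouette``. Among candidates the K with the best silhouette wins
    (ties go to the larger K). If none qualifies, fall back to the silhouette
    argmax with a warning. The decision trace is stored on the result.
    """
    candidates = [
        k
        for k in result.k_range
        if result.delta_area[k] > elbow_floor
        and np.isfinite(result.silhouette_avg[k])
        and result.silhouette_avg[k] >= min_silhouette
    ]
    trace = {
        "rule": (
            "argmax silhouette_avg over K with delta_area > elbow_floor "
            "and silhouette_avg >= min_silhouette"
        ),
        "min_silhouette": min_silhouette,
        "elbow_floor": elbow_floor,
        "delta_area": {int(k): result.delta_area[k] for k in result.k_range},
        "silhouette_avg": {int(k): result.silhouette_avg[k] for k in result.k_range},
        "candidates": [int(k) for k in candidates],
    }
    if candidates:
        chosen = int(max(candidates, key=lambda k: (result.silhouette_avg[k], k)))
        trace["fallback"] = False
    else:
        finite = {k: v for k, v in result.silhouette_avg.items() if np.isfinite(v)}
        chosen = int(max(finite, key=finite.get))
        trace["fallback"] = True
        warnings.warn(
            "no K passed the elbow/silhouette rule; falling back to the "
            f"silhouette argmax K={chosen}",
            stacklevel=2,
        )
    result.chosen_k = chosen
    result.selection_trace = trace
    return chosen


def silhouette_width(
    scores: ScoreMatrix | np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths s(i) = (b-a)/max(a,b) with Euclidean
    distance over the five scores, plus their average. Singletons get 0."""
    X = scores.values() if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette width needs at least two clusters")
    widths = silhouette_samples(X, labels, metric="euclidean")
    return widths, float(np.mean(widths))


def label_clusters(
    scores: ScoreMatrix, labels: np.ndarray
) -> list[ClusterLabeling]:
    """Assign canonical numbers and semantic names to clusters from their
    score centroids.

    With exactly six clusters the centroids are ranked by IC: the bottom,
    middle, and top pairs become the Low/Mid/High IC strata; the Low pair is
    split by IL1B, the Mid pair by CASP1-versus-IL18 dominance, and the High
    pair by IL18 — yielding the six names in SEMANTIC_NAMES (canonical
    numbering 1..6 in that order). Any other cluster count returns numeric
    labelings only.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    centroids = {
        int(c): scores.data.loc[labels == c].mean(axis=0) for c in uniq
    }
    if len(uniq) != 6:
        logger.info(
            "semantic labeling skipped: %d clusters (needs exactly 6)", len(uniq)
        )
        return [
            ClusterLabeling(numeric=i + 1, original_label=int(c), semantic=None,
                            centroid=centroids[int(c)])
            for i, c in enumerate(sorted(uniq, key=lambda c: centroids[int(c)]["IC"]))
        ]

    by_ic = sorted(uniq, key=lambda c: (centroids[int(c)]["IC"], centroids[int(c)]["CASP1"]))
    ics = [centroids[int(c)]["IC"] for c in by_ic]
    if len(set(np.round(ics, 12))) < len(ics):
        logger.info("IC centroid tie broken by CASP1 centroid")
    low, mid, high = by_ic[0:2], by_ic[2:4], by_ic[4:6]

    def order_pair(pair, key):
        return sorted(pair, key=lambda c: key(centroids[int(c)]))

    c1, c2 = order_pair(low, lambda v: v["IL1B"])
    c3, c4 = order_pair(mid, lambda v: v["IL18"] - v["CASP1"])
    c5, c6 = order_pair(high, lambda v: v["IL18"])
    ordered = [c1, c2, c3, c4, c5, c6]
    return [
        ClusterLabeling(
            numeric=i + 1,
            original_label=int(c),
            semantic=SEMANTIC_NAMES[i],
            centroid=centroids[int(c)],
        )
        for i, c in enumerate(ordered)
    ]


def semantic_sample_labels(
    scores: ScoreMatrix, labels: np.ndarray
) -> pd.Series:
    """Map each sample's cluster assignment to its semantic name (6 clusters)."""
    mapping = {
        lab.original_label: lab.semantic for lab in label_clusters(scores, labels)
    }
    if any(v is None for v in mapping.values()):
        raise ValueError("semantic labels are only defined for exactly six clusters")
    return pd.Series(
        [mapping[int(c)] for c in labels], index=scores.samples, name="semantic_cluster"
    )
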