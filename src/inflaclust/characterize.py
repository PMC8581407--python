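"""Cluster-descriptive statistics.

Four analyses that describe an established clustering:

* tumor-type composition — upper-tail hypergeometric enrichment of each
  tumor type within each cluster, BH-adjusted across all (type, cluster)
  pairs;
* one-vs-rest screens of binary genomic features (chi-square, with an exact
  fallback for sparse tables) and of expression (rank-sum test with
  class-specific logFC/FDR significance thresholds);
* a sample-similarity map, S = 1 / (1 + Euclidean distance) over the five
  scores;
* survival contrasts — an overall log-rank test plus a pairwise univariate
  Cox hazard-ratio table (row cluster versus column cluster).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test

from .scoring import ExpressionMatrix, ScoreMatrix

logger = logging.getLogger(__name__)

# class-specific significance thresholds: (|logFC| floor, FDR ceiling)
FEATURE_CLASS_THRESHOLDS = {
    "coding": (1.0, 0.01),
    "lncRNA": (2.0, 0.01),
    "miRNA": (1.0, 0.01),
}


@dataclass(frozen=True)
class EnrichmentRecord:
    """Hypergeometric enrichment of one tumor type within one cluster."""

    tumor_type: str
    cluster: int
    n_total: int
    n_type: int
    n_cluster: int
    overlap: int
    p: float
    fdr: float


@dataclass(frozen=True)
class DiffFeatureRecord:
    """One feature's one-vs-rest differential result for one cluster."""

    feature: str
    feature_class: str
    cluster: int
    effect: float  # logFC (expression) or frequency difference (binary)
    p: float
    fdr: float
    significant: bool
    note: str = ""


def _bh(pvals: Sequence[float]) -> np.ndarray:
    return multipletests(pvals, method="fdr_bh")[1]


def hypergeom_enrichment(
    cluster_labels: pd.Series | np.ndarray,
    tumor_types: pd.Series | np.ndarray,
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric test of every (tumor type, cluster) pair.

    p = P(X >= k) with X ~ Hypergeometric(N, K_type, n_cluster); BH across
    all records.
    """
    labels = np.asarray(cluster_labels)
    types = np.asarray(tumor_types)
    if labels.shape != types.shape:
        raise ValueError("cluster labels and tumor types must align on samples")
    N = len(labels)
    uniq_types = np.unique(types)
    uniq_clusters = np.unique(labels)
    if len(uniq_types) < 2:
        warnings.warn("single tumor type overall; all enrichment p-values are 1", stacklevel=2)

    rows = []
    for t in uniq_types:
        Kt = int((types == t).sum())
        for c in uniq_clusters:
            n = int((labels == c).sum())
            k = int(((types == t) & (labels == c)).sum())
            if len(uniq_types) < 2:
                p = 1.0
            else:
                p = float(stats.hypergeom.sf(k - 1, N, Kt, n))
            rows.append((str(t), int(c), N, Kt, n, k, min(p, 1.0)))
    fdrs = _bh([r[6] for r in rows])
    return [
        EnrichmentRecord(
            tumor_type=r[0], cluster=r[1], n_total=r[2], n_type=r[3],
            n_cluster=r[4], overlap=r[5], p=r[6], fdr=float(f),
        )
        for r, f in zip(rows, fdrs)
    ]


def chisq_feature_screen(
    cluster_labels: pd.Series | np.ndarray,
    features: pd.DataFrame,
    feature_class: str = "binary_genomic",
) -> list[DiffFeatureRecord]:
    """One-vs-rest chi-square screen of binary features (e.g. driver-gene
    mutation indicators), with Fisher's exact test when any expected cell
    count falls below 5. Effect = in-cluster frequency minus rest frequency.
    BH across all tested (feature, cluster) records."""
    labels = np.asarray(cluster_labels)
    F = features.to_numpy()
    if not np.isin(F, (0, 1)).all():
        raise ValueError("feature matrix must be binary (0/1)")
    if F.shape[0] != len(labels):
        raise ValueError("features and labels must align on samples")

    rows = []
    for c in np.unique(labels):
        in_c = labels == c
        n_in, n_out = int(in_c.sum()), int((~in_c).sum())
        for j, feat in enumerate(features.columns):
            x = F[:, j]
            a = int(x[in_c].sum())        # feature+ in cluster
            b = n_in - a
            d = int(x[~in_c].sum())       # feature+ outside
            e = n_out - d
            if x.sum() == 0 or x.sum() == len(x):
                logger.info("feature %s is constant; skipped for cluster %s", feat, c)
                continue
            table = np.array([[a, b], [d, e]], dtype=float)
            expected = stats.contingency.expected_freq(table)
            note = ""
            if (expected < 5).any():
                _, p = stats.fisher_exact([[a, b], [d, e]])
                note = "fisher_exact_fallback"
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            effect = a / n_in - d / n_out
            rows.append((str(feat), int(c), effect, float(p), note))
    if not rows:
        return []
    fdrs = _bh([r[3] for r in rows])
    return [
        DiffFeatureRecord(
            feature=r[0], feature_class=feature_class, cluster=r[1],
            effect=r[2], p=r[3], fdr=float(f), significant=bool(f < 0.05), note=r[4],
        )
        for r, f in zip(rows, fdrs)
    ]


def chi2_stat_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square statistic of a 2x2 table, no continuity correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0:
        return 0.0
    chi2, _, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2)


def diff_expression_one_vs_rest(
    expr: ExpressionMatrix,
    cluster_labels: pd.Series | np.ndarray,
    feature_class: str = "coding",
) -> list[DiffFeatureRecord]:
    """One-vs-rest differential expression with a two-sample rank-sum test.

    logFC = mean(in-cluster) - mean(rest) on the log scale; BH within the
    feature class; ``significant`` applies the class thresholds
    (coding/miRNA \\|logFC\\| > 1, lncRNA \\|logFC\\| > 2; FDR < 0.01).
    """
    if feature_class not in FEATURE_CLASS_THRESHOLDS:
        raise ValueError(f"unknown feature class {feature_class!r}")
    lfc_min, fdr_max = FEATURE_CLASS_THRESHOLDS[feature_class]
    labels = np.asarray(cluster_labels)
    V = expr.expr.to_numpy(dtype=float)
    genes = list(expr.genes)

    rows = []
    for c in np.unique(labels):
        in_c = labels == c
        if in_c.sum() < 3 or (~in_c).sum() < 3:
            raise ValueError(f"cluster {c}: need >=3 samples on each side")
        A, B = V[:, in_c], V[:, ~in_c]
        logfc = A.mean(axis=1) - B.mean(axis=1)
        constant = (V.std(axis=1) == 0)
        with np.errstate(all="ignore"):
            res = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided")
        pvals = np.where(constant, 1.0, res.pvalue)
        logfc = np.where(constant, 0.0, logfc)
        for g, fc, p in zip(genes, logfc, pvals):
            rows.append((str(g), int(c), float(fc), float(p)))
    fdrs = _bh([r[3] for r in rows])
    return [
        DiffFeatureRecord(
            feature=r[0], feature_class=feature_class, cluster=r[1],
            effect=r[2], p=r[3], fdr=float(f),
            significant=bool(abs(r[2]) > lfc_min and f < fdr_max),
        )
        for r, f in zip(rows, fdrs)
    ]


def tumor_map_similarity(scores: ScoreMatrix) -> pd.DataFrame:
    """Sample-by-sample Euclidean similarity S = 1 / (1 + distance) over the
    five scores; symmetric with unit diagonal."""
    D = squareform(pdist(scores.values(), metric="euclidean"))
    S = 1.0 / (1.0 + D)
    return pd.DataFrame(S, index=scores.samples, columns=scores.samples)


def survival_contrasts(
    cluster_labels: pd.Series | np.ndarray,
    time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
    p_mask: float = 0.05,
) -> dict:
    """Overall log-rank test across clusters plus a pairwise univariate Cox
    hazard-ratio table (row cluster versus column cluster; pairs with
    p >= ``p_mask`` reported as NaN in the masked table, mirroring the usual
    figure convention)."""
    labels = np.asarray(cluster_labels)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0/1")
    if e.sum() == 0:
        raise ValueError("no events observed; survival contrasts undefined")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters for survival contrasts")

    lr = multivariate_logrank_test(t, labels, e)
    hr = pd.DataFrame(np.nan, index=uniq, columns=uniq, dtype=float)
    pmat = pd.DataFrame(np.nan, index=uniq, columns=uniq, dtype=float)
    for row in uniq:
        for col in uniq:
            if row == col:
                continue
            sel = (labels == row) | (labels == col)
            if e[sel].sum() == 0:
                continue
            df = pd.DataFrame(
                {
                    "time": t[sel],
                    "event": e[sel],
                    "is_row": (labels[sel] == row).astype(float),
                }
            )
            cph = CoxPHFitter()
            try:
                cph.fit(df, duration_col="time", event_col="event")
            except Exception as err:  # degenerate pair (e.g. no events in one arm)
                logger.info("Cox fit failed for pair (%s, %s): %s", row, col, err)
                continue
            hr.loc[row, col] = float(np.exp(cph.params_["is_row"]))
            pmat.loc[row, col] = float(cph.summary.loc["is_row", "p"])
    masked = hr.where(pmat < p_mask)
    return {
        "logrank_stat": float(lr.test_statistic),
        "logrank_p": float(lr.p_value),
        "hazard_ratios": hr,
        "hr_pvalues": pmat,
        "hazard_ratios_masked": masked,
    }
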