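"""Per-sample enrichment scoring: ssGSEA and the five composite signaling scores.

The single-sample enrichment statistic is the rank-weighted running sum: for
one sample, genes are ordered by expression (highest first); walking down the
ordered list, the score accumulates the difference between the cumulative
weighted fraction of in-set genes (weight = rank value ** alpha, where the
most highly expressed gene carries the largest rank value) and the cumulative
count fraction of out-of-set genes. The enrichment score is the sum of that
difference over the whole list, not its supremum.

Composite scores subtract the down-regulated set's enrichment from the
up-regulated set's, so a positive value means the node's downstream program
looks transcriptionally active.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .signature_sets import SCORE_NAMES, GeneSet, SignatureScheme

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Log-scale gene x sample expression with optional per-sample metadata.

    ``expr``: DataFrame, genes in rows (unique symbols), samples in columns.
    ``metadata``: optional DataFrame indexed by sample; recognised columns
    are ``tumor_type``, ``time``, ``event``.
    """

    expr: pd.DataFrame
    metadata: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.expr.index.duplicated().any():
            dups = self.expr.index[self.expr.index.duplicated()].unique().tolist()
            raise ValueError(
                f"duplicate gene symbols (collapse first, e.g. via io.read_expression): {dups[:5]}"
            )
        if not np.isfinite(self.expr.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.metadata is not None:
            missing = self.expr.columns.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"metadata missing samples: {list(missing)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def samples(self) -> pd.Index:
        return self.expr.columns


@dataclass(frozen=True)
class ScoreParams:
    """ssGSEA parameters.

    alpha: rank-weight exponent (0 gives the unweighted KS-style sum;
    0.25 is the conventional single-sample default).
    tie_policy: how tied expression values are ranked.
    normalize: optional min-max rescaling of each set's scores across samples.
    """

    alpha: float = 0.25
    tie_policy: str = "average"  # average | min | random
    normalize: str = "none"  # none | minmax_across_samples
    tie_seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.tie_policy not in ("average", "min", "random"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")
        if self.normalize not in ("none", "minmax_across_samples"):
            raise ValueError(f"unknown normalize {self.normalize!r}")


@dataclass
class ScoreMatrix:
    """Samples x five named signaling scores; the sole clustering input."""

    data: pd.DataFrame
    scaling: Optional[dict] = None
    scheme_fingerprint: Optional[str] = None

    def __post_init__(self) -> None:
        if tuple(self.data.columns) != SCORE_NAMES:
            raise ValueError(
                f"score matrix must have exactly the columns {SCORE_NAMES}, "
                f"got {tuple(self.data.columns)}"
            )

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def upper_quartile_normalize(
    counts: pd.DataFrame, reference: float = 1000.0
) -> ExpressionMatrix:
    """Upper-quartile normalize a nonnegative count matrix, then log2(x+1).

    Each sample (column) is scaled so the 75th percentile of its nonzero
    counts equals ``reference``.
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be nonnegative")
    norm = np.empty_like(values)
    for j, sample in enumerate(counts.columns):
        col = values[:, j]
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {sample!r} is all zero; cannot normalize")
        uq = np.percentile(nonzero, 75)
        norm[:, j] = col * (reference / uq)
    logexpr = np.log2(norm + 1.0)
    return ExpressionMatrix(pd.DataFrame(logexpr, index=counts.index, columns=counts.columns))


def _rank_matrix(values: np.ndarray, params: ScoreParams) -> np.ndarray:
    """Ascending rank values per column (highest expression -> rank n_genes)."""
    if params.tie_policy == "average":
        return stats.rankdata(values, axis=0, method="average")
    if params.tie_policy == "min":
        return stats.rankdata(values, axis=0, method="min")
    rng = np.random.default_rng(params.tie_seed)
    jitter = rng.random(values.shape) * 1e-12
    return stats.rankdata(values + jitter, axis=0, method="ordinal").astype(float)


def ssgsea_score(
    expr: ExpressionMatrix, gene_set: GeneSet, params: ScoreParams | None = None
) -> pd.Series:
    """Single-sample enrichment score of one gene set for every sample."""
    params = params or ScoreParams()
    members = [g for g in gene_set.members if g in expr.genes]
    if not members:
        raise ValueError(f"no members of gene set {gene_set.name!r} present in the matrix")
    coverage = len(members) / len(gene_set.members)
    if coverage < 0.5:
        warnings.warn(
            f"gene set {gene_set.name!r}: only {len(members)}/{len(gene_set.members)} "
            "members present; score computed on the intersection",
            stacklevel=2,
        )
    in_set = np.asarray(expr.genes.isin(members))
    n_out = int((~in_set).sum())
    if n_out == 0:
        raise ValueError(f"gene set {gene_set.name!r} covers every gene in the matrix")

    values = expr.expr.to_numpy(dtype=float)
    ranks = _rank_matrix(values, params)
    # walk each column from the top-expressed gene downwards
    order = np.argsort(-values, axis=0, kind="stable")
    ranked_w = np.take_along_axis(ranks, order, axis=0) ** params.alpha
    ranked_in = in_set[order]
    w_in = np.where(ranked_in, ranked_w, 0.0)
    p_in = np.cumsum(w_in, axis=0) / np.sum(w_in, axis=0)
    p_out = np.cumsum(~ranked_in, axis=0) / n_out
    es = np.sum(p_in - p_out, axis=0)

    scores = pd.Series(es, index=expr.samples, name=gene_set.name)
    if params.normalize == "minmax_across_samples":
        rng_ = scores.max() - scores.min()
        if rng_ > 0:
            scores = (scores - scores.min()) / rng_
    return scores


def composite_score(pos: pd.Series, neg: pd.Series) -> pd.Series:
    """Directional composite: up-regulated-set score minus down-regulated-set score."""
    if not pos.index.equals(neg.index):
        raise ValueError("positive and negative score vectors have mismatched sample indices")
    return pos - neg


def score_matrix(
    expr: ExpressionMatrix,
    scheme: SignatureScheme,
    params: ScoreParams | None = None,
    standardize: bool = True,
) -> ScoreMatrix:
    """Compute the samples x 5 inflammasome-signaling score matrix.

    IC is the plain enrichment of the sensing set; CASP1/GSDMD/IL1B/IL18 are
    up-minus-down composites. With ``standardize`` each column is z-scored
    across samples (recorded in ``scaling``) — the default, so that no single
    score dominates the Euclidean geometry used downstream.
    """
    params = params or ScoreParams()
    cols: dict[str, pd.Series] = {}
    for name in SCORE_NAMES:
        pos, neg = scheme.scores[name]
        try:
            s_pos = ssgsea_score(expr, pos, params)
            if neg is None:
                cols[name] = s_pos
            else:
                cols[name] = composite_score(s_pos, ssgsea_score(expr, neg, params))
        except ValueError as err:
            raise ValueError(f"score {name}: {err}") from err

    data = pd.DataFrame(cols, columns=list(SCORE_NAMES))
    scaling = None
    if standardize:
        mean = data.mean(axis=0)
        sd = data.std(axis=0, ddof=0)
        sd = sd.replace(0.0, 1.0)
        data = (data - mean) / sd
        scaling = {
            "kind": "zscore",
            "mean": mean.to_dict(),
            "sd": sd.to_dict(),
        }
    return ScoreMatrix(data=data, scaling=scaling, scheme_fingerprint=scheme.fingerprint())
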