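"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator plants six clusters in log2-scale expression by shifting each
signature gene program per cluster according to the published score-pattern
table: cluster 1 (IC-low, IL1B-low) down-shifts sensing and IL1B-program
genes, cluster 6 (IC-high, IL18-high) up-shifts sensing and IL18-program
genes, and so on. For the directional programs an "activation" shift moves
up-regulated members up and down-regulated members down (and vice versa), so
the composite scores respond in the intended direction. On top sit a baseline
mu_g ~ Normal(5, 1) per gene and residual Gaussian noise. Tumor-type labels
are drawn from per-cluster multinomials (each cluster over-represents one
type so composition enrichment is non-trivial), and survival is exponential
with a per-cluster hazard multiplier (cluster 6 largest) under independent
exponential censoring.

Gaussian log-expression is the primary mode because every in-scope statistic
operates on log-normalized values; ``generate_counts`` provides a thin
Poisson-lognormal count mode solely to exercise upper-quartile normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .scoring import ExpressionMatrix
from .signature_sets import SCORE_NAMES, SignatureScheme, load_scheme

# per-cluster shift of each gene program, in units of (delta_high, delta_low):
# levels are -2 = -delta_high, -1 = -delta_low, 0, +1 = +delta_low, +2 = +delta_high
PATTERN_LEVELS: dict[int, dict[str, int]] = {
    1: {"IC": -2, "CASP1": -1, "GSDMD": -1, "IL1B": -2, "IL18": -1},
    2: {"IC": -2, "CASP1": -1, "GSDMD": 0, "IL1B": 2, "IL18": 0},
    3: {"IC": 0, "CASP1": 2, "GSDMD": 1, "IL1B": 0, "IL18": -1},
    4: {"IC": 0, "CASP1": -1, "GSDMD": 0, "IL1B": 1, "IL18": 2},
    5: {"IC": 2, "CASP1": 1, "GSDMD": 1, "IL1B": 0, "IL18": -2},
    6: {"IC": 2, "CASP1": 1, "GSDMD": 1, "IL1B": 1, "IL18": 2},
}

DEFAULT_TUMOR_TYPES = tuple(f"TT{i:02d}" for i in range(1, 9))


def _default_type_profile() -> np.ndarray:
    """6 clusters x 8 tumor types; each cluster over-represents one type."""
    k, t = 6, len(DEFAULT_TUMOR_TYPES)
    base = np.full((k, t), (1.0 - 0.45) / (t - 1))
    for c in range(k):
        base[c, :] = (1.0 - 0.45) / (t - 1)
        base[c, c] = 0.45
    return base


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults define the study conditions used in
    the test suite (six clusters of 100 samples, shift 1.5/0.6 log2 units,
    unit noise)."""

    n_genes: int = 2000
    samples_per_cluster: tuple[int, ...] = (100,) * 6
    delta_high: float = 1.5
    delta_low: float = 0.6
    noise_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    tumor_types: tuple[str, ...] = DEFAULT_TUMOR_TYPES
    tumor_type_profile: Optional[tuple[tuple[float, ...], ...]] = None
    base_hazard: float = 0.02
    hazard_multipliers: tuple[float, ...] = (0.7, 0.8, 1.1, 1.2, 1.0, 2.0)
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_cluster) != 6:
            raise ValueError("samples_per_cluster must have six entries")
        if any(n <= 0 for n in self.samples_per_cluster):
            raise ValueError("samples_per_cluster must be positive")
        if any(h <= 0 for h in self.hazard_multipliers):
            raise ValueError("hazard multipliers must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")

    def type_profile(self) -> np.ndarray:
        if self.tumor_type_profile is None:
            return _default_type_profile()
        prof = np.asarray(self.tumor_type_profile, dtype=float)
        if prof.shape != (6, len(self.tumor_types)):
            raise ValueError("tumor_type_profile must be 6 x n_types")
        return prof / prof.sum(axis=1, keepdims=True)

    def delta(self, level: int) -> float:
        return {0: 0.0, 1: self.delta_low, 2: self.delta_high,
                -1: -self.delta_low, -2: -self.delta_high}[level]


@dataclass
class SyntheticCohort:
    """Generated expression plus the planted ground truth."""

    expr: ExpressionMatrix
    true_labels: pd.Series
    tumor_types: pd.Series
    survival: pd.DataFrame  # columns: time, event
    config: SyntheticConfig


def _gene_shifts(scheme: SignatureScheme, genes: pd.Index, config: SyntheticConfig) -> np.ndarray:
    """Per-(cluster, gene) shift matrix (6 x n_genes) from the pattern table.

    A gene in several sets accumulates each program's contribution.
    """
    shifts = np.zeros((6, len(genes)))
    pos_of = {g: i for i, g in enumerate(genes)}
    for name in SCORE_NAMES:
        pos, neg = scheme.scores[name]
        for c in range(1, 7):
            d = config.delta(PATTERN_LEVELS[c][name])
            for g in pos.members:
                shifts[c - 1, pos_of[g]] += d
            if neg is not None:
                for g in neg.members:
                    shifts[c - 1, pos_of[g]] -= d
    return shifts


def generate(
    config: SyntheticConfig | None = None, scheme: SignatureScheme | None = None
) -> SyntheticCohort:
    """Generate a cohort with six planted clusters (see module docstring).

    Deterministic: the same config (including its seed) reproduces the cohort
    bitwise.
    """
    config = config or SyntheticConfig()
    scheme = scheme or load_scheme()
    sig_genes = list(scheme.unique_genes())
    if len(sig_genes) > config.n_genes:
        raise ValueError(
            f"scheme has {len(sig_genes)} genes but n_genes={config.n_genes}"
        )
    n_bg = config.n_genes - len(sig_genes)
    genes = pd.Index(sig_genes + [f"BG{i:04d}" for i in range(n_bg)], name="gene")

    ss = np.random.SeedSequence(config.seed)
    rng_expr, rng_types, rng_surv = (np.random.default_rng(s) for s in ss.spawn(3))

    n_total = sum(config.samples_per_cluster)
    clusters = np.repeat(np.arange(1, 7), config.samples_per_cluster)
    samples = pd.Index([f"S{i:04d}" for i in range(n_total)], name="sample")

    mu = rng_expr.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    shifts = _gene_shifts(scheme, genes, config)  # 6 x n_genes
    values = (
        mu[:, None]
        + shifts[clusters - 1].T
        + rng_expr.normal(0.0, config.noise_sd, size=(len(genes), n_total))
    )
    expr_df = pd.DataFrame(values, index=genes, columns=samples)

    profile = config.type_profile()
    type_idx = np.array(
        [rng_types.choice(len(config.tumor_types), p=profile[c - 1]) for c in clusters]
    )
    tumor_types = pd.Series(
        [config.tumor_types[i] for i in type_idx], index=samples, name="tumor_type"
    )

    hazards = config.base_hazard * np.asarray(config.hazard_multipliers)[clusters - 1]
    t_event = rng_surv.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        cens_hazard = config.base_hazard * config.censoring_rate / (1 - config.censoring_rate)
        t_cens = rng_surv.exponential(1.0 / cens_hazard, size=n_total)
    else:
        t_cens = np.full(n_total, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame({"time": time, "event": event}, index=samples)

    metadata = pd.DataFrame(
        {
            "tumor_type": tumor_types,
            "time": survival["time"],
            "event": survival["event"],
            "true_cluster": clusters,
        },
        index=samples,
    )
    return SyntheticCohort(
        expr=ExpressionMatrix(expr_df, metadata=metadata),
        true_labels=pd.Series(clusters, index=samples, name="true_cluster"),
        tumor_types=tumor_types,
        survival=survival,
        config=config,
    )


def generate_counts(
    config: SyntheticConfig | None = None, scheme: SignatureScheme | None = None
) -> pd.DataFrame:
    """Poisson-lognormal count matrix matching a generated cohort's log means;
    exists to exercise upper-quartile normalization."""
    cohort = generate(config, scheme)
    rng = np.random.default_rng(np.random.SeedSequence(cohort.config.seed).spawn(4)[3])
    lam = 2.0 ** cohort.expr.expr.to_numpy() - 1.0
    counts = rng.poisson(np.clip(lam, 0, None))
    return pd.DataFrame(counts, index=cohort.expr.genes, columns=cohort.expr.samples)


def generate_regulated_profiles(
    scheme: SignatureScheme | None = None,
    target: str = "IL18",
    n_datasets: int = 3,
    shift: float = 2.0,
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    n_background: int = 200,
    seed: int = 0,
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Paired case/control log-expression profiles in which the target score's
    up-set genes are shifted up and its down-set genes down by ``shift``.

    ``n_replicates=1`` produces single-column profiles (the logFC-only screen
    mode). Output feeds screen_degs / intersect_regulated round trips.
    """
    scheme = scheme or load_scheme()
    if target not in SCORE_NAMES[1:]:
        raise ValueError(f"target must be one of {SCORE_NAMES[1:]}")
    pos, neg = scheme.scores[target]
    up, dn = list(pos.members), list(neg.members if neg else [])
    genes = pd.Index(
        up + dn + [f"BG{i:04d}" for i in range(n_background)], name="gene"
    )
    delta = np.concatenate(
        [np.full(len(up), shift), np.full(len(dn), -shift), np.zeros(n_background)]
    )
    ss = np.random.SeedSequence(seed)
    out = []
    for sub in ss.spawn(n_datasets):
        rng = np.random.default_rng(sub)
        mu = rng.normal(5.0, 1.0, size=len(genes))
        ctrl = mu[:, None] + rng.normal(0, noise_sd, size=(len(genes), n_replicates))
        case = (
            mu[:, None]
            + delta[:, None]
            + rng.normal(0, noise_sd, size=(len(genes), n_replicates))
        )
        cols = [f"rep{r}" for r in range(n_replicates)]
        out.append(
            (
                pd.DataFrame(case, index=genes, columns=cols),
                pd.DataFrame(ctrl, index=genes, columns=cols),
            )
        )
    return out
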