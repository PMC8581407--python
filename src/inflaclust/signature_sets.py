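"""Directional inflammasome-signaling gene sets: representation, loading, curation.

The signaling cascade is profiled step-wise with five named scores:

* ``IC`` — enrichment of the inflammasome-complex (sensing step) genes;
* ``CASP1``, ``GSDMD``, ``IL1B``, ``IL18`` — each the enrichment of genes
  up-regulated downstream of that node minus the enrichment of genes
  down-regulated downstream of it (the nodes are post-translationally
  controlled, so their own mRNA is a poor proxy for activity).

The packaged fixture (``data/inflammasome_sets_synthetic.gmt``) is a
synthetic stand-in with the published set sizes (15 sensing genes, 34
CASP1-regulated, 13 GSDMD-regulated, 72 IL1B-regulated, 8 IL18-regulated;
141 unique symbols in total); it is not a transcription of the original
curated lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SCORE_NAMES = ("IC", "CASP1", "GSDMD", "IL1B", "IL18")
STEPS = ("sensing", "activation", "termination")
DIRECTIONS = ("core", "up_regulated", "down_regulated")

_FIXTURE_GMT = "inflammasome_sets_synthetic.gmt"
_FIXTURE_SIDECAR = "inflammasome_sets_synthetic.directions.tsv"


class SchemeError(ValueError):
    """Raised when gene sets do not assemble into a valid five-score scheme."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set tagged with its signaling step and regulation direction."""

    name: str
    step: str
    members: tuple[str, ...]
    direction: str

    def __post_init__(self) -> None:
        if not self.members:
            raise SchemeError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise SchemeError(f"gene set {self.name!r} has duplicate symbols")
        if self.step not in STEPS:
            raise SchemeError(f"gene set {self.name!r}: unknown step {self.step!r}")
        if self.direction not in DIRECTIONS:
            raise SchemeError(
                f"gene set {self.name!r}: unknown direction {self.direction!r}"
            )
        if self.direction == "core" and self.step != "sensing":
            raise SchemeError(
                f"gene set {self.name!r}: direction 'core' is reserved for the sensing set"
            )

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SignatureScheme:
    """The five-score signature: IC plus four directional (up, down) pairs."""

    scores: Mapping[str, tuple[GeneSet, Optional[GeneSet]]]

    def __post_init__(self) -> None:
        missing = [s for s in SCORE_NAMES if s not in self.scores]
        extra = [s for s in self.scores if s not in SCORE_NAMES]
        if missing or extra:
            raise SchemeError(
                f"incomplete scheme: missing scores {missing}, unexpected {extra}"
            )
        pos, neg = self.scores["IC"]
        if neg is not None:
            raise SchemeError("IC score takes no negative (down-regulated) set")
        if pos.direction != "core":
            raise SchemeError("IC positive set must have direction 'core'")
        for name in SCORE_NAMES[1:]:
            pos, neg = self.scores[name]
            if pos.direction != "up_regulated":
                raise SchemeError(f"{name}: positive set must be up_regulated")
            if neg is None or neg.direction != "down_regulated":
                raise SchemeError(f"{name}: missing or mis-directed negative set")

    def gene_sets(self) -> list[GeneSet]:
        out: list[GeneSet] = []
        for name in SCORE_NAMES:
            pos, neg = self.scores[name]
            out.append(pos)
            if neg is not None:
                out.append(neg)
        return out

    def unique_genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for gs in self.gene_sets():
            for g in gs.members:
                seen.setdefault(g, None)
        return tuple(seen)

    def fingerprint(self) -> str:
        """Stable hash of set names, directions, and membership."""
        import hashlib

        h = hashlib.sha256()
        for gs in self.gene_sets():
            h.update(gs.name.encode())
            h.update(gs.direction.encode())
            h.update(",".join(sorted(gs.members)).encode())
        return h.hexdigest()


@dataclass(frozen=True)
class DegRecord:
    """One differentially expressed gene from a case/control screen."""

    gene: str
    logfc: float
    p: Optional[float]

    @property
    def direction(self) -> int:
        return 1 if self.logfc > 0 else (-1 if self.logfc < 0 else 0)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file (name, description, genes...) into an ordered dict."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemeError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise SchemeError(f"{path}:{ln}: gene set {name!r} is empty")
            sets[name] = genes
    if not sets:
        raise SchemeError(f"{path}: no gene sets found")
    return sets


def load_scheme(
    gmt_path: str | Path | None = None,
    direction_sidecar: str | Path | None = None,
) -> SignatureScheme:
    """Load a SignatureScheme from a GMT file plus a direction sidecar TSV.

    The sidecar has columns ``set_name, score_name, step, direction`` and must
    annotate every set in the GMT. With no arguments, the packaged synthetic
    fixture is loaded.
    """
    if gmt_path is None and direction_sidecar is None:
        data = resources.files("inflaclust.data")
        with resources.as_file(data / _FIXTURE_GMT) as g, resources.as_file(
            data / _FIXTURE_SIDECAR
        ) as s:
            return load_scheme(g, s)
    if gmt_path is None or direction_sidecar is None:
        raise SchemeError("provide both gmt_path and direction_sidecar, or neither")

    raw_sets = read_gmt(gmt_path)
    sidecar = pd.read_csv(direction_sidecar, sep="\t", dtype=str)
    required = {"set_name", "score_name", "step", "direction"}
    if not required.issubset(sidecar.columns):
        raise SchemeError(f"direction sidecar must have columns {sorted(required)}")
    annot = sidecar.set_index("set_name")

    buckets: dict[str, dict[str, GeneSet]] = {}
    for set_name, genes in raw_sets.items():
        if set_name not in annot.index:
            raise SchemeError(f"gene set {set_name!r} has no direction annotation")
        row = annot.loc[set_name]
        gs = GeneSet(
            name=set_name,
            step=str(row["step"]),
            members=tuple(genes),
            direction=str(row["direction"]),
        )
        slot = "pos" if gs.direction in ("core", "up_regulated") else "neg"
        score = str(row["score_name"])
        buckets.setdefault(score, {})
        if slot in buckets[score]:
            raise SchemeError(f"score {score}: duplicate {slot} set")
        buckets[score][slot] = gs

    scores: dict[str, tuple[GeneSet, Optional[GeneSet]]] = {}
    for name in SCORE_NAMES:
        if name not in buckets or "pos" not in buckets[name]:
            raise SchemeError(f"incomplete scheme: score {name} has no positive set")
        scores[name] = (buckets[name]["pos"], buckets[name].get("neg"))
    scheme = SignatureScheme(scores=scores)
    logger.info(
        "loaded scheme: %d sets, %d unique genes",
        len(scheme.gene_sets()),
        len(scheme.unique_genes()),
    )
    return scheme


def screen_degs(
    case_profile: pd.DataFrame | pd.Series,
    control_profile: pd.DataFrame | pd.Series,
    logfc_min: float = 1.0,
    p_max: float = 0.05,
) -> list[DegRecord]:
    """Screen differentially expressed genes between two log-scale profiles.

    Each profile is a genes x replicates frame (or a Series for a single
    replicate). With >=2 replicates per arm, p-values come from a per-gene
    Welch t-test; with a single replicate on either side the screen runs in
    logFC-only mode (p is None and only the fold-change threshold applies).
    Records are sorted by \\|logFC\\| descending.
    """
    case = case_profile.to_frame() if isinstance(case_profile, pd.Series) else case_profile
    ctrl = (
        control_profile.to_frame()
        if isinstance(control_profile, pd.Series)
        else control_profile
    )
    shared = case.index.intersection(ctrl.index)
    if len(shared) == 0:
        raise ValueError("case and control profiles share no genes")
    case = case.loc[shared]
    ctrl = ctrl.loc[shared]

    logfc = case.mean(axis=1) - ctrl.mean(axis=1)
    if case.shape[1] >= 2 and ctrl.shape[1] >= 2:
        _, pvals = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
        pvals = pd.Series(pvals, index=shared)
    else:
        pvals = pd.Series([None] * len(shared), index=shared, dtype=object)

    records = []
    for gene in shared:
        fc = float(logfc.loc[gene])
        p = pvals.loc[gene]
        if abs(fc) <= logfc_min:
            continue
        if p is not None and not (float(p) < p_max):
            continue
        records.append(DegRecord(gene=gene, logfc=fc, p=None if p is None else float(p)))
    records.sort(key=lambda r: (-abs(r.logfc), r.gene))
    return records


def intersect_regulated(
    deg_lists: Sequence[Iterable[DegRecord]],
    min_support: Optional[int] = None,
    score_name: str = "TARGET",
    step: str = "termination",
) -> tuple[Optional[GeneSet], Optional[GeneSet]]:
    """Vote-counting meta-analysis over several DEG screens.

    A gene is retained when it appears with a consistent direction in at
    least ``min_support`` of the lists (default: all of them); any gene seen
    in both directions is dropped. Returns (up_regulated, down_regulated)
    GeneSets, either of which is None when empty.
    """
    lists = [list(lst) for lst in deg_lists]
    if not lists:
        raise ValueError("intersect_regulated needs at least one DEG list")
    if min_support is None:
        min_support = len(lists)
    if min_support > len(lists):
        raise ValueError("min_support exceeds the number of DEG lists")

    up_votes: dict[str, int] = {}
    dn_votes: dict[str, int] = {}
    for lst in lists:
        seen_up = {r.gene for r in lst if r.direction > 0}
        seen_dn = {r.gene for r in lst if r.direction < 0}
        for g in seen_up:
            up_votes[g] = up_votes.get(g, 0) + 1
        for g in seen_dn:
            dn_votes[g] = dn_votes.get(g, 0) + 1

    conflicted = set(up_votes) & set(dn_votes)
    up = sorted(g for g, n in up_votes.items() if n >= min_support and g not in conflicted)
    dn = sorted(g for g, n in dn_votes.items() if n >= min_support and g not in conflicted)
    up_set = (
        GeneSet(f"{score_name}_UP", step, tuple(up), "up_regulated") if up else None
    )
    dn_set = (
        GeneSet(f"{score_name}_DN", step, tuple(dn), "down_regulated") if dn else None
    )
    return up_set, dn_set
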