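"""Cross-sample merging and somatic/germline classification.

Somatic candidates are tumor-only loci with no insertion from any other
sample nearby (positional filter); whole TE families whose somatic-call
count is explained by singleton germline polymorphisms are excluded
(type-based filter); and loci are flagged against a known-polymorphism
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .io_formats import InsertionCall, KnownTeTable

MERGE_DISTANCE_BP = 50
SOMATIC_WINDOW_BP = 10
KNOWN_TE_WINDOW_BP = 300


@dataclass
class CohortCall:
    """One per-sample insertion in cohort space (TE or not)."""

    id: str
    sample_id: str
    tissue: str  # tumor | normal
    chrom: str
    pos: int
    sv_type: str = "INS"
    strand: str = "unknown"
    te_family: str = "none"
    read_support: int = 0


@dataclass
class MergedLocus:
    locus_id: str
    chrom: str
    pos: int
    sv_type: str
    strand: str
    te_family: str = "none"
    carriers: list[tuple[str, str]] = field(default_factory=list)  # (sample, tissue)
    calls: list[CohortCall] = field(default_factory=list)
    status: str = ""  # somatic_candidate | germline | excluded_by_type
    known: bool = False


def from_insertion_calls(
    calls: Sequence[InsertionCall],
    tissues: Mapping[str, str],
    families: Optional[Mapping[str, str]] = None,
) -> list[CohortCall]:
    """Lift :class:`InsertionCall` records into cohort space."""
    out = []
    for c in calls:
        out.append(
            CohortCall(
                id=c.id,
                sample_id=c.sample_id,
                tissue=tissues.get(c.sample_id, "normal"),
                chrom=c.chrom,
                pos=c.pos,
                sv_type=c.sv_type,
                strand=c.strand,
                te_family=(families or {}).get(c.id, "none"),
                read_support=c.read_support,
            )
        )
    return out


def merge_calls(
    calls: Sequence[CohortCall], max_distance: int = MERGE_DISTANCE_BP
) -> list[MergedLocus]:
    """Single-linkage merge of same-type, same-strand calls within 50 bp.

    The merged locus position is that of the highest-support call
    (leftmost on ties).  Input order does not matter: a canonical sort is
    applied first.
    """
    ordered = sorted(calls, key=lambda c: (c.chrom, c.sv_type, c.strand, c.pos, c.sample_id, c.id))
    loci: list[MergedLocus] = []
    cluster: list[CohortCall] = []

    def _flush() -> None:
        if not cluster:
            return
        rep = min(cluster, key=lambda c: (-c.read_support, c.pos))
        families = sorted({c.te_family for c in cluster if c.te_family != "none"})
        locus = MergedLocus(
            locus_id=f"locus_{len(loci):05d}",
            chrom=rep.chrom,
            pos=rep.pos,
            sv_type=rep.sv_type,
            strand=rep.strand,
            te_family=families[0] if families else "none",
            carriers=sorted({(c.sample_id, c.tissue) for c in cluster}),
            calls=list(cluster),
        )
        loci.append(locus)

    prev = None
    for call in ordered:
        if (
            prev is not None
            and call.chrom == prev.chrom
            and call.sv_type == prev.sv_type
            and call.strand == prev.strand
            and call.pos - prev.pos <= max_distance
        ):
            cluster.append(call)
        else:
            _flush()
            cluster = [call]
        prev = call
    _flush()
    return loci


def positional_somatic_filter(
    loci: Sequence[MergedLocus],
    all_calls: Sequence[CohortCall],
    window: int = SOMATIC_WINDOW_BP,
) -> None:
    """Classify tumor-only loci with no other-sample insertion nearby.

    A locus is a somatic candidate iff every carrier is the same single
    tumor sample and no call from any *other* sample — TE or not — lies
    within ``window`` bp (inclusive) of any of its calls.  Everything else
    is germline.  Statuses are written onto the loci in place.
    """
    by_chrom: dict[str, list[CohortCall]] = {}
    for c in all_calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda c: c.pos)

    for locus in loci:
        samples = {s for s, _ in locus.carriers}
        tumor_only = len(samples) == 1 and all(t == "tumor" for _, t in locus.carriers)
        if not tumor_only:
            locus.status = "germline"
            continue
        (sample,) = samples
        near_other = False
        for call in locus.calls:
            for other in by_chrom.get(call.chrom, ()):
                if other.sample_id == sample:
                    continue
                if abs(other.pos - call.pos) <= window:
                    near_other = True
                    break
            if near_other:
                break
        locus.status = "germline" if near_other else "somatic_candidate"


def expected_false_somatic_rate(
    mean_unique_per_sample: float, mean_somatic_per_tumor: float
) -> float:
    """Percent of somatic calls expected to be singleton germline events.

    ``100 * mean unique germline insertions per sample / mean somatic
    insertions per tumor`` — the cohort-level false-somatic estimate for
    tumors lacking a matched normal.
    """
    if mean_somatic_per_tumor <= 0:
        raise ValueError("mean_somatic_per_tumor must be positive")
    return 100.0 * mean_unique_per_sample / mean_somatic_per_tumor


@dataclass
class TypeFilterInput:
    n_germline_samples: int
    unique_germline_counts_by_type: Mapping[str, float]
    n_tumors_without_normal: int
    somatic_candidate_counts_by_type: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.n_germline_samples <= 0:
            raise ValueError("n_germline_samples must be positive")


@dataclass
class TypeFilterDecision:
    family: str
    expected: float
    observed: int
    decision: str  # keep | exclude


def te_type_somatic_filter(inp: TypeFilterInput) -> list[TypeFilterDecision]:
    """Per-family keep/exclude based on expected singleton-germline counts.

    ``expected[f] = (unique germline count of f / germline samples) x
    tumors without normal``; the family is excluded when the expected count
    reaches the observed somatic-candidate count.  Expected counts stay
    real-valued — the decision never depends on a rounding rule.
    """
    out = []
    families = sorted(
        set(inp.unique_germline_counts_by_type) | set(inp.somatic_candidate_counts_by_type)
    )
    for fam in families:
        expected = (
            inp.unique_germline_counts_by_type.get(fam, 0.0)
            / inp.n_germline_samples
            * inp.n_tumors_without_normal
        )
        observed = int(inp.somatic_candidate_counts_by_type.get(fam, 0))
        decision = "exclude" if expected >= observed else "keep"
        out.append(TypeFilterDecision(fam, expected, observed, decision))
    return out


def apply_type_filter(
    loci: Sequence[MergedLocus], decisions: Sequence[TypeFilterDecision]
) -> None:
    """Mark somatic candidates of excluded families ``excluded_by_type``."""
    excluded = {d.family for d in decisions if d.decision == "exclude"}
    for locus in loci:
        if locus.status == "somatic_candidate" and locus.te_family in excluded:
            locus.status = "excluded_by_type"


def known_db_compare(
    loci: Sequence[MergedLocus], known: KnownTeTable, window: int = KNOWN_TE_WINDOW_BP
) -> None:
    """Flag loci within 300 bp of a known polymorphism of the same TE type."""
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, pos, te_type in known.records:
        by_chrom.setdefault(chrom, []).append((pos, te_type))
    for locus in loci:
        locus.known = any(
            abs(pos - locus.pos) <= window and te_type == locus.te_family
            for pos, te_type in by_chrom.get(locus.chrom, ())
        )
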