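"""Synthetic TPRT insertion cohorts with fully known ground truth.

The generator builds a random reference with planted TE consensus copies
(including 5'-truncated L1 copies, so the reference shows the usual 3'
bias), genes, replication-timing and repeat tracks; plants TPRT insertion
events with configurable truncation, twin-priming inversion, TSD or
target-site deletion, polyA tail, EN motif, 3' transduction and processed
pseudogenes; and emits per-sample VCFs, reads and a truth table.

Planted events are constructed to be exactly recoverable from error-free
reads: the reference base on each side of every junction is guaranteed to
differ from the adjacent cassette base, so flank extension stops exactly
at the planted breakpoints, and consensus/cDNA 3' termini are A-sparse so
the polyA boundary is unambiguous.  These idealizations (absent from real
genomes) are what make exact-recovery testing meaningful; see the methods
notes for what that does and does not say about real data.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._dna import revcomp
from .io_formats import (
    InsertionCall,
    IntervalTrack,
    LibraryEntry,
    SequenceLibrary,
)
from .te_annotate import FullLengthElement

log = logging.getLogger(__name__)

CHROM = "chrS"
EVENT_FLANK_BP = 450       # haplotype window radius around each event
EVENT_SPACING_BP = 1200    # minimum distance between planted events

_MOTIF_NONE_PLUS = "C"     # ref base at the nick killing AAAA/GAAA
_MOTIF_NONE_MINUS = "G"    # ref base at nick-1 killing TTTT/TTTC


@dataclass
class EventSpec:
    """One planted insertion (or polymorphic-reference deletion) event."""

    event_id: str
    family: str                    # L1|Alu|SVA|ERV|PP|orphan|random|DEL_TE
    zygosity: str                  # somatic | germline_shared
    carrier_samples: list[str]
    strand: str = "+"
    truncation_len_bp: int = 0     # 3'-anchored cassette length; 0 = full
    full_length: bool = False
    invert: bool = False
    priming_point: int = 0         # inverted cDNA start (consensus coord c)
    inverted_len_bp: int = 0
    junction_distance_bp: int = 0  # b - c: positive gap, negative overlap
    tsd_kind: str = "none"         # duplication | deletion | none
    tsd_len: int = 0
    polyA_len: int = 0
    en_motif: str = "none"
    transduction_source: Optional[str] = None
    transduction_len_bp: int = 0
    pseudogene_cdna: Optional[str] = None
    target_class: Optional[str] = None  # plant inside a repeat of this class

    def __post_init__(self) -> None:
        if self.invert and self.family not in ("L1", "Alu", "SVA", "PP"):
            raise ValueError("inversion requires a TPRT family")
        if self.tsd_kind != "none" and not (5 <= self.tsd_len <= 25):
            raise ValueError("tsd_len must be within [5, 25]")


@dataclass
class SimConfig:
    seed: int = 1
    ref_len_bp: int = 400_000
    n_samples: int = 8
    n_tumors: int = 3
    repeat_fraction_by_class: dict = field(default_factory=dict)
    events: list[EventSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sum(self.repeat_fraction_by_class.values()) > 1:
            raise ValueError("repeat fractions must sum to <= 1")

    @property
    def tumor_samples(self) -> list[str]:
        return [f"T{i}" for i in range(self.n_tumors)]

    @property
    def normal_samples(self) -> list[str]:
        return [f"N{i}" for i in range(self.n_samples - self.n_tumors)]

    @property
    def samples(self) -> list[str]:
        return self.tumor_samples + self.normal_samples

    @property
    def tissues(self) -> dict[str, str]:
        out = {s: "tumor" for s in self.tumor_samples}
        out.update({s: "normal" for s in self.normal_samples})
        return out


@dataclass
class SimGenome:
    ref: dict[str, str]
    repeats: IntervalTrack
    timing: IntervalTrack
    genes: IntervalTrack
    library: SequenceLibrary
    registry: list[FullLengthElement]
    transducible: dict[str, tuple[int, int]]  # source id -> downstream block


@dataclass
class PlacedEvent:
    spec: EventSpec
    call_template: InsertionCall       # per-sample copies made downstream
    nick_pos: int
    left_bp: int
    right_bp: int
    hap_window: tuple[int, int]
    haplotype: str
    nv_span: tuple[int, int] = (0, 0)  # noninverted cDNA on consensus
    inv_span: tuple[int, int] = (0, 0)


def _rand_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(np.asarray(list(alphabet))[rng.integers(0, len(alphabet), n)])


def _a_sparse_tail(seq: str, rng: np.random.Generator, n: int = 15) -> str:
    """Replace the last ``n`` bases with non-A bases (unambiguous polyA boundary)."""
    return seq[:-n] + _rand_dna(rng, n, "CGT")


def build_library(rng: np.random.Generator) -> SequenceLibrary:
    """Synthetic consensus library: one entry per active TE family + cDNAs.

    Lengths mirror the real elements (L1HS 6019 bp, AluY 311 bp, SVA ~1.3 kb,
    an ERV internal segment); sequences are random, which preserves every
    property the pipeline relies on (uniqueness, orientation, spans).
    """
    entries = {}
    for name, family, length in (
        ("L1HS", "L1", 6019),
        ("AluY", "Alu", 311),
        ("SVA_E", "SVA", 1316),
        ("ERVK", "ERV", 968),
    ):
        seq = _a_sparse_tail(_rand_dna(rng, length), rng)
        entries[name] = LibraryEntry(name, seq, family)
    return SequenceLibrary(entries=entries)


def simulate_genome(cfg: SimConfig) -> SimGenome:
    """Reference + annotation tracks + consensus library, all seeded.

    Plants full-length and 5'-truncated L1 copies, Alu/SVA/ERV copies,
    simple and low-complexity repeats, and two genes whose spliced
    transcripts form the cDNA library (GENE1 with three exons for regular
    processed pseudogenes, single-exon GENE2 for inverted ones).
    """
    rng = np.random.default_rng(cfg.seed)
    lib = build_library(rng)
    ref = list(_rand_dna(rng, cfg.ref_len_bp))
    repeats: list[tuple] = []
    genes: list[tuple] = []
    registry: list[FullLengthElement] = []
    transducible: dict[str, tuple[int, int]] = {}

    def paste(seq: str, pos: int) -> None:
        ref[pos: pos + len(seq)] = list(seq)

    cursor = 3000
    spacing = max(2000, (cfg.ref_len_bp - 60_000) // 40)

    def next_slot(length: int) -> int:
        nonlocal cursor
        pos = cursor + int(rng.integers(500, spacing))
        cursor = pos + length
        if cursor > cfg.ref_len_bp - 3000:
            raise ValueError("reference too short for the planned repeats")
        return pos

    # Alu copies (within the canonical-length window, for profile analyses)
    alu = lib["AluY"].sequence
    n_alu_copies = max(14, cfg.ref_len_bp // 18_000)
    for i in range(n_alu_copies):
        strand = "+" if rng.random() < 0.5 else "-"
        seq = alu if strand == "+" else revcomp(alu)
        pos = next_slot(len(seq))
        paste(seq, pos)
        repeats.append((CHROM, pos, pos + len(seq), f"SINE|{strand}|AluY", None))

    # full-length L1 copies: transduction sources
    l1 = lib["L1HS"].sequence
    for i, strand in enumerate("+-"):
        seq = l1 if strand == "+" else revcomp(l1)
        pos = next_slot(len(seq) + 400)
        paste(seq, pos)
        repeats.append((CHROM, pos, pos + len(seq), f"LINE|{strand}|L1HS", None))
        src = FullLengthElement(CHROM, pos, pos + len(seq), strand, f"L1_ref_{i}")
        registry.append(src)
        if strand == "+":
            block = (pos + len(seq), pos + len(seq) + 320)
            # A-sparse end of the transducible block: exact polyA recovery
            paste(_rand_dna(rng, 15, "CGT"), block[0] + 300 - 15)
            transducible[src.id] = block

    # 5'-truncated L1 copies (reference 3' bias)
    for i in range(4):
        trunc = int(rng.integers(800, 2500))
        seq = l1[-trunc:]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        pos = next_slot(len(seq))
        paste(seq, pos)
        repeats.append((CHROM, pos, pos + len(seq), f"LINE|{strand}|L1HS", None))

    # SVA (registry members) and ERV copies
    sva = lib["SVA_E"].sequence
    for i in range(2):
        pos = next_slot(len(sva))
        paste(sva, pos)
        repeats.append((CHROM, pos, pos + len(sva), "SVA|+|SVA_E", None))
        registry.append(FullLengthElement(CHROM, pos, pos + len(sva), "+", f"SVA_ref_{i}"))
    erv = lib["ERVK"].sequence
    for i in range(2):
        pos = next_slot(len(erv))
        paste(erv, pos)
        repeats.append((CHROM, pos, pos + len(erv), "LTR|+|ERVK", None))

    # simple / low-complexity repeats
    for i in range(2):
        seq = "AT" * 60
        pos = next_slot(len(seq))
        paste(seq, pos)
        repeats.append((CHROM, pos, pos + len(seq), "Simple repeat|+|(AT)n", None))
    for i in range(2):
        seq = "".join(rng.choice(["A", "A", "A", "C"], size=100))
        pos = next_slot(len(seq))
        paste(seq, pos)
        repeats.append((CHROM, pos, pos + len(seq), "Low complexity|+|A-rich", None))

    # genes: GENE1 (3 exons -> cDNA1), GENE2 (single exon -> cDNA2)
    exon_lens, intron_len = (180, 140, 160), 220
    pos = next_slot(sum(exon_lens) + 2 * intron_len)
    exons1 = []
    p = pos
    for j, el in enumerate(exon_lens):
        exons1.append((p, p + el))
        p += el + (intron_len if j < 2 else 0)
    paste(_rand_dna(rng, 15, "CGT"), exons1[-1][1] - 15)  # A-sparse cDNA 3' end
    genes.append((CHROM, pos, p, "GENE1", None))
    cdna1 = "".join("".join(ref[a:b]) for a, b in exons1)
    bounds1, off = [], 0
    for a, b in exons1:
        bounds1.append((off, off + (b - a)))
        off += b - a

    pos = next_slot(620)
    paste(_rand_dna(rng, 15, "CGT"), pos + 620 - 15)
    genes.append((CHROM, pos, pos + 620, "GENE2", None))
    cdna2 = "".join(ref[pos: pos + 620])

    lib.entries["cDNA1"] = LibraryEntry("cDNA1", cdna1, "cDNA", exons=bounds1)
    lib.entries["cDNA2"] = LibraryEntry("cDNA2", cdna2, "cDNA", exons=[(0, 620)])

    # two decoy gene intervals over background
    for name in ("GENE3", "GENE4"):
        pos = next_slot(1500)
        genes.append((CHROM, pos, pos + 1500, name, None))

    # replication timing: smooth random walk over 5 kb bins
    timing_records = []
    value = float(rng.normal(0, 1))
    for start in range(0, cfg.ref_len_bp, 5000):
        value = 0.8 * value + float(rng.normal(0, 0.5))
        timing_records.append((CHROM, start, min(start + 5000, cfg.ref_len_bp), "", round(value, 4)))

    return SimGenome(
        ref={CHROM: "".join(ref)},
        repeats=IntervalTrack("repeats", repeats),
        timing=IntervalTrack("timing", timing_records),
        genes=IntervalTrack("genes", genes),
        library=lib,
        registry=registry,
        transducible=transducible,
    )


# ---------------------------------------------------------------------------
# event construction


def _build_cassette(
    spec: EventSpec, genome: SimGenome
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Element-frame cassette plus planted cDNA spans (for inversions)."""
    lib = genome.library
    nv_span = inv_span = (0, 0)
    if spec.family == "random":
        rng = np.random.default_rng(zlib.crc32(spec.event_id.encode()) % 2**31)
        body = _a_sparse_tail(_rand_dna(rng, max(120, spec.truncation_len_bp or 250)), rng)
    elif spec.family == "orphan":
        src = genome.transducible[spec.transduction_source]
        body = genome.ref[CHROM][src[0]: src[0] + spec.transduction_len_bp]
    elif spec.family == "PP":
        cons = lib[spec.pseudogene_cdna].sequence
        if spec.invert:
            c, b = spec.priming_point, spec.priming_point + spec.junction_distance_bp
            a = c - spec.inverted_len_bp
            body = revcomp(cons[a:c]) + cons[b:]
            nv_span, inv_span = (b, len(cons)), (a, c)
        else:
            body = cons
    else:
        name = {"L1": "L1HS", "Alu": "AluY", "SVA": "SVA_E", "ERV": "ERVK"}[spec.family]
        cons = lib[name].sequence
        if spec.invert:
            c, b = spec.priming_point, spec.priming_point + spec.junction_distance_bp
            a = c - spec.inverted_len_bp
            body = revcomp(cons[a:c]) + cons[b:]
            nv_span, inv_span = (b, len(cons)), (a, c)
        elif spec.full_length or not spec.truncation_len_bp:
            body = cons
        else:
            body = cons[-spec.truncation_len_bp:]
        if spec.transduction_source:
            src = genome.transducible[spec.transduction_source]
            body += genome.ref[CHROM][src[0]: src[0] + spec.transduction_len_bp]
    cassette = body + "A" * spec.polyA_len
    return cassette, nv_span, inv_span


def _motif_bases(
    nick: int, strand: str, motif: str, avoid: Optional[dict[int, str]] = None
) -> dict[int, str]:
    """Reference bases that realize (or rule out) the EN motif at the nick.

    For ``motif == "none"`` one guard base suffices (a non-A/G base at the
    nick on the plus strand kills AAAA/GAAA; a non-T/C base before the nick
    on the minus strand kills TTTT/TTTC); it is chosen to also avoid any
    junction-boundary base in ``avoid``.
    """
    avoid = avoid or {}

    def pick(pos: int, options: str) -> str:
        for b in options:
            if avoid.get(pos) != b:
                return b
        return options[0]

    if strand == "+":
        if motif == "none":
            return {nick: pick(nick, "CT")}
        before = {"TTTT/A": "T", "TTTT/G": "C", "TTTC/A": "T"}[motif]
        four = "AAAA" if motif.startswith("TTTT") else "GAAA"
        bases = {nick - 1: before}
        bases.update({nick + i: four[i] for i in range(4)})
        return bases
    if motif == "none":
        return {nick - 1: pick(nick - 1, "GA")}
    four = "TTTT" if motif.startswith("TTTT") else "TTTC"
    after = motif[-1]
    bases = {nick - 4 + i: four[i] for i in range(4)}
    bases[nick] = after
    return bases


def _boundary_requirements(
    cassette: str, pos: int, tsd_kind: str, tsd_len: int
) -> list[tuple[int, str]]:
    """(ref position, forbidden base) pairs guaranteeing exact junctions."""
    first, last = cassette[0], cassette[-1]
    if tsd_kind == "duplication":
        return [(pos + tsd_len, first), (pos - 1, last)]
    if tsd_kind == "deletion":
        return [(pos, first), (pos + tsd_len - 1, last)]
    return [(pos, first), (pos - 1, last)]


def _check_consistency(
    motif_bases: dict[int, str], requirements: list[tuple[int, str]]
) -> bool:
    return all(motif_bases.get(p) != b for p, b in requirements if p in motif_bases)


class PlacementError(RuntimeError):
    pass


def place_event(
    spec: EventSpec,
    genome: SimGenome,
    ref_list: list[str],
    pos: int,
) -> Optional[PlacedEvent]:
    """Try to realize one event at reference position ``pos``.

    Writes the EN-motif (or motif-breaking) bases and any free boundary
    bases into ``ref_list``; returns None when the site conflicts with the
    forced bases, in which case the caller resamples the site.
    """
    cassette_elem, nv_span, inv_span = _build_cassette(spec, genome)
    cassette = cassette_elem if spec.strand == "+" else revcomp(cassette_elem)
    t = spec.tsd_len if spec.tsd_kind != "none" else 0

    if spec.tsd_kind == "duplication":
        left_bp, right_bp = pos + t, pos
    elif spec.tsd_kind == "deletion":
        left_bp, right_bp = pos, pos + t
    else:
        left_bp = right_bp = pos
    nick = right_bp if spec.strand == "+" else left_bp

    requirements = _boundary_requirements(cassette, pos, spec.tsd_kind, t)
    motif_bases = _motif_bases(
        nick, spec.strand, spec.en_motif, avoid=dict(requirements)
    )
    if not _check_consistency(motif_bases, requirements):
        return None
    for p, base in motif_bases.items():
        ref_list[p] = base
    for p, forbidden in requirements:
        if p in motif_bases:
            continue
        if ref_list[p] == forbidden:
            choices = [b for b in "CGTA" if b != forbidden]
            # keep motif-none guards intact: never write A/G next to the nick
            ref_list[p] = choices[0]

    ref_str = "".join(ref_list)
    chrom_ref = ref_str  # single contig
    tsd_seq = chrom_ref[pos: pos + t] if spec.tsd_kind == "duplication" else ""
    vcf_seq = tsd_seq + cassette
    w0, w1 = pos - EVENT_FLANK_BP, pos + EVENT_FLANK_BP
    if spec.tsd_kind == "duplication":
        hap = chrom_ref[w0: pos + t] + cassette + chrom_ref[pos: w1]
    elif spec.tsd_kind == "deletion":
        hap = chrom_ref[w0: pos] + cassette + chrom_ref[pos + t: w1]
    else:
        hap = chrom_ref[w0: pos] + cassette + chrom_ref[pos: w1]

    call = InsertionCall(
        id=spec.event_id,
        sample_id="",
        chrom=CHROM,
        pos=pos,
        sv_type="INS",
        seq=vcf_seq,
        read_support=0,
        strand=spec.strand,
    )
    return PlacedEvent(
        spec=spec,
        call_template=call,
        nick_pos=nick,
        left_bp=left_bp,
        right_bp=right_bp,
        hap_window=(w0, w1),
        haplotype=hap,
        nv_span=nv_span,
        inv_span=inv_span,
    )


def _inversion_boundaries_clean(cons: str, a: int, b: int, c: int) -> bool:
    """No chance base-matches across the twin-priming junction.

    Guarantees segment mapping recovers the planted cDNA spans exactly
    instead of within a few bases.
    """
    if b >= len(cons) or a < 1 or c >= len(cons):
        return False
    junction_prev = revcomp(cons[a:c])[-1]
    if b >= 1 and cons[b - 1] == junction_prev:
        return False
    if cons[a - 1] == revcomp(cons[b:])[-1]:
        return False
    if c < len(cons) and cons[c] == revcomp(cons[b:])[0]:
        return False
    return True


def simulate_tprt_insertions(
    cfg: SimConfig, genome: SimGenome
) -> tuple[dict[str, list[InsertionCall]], pd.DataFrame, list[PlacedEvent]]:
    """Plant all configured events; per-sample calls plus the truth table.

    Mutates ``genome.ref`` (EN-motif and junction-boundary bases are
    written into the reference before haplotypes are built).  Event sites
    are drawn in unique sequence unless the spec requests a target repeat
    class, and kept >= 1.2 kb apart so event windows never interact.
    """
    rng = np.random.default_rng(cfg.seed + 101)
    ref_list = list(genome.ref[CHROM])
    n = len(ref_list)
    occupied = [(max(0, s - 100), e + 100) for _, s, e, _, _ in genome.repeats.records]
    occupied += [(s, e) for _, s, e, _, _ in genome.genes.records]
    source_windows = [
        (max(0, s - 5000), e + 5000 + 3000)
        for el in genome.registry
        for s, e in [(el.start, el.end)]
    ]
    taken: list[int] = []

    def site_free(pos: int, allow_repeat: bool, avoid_sources: bool) -> bool:
        if pos < EVENT_FLANK_BP + 50 or pos > n - EVENT_FLANK_BP - 50:
            return False
        if any(abs(pos - p) < EVENT_SPACING_BP for p in taken):
            return False
        if not allow_repeat and any(s <= pos < e for s, e in occupied):
            return False
        if avoid_sources and any(s <= pos < e for s, e in source_windows):
            return False
        return True

    sine_copies = [
        (s, e) for _, s, e, lab, _ in genome.repeats.records if lab.startswith("SINE")
    ]
    used_copies: set[tuple[int, int]] = set()

    calls: dict[str, list[InsertionCall]] = {s: [] for s in cfg.samples}
    truth_rows = []
    placed_events: list[PlacedEvent] = []

    for spec in cfg.events:
        if spec.family == "DEL_TE":
            copy = next(
                (c for c in sine_copies if c not in used_copies), None
            )
            if copy is None:
                raise PlacementError("no free Alu copy for a DEL event")
            used_copies.add(copy)
            start = copy[0] - int(rng.integers(0, 30))
            end = copy[1] + int(rng.integers(0, 30))
            for sample in spec.carrier_samples:
                calls[sample].append(
                    InsertionCall(
                        id=f"{spec.event_id}.{sample}", sample_id=sample,
                        chrom=CHROM, pos=start, sv_type="DEL",
                        del_span=(start, end), read_support=6, strand="+",
                    )
                )
            truth_rows.append(_truth_row(spec, None, start))
            continue

        placed = None
        for _attempt in range(200):
            if spec.target_class:
                candidates = [c for c in sine_copies if c not in used_copies]
                if not candidates:
                    raise PlacementError("no free target copy")
                copy = candidates[int(rng.integers(0, len(candidates)))]
                pos = int(rng.integers(copy[0] + 40, copy[1] - 40))
                if not site_free(pos, allow_repeat=True, avoid_sources=False):
                    continue
            else:
                pos = int(rng.integers(EVENT_FLANK_BP + 100, n - EVENT_FLANK_BP - 100))
                if not site_free(
                    pos, allow_repeat=False,
                    avoid_sources=spec.transduction_source is not None,
                ):
                    continue
            placed = place_event(spec, genome, ref_list, pos)
            if placed is not None:
                if spec.target_class:
                    used_copies.add(copy)
                break
        if placed is None:
            raise PlacementError(f"could not place event {spec.event_id}")
        taken.append(placed.call_template.pos)
        placed_events.append(placed)
        for sample in spec.carrier_samples:
            call = replace(
                placed.call_template,
                id=f"{spec.event_id}.{sample}",
                sample_id=sample,
            )
            calls[sample].append(call)
        truth_rows.append(_truth_row(spec, placed, placed.call_template.pos))

    genome.ref[CHROM] = "".join(ref_list)
    # rebuild haplotypes against the final reference (later events may have
    # written motif bases after earlier haplotypes were built -- windows
    # never overlap, but this keeps the invariant airtight)
    for ev in placed_events:
        refreshed = place_event(ev.spec, genome, ref_list, ev.call_template.pos)
        ev.haplotype = refreshed.haplotype
        ev.call_template = replace(ev.call_template, seq=refreshed.call_template.seq)
        for sample in ev.spec.carrier_samples:
            for call in calls[sample]:
                if call.id == f"{ev.spec.event_id}.{sample}":
                    call.seq = ev.call_template.seq

    truth = pd.DataFrame(truth_rows)
    return calls, truth, placed_events


def _truth_row(spec: EventSpec, placed: Optional[PlacedEvent], pos: int) -> dict:
    expected_status = (
        "somatic_candidate" if spec.zygosity == "somatic" else "germline"
    )
    return {
        "event_id": spec.event_id,
        "chrom": CHROM,
        "pos": pos,
        "sv_type": "DEL" if spec.family == "DEL_TE" else "INS",
        "family": "Alu" if spec.family == "DEL_TE" else spec.family,
        "strand": spec.strand,
        "zygosity": spec.zygosity,
        "expected_status": expected_status,
        "carriers": ",".join(spec.carrier_samples),
        "tsd_kind": spec.tsd_kind,
        "tsd_len": spec.tsd_len if spec.tsd_kind != "none" else 0,
        "polyA_len": spec.polyA_len,
        "en_motif": spec.en_motif,
        "invert": spec.invert,
        "nv_start": placed.nv_span[0] if placed else 0,
        "nv_end": placed.nv_span[1] if placed else 0,
        "inv_start": placed.inv_span[0] if placed else 0,
        "inv_end": placed.inv_span[1] if placed else 0,
        "junction_distance": spec.junction_distance_bp if spec.invert else 0,
        "transduction_source": spec.transduction_source or "",
        "transduction_len": spec.transduction_len_bp,
        "pseudogene_cdna": spec.pseudogene_cdna or "",
        "full_length": spec.full_length,
        "nick_pos": placed.nick_pos if placed else -1,
        "left_bp": placed.left_bp if placed else -1,
        "right_bp": placed.right_bp if placed else -1,
        "target_class": spec.target_class or "",
    }


# ---------------------------------------------------------------------------
# reads


@dataclass
class ReadSet:
    """Reads per (event, sample): insertion-allele and reference-allele."""

    reads: dict[tuple[str, str], dict[str, list[tuple[str, str]]]]

    def supporting(self, event_id: str, sample: str) -> list[str]:
        return [seq for _, seq in self.reads.get((event_id, sample), {}).get("ins", [])]


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        alternatives = bases[bases != arr[i]]
        arr[i] = alternatives[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_reads(
    genome: SimGenome,
    placed: Sequence[PlacedEvent],
    cfg: SimConfig,
    depth: int = 8,
    error_rate: float = 0.0,
    seed: Optional[int] = None,
) -> ReadSet:
    """Error-prone reads over both alleles of every placed event.

    Carrier samples are heterozygous (half the reads carry the insertion);
    tumor-matched normals and non-carriers yield reference reads only.
    Substitution-only error model; deterministic under the seed.
    """
    rng = np.random.default_rng(cfg.seed + 7919 if seed is None else seed)
    reads: dict[tuple[str, str], dict[str, list[tuple[str, str]]]] = {}
    per_allele = max(2, depth // 2)
    ref_seq = genome.ref[CHROM]
    for ev in placed:
        w0, w1 = ev.hap_window
        ref_window = ref_seq[w0:w1]
        for sample in cfg.samples:
            is_carrier = sample in ev.spec.carrier_samples
            entry = {"ins": [], "ref": []}
            n_ins = per_allele if is_carrier else 0
            n_ref = per_allele
            for k in range(n_ins):
                jit0 = int(rng.integers(0, 40))
                jit1 = int(rng.integers(0, 40))
                seq = _mutate(ev.haplotype[jit0: len(ev.haplotype) - jit1], rng, error_rate)
                entry["ins"].append((f"{ev.spec.event_id}_{sample}_i{k}", seq))
            for k in range(n_ref):
                jit0 = int(rng.integers(0, 40))
                jit1 = int(rng.integers(0, 40))
                seq = _mutate(ref_window[jit0: len(ref_window) - jit1], rng, error_rate)
                entry["ref"].append((f"{ev.spec.event_id}_{sample}_r{k}", seq))
            if entry["ins"] or entry["ref"]:
                reads[(ev.spec.event_id, sample)] = entry
    return ReadSet(reads=reads)


def attach_read_support(
    calls: dict[str, list[InsertionCall]], readset: ReadSet
) -> None:
    """Fill read_support / supporting_read_ids from the simulated reads."""
    for sample, sample_calls in calls.items():
        for call in sample_calls:
            event_id = call.id.rsplit(".", 1)[0]
            entry = readset.reads.get((event_id, sample), {})
            ins = entry.get("ins", [])
            call.read_support = len(ins)
            call.supporting_read_ids = [rid for rid, _ in ins]


# ---------------------------------------------------------------------------
# default event panel


EN_MOTIF_POOL = ["TTTT/A", "TTTT/G", "TTTC/A", "none"]


def _element_first_base(family: str, lib: SequenceLibrary, spec: EventSpec) -> str:
    """First element-frame base of the cassette body (no polyA)."""
    name = {"L1": "L1HS", "Alu": "AluY", "SVA": "SVA_E", "ERV": "ERVK"}.get(family)
    if name is None:
        return "?"
    cons = lib[name].sequence
    if spec.invert:
        return revcomp(cons[spec.priming_point - 1])
    if spec.full_length or not spec.truncation_len_bp:
        return cons[0]
    return cons[-spec.truncation_len_bp:][0]


def _tsd_none_allowed(spec: EventSpec, lib: SequenceLibrary) -> bool:
    """Whether a clean target site is realizable for this motif/strand.

    The boundary-exactness rules forbid the cassette's junction base from
    equalling a motif-forced reference base; for a motif-bearing event with
    no TSD this can be impossible regardless of site, in which case the
    panel assigns a duplication instead.
    """
    if spec.en_motif == "none":
        return True
    first = _element_first_base(spec.family, lib, spec)
    if first == "?":
        return False
    if spec.strand == "+":
        forced = "A" if spec.en_motif.startswith("TTTT") else "G"
        return first != forced
    # minus strand: cassette's genome-frame last base is complement(first)
    forced_before = "T" if spec.en_motif.startswith("TTTT") else "C"
    return revcomp(first) != forced_before


def _clean_inversion_geometry(
    cons: str, rng: np.random.Generator, p_lo: int, p_hi: int,
    inv_lo: int, inv_hi: int, jd_lo: int, jd_hi: int,
) -> tuple[int, int, int]:
    """Draw (priming_point, inverted_len, junction_distance) with clean
    junction boundaries, so segment mapping recovers the spans exactly."""
    for _ in range(60):
        c = int(rng.integers(p_lo, p_hi))
        inv_len = int(rng.integers(inv_lo, inv_hi))
        jd = int(rng.integers(jd_lo, jd_hi))
        a, b = c - inv_len, c + jd
        if a < 1 or b < 1 or b >= len(cons):
            continue
        if _inversion_boundaries_clean(cons, a, b, c):
            return c, inv_len, jd
    raise PlacementError("no clean inversion geometry found")


def default_event_panel(cfg: SimConfig, n_events: int = 60) -> list[EventSpec]:
    """A study-conditions panel spanning every family and hallmark.

    Event proportions mirror the structure of real cohorts (Alu-dominated
    germline, L1-dominated soma, rare SVA/ERV/PP/orphan events); hallmark
    values sweep the TSD window (including both boundaries), polyA lengths
    around the observed medians, all three EN motifs plus motif-free sites,
    and twin-priming geometries with both gaps and overlaps.
    """
    rng = np.random.default_rng(cfg.seed + 31337)
    lib = build_library(np.random.default_rng(cfg.seed))  # same as simulate_genome
    l1 = lib["L1HS"].sequence
    tumors, normals = cfg.tumor_samples, cfg.normal_samples
    specs: list[EventSpec] = []

    def germline_carriers() -> list[str]:
        k = int(rng.integers(1, min(4, len(normals)) + 1))
        chosen = list(rng.choice(normals, size=k, replace=False))
        if rng.random() < 0.4:
            chosen.append(tumors[int(rng.integers(0, len(tumors)))])
        return sorted(set(chosen))

    def tsd_choice() -> tuple[str, int]:
        r = rng.random()
        if r < 0.66:
            return "duplication", int(rng.integers(5, 26))
        if r < 0.80:
            return "deletion", int(rng.integers(5, 14))
        return "none", 0

    def motif_choice() -> str:
        return str(rng.choice(EN_MOTIF_POOL, p=[0.6, 0.12, 0.12, 0.16]))

    def settle_tsd(spec: EventSpec) -> EventSpec:
        if spec.tsd_kind == "none" and not _tsd_none_allowed(spec, lib):
            return replace(spec, tsd_kind="duplication", tsd_len=int(rng.integers(5, 26)))
        return spec

    counts = {
        "alu": max(4, int(0.34 * n_events)),
        "l1_som": max(4, int(0.24 * n_events)),
        "l1_germ": max(3, int(0.10 * n_events)),
        "l1_trans": max(2, int(0.04 * n_events)),
        "orphan": max(2, int(0.03 * n_events)),
        "sva": max(2, int(0.07 * n_events)),
        "erv": max(2, int(0.03 * n_events)),
        "random": max(3, int(0.06 * n_events)),
        "del_te": 2,
    }

    idx = 0

    def next_id(prefix: str) -> str:
        nonlocal idx
        idx += 1
        return f"{prefix}_{idx:04d}"

    for _ in range(counts["alu"]):
        kind, length = tsd_choice()
        specs.append(settle_tsd(EventSpec(
            event_id=next_id("alu"), family="Alu", zygosity="germline_shared",
            carrier_samples=germline_carriers(),
            strand="+" if rng.random() < 0.5 else "-",
            tsd_kind=kind, tsd_len=length,
            polyA_len=int(rng.integers(20, 51)), en_motif=motif_choice(),
            target_class="SINE" if rng.random() < 0.25 else None,
        )))

    for _ in range(counts["l1_som"]):
        kind, length = tsd_choice()
        spec = EventSpec(
            event_id=next_id("l1s"), family="L1", zygosity="somatic",
            carrier_samples=[tumors[int(rng.integers(0, len(tumors)))]],
            strand="+" if rng.random() < 0.5 else "-",
            truncation_len_bp=int(rng.integers(150, 2000)),
            tsd_kind=kind, tsd_len=length,
            polyA_len=int(rng.integers(15, 61)), en_motif=motif_choice(),
        )
        if rng.random() < 0.3:
            c, inv_len, jd = _clean_inversion_geometry(
                l1, rng, 3800, 5600, 150, 700, -25, 41
            )
            spec = replace(
                spec, invert=True, priming_point=c, inverted_len_bp=inv_len,
                junction_distance_bp=jd,
            )
        specs.append(settle_tsd(spec))

    full_length_budget = 2
    for _ in range(counts["l1_germ"]):
        full = full_length_budget > 0
        if full:
            full_length_budget -= 1
        kind, length = tsd_choice()
        specs.append(settle_tsd(EventSpec(
            event_id=next_id("l1g"), family="L1", zygosity="germline_shared",
            carrier_samples=germline_carriers(),
            strand="+" if rng.random() < 0.5 else "-",
            truncation_len_bp=0 if full else int(rng.integers(400, 4000)),
            full_length=full, tsd_kind=kind, tsd_len=length,
            polyA_len=int(rng.integers(20, 51)), en_motif=motif_choice(),
        )))

    for _ in range(counts["l1_trans"]):
        specs.append(EventSpec(
            event_id=next_id("l1t"), family="L1", zygosity="germline_shared",
            carrier_samples=germline_carriers(), strand="+",
            truncation_len_bp=int(rng.integers(400, 1200)),
            tsd_kind="duplication", tsd_len=int(rng.integers(8, 18)),
            polyA_len=int(rng.integers(25, 45)), en_motif="TTTT/A",
            transduction_source="L1_ref_0", transduction_len_bp=300,
        ))

    for _ in range(counts["orphan"]):
        specs.append(EventSpec(
            event_id=next_id("orp"), family="orphan", zygosity="germline_shared",
            carrier_samples=germline_carriers(), strand="+",
            tsd_kind="duplication", tsd_len=int(rng.integers(6, 20)),
            polyA_len=int(rng.integers(25, 45)), en_motif="TTTT/A",
            transduction_source="L1_ref_0", transduction_len_bp=300,
        ))

    for _ in range(counts["sva"]):
        kind, length = tsd_choice()
        specs.append(settle_tsd(EventSpec(
            event_id=next_id("sva"), family="SVA", zygosity="germline_shared",
            carrier_samples=germline_carriers(),
            strand="+" if rng.random() < 0.5 else "-",
            truncation_len_bp=int(rng.integers(500, 1316)),
            tsd_kind=kind, tsd_len=length,
            polyA_len=int(rng.integers(20, 51)), en_motif=motif_choice(),
        )))

    for _ in range(counts["erv"]):
        specs.append(EventSpec(
            event_id=next_id("erv"), family="ERV", zygosity="germline_shared",
            carrier_samples=germline_carriers(),
            strand="+" if rng.random() < 0.5 else "-",
            tsd_kind="none", tsd_len=0, polyA_len=0, en_motif="none",
        ))

    # processed pseudogenes: two straight germline, one inverted somatic
    specs.append(EventSpec(
        event_id=next_id("pp"), family="PP", zygosity="germline_shared",
        carrier_samples=germline_carriers(), strand="+",
        tsd_kind="duplication", tsd_len=13, polyA_len=38, en_motif="TTTT/A",
        pseudogene_cdna="cDNA1",
    ))
    specs.append(EventSpec(
        event_id=next_id("pp"), family="PP", zygosity="germline_shared",
        carrier_samples=germline_carriers(), strand="-",
        tsd_kind="duplication", tsd_len=8, polyA_len=30, en_motif="TTTC/A",
        pseudogene_cdna="cDNA1",
    ))
    specs.append(EventSpec(
        event_id=next_id("pp"), family="PP", zygosity="somatic",
        carrier_samples=[tumors[0]], strand="+",
        invert=True, priming_point=380, inverted_len_bp=160,
        junction_distance_bp=-12,
        tsd_kind="duplication", tsd_len=12, polyA_len=35, en_motif="TTTT/A",
        pseudogene_cdna="cDNA2",
    ))

    for _ in range(counts["random"]):
        specs.append(EventSpec(
            event_id=next_id("rnd"), family="random", zygosity="germline_shared",
            carrier_samples=germline_carriers(),
            truncation_len_bp=int(rng.integers(150, 400)),
            tsd_kind="none", tsd_len=0, polyA_len=0, en_motif="none",
        ))

    for _ in range(counts["del_te"]):
        specs.append(EventSpec(
            event_id=next_id("del"), family="DEL_TE", zygosity="germline_shared",
            carrier_samples=germline_carriers(),
        ))

    return specs
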