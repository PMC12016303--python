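"""TE family classification and retrotransposition-hallmark annotation.

The annotator reproduces the classic target-primed reverse transcription
(TPRT) signature on each candidate insertion: a polyA tail at the element
3' end, a 5-25 bp target site duplication (or deletion), and an
endonuclease nick at the TTTT/A-family consensus motif.  Insertions are
classified against a TE consensus library; leftover 3' sequence is tested
for transductions and cDNA content for processed pseudogenes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import edlib

from ._dna import revcomp
from .align import Segment, map_segments, unique_ref_hits
from .io_formats import InsertionCall, IntervalTrack, SequenceLibrary

log = logging.getLogger(__name__)

TPRT_FAMILIES = ("L1", "Alu", "SVA", "PP")

EN_MOTIFS = ("TTTT/A", "TTTT/G", "TTTC/A")

# repeat annotation class -> TE family of a polymorphic reference element
_CLASS_TO_FAMILY = {"LINE": "L1", "SINE": "Alu", "SVA": "SVA", "LTR": "ERV"}


@dataclass
class AnnotationConfig:
    """Thresholds of the annotation stage.

    The interval bounds (TSD 5-25 bp, full length > 5990 bp, transduction
    within 3000 bp, MAPQ-proxy > 10) are the pipeline's published operating
    points; polyA and classification thresholds are this implementation's
    own documented choices.
    """

    tsd_min: int = 5
    tsd_max: int = 25
    full_length_bp: int = 5990
    transduction_window_bp: int = 3000
    polyA_min_len: int = 10
    polyA_min_purity: float = 0.8
    min_te_identity: float = 0.8
    min_te_cov: float = 0.5
    unique_mapq_min: int = 10
    del_near_bp: int = 50          # DEL breakpoint distance to a reference TE
    min_segment_len: int = 30      # minimum mapped block
    junction_flank_bp: int = 300   # reference context used for junction placement

    def __post_init__(self) -> None:
        if not (0 < self.tsd_min <= self.tsd_max):
            raise ValueError("require 0 < tsd_min <= tsd_max")
        for name in ("full_length_bp", "transduction_window_bp", "polyA_min_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TsdRecord:
    kind: str = "none"  # duplication | deletion | none
    length: int = 0
    sequence: str = ""


@dataclass
class TransductionRecord:
    chrom: str
    pos: int
    length: int
    source_element_id: str


@dataclass
class PseudogeneRecord:
    cdna_name: str
    exon_count_matched: int


@dataclass
class FullLengthElement:
    """Registry entry: a full-length TE whose downstream flank can be
    carried along as a 3' transduction."""

    chrom: str
    start: int
    end: int
    strand: str
    id: str

    def downstream_window(self, size: int) -> tuple[int, int]:
        if self.strand == "-":
            return (max(0, self.start - size), self.start)
        return (self.end, self.end + size)


@dataclass
class TEAnnotation:
    call_id: str
    te_family: str = "none"  # L1|Alu|SVA|ERV|PP|orphan|none
    te_subfamily: str = ""
    te_strand: str = "+"
    consensus_spans: list[Segment] = field(default_factory=list)
    polyA_present: bool = False
    polyA_len: int = 0
    tsd: TsdRecord = field(default_factory=TsdRecord)
    en_motif: str = "none"
    transduction: Optional[TransductionRecord] = None
    pseudogene: Optional[PseudogeneRecord] = None
    full_length: bool = False
    hallmark_count: int = 0
    # placement details used by downstream stages
    chrom: str = ""
    left_bp: int = -1
    right_bp: int = -1
    nick_pos: int = -1
    ins_seq: str = ""
    polymorphic_reference: bool = False

    def recount_hallmarks(self) -> None:
        self.hallmark_count = int(self.polyA_present) + int(self.tsd.kind != "none") + int(
            self.en_motif != "none"
        )


# ---------------------------------------------------------------------------
# consensus polishing


def _cigar_walk(cigar: str):
    n = ""
    for c in cigar:
        if c.isdigit():
            n += c
        else:
            yield int(n), c
            n = ""


def consensus_polish(supporting_reads: Sequence[str], window=None, rounds: int = 2) -> str:
    """Majority-vote consensus of reads covering one insertion locus.

    The longest read is the backbone; every other read is aligned to it
    and votes per backbone column (substitutions only; read insertions
    relative to the backbone are ignored).  Ties keep the backbone base.
    A second round realigns all reads against the first-round consensus,
    clearing vote ties caused by backbone errors.  With a single read,
    that read is returned unchanged.
    """
    if not supporting_reads:
        raise ValueError("consensus_polish requires at least one read")
    if len(supporting_reads) == 1:
        return supporting_reads[0]
    backbone = max(supporting_reads, key=len)
    coverage: list[int] = []
    for _ in range(max(1, rounds)):
        improved, coverage = _polish_round(supporting_reads, backbone)
        if improved == backbone:
            break
        backbone = improved
    # trim low-coverage edge columns: only the longest read spans them, so
    # their errors are uncorrectable and would derail junction placement
    min_cov = min(max(2, len(supporting_reads) // 3), max(coverage, default=1))
    lo = 0
    while lo < len(backbone) and coverage[lo] < min_cov:
        lo += 1
    hi = len(backbone)
    while hi > lo and coverage[hi - 1] < min_cov:
        hi -= 1
    return backbone[lo:hi]


def _polish_round(supporting_reads: Sequence[str], backbone: str) -> tuple[str, list[int]]:
    votes = [{} for _ in backbone]
    for b, base in enumerate(backbone):
        votes[b][base] = votes[b].get(base, 0) + 1
    for read in supporting_reads:
        if read == backbone:
            continue
        # infix alignment: read ends are free, so length jitter between
        # reads never forces gaps into the aligned interior
        res = edlib.align(read, backbone, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        b = res["locations"][0][0]
        span = res["locations"][0][1] + 1 - b
        if span == len(read):
            # substitution-only placement: vote column by column
            for i, base in enumerate(read):
                votes[b + i][base] = votes[b + i].get(base, 0) + 1
            continue
        q = 0
        for length, op in _cigar_walk(res["cigar"]):
            if op in "=X":
                for i in range(length):
                    votes[b + i][read[q + i]] = votes[b + i].get(read[q + i], 0) + 1
                b += length
                q += length
            elif op == "D":  # gap in read relative to backbone
                b += length
            elif op == "I":
                q += length
    out = []
    for b, base in enumerate(backbone):
        best = max(votes[b].items(), key=lambda kv: (kv[1], kv[0] == base))
        out.append(best[0])
    return "".join(out), [sum(v.values()) for v in votes]


# ---------------------------------------------------------------------------
# junction placement


def locate_junctions(
    hap: str, ref_window: str, window_start: int
) -> tuple[int, int, str]:
    """Place the insertion junctions of a locus haplotype on the reference.

    ``hap`` is the (polished) sample haplotype across the locus and
    ``ref_window`` the corresponding reference sequence starting at
    ``window_start``.  Returns ``(left_bp, right_bp, ins_seq)``: the
    reference coordinate where the left flank alignment ends, where the
    right flank alignment begins, and the inserted sequence between them.
    ``left_bp > right_bp`` means both flanks cover the duplicated target
    bases (a TSD); ``left_bp < right_bp`` a target-site deletion.
    """
    res = edlib.align(hap[: min(60, len(hap))], ref_window, mode="HW", task="locations")
    ls = res["locations"][0][0] if res["editDistance"] >= 0 else 0
    i = _extend_with_bridging(hap, ref_window, ls)
    left_bp = window_start + ls + i

    hap_r, ref_r = hap[::-1], ref_window[::-1]
    res = edlib.align(hap_r[: min(60, len(hap_r))], ref_r, mode="HW", task="locations")
    rs = res["locations"][0][0] if res["editDistance"] >= 0 else 0
    j = _extend_with_bridging(hap_r, ref_r, rs)
    right_bp = window_start + len(ref_window) - rs - j

    ins_seq = hap[i : len(hap) - j]
    return left_bp, right_bp, ins_seq


_BRIDGE_WINDOW = 20
_BRIDGE_MIN_MATCHES = 18


def _extend_with_bridging(hap: str, ref: str, offset: int) -> int:
    """Length of the hap prefix aligning to ``ref[offset:]`` columnwise.

    Extension crosses an isolated mismatch (a residual consensus error)
    only when the following 20 bases match at >= 90%; at a true insertion
    junction the downstream sequence is unrelated to the reference, so the
    bridge test fails there and the extension stops exactly at the
    junction.
    """
    i = 0
    n = min(len(hap), len(ref) - offset)
    while i < n:
        if hap[i] == ref[offset + i]:
            i += 1
            continue
        end = min(n, i + 1 + _BRIDGE_WINDOW)
        window = range(i + 1, end)
        if len(window) >= _BRIDGE_WINDOW:
            matches = sum(hap[k] == ref[offset + k] for k in window)
            if matches >= _BRIDGE_MIN_MATCHES:
                i += 1  # consensus error; bridge and keep extending
                continue
        break
    return i


# ---------------------------------------------------------------------------
# hallmark detectors


def detect_polyA(seq: str, cfg: AnnotationConfig) -> tuple[bool, int]:
    """Longest A-rich suffix of ``seq`` (element 3' end at the sequence end).

    The suffix must start and end in A, have A-purity >=
    ``polyA_min_purity`` and length >= ``polyA_min_len``; the longest
    qualifying suffix is reported.  (Without the leading-A condition any
    tail would creep into the element body one non-A base at a time.)
    """
    if not seq or seq[-1] != "A":
        return False, 0
    a_count = 0
    best = 0
    for i, base in enumerate(reversed(seq), start=1):
        if base == "A":
            a_count += 1
            if a_count / i >= cfg.polyA_min_purity:
                best = i
    if best >= cfg.polyA_min_len:
        return True, best
    return False, 0


def detect_tsd(
    ref: Mapping[str, str], chrom: str, left_bp: int, right_bp: int, cfg: AnnotationConfig
) -> TsdRecord:
    """Target-site duplication/deletion from the two flank placements.

    ``d = left_bp - right_bp``: within [tsd_min, tsd_max] the flanks overlap
    on the reference (duplication of those bases); ``-d`` in the window is a
    target-site deletion.
    """
    seq = ref[chrom]
    for bp in (left_bp, right_bp):
        if bp < 0 or bp > len(seq):
            raise ValueError(f"breakpoint {bp} outside {chrom}")
    d = left_bp - right_bp
    if cfg.tsd_min <= d <= cfg.tsd_max:
        return TsdRecord("duplication", d, seq[right_bp:left_bp])
    if cfg.tsd_min <= -d <= cfg.tsd_max:
        return TsdRecord("deletion", -d, seq[left_bp:right_bp])
    return TsdRecord()


def detect_en_cut(upstream: str, downstream: str) -> str:
    """Endonuclease motif at the first-strand nick.

    ``upstream`` ends at the nick on the nick strand; ``downstream`` starts
    immediately 3' of it.  Returns "TTTT/A", "TTTT/G", "TTTC/A" or "none".
    """
    if len(upstream) < 4 or len(downstream) < 1:
        raise ValueError("EN context shorter than 5 bp")
    four, nxt = upstream[-4:], downstream[0]
    if four == "TTTT" and nxt == "A":
        return "TTTT/A"
    if four == "TTTT" and nxt == "G":
        return "TTTT/G"
    if four == "TTTC" and nxt == "A":
        return "TTTC/A"
    return "none"


def en_context(ref_seq: str, nick: int, strand: str, flank: int = 10) -> tuple[str, str]:
    """Reference context around the first-strand nick, on the nick strand.

    For a plus-strand insertion the nick strand is the reverse strand at the
    polyA-side junction (the genomic A-tract the element polyA annealed to
    reads TTTT on that strand); for a minus-strand insertion the motif lies
    on the forward strand.  Returns (upstream-ending-at-nick, downstream).
    """
    if strand == "-":
        return ref_seq[max(0, nick - flank): nick], ref_seq[nick: nick + flank]
    return (
        revcomp(ref_seq[nick: nick + flank]),
        revcomp(ref_seq[max(0, nick - flank): nick]),
    )


# ---------------------------------------------------------------------------
# classification


def _coverage(segments: Sequence[Segment], seq_len: int) -> float:
    if not seq_len:
        return 0.0
    covered = [False] * seq_len
    for seg in segments:
        for i in range(seg.q_start, seg.q_end):
            covered[i] = True
    return sum(covered) / seq_len


def _weighted_identity(segments: Sequence[Segment]) -> float:
    total = sum(s.q_len for s in segments)
    if not total:
        return 0.0
    return sum(s.q_len * s.identity for s in segments) / total


def _trim_tails(seq: str, cfg: AnnotationConfig) -> tuple[str, int, int]:
    """Strip an A-rich suffix and/or T-rich prefix before TE alignment.

    Returns (core, suffix_a_len, prefix_t_len).
    """
    ok_a, a_len = detect_polyA(seq, cfg)
    ok_t, t_len = detect_polyA(revcomp(seq), cfg)
    a_len = a_len if ok_a else 0
    t_len = t_len if ok_t else 0
    if a_len and t_len and a_len + t_len >= len(seq):
        # degenerate A/T homopolymer insertion
        if a_len >= t_len:
            t_len = 0
        else:
            a_len = 0
    core = seq[t_len: len(seq) - a_len if a_len else len(seq)]
    return core, a_len, t_len


def classify_te(
    seq: str, lib: SequenceLibrary, cfg: AnnotationConfig
) -> tuple[str, str, str, list[Segment]]:
    """Assign a TE family by local alignment against the consensus library.

    All entries of TE families are tried on both strands; the entry with
    the highest total aligned score passing the identity and coverage
    thresholds wins (ties: higher identity, then lexicographic name).  A
    sequence with no TE hit but a terminal polyA tail is an ``orphan``
    (candidate orphan transduction); otherwise ``none``.  The element
    strand is the orientation of the polyA-proximal (noninverted) segment.
    """
    entries = lib.by_family("L1", "Alu", "SVA", "ERV", "Other")
    if not entries:
        raise ValueError("empty TE library")
    if len(seq) < 50:
        return "none", "", "+", []
    core, a_len, t_len = _trim_tails(seq, cfg)
    has_tail = bool(a_len or t_len)
    candidates = []  # (-score, -identity, name, entry, segments)
    for entry in sorted(entries, key=lambda e: e.name):
        segs = map_segments(core, entry.sequence, min_len=cfg.min_segment_len,
                            min_identity=cfg.min_te_identity)
        segs = [s for s in segs if s.identity >= cfg.min_te_identity]
        if not segs:
            continue
        cov = _coverage(segs, len(core))
        if cov < cfg.min_te_cov:
            continue
        score = sum(s.q_len * s.identity for s in segs)
        ident = _weighted_identity(segs)
        candidates.append((-score, -ident, entry.name, entry, segs))
    best = min(candidates) if candidates else None
    if best is None:
        if has_tail:
            return "orphan", "", ("+" if a_len >= t_len else "-"), []
        return "none", "", "+", []
    _, _, _, entry, segs = best
    # strand: orientation of the segment adjacent to the polyA tail
    if a_len and not t_len:
        strand = max(segs, key=lambda s: s.q_end).orientation
    elif t_len and not a_len:
        strand = min(segs, key=lambda s: s.q_start).orientation
    else:
        strand = max(segs, key=lambda s: s.q_len).orientation
    # shift segment query coordinates back onto the untrimmed sequence
    segs = [
        Segment(s.q_start + t_len, s.q_end + t_len, s.t_start, s.t_end, s.orientation, s.identity)
        for s in segs
    ]
    return entry.family, entry.name, strand, segs


def detect_pseudogene(
    seq: str, lib: SequenceLibrary, cfg: AnnotationConfig
) -> Optional[PseudogeneRecord]:
    """Processed-pseudogene call: the insertion is a cDNA copy.

    Requires identity >= ``min_te_identity`` over >= ``min_te_cov`` of the
    non-polyA insertion length against one cDNA entry.  TE classification
    takes precedence upstream; this is only consulted for non-TE calls.
    """
    if len(seq) < 200:
        return None
    core, _, _ = _trim_tails(seq, cfg)
    best = None
    for entry in sorted(lib.by_family("cDNA"), key=lambda e: e.name):
        segs = map_segments(core, entry.sequence, min_len=cfg.min_segment_len,
                            min_identity=cfg.min_te_identity)
        if not segs:
            continue
        cov = _coverage(segs, len(core))
        ident = _weighted_identity(segs)
        if cov < cfg.min_te_cov or ident < cfg.min_te_identity:
            continue
        score = sum(s.q_len * s.identity for s in segs)
        if best is None or score > best[0]:
            if entry.exons:
                matched = 0
                for (a, b) in entry.exons:
                    hit = any(min(s.t_end, b) - max(s.t_start, a) >= min(20, b - a) for s in segs)
                    matched += bool(hit)
            else:
                matched = len(segs)
            best = (score, PseudogeneRecord(entry.name, matched))
    return best[1] if best else None


def detect_transduction(
    tail_seq: str,
    chrom: str,
    target_span: tuple[int, int],
    ref: Mapping[str, str],
    registry: Sequence[FullLengthElement],
    cfg: AnnotationConfig,
) -> Optional[TransductionRecord]:
    """3' transduction: unique non-TE tail downstream of a full-length element.

    The tail must map uniquely to the reference (away from the target site)
    and lie within ``transduction_window_bp`` downstream of the 3' end of a
    registered full-length element.
    """
    if len(tail_seq) < cfg.min_segment_len:
        return None
    pad = cfg.transduction_window_bp
    hits = unique_ref_hits(
        tail_seq, dict(ref), mapq_margin=max(2, cfg.unique_mapq_min // 2),
        exclude=(chrom, target_span[0] - pad, target_span[1] + pad),
    )
    if not hits:
        return None
    h_chrom, h_start, h_end, _ = hits[0]
    for element in registry:
        if element.chrom != h_chrom:
            continue
        w_start, w_end = element.downstream_window(cfg.transduction_window_bp)
        if h_start < w_end and h_end > w_start:
            return TransductionRecord(h_chrom, h_start, len(tail_seq), element.id)
    return None


# ---------------------------------------------------------------------------
# orchestration


def _uncovered_3p_tail(
    ins_seq: str, segs: Sequence[Segment], strand: str, a_len: int, t_len: int
) -> str:
    """Non-TE sequence between the TE 3' end and the polyA, element frame.

    Segment coordinates are on ``ins_seq``; the polyA occupies its last
    ``a_len`` bases (plus strand) or, as a T-tract, its first ``t_len``
    bases (minus strand).
    """
    if not segs:
        return ""
    if strand == "+":
        te_end = max(s.q_end for s in segs)
        return ins_seq[te_end: len(ins_seq) - a_len]
    te_start = min(s.q_start for s in segs)
    return revcomp(ins_seq[t_len: te_start])


def annotate_insertion(
    call: InsertionCall,
    ref: Mapping[str, str],
    lib: SequenceLibrary,
    cfg: AnnotationConfig,
    reads: Optional[Sequence[str]] = None,
    repeats: Optional[IntervalTrack] = None,
    full_length_registry: Optional[Sequence[FullLengthElement]] = None,
) -> TEAnnotation:
    """Full hallmark annotation of one insertion (or polymorphic-TE deletion).

    For INS calls the locus haplotype (a polished read consensus when
    ``reads`` are given, otherwise the VCF sequence embedded in its
    reference flanks) is placed on the reference to obtain the two junction
    coordinates; classification and every hallmark detector run from that
    placement.  Target-site deletions are only recoverable when reads are
    provided, since a bare VCF INS record cannot encode the missing bases.
    """
    ann = TEAnnotation(call_id=call.id, chrom=call.chrom)

    if call.sv_type == "DEL":
        ann.polymorphic_reference = True
        if repeats is not None and call.del_span is not None:
            start, end = call.del_span
            for chrom, r_start, r_end, full_label, _ in repeats.records:
                label = full_label.split("|")[0]
                if chrom != call.chrom or label not in _CLASS_TO_FAMILY:
                    continue
                if (
                    abs(start - r_start) <= cfg.del_near_bp
                    and abs(end - r_end) <= cfg.del_near_bp
                ):
                    ann.te_family = _CLASS_TO_FAMILY[label]
                    break
        return ann

    chrom_seq = ref[call.chrom]
    if reads:
        hap = consensus_polish(list(reads))
        # the reference window must cover the haplotype's full extent
        flank = len(hap) + 50
    else:
        flank = cfg.junction_flank_bp
    w_start = max(0, call.pos - flank)
    w_end = min(len(chrom_seq), call.pos + flank)
    ref_window = chrom_seq[w_start:w_end]
    if not reads:
        hap = chrom_seq[w_start: call.pos] + call.seq + chrom_seq[call.pos: w_end]
    left_bp, right_bp, ins_seq = locate_junctions(hap, ref_window, w_start)
    if not ins_seq:
        # placement collapsed (e.g. insertion identical to reference); keep
        # the raw call sequence so classification still sees something
        ins_seq = call.seq
        left_bp = right_bp = call.pos
    ann.left_bp, ann.right_bp, ann.ins_seq = left_bp, right_bp, ins_seq

    family, subfamily, strand, segs = classify_te(ins_seq, lib, cfg)
    ann.te_family, ann.te_subfamily, ann.te_strand = family, subfamily, strand
    ann.consensus_spans = segs

    core, a_len, t_len = _trim_tails(ins_seq, cfg)

    if family in ("none", "orphan"):
        pp = detect_pseudogene(ins_seq, lib, cfg)
        if pp is not None:
            ann.te_family, ann.pseudogene = "PP", pp
            family = "PP"
            cdna_segs = map_segments(core, lib[pp.cdna_name].sequence,
                                     min_len=cfg.min_segment_len,
                                     min_identity=cfg.min_te_identity)
            if cdna_segs:
                strand = max(cdna_segs, key=lambda s: s.q_len).orientation
                ann.te_strand = strand

    element_seq = ins_seq if strand == "+" else revcomp(ins_seq)
    ann.polyA_present, ann.polyA_len = detect_polyA(element_seq, cfg)

    ann.tsd = detect_tsd(ref, call.chrom, left_bp, right_bp, cfg)

    nick = right_bp if strand == "+" else left_bp
    ann.nick_pos = nick
    up, down = en_context(chrom_seq, nick, strand)
    try:
        ann.en_motif = detect_en_cut(up, down)
    except ValueError:
        ann.en_motif = "none"

    if family == "L1":
        aligned = sum(s.q_len for s in segs)
        ann.full_length = aligned > cfg.full_length_bp

    if family in ("L1", "SVA", "Alu") and full_length_registry:
        tail = _uncovered_3p_tail(ins_seq, segs, strand, a_len, t_len)
        if tail:
            ann.transduction = detect_transduction(
                tail, call.chrom, (min(left_bp, right_bp), max(left_bp, right_bp)),
                ref, full_length_registry, cfg,
            )
    elif family == "orphan" and full_length_registry:
        tail = core if strand == "+" else revcomp(core)
        ann.transduction = detect_transduction(
            tail, call.chrom, (min(left_bp, right_bp), max(left_bp, right_bp)),
            ref, full_length_registry, cfg,
        )

    ann.recount_hallmarks()
    return ann


def hallmark_filter(anns: Sequence[TEAnnotation]) -> list[TEAnnotation]:
    """Drop TPRT-type insertions carrying no TPRT hallmark at all.

    L1/Alu/SVA/PP calls with zero of {polyA, TSD-or-TS-deletion, EN cut}
    are most likely not retrotransposition products; other families pass
    unconditionally.  Idempotent; never grows the list.
    """
    return [
        a for a in anns
        if a.te_family not in TPRT_FAMILIES or a.hallmark_count > 0 or a.polymorphic_reference
    ]
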