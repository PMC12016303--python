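"""Read-level evidence for insertion calls.

Each insertion locus becomes a two-path sequence graph (a bubble): the
insertion path runs left flank -> insertion -> right flank, the reference
path runs through the unmodified reference span.  Reads are assigned to at
most one path, and the package's nanopore supporting-read rules, the
short-read discordant-pair proxy, and the manual-curation decision rules
are exposed as pure functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import edlib

from .io_formats import InsertionCall

FLANK_BP = 2000
SUPPORT_OVERLAP_NT = 50
DISCORDANT_WINDOW_BP = 100
DISCORDANT_MATE_BP = 600
SOFTCLIP_MIN_BP = 30
SOFTCLIP_END_BP = 10
NANOPORE_POS_BP = 100
TUMOR_MIN_SUPPORT = 3
ILLUMINA_GERMLINE_MIN_DISCORDANT = 4
DISCORDANT_RATIO_THRESHOLD = 0.10


@dataclass
class AlleleGraph:
    """Single-bubble allele graph for one insertion locus."""

    locus_id: str
    chrom: str
    left_span: tuple[int, int]    # reference coords of the left flank node
    right_span: tuple[int, int]   # reference coords of the right flank node
    left_flank: str
    insertion: str
    right_flank: str
    reference_span: str           # reference allele between the flanks
    truncated: bool = False       # flank shorter than requested (contig end)

    @property
    def insertion_path(self) -> str:
        return self.left_flank + self.insertion + self.right_flank

    @property
    def reference_path(self) -> str:
        return self.left_flank + self.reference_span + self.right_flank

    def node_offsets(self, path: str) -> dict[str, tuple[int, int]]:
        mid = self.insertion if path == "insertion" else self.reference_span
        lf = len(self.left_flank)
        return {
            "left_flank": (0, lf),
            ("insertion" if path == "insertion" else "reference_span"): (lf, lf + len(mid)),
            "right_flank": (lf + len(mid), lf + len(mid) + len(self.right_flank)),
        }

    def to_gfa(self) -> str:
        lines = ["H\tVN:Z:1.0"]
        nodes = [
            ("left_flank", self.left_flank),
            ("insertion", self.insertion),
            ("reference_span", self.reference_span),
            ("right_flank", self.right_flank),
        ]
        for name, seq in nodes:
            lines.append(f"S\t{self.locus_id}:{name}\t{seq}")
        for a, b in (
            ("left_flank", "insertion"),
            ("insertion", "right_flank"),
            ("left_flank", "reference_span"),
            ("reference_span", "right_flank"),
        ):
            lines.append(f"L\t{self.locus_id}:{a}\t+\t{self.locus_id}:{b}\t+\t0M")
        return "\n".join(lines) + "\n"


def build_allele_graph(
    ref: Mapping[str, str], call: InsertionCall, flank: int = FLANK_BP
) -> AlleleGraph:
    """Bubble graph with ~``flank`` bp reference flanks around the call.

    Flanks are truncated (and the graph flagged) at contig ends.  The
    reference span between the flank nodes is empty for a clean insertion;
    for calls whose flank placements overlap (a TSD) the duplicated bases
    are carried in both flanks, which is how the reads see them.
    """
    if call.sv_type != "INS" or not call.seq:
        raise ValueError("allele graph requires an INS call with sequence")
    chrom_seq = ref[call.chrom]
    left_start = max(0, call.pos - flank)
    right_end = min(len(chrom_seq), call.pos + flank)
    truncated = (call.pos - left_start < flank) or (right_end - call.pos < flank)
    return AlleleGraph(
        locus_id=call.id,
        chrom=call.chrom,
        left_span=(left_start, call.pos),
        right_span=(call.pos, right_end),
        left_flank=chrom_seq[left_start: call.pos],
        insertion=call.seq,
        right_flank=chrom_seq[call.pos: right_end],
        reference_span="",
        truncated=truncated,
    )


@dataclass
class NodeInterval:
    node: str   # left_flank | insertion | reference_span | right_flank
    start: int  # node-local, 0-based half-open
    end: int


def align_read_to_graph(graph: AlleleGraph, read: str) -> list[NodeInterval]:
    """Bundled path aligner: best of the two linear path sequences.

    For a single-bubble graph, aligning against both path sequences and
    keeping the better (reference path on ties) is equivalent to a general
    graph alignment.  The aligned span is projected onto node intervals.
    """
    results = []
    for path_name in ("reference", "insertion"):
        path_seq = graph.insertion_path if path_name == "insertion" else graph.reference_path
        if not path_seq:
            continue
        res = edlib.align(read, path_seq, mode="HW", task="locations")
        if res["editDistance"] >= 0:
            start, end = res["locations"][0]
            results.append((res["editDistance"], path_name == "insertion", path_name, start, end + 1))
    if not results:
        return []
    results.sort()
    _, _, path_name, start, end = results[0]
    offsets = graph.node_offsets(path_name)
    chain = []
    for node, (n_start, n_end) in offsets.items():
        ov_start, ov_end = max(start, n_start), min(end, n_end)
        if ov_end > ov_start:
            chain.append(NodeInterval(node, ov_start - n_start, ov_end - n_start))
    return chain


def count_graph_support(
    graph: AlleleGraph, read_alignments: Sequence[Sequence[NodeInterval]]
) -> tuple[int, int]:
    """Count reads supporting the insertion path vs the reference path.

    A read supports the insertion when it overlaps a flank node and the
    insertion node for >= 50 nt each; it supports the reference when its
    aligned span encloses the 50 nt on either side of the reference
    junction.  A read counts for at most one path.
    """
    ins_support = ref_support = 0
    lf = len(graph.left_flank)
    mid = len(graph.reference_span)
    for chain in read_alignments:
        by_node = {iv.node: iv for iv in chain}
        ins_iv = by_node.get("insertion")
        flank_nt = max(
            (by_node[n].end - by_node[n].start) if n in by_node else 0
            for n in ("left_flank", "right_flank")
        )
        if ins_iv is not None and (ins_iv.end - ins_iv.start) >= SUPPORT_OVERLAP_NT and flank_nt >= SUPPORT_OVERLAP_NT:
            ins_support += 1
            continue
        if "insertion" not in by_node:
            # reference-path chain; check enclosure of the junction span
            left = by_node.get("left_flank")
            right = by_node.get("right_flank")
            mid_iv = by_node.get("reference_span")
            left_ok = left is not None and left.end == lf and left.end - left.start >= SUPPORT_OVERLAP_NT
            right_ok = right is not None and right.start == 0 and right.end - right.start >= SUPPORT_OVERLAP_NT
            mid_ok = mid == 0 or (mid_iv is not None and mid_iv.start == 0 and mid_iv.end == mid)
            if left_ok and right_ok and mid_ok:
                ref_support += 1
    return ins_support, ref_support


@dataclass
class NanoporeEvidence:
    """Candidate insertion-bearing or soft-clipped reads from a normal."""

    insertions: list[tuple[int, int]] = field(default_factory=list)  # (pos, length)
    softclips: list[tuple[int, int]] = field(default_factory=list)   # (clip_len, clip_end_pos)


def nanopore_support_reads(call: InsertionCall, evidence: NanoporeEvidence) -> int:
    """Nanopore supporting-read count in a normal sample.

    An insertion-bearing read counts when its length is within a factor of
    two of the call and its position within 100 bp; a soft-clipped read
    counts when the clip exceeds 30 bp and ends within 10 bp of the
    breakpoint.
    """
    n = 0
    call_len = len(call.seq)
    for pos, length in evidence.insertions:
        if abs(pos - call.pos) <= NANOPORE_POS_BP and call_len / 2 <= length <= 2 * call_len:
            n += 1
    for clip_len, clip_end in evidence.softclips:
        if clip_len > SOFTCLIP_MIN_BP and abs(clip_end - call.pos) <= SOFTCLIP_END_BP:
            n += 1
    return n


@dataclass
class ReadPair:
    pos: int            # mapped position of the read near the breakpoint
    mate_chrom: str
    mate_pos: int
    chrom: str = ""


def discordant_ratio(
    call: InsertionCall, pairs: Sequence[ReadPair]
) -> tuple[int, int, Optional[float]]:
    """Discordant short-read pairs within 100 bp of the breakpoint.

    A pair is discordant when the mate maps to a different chromosome or
    more than 600 bp away.  Returns (discordant, local_reads, ratio);
    ratio is None when no read falls in the window.
    """
    discordant = local = 0
    for pair in pairs:
        if abs(pair.pos - call.pos) > DISCORDANT_WINDOW_BP:
            continue
        local += 1
        chrom = pair.chrom or call.chrom
        if pair.mate_chrom != chrom or abs(pair.mate_pos - pair.pos) > DISCORDANT_MATE_BP:
            discordant += 1
    return discordant, local, (discordant / local if local else None)


def auto_curate(
    call: InsertionCall,
    tumor_support: int,
    normal_nanopore: Optional[int] = None,
    normal_discordant: Optional[int] = None,
    normal_depth_ok: bool = True,
) -> str:
    """Automatic version of the manual-curation decision rules.

    ``false_positive`` below 3 tumor supporting reads; ``germline`` on any
    normal evidence (>= 1 nanopore supporting read, or >= 4 discordant
    Illumina reads); ``true_somatic`` when a clean normal channel certifies
    it — nanopore at zero, or Illumina below 4 discordant reads at adequate
    (>= 40x) depth; ``unclassifiable`` without any usable normal channel.
    """
    if tumor_support < TUMOR_MIN_SUPPORT:
        return "false_positive"
    if normal_nanopore is None and normal_discordant is None:
        return "unclassifiable"
    if normal_nanopore is not None and normal_nanopore >= 1:
        return "germline"
    if normal_discordant is not None and normal_discordant >= ILLUMINA_GERMLINE_MIN_DISCORDANT:
        return "germline"
    if normal_nanopore is not None and normal_nanopore == 0:
        return "true_somatic"
    if normal_discordant is not None and normal_discordant < ILLUMINA_GERMLINE_MIN_DISCORDANT:
        return "true_somatic" if normal_depth_ok else "unclassifiable"
    return "unclassifiable"
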