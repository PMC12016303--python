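"""Twin-priming (5' inversion) detection and characterization.

Twin priming is the TPRT variant in which both target-site DNA strands
prime reverse transcription, yielding an insertion made of two cDNAs with
opposite orientations: the polyA-primed *noninverted* cDNA covering the
element 3' end, and an internally primed *inverted* cDNA 5' of it.  The
detector applies three criteria in order: (1) two consensus-mapped areas
of opposite orientation; (2) one consensus-mapped area plus one uniquely
reference-mapped area of opposite orientation; (3) two uniquely mapped
areas in opposite orientation whose reference loci are within 500 bp.

Span convention: both cDNA spans are stored ascending on the L1 consensus;
``junction_distance = noninverted_span.start - inverted_span.end``.  A
positive distance is a consensus interval reverse-transcribed into neither
cDNA (a gap); a negative distance is an interval present in both cDNAs (an
overlap), whose length equals the shared consensus interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from ._dna import revcomp
from .align import map_segments, unique_ref_hits
from .te_annotate import AnnotationConfig, TEAnnotation, _trim_tails

INVERSION_PROXIMITY_BP = 500  # criterion-3 distance bound between unique loci


@dataclass
class InversionCall:
    call_id: str
    criterion: int
    noninverted_span: tuple[int, int]  # ascending on consensus; polyA-primed cDNA
    inverted_span: tuple[int, int]     # ascending on consensus; internally primed cDNA
    noninverted_len: int = 0
    inverted_len: int = 0

    def __post_init__(self) -> None:
        if not self.noninverted_len:
            self.noninverted_len = self.noninverted_span[1] - self.noninverted_span[0]
        if not self.inverted_len:
            self.inverted_len = self.inverted_span[1] - self.inverted_span[0]

    @property
    def sum_len(self) -> int:
        return self.noninverted_len + self.inverted_len


def junction_distance(inv: InversionCall) -> int:
    """Distance between noninverted cDNA end and inverted cDNA start.

    Positive = gap (consensus bases in neither cDNA); negative = overlap
    (bases reverse-transcribed into both cDNAs).
    """
    if inv.noninverted_span is None or inv.inverted_span is None:
        raise ValueError("both cDNA spans must be mapped to the consensus")
    return inv.noninverted_span[0] - inv.inverted_span[1]


def detect_inversion(
    ann: TEAnnotation,
    seq: str,
    l1_consensus: str,
    cfg: AnnotationConfig,
    ref: Optional[Mapping[str, str]] = None,
) -> Optional[InversionCall]:
    """Detect a 5' inversion in one annotated insertion.

    Criteria 1-2 are evaluated for L1 and processed-pseudogene calls
    against the L1 consensus; criterion 3 uses unique reference placements
    and needs ``ref``.  The polyA tail is excluded from all spans and
    lengths.  Returns the first satisfied criterion or ``None``.
    """
    core, a_len, t_len = _trim_tails(seq, cfg)
    if ann.te_strand == "-":
        core = revcomp(core)  # element frame: noninverted cDNA reads forward

    segs = []
    if ann.te_family in ("L1", "PP"):
        segs = map_segments(core, l1_consensus, min_len=cfg.min_segment_len,
                            min_identity=cfg.min_te_identity)
        fwd = [s for s in segs if s.orientation == "+"]
        rev = [s for s in segs if s.orientation == "-"]
        # criterion 1: two consensus-mapped areas in opposite orientations
        if fwd and rev:
            noninv = max(fwd, key=lambda s: s.q_end)    # polyA-proximal
            invseg = max(rev, key=lambda s: s.q_len)
            return InversionCall(
                ann.call_id, 1,
                noninverted_span=(noninv.t_start, noninv.t_end),
                inverted_span=(invseg.t_start, invseg.t_end),
            )
        # criterion 2: consensus area + unique reference area, opposite strands
        if ref is not None and segs:
            te = max(segs, key=lambda s: s.q_len)
            for q_start, q_end in _uncovered_blocks(len(core), segs, cfg.min_segment_len):
                hits = unique_ref_hits(core[q_start:q_end], dict(ref))
                if hits and hits[0][3] != te.orientation:
                    if te.orientation == "+":
                        return InversionCall(
                            ann.call_id, 2,
                            noninverted_span=(te.t_start, te.t_end),
                            inverted_span=(te.t_start, te.t_start),
                            inverted_len=q_end - q_start,
                        )
                    return InversionCall(
                        ann.call_id, 2,
                        noninverted_span=(te.t_end, te.t_end),
                        inverted_span=(te.t_start, te.t_end),
                        noninverted_len=q_end - q_start,
                    )

    # criterion 3: two unique reference areas, opposite orientation, < 500 bp
    # apart.  Blocks come from the annotated segments (e.g. the cDNA pieces
    # of a processed pseudogene) when available, else two halves.
    if ref is not None:
        if ann.consensus_spans and len(ann.consensus_spans) >= 2:
            frame = seq if ann.te_strand == "+" else revcomp(seq)
            offset = t_len if ann.te_strand == "+" else a_len
            blocks = []
            for s in ann.consensus_spans:
                # annotation spans are on the genome-frame insertion; shift
                # into the tail-trimmed element frame used here
                q0, q1 = s.q_start, s.q_end
                if ann.te_strand == "-":
                    q0, q1 = len(seq) - s.q_end, len(seq) - s.q_start
                q0, q1 = max(0, q0 - offset), min(len(core), q1 - offset)
                if q1 - q0 >= cfg.min_segment_len:
                    blocks.append((q0, q1))
        else:
            blocks = _split_blocks(len(core), cfg.min_segment_len)
        placements = []
        for q_start, q_end in blocks:
            hits = unique_ref_hits(core[q_start:q_end], dict(ref))
            if hits:
                placements.append((q_start, q_end, hits[0]))
        for i in range(len(placements)):
            for j in range(i + 1, len(placements)):
                (_, _, a), (_, _, b) = placements[i], placements[j]
                if a[0] != b[0] or a[3] == b[3]:
                    continue
                gap = max(a[1], b[1]) - min(a[2], b[2])
                if gap <= INVERSION_PROXIMITY_BP:
                    p_i, p_j = placements[i], placements[j]
                    return InversionCall(
                        ann.call_id, 3,
                        noninverted_span=(0, 0),
                        inverted_span=(0, 0),
                        noninverted_len=p_j[1] - p_j[0],
                        inverted_len=p_i[1] - p_i[0],
                    )
    return None


def _uncovered_blocks(length: int, segs, min_len: int) -> list[tuple[int, int]]:
    """Maximal query intervals not covered by any mapped segment."""
    covered = np.zeros(length, dtype=bool)
    for s in segs:
        covered[s.q_start: s.q_end] = True
    blocks = []
    start = None
    for i in range(length + 1):
        free = i < length and not covered[i]
        if free and start is None:
            start = i
        elif not free and start is not None:
            if i - start >= min_len:
                blocks.append((start, i))
            start = None
    return blocks


def _split_blocks(length: int, min_len: int) -> list[tuple[int, int]]:
    """Two halves of an unannotated insertion, for criterion 3."""
    if length < 2 * min_len:
        return []
    mid = length // 2
    return [(0, mid), (mid, length)]


def inversion_breakpoint_profile(
    invs: Sequence[InversionCall], consensus_len: int
) -> dict[str, np.ndarray]:
    """Per-position counts of the three twin-priming breakpoints.

    The three breakpoint classes on the consensus are the noninverted cDNA
    end (its 5'-most base), the inverted cDNA start (the internal priming
    point) and the inverted cDNA end.  1-bp bins; smoothing is left to the
    caller.
    """
    if not invs:
        raise ValueError("no inversion calls")
    profiles = {
        "noninverted_end": np.zeros(consensus_len + 1, dtype=int),
        "inverted_start": np.zeros(consensus_len + 1, dtype=int),
        "inverted_end": np.zeros(consensus_len + 1, dtype=int),
    }
    for inv in invs:
        profiles["noninverted_end"][inv.noninverted_span[0]] += 1
        profiles["inverted_start"][inv.inverted_span[1]] += 1
        profiles["inverted_end"][inv.inverted_span[0]] += 1
    return profiles
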