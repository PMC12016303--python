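"""Local segment mapping of insertion sequences against consensus/reference.

Candidate segments are found by exact k-mer anchor chaining (both strands)
and their boundaries refined with edlib infix alignment.  This gives exact
spans on error-free sequence and spans within a few bases under the
substitution error rates the simulator produces, which is what the
downstream hallmark and inversion logic needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from ._dna import revcomp


@dataclass
class Segment:
    """One aligned block between a query and a target sequence.

    ``q_start/q_end`` are on the query as given; ``t_start/t_end`` on the
    target (both 0-based half-open).  ``orientation`` is "+" when the query
    block matches the target forward strand, "-" when it matches the
    reverse complement.  ``identity`` = matches / alignment columns.
    """

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    orientation: str
    identity: float

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    return index


def _chain_anchors(anchors: list[tuple[int, int]], k: int, max_gap: int = 60) -> list[tuple[int, int, int, int]]:
    """Greedy chaining of (q, t) anchors into collinear blocks.

    Anchors are collinear when consecutive diagonal offsets differ by at
    most ``max_gap``.  Returns (q_start, q_end, t_start, t_end) blocks.
    """
    if not anchors:
        return []
    anchors = sorted(anchors)
    chains: list[list[tuple[int, int]]] = []
    for q, t in anchors:
        placed = False
        for chain in chains:
            lq, lt = chain[-1]
            if q >= lq and t >= lt and 0 <= q - lq <= max_gap and abs((q - t) - (lq - lt)) <= max_gap // 2:
                chain.append((q, t))
                placed = True
                break
        if not placed:
            chains.append([(q, t)])
    blocks = []
    for chain in chains:
        q0, t0 = chain[0]
        q1, t1 = chain[-1]
        blocks.append((q0, q1 + k, t0, t1 + k))
    return blocks


def _extend_block(query: str, target: str, q0: int, q1: int, t0: int, t1: int) -> tuple[int, int, int, int]:
    """Extend an exact block over matching bases in both directions."""
    while q0 > 0 and t0 > 0 and query[q0 - 1] == target[t0 - 1]:
        q0 -= 1
        t0 -= 1
    n_q, n_t = len(query), len(target)
    while q1 < n_q and t1 < n_t and query[q1] == target[t1]:
        q1 += 1
        t1 += 1
    return q0, q1, t0, t1


def _refine(query_block: str, target: str) -> tuple[int, int, float]:
    """Infix-align a query block inside the target; return span + identity."""
    res = edlib.align(query_block, target, mode="HW", task="locations")
    start, end = res["locations"][0]
    end += 1  # edlib end is inclusive
    ident = 1.0 - res["editDistance"] / max(len(query_block), end - start)
    return start, end, ident


def map_segments(
    query: str,
    target: str,
    k: int = 13,
    min_len: int = 30,
    min_identity: float = 0.7,
) -> list[Segment]:
    """All local alignments of ``query`` against both strands of ``target``.

    Overlapping blocks on the query are resolved greedily by length: a block
    is kept only if at most 25% of it is already covered by a longer kept
    block.  Segments shorter than ``min_len`` or below ``min_identity`` are
    dropped.  Deterministic for fixed inputs.
    """
    if not query or not target:
        return []
    index_f = _kmer_index(target, k)
    candidates: list[tuple[int, int, int, int, str]] = []
    for orient, q in (("+", query), ("-", revcomp(query))):
        anchors = []
        for i in range(len(q) - k + 1):
            for t in index_f.get(q[i:i + k], ()):
                anchors.append((i, t))
            if len(anchors) > 200000:  # pathological repeat guard
                break
        for q0, q1, t0, t1 in _chain_anchors(anchors, k):
            q0, q1, t0, t1 = _extend_block(q, target, q0, q1, t0, t1)
            candidates.append((q0, q1, t0, t1, orient))

    segments: list[Segment] = []
    for q0, q1, t0, t1, orient in candidates:
        q = query if orient == "+" else revcomp(query)
        t_start, t_end, ident = _refine(q[q0:q1], target)
        if orient == "-":
            # convert coordinates on the reverse-complemented query back
            q0, q1 = len(query) - q1, len(query) - q0
        if q1 - q0 >= min_len and ident >= min_identity:
            segments.append(Segment(q0, q1, t_start, t_end, orient, round(ident, 4)))

    # greedy non-redundancy on the query
    segments.sort(key=lambda s: (-(s.q_len), -s.identity, s.q_start, s.t_start))
    kept: list[Segment] = []
    for seg in segments:
        overlap = 0
        for other in kept:
            overlap += max(0, min(seg.q_end, other.q_end) - max(seg.q_start, other.q_start))
        if overlap <= 0.25 * seg.q_len:
            kept.append(seg)
    kept.sort(key=lambda s: s.q_start)
    return kept


def best_alignment(query: str, target: str) -> tuple[str, float]:
    """Best-strand global identity of ``query`` inside ``target`` (infix).

    Returns (orientation, identity); identity is 0 when nothing aligns.
    """
    best = ("+", 0.0)
    for orient, q in (("+", query), ("-", revcomp(query))):
        res = edlib.align(q, target, mode="HW", task="distance")
        if res["editDistance"] < 0:
            continue
        ident = 1.0 - res["editDistance"] / len(q)
        if ident > best[1]:
            best = (orient, ident)
    return best


def unique_ref_hits(
    seq: str,
    ref: dict[str, str],
    min_identity: float = 0.85,
    mapq_margin: int = 5,
    exclude: tuple[str, int, int] | None = None,
) -> list[tuple[str, int, int, str]]:
    """Loci where ``seq`` maps uniquely to the reference.

    A hit is "unique" (MAPQ-proxy above threshold) when its edit distance
    beats every other candidate locus by at least ``mapq_margin`` edits.
    ``exclude`` masks a (chrom, start, end) window, typically the insertion
    target site itself.  Returns [(chrom, start, end, orientation)] — empty
    when the placement is absent or ambiguous.
    """
    hits: list[tuple[int, str, int, int, str]] = []  # (dist, chrom, start, end, orient)
    for chrom, target in sorted(ref.items()):
        for orient, q in (("+", seq), ("-", revcomp(seq))):
            res = edlib.align(q, target, mode="HW", task="locations", k=int(len(seq) * (1 - min_identity)) + 1)
            if res["editDistance"] < 0:
                continue
            for start, end in res["locations"][:20]:
                end += 1
                if exclude and chrom == exclude[0] and start < exclude[2] and end > exclude[1]:
                    continue
                hits.append((res["editDistance"], chrom, start, end, orient))
    if not hits:
        return []
    hits.sort()
    best = hits[0]
    # collapse near-duplicate locations of the best hit
    rivals = [
        h for h in hits[1:]
        if not (h[1] == best[1] and abs(h[2] - best[2]) < len(seq))
    ]
    if rivals and rivals[0][0] - best[0] < mapq_margin:
        return []  # ambiguous placement
    return [(best[1], best[2], best[3], best[4])]
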