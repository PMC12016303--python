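"""Small DNA utilities shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of an upper/lowercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Uppercase and replace any non-ACGTN character with N.

    Returns the normalized sequence and leaves counting of replacements
    to the caller (see :func:`normalize_counted`).
    """
    return normalize_counted(seq)[0]


def normalize_counted(seq: str) -> tuple[str, int]:
    seq = seq.upper()
    out = []
    replaced = 0
    for c in seq:
        if c in "ACGTN":
            out.append(c)
        else:
            out.append("N")
            replaced += 1
    return "".join(out), replaced


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA of length ``n``."""
    return "".join(rng.choice(list(ALPHABET), size=n))


def common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n
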