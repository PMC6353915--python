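"""Small sequence helpers shared across modules (circular coordinates, strands)."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def ref_window(ref_seq: str, start: int, end: int) -> str:
    """Extract [start, end) from a circular reference.

    start must lie in [0, L); end may exceed L, in which case the window
    wraps through the origin.
    """
    L = len(ref_seq)
    if not 0 <= start < L:
        raise ValueError(f"start {start} outside [0, {L})")
    if end <= start:
        raise ValueError(f"empty or inverted window [{start}, {end})")
    if end - start > L:
        raise ValueError("window longer than the reference circle")
    if end <= L:
        return ref_seq[start:end]
    return ref_seq[start:] + ref_seq[: end - L]
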