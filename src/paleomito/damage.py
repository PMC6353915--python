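"""Cytosine-deamination profiling and damage-based authentication.

Ancient DNA carries post-mortem deamination of cytosine, read as thymine,
concentrated at fragment ends. This module measures per-position C→T
mismatch frequencies relative to the reference from both read ends,
computes them conditional on damage at the opposite end (a mixture of
damaged endogenous and undamaged contaminant molecules shows conditional
enrichment), flags/filters deaminated fragments, and masks terminal T
bases before consensus calling.

All bookkeeping is in read orientation: for minus-strand fragments the
5' end of the read is the right-hand reference coordinate, and the
read-oriented bases are the reverse complement of the stored
reference-forward bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seq import ref_window, revcomp
from .fragment_io import AlignedFragment

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


@dataclass
class DamageProfile:
    """Per-position C→T mismatch counts from each read end.

    ``*_sites[d]`` counts aligned positions at distance ``d`` from the end
    whose reference base is C; ``*_obs[d]`` counts those reading T. N bases
    are excluded. Frequencies are NaN where no sites were observed.
    """

    five_prime_sites: np.ndarray
    five_prime_obs: np.ndarray
    three_prime_sites: np.ndarray
    three_prime_obs: np.ndarray
    conditional: bool = False
    conditioning: str = ""
    n_fragments: int = 0

    @staticmethod
    def _freq(obs: np.ndarray, sites: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sites > 0, obs / np.maximum(sites, 1), np.nan)

    @property
    def five_prime_freq(self) -> np.ndarray:
        return self._freq(self.five_prime_obs, self.five_prime_sites)

    @property
    def three_prime_freq(self) -> np.ndarray:
        return self._freq(self.three_prime_obs, self.three_prime_sites)

    @property
    def empty(self) -> bool:
        return self.n_fragments == 0

    def to_dict(self) -> dict:
        def col(x):
            return [None if np.isnan(v) else float(v) for v in x]

        return {
            "conditional": self.conditional,
            "conditioning": self.conditioning,
            "n_fragments": self.n_fragments,
            "five_prime": {
                "sites": self.five_prime_sites.tolist(),
                "observations": self.five_prime_obs.tolist(),
                "frequency": col(self.five_prime_freq),
            },
            "three_prime": {
                "sites": self.three_prime_sites.tolist(),
                "observations": self.three_prime_obs.tolist(),
                "frequency": col(self.three_prime_freq),
            },
        }


def read_oriented(frag: AlignedFragment, ref_seq: str) -> tuple[str, str]:
    """Return (read bases, reference bases) in read orientation.

    For plus-strand fragments these are the stored sequence and the
    reference window; for minus-strand fragments both are reverse
    complemented so index 0 is the 5' end of the sequenced read.
    """
    ref = ref_window(ref_seq, frag.start, frag.end)
    if frag.strand == "-":
        return revcomp(frag.sequence), revcomp(ref)
    return frag.sequence, ref


def _ct_at(read: str, ref: str, idx: int) -> bool:
    return ref[idx] == "C" and read[idx] == "T"


def mismatch_profile(
    frags: Sequence[AlignedFragment],
    ref_seq: str,
    n_pos: int = 15,
) -> DamageProfile:
    """Unconditional C→T mismatch frequencies at the first ``n_pos``
    positions from the 5' and 3' read ends."""
    p5_sites = np.zeros(n_pos, dtype=np.int64)
    p5_obs = np.zeros(n_pos, dtype=np.int64)
    p3_sites = np.zeros(n_pos, dtype=np.int64)
    p3_obs = np.zeros(n_pos, dtype=np.int64)
    for frag in frags:
        read, ref = read_oriented(frag, ref_seq)
        n = len(read)
        for d in range(min(n_pos, n)):
            if ref[d] == "C" and read[d] != "N":
                p5_sites[d] += 1
                if read[d] == "T":
                    p5_obs[d] += 1
            j = n - 1 - d
            if ref[j] == "C" and read[j] != "N":
                p3_sites[d] += 1
                if read[j] == "T":
                    p3_obs[d] += 1
    return DamageProfile(
        five_prime_sites=p5_sites,
        five_prime_obs=p5_obs,
        three_prime_sites=p3_sites,
        three_prime_obs=p3_obs,
        n_fragments=len(frags),
    )


def _has_terminal_ct(read: str, ref: str, end: str, window: int) -> bool:
    n = len(read)
    if end == FIVE_PRIME:
        idxs = range(min(window, n))
    elif end == THREE_PRIME:
        idxs = range(max(n - window, 0), n)
    else:
        raise ValueError(f"unknown end {end!r}")
    return any(_ct_at(read, ref, i) for i in idxs)


def conditional_profile(
    frags: Sequence[AlignedFragment],
    ref_seq: str,
    cond_end: str,
    cond_window: int = 1,
    n_pos: int = 15,
) -> DamageProfile:
    """C→T profile over fragments already damaged at ``cond_end``.

    Conditioning selects fragments with at least one C→T within
    ``cond_window`` positions of the conditioning end; in a mixture of
    damaged and undamaged molecules this enriches for the damaged
    component, raising the frequency observed at the opposite end.
    An empty conditioning set yields a profile flagged ``empty``.
    """
    subset = []
    for frag in frags:
        read, ref = read_oriented(frag, ref_seq)
        if _has_terminal_ct(read, ref, cond_end, cond_window):
            subset.append(frag)
    prof = mismatch_profile(subset, ref_seq, n_pos=n_pos)
    prof.conditional = True
    prof.conditioning = f"C->T within {cond_window} of {cond_end}"
    return prof


def is_deaminated(frag: AlignedFragment, ref_seq: str, n_terminal: int = 3) -> bool:
    """True iff the fragment shows a C→T mismatch among its first or last
    ``n_terminal`` read positions (overlapping windows on short fragments
    are evaluated without double counting)."""
    read, ref = read_oriented(frag, ref_seq)
    n = len(read)
    idxs = set(range(min(n_terminal, n))) | set(range(max(n - n_terminal, 0), n))
    return any(_ct_at(read, ref, i) for i in idxs)


def filter_deaminated(
    frags: Sequence[AlignedFragment], ref_seq: str, n_terminal: int = 3
) -> list[AlignedFragment]:
    """Subset of fragments showing terminal deamination; order preserved."""
    return [f for f in frags if is_deaminated(f, ref_seq, n_terminal)]


def mask_terminal_t(frag: AlignedFragment, n: int = 3) -> AlignedFragment:
    """Replace every T among the first and last ``n`` read positions with N.

    Applied in read orientation (a minus-strand read's terminal T is an A
    in the stored reference-forward bases). On fragments shorter than 2n
    the windows overlap and every position is treated as terminal.
    Idempotent; bases other than T are untouched.
    """
    read = frag.sequence if frag.strand == "+" else revcomp(frag.sequence)
    m = len(read)
    chars = list(read)
    idxs = set(range(min(n, m))) | set(range(max(m - n, 0), m))
    for i in idxs:
        if chars[i] == "T":
            chars[i] = "N"
    masked = "".join(chars)
    stored = masked if frag.strand == "+" else revcomp(masked)
    return AlignedFragment(
        id=frag.id,
        library=frag.library,
        start=frag.start,
        end=frag.end,
        strand=frag.strand,
        sequence=stored,
        truth_label=frag.truth_label,
    )


def mask_fragments(frags: Sequence[AlignedFragment], n: int = 3
                   ) -> list[AlignedFragment]:
    return [mask_terminal_t(f, n) for f in frags]
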