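"""Pileup construction and threshold consensus calling.

A position is called when at least ``min_cov`` fragments cover it (N bases
excluded) and the majority base is supported by at least ``min_support`` of
them — both thresholds inclusive. Well-covered positions failing the
support rule are reported as heteroplasmy candidates and left uncalled
(N in the consensus), never resolved into the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fragment_io import AlignedFragment

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"

STATUS_CALLED = "called"
STATUS_LOW_COVERAGE = "low_coverage"
STATUS_LOW_SUPPORT = "low_support"
STATUS_PATCHED = "patched"


@dataclass
class PileupColumn:
    """Base counts at one reference position (N bases contribute nothing)."""

    position: int
    counts: dict[str, int]

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())

    @property
    def majority_base(self) -> str | None:
        if self.coverage == 0:
            return None
        return max(_BASES, key=lambda b: self.counts.get(b, 0))

    @property
    def support(self) -> float | None:
        cov = self.coverage
        if cov == 0:
            return None
        return self.counts.get(self.majority_base, 0) / cov


class Pileup:
    """Per-position A/C/G/T counts over a circular reference of length L."""

    def __init__(self, counts: np.ndarray):
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("pileup counts must have shape (L, 4)")
        self.counts = counts

    @property
    def L(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column(self, position: int) -> PileupColumn:
        row = self.counts[position]
        return PileupColumn(
            position=position,
            counts={b: int(row[i]) for b, i in _BASE_INDEX.items()},
        )


def build_pileup(frags: Sequence[AlignedFragment], L: int) -> Pileup:
    """Accumulate base counts; fragments wrapping the origin contribute to
    both ends of the coordinate system. Masked (N) bases are not counted."""
    counts = np.zeros((L, 4), dtype=np.int64)
    base_code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        base_code[ord(b)] = i
    for frag in frags:
        codes = base_code[np.frombuffer(frag.sequence.encode(), dtype=np.uint8)]
        pos = np.arange(frag.start, frag.end) % L
        keep = codes >= 0
        np.add.at(counts, (pos[keep], codes[keep]), 1)
    return Pileup(counts)


@dataclass
class ConsensusSequence:
    """Per-position consensus calls with status and heteroplasmy candidates."""

    sequence: str
    status: list[str]
    heteroplasmy: list[PileupColumn]
    mean_coverage: float

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.status):
            raise ValueError("sequence/status length mismatch")

    @property
    def L(self) -> int:
        return len(self.sequence)

    @property
    def n_called(self) -> int:
        return sum(1 for s in self.status if s in (STATUS_CALLED, STATUS_PATCHED))

    @property
    def called_positions(self) -> list[int]:
        return [i for i, s in enumerate(self.status)
                if s in (STATUS_CALLED, STATUS_PATCHED)]


def call_consensus(
    pileup: Pileup,
    min_cov: int = 5,
    min_support: float = 0.8,
) -> ConsensusSequence:
    """Threshold consensus over all pileup columns (thresholds inclusive)."""
    counts = pileup.counts
    coverage = counts.sum(axis=1)
    majority_idx = counts.argmax(axis=1)
    majority_count = counts.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        support = np.where(coverage > 0, majority_count / np.maximum(coverage, 1), 0.0)

    seq = []
    status = []
    hetero: list[PileupColumn] = []
    for i in range(pileup.L):
        if coverage[i] < min_cov:
            seq.append("N")
            status.append(STATUS_LOW_COVERAGE)
        elif support[i] < min_support:
            seq.append("N")
            status.append(STATUS_LOW_SUPPORT)
            hetero.append(pileup.column(i))
        else:
            seq.append(_BASES[majority_idx[i]])
            status.append(STATUS_CALLED)
    return ConsensusSequence(
        sequence="".join(seq),
        status=status,
        heteroplasmy=hetero,
        mean_coverage=float(coverage.mean()),
    )


def apply_patches(
    consensus: ConsensusSequence, patches: Sequence[tuple[int, str]]
) -> ConsensusSequence:
    """Override declared positions (e.g. a manually curated homopolymer
    region) with explicit bases; patched positions are marked as such."""
    seq = list(consensus.sequence)
    status = list(consensus.status)
    for pos, base in patches:
        if not 0 <= pos < len(seq):
            raise ValueError(f"patch position {pos} outside [0, {len(seq)})")
        if base not in "ACGTN":
            raise ValueError(f"patch base must be one of ACGTN, got {base!r}")
        seq[pos] = base
        status[pos] = STATUS_PATCHED
    return ConsensusSequence(
        sequence="".join(seq),
        status=status,
        heteroplasmy=consensus.heteroplasmy,
        mean_coverage=consensus.mean_coverage,
    )


def compare_consensus(a: str, b: str) -> tuple[list[int], int]:
    """Positions where two equal-length sequences are both called and
    differ; returns (mismatch positions, count of uncomparable positions
    where either side is N)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    mismatches = []
    uncomparable = 0
    for i, (x, y) in enumerate(zip(a, b)):
        if x == "N" or y == "N":
            uncomparable += 1
        elif x != y:
            mismatches.append(i)
    return mismatches, uncomparable
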