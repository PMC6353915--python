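"""Length filtering, PCR-duplicate fusing, and fragment/coverage accounting."""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Sequence

from .fragment_io import AlignedFragment


def filter_length(frags: Sequence[AlignedFragment], min_len: int = 35
                  ) -> list[AlignedFragment]:
    """Retain fragments of at least ``min_len`` bases (boundary inclusive)."""
    return [f for f in frags if f.length >= min_len]


def _fuse_sequences(seqs: list[str]) -> str:
    """Per-column majority base over equal-length sequences; ties become N."""
    if len(seqs) == 1:
        return seqs[0]
    fused = []
    for column in zip(*seqs):
        counts = Counter(b for b in column if b != "N")
        if not counts:
            fused.append("N")
            continue
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            fused.append("N")
        else:
            fused.append(ranked[0][0])
    return "".join(fused)


def collapse_duplicates(frags: Sequence[AlignedFragment]) -> list[AlignedFragment]:
    """Fuse fragments sharing (library, start, end, strand) into one.

    PCR duplicates of one molecule share alignment coordinates; the fused
    sequence takes the per-column majority base, with ties recorded as N.
    The key includes library (duplication happens within a library) and
    strand (coordinate identity across strands is molecular coincidence).
    First-occurrence order is preserved.
    """
    groups: dict[tuple, list[AlignedFragment]] = defaultdict(list)
    order: list[tuple] = []
    for f in frags:
        key = (f.library, f.start, f.end, f.strand)
        if key not in groups:
            order.append(key)
        groups[key].append(f)

    out: list[AlignedFragment] = []
    for key in order:
        members = groups[key]
        first = members[0]
        labels = {m.truth_label for m in members}
        out.append(
            AlignedFragment(
                id=first.id,
                library=first.library,
                start=first.start,
                end=first.end,
                strand=first.strand,
                sequence=_fuse_sequences([m.sequence for m in members]),
                truth_label=labels.pop() if len(labels) == 1 else None,
            )
        )
    return out


def summarize(frags: Iterable[AlignedFragment], L: int) -> dict:
    """Unique-fragment counts and mean coverage, per library and overall.

    Coverage is total aligned bases divided by the reference length.
    """
    if L <= 0:
        raise ValueError("reference length must be positive")
    per_library: dict[str, dict] = {}
    total_n = 0
    total_bases = 0
    for f in frags:
        rec = per_library.setdefault(f.library, {"n_fragments": 0, "bases": 0})
        rec["n_fragments"] += 1
        rec["bases"] += f.length
        total_n += 1
        total_bases += f.length
    for rec in per_library.values():
        rec["coverage"] = rec["bases"] / L
        rec["mean_length"] = rec["bases"] / rec["n_fragments"]
        del rec["bases"]
    return {
        "libraries": per_library,
        "total": {
            "n_fragments": total_n,
            "coverage": total_bases / L,
            "mean_length": (total_bases / total_n) if total_n else 0.0,
        },
    }
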