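"""Present-day contamination estimation from diagnostic positions.

A diagnostic position is a site where the specimen consensus is called and
differs from every member of a present-day comparison panel. Each fragment
covering a diagnostic position contributes one Bernoulli observation:
carrying the panel state counts as a contaminant observation, the
endogenous state as endogenous; N bases and third alleles (neither
segregating state, putative damage or sequencing error) are excluded from
both numerator and denominator and reported separately. Observations are
pooled across diagnostic positions, per library and overall, with Wilson
95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from statsmodels.stats.proportion import proportion_confint

from .damage import filter_deaminated, mask_fragments
from .fragment_io import AlignedFragment

POOLED = "__pooled__"


@dataclass
class DiagnosticPosition:
    position: int
    endogenous_state: str
    panel_states: frozenset[str]


@dataclass
class ContaminationEstimate:
    library: str
    n_informative: int
    n_mismatch: int
    n_excluded: int
    positions: list[int]

    @property
    def proportion(self) -> float | None:
        if self.n_informative == 0:
            return None
        return self.n_mismatch / self.n_informative

    @property
    def ci95(self) -> tuple[float, float] | None:
        if self.n_informative == 0:
            return None
        lo, hi = proportion_confint(
            self.n_mismatch, self.n_informative, alpha=0.05, method="wilson"
        )
        return (float(lo), float(hi))

    def to_dict(self) -> dict:
        prop = self.proportion
        ci = self.ci95
        return {
            "library": self.library,
            "n_informative": self.n_informative,
            "n_mismatch": self.n_mismatch,
            "n_excluded": self.n_excluded,
            "proportion": prop,
            "percent": None if prop is None else 100.0 * prop,
            "ci95": ci,
            "positions": self.positions,
        }


def find_diagnostic_positions(
    consensus_seq: str, panel: Sequence[str]
) -> list[DiagnosticPosition]:
    """Positions where the called consensus differs from every panel member.

    Positions where the consensus is uncalled (N) or any panel member is N
    are excluded.
    """
    if not panel:
        raise ValueError("panel must contain at least one haplotype")
    L = len(consensus_seq)
    for h in panel:
        if len(h) != L:
            raise ValueError("panel haplotypes must match the consensus length")
    out: list[DiagnosticPosition] = []
    for i in range(L):
        c = consensus_seq[i]
        if c == "N":
            continue
        states = {h[i] for h in panel}
        if "N" in states or c in states:
            continue
        out.append(
            DiagnosticPosition(
                position=i, endogenous_state=c, panel_states=frozenset(states)
            )
        )
    return out


def _covers(frag: AlignedFragment, position: int, L: int) -> int | None:
    """Offset of a reference position within the fragment, or None."""
    offset = (position - frag.start) % L
    return offset if offset < frag.length else None


def estimate_contamination(
    frags: Sequence[AlignedFragment],
    diagnostics: Sequence[DiagnosticPosition],
    L: int,
    per_library: bool = True,
) -> dict[str, ContaminationEstimate]:
    """Proportion of panel-state observations at diagnostic positions.

    Returns one estimate per library (when ``per_library``) plus a pooled
    estimate under the key ``POOLED``. A fragment contributes one
    observation per diagnostic position it covers.
    """
    if not diagnostics:
        raise ValueError("at least one diagnostic position is required")
    tallies: dict[str, dict[str, int]] = {}

    def tally(lib: str) -> dict[str, int]:
        return tallies.setdefault(lib, {"informative": 0, "mismatch": 0, "excluded": 0})

    tally(POOLED)  # always reported, even with zero informative observations
    if per_library:
        for frag in frags:
            tally(frag.library)
    for frag in frags:
        for diag in diagnostics:
            offset = _covers(frag, diag.position, L)
            if offset is None:
                continue
            base = frag.sequence[offset]
            keys = [POOLED] + ([frag.library] if per_library else [])
            if base == diag.endogenous_state:
                for k in keys:
                    tally(k)["informative"] += 1
            elif base in diag.panel_states:
                for k in keys:
                    tally(k)["informative"] += 1
                    tally(k)["mismatch"] += 1
            else:  # N or third allele: damage/error, not informative
                for k in keys:
                    tally(k)["excluded"] += 1

    positions = [d.position for d in diagnostics]
    return {
        lib: ContaminationEstimate(
            library=lib,
            n_informative=t["informative"],
            n_mismatch=t["mismatch"],
            n_excluded=t["excluded"],
            positions=positions,
        )
        for lib, t in tallies.items()
    }


def contamination_before_after(
    frags: Sequence[AlignedFragment],
    ref_seq: str,
    diagnostics: Sequence[DiagnosticPosition],
    L: int,
    n_terminal: int = 3,
    per_library: bool = True,
    mask: bool = True,
) -> dict:
    """Contamination on all fragments vs the deaminated-only subset.

    ``frags`` must be unmasked: the deamination filter needs the terminal
    T evidence that masking erases. With ``mask`` (default), terminal T
    bases are masked *after* the split and *before* counting, so that
    residual terminal damage cannot masquerade as a panel-state observation
    at T-segregating diagnostic sites.

    Restricting to fragments with terminal C→T damage enriches for
    endogenous molecules, so the deaminated-only estimate is expected to
    drop whenever contaminants carry less terminal damage.
    """
    deam = filter_deaminated(frags, ref_seq, n_terminal)
    all_set = mask_fragments(frags, n_terminal) if mask else list(frags)
    deam_set = mask_fragments(deam, n_terminal) if mask else deam
    all_est = estimate_contamination(all_set, diagnostics, L, per_library)
    deam_est = estimate_contamination(deam_set, diagnostics, L, per_library)

    reduction = None
    a, d = all_est.get(POOLED), deam_est.get(POOLED)
    if a and d and a.proportion is not None and d.proportion is not None:
        reduction = a.proportion - d.proportion
    return {
        "all": all_est,
        "deaminated_only": deam_est,
        "n_deaminated": len(deam),
        "pooled_reduction": reduction,
    }
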