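"""Poisson molecular clock on private substitutions.

A lineage that accumulated ``k`` private substitutions over ``L`` comparable
sites at mutation rate ``mu`` (substitutions per site per year) has point
divergence time t = k / (mu * L). Treating k as Poisson with mean mu*L*t,
exact (Garwood) bounds on the Poisson mean divided by mu*L give a
confidence interval for t; when a rate interval [mu_lo, mu_hi] is supplied
the envelope of the bounds over that interval is reported as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import chi2

#: Human mtDNA mutation rate commonly used for shallow divergence dating
#: (substitutions per site per year).
DEFAULT_MT_RATE = 2.67e-8


@dataclass
class ClockModel:
    """Inputs of the clock: rate, comparable sites, observed count."""

    mu: float
    L: int
    k: int
    mu_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if not self.L > 0:
            raise ValueError("L must be positive")
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.mu_interval is not None:
            lo, hi = self.mu_interval
            if not 0 < lo <= hi:
                raise ValueError("mu_interval must satisfy 0 < mu_lo <= mu_hi")


@dataclass
class DivergenceEstimate:
    t_point: float
    t_lower: float
    t_upper: float
    ci: float
    k: int
    mu: float
    L: int
    envelope: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "t_point_years": self.t_point,
            "t_lower_years": self.t_lower,
            "t_upper_years": self.t_upper,
            "ci": self.ci,
            "k": self.k,
            "mu": self.mu,
            "L": self.L,
            "rate_envelope_years": self.envelope,
        }


def poisson_interval(k: int, ci: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence bounds on a Poisson mean from one count.

    Lower bound is 0 at k = 0; the upper bound at k = 0 reduces to
    -ln(alpha/2).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if not 0 < ci < 1:
        raise ValueError("ci must lie in (0, 1)")
    alpha = 1.0 - ci
    lower = 0.0 if k == 0 else chi2.ppf(alpha / 2.0, 2 * k) / 2.0
    upper = chi2.ppf(1.0 - alpha / 2.0, 2 * k + 2) / 2.0
    return float(lower), float(upper)


def count_private_substitutions(
    consensus_seq: str,
    root_seq: str,
    panel: Sequence[str] | None = None,
) -> tuple[int, list[int], int]:
    """Count called positions where the consensus differs from the root.

    With a panel supplied, the count is restricted to positions that also
    differ from every panel member (private substitutions in the strict
    sense). Returns (k, positions, n_uncomparable); uncalled (N) consensus
    positions are uncomparable and excluded from the effective length.
    """
    if len(consensus_seq) != len(root_seq):
        raise ValueError("consensus and root must have equal length")
    if all(c == "N" for c in consensus_seq):
        raise ValueError("consensus is entirely uncalled")
    positions: list[int] = []
    uncomparable = 0
    for i, (c, r) in enumerate(zip(consensus_seq, root_seq)):
        if c == "N" or r == "N":
            uncomparable += 1
            continue
        if c == r:
            continue
        if panel is not None:
            states = {h[i] for h in panel}
            if c in states or "N" in states:
                continue
        positions.append(i)
    return len(positions), positions, uncomparable


def divergence_time(model: ClockModel, ci: float = 0.95) -> DivergenceEstimate:
    """Point divergence time k/(mu*L) with exact Poisson bounds."""
    denom = model.mu * model.L
    lower, upper = poisson_interval(model.k, ci)
    envelope = None
    if model.mu_interval is not None:
        mu_lo, mu_hi = model.mu_interval
        envelope = (lower / (mu_hi * model.L), upper / (mu_lo * model.L))
    return DivergenceEstimate(
        t_point=model.k / denom,
        t_lower=lower / denom,
        t_upper=upper / denom,
        ci=ci,
        k=model.k,
        mu=model.mu,
        L=model.L,
        envelope=envelope,
    )
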