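"""Simulation of ancient mitochondrial DNA fragment sets.

The generator emulates what a single-stranded sequencing library prepared
from ancient skeletal material contains after mtDNA enrichment and mapping:
a mixture of endogenous fragments carrying cytosine-deamination damage
(C→T substitutions concentrated at both molecule ends) and present-day
contaminant fragments drawn from a panel of modern haplotypes, with a
fragment-length floor at 35 bp, uniform sequencing error, and PCR duplicates
sharing start/end coordinates.

The endogenous haplotype is planted with a known number of private
substitutions — positions where it differs from the reference root and from
every panel member — so that diagnostic-position discovery, contamination
estimation and molecular-clock counting downstream can all be validated
against ground truth.

Damage model: an endogenous fragment's cytosines flip to thymine with
probability ``delta_term * exp(-d / lambda_decay) + delta_bg`` where ``d``
is the distance to the nearer read end (both ends decay, as single-stranded
library chemistry produces); contaminant fragments receive only the
background rate. The exponential form is a modelling convenience; its
default intensity (``delta_term=0.4``) mirrors terminal C→T frequencies of
35-42% typical of well-preserved Pleistocene material.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from ._seq import BASES, ref_window, revcomp
from .fragment_io import AlignedFragment, write_fasta, write_fastq, write_fragments_tsv

#: mtDNA reference length used throughout (human mitochondrial genome size).
DEFAULT_MT_LENGTH = 16_569

_MIN_GENOME = 1_000


@dataclass
class MtGenome:
    """A circular mitochondrial reference sequence."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) < _MIN_GENOME:
            raise ValueError(
                f"genome length {len(self.sequence)} below minimum {_MIN_GENOME}"
            )
        bad = set(self.sequence) - set(BASES)
        if bad:
            raise ValueError(f"genome contains non-ACGT symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Haplotype:
    """A full-length haplotype and its substitutions relative to the root."""

    sequence: str
    substitutions: dict[int, str]  # position -> derived state


@dataclass
class HaplotypeSet:
    """Root, endogenous haplotype with private substitutions, and a panel."""

    root: MtGenome
    endogenous: Haplotype
    panel: list[Haplotype]
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = self.root.length
        for h in [self.endogenous, *self.panel]:
            if len(h.sequence) != L:
                raise ValueError("all haplotypes must match the root length")

    @property
    def private_positions(self) -> list[int]:
        return sorted(self.endogenous.substitutions)


@dataclass
class DamageModel:
    """Terminal-decaying C→T deamination plus background error rates."""

    delta_term: float = 0.4
    lambda_decay: float = 3.0
    delta_bg: float = 0.01
    seq_error: float = 0.001
    both_ends: bool = True

    def __post_init__(self) -> None:
        for name in ("delta_term", "delta_bg", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.lambda_decay > 0:
            raise ValueError("lambda_decay must be positive")

    def ct_rate(self, n: int, endogenous: bool) -> np.ndarray:
        """Per-position C→T probability along a fragment of length n."""
        if not endogenous:
            return np.full(n, self.delta_bg)
        d = np.arange(n, dtype=float)
        if self.both_ends:
            d = np.minimum(d, n - 1 - d)
        rate = self.delta_term * np.exp(-d / self.lambda_decay) + self.delta_bg
        return np.minimum(rate, 1.0)


@dataclass
class SimConfig:
    """One library's simulation parameters."""

    n_fragments: int = 10_000
    contamination_fraction: float = 0.0
    length_model: tuple[str, dict] = (
        "geometric",
        {"mean": 55, "min_length": 35, "max_length": 150},
    )
    duplicate_rate: float = 0.0
    damage: DamageModel = field(default_factory=DamageModel)
    seed: int = 0
    library: str = "sim"

    def __post_init__(self) -> None:
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be non-negative")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction must lie in [0, 1]")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate must lie in [0, 1]")
        name, params = self.length_model
        if name != "geometric":
            raise ValueError(f"unknown length model {name!r}")
        if params.get("min_length", 35) < 1:
            raise ValueError("min_length must be >= 1")


# ---------------------------------------------------------------------------
# Generators


def generate_reference(L: int = DEFAULT_MT_LENGTH, seed: int = 0,
                       name: str = "mt_ref") -> MtGenome:
    """Uniform-random circular reference of length L (deterministic in seed)."""
    if L < _MIN_GENOME:
        raise ValueError(f"reference length {L} below minimum {_MIN_GENOME}")
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=L)])
    return MtGenome(name=name, sequence=seq)


def _mutate(sequence: str, positions: np.ndarray, rng: np.random.Generator
            ) -> tuple[str, dict[int, str]]:
    """Substitute each position with a uniformly chosen different base."""
    seq = list(sequence)
    subs: dict[int, str] = {}
    for pos in positions:
        pos = int(pos)
        alternatives = [b for b in BASES if b != seq[pos]]
        state = alternatives[rng.integers(0, 3)]
        seq[pos] = state
        subs[pos] = state
    return "".join(seq), subs


def generate_haplotypes(
    ref: MtGenome,
    k_private: int = 10,
    n_panel: int = 311,
    panel_div: int = 20,
    seed: int = 0,
) -> HaplotypeSet:
    """Plant an endogenous haplotype and a present-day panel on the root.

    The endogenous haplotype differs from the root at exactly ``k_private``
    positions; panel members each carry ``panel_div`` substitutions drawn
    away from the private positions, so the private positions remain
    diagnostic (endogenous state differs from root AND every panel member).
    """
    L = ref.length
    if k_private + panel_div > L:
        raise ValueError(
            f"requested substitutions ({k_private} private + {panel_div} panel) "
            f"exceed available positions ({L})"
        )
    rng = np.random.default_rng(seed)
    private = rng.choice(L, size=k_private, replace=False) if k_private else np.array([], dtype=int)
    endo_seq, endo_subs = _mutate(ref.sequence, np.sort(private), rng)

    non_private = np.setdiff1d(np.arange(L), private)
    panel: list[Haplotype] = []
    for _ in range(n_panel):
        pos = rng.choice(non_private, size=panel_div, replace=False) if panel_div else np.array([], dtype=int)
        seq, subs = _mutate(ref.sequence, np.sort(pos), rng)
        panel.append(Haplotype(sequence=seq, substitutions=subs))

    return HaplotypeSet(
        root=ref,
        endogenous=Haplotype(sequence=endo_seq, substitutions=endo_subs),
        panel=panel,
        seed=seed,
        params={"k_private": k_private, "n_panel": n_panel, "panel_div": panel_div},
    )


def _draw_length(rng: np.random.Generator, params: Mapping) -> int:
    mean = params.get("mean", 55)
    lo = params.get("min_length", 35)
    hi = params.get("max_length", 150)
    # shifted geometric: support lo, lo+1, ... with mean `mean`, clipped at hi
    p = 1.0 / (mean - lo + 1)
    return min(lo - 1 + int(rng.geometric(p)), hi)


def _apply_seq_error(read: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Uniform miscalls in place: each base replaced by one of the 3 others."""
    if rate <= 0:
        return
    hit = np.flatnonzero(rng.random(len(read)) < rate)
    for i in hit:
        alternatives = [b for b in BASES if b != read[i]]
        read[i] = alternatives[rng.integers(0, 3)]


def simulate_fragments(haps: HaplotypeSet, cfg: SimConfig) -> list[AlignedFragment]:
    """Draw a labelled fragment set from the endogenous/contaminant mixture.

    Each molecule is endogenous with probability 1 − contamination_fraction,
    else a uniformly chosen panel member; start is uniform on the circle and
    the length follows the configured model. Deamination is applied in read
    orientation (minus-strand molecules are damaged on their own strand and
    stored back as reference-forward bases, so their C→T damage appears as
    G→A in reference-forward coordinates, as in real alignments). Duplicate
    emissions share the damaged molecule and coordinates but draw
    independent sequencing errors.
    """
    rng = np.random.default_rng(cfg.seed)
    L = haps.root.length
    _, len_params = cfg.length_model
    frags: list[AlignedFragment] = []

    for i in range(cfg.n_fragments):
        is_contaminant = rng.random() < cfg.contamination_fraction
        if is_contaminant:
            source = haps.panel[rng.integers(0, len(haps.panel))].sequence
            label = "contaminant"
        else:
            source = haps.endogenous.sequence
            label = "endogenous"
        start = int(rng.integers(0, L))
        length = _draw_length(rng, len_params)
        length = min(length, L)  # cannot exceed the circle
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"

        window = ref_window(source, start, end)
        molecule = revcomp(window) if strand == "-" else window
        read = np.array(list(molecule))

        # deamination on the molecule's own strand
        rate = cfg.damage.ct_rate(length, endogenous=(label == "endogenous"))
        flips = (read == "C") & (rng.random(length) < rate)
        read[flips] = "T"

        n_emit = 2 if rng.random() < cfg.duplicate_rate else 1
        for j in range(n_emit):
            emitted = read.copy()
            _apply_seq_error(emitted, cfg.damage.seq_error, rng)
            read_seq = "".join(emitted)
            stored = revcomp(read_seq) if strand == "-" else read_seq
            frag_id = f"{cfg.library}.{i:06d}" + ("" if j == 0 else f".dup{j}")
            frags.append(
                AlignedFragment(
                    id=frag_id,
                    library=cfg.library,
                    start=start,
                    end=end,
                    strand=strand,
                    sequence=stored,
                    truth_label=label,
                )
            )
    return frags


# ---------------------------------------------------------------------------
# On-disk simulation bundle


def write_simulation(
    haps: HaplotypeSet,
    frags: list[AlignedFragment],
    outdir: str | Path,
    fastq: bool = False,
) -> dict[str, Path]:
    """Persist reference, haplotypes and fragments as FASTA/TSV (+ FASTQ)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "haplotypes": outdir / "haplotypes.fa",
        "panel": outdir / "panel.fa",
        "fragments": outdir / "fragments.tsv",
    }
    write_fasta({haps.root.name: haps.root.sequence}, paths["reference"])
    write_fasta({"endogenous": haps.endogenous.sequence}, paths["haplotypes"])
    write_fasta(
        {f"panel_{i:03d}": h.sequence for i, h in enumerate(haps.panel)},
        paths["panel"],
    )
    write_fragments_tsv(frags, paths["fragments"])
    if fastq:
        paths["fastq"] = outdir / "fragments.fastq"
        write_fastq(frags, paths["fastq"])
    return paths
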