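# Methods

This note documents the models, conventions and design choices behind
`paleomito`, in the order the pipeline applies them.

## Coordinate and strand conventions

The mitochondrial reference is circular. Fragment coordinates are 0-based,
half-open; `start < L` always, and `end` may exceed `L`, meaning the
fragment wraps through the origin (arithmetic on the circle then reduces to
indexing the doubled reference). Fragment sequences are stored as aligned,
reference-forward bases; all damage bookkeeping happens in **read
orientation** — for a minus-strand fragment the 5′ end of the read is the
right-hand reference coordinate and the read bases are the reverse
complement of the stored ones. Consequently a minus-strand read's C→T
damage appears as G→A in reference-forward coordinates, exactly as in real
alignments of single-stranded libraries. SAM/BAM input is converted from
1-based inclusive coordinates on ingestion; unmapped, secondary and
supplementary records are dropped, soft-clips are trimmed, and reads whose
CIGAR contains indels are excluded with a logged count. The whole analysis
is a gapless substitution model: every statistic is positionwise, so
indel-containing reads (a small minority in short ancient fragments) carry
no usable signal for it.

## Synthetic data: what it emulates and what it does not

The generator draws a uniform-random circular reference (default
L = 16,569, the human mtDNA genome size), plants an endogenous haplotype
with `k_private` substitutions (default 10) placed away from the
substitutions of an `n_panel`-member present-day panel (default 311 members,
each `panel_div` = 20 substitutions from the root), and emits fragments
that are endogenous with probability 1 − c and otherwise drawn uniformly
from the panel. Keeping panel substitutions off the private positions makes
the planted positions diagnostic by construction, so
diagnostic-position discovery and the clock can be checked against truth.

Per-fragment model:

* **Start** uniform on the circle; **strand** uniform; **length** from a
  shifted geometric distribution with mean 55 bp, floor 35 bp and cap
  150 bp — typical ancient-DNA insert sizes, with the floor matching the
  35-bp retention filter.
* **Deamination**: each cytosine of an endogenous molecule (in read
  orientation) flips to T with probability
  `delta_term · exp(−d/lambda_decay) + delta_bg`, `d` the distance to the
  nearer read end. Defaults `delta_term = 0.4`, `lambda_decay = 3`,
  `delta_bg = 0.01` produce terminal C→T frequencies in the 35–42 % range
  observed in well-preserved Pleistocene material from single-stranded
  libraries (which show elevation at both ends). Contaminants receive only
  `delta_bg` — modern DNA is essentially undamaged. The exponential decay
  is a modelling convenience; real damage profiles decay roughly
  geometrically but are sequence-context dependent, which is not modelled.
* **Sequencing error**: uniform miscalls at `seq_error = 0.001` per base.
* **Duplicates**: with probability `duplicate_rate` a molecule is emitted
  twice with identical coordinates and damage but independent sequencing
  errors, emulating PCR duplication after damage is fixed in the template.

Not modelled: amplification bias, indels, strand-specific G→A patterns of
double-stranded library chemistry, contamination that is itself ancient,
within-panel phylogenetic structure, and reference bias from mapping.
Passing tests therefore demonstrate correctness of the estimators under the
mixture model they assume, not robustness to mapping artefacts or to
contaminants sharing damage with the endogenous component (the latter is
exercised explicitly as a negative control).

## Duplicate fusing

One fragment is kept per (library, start, end, strand). The key includes
the library because PCR duplication happens within a library — coordinate
identity across libraries is coincidence — and the strand because
single-stranded libraries preserve molecule ends, so opposite-strand
coordinate matches are distinct molecules. Fused sequences take the
per-column majority base with ties recorded as N; a majority rule is the
natural reconciliation when duplicate copies disagree through sequencing
error, and N is the honest call for a tie.

## Damage profiles and the deamination filter

Profiles count, at each distance d from the 5′ and 3′ read ends (default
15 positions), the aligned positions whose reference base is C (the
denominator) and among them those reading T (the numerator); N bases are
excluded from both. The conditional profile is the same quantity over the
subset of fragments with at least one C→T within `cond_window` positions of
the opposite end. The default window is 1 (the strictest reading of damage
"at one end"); it is a parameter because the choice is a convention, not a
derivable quantity. In a two-component mixture, conditioning on one end
selects the damaged component with probability approaching 1 when
contaminant terminal damage is negligible, so the conditional terminal
frequency estimates the endogenous damage rate while the unconditional one
estimates the mixture average — the enrichment is the authenticity signal.

A fragment is "deaminated" when it carries a C→T in its first or last
three read positions. Terminal masking then replaces **every** T in the
first and last three read positions with N — not only T over reference C.
This is deliberately aggressive: at a position where the endogenous allele
truly is T, a terminal T is indistinguishable from damage on a C allele,
so masking all terminal Ts removes the damage signal entirely at the cost
of discarding some genuine T evidence, which interior coverage restores.
On fragments shorter than six bases the two windows overlap and every
position is treated as terminal.

## Consensus

Pileup counts exclude N bases; wrapping fragments contribute to both ends
of the coordinate system. A position is called when coverage ≥ `min_cov`
(default 5) **and** majority support ≥ `min_support` (default 0.8), both
inclusive — "at least" semantics. Positions with adequate coverage but
failing support are reported as heteroplasmy candidates with their counts
and left uncalled; the package never resolves them into the sequence.
Majority ties are broken deterministically in A<C<G<T order, which can
matter only at support ≤ 0.5, far below any sensible calling threshold.
Manually curated regions (e.g. a homopolymer stretch corrected after
visual inspection) are supported as explicit position/base patches applied
after calling and marked `patched`; no automatic homopolymer logic is
attempted because such corrections are judgement calls the software should
record, not invent.

## Contamination estimation

Diagnostic positions are called consensus sites differing from every panel
member (panel-N or consensus-N sites excluded). Each fragment contributes
one Bernoulli observation per diagnostic position it covers; observations
are pooled across positions, because a single ~55-bp fragment essentially
never spans two diagnostic sites placed thousands of bases apart. Bases
that are neither the endogenous nor a panel state (third alleles, N) are
excluded from numerator and denominator and reported separately as putative
damage/error. Estimation runs on terminally-masked fragments so that
residual deamination cannot masquerade as a panel-state observation at
T-segregating sites; the deaminated/all split is made *before* masking,
since the filter needs the terminal T evidence that masking erases.
Intervals are Wilson 95 % (better small-count behaviour than Wald).

## Clock

Private substitutions are called consensus positions differing from the
root and — when a panel is supplied — from every panel member; uncalled
positions are excluded and reported, and the effective site count
`L_effective = L − uncomparable` is used in place of the full genome length
to avoid bias from masked regions. The point estimate is `t = k/(μ·L)` with
the default rate μ = 2.67 × 10⁻⁸ substitutions·site⁻¹·yr⁻¹. Interval:
exact (Garwood) Poisson bounds on the expected count, divided by μ·L; at
k = 0 the lower bound is 0 and the upper reduces to −ln(α/2)/(μ·L). With
k = 10 these bounds are wide (≈ 10,800–41,600 y around a 22,600-y point
estimate) — substantially wider than intervals obtainable by propagating
rate uncertainty through a tree-based posterior, which this package does
not attempt. When a rate interval is supplied, the envelope of the bounds
over [μ_lo, μ_hi] is reported alongside.

## Radiocarbon QC and calibration

C:N ratios come either from a molecular formula (#C/#N; hydroxyproline
C₅H₉NO₃ gives the theoretical 5.0) or from mass percentages via atomic
masses 12.011 and 14.007. Percent yield is reported to one decimal. F¹⁴C
uses the Libby mean life 8,033 y (the universal convention for
conventional ages). Calibration evaluates, on a 1-year calendar grid over
the curve support, `mass(θ) ∝ exp(−(age − μ(θ))²/(2(σ² + τ(θ)²)))` with the
curve linearly interpolated and a flat calendar prior, then normalises.
The σ-dependent Gaussian prefactor is deliberately omitted: with
slowly-varying τ its effect is far below reporting resolution, and the
simpler kernel makes the identity-curve behaviour exactly Gaussian.
Reported ranges are highest-posterior-density sets at p = 0.954 by default
(the two-sigma convention of common calibration software; p is a flag, so
0.950 is available), with ties broken toward older ages and bounds rounded
outward to 10 years, matching conventional reporting. Posterior mass
truncated at the curve edge raises a warning. The curve reader accepts the
`.14c` CSV dialect (comment lines `#`, first three numeric columns =
cal BP, ¹⁴C age, 1σ error) as well as whitespace-separated tables, and
sorts rows by calendar age.

## Problem sizes and numerical checks

The test battery validates, among others: end-to-end consensus recovery
(five replicates of 30,000 fragments on the full 16,569-bp reference at
30 % contamination, ≥ 99.9 % called-position accuracy and all 10 planted
private substitutions recovered); Wilson-interval coverage for the
contamination estimator (100 replicates at truth 0.30 with ≥ 500
informative observations each, on a 5-kb reference to keep the battery
fast — diagnostic sites then sit far enough apart that pooled observations
are effectively independent); damage-rate recovery within 3 binomial SE;
Poisson-interval coverage at a fixed true divergence time; and HPD
selection against exhaustive subset enumeration on small grids. The
acceptance script simulates three libraries of 15,000 fragments at
contamination 0.20/0.35/0.42 — spanning the range a badly handled specimen
can show — which yields ≈ 150× raw and ≈ 37× deaminated-only coverage,
comfortably above the calling thresholds. All simulation sizes are the
package's own choices balancing statistical resolution against quick,
repeatable runs.

## Known limitations

* Gapless model: indels are neither simulated nor called.
* No quality-aware calling and no probabilistic damage-model fitting
  (no maximum-likelihood estimation of δ/λ).
* The contamination estimator assumes contaminants match the panel at
  diagnostic sites; a contaminant lineage absent from the panel biases the
  estimate downward.
* Calibration handles a single determination; no multi-date phase/sequence
  modelling, no marine or reservoir corrections.
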