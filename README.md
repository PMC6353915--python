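# paleomito

Authentication, decontamination, consensus calling and dating of ancient
mitochondrial genomes from heavily contaminated skeletal material.

When a bone yields a sequencing library that is a mixture of authentic
ancient molecules and present-day human contamination, reconstructing a
trustworthy mtDNA genome requires exploiting the one signature contamination
does not share: post-mortem cytosine deamination, read as C→T substitutions
concentrated at fragment ends (at *both* ends for single-stranded libraries).
`paleomito` implements that analysis chain as a tested, reusable library and
CLI, aimed at ancient-DNA practitioners and methods developers:

1. **Preprocess** — discard fragments < 35 bp, fuse PCR duplicates sharing
   alignment start/end coordinates (per-column majority, ties → N), and
   tabulate unique-fragment counts and coverage per library.
2. **Authenticate** — per-position terminal C→T mismatch profiles, plus the
   same profiles *conditional* on a C→T at the opposite end: in a mixture of
   damaged (ancient) and undamaged (modern) molecules the conditional
   frequency exceeds the unconditional one.
3. **Decontaminate** — restrict to fragments carrying a C→T in their first
   or last three read positions, then mask all terminal T bases to N.
4. **Call the consensus** — threshold calling on the pileup: a base is
   called where coverage ≥ 5 and ≥ 80 % of fragments agree; well-covered
   positions failing the support rule are reported as heteroplasmy
   candidates and left uncalled.
5. **Estimate contamination** — at diagnostic positions (sites where the
   consensus differs from every member of a present-day panel), the fraction
   of fragment observations carrying a panel state, with Wilson 95 % CIs,
   before and after the deamination filter.
6. **Date the lineage** — a Poisson molecular clock on the `k` private
   substitutions over `L` comparable sites: `t = k / (μ·L)`, with exact
   (Garwood) Poisson confidence bounds; and, on the radiocarbon side,
   collagen-QC arithmetic (atomic C:N, percent yield, F¹⁴C = exp(−age/8033))
   and calibration of a conventional ¹⁴C age against a tabulated curve with
   highest-posterior-density calendar ranges.

A first-class synthetic-data module generates labelled fragment sets with
exactly the structure these estimators assume — endogenous molecules with
terminal-decaying C→T damage, panel-drawn contaminants, a 35-bp length
floor, sequencing error and coordinate-sharing duplicates — so the entire
pipeline is validated against planted ground truth without any sequencing
data.

## Worked example

```python
from paleomito.pipeline import run_pipeline

report = run_pipeline({
    "seed": 1,
    "input": {"sim": {
        "L": 16_569, "k_private": 10, "n_panel": 311, "panel_div": 20,
        "duplicate_rate": 0.02,
        "libraries": [{"name": "libB", "n_fragments": 15_000,
                       "contamination": 0.20}],
    }},
})
b = report["libraries"][0]
contam = report["contamination"]
print(b["ct_5p_percent"], b["cond_ct_5p_percent"])
print(round(contam["all"]["__pooled__"]["percent"], 1),
      round(contam["deaminated_only"]["__pooled__"]["percent"], 1))
print(report["clock"]["k_private"], round(report["clock"]["t_point_years"]))
```

prints

```
32.3 42.5
21.5 3.3
10 22619
```

i.e. the library shows 32.3 % terminal 5′ C→T rising to 42.5 % when
conditioning on damage at the 3′ end (the signature of an
ancient/modern mixture); the contamination estimate at the 10 diagnostic
positions falls from 21.5 % to 3.3 % once only deaminated fragments are
used; and the consensus recovers all 10 planted private substitutions,
dating the lineage's divergence to ≈ 22,600 years at
μ = 2.67 × 10⁻⁸ substitutions · site⁻¹ · yr⁻¹ (over the 16,558 positions
called at this single-library coverage).

The same stages are available from the shell:

```bash
paleomito simulate --config sim.yaml --seed 1 --out simdir/
paleomito preprocess --in simdir/fragments.tsv -L 16569 --out unique.tsv
paleomito filter-deam --in unique.tsv --ref simdir/reference.fa --out deam.tsv
paleomito consensus --in deam.tsv --ref simdir/reference.fa --out cons.fa
paleomito contam --in unique.tsv --consensus cons.fa \
    --panel simdir/panel.fa --ref simdir/reference.fa --out contam.json
paleomito clock --consensus cons.fa --root simdir/reference.fa \
    --panel simdir/panel.fa --out clock.json
paleomito calibrate --age 30430 --sigma 300 --curve intcal13.14c --p 0.954
```

`paleomito ingest` converts mapped SAM/BAM records (secondary/supplementary
dropped, soft-clips trimmed, indel-containing reads excluded) into the
fragment TSV dialect the other commands consume, and `paleomito run` drives
everything from one YAML config into an auditable run directory.

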