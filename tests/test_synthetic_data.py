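"""The simulator must produce mixtures with the structure the estimators assume."""

import numpy as np
import pytest

from paleomito._seq import ref_window, revcomp
from paleomito.synthetic_data import (
    DamageModel,
    SimConfig,
    generate_haplotypes,
    generate_reference,
    simulate_fragments,
)


class TestGenerateReference:
    def test_length_and_determinism(self):
        ref = generate_reference(L=16_569, seed=1)
        assert ref.length == 16_569
        assert ref.sequence == generate_reference(L=16_569, seed=1).sequence

    def test_seed_changes_sequence(self):
        assert (
            generate_reference(L=2000, seed=1).sequence
            != generate_reference(L=2000, seed=2).sequence
        )

    def test_base_composition_roughly_uniform(self):
        # binomial bound: at n=2000, each base frequency within 0.25 +/- 0.05
        seq = generate_reference(L=2000, seed=7).sequence
        for base in "ACGT":
            assert abs(seq.count(base) / 2000 - 0.25) < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="below minimum"):
            generate_reference(L=999, seed=0)


class TestGenerateHaplotypes:
    def test_planted_positions_are_diagnostic(self, small_ref):
        """Exhaustive comparison oracle: the planted private positions are
        exactly the sites where the endogenous haplotype differs from the
        root and from every panel member."""
        haps = generate_haplotypes(
            small_ref, k_private=2, n_panel=3, panel_div=5, seed=42
        )
        root = haps.root.sequence
        endo = haps.endogenous.sequence
        diagnostic = [
            i
            for i in range(len(root))
            if endo[i] != root[i]
            and all(endo[i] != h.sequence[i] for h in haps.panel)
        ]
        assert diagnostic == haps.private_positions
        assert len(diagnostic) == 2

    def test_zero_private_is_root(self, small_ref):
        haps = generate_haplotypes(small_ref, k_private=0, n_panel=2,
                                   panel_div=3, seed=1)
        assert haps.endogenous.sequence == small_ref.sequence

    def test_panel_divergence_count(self, small_ref):
        haps = generate_haplotypes(small_ref, k_private=3, n_panel=5,
                                   panel_div=7, seed=3)
        for h in haps.panel:
            diffs = sum(
                a != b for a, b in zip(h.sequence, small_ref.sequence)
            )
            assert diffs == 7

    def test_excessive_substitutions_rejected(self, small_ref):
        with pytest.raises(ValueError, match="exceed available"):
            generate_haplotypes(small_ref, k_private=1500, n_panel=1,
                                panel_div=1000, seed=0)


class TestSimulateFragments:
    def test_zero_contamination_all_endogenous(self, small_haps):
        cfg = SimConfig(n_fragments=200, contamination_fraction=0.0, seed=1)
        frags = simulate_fragments(small_haps, cfg)
        assert all(f.truth_label == "endogenous" for f in frags)

    def test_contaminant_count_binomial(self, small_haps):
        # n=1000, fraction 0.3: contaminant count within 300 +/- 3*sqrt(npq)
        cfg = SimConfig(n_fragments=1000, contamination_fraction=0.3, seed=5)
        frags = simulate_fragments(small_haps, cfg)
        n_cont = sum(f.truth_label == "contaminant" for f in frags)
        assert abs(n_cont - 300) <= 3 * np.sqrt(1000 * 0.3 * 0.7)

    def test_label_conservation(self, small_haps):
        cfg = SimConfig(n_fragments=500, contamination_fraction=0.4,
                        duplicate_rate=0.0, seed=2)
        frags = simulate_fragments(small_haps, cfg)
        n_endo = sum(f.truth_label == "endogenous" for f in frags)
        n_cont = sum(f.truth_label == "contaminant" for f in frags)
        assert n_endo + n_cont == 500

    def test_determinism_byte_identical(self, small_haps):
        cfg = SimConfig(n_fragments=300, contamination_fraction=0.2,
                        duplicate_rate=0.1, seed=9)
        a = simulate_fragments(small_haps, cfg)
        b = simulate_fragments(small_haps, cfg)
        assert [(f.id, f.start, f.end, f.strand, f.sequence) for f in a] == [
            (f.id, f.start, f.end, f.strand, f.sequence) for f in b
        ]

    def test_length_floor_and_cap(self, small_haps):
        cfg = SimConfig(n_fragments=2000, seed=3)
        lengths = [f.length for f in simulate_fragments(small_haps, cfg)]
        assert min(lengths) >= 35
        assert max(lengths) <= 150

    def test_terminal_damage_rate_recovered(self, small_haps):
        """Bernoulli counting oracle: with pure endogenous input, no
        background damage and no sequencing error, the observed C->T
        frequency at read position 0 over reference-C sites recovers
        delta_term within 3 binomial SE."""
        cfg = SimConfig(
            n_fragments=4000,
            contamination_fraction=0.0,
            damage=DamageModel(delta_term=0.4, delta_bg=0.0, seq_error=0.0),
            seed=21,
        )
        frags = simulate_fragments(small_haps, cfg)
        endo = small_haps.endogenous.sequence
        sites = obs = 0
        for f in frags:
            window = ref_window(endo, f.start, f.end)
            mol_ref = revcomp(window) if f.strand == "-" else window
            read = revcomp(f.sequence) if f.strand == "-" else f.sequence
            if mol_ref[0] == "C":
                sites += 1
                obs += read[0] == "T"
        freq = obs / sites
        se = np.sqrt(0.4 * 0.6 / sites)
        assert abs(freq - 0.4) <= 3 * se

    def test_damage_asymmetry_between_labels(self, mixture_frags, small_haps):
        """Endogenous fragments must show more terminal C->T (against the
        reference) than contaminants whenever delta_term > 0."""
        ref = small_haps.root.sequence

        def terminal_ct_rate(frags):
            sites = obs = 0
            for f in frags:
                window = ref_window(ref, f.start, f.end)
                r = revcomp(window) if f.strand == "-" else window
                s = revcomp(f.sequence) if f.strand == "-" else f.sequence
                for i in (0, len(s) - 1):
                    if r[i] == "C":
                        sites += 1
                        obs += s[i] == "T"
            return obs / sites

        endo = [f for f in mixture_frags if f.truth_label == "endogenous"]
        cont = [f for f in mixture_frags if f.truth_label == "contaminant"]
        assert len(endo) + len(cont) >= 4000
        assert terminal_ct_rate(endo) > terminal_ct_rate(cont)

    def test_origin_spanning_fragments_reconstruct(self, small_haps):
        """Circularity: an undamaged fragment wrapping the origin equals the
        corresponding window of the doubled source sequence."""
        cfg = SimConfig(
            n_fragments=3000,
            contamination_fraction=0.0,
            damage=DamageModel(delta_term=0.0, delta_bg=0.0, seq_error=0.0),
            seed=4,
        )
        frags = simulate_fragments(small_haps, cfg)
        endo = small_haps.endogenous.sequence
        doubled = endo + endo
        wrapped = [f for f in frags if f.end > len(endo)]
        assert wrapped, "expected some origin-spanning fragments"
        for f in wrapped:
            # stored bases are reference-forward regardless of strand
            assert f.sequence == doubled[f.start : f.end]

    def test_duplicates_share_coordinates(self, small_haps):
        cfg = SimConfig(n_fragments=500, duplicate_rate=1.0, seed=6)
        frags = simulate_fragments(small_haps, cfg)
        assert len(frags) == 1000
        by_molecule = {}
        for f in frags:
            by_molecule.setdefault(f.id.split(".dup")[0], []).append(f)
        for members in by_molecule.values():
            assert len(members) == 2
            assert len({(m.start, m.end, m.strand) for m in members}) == 1
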