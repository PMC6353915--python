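"""Deamination profiling, conditional enrichment, filtering and masking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleomito._seq import revcomp
from paleomito.damage import (
    FIVE_PRIME,
    THREE_PRIME,
    conditional_profile,
    filter_deaminated,
    is_deaminated,
    mask_fragments,
    mask_terminal_t,
    mismatch_profile,
)
from paleomito.fragment_io import AlignedFragment
from paleomito.synthetic_data import (
    DamageModel,
    SimConfig,
    generate_reference,
    simulate_fragments,
)

REF = "C" * 20 + "A" * 20 + "C" * 20 + "A" * 940  # length 1000 < genome min, fine here


def frag(seq, start=0, strand="+", id="f", library="l"):
    return AlignedFragment(id=id, library=library, start=start,
                           end=start + len(seq), strand=strand, sequence=seq)


class TestMismatchProfile:
    def test_identical_to_reference_gives_zero(self):
        frags = [frag("C" * 10, start=0), frag("A" * 10, start=20)]
        prof = mismatch_profile(frags, REF, n_pos=5)
        assert np.nansum(prof.five_prime_obs) == 0
        assert np.nansum(prof.three_prime_obs) == 0

    def test_counting_oracle_forty_percent(self):
        # 10 fragments over ref C at read position 0; 4 read T
        frags = [
            frag(("T" if i < 4 else "C") + "C" * 9, start=0, id=f"f{i}")
            for i in range(10)
        ]
        prof = mismatch_profile(frags, REF, n_pos=3)
        assert prof.five_prime_sites[0] == 10
        assert prof.five_prime_obs[0] == 4
        assert prof.five_prime_freq[0] == pytest.approx(0.40)

    def test_non_c_reference_excluded_from_denominator(self):
        frags = [frag("AAAA", start=20)]  # ref A at every position
        prof = mismatch_profile(frags, REF, n_pos=2)
        assert prof.five_prime_sites[0] == 0
        assert np.isnan(prof.five_prime_freq[0])

    def test_n_bases_excluded(self):
        frags = [frag("N" + "C" * 9, start=0)]
        prof = mismatch_profile(frags, REF, n_pos=1)
        assert prof.five_prime_sites[0] == 0

    def test_minus_strand_counts_in_read_orientation(self):
        # aligned bases ref-forward; read 5' of a minus fragment is the
        # right-hand coordinate. Ref window CCCC; aligned GGGA reads
        # revcomp = TCCC: C->T at read position 0.
        f = frag("GGGA", start=0, strand="-")
        ref = "G" * 1000
        prof = mismatch_profile([f], ref, n_pos=2)
        # read-oriented reference is revcomp("GGGG") = CCCC
        assert prof.five_prime_sites[0] == 1
        assert prof.five_prime_obs[0] == 1


class TestConditionalProfile:
    def test_mixture_algebra(self, small_haps):
        """50/50 mixture of damaged (delta=0.4) and undamaged molecules with
        no background damage or error: conditioning on a 3' C->T selects the
        damaged component, so the 5' terminal frequency rises from ~0.2
        (unconditional) to ~0.4 (conditional)."""
        damaged = SimConfig(
            n_fragments=4000, contamination_fraction=0.0,
            damage=DamageModel(delta_term=0.4, delta_bg=0.0, seq_error=0.0),
            seed=31, library="m",
        )
        undamaged = SimConfig(
            n_fragments=4000, contamination_fraction=0.0,
            damage=DamageModel(delta_term=0.0, delta_bg=0.0, seq_error=0.0),
            seed=32, library="m",
        )
        frags = (simulate_fragments(small_haps, damaged)
                 + simulate_fragments(small_haps, undamaged))
        ref = small_haps.root.sequence
        uncond = mismatch_profile(frags, ref)
        cond = conditional_profile(frags, ref, cond_end=THREE_PRIME)
        se_u = np.sqrt(0.2 * 0.8 / uncond.five_prime_sites[0])
        se_c = np.sqrt(0.4 * 0.6 / cond.five_prime_sites[0])
        assert uncond.five_prime_freq[0] == pytest.approx(0.20, abs=3 * se_u)
        assert cond.five_prime_freq[0] == pytest.approx(0.40, abs=3 * se_c)

    def test_conditional_at_least_unconditional(self, mixture_frags, small_haps):
        ref = small_haps.root.sequence
        uncond = mismatch_profile(mixture_frags, ref)
        for cond_end, attr in [(THREE_PRIME, "five_prime_freq"),
                               (FIVE_PRIME, "three_prime_freq")]:
            cond = conditional_profile(mixture_frags, ref, cond_end=cond_end)
            assert getattr(cond, attr)[0] >= getattr(uncond, attr)[0]

    def test_empty_conditioning_set_flagged(self):
        frags = [frag("C" * 10)]
        prof = conditional_profile(frags, REF, cond_end=THREE_PRIME)
        assert prof.conditional
        assert prof.empty
        assert prof.five_prime_sites.sum() == 0


class TestIsDeaminated:
    def test_terminal_ct_detected(self):
        assert is_deaminated(frag("CTC" + "C" * 7), REF)  # position 1

    def test_no_mismatch_false(self):
        assert not is_deaminated(frag("C" * 10), REF)

    def test_interior_ct_not_terminal(self):
        # C->T only at position 3 from each end of an 8-mer: outside windows
        assert not is_deaminated(frag("CCCTTCCC", start=0), REF)

    def test_short_fragment_windows_overlap(self):
        assert is_deaminated(frag("CTCC", start=0), REF, n_terminal=3)


class TestFilterDeaminated:
    def test_all_undamaged_empty(self):
        assert filter_deaminated([frag("C" * 10)], REF) == []

    def test_idempotent(self, mixture_frags, small_haps):
        ref = small_haps.root.sequence
        once = filter_deaminated(mixture_frags, ref)
        assert filter_deaminated(once, ref) == once

    def test_enriches_for_endogenous(self, mixture_frags, small_haps):
        """Truth-label oracle: the contaminant share among retained
        fragments must drop below the overall contaminant share."""
        ref = small_haps.root.sequence
        kept = filter_deaminated(mixture_frags, ref)

        def cont_share(fr):
            return sum(f.truth_label == "contaminant" for f in fr) / len(fr)

        assert cont_share(kept) < cont_share(mixture_frags)


class TestMaskTerminalT:
    def test_direct_application(self):
        f = frag("TTACGT")
        assert mask_terminal_t(f, n=3).sequence == "NNACGN"

    def test_no_terminal_t_unchanged(self):
        f = frag("CCACGC")
        assert mask_terminal_t(f, n=3).sequence == "CCACGC"

    def test_short_fragment_fully_terminal(self):
        f = frag("TATTA")
        assert mask_terminal_t(f, n=3).sequence == "NANNA"

    def test_minus_strand_masks_read_orientation_t(self):
        # stored bases are reference-forward; the read is their revcomp,
        # so a read-terminal T is a stored A at the opposite end
        f = frag("AAAGGCCC", strand="-")  # read = GGGCCTTT
        masked = mask_terminal_t(f, n=3)
        assert revcomp(masked.sequence) == "GGGCCNNN"
        assert masked.sequence == "NNNGGCCC"

    def test_idempotent_and_preserves_other_bases(self, mixture_frags):
        masked = mask_fragments(mixture_frags, 3)
        again = mask_fragments(masked, 3)
        assert [f.sequence for f in again] == [f.sequence for f in masked]
        for before, after in zip(mixture_frags, masked):
            assert len(before.sequence) == len(after.sequence)
            for a, b in zip(before.sequence, after.sequence):
                if a != b:
                    assert b == "N"

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=30),
           st.integers(min_value=0, max_value=5))
    @settings(max_examples=50, deadline=None)
    def test_property_only_terminal_t_changes(self, seq, n):
        f = frag(seq)
        masked = mask_terminal_t(f, n=n).sequence
        m = len(seq)
        terminal = set(range(min(n, m))) | set(range(max(m - n, 0), m))
        for i, (a, b) in enumerate(zip(seq, masked)):
            if i in terminal and a == "T":
                assert b == "N"
            else:
                assert b == a


class TestDamageRateRecovery:
    def test_delta_term_recovered_within_3_se(self):
        """Profiling the simulator's endogenous output recovers the planted
        terminal damage intensity within 3 binomial SE."""
        ref = generate_reference(L=3000, seed=51)
        from paleomito.synthetic_data import generate_haplotypes

        haps = generate_haplotypes(ref, k_private=2, n_panel=2, panel_div=2,
                                   seed=52)
        cfg = SimConfig(
            n_fragments=6000, contamination_fraction=0.0,
            damage=DamageModel(delta_term=0.35, delta_bg=0.0, seq_error=0.0),
            seed=53,
        )
        frags = simulate_fragments(haps, cfg)
        prof = mismatch_profile(frags, ref.sequence)
        for freq, sites in [(prof.five_prime_freq[0], prof.five_prime_sites[0]),
                            (prof.three_prime_freq[0], prof.three_prime_sites[0])]:
            se = np.sqrt(0.35 * 0.65 / sites)
            assert abs(freq - 0.35) <= 3 * se
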