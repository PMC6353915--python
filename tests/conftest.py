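import pytest

from paleomito.synthetic_data import (
    DamageModel,
    SimConfig,
    generate_haplotypes,
    generate_reference,
    simulate_fragments,
)


@pytest.fixture(scope="session")
def small_ref():
    """A 2 kb circular reference used by most unit tests."""
    return generate_reference(L=2000, seed=11)


@pytest.fixture(scope="session")
def small_haps(small_ref):
    return generate_haplotypes(
        small_ref, k_private=4, n_panel=8, panel_div=6, seed=12
    )


@pytest.fixture(scope="session")
def mixture_frags(small_haps):
    """A labelled 30% contaminated fragment set with default damage."""
    cfg = SimConfig(
        n_fragments=4000,
        contamination_fraction=0.3,
        duplicate_rate=0.05,
        damage=DamageModel(),
        seed=13,
        library="mix",
    )
    return simulate_fragments(small_haps, cfg)
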