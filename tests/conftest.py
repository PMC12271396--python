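import pytest

from admixscreen.simulate import (
    ClusterSpec,
    simulate_admixture_profiles,
    simulate_ancestral_freqs,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def small_panel():
    """Three-population Balding-Nichols panel, 400 sites, F = 0.15."""
    return simulate_ancestral_freqs(m=400, divergence=0.15, seed=101)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    """120-sample admixed cohort with ground truth on the small panel."""
    truth = simulate_admixture_profiles(ClusterSpec(n_samples=120), seed=102)
    g = simulate_genotypes(small_panel, truth, seed=103)
    return g, truth
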