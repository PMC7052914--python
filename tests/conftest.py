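import numpy as np
import pytest

from rpindex.simulate import SyntheticSpec, simulate_cohort


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small cohort with every artefact switched on: missingness, multi-allelic
    sites, off-reference calls and planted heterozygote-excess sites."""
    spec = SyntheticSpec(
        n_samples=80,
        n_snps=200,
        n_causal=3,
        causal_coefficients=(1.8, -1.6, 1.5),
        intercept=-0.3,
        maf_distribution=("uniform", 0.05, 0.5),
        missing_rate=0.02,
        fraction_multiallelic=0.03,
        fraction_offref=0.01,
        n_hwe_violating=4,
        seed=11,
    )
    return spec, *simulate_cohort(spec)


@pytest.fixture(scope="session")
def clean_cohort():
    """Artefact-free cohort whose encoding equals the simulated dosages."""
    spec = SyntheticSpec(
        n_samples=120,
        n_snps=100,
        n_causal=2,
        causal_coefficients=(2.0, -2.0),
        intercept=0.0,
        maf_distribution=("uniform", 0.1, 0.5),
        missing_rate=0.0,
        fraction_multiallelic=0.0,
        fraction_offref=0.0,
        seed=7,
    )
    return spec, *simulate_cohort(spec)
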