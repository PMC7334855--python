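import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_spec():
    """A small but complete simulation: 4 tissues x 3 samples, 200 genes."""
    from epimark.synthetic import SimulationSpec

    return SimulationSpec(
        seed=20240915, n_chrom=2, chrom_len=2_000_000, n_genes=200,
        n_tissues=4, samples_per_tissue=3, n_specific_per_tissue=12,
        n_markers=1000, n_traits=4, rho_modality=0.4,
    )


@pytest.fixture
def tiny_genes(tiny_spec):
    from epimark.synthetic import generate_genome_annotation

    return generate_genome_annotation(tiny_spec)


@pytest.fixture
def tiny_peaks(tiny_spec, tiny_genes):
    from epimark.synthetic import generate_peak_samples

    return generate_peak_samples(tiny_spec, tiny_genes)
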