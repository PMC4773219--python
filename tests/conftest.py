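import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rarecnv import SimulationConfig, run_pipeline, simulate

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


def small_config(seed: int = 17, **overrides) -> SimulationConfig:
    """A desk-sized study (20 samples, two small autosomes + chrX) for fast
    unit tests; the full 116-sample default is reserved for acceptance runs."""
    base = dict(
        seed=seed,
        chromosome_lengths={"chr1": 8_000_000, "chr2": 6_000_000, "chrX": 3_000_000},
        probe_spacing_bp=2_000,
        centromere_bp=1_000_000,
        n_case=8,
        n_control=12,
        p_male_case=0.8,
        p_male_control=0.6,
        n_cnp_loci=6,
        n_shared_rare_loci=2,
        case_singleton_rate=1.0,
        control_singleton_rate=0.8,
        recurrent_case_carriers=(2,),
        n_decoy_reference=8,
        n_genes=40,
        qc_probe_count=1_000,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_noiseless_bundle():
    return simulate(small_config().noiseless())


@pytest.fixture(scope="session")
def small_noisy_bundle():
    return simulate(small_config())


@pytest.fixture(scope="session")
def small_noiseless_result(small_noiseless_bundle):
    b = small_noiseless_bundle
    return run_pipeline(
        b.callsets, b.samples, b.annotation, b.manifest, b.reference_sets,
        signals=b.signals,
    )
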