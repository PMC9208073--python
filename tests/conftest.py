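import logging

import pytest

from ccrcc_wes.io_formats import RunConfig, VariantCall
from ccrcc_wes.synthetic import SimConfig, build_reference, simulate_cohort

logging.getLogger("ccrcc_wes").setLevel(logging.ERROR)


@pytest.fixture
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def reference():
    """Capture regions and cytobands of the default synthetic genome."""
    return build_reference(SimConfig())


@pytest.fixture(scope="session")
def mini_cohort():
    """A small in-memory cohort shared by read-only tests."""
    config = SimConfig(n_patients=6, n_multi_sample_patients=2, rng_seed=42)
    truth, obs = simulate_cohort(config)
    return config, truth, obs


def make_variant(**overrides) -> VariantCall:
    """A kept-by-default nonsynonymous SNV with sensible read support."""
    kwargs = dict(
        chrom="1", pos=1000, ref="A", alt="T", gene="GENE1",
        effect="missense", tumor_ref_reads=60, tumor_alt_reads=40,
        normal_ref_reads=100, normal_alt_reads=0,
    )
    kwargs.update(overrides)
    return VariantCall(**kwargs)


@pytest.fixture
def variant_factory():
    return make_variant
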