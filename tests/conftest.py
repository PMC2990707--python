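import dataclasses

import pytest

from cnvdosage.simulate import GeneratorConfig, generate_dataset, generate_strain_reference


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Desk-scale study: 800 probes, 200 on the CNV chromosome, 40 in the interval."""
    return GeneratorConfig(
        n_probes=800, n_cnv_chr_probes=200, n_interval_probes=40, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_reference(small_config, small_dataset):
    return generate_strain_reference(small_config, small_dataset)


@pytest.fixture(scope="session")
def noiseless_dataset(small_config):
    return generate_dataset(dataclasses.replace(small_config, noise_sd=0.0))
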