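import pytest

from glunet.synthetic import SimulationConfig, SyntheticDataset, generate_all


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    """The noiseless desk-scale study: 200 genes, 60 miRNAs, 2-fold effects,
    50 planted interactions, decoys at half the true rate, 40% IP support."""
    return SimulationConfig(
        n_genes=200,
        n_mirnas=60,
        noise_log2_sd=0.0,
        effect_size_log2=1.0,
        frac_true_mti=50 / (200 * 60),
        decoy_rate=0.5,
        ip_support_prob=0.4,
        seed=1,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config) -> SyntheticDataset:
    return generate_all(noiseless_config)
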