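import pytest

from polykmer import ModelParams, SimulationConfig, calibrate_theta_T, simulate_spectrum

# the study regime: 0.2% per-site heterozygosity, 5% sub-genome
# divergence, 30x per-copy depth, bias 2, k = 21
HET_PCT = 0.2
DIV_PCT = 5.0
C = 30.0
B = 2.0
K = 21


@pytest.fixture(scope="session")
def allo_params():
    theta, T = calibrate_theta_T(HET_PCT, DIV_PCT, K)
    return ModelParams(model="allotetraploid", c=C, G=2e6, b=B,
                       theta=theta, T=T, k=K)


@pytest.fixture(scope="session")
def diploid_params():
    theta, _ = calibrate_theta_T(HET_PCT, None, K)
    return ModelParams(model="diploid", c=C, G=2e6, b=B, theta=theta, k=K)


@pytest.fixture(scope="session")
def allo_spectrum(allo_params):
    """One simulated allotetraploid spectrum at the study regime."""
    config = SimulationConfig(params=allo_params, n_loci=500_000, seed=41)
    return simulate_spectrum(config)


@pytest.fixture(scope="session")
def diploid_spectrum(diploid_params):
    config = SimulationConfig(params=diploid_params, n_loci=500_000, seed=42)
    return simulate_spectrum(config)
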