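import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ufsieve as uf

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_design():
    return uf.default_design()


@pytest.fixture(scope="session")
def noiseless_truth():
    return uf.default_ground_truth(noise_sd_conc=0.0)


@pytest.fixture(scope="session")
def noiseless_datasets(default_design, noiseless_truth):
    return uf.simulate_dataset(default_design, noiseless_truth)


@pytest.fixture()
def single_condition_dataset():
    """Ten noise-free observations from known advection-model parameters."""
    v = np.linspace(1e-6, 1.5e-5, 10)
    r = uf.rejection_advection(0.97, v / 7.34e-6)
    return uf.RejectionDataset.from_arrays("one", v, r)


def random_microscopic(rng):
    """Random pore-scale parameters with Peclet numbers in the working range."""
    phi = rng.uniform(0.02, 0.9)
    K_c = rng.uniform(0.3, 1.0)
    K_d = rng.uniform(0.3, 1.0)
    D_i = 10 ** rng.uniform(-11, -10)
    D_m = 10 ** rng.uniform(-12, -11)
    pe_d = rng.uniform(0.1, 5.0)
    pe_m = rng.uniform(0.1, 5.0)
    v_w = 10 ** rng.uniform(-6, -5)
    return (
        uf.MicroscopicParameters(
            K_c=K_c, K_d=K_d, D_m=D_m, D_i=D_i,
            delta_mem=pe_m * K_d * D_m / (K_c * v_w),
            delta_pol=pe_d * D_i / v_w,
            phi=phi,
        ),
        v_w,
        pe_d,
        pe_m,
    )
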