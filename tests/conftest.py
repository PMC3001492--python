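import numpy as np
import pytest

from loopma.array_io import MASet
from loopma.design import build_pe_loop, pe_samples, study_design
from loopma.simulate import SimulationConfig, simulate_study
from loopma.temporal import temporal_design_matrix


@pytest.fixture(scope="session")
def full_design():
    return study_design()


@pytest.fixture(scope="session")
def pe_loop_16():
    return build_pe_loop(pe_samples())


@pytest.fixture(scope="session")
def small_study():
    """Default-condition synthetic study at a test-friendly probe count."""
    return simulate_study(SimulationConfig(n_probes=800, seed=11))


@pytest.fixture(scope="session")
def noiseless_study():
    cfg = SimulationConfig(
        n_probes=400,
        seed=2,
        noise_sd=0.0,
        dye_offset_sd=0.0,
        dye_trend_amplitude=0.0,
        flag_rate=0.0,
        a_noise_sd=0.0,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def null_pe_maset(pe_loop_16):
    """Gaussian-null M values over the 16-array PE loop (5,000 probes)."""
    rng = np.random.default_rng(123)
    n = 5000
    M = rng.normal(0.0, 0.3, (n, 16))
    return MASet(
        probes=[f"P{i:05d}" for i in range(n)],
        arrays=pe_loop_16.array_ids,
        M=M,
        A=np.full((n, 16), 10.0),
        W=np.ones((n, 16)),
    )


@pytest.fixture(scope="session")
def pe_design_matrix(pe_loop_16):
    return temporal_design_matrix(pe_loop_16)
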