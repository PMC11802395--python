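import numpy as np
import pytest

from clampkit.secretion import population_kinetics
from clampkit.simulate import SimNoise, SimTruth, simulate_clamp
from clampkit.tracer import ClampSeries, SteeleConfig


@pytest.fixture(scope="session")
def ref_kinetics():
    """Population C-peptide kinetics for a reference adult with T2D."""
    return population_kinetics(age=58, sex="male", bmi=33, diabetic=True, weight=100, height=172)


@pytest.fixture(scope="session")
def mmtt_grid():
    return np.arange(0.0, 121.0, 10.0)


def make_constant_series(
    glucose=5.0, ttr=0.01, f=0.02, gir=0.0, insulin=600.0, cpep=1200.0, n_per_phase=12, dt=5.0
):
    """Clamp series with every channel constant (exact steady state)."""
    n = 3 * n_per_phase
    t = np.arange(n) * dt
    phase = np.array(["basal"] * n_per_phase + ["step1"] * n_per_phase + ["step2"] * n_per_phase)
    return ClampSeries(
        time=t,
        glucose=np.full(n, glucose),
        ttr=np.full(n, ttr),
        tracer_inf=np.full(n, f),
        gir=np.full(n, gir),
        insulin=np.full(n, insulin),
        c_peptide=np.full(n, cpep),
        phase=phase,
    )


@pytest.fixture
def constant_series():
    return make_constant_series()


@pytest.fixture(scope="session")
def noiseless_clamp():
    """One noise-free forward-simulated clamp with its truth table."""
    truth = SimTruth(noise=SimNoise.none(), seed=1)
    series, truth_df = simulate_clamp(truth)
    return series, truth_df


@pytest.fixture(scope="session")
def steele_exact():
    """Config for noiseless data: interpolating spline, no smoothing."""
    return SteeleConfig(smoothing="none")
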