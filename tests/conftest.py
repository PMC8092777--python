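"""Shared fixtures: reference kinematics, synthetic tracks and cached runs.

Simulation fixtures are session-scoped and deliberately modest in size
(24 panels, 50 steps per tail-beat period, 4 periods with 2 discarded) so
the whole suite stays interactive; convergence tests refine from there.
"""

from __future__ import annotations

import numpy as np
import pytest

from fishwake.hydro import SimConfig, balance_frequency, simulate
from fishwake.kinematics import MEASURED_SWIMMING_PARAMS, BodyWaveParams
from fishwake.synthetic import TrackGenConfig, generate_track

#: Station layout used for estimation round trips: four head-region points
#: (x < 0.25) and six tail-region points (x > 0.4), tail tip at 1.13 BL.
FIT_STATIONS = (0.05, 0.1, 0.15, 0.2, 0.45, 0.6, 0.75, 0.85, 1.0, 1.13)

#: Discretization of the shared solver fixtures.
COARSE = dict(n_panels=24, steps_per_period=50, n_periods=4, transient_periods=2)


@pytest.fixture(scope="session")
def params152() -> BodyWaveParams:
    """Fitted body-wave constants of the 1.52 BL/s steady-swimming condition."""
    return MEASURED_SWIMMING_PARAMS[1.52]


@pytest.fixture(scope="session")
def rigid_params() -> BodyWaveParams:
    """Zero-envelope wave: the body does not deform."""
    return BodyWaveParams(a=0.0, b=-1.0, c=0.0, d=1.0, wavelength=1.0, frequency=2.12)


@pytest.fixture(scope="session")
def clean_track(params152):
    """Noiseless 60 fps, 4 s synthetic track on the fitting stations."""
    return generate_track(
        TrackGenConfig(params=params152, stations=FIT_STATIONS, fps=60.0, duration=4.0)
    )


@pytest.fixture(scope="session")
def solitary_run(params152):
    return simulate(SimConfig.solitary(1.52, params152, **COARSE))


@pytest.fixture(scope="session")
def solitary_run_uncapped(params152):
    """Same run without wake truncation, for momentum bookkeeping checks."""
    return simulate(
        SimConfig.solitary(1.52, params152, wake_cap_L=50.0, **COARSE)
    )


@pytest.fixture(scope="session")
def rigid_run(rigid_params):
    return simulate(SimConfig.solitary(1.52, rigid_params, **COARSE))


@pytest.fixture(scope="session")
def antiphase_run(params152):
    return simulate(
        SimConfig.pair(1.52, params152, separation_L=0.8, phase_relation="antiphase", **COARSE)
    )


@pytest.fixture(scope="session")
def inphase_run(params152):
    return simulate(
        SimConfig.pair(1.52, params152, separation_L=0.8, phase_relation="inphase", **COARSE)
    )


@pytest.fixture(scope="session")
def fine_solitary_run(params152):
    """Doubled panels and halved timestep relative to ``solitary_run``."""
    return simulate(
        SimConfig.solitary(
            1.52, params152, n_panels=48, steps_per_period=100,
            n_periods=4, transient_periods=2,
        )
    )


@pytest.fixture(scope="session")
def balanced_frequency(params152):
    """Self-propelled tail-beat frequency of the coarse solitary setup."""
    config = SimConfig.solitary(1.52, params152, **COARSE)
    return balance_frequency(config, bracket=(0.9, 2.8))


@pytest.fixture(scope="session")
def balanced_run(params152, balanced_frequency):
    config = SimConfig.solitary(1.52, params152, **COARSE)
    return simulate(config.with_frequency(balanced_frequency))
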