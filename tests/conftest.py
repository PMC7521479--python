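"""Shared fixtures: default model objects and a few expensive reference runs.

The long coupled runs (traveling wave, line oscillation, default 2D
orientation) are computed once per session and shared across tests.
"""

import numpy as np
import pytest

import spindlecortex as sc


@pytest.fixture(scope="session")
def kinetics():
    return sc.LgnKinetics()


@pytest.fixture(scope="session")
def mt():
    return sc.MicrotubuleModel.exponential()


@pytest.fixture(scope="session")
def domain():
    return sc.Domain1D(80.0, periodic=True)


@pytest.fixture(scope="session")
def traveling_run(kinetics, mt, domain):
    """Default coupled monopolar run, long enough to settle into the wave."""
    spindle = sc.MonopolarSpindle(dna_center=40.0)
    return sc.simulate_monopolar(kinetics, spindle, mt, domain, T=450.0,
                                 seed=1, sample_interval=2.0)


@pytest.fixture(scope="session")
def line_run(kinetics, mt):
    """Default run on a 60 μm micropatterned line."""
    dom = sc.Domain1D(60.0, periodic=False)
    spindle = sc.MonopolarSpindle(dna_center=30.0)
    return sc.simulate_on_line(kinetics, spindle, mt, dom, T=450.0, seed=1,
                               sample_interval=2.0)


@pytest.fixture(scope="session")
def orientation_run(kinetics, mt):
    """Default 2D rounding + orientation run from φ0 = π/4."""
    schedule = sc.RoundingSchedule()
    spindle = sc.SpindleState2D(phi=np.pi / 4)
    return sc.run_orientation(schedule, spindle, kinetics, mt, T=49.0)


@pytest.fixture(scope="session")
def basin_runs(kinetics, mt):
    """Orientation runs over 12 initial angles x 4 LGN levels."""
    phi0 = np.linspace(-np.pi / 2, np.pi / 2, 14)[1:-1]
    runs = {}
    for scale in (1.0, 0.5, 0.2, 0.05):
        runs[scale] = [
            sc.run_orientation(sc.RoundingSchedule(),
                               sc.SpindleState2D(phi=float(p)), kinetics, mt,
                               lgn_scale=scale, T=49.0, sample_interval=2.0)
            for p in phi0
        ]
    return runs


@pytest.fixture(scope="session")
def monopolar_frames_run(kinetics, mt, domain):
    """Defaults sampled at 3-min frames for 120 min (quantification input)."""
    spindle = sc.MonopolarSpindle(dna_center=40.0, v0=6.7)
    return sc.simulate_monopolar(kinetics, spindle, mt, domain, T=120.0,
                                 seed=3, sample_interval=3.0)
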