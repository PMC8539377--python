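"""Shared fixtures: the calibrated system parameters and (session-scoped)
synthetic through-focus series used across analysis and acceptance tests."""

import numpy as np
import pytest

from octsim.beam_optics import BeamParameters, WavenumberGrid
from octsim.synthetic_io import (ExperimentRecipe, default_focus_setup,
                                 default_wavenumber_grid,
                                 generate_focus_series)

#: calibrated beam waist [μm] and acceptance half-angle [deg]
W0 = 14.15
THETA_MAX = 1.5709
#: tilt of the through-focus experiments [deg] and coverglass parameters
TILT = 2.75
N_COVERGLASS = 1.5088
THICKNESS = 150.0


@pytest.fixture(scope="session")
def sweep_grid() -> WavenumberGrid:
    return default_wavenumber_grid()


@pytest.fixture(scope="session")
def beam() -> BeamParameters:
    return BeamParameters(w0=W0, r0=-1000.0)


@pytest.fixture(scope="session")
def focus_setup():
    """(beam, geometry, x3_center) of the through-focus configuration."""
    return default_focus_setup(tilt_deg=TILT, w0=W0, theta_max_deg=THETA_MAX)


@pytest.fixture(scope="session")
def mirror_series(focus_setup, sweep_grid):
    b, geom, x3c = focus_setup
    recipe = ExperimentRecipe(kind="focus_series", seed=11)
    return generate_focus_series(recipe, "mirror", b, geom, sweep_grid, x3c,
                                 tilt_deg=TILT)


@pytest.fixture(scope="session")
def coverglass_series(focus_setup, sweep_grid):
    b, geom, x3c = focus_setup
    recipe = ExperimentRecipe(kind="focus_series", seed=7,
                              n_stage_positions=7)
    return generate_focus_series(recipe, "coverglass", b, geom, sweep_grid,
                                 x3c, tilt_deg=TILT, n1=N_COVERGLASS,
                                 thickness=THICKNESS)
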