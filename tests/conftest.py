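import numpy as np
import pytest

from ettnir import (
    ElectronicsSpec,
    SensorGeometry,
    SpotProfileParams,
    default_tracheal_stack,
    fit_calibration,
    generate_calibration_log,
    make_forward_curves,
    run_mc,
    smooth_profile,
)
from ettnir.calibration import calibration_set_from_log
from ettnir.montecarlo import SourceSpec


@pytest.fixture(scope="session")
def stack():
    return default_tracheal_stack()


@pytest.fixture(scope="session")
def mc_profile(stack):
    """One moderately sized planar run on the default stack, shared by tests."""
    profile, tally = run_mc(stack, SourceSpec(n_packets=300_000, seed=9))
    return smooth_profile(profile, 6), tally


@pytest.fixture(scope="session")
def geometry():
    return SensorGeometry()


@pytest.fixture(scope="session")
def electronics():
    return ElectronicsSpec()


@pytest.fixture(scope="session")
def pseudo_curves(geometry):
    return make_forward_curves(SpotProfileParams(), geometry)


@pytest.fixture(scope="session")
def fitted_model(pseudo_curves):
    """Estimator fitted on a noiseless synthetic calibration log."""
    log = generate_calibration_log(pseudo_curves, electronics=None)
    return fit_calibration(calibration_set_from_log(log))
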