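import numpy as np
import pandas as pd
import pytest

from dropflux.calibration import FourPLModel, ExponentialRelocationModel
from dropflux.synthetic import (
    SimulationConfig,
    default_lactate_truth,
    default_relocation_truth,
    simulate_calibration_standards,
)


@pytest.fixture(scope="session")
def lactate_truth() -> FourPLModel:
    return default_lactate_truth()


@pytest.fixture(scope="session")
def relocation_truth() -> ExponentialRelocationModel:
    return default_relocation_truth()


@pytest.fixture(scope="session")
def noiseless_lactate_standards(lactate_truth) -> pd.DataFrame:
    return simulate_calibration_standards("lactate", 0.0, 3, seed=0,
                                          lactate_model=lactate_truth)


@pytest.fixture(scope="session")
def noiseless_ig_standards(relocation_truth) -> pd.DataFrame:
    return simulate_calibration_standards("IgG", 0.0, 3, seed=0,
                                          relocation_model=relocation_truth)


@pytest.fixture
def noiseless_config() -> SimulationConfig:
    """Study conditions with every noise scale at zero (exact forward model)."""
    return SimulationConfig(
        n_droplets=200,
        lambda_=0.3,
        blank_mad=0.0,
        relocation_blank_mad=0.0,
        ros_point_noise_sd=0.0,
        ros_low_sd=0.0,
        ros_high_sd=0.0,
        ph_physiological_sd=0.0,
        ph_acidic_sd=0.0,
        sd_wdf_empty_sd=0.0,
        seed=0,
    )


def make_trace(time_s, **channels) -> pd.DataFrame:
    """One-droplet trace DataFrame from explicit channel arrays."""
    n = len(time_s)
    base = {
        "droplet_id": np.zeros(n, dtype=int),
        "time_index": np.arange(n),
        "time_s": np.asarray(time_s, dtype=float),
        "n_cells": np.ones(n, dtype=int),
    }
    base.update({k: np.asarray(v, dtype=float) for k, v in channels.items()})
    return pd.DataFrame(base)
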