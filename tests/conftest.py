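from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sparkdrop as sd

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_single_cell_config(**overrides) -> sd.SyntheticConfig:
    """One bright cell in a small frame (demo geometry)."""
    defaults = dict(
        n_cells=1,
        frame_shape=(96, 96),
        cell_radius=15.0,
        frac_capable=1.0,
        expression_sigma=0.0,
        activator_amplitude_cv=0.0,
        seed=11,
    )
    defaults.update(overrides)
    return sd.SyntheticConfig(**defaults)


def empty_roster(frame_shape=(64, 64)) -> sd.CellRoster:
    """A roster with zero cells (for pure-background rendering)."""
    import pandas as pd

    config = sd.SyntheticConfig(n_cells=1, frame_shape=frame_shape, cell_radius=5.0)
    cols = [
        "cell_id", "x", "y", "radius", "expression", "capable",
        "pka_responsive", "activator_amplitude",
    ]
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    return sd.CellRoster(cells=df, hormones=(), config=config)


@pytest.fixture(scope="session")
def field_design():
    """Small replicate-field geometry shared by the heavier fixtures."""
    return sd.replicate_field_design(n_cells=60, seed=3)


@pytest.fixture(scope="session")
def forskolin_field(field_design):
    """A rendered + quantified field under an adenylyl-cyclase activator."""
    cfg, optics, quant = field_design
    proto = sd.single_stimulus_protocol("forskolin", "adenylyl_cyclase_activator")
    return sd.run_field(cfg, proto, optics, quant)


@pytest.fixture(scope="session")
def adenosine_field(field_design):
    """A rendered + quantified field under a transient receptor agonist."""
    cfg, optics, quant = field_design
    proto = sd.single_stimulus_protocol("adenosine")
    return sd.run_field(cfg, proto, optics, quant)
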