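import numpy as np
import pytest

from leafvoc import ChamberGeometry, KineticParams
from leafvoc.synth_leaf import (
    ExperimentConfig,
    NoiseModel,
    TreatmentCell,
    simulate_leaf,
)


@pytest.fixture
def geometry():
    """Study geometry: 500 µmol s^-1 flow through a 6 cm^2 cuvette."""
    return ChamberGeometry(q_flow_umol_s=500.0, a_leaf_m2=6.0e-4)


@pytest.fixture
def clean_exponential_trace():
    """Noise-free leaf: k=0.05 s^-1, amplitude 15 nmol m^-2 s^-1, zero dark
    floor, 300 s light hold + 300 s dark tail at 1 Hz."""
    cfg = ExperimentConfig(
        noise=NoiseModel(0.0, 0.0),
        geometry=ChamberGeometry(chi_in=0.0),
        replicate_cv_supply=0.0,
        replicate_cv_k=0.0,
        kinetics=lambda t, c: KineticParams(300.0, 15.0, 0.05, 0.0),
        dark_duration_s=300.0,
    )
    trace, truth = simulate_leaf(TreatmentCell(30.0, 400.0), cfg,
                                 np.random.default_rng(0))
    return trace, truth


def make_clean_trace(k, f_supply, dark_s=None, floor=0.0, seed=0,
                     t_leaf=30.0, co2=400.0, **cfg_kwargs):
    """Noise-free single-leaf factory used across decay tests."""
    cfg = ExperimentConfig(
        noise=NoiseModel(0.0, 0.0),
        geometry=cfg_kwargs.pop("geometry", ChamberGeometry(chi_in=0.0)),
        replicate_cv_supply=0.0,
        replicate_cv_k=0.0,
        kinetics=lambda t, c: KineticParams(f_supply / k, f_supply, k, floor),
        dark_duration_s=dark_s,
        **cfg_kwargs,
    )
    return simulate_leaf(TreatmentCell(t_leaf, co2), cfg,
                         np.random.default_rng(seed))
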