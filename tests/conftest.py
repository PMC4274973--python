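"""Shared fixtures: small synthetic records and envelope helpers."""

import numpy as np
import pytest

from neoasi.asi import ASIConfig, quantize
from neoasi.records import Annotation, EEGRecord
from neoasi.synthetic import (
    BurstModel,
    SynchronyPlant,
    generate_burst_train,
    generate_record,
)


@pytest.fixture(scope="session")
def burst_model():
    return BurstModel()


@pytest.fixture(scope="session")
def asi_config():
    return ASIConfig()


@pytest.fixture(scope="session")
def sync_record(burst_model):
    """A 1200-s record with perfectly mirrored hemispheres (degenerate plant)."""
    return generate_record(burst_model, SynchronyPlant(), 1200.0, rng_seed=7)


@pytest.fixture(scope="session")
def async_record(burst_model):
    """A 1200-s record with heavy burst-onset jitter (8 s) on the right."""
    return generate_record(burst_model, SynchronyPlant(0.0, 8.0, 0.0), 1200.0,
                           rng_seed=7)


def gate_envelope(seed: int, duration: float = 600.0,
                  model: BurstModel | None = None) -> np.ndarray:
    """A structured envelope at 16 Hz: the burst gate itself, decimated."""
    m = model or BurstModel()
    return generate_burst_train(m, duration, seed)[:: int(m.fs / 16)]


def quantized_gate(seed: int, duration: float = 600.0, q: int = 8):
    return quantize(gate_envelope(seed, duration), q_levels=q, frame_rate=16.0)


@pytest.fixture
def const_record():
    """Four constant channels for bipolar arithmetic checks."""
    n = 2560
    data = np.vstack([
        np.full(n, 2.0),   # C3
        np.full(n, 0.5),   # O1
        np.full(n, 2.0),   # C4
        np.full(n, 0.5),   # O2
    ])
    return EEGRecord(data=data, fs=256.0, labels=["C3", "O1", "C4", "O2"],
                     annotations=[Annotation(0.0, 10.0, "QS1")])
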