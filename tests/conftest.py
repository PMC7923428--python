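"""Shared fixtures: scaled-down synthetic sessions generated at test time."""

import numpy as np
import pandas as pd
import pytest

from efrp.config import PipelineConfig
from efrp.session_io import MONTAGE, EEGRecording, ScreenGeometry, SessionBundle
from efrp.synthetic import generate_layout, generate_session

#: Road layout scaled to 8 regions for quick integration tests.
SMALL_COUNTS = {40: 3, 60: 2, 80: 3}


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture(scope="session")
def small_layout():
    return generate_layout(7, counts=SMALL_COUNTS)


@pytest.fixture(scope="session")
def small_session(small_layout):
    """One 8-region synthetic session with EEG at default noise."""
    return generate_session(11, layout=small_layout)


@pytest.fixture(scope="session")
def small_session_gaze_only(small_layout):
    return generate_session(12, layout=small_layout, with_eeg=False)


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture()
def tiny_bundle(geometry) -> SessionBundle:
    """A hand-built, fully valid miniature bundle for I/O tests."""
    rng = np.random.default_rng(3)
    n = 240  # 2 s of gaze
    ts = np.arange(n) / 120.0
    x = 400.0 + rng.normal(0, 1.0, n)
    y = 350.0 + rng.normal(0, 1.0, n)
    gaze = pd.DataFrame({
        "timestamp": ts,
        "left_x": x - 1.0, "left_y": y, "right_x": x + 1.0, "right_y": y,
        "left_valid": np.ones(n, int), "right_valid": np.ones(n, int),
    })
    eeg = EEGRecording(512.0, list(MONTAGE),
                       rng.normal(0, 3.0, (16, 1024)), 0.0)
    events = pd.DataFrame({
        "timestamp": [0.5, 1.5], "kind": ["billboard_threshold",
                                          "region_enter"],
        "region_index": [1, 1], "billboard_type": ["static", "static"],
        "car_x": [220.0, 300.0], "speed": [60.0, 60.0],
        "accelerator": [0.6, 0.6],
    })
    speed = pd.DataFrame({"timestamp": np.arange(0, 2.0, 0.1),
                          "speed_kmh": 60.0})
    return SessionBundle(gaze=gaze, eeg=eeg, events=events, speed=speed,
                         geometry=geometry,
                         metadata={"participant": "T1", "primed": False,
                                   "seed": 3})
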