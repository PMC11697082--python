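import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hrtoct as h

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Keep per-vessel warning chatter out of the test log.
logging.getLogger("hrtoct").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_scan():
    """Down-scaled scan geometry used for fast image-based tests."""
    return h.ScanParams(width_px=96, height_px=72)


@pytest.fixture(scope="session")
def washout_params():
    return h.WashoutParams.from_scan(h.ScanParams())


def quiet_config(**overrides):
    """Simulation config without eye motion (registration becomes identity)."""
    kw = dict(
        scan=h.ScanParams(width_px=96, height_px=72),
        jitter_max_px=0.0,
        jitter_max_deg=0.0,
    )
    kw.update(overrides)
    return h.SimConfig(**kw)


@pytest.fixture(scope="session")
def quiet_exam():
    """One motion-free synthetic exam shared by read-only tests.

    Uses the fast-frame regime (11.2 us, ~74 B-scans/s), where the pulse
    arrival quantisation is well below the R-R jitter.
    """
    return h.generate_exam(
        quiet_config(
            seed=11,
            duration_s=5.0,
            frame_rate_hz=74.4,
            scan=h.ScanParams(width_px=96, height_px=72, integration_time_s=11.2e-6),
        )
    )


def match_events(detected: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Distance from each true event to the nearest detected event (ms)."""
    if detected.size == 0:
        return np.full(truth.size, np.inf)
    return np.abs(detected[:, None] - truth[None, :]).min(axis=0)
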