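import logging

import numpy as np
import pytest

from corticoflow.config import SimConfig
from corticoflow.geometry import default_geometry

logging.getLogger("corticoflow").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return default_geometry()


@pytest.fixture
def small_cfg():
    """Short sessions for fast generator tests."""
    return SimConfig(n_mice=2, sessions_per_condition=1, fs_hz=100.0,
                     session_duration_s=60.0, drift_slope=0.0, seed=0)


def naive_running_percentile(values, window, percentile):
    """Independent O(N*W) oracle: per-sample centred-window percentile with
    edge truncation, linear-interpolation quantile."""
    values = np.asarray(values, dtype=float)
    n = values.size
    hl = (window - 1) // 2
    hr = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - hl)
        hi = min(n, i + hr + 1)
        out[i] = np.quantile(values[lo:hi], percentile)
    return out


def naive_onset_scan(primary, other, fs_hz, threshold, window_s, quiescence):
    """Independent per-sample scan implementing the threshold-crossing and
    pre-window quiescence rules directly."""
    events = []
    w = int(round(window_s * fs_hz))
    for i in range(len(primary)):
        if primary[i] < threshold:
            continue
        if i > 0 and primary[i - 1] >= threshold:
            continue
        if i == 0:
            continue  # starts above threshold: no upward crossing
        if i - w < 0:
            events.append((i / fs_hz, False, "pre-window out of bounds"))
            continue
        quiet = True
        for j in range(i - w, i):
            if primary[j] > quiescence or other[j] > quiescence:
                quiet = False
                break
        if quiet:
            events.append((i / fs_hz, True, ""))
        else:
            events.append((i / fs_hz, False, "activity in pre-window"))
    return events
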