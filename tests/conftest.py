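"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mdbn.containers import Recording
from mdbn.synthetic import CouplingSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_pair_spec(c: float, *, noise_sd: float = 0.5, n_trials: int = 10,
                   seed: int = 0, lag: float = np.pi / 2,
                   center_freq: float = 10.0) -> CouplingSpec:
    """Two-channel spec with constant coupling c across all five windows."""
    g = np.zeros((5, 2, 2))
    g[:, 0, 1] = g[:, 1, 0] = c
    lag_m = np.array([[0.0, lag], [-lag, 0.0]])
    return CouplingSpec(
        {"NAS": g}, lag_m, n_channels=2, n_trials=n_trials,
        noise_sd=noise_sd, seed=seed, center_freq=center_freq,
    )


@pytest.fixture
def sine_recording():
    """Two-channel 10 Hz recording: channel 1 lags channel 0 by pi/2."""
    fs = 256.0
    t = np.arange(int(12 * fs)) / fs
    x0 = np.cos(2 * np.pi * 10 * t)
    x1 = np.cos(2 * np.pi * 10 * t - np.pi / 2)
    events = pd.DataFrame(
        {"time_s": [4.0, 8.0, 12.0], "condition": ["NAS"] * 3, "trial_index": [1, 2, 3]}
    )
    return Recording(np.stack([x0, x1]), fs, ["A", "B"], events)


def random_metric_table(rng, n_trials: int = 12, shift: float = 0.0) -> pd.DataFrame:
    """Long-form metric table covering every default biomarker cell.

    ``shift`` displaces the AS-CE values so the two classes separate.
    """
    from mdbn.classify import TABLE1_BIOMARKERS

    rows = []
    for cond in ("AS-CE", "AS-NC"):
        mu = shift if cond == "AS-CE" else 0.0
        for trial in range(1, n_trials + 1):
            for entry in TABLE1_BIOMARKERS:
                channels = entry["channels"] or ["GLOBAL"]
                win = -1 if entry["window"] is None else entry["window"]
                for ch in channels:
                    rows.append(
                        {
                            "condition": cond, "band": entry["band"],
                            "window": win, "trial": trial, "channel": ch,
                            "metric": entry["metric"],
                            "value": mu + rng.normal(),
                        }
                    )
    return pd.DataFrame(rows)
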