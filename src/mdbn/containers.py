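"""Core data containers: raw recordings, epoched band-limited data, events.

The pipeline moves data through two containers.  A :class:`Recording` is a
continuous multi-channel signal block with an event table attached; an
:class:`EpochSet` is the event-locked, band-filtered tensor the network
construction operates on.  Both are plain dataclasses around numpy arrays so
they serialize naturally to ``.npz`` containers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Canonical frequency bands (Hz).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: The three task conditions: non-alert state, alert state ending in a
#: collision, alert state with no collision.
CONDITIONS = ("NAS", "AS-CE", "AS-NC")

EVENT_COLUMNS = ("time_s", "condition", "trial_index")


@dataclass
class Recording:
    """A continuous multi-channel recording with an event table.

    Parameters
    ----------
    samples
        ``(n_channels, n_times)`` signal in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        Ordered electrode labels (10-20 convention).
    events
        DataFrame with columns ``time_s`` (seconds from recording start),
        ``condition`` and ``trial_index``.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(EVENT_COLUMNS))
    )

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length must match samples rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if np.isnan(self.samples).any():
            raise ValueError("samples contain NaN")
        self.events = pd.DataFrame(self.events)
        missing = set(EVENT_COLUMNS) - set(self.events.columns)
        if missing:
            raise ValueError(f"events missing columns: {sorted(missing)}")
        if len(self.events):
            tmax = self.samples.shape[1] / self.fs
            if (self.events["time_s"] < 0).any() or (
                self.events["time_s"] > tmax + 1e-9
            ).any():
                raise ValueError("event times outside recording duration")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def copy(self) -> "Recording":
        return Recording(
            self.samples.copy(), self.fs, list(self.channel_names), self.events.copy()
        )


@dataclass
class EpochSet:
    """Band-filtered, event-locked epochs (and optionally their phases).

    ``data`` is ``(n_epochs, n_channels, n_times)``; ``phase``, when
    populated by :func:`mdbn.signal_prep.analytic_phase`, has the same shape
    with values in ``(-pi, pi]``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    condition: np.ndarray
    trial_index: np.ndarray
    band: Optional[str] = None
    band_edges: Optional[tuple[float, float]] = None
    phase: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x time")
        self.condition = np.asarray(self.condition)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        if len(self.condition) != self.data.shape[0]:
            raise ValueError("condition length must match epoch count")
        if len(self.trial_index) != self.data.shape[0]:
            raise ValueError("trial_index length must match epoch count")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel axis")
        if self.band is not None and self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
            if self.phase.shape != self.data.shape:
                raise ValueError("phase shape must match data shape")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(),
            self.fs,
            list(self.channel_names),
            self.condition.copy(),
            self.trial_index.copy(),
            self.band,
            self.band_edges,
            None if self.phase is None else self.phase.copy(),
        )

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Return the epochs selected by a boolean or index mask."""
        return EpochSet(
            self.data[mask],
            self.fs,
            list(self.channel_names),
            self.condition[mask],
            self.trial_index[mask],
            self.band,
            self.band_edges,
            None if self.phase is None else self.phase[mask],
        )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_events_csv(path: str | Path) -> pd.DataFrame:
    """Read an event table CSV with columns time_s, condition, trial_index."""
    ev = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(ev.columns)
    if missing:
        raise ValueError(f"event CSV missing columns: {sorted(missing)}")
    return ev[list(EVENT_COLUMNS)]


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    pd.DataFrame(events)[list(EVENT_COLUMNS)].to_csv(path, index=False)


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording to an ``.npz`` container (events stored as columns)."""
    np.savez(
        path,
        samples=rec.samples,
        fs=np.asarray(rec.fs),
        channel_names=np.asarray(rec.channel_names),
        event_time_s=rec.events["time_s"].to_numpy(dtype=float),
        event_condition=rec.events["condition"].to_numpy(dtype=str),
        event_trial_index=rec.events["trial_index"].to_numpy(dtype=int),
    )


def load_recording(path: str | Path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        events = pd.DataFrame(
            {
                "time_s": z["event_time_s"],
                "condition": z["event_condition"].astype(str),
                "trial_index": z["event_trial_index"],
            }
        )
        return Recording(
            z["samples"], float(z["fs"]), [str(c) for c in z["channel_names"]], events
        )


def read_recording_edf(path: str | Path, events: pd.DataFrame | str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (requires ``mne``).

    ``events`` is an event table or a path to an events CSV; EDF annotations
    are not interpreted.
    """
    import mne  # deferred: optional dependency

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if not isinstance(events, pd.DataFrame):
        events = read_events_csv(events)
    # MNE loads EDF in volts; the pipeline works in microvolts.
    return Recording(raw.get_data() * 1e6, float(raw.info["sfreq"]), raw.ch_names, events)


def save_epochset(ep: EpochSet, path: str | Path) -> None:
    payload = {
        "data": ep.data,
        "fs": np.asarray(ep.fs),
        "channel_names": np.asarray(ep.channel_names),
        "condition": ep.condition.astype(str),
        "trial_index": ep.trial_index,
        "band": np.asarray(ep.band if ep.band is not None else ""),
    }
    if ep.band_edges is not None:
        payload["band_edges"] = np.asarray(ep.band_edges, dtype=float)
    if ep.phase is not None:
        payload["phase"] = ep.phase
    np.savez(path, **payload)


def load_epochset(path: str | Path) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        band = str(z["band"]) or None
        return EpochSet(
            z["data"],
            float(z["fs"]),
            [str(c) for c in z["channel_names"]],
            z["condition"].astype(str),
            z["trial_index"],
            band,
            tuple(z["band_edges"]) if "band_edges" in z else None,
            z["phase"] if "phase" in z else None,
        )
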