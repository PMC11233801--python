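"""Preprocessing: resampling, FIR band-pass, epoching, referencing, phase.

The canonical pipeline order is::

    resample -> bandpass -> epoch -> average_reference -> analytic_phase

Every stage preserves channel count and ordering.  The analytic phase is
computed on the whole epoch before any sliding-window slicing, so window
boundaries carry no Hilbert edge artifacts.
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import BANDS, EpochSet, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "resample",
    "bandpass",
    "epoch",
    "average_reference",
    "split_training_phase",
    "analytic_phase",
    "drop_channels",
    "wrap_phase",
]


class UpsamplingRefusedError(ValueError):
    """Raised when the requested rate exceeds the recording's rate."""


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles to the principal value interval ``(-pi, pi]``."""
    w = np.mod(np.asarray(x, dtype=float), 2.0 * np.pi)
    w = np.where(w > np.pi, w - 2.0 * np.pi, w)
    return w


def resample(rec: Recording, target_fs: float) -> Recording:
    """Resample to ``target_fs`` with polyphase anti-alias filtering.

    Event times are expressed in seconds and are therefore unchanged.
    Upsampling is refused: the pipeline only ever reduces the rate.
    """
    if target_fs > rec.fs:
        raise UpsamplingRefusedError(
            f"target_fs={target_fs} exceeds recording fs={rec.fs}; upsampling refused"
        )
    if target_fs == rec.fs:
        return rec.copy()
    frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    return Recording(out, float(target_fs), list(rec.channel_names), rec.events.copy())


def _fir_taps(low: float, high: float, fs: float) -> np.ndarray:
    # Windowed-sinc (Hamming) band-pass; transition bandwidth 25% of the low
    # cutoff keeps the theta edge sharp without an excessively long filter.
    trans = 0.25 * low
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps += 1 - numtaps % 2  # odd length -> exactly linear phase
    return sps.firwin(numtaps, [low, high], pass_zero=False, fs=fs, window="hamming")


def bandpass(rec: Recording, band: str) -> Recording:
    """Zero-phase FIR band-pass into one of the theta/alpha/beta bands.

    The filter is applied forward and backward (``filtfilt``) so the passband
    phase response is identically zero.
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    low, high = BANDS[band]
    taps = _fir_taps(low, high, rec.fs)
    if rec.n_times <= 3 * len(taps):
        raise ValueError(
            f"recording too short ({rec.n_times} samples) for the {band} "
            f"band filter ({len(taps)} taps)"
        )
    out = sps.filtfilt(taps, [1.0], rec.samples, axis=1)
    return Recording(out, rec.fs, list(rec.channel_names), rec.events.copy())


def epoch(rec: Recording, duration_s: float = 3.0) -> EpochSet:
    """Cut one epoch per event, ending exactly at the event sample.

    The epoch covers the half-open interval ``[t - duration_s, t)``: the
    event sample itself is excluded.  Events closer than ``duration_s`` to
    the recording start are dropped with a warning.
    """
    n = int(round(duration_s * rec.fs))
    chunks, conds, trials = [], [], []
    for _, row in rec.events.iterrows():
        end = int(round(float(row["time_s"]) * rec.fs))
        start = end - n
        if start < 0:
            logger.warning(
                "dropping event at t=%.3fs: starts %.3fs before the recording",
                row["time_s"], -start / rec.fs,
            )
            continue
        chunks.append(rec.samples[:, start:end])
        conds.append(row["condition"])
        trials.append(int(row["trial_index"]))
    if not chunks:
        data = np.empty((0, rec.n_channels, n))
    else:
        data = np.stack(chunks)
    return EpochSet(
        data, rec.fs, list(rec.channel_names),
        np.asarray(conds, dtype=object), np.asarray(trials, dtype=int),
    )


def average_reference(ep: EpochSet) -> EpochSet:
    """Re-reference to the instantaneous channel mean (common average).

    After this step the mean across channels is zero at every time point,
    which removes reference-electrode noise common to all channels.
    """
    if ep.n_channels < 2:
        raise ValueError("average reference undefined for a single channel")
    out = ep.copy()
    out.data = ep.data - ep.data.mean(axis=1, keepdims=True)
    return out


def split_training_phase(ep: EpochSet, phase: str) -> EpochSet:
    """Select the initial (ITIP) or advanced (ITAP) training-phase trials.

    ITIP keeps, per condition, the trials with the five smallest trial
    indices; ITAP the five largest.  Conditions with fewer than five trials
    are kept whole with a warning.
    """
    phase = phase.upper()
    if phase not in {"ITIP", "ITAP"}:
        raise ValueError(f"phase must be 'ITIP' or 'ITAP', got {phase!r}")
    keep = np.zeros(ep.n_epochs, dtype=bool)
    for cond in pd.unique(ep.condition):
        idx = np.flatnonzero(ep.condition == cond)
        uniq = np.unique(ep.trial_index[idx])
        if len(uniq) < 5:
            logger.warning(
                "condition %s has only %d trials; keeping all for %s",
                cond, len(uniq), phase,
            )
            chosen = uniq
        else:
            chosen = np.sort(uniq)[:5] if phase == "ITIP" else np.sort(uniq)[-5:]
        keep[idx[np.isin(ep.trial_index[idx], chosen)]] = True
    return ep.select(keep)


def analytic_phase(ep: EpochSet) -> EpochSet:
    """Populate the instantaneous phase via the Hilbert analytic signal.

    Computed over the full epoch (not per window); values wrapped to
    ``(-pi, pi]``.  A warning is issued for broadband (unfiltered) input,
    where instantaneous phase is ill-defined.
    """
    if ep.band is None:
        warnings.warn(
            "analytic phase of broadband data is ill-defined; band-pass first",
            stacklevel=2,
        )
    out = ep.copy()
    analytic = sps.hilbert(ep.data, axis=2)
    out.phase = wrap_phase(np.angle(analytic))
    return out


def drop_channels(rec: Recording, exclude: list[str]) -> Recording:
    """Remove the named channels (e.g. outer-ring electrodes) if present."""
    keep = [i for i, c in enumerate(rec.channel_names) if c not in set(exclude)]
    return Recording(
        rec.samples[keep], rec.fs,
        [rec.channel_names[i] for i in keep], rec.events.copy(),
    )
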