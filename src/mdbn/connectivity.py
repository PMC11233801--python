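"""Phase-lag index (PLI) within and across sliding windows.

The PLI between two phase series is the absolute time-average of the sign
of their wrapped phase difference,

    PLI = | (1/N) sum_n sign(dphi(t_n)) |,

which is 0 when neither signal consistently leads the other (including the
zero-lag case produced by volume conduction) and 1 when the wrapped
difference keeps a constant sign.  Computed within one window it gives an
intra-layer connectivity matrix; computed between two different windows
(samples aligned by within-window offset) it gives the inter-layer blocks
of the supra-adjacency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet
from .signal_prep import wrap_phase

__all__ = [
    "WindowSpec",
    "ConnMatrix",
    "sliding_windows",
    "window_slices",
    "pli",
    "pli_matrix",
    "intra_layer",
    "inter_layer",
    "trial_average",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 1-s windows stepped by 0.5 s by default."""

    width_s: float = 1.0
    step_s: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.step_s <= self.width_s):
            raise ValueError("require 0 < step_s <= width_s")


@dataclass
class ConnMatrix:
    """Symmetric channels x channels PLI matrix for one (window, window) pair."""

    values: np.ndarray
    window_pair: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("values must be a square matrix")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("PLI values must lie in [0, 1]")

    @property
    def kind(self) -> str:
        l, m = self.window_pair
        return "intra" if l == m else "inter"

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def sliding_windows(epoch_length_s: float, spec: WindowSpec) -> list[tuple[float, float]]:
    """Window (start, end) times covering an epoch; count is
    ``floor((length - width)/step) + 1``."""
    if epoch_length_s < spec.width_s:
        raise ValueError("epoch shorter than window width")
    n = int(np.floor((epoch_length_s - spec.width_s) / spec.step_s + 1e-9)) + 1
    return [
        (i * spec.step_s, i * spec.step_s + spec.width_s) for i in range(n)
    ]


def window_slices(n_times: int, fs: float, spec: WindowSpec) -> list[slice]:
    """Sample-index slices for each sliding window of an epoch."""
    wins = sliding_windows(n_times / fs, spec)
    width = int(round(spec.width_s * fs))
    return [
        slice(int(round(start * fs)), int(round(start * fs)) + width)
        for start, _ in wins
    ]


def pli(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase-lag index between two equal-length phase series (radians).

    Symmetric in its arguments and invariant to adding a common constant to
    both series.  Exact-zero wrapped differences contribute 0 (they are
    kept, not dropped), so identical series give PLI 0.
    """
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase series must have equal length")
    if phase_a.size == 0:
        raise ValueError("empty phase series")
    d = wrap_phase(phase_a - phase_b)
    return float(abs(np.mean(np.sign(d))))


def pli_matrix(phases_a: np.ndarray, phases_b: np.ndarray) -> np.ndarray:
    """All-pairs PLI between the rows of two (channels x samples) blocks."""
    d = wrap_phase(phases_a[:, None, :] - phases_b[None, :, :])
    return np.abs(np.mean(np.sign(d), axis=2))


def _epoch_phase(ep: EpochSet, epoch_idx: int) -> np.ndarray:
    if ep.phase is None:
        raise ValueError("EpochSet has no phase; run analytic_phase first")
    return ep.phase[epoch_idx]


def intra_layer(
    ep: EpochSet, epoch_idx: int, window: int, spec: WindowSpec = WindowSpec()
) -> ConnMatrix:
    """PLI matrix between all channel pairs within one window (one layer).

    The diagonal is zeroed: a channel is never connected to itself within a
    layer.
    """
    sl = window_slices(ep.n_times, ep.fs, spec)[window]
    ph = _epoch_phase(ep, epoch_idx)[:, sl]
    m = pli_matrix(ph, ph)
    np.fill_diagonal(m, 0.0)
    return ConnMatrix(m, (window, window))


def inter_layer(
    ep: EpochSet,
    epoch_idx: int,
    window_l: int,
    window_m: int,
    spec: WindowSpec = WindowSpec(),
) -> ConnMatrix:
    """PLI between all channel pairs across two different windows.

    Entry (i, j) couples channel i's phase in window l with channel j's in
    window m, samples aligned by their within-window offset.  All pairs are
    included, i == j among them, since a channel's own past and future
    synchronization is part of the inter-layer structure.
    """
    if window_l == window_m:
        raise ValueError("inter_layer requires two distinct windows; use intra_layer")
    slices = window_slices(ep.n_times, ep.fs, spec)
    sl_l, sl_m = slices[window_l], slices[window_m]
    if (sl_l.stop - sl_l.start) != (sl_m.stop - sl_m.start):
        raise ValueError("windows must have identical sample counts")
    ph = _epoch_phase(ep, epoch_idx)
    return ConnMatrix(
        pli_matrix(ph[:, sl_l], ph[:, sl_m]), (window_l, window_m)
    )


def trial_average(mats: list[ConnMatrix]) -> ConnMatrix:
    """Element-wise mean of same-shaped connectivity matrices over trials."""
    if not mats:
        raise ValueError("cannot average an empty list of matrices")
    pair = mats[0].window_pair
    shape = mats[0].values.shape
    for m in mats:
        if m.window_pair != pair or m.values.shape != shape:
            raise ValueError("matrices must share shape and window_pair")
    return ConnMatrix(np.mean([m.values for m in mats], axis=0), pair)
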