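"""Delta-brush detection.

A delta brush — the canonical immature-EEG event — is detected as the
co-occurrence of a slow wave (0.5-2 Hz) and nested higher-frequency
activity (8-22 Hz). Per channel:

* the *slow* signal is the 0.5-2 Hz band-pass of the trace;
* the *fast envelope* is the magnitude of the analytic signal of the
  8-22 Hz band-pass;
* slow-wave intervals are runs where |slow| exceeds its threshold for at
  least ``min_slow_s`` (default 0.25 s);
* fast bursts are runs where the envelope exceeds its threshold for at
  least ``min_fast_s`` (default 0.1 s);
* a brush is emitted when a fast burst *starts* inside a slow-wave
  interval. The event is timestamped by the fast-burst start, because the
  slow deflection begins earlier and its onset is poorly defined.

Thresholds are scale-free: ``mad_mult`` x the median absolute deviation of
the respective trace over the whole recording, floored at ``rel_floor`` x
the peak of the channel's broadband (0.5-22 Hz) signal. The floor serves
two purposes: near-silent recordings (where the MAD collapses toward zero)
do not promote filter ringing to events, and energy that merely leaks
across bands (e.g. the low-frequency sidelobes of a gated fast burst)
cannot masquerade as a slow wave. Both multipliers, both
minimum durations, and the floor are configuration keys; the underlying
published burst-detection parameters are not printed in the source
literature, so these defaults are a documented reconstruction.

A brush counts as *stimulus-evoked* when it occurs at any non-excluded
electrode and the nested fast activity starts within ``window_s``
(default 2 s) *after* the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator

from .preprocess import EpochedTrial

__all__ = ["BrushEvent", "DeltaBrushDetector", "detect_brushes", "evoked_brush"]


@dataclass
class BrushEvent:
    """One detected delta brush on one channel (times in trial seconds)."""

    channel: str
    slow_start: float
    slow_end: float
    fast_start: float
    fast_duration: float

    def __post_init__(self) -> None:
        if not self.slow_start <= self.fast_start <= self.slow_end:
            raise ValueError("fast-burst start must lie inside the slow interval")
        if self.fast_duration <= 0 or self.slow_end <= self.slow_start:
            raise ValueError("durations must be positive")


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


class DeltaBrushDetector(BaseEstimator):
    """Slow-wave / nested-fast-burst co-occurrence detector.

    Parameters are the four reconstruction keys described in the module
    docstring plus the band edges. The detector is stateless (``fit`` is a
    no-op kept for pipeline compatibility); detection statistics are
    computed per recording, which makes the output invariant to rescaling
    the signal.
    """

    def __init__(
        self,
        slow_band: tuple[float, float] = (0.5, 2.0),
        fast_band: tuple[float, float] = (8.0, 22.0),
        mad_mult_slow: float = 3.0,
        mad_mult_fast: float = 3.0,
        min_slow_s: float = 0.25,
        min_fast_s: float = 0.1,
        rel_floor: float = 0.1,
        filter_order: int = 4,
    ):
        self.slow_band = slow_band
        self.fast_band = fast_band
        self.mad_mult_slow = mad_mult_slow
        self.mad_mult_fast = mad_mult_fast
        self.min_slow_s = min_slow_s
        self.min_fast_s = min_fast_s
        self.rel_floor = rel_floor
        self.filter_order = filter_order

    def fit(self, X=None, y=None):
        return self

    def _bandpass(self, x: np.ndarray, band: tuple[float, float], fs: float):
        sos = signal.butter(
            self.filter_order, band, btype="bandpass", fs=fs, output="sos"
        )
        return signal.sosfiltfilt(sos, x, padtype="even")

    def _detect_channel(
        self, x: np.ndarray, fs: float, label: str, t0: float
    ) -> list[BrushEvent]:
        slow = self._bandpass(x, self.slow_band, fs)
        fast = self._bandpass(x, self.fast_band, fs)
        env = np.abs(signal.hilbert(fast))
        broad = self._bandpass(x, (self.slow_band[0], self.fast_band[1]), fs)
        floor = self.rel_floor * np.max(np.abs(broad), initial=0.0)

        thr_slow = max(self.mad_mult_slow * _mad(slow), floor)
        thr_fast = max(self.mad_mult_fast * _mad(env), floor)
        if thr_slow <= 0 or thr_fast <= 0:
            return []

        min_slow = int(round(self.min_slow_s * fs))
        min_fast = int(round(self.min_fast_s * fs))
        slow_runs = [
            r for r in _runs_above(np.abs(slow) > thr_slow) if r[1] - r[0] >= min_slow
        ]
        fast_runs = [
            r for r in _runs_above(env > thr_fast) if r[1] - r[0] >= min_fast
        ]

        events = []
        for fstart, fstop in fast_runs:
            for sstart, sstop in slow_runs:
                if sstart <= fstart < sstop:
                    events.append(
                        BrushEvent(
                            channel=label,
                            slow_start=t0 + sstart / fs,
                            slow_end=t0 + (sstop - 1) / fs,
                            fast_start=t0 + fstart / fs,
                            fast_duration=(fstop - fstart) / fs,
                        )
                    )
                    break
        return events

    def detect(self, trial: EpochedTrial) -> list[BrushEvent]:
        """Detect brushes on every non-excluded channel of one trial."""
        n = trial.times.size
        if n / trial.fs < 4.0:
            raise ValueError(
                "signal shorter than 4 s cannot resolve the 0.5 Hz slow band"
            )
        t0 = float(trial.times[0])
        events: list[BrushEvent] = []
        for i, ch in enumerate(trial.channels):
            if ch in trial.excluded_channels:
                continue
            events.extend(self._detect_channel(trial.data[i], trial.fs, ch, t0))
        return events

    def detect_array(
        self, data: np.ndarray, fs: float, channels: list[str] | None = None
    ) -> list[BrushEvent]:
        """Detect brushes on a raw (channels x samples) array, t0 = 0."""
        data = np.atleast_2d(np.asarray(data, dtype=float))
        if data.shape[1] / fs < 4.0:
            raise ValueError(
                "signal shorter than 4 s cannot resolve the 0.5 Hz slow band"
            )
        if channels is None:
            channels = [f"ch{i}" for i in range(data.shape[0])]
        events: list[BrushEvent] = []
        for i, ch in enumerate(channels):
            events.extend(self._detect_channel(data[i], fs, ch, 0.0))
        return events


def detect_brushes(trial: EpochedTrial, **params) -> list[BrushEvent]:
    """Functional wrapper over :class:`DeltaBrushDetector`."""
    return DeltaBrushDetector(**params).detect(trial)


def evoked_brush(
    events: list[BrushEvent],
    stimulus_time: float = 0.0,
    window_s: float = 2.0,
    excluded_channels: tuple[str, ...] = (),
) -> bool:
    """True iff any brush's fast burst starts within ``window_s`` after the stimulus.

    Any electrode counts; pre-stimulus brushes do not (the window is the
    one-sided post-stimulus interval ``[stimulus, stimulus + window_s]``).
    """
    return any(
        ev.channel not in excluded_channels
        and stimulus_time <= ev.fast_start <= stimulus_time + window_s
        for ev in events
    )
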