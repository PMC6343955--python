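"""Deterministic conditioning of continuous EEG into stimulus-locked epochs.

The processing chain mirrors standard infant-ERP practice: zero-phase
band-pass (0.5-70 Hz) with a 50 Hz notch, epoching around stimulus markers
(typically +/-4 s), baseline correction to the pre-stimulus mean, and
amplitude-threshold channel rejection. Filters are forward-backward
(``sosfiltfilt``) order-4 Butterworth band-pass plus a second-order IIR
notch (Q = 30), so the chain is linear and phase-free.

Time conventions: time 0 is the stimulus sample; the pre-stimulus baseline
interval is half-open, ``[-t_pre, 0)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "ContinuousRecording",
    "EpochedTrial",
    "bandpass_notch",
    "epoch_recording",
    "baseline_correct",
    "reject_channels",
    "save_epochs_npz",
    "load_epochs_npz",
    "read_edf",
]


@dataclass
class ContinuousRecording:
    """Multichannel continuous EEG with stimulus markers.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate, Hz.
    channels : list of str
        Channel labels in row order (e.g. Cz, CPz, C3, C4, FCz, Oz, T3, T4).
    markers : list of (int, str)
        (sample index, stimulus kind) pairs.
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    markers: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel label count does not match data rows")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.data.shape[1]
        for idx, _kind in self.markers:
            if not 0 <= idx < n:
                raise ValueError(f"marker sample {idx} outside record length {n}")


@dataclass
class EpochedTrial:
    """One stimulus-locked trial: channels x time, time 0 = stimulus."""

    data: np.ndarray
    times: np.ndarray  # seconds relative to stimulus, strictly increasing, contains 0
    fs: float
    stimulus: str
    channels: list[str]
    infant_id: str | None = None
    excluded_channels: list[str] = field(default_factory=list)
    baseline_corrected: bool = False
    usable: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape != (len(self.channels), self.times.size):
            raise ValueError("data shape must be (n_channels, n_times)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.any(np.isclose(self.times, 0.0, atol=0.25 / self.fs)):
            raise ValueError("time axis must contain 0 (the stimulus sample)")

    @property
    def stim_index(self) -> int:
        return int(np.argmin(np.abs(self.times)))

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's trace; raises if the channel was rejected."""
        if label in self.excluded_channels:
            raise KeyError(f"channel {label} was excluded as artefactual")
        return self.data[self.channels.index(label)]

    def has_channel(self, label: str) -> bool:
        return label in self.channels and label not in self.excluded_channels


def bandpass_notch(
    rec: ContinuousRecording,
    low: float,
    high: float,
    notch: float | None = 50.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> ContinuousRecording:
    """Zero-phase band-pass (Butterworth, order ``order``) plus IIR notch.

    ``sosfiltfilt`` is run with even (reflect) padding; passband ripple is
    the Butterworth maximally-flat response (monotone, -3 dB at the band
    edges). The notch attenuates its centre frequency by far more than
    20 dB after the forward-backward pass.
    """
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"invalid band ({low}, {high}) for fs={rec.fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=-1, padtype="even")
    if notch is not None:
        if not (0 < notch < nyq):
            raise ValueError(f"notch frequency {notch} outside (0, {nyq})")
        b, a = signal.iirnotch(notch, notch_q, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=-1, padtype="even")
    return replace(rec, data=out)


def epoch_recording(
    rec: ContinuousRecording,
    t_pre: float,
    t_post: float,
    infant_id: str | None = None,
) -> list[EpochedTrial]:
    """Cut one trial per marker; markers without headroom are skipped.

    The sample at time 0 is exactly the marker sample. A marker within
    ``t_pre`` of the record start or ``t_post`` of the end cannot be epoched
    and is skipped with a warning.
    """
    if t_pre < 0 or t_post < 0:
        raise ValueError("t_pre and t_post must be non-negative")
    n_pre = int(round(t_pre * rec.fs))
    n_post = int(round(t_post * rec.fs))
    n = rec.data.shape[1]
    times = np.arange(-n_pre, n_post + 1) / rec.fs
    trials: list[EpochedTrial] = []
    for idx, kind in rec.markers:
        if idx - n_pre < 0 or idx + n_post >= n:
            warnings.warn(
                f"marker at sample {idx} lacks {t_pre}/{t_post} s headroom; "
                "trial skipped",
                stacklevel=2,
            )
            continue
        seg = rec.data[:, idx - n_pre : idx + n_post + 1].copy()
        trials.append(
            EpochedTrial(
                data=seg,
                times=times.copy(),
                fs=rec.fs,
                stimulus=kind,
                channels=list(rec.channels),
                infant_id=infant_id,
            )
        )
    return trials


def baseline_correct(trial: EpochedTrial) -> EpochedTrial:
    """Subtract each channel's mean over the pre-stimulus interval [-t_pre, 0).

    Idempotent; the post-stimulus shape is unchanged up to the constant
    shift.
    """
    pre = trial.times < 0
    if not np.any(pre):
        raise ValueError("empty pre-stimulus baseline interval")
    base = trial.data[:, pre].mean(axis=1, keepdims=True)
    return replace(trial, data=trial.data - base, baseline_corrected=True)


def reject_channels(trial: EpochedTrial, amplitude_limit: float = 500.0) -> EpochedTrial:
    """Mark channels whose peak |amplitude| exceeds ``amplitude_limit`` uV.

    Excluded channels stay in the data matrix but are listed in
    ``excluded_channels`` and masked from downstream operations. If every
    channel is rejected the trial is flagged unusable.
    """
    if amplitude_limit <= 0:
        raise ValueError("amplitude_limit must be positive")
    peaks = np.max(np.abs(trial.data), axis=1)
    bad = [ch for ch, p in zip(trial.channels, peaks) if p > amplitude_limit]
    excluded = sorted(set(trial.excluded_channels) | set(bad))
    usable = len(excluded) < len(trial.channels)
    if not usable:
        warnings.warn("all channels rejected; trial marked unusable", stacklevel=2)
    return replace(trial, excluded_channels=excluded, usable=usable)


# ---------------------------------------------------------------------------
# I/O: NPZ + JSON-sidecar container for epochs, EDF via mne (optional).

def save_epochs_npz(path, trials: list[EpochedTrial]) -> None:
    """Write epochs to an ``.npz`` array container (metadata in JSON strings)."""
    import json

    arrays = {}
    meta = []
    for i, tr in enumerate(trials):
        arrays[f"data_{i}"] = tr.data
        arrays[f"times_{i}"] = tr.times
        meta.append(
            {
                "fs": tr.fs,
                "stimulus": tr.stimulus,
                "channels": tr.channels,
                "infant_id": tr.infant_id,
                "excluded_channels": tr.excluded_channels,
                "baseline_corrected": tr.baseline_corrected,
                "usable": tr.usable,
            }
        )
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_epochs_npz(path) -> list[EpochedTrial]:
    import json

    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta_json"]))
        trials = []
        for i, m in enumerate(meta):
            trials.append(
                EpochedTrial(
                    data=npz[f"data_{i}"],
                    times=npz[f"times_{i}"],
                    fs=m["fs"],
                    stimulus=m["stimulus"],
                    channels=m["channels"],
                    infant_id=m["infant_id"],
                    excluded_channels=m["excluded_channels"],
                    baseline_corrected=m["baseline_corrected"],
                    usable=m["usable"],
                )
            )
    return trials


def read_edf(path, marker_channel: str | None = None) -> ContinuousRecording:
    """Load a continuous EEG recording from EDF (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return ContinuousRecording(
        data=data, fs=float(raw.info["sfreq"]), channels=list(raw.ch_names)
    )
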