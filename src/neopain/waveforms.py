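"""Canonical synthetic evoked waveforms.

Three stereotyped events are used throughout the package, each defined by an
analytic formula on a post-stimulus time axis and normalised to unit peak
amplitude:

``noxious_specific``
    A biphasic deflection with its energy concentrated in the 400-700 ms
    post-stimulus window: a single-cycle sinusoid (period 300 ms, i.e. a
    3.33 Hz carrier) under a Gaussian envelope centred at 550 ms
    (sd 60 ms)::

        w(t) = sin(2*pi*(t - 550 ms)/300 ms) * exp(-(t - 550 ms)^2 / (2*(60 ms)^2))

``sensory_evoked``
    A single monophasic deflection peaking at 250 ms, a Gaussian bump with
    sd 45 ms::

        w(t) = exp(-(t - 250 ms)^2 / (2*(45 ms)^2))

``delta_brush``
    An immature-EEG event: a 1 Hz slow half-wave (500 ms positive half-sine)
    with a nested fast burst, a 14 Hz sinusoid under a Gaussian envelope
    (sd 80 ms) centred on the half-wave peak, at the slow-wave amplitude
    (neonatal brushes often show fast activity as prominent as the slow
    deflection).
    Both the slow (0.5-2 Hz) and the nested fast (8-22 Hz) constituents sit
    inside the bands the brush detector looks for.

The waveforms are synthetic stand-ins: the real noxious-evoked template used
in the literature is derived from term-infant data that are not distributed
with this package. Any user-supplied template can be loaded instead (see
:mod:`neopain.templates`).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "canonical_waveforms",
    "NOXIOUS_WINDOW_MS",
    "SENSORY_WINDOW_MS",
    "HIGHEST_CONSTITUENT_HZ",
]

#: Post-stimulus analysis window (ms) for noxious-specific activity.
NOXIOUS_WINDOW_MS = (400.0, 700.0)
#: Post-stimulus analysis window (ms) for the sensory-evoked potential.
SENSORY_WINDOW_MS = (100.0, 300.0)
#: Highest frequency present in any canonical waveform (delta-brush nest).
HIGHEST_CONSTITUENT_HZ = 22.0


def _unit_peak(x: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def canonical_waveforms(fs: float) -> dict[str, dict]:
    """Build the three canonical waveforms sampled at ``fs`` Hz.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz. Must be at least four times the highest
        constituent frequency (the 8-22 Hz delta-brush nest), i.e. >= 88 Hz.

    Returns
    -------
    dict
        Keys ``"noxious_specific"``, ``"sensory_evoked"``, ``"delta_brush"``.
        Each value is a dict with:

        ``waveform`` : 1-D float array, unit peak amplitude
        ``t`` : time axis in seconds relative to the stimulus (waveforms are
        defined on [0, 1.0] s post-stimulus)
        ``onset_s`` : nominal event onset used when injecting into epochs
        ``fast_onset_s`` : for the delta brush only, the onset of the nested
        fast burst (the detector timestamps brushes by this)

    Raises
    ------
    ValueError
        If ``fs`` is too low to represent the waveforms.
    """
    if fs < 4.0 * HIGHEST_CONSTITUENT_HZ:
        raise ValueError(
            f"sampling rate {fs} Hz is too low: need fs >= "
            f"{4.0 * HIGHEST_CONSTITUENT_HZ:.0f} Hz to represent the "
            f"{HIGHEST_CONSTITUENT_HZ:.0f} Hz delta-brush nest"
        )
    t = np.arange(0.0, 1.0, 1.0 / fs)

    # Noxious-specific: biphasic, energy in 400-700 ms.
    c, sd = 0.550, 0.060
    nox = np.sin(2 * np.pi * (t - c) / 0.300) * np.exp(-((t - c) ** 2) / (2 * sd**2))

    # Sensory-evoked potential: monophasic bump at 250 ms.
    sep = np.exp(-((t - 0.250) ** 2) / (2 * 0.045**2))

    # Delta brush: 1 Hz half-wave (0-500 ms) + nested 14 Hz burst at its peak.
    slow = np.where((t >= 0) & (t < 0.5), np.sin(2 * np.pi * 1.0 * t), 0.0)
    nest_c, nest_sd = 0.250, 0.080
    nest_env = np.exp(-((t - nest_c) ** 2) / (2 * nest_sd**2))
    nest = nest_env * np.sin(2 * np.pi * 14.0 * (t - nest_c))
    brush = slow + nest
    # Fast-burst onset: where the nest envelope first reaches 10% of its peak.
    fast_onset_s = float(t[np.argmax(nest_env >= 0.1)])

    return {
        "noxious_specific": {
            "waveform": _unit_peak(nox),
            "t": t,
            "onset_s": 0.0,
        },
        "sensory_evoked": {
            "waveform": _unit_peak(sep),
            "t": t,
            "onset_s": 0.0,
        },
        "delta_brush": {
            "waveform": _unit_peak(brush),
            "t": t,
            "onset_s": 0.0,
            "fast_onset_s": fast_onset_s,
        },
    }
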