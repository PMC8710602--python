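"""Auditory envelope extraction and EEG preprocessing.

The speech envelope used for stimulus reconstruction is obtained by passing the
waveform through a gammatone filterbank (28 bands, 50–5000 Hz, equally spaced on
the ERB_N scale), full-wave rectifying each band, applying a compressive power
law (exponent 0.6), averaging across bands, resampling to the 64 Hz model rate
and low-pass filtering below 8 Hz.  EEG is band-pass filtered 2–8 Hz (zero
phase) and resampled to the same 64 Hz grid.

All trial-level signals share a 64 Hz grid starting at trial onset t = 0 s;
sample index 0 covers [0, 1/64) s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

MODEL_RATE_HZ = 64.0

__all__ = [
    "MODEL_RATE_HZ",
    "Waveform",
    "Envelope",
    "FilterbankSpec",
    "EEGRecord",
    "erb_number",
    "erb_number_inverse",
    "erb_center_frequencies",
    "gammatone_filterbank",
    "extract_envelope",
    "preprocess_eeg",
    "resample_to",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class Waveform:
    """A single-channel audio signal with its sampling rate."""

    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("waveform must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz


@dataclass
class Envelope:
    """A one-dimensional acoustic-energy signal at the 64 Hz model rate.

    Values before smoothing are nonnegative; the final low-pass stage may let
    them dip slightly below zero, which is left as-is (Pearson correlation is
    shift/scale invariant, so clipping would add nothing).
    """

    samples: np.ndarray
    rate_hz: float = MODEL_RATE_HZ
    trial_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("envelope must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("envelope contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class FilterbankSpec:
    """Gammatone filterbank layout and the compressive power law."""

    n_bands: int = 28
    f_min_hz: float = 50.0
    f_max_hz: float = 5000.0
    compression_exponent: float = 0.6

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        if not (0 < self.f_min_hz < self.f_max_hz):
            raise ValueError("need 0 < f_min_hz < f_max_hz")

    def center_frequencies(self) -> np.ndarray:
        return erb_center_frequencies(self.f_min_hz, self.f_max_hz, self.n_bands)


@dataclass
class EEGRecord:
    """Multichannel EEG as a channels × samples matrix."""

    data: np.ndarray
    rate_hz: float
    channel_labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG contains non-finite entries")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.channel_labels is not None and len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# ERB scale

_ERB_A = 21.4
_ERB_B = 0.00437


def erb_number(f_hz):
    """ERB-number (Cam) of frequency ``f_hz``: E(f) = 21.4 log10(0.00437 f + 1)."""
    return _ERB_A * np.log10(_ERB_B * np.asarray(f_hz, dtype=float) + 1.0)


def erb_number_inverse(erb):
    """Inverse of :func:`erb_number`."""
    return (10.0 ** (np.asarray(erb, dtype=float) / _ERB_A) - 1.0) / _ERB_B


def erb_center_frequencies(f_min_hz: float, f_max_hz: float, n: int) -> np.ndarray:
    """``n`` frequencies from ``f_min_hz`` to ``f_max_hz`` equally spaced in ERB number.

    Endpoints are returned exactly.
    """
    if not (0 < f_min_hz < f_max_hz):
        raise ValueError("need 0 < f_min_hz < f_max_hz")
    if n < 2:
        raise ValueError("need n >= 2")
    cf = erb_number_inverse(np.linspace(erb_number(f_min_hz), erb_number(f_max_hz), n))
    cf[0], cf[-1] = f_min_hz, f_max_hz
    return cf


# ---------------------------------------------------------------------------
# gammatone filterbank (4th-order all-pole IIR approximation)


def _gammatone_coeffs(cf: float, fs: float):
    """Coefficients of the 4-stage IIR gammatone filter at center frequency ``cf``.

    Classic digital approximation of the 4th-order gammatone: four cascaded
    first-order-numerator biquads sharing the same poles, with an analytic gain
    normalisation to unity at the center frequency.
    """
    T = 1.0 / fs
    erb_width = 24.7 * (4.37 * cf / 1000.0 + 1.0)
    B = 1.019 * 2.0 * np.pi * erb_width

    theta = 2.0 * np.pi * cf * T
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    e1 = np.exp(B * T)

    b1 = -2.0 * cos_t / e1
    b2 = np.exp(-2.0 * B * T)

    rp = np.sqrt(3.0 + 2.0**1.5)
    rm = np.sqrt(3.0 - 2.0**1.5)
    a11 = -(2.0 * T * cos_t / e1 + 2.0 * rp * T * sin_t / e1) / 2.0
    a12 = -(2.0 * T * cos_t / e1 - 2.0 * rp * T * sin_t / e1) / 2.0
    a13 = -(2.0 * T * cos_t / e1 + 2.0 * rm * T * sin_t / e1) / 2.0
    a14 = -(2.0 * T * cos_t / e1 - 2.0 * rm * T * sin_t / e1) / 2.0

    z = np.exp(4j * np.pi * cf * T)
    w = np.exp(-(B * T) + 2j * np.pi * cf * T)
    gain = np.abs(
        (-2.0 * z * T + 2.0 * w * T * (cos_t - rm * sin_t))
        * (-2.0 * z * T + 2.0 * w * T * (cos_t + rm * sin_t))
        * (-2.0 * z * T + 2.0 * w * T * (cos_t - rp * sin_t))
        * (-2.0 * z * T + 2.0 * w * T * (cos_t + rp * sin_t))
        / (-2.0 / np.exp(2.0 * B * T) - 2.0 * z + 2.0 * (1.0 + z) / e1) ** 4
    )

    a = np.array([1.0, b1, b2])
    bs = [np.array([T / gain, a11 / gain, 0.0])] + [
        np.array([T, a1i, 0.0]) for a1i in (a12, a13, a14)
    ]
    return bs, a


def gammatone_filterbank(x: np.ndarray, rate_hz: float, center_hz: Sequence[float]) -> np.ndarray:
    """Filter ``x`` through gammatone filters; returns a bands × samples array."""
    x = np.asarray(x, dtype=float)
    out = np.empty((len(center_hz), x.size))
    for i, cf in enumerate(center_hz):
        bs, a = _gammatone_coeffs(float(cf), rate_hz)
        y = x
        for b in bs:
            y = sps.lfilter(b, a, y)
        out[i] = y
    return out


# ---------------------------------------------------------------------------
# resampling and filtering helpers


def resample_to(x: np.ndarray, rate_in: float, rate_out: float, axis: int = -1) -> np.ndarray:
    """Polyphase (anti-aliased) resampling from ``rate_in`` to ``rate_out``."""
    if rate_in == rate_out:
        return np.asarray(x, dtype=float)
    frac = Fraction(rate_out / rate_in).limit_denominator(10000)
    return sps.resample_poly(x, frac.numerator, frac.denominator, axis=axis)


def _lowpass_sos(cutoff_hz: float, rate_hz: float, order: int = 4):
    return sps.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")


def _bandpass_sos(lo_hz: float, hi_hz: float, rate_hz: float, order: int = 4):
    return sps.butter(order, [lo_hz, hi_hz], btype="band", fs=rate_hz, output="sos")


# ---------------------------------------------------------------------------
# main operations


def extract_envelope(
    w: Waveform,
    spec: FilterbankSpec = FilterbankSpec(),
    trial_id: str | None = None,
    lowpass_hz: float = 8.0,
) -> Envelope:
    """Model-rate speech envelope of a waveform.

    Per band: full-wave rectify the gammatone-filtered signal and raise it to
    the compression exponent; average the bands; resample to 64 Hz with an
    anti-aliased polyphase stage; low-pass below 8 Hz with a zero-phase
    Butterworth filter.
    """
    if w.samples.size == 0:
        raise ValueError("empty waveform")
    if w.rate_hz <= 2.0 * spec.f_max_hz:
        raise ValueError(
            f"audio rate {w.rate_hz} Hz too low for filterbank f_max {spec.f_max_hz} Hz"
        )
    bands = gammatone_filterbank(w.samples, w.rate_hz, spec.center_frequencies())
    compressed = np.abs(bands) ** spec.compression_exponent
    broadband = compressed.mean(axis=0)
    env64 = resample_to(broadband, w.rate_hz, MODEL_RATE_HZ)
    # pad length of the zero-phase filter is > signal for very short inputs
    padlen = min(env64.size - 1, 3 * 2 * 4)
    env64 = sps.sosfiltfilt(_lowpass_sos(lowpass_hz, MODEL_RATE_HZ), env64, padlen=padlen)
    return Envelope(env64, MODEL_RATE_HZ, trial_id=trial_id)


def preprocess_eeg(
    raw: EEGRecord,
    band_hz: tuple[float, float] = (2.0, 8.0),
    out_rate_hz: float = MODEL_RATE_HZ,
) -> EEGRecord:
    """Zero-phase band-pass (2–8 Hz) then anti-aliased downsample to 64 Hz."""
    if raw.rate_hz < out_rate_hz:
        raise ValueError(f"EEG rate {raw.rate_hz} Hz below the {out_rate_hz} Hz model rate")
    sos = _bandpass_sos(band_hz[0], band_hz[1], raw.rate_hz)
    padlen = min(raw.n_samples - 1, 3 * 2 * 2 * 4)
    filtered = sps.sosfiltfilt(sos, raw.data, axis=1, padlen=padlen)
    down = resample_to(filtered, raw.rate_hz, out_rate_hz, axis=1)
    return EEGRecord(down, out_rate_hz, channel_labels=raw.channel_labels)
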