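"""Windowed time-domain and wavelet frequency-domain PPG features.

Feature names follow ``<wavelength>_<domain>_<function>[_<channel>]`` where
domain is ``td`` (raw-signal statistics) or ``fd`` (statistics of one wavelet
channel's magnitude time series), e.g. ``970_td_skew`` or ``1450_fd_median_7``.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.fft import fft, ifft, next_fast_len

from .synthetic_ppg import CHANNEL_ALIASES, PPG_WAVELENGTHS, PPGRecording


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window placement: duration, sweep step and anchor offset."""

    duration_s: float = 210.0
    step_s: float = 20.0
    anchor_s: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.step_s <= 0:
            raise FeatureError("window duration and step must be > 0")


STAT_NAMES = (
    "mean",
    "median",
    "max",
    "min",
    "std",
    "var",
    "skew",
    "kurtosis",
    "iqr",
    "mad",
    "slope",
)

_NAME_RE = re.compile(
    r"^(?P<wavelength>\d+)_(?P<domain>td|fd)_(?P<function>[a-z]+)(?:_(?P<channel>\d+))?$"
)


def make_feature_name(
    wavelength: int, domain: str, function: str, channel: int | None = None
) -> str:
    if domain not in ("td", "fd"):
        raise FeatureError(f"unknown domain {domain!r}")
    if function not in STAT_NAMES:
        raise FeatureError(f"unknown function {function!r}")
    if domain == "fd":
        if channel is None:
            raise FeatureError("frequency-domain names carry a channel id")
        return f"{wavelength}_fd_{function}_{channel}"
    if channel is not None:
        raise FeatureError("time-domain names carry no channel id")
    return f"{wavelength}_td_{function}"


def parse_feature_name(name: str) -> tuple[int, str, str, int | None]:
    """Inverse of :func:`make_feature_name`."""
    m = _NAME_RE.match(name)
    if not m:
        raise FeatureError(f"feature name {name!r} does not match the pattern")
    wavelength = int(m.group("wavelength"))
    domain = m.group("domain")
    function = m.group("function")
    channel = m.group("channel")
    if function not in STAT_NAMES:
        raise FeatureError(f"feature name {name!r}: unknown function")
    if (domain == "fd") != (channel is not None):
        raise FeatureError(f"feature name {name!r}: channel/domain mismatch")
    return wavelength, domain, function, None if channel is None else int(channel)


def _stat_matrix(x: np.ndarray, fs_hz: float) -> np.ndarray:
    """The 11 statistics for each row of a (channels, samples) matrix."""
    n = x.shape[1]
    t = np.arange(n) / fs_hz
    out = np.empty((x.shape[0], len(STAT_NAMES)))
    constant = np.ptp(x, axis=1) == 0
    std = np.where(constant, 0.0, np.std(x, axis=1, ddof=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = stats.skew(x, axis=1)
        kurt = stats.kurtosis(x, axis=1)  # excess kurtosis
    skew = np.where(constant, 0.0, skew)
    kurt = np.where(constant, 0.0, kurt)
    tc = t - t.mean()
    slope = (x - x.mean(axis=1, keepdims=True)) @ tc / np.sum(tc * tc)
    slope = np.where(constant, 0.0, slope)
    out[:, 0] = x.mean(axis=1)
    out[:, 1] = np.median(x, axis=1)
    out[:, 2] = x.max(axis=1)
    out[:, 3] = x.min(axis=1)
    out[:, 4] = std
    out[:, 5] = std**2
    out[:, 6] = skew
    out[:, 7] = kurt
    out[:, 8] = np.where(constant, 0.0, stats.iqr(x, axis=1))
    out[:, 9] = np.where(constant, 0.0, stats.median_abs_deviation(x, axis=1))
    out[:, 10] = slope  # least-squares trend, signal units per second
    return out


def time_domain_features(window: np.ndarray, fs_hz: float = 25.0) -> dict[str, float]:
    """The 11 named statistics of a raw signal window."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or len(window) < 4:
        raise FeatureError("window must be 1-D with at least 4 samples")
    vals = _stat_matrix(window[None, :], fs_hz)[0]
    if np.ptp(window) == 0:
        warnings.warn("constant window: skew/kurtosis reported as 0")
    return dict(zip(STAT_NAMES, (float(v) for v in vals)))


# --- generalized Morse wavelet CWT -----------------------------------------

MORSE_GAMMA = 3.0
MORSE_BETA = 20.0
DEFAULT_FREQ_MIN_HZ = 0.1
DEFAULT_FREQ_MAX_HZ = 12.5
DEFAULT_N_CHANNELS = 24


def morse_wavelet_ft(omega: np.ndarray, gamma: float, beta: float) -> np.ndarray:
    """Frequency-domain generalized Morse wavelet, unit peak value."""
    peak = (beta / gamma) ** (1.0 / gamma)
    psi = np.zeros_like(omega)
    pos = omega > 0
    w = omega[pos]
    # normalize so that psi(peak) == 2 (analytic-wavelet convention)
    lognorm = beta * np.log(w / peak) - (w**gamma - peak**gamma)
    psi[pos] = 2.0 * np.exp(lognorm)
    return psi


@dataclass
class WaveletSpectrum:
    """CWT magnitudes (channels x time) with per-channel center frequencies."""

    magnitude: np.ndarray
    center_freqs_hz: np.ndarray
    fs_hz: float

    @property
    def n_channels(self) -> int:
        return self.magnitude.shape[0]


def wavelet_spectrum(
    window: np.ndarray,
    fs_hz: float,
    freq_min_hz: float = DEFAULT_FREQ_MIN_HZ,
    freq_max_hz: float = DEFAULT_FREQ_MAX_HZ,
    n_channels: int = DEFAULT_N_CHANNELS,
    gamma: float = MORSE_GAMMA,
    beta: float = MORSE_BETA,
) -> WaveletSpectrum:
    """Continuous wavelet transform over log-spaced center frequencies."""
    if fs_hz <= 0:
        raise FeatureError("sampling rate must be > 0")
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or len(x) < 64:
        raise FeatureError("window must be 1-D with at least 64 samples")
    n = len(x)
    nfft = next_fast_len(2 * n)
    xf = fft(x - x.mean(), nfft)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=1.0 / fs_hz)
    freqs = np.geomspace(freq_min_hz, min(freq_max_hz, fs_hz / 2.0), n_channels)
    peak = (beta / gamma) ** (1.0 / gamma)
    mags = np.empty((n_channels, n))
    for i, fc in enumerate(freqs):
        scale = peak / (2.0 * np.pi * fc)
        psi = morse_wavelet_ft(scale * omega, gamma, beta)
        mags[i] = np.abs(ifft(xf * psi)[:n])
    return WaveletSpectrum(magnitude=mags, center_freqs_hz=freqs, fs_hz=fs_hz)


def frequency_domain_features(
    spectrum: WaveletSpectrum, wavelength: int
) -> dict[str, float]:
    """The 11 statistics of each wavelet channel's magnitude time series."""
    vals = _stat_matrix(spectrum.magnitude, spectrum.fs_hz)
    out: dict[str, float] = {}
    for ch in range(spectrum.n_channels):
        for j, fn in enumerate(STAT_NAMES):
            out[make_feature_name(wavelength, "fd", fn, ch)] = float(vals[ch, j])
    return out


@dataclass
class FeatureVector:
    """Ordered named features of one analysis window."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for name in self.values:
            parse_feature_name(name)
        bad = [k for k, v in self.values.items() if not math.isfinite(v)]
        if bad:
            raise FeatureError(f"non-finite feature value(s): {bad[:5]}")

    def names(self) -> list[str]:
        return list(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()))


def extract_window_features(
    recording: PPGRecording,
    start_s: float,
    window: WindowSpec | None = None,
    wavelengths=PPG_WAVELENGTHS,
    include_frequency_domain: bool = True,
    n_channels: int = DEFAULT_N_CHANNELS,
    artifact_profile=None,
) -> FeatureVector:
    """Time + frequency-domain features of one window of a recording.

    When ``artifact_profile`` (from :mod:`sweatsense.sensor_fusion`) is given,
    wavelet channels whose center frequency falls inside an artifact band are
    dropped before the frequency-domain statistics are computed.
    """
    window = window or WindowSpec()
    fs = recording.fs_hz
    i0 = int(round(start_s * fs))
    i1 = i0 + int(round(window.duration_s * fs))
    if i0 < 0 or i1 > len(recording.data):
        raise FeatureError(
            f"window [{start_s}, {start_s + window.duration_s}] s is outside "
            f"the recording (duration {recording.duration_s:.1f} s)"
        )
    values: dict[str, float] = {}
    for wl in wavelengths:
        wl = CHANNEL_ALIASES.get(int(wl), int(wl))
        if wl not in PPG_WAVELENGTHS:
            raise FeatureError(f"unknown wavelength {wl}")
        sig = recording.channel(wl)[i0:i1]
        td = time_domain_features(sig, fs)
        for fn, v in td.items():
            values[make_feature_name(wl, "td", fn)] = v
        if include_frequency_domain:
            spec = wavelet_spectrum(sig, fs, n_channels=n_channels)
            if artifact_profile is not None and artifact_profile.frequencies_hz:
                # zero (rather than drop) masked channels so the feature
                # schema stays identical across recordings
                masked = artifact_profile.mask_frequencies(spec.center_freqs_hz)
                spec.magnitude[masked] = 0.0
            values.update(frequency_domain_features(spec, wl))
    return FeatureVector(values)
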