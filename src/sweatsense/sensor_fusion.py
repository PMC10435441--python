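"""IMU-informed identification and suppression of PPG motion artifacts.

Dominant IMU spectral peaks (cadence, arm swing and their first harmonics)
define artifact bands; PPG content inside those bands is removed in the
Fourier domain before feature extraction, and a channel is flagged unusable
when the cardiac peak itself falls inside an artifact band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps


class FusionError(ValueError):
    pass


DEFAULT_BANDWIDTH_HZ = 0.15
PULSE_BAND_HZ = (0.7, 3.5)


@dataclass
class ArtifactProfile:
    """Dominant IMU frequencies with magnitudes and exclusion bandwidths."""

    frequencies_hz: tuple[float, ...]
    magnitudes: tuple[float, ...]
    bandwidth_hz: float = DEFAULT_BANDWIDTH_HZ
    include_harmonics: bool = True

    def __post_init__(self) -> None:
        if self.bandwidth_hz <= 0:
            raise FusionError("bandwidth must be > 0")
        if any(f <= 0 for f in self.frequencies_hz):
            raise FusionError("artifact frequencies must be > 0")

    def bands(self) -> list[tuple[float, float]]:
        out = []
        for f in self.frequencies_hz:
            out.append((f - self.bandwidth_hz, f + self.bandwidth_hz))
            if self.include_harmonics:
                out.append((2 * f - self.bandwidth_hz, 2 * f + self.bandwidth_hz))
        return out

    def mask_frequencies(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Boolean mask of frequencies falling inside any artifact band."""
        freqs_hz = np.asarray(freqs_hz, dtype=float)
        mask = np.zeros(freqs_hz.shape, dtype=bool)
        for lo, hi in self.bands():
            mask |= (freqs_hz >= lo) & (freqs_hz <= hi)
        return mask

    @property
    def empty(self) -> bool:
        return len(self.frequencies_hz) == 0


def identify_motion_frequencies(
    imu: pd.DataFrame,
    fs_hz: float,
    floor_factor: float = 10.0,
    min_freq_hz: float = 0.3,
    max_peaks: int = 4,
) -> ArtifactProfile:
    """Spectral peaks of the combined IMU channels above a noise floor.

    The amplitude spectra of all IMU channels (means removed) are summed;
    peaks exceeding ``floor_factor`` times the median spectral amplitude
    become artifact frequencies.  Peak magnitudes are amplitude-spectrum
    values and therefore scale linearly with the IMU signal amplitude.
    """
    arr = imu.to_numpy(dtype=float) if hasattr(imu, "to_numpy") else np.asarray(imu)
    if arr.ndim == 1:
        arr = arr[:, None]
    n = arr.shape[0]
    if n < 30 * fs_hz:
        raise FusionError("need at least 30 s of IMU data")
    nper = min(n, int(64 * fs_hz))
    total = None
    for k in range(arr.shape[1]):
        f, pxx = sps.welch(arr[:, k] - arr[:, k].mean(), fs=fs_hz, nperseg=nper)
        amp = np.sqrt(pxx)
        total = amp if total is None else total + amp
    if total is None or not np.any(total > 0):
        return ArtifactProfile((), ())
    floor = np.median(total)
    sel = f >= min_freq_hz
    if floor <= 0:
        return ArtifactProfile((), ())
    idx, _ = sps.find_peaks(total, height=floor_factor * floor)
    idx = [i for i in idx if sel[i]]
    idx = sorted(idx, key=lambda i: -total[i])[:max_peaks]
    # merge near-duplicate peaks (within one bandwidth)
    freqs: list[float] = []
    mags: list[float] = []
    for i in sorted(idx, key=lambda i: f[i]):
        if freqs and abs(f[i] - freqs[-1]) < DEFAULT_BANDWIDTH_HZ:
            if total[i] > mags[-1]:
                freqs[-1], mags[-1] = float(f[i]), float(total[i])
            continue
        freqs.append(float(f[i]))
        mags.append(float(total[i]))
    return ArtifactProfile(tuple(freqs), tuple(mags))


@dataclass
class SuppressionReport:
    """Outcome of artifact suppression on one PPG channel."""

    usable: bool
    cardiac_freq_hz: float | None
    removed_bands_hz: list[tuple[float, float]]
    energy_in: float
    energy_out: float


def suppress_artifacts(
    ppg: np.ndarray,
    profile: ArtifactProfile,
    fs_hz: float,
    pulse_band_hz: tuple[float, float] = PULSE_BAND_HZ,
) -> tuple[np.ndarray, SuppressionReport]:
    """Remove artifact bands from a PPG channel in the Fourier domain.

    Returns the cleaned channel and a report.  If the dominant pulse-band
    peak lies inside an artifact band the channel is flagged unusable and
    returned unmodified.
    """
    x = np.asarray(ppg, dtype=float)
    if x.ndim != 1:
        raise FusionError("ppg channel must be 1-D")
    mean = x.mean()
    xf = np.fft.rfft(x - mean)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs_hz)
    energy_in = float(np.sum(np.abs(xf) ** 2))

    lo, hi = pulse_band_hz
    band = (freqs >= lo) & (freqs <= hi)
    cardiac = None
    if np.any(band):
        amp = np.abs(xf)
        cardiac = float(freqs[band][np.argmax(amp[band])])

    if profile.empty:
        return x.copy(), SuppressionReport(
            usable=True,
            cardiac_freq_hz=cardiac,
            removed_bands_hz=[],
            energy_in=energy_in,
            energy_out=energy_in,
        )

    if cardiac is not None and profile.mask_frequencies(np.array([cardiac]))[0]:
        return x.copy(), SuppressionReport(
            usable=False,
            cardiac_freq_hz=cardiac,
            removed_bands_hz=[],
            energy_in=energy_in,
            energy_out=energy_in,
        )

    mask = profile.mask_frequencies(freqs)
    xf[mask] = 0.0
    cleaned = mean + np.fft.irfft(xf, n=len(x))
    return cleaned, SuppressionReport(
        usable=True,
        cardiac_freq_hz=cardiac,
        removed_bands_hz=profile.bands(),
        energy_in=energy_in,
        energy_out=float(np.sum(np.abs(xf) ** 2)),
    )
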