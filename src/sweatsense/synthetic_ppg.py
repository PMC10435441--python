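"""Synthetic multi-wavelength PPG + IMU run recordings with known ground truth.

Each recording emulates a wrist-worn run session sampled at 25 Hz: four PPG
channels (535, 940, 970, 1450 nm), a 3-axis accelerometer and gyroscope, a
drifting heart rate, cadence/arm-swing motion artifacts coupled into the PPG,
and a water-film drift that begins at a known onset time t0 and pushes the
970 nm channel up and the 1450 nm channel down.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

PPG_WAVELENGTHS = (535, 940, 970, 1450)
#: the hardware description lists a 645 nm emitter where recordings carry
#: 940 nm; the alias lets configs address either name for the same channel
CHANNEL_ALIASES = {645: 940}

PPG_COLUMNS = tuple(f"ppg_{w}" for w in PPG_WAVELENGTHS)
IMU_COLUMNS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")
ALL_COLUMNS = ("time_s",) + PPG_COLUMNS + IMU_COLUMNS


class RecordingError(ValueError):
    pass


@dataclass(frozen=True)
class RunProfile:
    """Ground-truth trajectory parameters for one synthetic run."""

    duration_s: float = 1320.0
    fs_hz: float = 25.0
    # heart rate: exponential rest -> plateau transition
    hr_rest_bpm: float = 75.0
    hr_peak_bpm: float = 155.0
    hr_tau_s: float = 180.0
    # motion
    motion_start_s: float = 30.0
    cadence_spm: float = 168.0
    arm_swing_hz: float = 1.4
    motion_amp: float = 1.0
    # film drift: zero before onset, saturating ramp afterwards
    film_onset_s: float = 600.0
    film_max_um: float = 120.0
    film_tau_s: float = 300.0
    noise_scale: float = 1.0
    # slow Brownian baseline wander, ADC units reached by run end (per channel)
    baseline_wander: float = 3.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise RecordingError("duration must be > 0")
        if self.fs_hz <= 0:
            raise RecordingError("sampling rate must be > 0")
        for hr in (self.hr_rest_bpm, self.hr_peak_bpm):
            if not 40.0 <= hr <= 220.0:
                raise RecordingError("heart rate must lie in [40, 220] bpm")
        if self.film_max_um < 0:
            raise RecordingError("film thickness must be >= 0")

    def times(self) -> np.ndarray:
        n = int(round(self.duration_s * self.fs_hz))
        return np.arange(n) / self.fs_hz

    def heart_rate_bpm(self, t: np.ndarray) -> np.ndarray:
        return self.hr_rest_bpm + (self.hr_peak_bpm - self.hr_rest_bpm) * (
            1.0 - np.exp(-t / self.hr_tau_s)
        )

    def film_um(self, t: np.ndarray) -> np.ndarray:
        """Film thickness trajectory: 0 before onset, saturating ramp after."""
        dt = np.clip(t - self.film_onset_s, 0.0, None)
        film = self.film_max_um * (1.0 - np.exp(-dt / self.film_tau_s))
        film[t < self.film_onset_s] = 0.0
        return film


# Per-channel signal model defaults (arbitrary ADC units).
CHANNEL_BASELINE = {535: 2000.0, 940: 1500.0, 970: 1200.0, 1450: 800.0}
CHANNEL_CARDIAC_AMP = {535: 30.0, 940: 15.0, 970: 12.0, 1450: 4.0}
CHANNEL_MOTION_AMP = {535: 10.0, 940: 8.0, 970: 8.0, 1450: 6.0}
CHANNEL_NOISE_SD = {535: 6.0, 940: 4.0, 970: 4.0, 1450: 3.0}
#: parametric fallback for the reflectance-vs-film response, ADC units per um
#: of film (up at 970 nm, down at 1450 nm, weak elsewhere)
CHANNEL_FILM_SLOPE = {535: 0.0, 940: 0.05, 970: 0.5, 1450: -2.0}
CARDIAC_HARMONICS = (1.0, 0.35, 0.15)


@dataclass
class PPGRecording:
    """Uniformly sampled multi-channel PPG + IMU time series with metadata."""

    data: pd.DataFrame
    fs_hz: float
    seed: int
    profile: RunProfile
    onset_s: float | None

    def __post_init__(self) -> None:
        missing = [c for c in ALL_COLUMNS if c not in self.data.columns]
        if missing:
            raise RecordingError(f"recording missing column(s): {missing}")
        t = self.data["time_s"].to_numpy()
        if len(t) < 2:
            raise RecordingError("recording too short")
        dt = np.diff(t)
        if not np.allclose(dt, 1.0 / self.fs_hz, atol=1e-6):
            raise RecordingError(
                "timestamps are not uniform at the declared sampling rate"
            )

    @property
    def duration_s(self) -> float:
        return len(self.data) / self.fs_hz

    def channel(self, wavelength: int) -> np.ndarray:
        wavelength = CHANNEL_ALIASES.get(wavelength, wavelength)
        col = f"ppg_{wavelength}"
        if col not in self.data.columns:
            raise RecordingError(f"unknown PPG wavelength {wavelength}")
        return self.data[col].to_numpy()

    def imu(self) -> pd.DataFrame:
        return self.data[list(IMU_COLUMNS)]


def generate_run(
    profile: RunProfile | None = None,
    seed: int = 0,
    film_response: dict[int, float] | None = None,
) -> PPGRecording:
    """Generate one seeded run recording.

    ``film_response`` maps wavelength -> ADC units per um of film and defaults
    to the parametric fallback of CHANNEL_FILM_SLOPE; pass slopes derived from
    a simulated reflectance-vs-thickness curve to couple the generator to the
    Monte Carlo trends.
    """
    profile = profile or RunProfile()
    rng = np.random.default_rng(seed)
    t = profile.times()
    n = len(t)
    fs = profile.fs_hz
    response = dict(CHANNEL_FILM_SLOPE)
    if film_response:
        for k, v in film_response.items():
            response[CHANNEL_ALIASES.get(k, k)] = v

    # cardiac phase from the instantaneous heart rate
    hr = profile.heart_rate_bpm(t)
    phase = 2.0 * math.pi * np.cumsum(hr / 60.0) / fs
    cardiac = sum(
        a * np.sin((h + 1) * phase) for h, a in enumerate(CARDIAC_HARMONICS)
    )

    # motion: step cadence + arm swing, switched on at motion_start_s
    env = (t >= profile.motion_start_s).astype(float) * profile.motion_amp
    step_hz = profile.cadence_spm / 60.0
    ph_step = 2.0 * math.pi * step_hz * t + rng.uniform(0, 2 * math.pi)
    ph_arm = 2.0 * math.pi * profile.arm_swing_hz * t + rng.uniform(0, 2 * math.pi)
    step = np.sin(ph_step)
    arm = np.sin(ph_arm)

    film = profile.film_um(t)

    cols: dict[str, np.ndarray] = {"time_s": t}
    for wl in PPG_WAVELENGTHS:
        drift = response[wl] * film
        motion = CHANNEL_MOTION_AMP[wl] * env * (0.6 * arm + 0.4 * step)
        noise = (
            profile.noise_scale
            * CHANNEL_NOISE_SD[wl]
            * rng.standard_normal(n)
        )
        wander = (
            profile.baseline_wander
            * profile.noise_scale
            * np.cumsum(rng.standard_normal(n))
            / math.sqrt(n)
        )
        cols[f"ppg_{wl}"] = (
            CHANNEL_BASELINE[wl]
            + CHANNEL_CARDIAC_AMP[wl] * cardiac
            + motion
            + drift
            + wander
            + noise
        )

    acc_noise = 0.3 * profile.noise_scale
    gyr_noise = 0.05 * profile.noise_scale
    cols["acc_x"] = env * (3.0 * step + 0.8 * arm) + acc_noise * rng.standard_normal(n)
    cols["acc_y"] = env * (1.5 * arm) + acc_noise * rng.standard_normal(n)
    cols["acc_z"] = 9.81 + env * (2.0 * step) + acc_noise * rng.standard_normal(n)
    cols["gyr_x"] = env * (1.0 * arm) + gyr_noise * rng.standard_normal(n)
    cols["gyr_y"] = env * (0.6 * arm + 0.3 * step) + gyr_noise * rng.standard_normal(n)
    cols["gyr_z"] = gyr_noise * rng.standard_normal(n)

    data = pd.DataFrame(cols, columns=list(ALL_COLUMNS))
    onset = profile.film_onset_s if profile.film_max_um > 0 else None
    return PPGRecording(
        data=data, fs_hz=fs, seed=seed, profile=profile, onset_s=onset
    )


def write_recording(recording: PPGRecording, path) -> None:
    """Write the recording as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    recording.data.to_csv(path, index=False)
    meta = {
        "fs_hz": recording.fs_hz,
        "seed": recording.seed,
        "onset_s": recording.onset_s,
        "profile": asdict(recording.profile),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_recording(path) -> PPGRecording:
    """Lossless inverse of :func:`write_recording`."""
    path = Path(path)
    try:
        data = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise RecordingError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in ALL_COLUMNS if c not in data.columns]
    if missing:
        raise RecordingError(f"{path}: missing column(s) {missing}")
    meta_path = path.with_suffix(".json")
    if not meta_path.exists():
        raise RecordingError(f"metadata sidecar not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    profile = RunProfile(**meta["profile"])
    fs = float(meta["fs_hz"])
    t = data["time_s"].to_numpy()
    if len(t) > 1 and not np.allclose(np.diff(t), 1.0 / fs, atol=1e-6):
        raise RecordingError(
            f"{path}: sampling-rate mismatch between header ({fs} Hz) and data"
        )
    return PPGRecording(
        data=data,
        fs_hz=fs,
        seed=int(meta["seed"]),
        profile=profile,
        onset_s=meta["onset_s"],
    )
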