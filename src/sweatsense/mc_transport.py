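"""Photon-packet Monte Carlo transport through a planar layered medium.

Packets of statistical weight 1 are launched as a pencil beam, propagate by
exponentially sampled free paths between scattering events (Henyey-Greenstein
deflection), lose weight continuously by Beer-Lambert absorption along every
traveled segment, and undergo unpolarized Fresnel reflection/refraction at
layer interfaces.  Low-weight packets are terminated by unbiased Russian
roulette.  Detection requires exit through the top surface inside the sensor
aperture within the configured acceptance angle.

Coordinates: z increases into the tissue, the top surface is z = 0, the
source-detector axis is x.  Lengths in mm, angles in degrees at the API.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .optics_model import SkinStack

# terminal event codes
DETECTED = 0
ABSORBED = 1  # terminated by roulette (weight credited to the absorbed tally)
TRANSMITTED = 2
ESCAPED = 3
TRUNCATED = 4

EVENT_NAMES = {
    DETECTED: "detected",
    ABSORBED: "absorbed",
    TRANSMITTED: "transmitted",
    ESCAPED: "escaped",
    TRUNCATED: "truncated",
}


class TransportError(ValueError):
    """Raised for invalid transport inputs."""


# ---------------------------------------------------------------------------
# elementary sampling operations (numba-compiled; callable as plain floats)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _free_path(mu: float, xi: float) -> float:
    return -math.log(xi) / mu


def sample_free_path(mu_t: float, deviate: float) -> float:
    """Exponential free path l = -ln(xi)/mu, mean 1/mu.

    ``mu_t`` is the interaction coefficient governing the event being
    sampled (the scattering coefficient for the random walk between
    scattering events, since absorption is handled continuously).
    """
    if mu_t <= 0:
        raise TransportError("mu_t must be > 0 (non-interacting layers "
                             "are handled by direct boundary transfer)")
    if not 0.0 < deviate < 1.0:
        raise TransportError("deviate must be in (0, 1)")
    return float(_free_path(mu_t, deviate))


@njit(cache=True)
def _hg_cos_theta(g: float, xi: float) -> float:
    if g == 0.0:
        ct = 2.0 * xi - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True)
def _spin(ux: float, uy: float, uz: float, ct: float, phi: float):
    """Rotate a unit direction by polar deflection cos(theta)=ct, azimuth phi."""
    st = math.sqrt(max(1.0 - ct * ct, 0.0))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz >= 0.0 else -ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


def henyey_greenstein_pdf(cos_theta, g: float):
    """Phase-function density per unit solid angle."""
    if not -1.0 < g < 1.0:
        raise TransportError("anisotropy g must be in (-1, 1)")
    ct = np.asarray(cos_theta, dtype=float)
    return (1.0 - g * g) / (4.0 * np.pi * (1.0 + g * g - 2.0 * g * ct) ** 1.5)


def sample_scatter_direction(g: float, direction, u1: float, u2: float):
    """New unit direction after a Henyey-Greenstein scattering event."""
    if not -1.0 < g < 1.0:
        raise TransportError("anisotropy g must be in (-1, 1)")
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise TransportError("incoming direction must be a unit vector")
    ct = _hg_cos_theta(g, u1)
    phi = 2.0 * math.pi * u2
    return np.array(_spin(d[0], d[1], d[2], ct, phi))


def attenuate_weight(weight: float, mu_a: float, length: float):
    """Beer-Lambert weight attenuation over a traveled segment.

    Returns ``(new_weight, absorbed)`` with absorbed = W - W * exp(-mu_a*l).
    """
    if not 0.0 < weight <= 1.0:
        raise TransportError("weight must be in (0, 1]")
    if mu_a < 0 or length < 0:
        raise TransportError("mu_a and length must be >= 0")
    new_w = weight * math.exp(-mu_a * length)
    return new_w, weight - new_w


@njit(cache=True)
def _fresnel(n1: float, n2: float, ci: float):
    """Unpolarized Fresnel reflectance and transmitted cosine.

    ``ci`` is the magnitude of the incident cosine w.r.t. the normal.
    Returns (R, cos_t); beyond the critical angle R = 1.
    """
    if n1 == n2:
        return 0.0, ci
    if ci > 1.0:
        ci = 1.0
    st2 = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
    if st2 >= 1.0:
        return 1.0, 0.0
    ct = math.sqrt(1.0 - st2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp), ct


def fresnel_reflectance(n1: float, n2: float, cos_incident: float) -> float:
    """Unpolarized Fresnel power reflectance."""
    if n1 < 1 or n2 < 1:
        raise TransportError("refractive indices must be >= 1")
    r, _ = _fresnel(n1, n2, abs(cos_incident))
    return float(r)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PhotonPacket:
    """Monte Carlo random walker state."""

    position: np.ndarray
    direction: np.ndarray
    weight: float
    layer: int

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise TransportError("direction must be a unit vector")
        if not 0.0 < self.weight <= 1.0:
            raise TransportError("weight must be in (0, 1]")
        if self.layer < 0:
            raise TransportError("layer index must be >= 0")


@dataclass(frozen=True)
class SensorGeometry:
    """Pencil-beam source and square detector on the top surface."""

    sd_separation_mm: float = 3.5
    detector_side_mm: float = 1.5
    incidence_deg: float = 0.0
    na_half_angle_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.detector_side_mm <= 0:
            raise TransportError("detector side must be > 0")
        if not 0.0 <= self.incidence_deg < 90.0:
            raise TransportError("incidence angle must be in [0, 90)")
        if not 0.0 < self.na_half_angle_deg <= 90.0:
            raise TransportError("NA half-angle must be in (0, 90]")

    @classmethod
    def full_surface(cls, incidence_deg: float = 0.0) -> "SensorGeometry":
        """Detector covering the whole top surface: total diffuse reflectance."""
        return cls(
            sd_separation_mm=0.0,
            detector_side_mm=1e9,
            incidence_deg=incidence_deg,
            na_half_angle_deg=90.0,
        )


@dataclass(frozen=True)
class SimConfig:
    """Run-level Monte Carlo parameters."""

    photons: int = 100_000
    seed: int = 0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    max_interactions: int = 1_000_000

    def __post_init__(self) -> None:
        if self.photons < 1:
            raise TransportError("photon count must be >= 1")
        if not 0.0 < self.roulette_threshold < 1.0:
            raise TransportError("roulette threshold must be in (0, 1)")
        if not 0.0 < self.roulette_survival <= 1.0:
            raise TransportError("roulette survival must be in (0, 1]")


@dataclass
class DetectionRecord:
    """Weight ledger and detected-signal estimate of one MC run."""

    wavelength_nm: float
    launched_weight: float
    detected_weight: float
    detected_count: int
    absorbed_weight: float
    transmitted_weight: float
    escaped_weight: float
    truncated_weight: float
    truncated_count: int
    photons: int
    seed: int
    detected_sumsq: float
    provenance: dict = field(default_factory=dict)

    @property
    def reflectance(self) -> float:
        """Detected signal estimate: detected weight / launched weight."""
        return self.detected_weight / self.launched_weight

    @property
    def total_top_exit(self) -> float:
        """Total diffuse+specular reflectance (detected + escaped)."""
        return (self.detected_weight + self.escaped_weight) / self.launched_weight

    @property
    def standard_error(self) -> float:
        """MC standard error of the detected-signal estimate."""
        n = self.photons
        mean = self.detected_weight / n
        var = max(self.detected_sumsq / n - mean * mean, 0.0)
        return math.sqrt(var / n)

    def conservation_residual(self) -> float:
        total = (
            self.detected_weight
            + self.absorbed_weight
            + self.transmitted_weight
            + self.escaped_weight
            + self.truncated_weight
        )
        return abs(total - self.launched_weight) / self.launched_weight

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reflectance"] = self.reflectance
        d["standard_error"] = self.standard_error
        return d


# ---------------------------------------------------------------------------
# transport kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _trace_kernel(
    z_hi,  # cumulative lower boundary depth per layer (inf for deepest)
    mua,
    mus,
    gs,
    ns,
    n_ambient,
    sin_in,
    cos_in,
    det_x,
    det_half,
    cos_na,
    w_min,
    p_surv,
    max_events,
):
    """Trace one packet; RNG = numba global stream (seeded by the caller).

    Returns (event_code, exit_weight, absorbed_weight).
    ``exit_weight`` goes to the tally named by the event; ``absorbed_weight``
    is the continuous-absorption credit including roulette bookkeeping.
    """
    nlayers = z_hi.shape[0]
    absorbed = 0.0
    w = 1.0

    # entry through the top surface
    r_spec, ct = _fresnel(n_ambient, ns[0], cos_in)
    if np.random.random() < r_spec:
        return ESCAPED, w, absorbed
    scale = n_ambient / ns[0]
    ux = sin_in * scale
    uy = 0.0
    uz = ct
    x = 0.0
    y = 0.0
    z = 0.0
    layer = 0
    tau = -1.0  # no sampled optical depth pending

    for _ in range(max_events):
        ms = mus[layer]
        if ms > 0.0:
            if tau < 0.0:
                tau = -math.log(np.random.random())
            s = tau / ms
        else:
            s = math.inf

        # distance to the layer boundary along the flight direction
        if uz > 0.0:
            db = (z_hi[layer] - z) / uz
        elif uz < 0.0:
            z_lo = z_hi[layer - 1] if layer > 0 else 0.0
            db = (z_lo - z) / uz
        else:
            db = math.inf

        if s < db:
            # scattering event inside the layer
            x += ux * s
            y += uy * s
            z += uz * s
            f = math.exp(-mua[layer] * s)
            absorbed += w * (1.0 - f)
            w *= f
            ct_s = _hg_cos_theta(gs[layer], np.random.random())
            phi = 2.0 * math.pi * np.random.random()
            ux, uy, uz = _spin(ux, uy, uz, ct_s, phi)
            tau = -1.0
        else:
            if db == math.inf:
                # grazing flight in a non-scattering layer: cannot progress
                return TRUNCATED, w, absorbed
            # move to the boundary, keep the unspent optical depth
            x += ux * db
            y += uy * db
            z += uz * db
            f = math.exp(-mua[layer] * db)
            absorbed += w * (1.0 - f)
            w *= f
            if ms > 0.0:
                tau -= db * ms
                if tau < 0.0:
                    tau = 0.0
            going_down = uz > 0.0
            if going_down:
                n2 = ns[layer + 1] if layer + 1 < nlayers else n_ambient
            else:
                n2 = ns[layer - 1] if layer > 0 else n_ambient
            r, ct2 = _fresnel(ns[layer], n2, abs(uz))
            if np.random.random() < r:
                uz = -uz  # specular reflection, stay in layer
            else:
                scale = ns[layer] / n2
                ux *= scale
                uy *= scale
                uz = ct2 if going_down else -ct2
                if going_down:
                    if layer + 1 < nlayers:
                        layer += 1
                        tau = -1.0
                    else:
                        return TRANSMITTED, w, absorbed
                else:
                    if layer > 0:
                        layer -= 1
                        tau = -1.0
                    else:
                        # exit through the top surface into the ambient
                        in_aperture = (
                            abs(x - det_x) <= det_half and abs(y) <= det_half
                        )
                        if in_aperture and (-uz) >= cos_na:
                            return DETECTED, w, absorbed
                        return ESCAPED, w, absorbed

        # Russian roulette on low weight (unbiased ledger bookkeeping)
        if w < w_min:
            if np.random.random() < p_surv:
                boost = w / p_surv - w
                absorbed -= boost
                w += boost
            else:
                absorbed += w
                return ABSORBED, 0.0, absorbed

    return TRUNCATED, w, absorbed


@njit(cache=True)
def _seed_rng(seed: int) -> None:
    # numba keeps its own RNG state; it must be seeded from jitted code
    np.random.seed(seed)


@njit(cache=True)
def _run_kernel(
    z_hi, mua, mus, gs, ns, n_ambient,
    sin_in, cos_in, det_x, det_half, cos_na,
    w_min, p_surv, max_events, photons, seed,
):
    np.random.seed(seed)
    tallies = np.zeros(5)
    detected_count = 0
    truncated_count = 0
    detected_sumsq = 0.0
    absorbed_total = 0.0
    for _ in range(photons):
        code, w_exit, absorbed = _trace_kernel(
            z_hi, mua, mus, gs, ns, n_ambient,
            sin_in, cos_in, det_x, det_half, cos_na,
            w_min, p_surv, max_events,
        )
        tallies[code] += w_exit
        absorbed_total += absorbed
        if code == DETECTED:
            detected_count += 1
            detected_sumsq += w_exit * w_exit
        elif code == TRUNCATED:
            truncated_count += 1
    return tallies, absorbed_total, detected_count, truncated_count, detected_sumsq


def _layer_arrays(stack: SkinStack, wavelength_nm: float):
    thick, mua, mus, g, n = stack.at_wavelength(wavelength_nm)
    z_hi = np.cumsum(thick)
    return z_hi, mua, mus, g, n


def trace_photon(
    stack: SkinStack,
    geometry: SensorGeometry,
    config: SimConfig,
    wavelength_nm: float,
    seed: int | None = None,
):
    """Trace a single packet; returns (event name, exit weight, absorbed weight)."""
    z_hi, mua, mus, g, n = _layer_arrays(stack, wavelength_nm)
    theta = math.radians(geometry.incidence_deg)
    _seed_rng(config.seed if seed is None else seed)
    code, w_exit, absorbed = _trace_kernel(
        z_hi, mua, mus, g, n, stack.n_ambient,
        math.sin(theta), math.cos(theta),
        geometry.sd_separation_mm, geometry.detector_side_mm / 2.0,
        math.cos(math.radians(geometry.na_half_angle_deg)),
        config.roulette_threshold, config.roulette_survival,
        config.max_interactions,
    )
    return EVENT_NAMES[code], w_exit, absorbed


def run_mc(
    stack: SkinStack,
    geometry: SensorGeometry,
    config: SimConfig,
    wavelength_nm: float,
) -> DetectionRecord:
    """Aggregate packet traces into a DetectionRecord at one wavelength."""
    z_hi, mua, mus, g, n = _layer_arrays(stack, wavelength_nm)
    theta = math.radians(geometry.incidence_deg)
    cos_na = math.cos(math.radians(geometry.na_half_angle_deg))
    tallies, absorbed, det_count, trunc_count, sumsq = _run_kernel(
        z_hi, mua, mus, g, n, stack.n_ambient,
        math.sin(theta), math.cos(theta),
        geometry.sd_separation_mm, geometry.detector_side_mm / 2.0, cos_na,
        config.roulette_threshold, config.roulette_survival,
        config.max_interactions, config.photons, config.seed,
    )
    provenance = {
        "seed": config.seed,
        "photons": config.photons,
        "wavelength_nm": wavelength_nm,
        "geometry": asdict(geometry),
        "config_hash": hashlib.sha256(
            json.dumps(
                {"geometry": asdict(geometry), "config": asdict(config)},
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
    }
    return DetectionRecord(
        wavelength_nm=wavelength_nm,
        launched_weight=float(config.photons),
        detected_weight=float(tallies[DETECTED]),
        detected_count=int(det_count),
        absorbed_weight=float(absorbed),
        transmitted_weight=float(tallies[TRANSMITTED]),
        escaped_weight=float(tallies[ESCAPED]),
        truncated_weight=float(tallies[TRUNCATED]),
        truncated_count=int(trunc_count),
        photons=config.photons,
        seed=config.seed,
        detected_sumsq=float(sumsq),
        provenance=provenance,
    )
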