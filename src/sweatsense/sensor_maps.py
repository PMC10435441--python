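"""In-silico sensor experiments: spectra, film-thickness trends, film x angle maps.

Reflectance here means the detected-signal estimate of :func:`run_mc` for the
configured sensor geometry; the shipped default geometry integrates the whole
top surface (total diffuse reflectance), which is what the film/angle sweeps
summarize.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace, field
from typing import Sequence

import numpy as np

from .mc_transport import DetectionRecord, SensorGeometry, SimConfig, run_mc
from .optics_model import (
    Composition,
    LayerSpec,
    SkinStack,
    WavelengthGrid,
    build_skin_stack,
)


class MapError(ValueError):
    pass


@dataclass
class ReflectanceMap:
    """Detected reflectance over a film-thickness x incidence-angle grid."""

    film_um: np.ndarray         # (F,)
    angle_deg: np.ndarray       # (A,)
    wavelengths_nm: np.ndarray  # (W,)
    reflectance: np.ndarray     # (F, A, W)
    standard_error: np.ndarray  # (F, A, W)

    def __post_init__(self) -> None:
        shape = (len(self.film_um), len(self.angle_deg), len(self.wavelengths_nm))
        if self.reflectance.shape != shape or self.standard_error.shape != shape:
            raise MapError(f"map grid incomplete: expected shape {shape}")
        if np.any(~np.isfinite(self.reflectance)):
            raise MapError("map contains missing cells")
        if np.any((self.reflectance < 0) | (self.reflectance > 1)):
            raise MapError("reflectance estimates must lie in [0, 1]")

    def slice_wavelength(self, wavelength_nm: float):
        k = int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))
        if abs(self.wavelengths_nm[k] - wavelength_nm) > 1e-6:
            raise MapError(f"wavelength {wavelength_nm} nm not in map")
        return self.reflectance[:, :, k], self.standard_error[:, :, k]

    def to_dict(self) -> dict:
        return {
            "film_um": self.film_um.tolist(),
            "angle_deg": self.angle_deg.tolist(),
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "reflectance": self.reflectance.tolist(),
            "standard_error": self.standard_error.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ReflectanceMap":
        return cls(
            film_um=np.asarray(d["film_um"], dtype=float),
            angle_deg=np.asarray(d["angle_deg"], dtype=float),
            wavelengths_nm=np.asarray(d["wavelengths_nm"], dtype=float),
            reflectance=np.asarray(d["reflectance"], dtype=float),
            standard_error=np.asarray(d["standard_error"], dtype=float),
        )


def simulate_reflectance_spectrum(
    stack: SkinStack,
    geometry: SensorGeometry,
    grid: WavelengthGrid,
    config: SimConfig,
) -> list[DetectionRecord]:
    """One Monte Carlo run per grid wavelength, aligned to the grid order."""
    records = []
    for wl in grid.wavelengths:
        # seed derived from the wavelength itself so a coarse grid is an
        # exact subsample of a fine-grid run
        cfg = replace(config, seed=config.seed + int(round(wl * 1000)))
        records.append(run_mc(stack, geometry, cfg, wl))
    return records


DEFAULT_FILM_GRID_UM = tuple(np.linspace(0.0, 500.0, 11))
DEFAULT_ANGLE_GRID_DEG = tuple(np.linspace(0.0, 45.0, 10))


def film_angle_map(
    composition: Composition | None = None,
    layer_specs: Sequence[LayerSpec] | None = None,
    geometry: SensorGeometry | None = None,
    film_grid_um: Sequence[float] = DEFAULT_FILM_GRID_UM,
    angle_grid_deg: Sequence[float] = DEFAULT_ANGLE_GRID_DEG,
    wavelengths_nm: Sequence[float] = (970.0, 1450.0),
    config: SimConfig | None = None,
) -> ReflectanceMap:
    """Full Cartesian sweep of film thickness x incidence angle x wavelength."""
    film_grid_um = np.asarray(film_grid_um, dtype=float)
    angle_grid_deg = np.asarray(angle_grid_deg, dtype=float)
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    if film_grid_um.size == 0 or angle_grid_deg.size == 0 or wavelengths_nm.size == 0:
        raise MapError("film, angle and wavelength grids must be non-empty")
    geometry = geometry or SensorGeometry.full_surface()
    config = config or SimConfig()
    grid = WavelengthGrid(tuple(np.sort(wavelengths_nm)))

    refl = np.zeros((len(film_grid_um), len(angle_grid_deg), len(wavelengths_nm)))
    se = np.zeros_like(refl)
    for i, film in enumerate(film_grid_um):
        stack = build_skin_stack(
            composition=composition,
            layer_specs=layer_specs,
            film_thickness_mm=film / 1000.0,
            grid=grid,
        )
        for j, angle in enumerate(angle_grid_deg):
            geo = replace(geometry, incidence_deg=float(angle))
            for k, wl in enumerate(wavelengths_nm):
                cfg = replace(
                    config,
                    seed=config.seed
                    + 100_003 * i
                    + 1_009 * j
                    + 13 * k,
                )
                rec = run_mc(stack, geo, cfg, float(wl))
                refl[i, j, k] = rec.reflectance
                se[i, j, k] = rec.standard_error
    return ReflectanceMap(
        film_um=film_grid_um,
        angle_deg=angle_grid_deg,
        wavelengths_nm=wavelengths_nm,
        reflectance=refl,
        standard_error=se,
    )


@dataclass(frozen=True)
class TrendResult:
    """Signed film-thickness trend of detected reflectance at one wavelength."""

    wavelength_nm: float
    angle_deg: float
    slope_per_um: float
    slope_se: float
    label: str  # "up" | "down" | "flat"


def wavelength_trend_curve(
    rmap: ReflectanceMap,
    wavelength_nm: float,
    angle_deg: float = 0.0,
    n_sigma: float = 3.0,
) -> TrendResult:
    """Least-squares reflectance-vs-film slope with an MC-error sign test."""
    if len(rmap.film_um) < 3:
        raise MapError("trend requires at least 3 film thicknesses")
    refl, se = rmap.slice_wavelength(wavelength_nm)
    j = int(np.argmin(np.abs(rmap.angle_deg - angle_deg)))
    y = refl[:, j]
    y_se = se[:, j]
    x = rmap.film_um - rmap.film_um.mean()
    sxx = float(np.sum(x * x))
    if sxx == 0:
        warnings.warn("degenerate film grid: trend reported as flat")
        return TrendResult(wavelength_nm, float(rmap.angle_deg[j]), 0.0, 0.0, "flat")
    slope = float(np.sum(x * y) / sxx)
    # MC-error propagation through the linear estimator
    slope_se = float(np.sqrt(np.sum((x / sxx) ** 2 * y_se**2)))
    if slope > n_sigma * slope_se:
        label = "up"
    elif slope < -n_sigma * slope_se:
        label = "down"
    else:
        label = "flat"
    return TrendResult(wavelength_nm, float(rmap.angle_deg[j]), slope, slope_se, label)
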