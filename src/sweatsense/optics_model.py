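"""Spectrally resolved optical model of layered skin with a topical water film.

The skin is represented as an ordered stack of planar layers: an optional
water/sweat film on top, seven functional sub-layers (grouped into
epidermis, dermis and hypodermis) and a semi-infinite base.  Absorption is
assembled additively from chromophore spectra (water, oxy-/deoxy-hemoglobin,
melanin, tissue baseline); scattering follows a per-layer power law.

Units: wavelengths in nm (vacuum), coefficients in 1/mm, thicknesses in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

WAVELENGTH_MIN_NM = 450.0
WAVELENGTH_MAX_NM = 1750.0

#: refractive index of the topical water/sweat film
N_WATER = 1.33


class OpticsError(ValueError):
    """Raised for invalid optical-model inputs."""


class WavelengthRangeError(OpticsError):
    """Wavelength outside the tabulated/validated range."""


def _load_table(name: str) -> np.ndarray:
    path = resources.files("sweatsense.data").joinpath(name)
    with path.open("rb") as fh:
        return np.loadtxt(fh, delimiter=",", skiprows=1)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing vacuum wavelengths within the validated range."""

    wavelengths: tuple[float, ...]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.size == 0:
            raise OpticsError("wavelength grid is empty")
        if np.any(np.diff(wl) <= 0):
            raise OpticsError("wavelengths must be strictly increasing")
        if wl[0] < WAVELENGTH_MIN_NM or wl[-1] > WAVELENGTH_MAX_NM:
            raise WavelengthRangeError(
                f"wavelengths must lie within "
                f"[{WAVELENGTH_MIN_NM:g}, {WAVELENGTH_MAX_NM:g}] nm"
            )
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in wl))

    @classmethod
    def regular(cls, start: float, stop: float, step: float = 1.0) -> "WavelengthGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(tuple(start + i * step for i in range(n)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.wavelengths, dtype=float)

    def __len__(self) -> int:
        return len(self.wavelengths)


class ChromophoreSet:
    """Tabulated chromophore absorption spectra and scattering laws.

    Water and hemoglobin are shipped as packaged CSV tables; melanin and the
    tissue baseline use standard closed-form spectra.  All interpolation is
    linear and restricted to the tabulated range.
    """

    def __init__(self) -> None:
        water = _load_table("water_absorption.csv")
        hemo = _load_table("hemoglobin_absorption.csv")
        self._water_wl = water[:, 0]
        self._water_mua = water[:, 1]
        self._hemo_wl = hemo[:, 0]
        self._hemo_oxy = hemo[:, 1]
        self._hemo_deoxy = hemo[:, 2]
        if np.any(self._water_mua < 0) or np.any(hemo[:, 1:] < 0):
            raise OpticsError("chromophore tables contain negative coefficients")

    def _interp(self, wl, table_wl, table_val) -> np.ndarray:
        wl = np.atleast_1d(np.asarray(wl, dtype=float))
        if wl.min() < table_wl[0] or wl.max() > table_wl[-1]:
            raise WavelengthRangeError(
                f"wavelength outside tabulated range "
                f"[{table_wl[0]:g}, {table_wl[-1]:g}] nm"
            )
        return np.interp(wl, table_wl, table_val)

    def water(self, wl) -> np.ndarray:
        """Absorption of pure water, 1/mm."""
        return self._interp(wl, self._water_wl, self._water_mua)

    def oxyhemoglobin(self, wl) -> np.ndarray:
        """Absorption of fully oxygenated whole blood, 1/mm."""
        return self._interp(wl, self._hemo_wl, self._hemo_oxy)

    def deoxyhemoglobin(self, wl) -> np.ndarray:
        """Absorption of fully deoxygenated whole blood, 1/mm."""
        return self._interp(wl, self._hemo_wl, self._hemo_deoxy)

    def melanin(self, wl) -> np.ndarray:
        """Melanosome absorption, 1/mm: 51.9 * (lambda/500)^-3.5."""
        wl = np.atleast_1d(np.asarray(wl, dtype=float))
        self._check_range(wl)
        return 51.9 * (wl / 500.0) ** -3.5

    def baseline(self, wl) -> np.ndarray:
        """Bloodless, waterless tissue baseline absorption, 1/mm."""
        wl = np.atleast_1d(np.asarray(wl, dtype=float))
        self._check_range(wl)
        return 7.84e7 * wl**-3.255

    @staticmethod
    def _check_range(wl: np.ndarray) -> None:
        if wl.min() < WAVELENGTH_MIN_NM or wl.max() > WAVELENGTH_MAX_NM:
            raise WavelengthRangeError("wavelength outside validated range")

    def reduced_scattering(self, wl, a_500_per_mm: float, b: float) -> np.ndarray:
        """Power-law reduced scattering mu_s' = a * (lambda/500)^-b, 1/mm."""
        wl = np.atleast_1d(np.asarray(wl, dtype=float))
        self._check_range(wl)
        return a_500_per_mm * (wl / 500.0) ** -b


@dataclass(frozen=True)
class LayerOptics:
    """Optical properties of one planar layer on a wavelength grid."""

    name: str
    thickness: float  # mm; math.inf allowed for the deepest layer
    mu_a: np.ndarray  # 1/mm per grid wavelength
    mu_s: np.ndarray  # 1/mm per grid wavelength
    g: float
    n: float

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise OpticsError(f"layer {self.name!r}: thickness must be > 0")
        if np.any(np.asarray(self.mu_a) < 0) or np.any(np.asarray(self.mu_s) < 0):
            raise OpticsError(f"layer {self.name!r}: negative coefficient")
        if not -1.0 < self.g < 1.0:
            raise OpticsError(f"layer {self.name!r}: anisotropy must be in (-1, 1)")
        if self.n < 1.0:
            raise OpticsError(f"layer {self.name!r}: refractive index must be >= 1")


@dataclass(frozen=True)
class LayerSpec:
    """Configuration of one functional skin sub-layer (wavelength independent)."""

    name: str
    thickness_mm: float
    water_fraction: float
    blood_fraction: float
    melanin_fraction: float
    n: float
    scatter_a_per_mm: float  # reduced scattering at 500 nm
    scatter_b: float
    g: float


# Default seven-sub-layer parameterization (epidermis 1-2, dermis 3-6,
# hypodermis 7) in the style of the layered skin models this stack follows;
# every number is overridable through configuration.
DEFAULT_LAYERS: tuple[LayerSpec, ...] = (
    LayerSpec("stratum_corneum", 0.02, 0.05, 0.00, 0.0, 1.45, 7.0, 1.4, 0.90),
    LayerSpec("living_epidermis", 0.08, 0.20, 0.00, 1.0, 1.40, 5.0, 1.4, 0.90),
    LayerSpec("papillary_dermis", 0.15, 0.50, 0.04, 0.0, 1.39, 4.5, 1.4, 0.90),
    LayerSpec("upper_blood_net", 0.08, 0.60, 0.20, 0.0, 1.40, 4.2, 1.4, 0.90),
    LayerSpec("reticular_dermis", 1.40, 0.70, 0.04, 0.0, 1.38, 4.0, 1.4, 0.90),
    LayerSpec("deep_blood_net", 0.20, 0.70, 0.10, 0.0, 1.39, 3.8, 1.4, 0.90),
    LayerSpec("hypodermis", 6.00, 0.70, 0.05, 0.0, 1.44, 3.5, 1.0, 0.90),
)


@dataclass(frozen=True)
class Composition:
    """Global chromophore scaling shared by all sub-layers.

    ``c_mel`` is the melanosome volume fraction of the melanated epidermal
    sub-layer; ``c_blood`` scales each sub-layer's default blood fraction;
    ``s_blood`` is hemoglobin oxygen saturation.
    """

    c_mel: float = 0.04
    c_blood: float = 1.0
    s_blood: float = 0.97

    def __post_init__(self) -> None:
        for fname in ("c_mel", "c_blood", "s_blood"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0 and fname != "c_blood":
                raise OpticsError(f"{fname} must be in [0, 1], got {v}")
        if self.c_blood < 0:
            raise OpticsError("c_blood must be >= 0")


def absorption_coefficient(
    wavelength_nm,
    water_fraction: float = 0.0,
    blood_fraction: float = 0.0,
    melanin_fraction: float = 0.0,
    oxygen_saturation: float = 0.97,
    chromophores: ChromophoreSet | None = None,
) -> np.ndarray:
    """Mix chromophore spectra into a layer absorption coefficient, 1/mm.

    mu_a = baseline + W*mu_water + B*(S*mu_oxy + (1-S)*mu_deoxy) + M*mu_mel,
    linear in every fraction.
    """
    for label, v in (
        ("water_fraction", water_fraction),
        ("blood_fraction", blood_fraction),
        ("melanin_fraction", melanin_fraction),
        ("oxygen_saturation", oxygen_saturation),
    ):
        if v < 0 or v > 1:
            raise OpticsError(f"{label} must be in [0, 1], got {v}")
    ch = chromophores or get_chromophores()
    mu = ch.baseline(wavelength_nm).copy()
    if water_fraction:
        mu += water_fraction * ch.water(wavelength_nm)
    if blood_fraction:
        mu += blood_fraction * (
            oxygen_saturation * ch.oxyhemoglobin(wavelength_nm)
            + (1.0 - oxygen_saturation) * ch.deoxyhemoglobin(wavelength_nm)
        )
    if melanin_fraction:
        mu += melanin_fraction * ch.melanin(wavelength_nm)
    return mu


_CHROMOPHORES: ChromophoreSet | None = None


def get_chromophores() -> ChromophoreSet:
    global _CHROMOPHORES
    if _CHROMOPHORES is None:
        _CHROMOPHORES = ChromophoreSet()
    return _CHROMOPHORES


@dataclass(frozen=True)
class SkinStack:
    """Film + seven skin sub-layers + semi-infinite base, spectrally resolved."""

    grid: WavelengthGrid
    layers: tuple[LayerOptics, ...]
    composition: Composition
    film_thickness_mm: float
    n_ambient: float = 1.0

    @property
    def has_film(self) -> bool:
        return self.film_thickness_mm > 0

    @property
    def skin_layers(self) -> tuple[LayerOptics, ...]:
        return self.layers[1:-1] if self.has_film else self.layers[:-1]

    def wavelength_index(self, wavelength_nm: float) -> int:
        wl = self.grid.as_array()
        idx = int(np.argmin(np.abs(wl - wavelength_nm)))
        if abs(wl[idx] - wavelength_nm) > 1e-6:
            raise OpticsError(
                f"wavelength {wavelength_nm} nm is not on the stack grid"
            )
        return idx

    def at_wavelength(self, wavelength_nm: float):
        """Per-layer (thickness, mu_a, mu_s, g, n) arrays at one grid wavelength."""
        k = self.wavelength_index(wavelength_nm)
        thick = np.array([la.thickness for la in self.layers])
        mua = np.array([la.mu_a[k] for la in self.layers])
        mus = np.array([la.mu_s[k] for la in self.layers])
        g = np.array([la.g for la in self.layers])
        n = np.array([la.n for la in self.layers])
        return thick, mua, mus, g, n


def build_skin_stack(
    composition: Composition | None = None,
    layer_specs: Sequence[LayerSpec] | None = None,
    film_thickness_mm: float = 0.0,
    grid: WavelengthGrid | None = None,
    n_ambient: float = 1.0,
    chromophores: ChromophoreSet | None = None,
) -> SkinStack:
    """Assemble the spectrally resolved stack from composition parameters.

    The seven skin sub-layers are followed by a semi-infinite base with the
    optical properties of the deepest sub-layer; a water film is prepended
    iff ``film_thickness_mm`` > 0.
    """
    composition = composition or Composition()
    layer_specs = tuple(layer_specs if layer_specs is not None else DEFAULT_LAYERS)
    if len(layer_specs) != 7:
        raise OpticsError(f"expected exactly 7 skin sub-layers, got {len(layer_specs)}")
    if film_thickness_mm < 0:
        raise OpticsError("film_thickness_mm must be >= 0")
    grid = grid or WavelengthGrid((535.0, 940.0, 970.0, 1450.0))
    ch = chromophores or get_chromophores()
    wl = grid.as_array()

    layers: list[LayerOptics] = []
    if film_thickness_mm > 0:
        layers.append(
            LayerOptics(
                name="film",
                thickness=film_thickness_mm,
                mu_a=ch.water(wl),
                mu_s=np.zeros_like(wl),
                g=0.0,
                n=N_WATER,
            )
        )
    for spec in layer_specs:
        blood = min(spec.blood_fraction * composition.c_blood, 1.0)
        mel = spec.melanin_fraction * composition.c_mel
        mu_a = absorption_coefficient(
            wl,
            water_fraction=spec.water_fraction,
            blood_fraction=blood,
            melanin_fraction=mel,
            oxygen_saturation=composition.s_blood,
            chromophores=ch,
        )
        mu_s_reduced = ch.reduced_scattering(wl, spec.scatter_a_per_mm, spec.scatter_b)
        mu_s = mu_s_reduced / (1.0 - spec.g)
        layers.append(
            LayerOptics(
                name=spec.name,
                thickness=spec.thickness_mm,
                mu_a=mu_a,
                mu_s=mu_s,
                g=spec.g,
                n=spec.n,
            )
        )
    base = layers[-1]
    layers.append(replace(base, name="base", thickness=math.inf))
    return SkinStack(
        grid=grid,
        layers=tuple(layers),
        composition=composition,
        film_thickness_mm=film_thickness_mm,
        n_ambient=n_ambient,
    )


def load_stack_config(path) -> dict:
    """Read a stack/simulation YAML config into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise OpticsError("stack config must be a mapping")
    return cfg


def stack_from_config(cfg: dict) -> SkinStack:
    """Build a SkinStack from a parsed YAML config dict."""
    comp = Composition(**cfg.get("composition", {}))
    grid_cfg = cfg.get("grid")
    if grid_cfg is None:
        grid = None
    elif "wavelengths" in grid_cfg:
        grid = WavelengthGrid(tuple(grid_cfg["wavelengths"]))
    else:
        grid = WavelengthGrid.regular(
            grid_cfg["start"], grid_cfg["stop"], grid_cfg.get("step", 1.0)
        )
    specs = None
    if "layers" in cfg:
        specs = []
        for base, override in zip(DEFAULT_LAYERS, cfg["layers"]):
            specs.append(replace(base, **(override or {})))
    return build_skin_stack(
        composition=comp,
        layer_specs=specs,
        film_thickness_mm=cfg.get("film_thickness_um", 0.0) / 1000.0,
        grid=grid,
        n_ambient=cfg.get("n_ambient", 1.0),
    )
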