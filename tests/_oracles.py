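"""Independent brute-force Monte Carlo oracles.

These deliberately use a different algorithm (analog absorption: packets die
at collisions with probability mu_a/mu_t) and a different RNG stream than the
package implementation, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def semi_infinite_isotropic_reflectance(
    albedo: float, n_photons: int, seed: int
) -> tuple[float, float]:
    """Analog MC estimate of diffuse reflectance of a semi-infinite,
    isotropically scattering, index-matched half space.

    Returns (reflectance, standard error)."""
    rng = np.random.default_rng(seed)
    z = np.zeros(n_photons)
    mu = np.ones(n_photons)  # direction cosine w.r.t. +z (into the medium)
    alive = np.ones(n_photons, dtype=bool)
    escaped = 0
    while alive.any():
        idx = np.flatnonzero(alive)
        s = -np.log(rng.random(idx.size))  # path in units of 1/mu_t
        z_new = z[idx] + mu[idx] * s
        out = z_new < 0.0
        escaped += int(out.sum())
        alive[idx[out]] = False
        stay = idx[~out]
        z[stay] = z_new[~out]
        # analog absorption at the collision
        dead = rng.random(stay.size) >= albedo
        alive[stay[dead]] = False
        live = stay[~dead]
        mu[live] = rng.uniform(-1.0, 1.0, live.size)
    r = escaped / n_photons
    se = np.sqrt(r * (1.0 - r) / n_photons)
    return r, se


def _hg_cos(g: float, u: np.ndarray) -> np.ndarray:
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0)


def two_layer_reflectance(
    d1: float,
    mua1: float,
    mus1: float,
    g1: float,
    mua2: float,
    mus2: float,
    g2: float,
    n_photons: int,
    seed: int,
    max_steps: int = 100_000,
) -> tuple[float, float]:
    """Analog MC total reflectance of a finite layer over a semi-infinite
    base, matched refractive indices, normal-incidence pencil beam.

    Returns (reflectance, standard error)."""
    rng = np.random.default_rng(seed)
    z = np.zeros(n_photons)
    ux = np.zeros(n_photons)
    uy = np.zeros(n_photons)
    uz = np.ones(n_photons)
    layer = np.zeros(n_photons, dtype=np.int8)
    alive = np.ones(n_photons, dtype=bool)
    escaped = 0
    mua = np.array([mua1, mua2])
    mus = np.array([mus1, mus2])
    gs = np.array([g1, g2])
    mut = mua + mus

    for _ in range(max_steps):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        lay = layer[idx]
        s = -np.log(rng.random(idx.size)) / mut[lay]
        # distance to the nearest boundary along the flight direction
        uzi = uz[idx]
        db = np.full(idx.size, np.inf)
        up = uzi < 0
        down = uzi > 0
        # layer 0: boundaries z=0 (top) and z=d1; layer 1: z=d1 and +inf
        db[up & (lay == 0)] = (0.0 - z[idx][up & (lay == 0)]) / uzi[up & (lay == 0)]
        db[up & (lay == 1)] = (d1 - z[idx][up & (lay == 1)]) / uzi[up & (lay == 1)]
        db[down & (lay == 0)] = (d1 - z[idx][down & (lay == 0)]) / uzi[down & (lay == 0)]

        cross = s >= db
        # crossing photons move to the boundary and change layer / escape
        ci = idx[cross]
        z[ci] = z[ci] + uz[ci] * db[cross]
        top_exit = cross & (lay == 0) & up
        escaped += int(top_exit.sum())
        alive[idx[top_exit]] = False
        moved_up = cross & (lay == 1) & up
        layer[idx[moved_up]] = 0
        z[idx[moved_up]] = d1
        moved_down = cross & (lay == 0) & down
        layer[idx[moved_down]] = 1
        z[idx[moved_down]] = d1

        # non-crossing photons collide: absorb or scatter
        ni = idx[~cross]
        z[ni] = z[ni] + uz[ni] * s[~cross]
        lay_n = layer[ni]
        die = rng.random(ni.size) >= mus[lay_n] / mut[lay_n]
        alive[ni[die]] = False
        live = ni[~die]
        if live.size:
            ct = _hg_cos(0.0, rng.random(live.size))
            for gval in np.unique(gs[layer[live]]):
                sel = gs[layer[live]] == gval
                ct[sel] = _hg_cos(float(gval), rng.random(int(sel.sum())))
            phi = rng.uniform(0.0, 2.0 * np.pi, live.size)
            st = np.sqrt(np.clip(1.0 - ct * ct, 0.0, None))
            cp, sp = np.cos(phi), np.sin(phi)
            uxl, uyl, uzl = ux[live], uy[live], uz[live]
            near_pole = np.abs(uzl) > 0.99999
            den = np.sqrt(np.clip(1.0 - uzl**2, 1e-30, None))
            nx = st * (uxl * uzl * cp - uyl * sp) / den + uxl * ct
            ny = st * (uyl * uzl * cp + uxl * sp) / den + uyl * ct
            nz = -st * cp * den + uzl * ct
            nx[near_pole] = (st * cp)[near_pole]
            ny[near_pole] = (st * sp)[near_pole]
            nz[near_pole] = np.where(uzl[near_pole] >= 0, ct[near_pole], -ct[near_pole])
            norm = np.sqrt(nx * nx + ny * ny + nz * nz)
            ux[live], uy[live], uz[live] = nx / norm, ny / norm, nz / norm

    r = escaped / n_photons
    se = np.sqrt(r * (1.0 - r) / n_photons)
    return r, se
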