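"""Voxelized Monte Carlo photon transport for optical fluence estimation.

The estimator follows the standard continuous-absorption-weighting scheme:
photons random-walk on the voxel grid with step lengths sampled from the
local scattering coefficient, Henyey-Greenstein deflection with the local
anisotropy, and exact exponential weight attenuation by the local absorption
along every voxel-path segment. Fluence is accumulated with the track-length
estimator (integrated photon weight per segment divided by voxel volume), so
a voxel's absorbed energy is exactly ``mu_a * Phi * V``. Photons are
terminated by Russian roulette below a weight threshold; the roulette
bookkeeping keeps the energy balance exact in every realization.

Refractive-index boundaries are treated as matched (no Fresnel reflection or
refraction); the index map is carried for completeness but does not bend
rays. All fluence is reported per unit delivered energy, so absolute pulse
energy never enters (the Grueneisen parameter is taken as 1 downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .grids import GridSpec
from .phantom import OpticalMaps, Phantom, load_tissue_table

__all__ = [
    "SourceModel",
    "FluenceVolume",
    "mc_fluence",
    "homogeneous_fluence",
    "ensemble_average_props",
]


@dataclass(frozen=True)
class SourceModel:
    """Illumination geometry: arc illuminators, a pencil beam, or a point.

    The default configuration mirrors a hemispherical breast imager: 20
    arc-shaped illuminators each spanning 80 degrees on a 145 mm-radius
    shell, five fiber segments per arc (100 line beams total), each beam
    emitting into a cone of 12.5 degree half-angle aimed at the breast.
    ``shell_radius_mm=None`` scales the shell to 1.5x the grid half-extent,
    so desk-scale grids keep the same angular coverage.
    """

    kind: str = "arcs"  # arcs | pencil | isotropic
    n_arcs: int = 20
    arc_span_deg: float = 80.0
    segments_per_arc: int = 5
    cone_half_angle_deg: float = 12.5
    shell_radius_mm: float | None = 145.0
    polar_offset_deg: float = 10.0
    # pencil / isotropic parameters
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    @staticmethod
    def pencil(origin_mm, direction) -> "SourceModel":
        d = np.asarray(direction, dtype=float)
        d = tuple(d / np.linalg.norm(d))
        return SourceModel(kind="pencil", origin_mm=tuple(float(o) for o in origin_mm),
                           direction=d, cone_half_angle_deg=0.0)

    @staticmethod
    def isotropic(origin_mm) -> "SourceModel":
        return SourceModel(kind="isotropic", origin_mm=tuple(float(o) for o in origin_mm))

    def beams(self, grid: GridSpec) -> tuple[np.ndarray, np.ndarray, float]:
        """(origins, unit directions, cos of cone half-angle), origins in mm."""
        if self.kind == "pencil":
            o = np.asarray([self.origin_mm], dtype=float)
            d = np.asarray([self.direction], dtype=float)
            return o, d, math.cos(math.radians(self.cone_half_angle_deg))
        if self.kind == "isotropic":
            o = np.asarray([self.origin_mm], dtype=float)
            d = np.asarray([[0.0, 0.0, 1.0]])
            return o, d, -1.0  # full-sphere emission
        if self.kind != "arcs":
            raise ValueError(f"unknown source kind {self.kind!r}")
        radius = self.shell_radius_mm
        if radius is None:
            radius = 1.5 * max(grid.extent_mm) / 2.0
        center = np.array([0.0, 0.0, 0.0])
        origins, dirs = [], []
        span = math.radians(self.arc_span_deg)
        theta0 = math.radians(self.polar_offset_deg)
        for i in range(self.n_arcs):
            phi = 2.0 * math.pi * i / self.n_arcs
            for j in range(self.segments_per_arc):
                theta = theta0 + span * (j + 0.5) / self.segments_per_arc
                pos = center + radius * np.array(
                    [math.sin(theta) * math.cos(phi),
                     math.sin(theta) * math.sin(phi),
                     math.cos(theta)]
                )
                aim = center + np.array([0.0, 0.0, 0.4 * grid.extent_mm[2] / 2.0])
                d = aim - pos
                origins.append(pos)
                dirs.append(d / np.linalg.norm(d))
        n_beams = self.n_arcs * self.segments_per_arc
        assert len(origins) == n_beams
        return (np.asarray(origins), np.asarray(dirs),
                math.cos(math.radians(self.cone_half_angle_deg)))


@dataclass
class FluenceVolume:
    """Per-wavelength fluence in mm^-2 per unit delivered energy."""

    phi: np.ndarray
    wavelength: float
    n_photons: int
    seed: int
    energy_balance: dict = field(default_factory=dict)


@njit(cache=True)
def _hg_cos(g: float, u: float) -> float:
    if abs(g) < 1e-6:
        return 1.0 - 2.0 * u
    s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - s * s) / (2.0 * g)


@njit(cache=True)
def _rotate(ux, uy, uz, cost, phi):
    """Rotate unit vector u by polar angle acos(cost), azimuth phi."""
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    cosp, sinp = math.cos(phi), math.sin(phi)
    if abs(uz) > 0.99999:
        nx = sint * cosp
        ny = sint * sinp
        nz = cost * (1.0 if uz > 0 else -1.0)
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
        nz = -sint * cosp * den + uz * cost
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _mc_kernel(mua, mus, gvol, voxel_size, origins, dirs, cone_cos,
               n_photons, seed, w_min, m_roulette):
    """Single-threaded photon loop. Positions are in voxel units.

    Returns (phi_accumulator, absorbed, escaped, roulette_net) where the
    accumulator is sum of w*l (mm) per voxel, not yet normalized.
    """
    np.random.seed(seed)
    nx, ny, nz = mua.shape
    acc = np.zeros(mua.shape)
    absorbed = 0.0
    escaped = 0.0
    roulette_net = 0.0
    n_beams = origins.shape[0]
    eps = 1e-9

    for ip in range(n_photons):
        b = ip % n_beams
        # emission direction: uniform in the spherical cap of the beam cone
        u = np.random.random()
        cost = cone_cos + (1.0 - cone_cos) * u
        phi_ang = 2.0 * math.pi * np.random.random()
        dx, dy, dz = _rotate(dirs[b, 0], dirs[b, 1], dirs[b, 2], cost, phi_ang)
        # position in voxel units (voxel i spans [i, i+1))
        px = origins[b, 0] / voxel_size
        py = origins[b, 1] / voxel_size
        pz = origins[b, 2] / voxel_size

        # advance to the grid box if starting outside (matched boundaries)
        t_enter = 0.0
        t_exit = 1e30
        for ax in range(3):
            p = px if ax == 0 else (py if ax == 1 else pz)
            d = dx if ax == 0 else (dy if ax == 1 else dz)
            lo, hi = 0.0, float(mua.shape[ax])
            if abs(d) < 1e-12:
                if p < lo or p >= hi:
                    t_enter = 1e31
            else:
                t0 = (lo - p) / d
                t1 = (hi - p) / d
                if t0 > t1:
                    t0, t1 = t1, t0
                if t0 > t_enter:
                    t_enter = t0
                if t1 < t_exit:
                    t_exit = t1
        if t_enter >= t_exit or t_enter > 1e30:
            escaped += 1.0  # beam misses the computational volume
            continue
        if t_enter > 0.0:
            px += dx * (t_enter + eps)
            py += dy * (t_enter + eps)
            pz += dz * (t_enter + eps)

        w = 1.0
        tau = -math.log(np.random.random())
        alive = True
        steps = 0
        while alive and steps < 1_000_000:
            steps += 1
            ix = int(math.floor(px))
            iy = int(math.floor(py))
            iz = int(math.floor(pz))
            if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
                escaped += w
                break
            ma = mua[ix, iy, iz]
            ms = mus[ix, iy, iz]
            gg = gvol[ix, iy, iz]
            # distance (voxel units) to the next voxel boundary
            tb = 1e30
            if dx > eps:
                t = (ix + 1.0 - px) / dx
                if t < tb:
                    tb = t
            elif dx < -eps:
                t = (ix - px) / dx
                if t < tb:
                    tb = t
            if dy > eps:
                t = (iy + 1.0 - py) / dy
                if t < tb:
                    tb = t
            elif dy < -eps:
                t = (iy - py) / dy
                if t < tb:
                    tb = t
            if dz > eps:
                t = (iz + 1.0 - pz) / dz
                if t < tb:
                    tb = t
            elif dz < -eps:
                t = (iz - pz) / dz
                if t < tb:
                    tb = t
            tb += eps
            # remaining path to the next scattering event
            s_scat = tau / (ms * voxel_size) if ms > 0.0 else 1e30
            scatter_here = s_scat < tb
            l = s_scat if scatter_here else tb
            l_mm = l * voxel_size
            # continuous absorption weighting + track-length fluence tally
            if ma > 1e-12:
                trans = math.exp(-ma * l_mm)
                acc[ix, iy, iz] += w * (1.0 - trans) / ma
                absorbed += w * (1.0 - trans)
                w *= trans
            else:
                acc[ix, iy, iz] += w * l_mm
            px += dx * l
            py += dy * l
            pz += dz * l
            if scatter_here:
                cost = _hg_cos(gg, np.random.random())
                phi_ang = 2.0 * math.pi * np.random.random()
                dx, dy, dz = _rotate(dx, dy, dz, cost, phi_ang)
                tau = -math.log(np.random.random())
            else:
                tau -= ms * l_mm
                if tau < 0.0:
                    tau = 0.0
            if w < w_min:
                if np.random.random() < 1.0 / m_roulette:
                    roulette_net -= w * (m_roulette - 1.0)
                    w *= m_roulette
                else:
                    roulette_net += w
                    alive = False
    return acc, absorbed, escaped, roulette_net


def mc_fluence(
    optical: OpticalMaps,
    grid: GridSpec,
    source: SourceModel,
    wavelength: float,
    n_photons: int,
    seed: int,
    roulette_threshold: float = 1e-4,
    roulette_boost: float = 10.0,
) -> FluenceVolume:
    """Monte Carlo fluence (mm^-2 per unit delivered energy) at one wavelength."""
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    mua = np.ascontiguousarray(optical.mua[wavelength], dtype=np.float64)
    mus = np.ascontiguousarray(optical.mus[wavelength], dtype=np.float64)
    g = np.ascontiguousarray(optical.g, dtype=np.float64)
    for name, vol in (("mua", mua), ("mus", mus), ("g", g)):
        if not np.all(np.isfinite(vol)):
            raise ValueError(f"non-finite values in optical map {name!r}")
    origins, dirs, cone_cos = source.beams(grid)
    # positions relative to the grid's physical origin (voxel 0 center at 0.5 vox)
    origin_mm = np.asarray(grid.origin) - 0.5 * grid.voxel_size
    origins = np.ascontiguousarray(origins - origin_mm[None, :])
    acc, absorbed, escaped, roulette_net = _mc_kernel(
        mua, mus, g, grid.voxel_size, origins, np.ascontiguousarray(dirs),
        cone_cos, int(n_photons), int(seed) & 0x7FFFFFFF,
        roulette_threshold, roulette_boost,
    )
    phi = acc / (n_photons * grid.voxel_volume_mm3)
    balance = {
        "launched": float(n_photons),
        "absorbed": float(absorbed),
        "escaped": float(escaped),
        "roulette_net": float(roulette_net),
    }
    balance["relative_error"] = abs(
        balance["launched"] - balance["absorbed"] - balance["escaped"] - balance["roulette_net"]
    ) / balance["launched"]
    return FluenceVolume(phi=phi, wavelength=wavelength, n_photons=int(n_photons),
                         seed=int(seed), energy_balance=balance)


def homogeneous_fluence(
    breast_mask: np.ndarray,
    avg_props: dict,
    source: SourceModel,
    wavelength: float,
    n_photons: int,
    seed: int,
    grid: GridSpec,
    floor: float | None = None,
) -> FluenceVolume:
    """Fluence under uniform breast optical properties (compensated baseline).

    The breast region takes the supplied ensemble-average properties; the
    water bath keeps water optical properties. The returned fluence is
    clamped below by ``floor`` (default 1e-6 of its maximum) so downstream
    division is safe.
    """
    if not np.any(breast_mask):
        raise ValueError("empty breast mask")
    table = load_tissue_table()
    water_opt = table["tissues"]["water"]["optical"]
    wl_tab = [757.0, 800.0, 850.0]
    props = avg_props[wavelength]
    mua = np.where(breast_mask, props["mua"],
                   0.0)  # water NIR absorption is negligible next to tissue
    mus = np.where(breast_mask, props["mus"],
                   float(np.interp(wavelength, wl_tab, water_opt["mus"])))
    g = np.where(breast_mask, props["g"], water_opt["g"])
    n = np.where(breast_mask, props["n"], water_opt["n"])
    optical = OpticalMaps(mua={wavelength: mua}, mus={wavelength: mus}, g=g, n=n)
    fv = mc_fluence(optical, grid, source, wavelength, n_photons, seed)
    lo = floor if floor is not None else 1e-6 * float(fv.phi.max())
    fv.phi = np.maximum(fv.phi, lo)
    fv.energy_balance["floor"] = float(lo)
    return fv


def ensemble_average_props(cohort: list[Phantom], wavelengths=None) -> dict:
    """Voxel-weighted per-wavelength means of breast optical properties.

    Pools all breast voxels of all phantoms (equivalently, a voxel-count
    weighted mean of per-phantom means) and returns
    ``{wavelength: {"mua": .., "mus": .., "g": .., "n": ..}}``.
    """
    if not cohort:
        raise ValueError("empty cohort")
    wavelengths = wavelengths or sorted(cohort[0].optical.mua)
    out: dict = {}
    masks = [p.breast_mask for p in cohort]
    total = sum(int(m.sum()) for m in masks)
    for wl in wavelengths:
        mua = sum(float(p.optical.mua[wl][m].sum()) for p, m in zip(cohort, masks))
        mus = sum(float(p.optical.mus[wl][m].sum()) for p, m in zip(cohort, masks))
        g = sum(float(p.optical.g[m].sum()) for p, m in zip(cohort, masks))
        n = sum(float(p.optical.n[m].sum()) for p, m in zip(cohort, masks))
        out[wl] = {"mua": mua / total, "mus": mus / total, "g": g / total, "n": n / total}
    return out
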