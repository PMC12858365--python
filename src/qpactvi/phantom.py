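"""Stochastic synthetic breast phantoms for virtual photoacoustic imaging.

Each phantom is a hemispherical breast immersed in a water bath: a two-layer
skin shell (epidermis + dermis) over an interior mixture of adipose and
fibroglandular tissue whose proportion follows the BI-RADS density category,
threaded by stochastically branching arterial and venous trees, optionally
with an inserted malignant tumor (spiculated viable rim, necrotic core,
peripheral angiogenesis shell). Skin tone is modeled as the epidermal
melanosome volume fraction, sampled from monotone ranges indexed by the
Fitzpatrick scale 1-6.

On top of the anatomy the generator assigns functional maps (sO2 and volume
fractions of blood, water, fat and melanosome), per-wavelength optical maps
with the absorption coefficient formed as the chromophore sum

    mu_a = thb*so2*eps_HbO2 + thb*(1-so2)*eps_Hb
         + water_vf*eps_water + fat_vf*eps_fat + melanosome_vf*eps_melanin,

and acoustic maps (sound speed, density, power-law attenuation). All
stochastic choices are driven by a single integer seed, so a (config, seed)
pair reproduces a phantom bit for bit.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from scipy import ndimage

from .grids import GridSpec
from .spectra import DEFAULT_WAVELENGTHS_NM, SpectraSet, load_default_spectra

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "PhantomConfig",
    "FunctionalMaps",
    "OpticalMaps",
    "AcousticMaps",
    "Phantom",
    "load_tissue_table",
    "make_breast_phantom",
    "assign_optical_properties",
    "assign_acoustic_properties",
    "sample_cohort",
    "paired_phantom",
]

# integer tissue labels
LABELS = {
    "water": 0,
    "epidermis": 1,
    "dermis": 2,
    "fat": 3,
    "fibroglandular": 4,
    "artery": 5,
    "vein": 6,
    "tumor_viable": 7,
    "tumor_necrotic": 8,
    "tumor_angiogenesis": 9,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

#: interior fibroglandular volume fraction targets per BI-RADS density type
_DENSITY_FRACTION = {"A": 0.08, "B": 0.20, "C": 0.42, "D": 0.68}


def load_tissue_table() -> dict:
    """Packaged per-tissue property table (``data/tissues.yaml``)."""
    with resources.files("qpactvi.data").joinpath("tissues.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class PhantomConfig:
    """Generator parameters. Defaults define a 64^3, 0.5 mm desk-scale study."""

    grid: GridSpec = field(default_factory=lambda: GridSpec((64, 64, 64), 0.5))
    breast_radius_mm: float = 13.0
    epidermis_thickness_mm: float = 0.15
    dermis_thickness_mm: float = 1.35
    density_type: str = "B"
    skin_tone: int = 1
    tumor_location: str = "none"  # none | middle | posterior
    # vessel-tree parameters
    n_arteries: int = 2
    n_veins: int = 2
    vessel_root_radius_mm: float = 1.1
    vessel_min_radius_mm: float = 0.35
    vessel_segment_length_mm: float = 3.0
    vessel_branch_prob: float = 0.45
    vessel_max_depth: int = 7
    # tumor parameters
    tumor_radius_mm: float = 2.4
    tumor_necrotic_fraction: float = 0.45  # core radius as fraction of viable radius
    tumor_angio_fraction: float = 1.35  # angiogenesis outer radius / viable radius
    tumor_spiculation: float = 0.18
    posterior_depth_fraction: float = 0.25  # tumor center z as fraction of radius

    def __post_init__(self) -> None:
        if self.density_type not in _DENSITY_FRACTION:
            raise ValueError(f"density_type must be one of A-D, got {self.density_type!r}")
        if not 1 <= int(self.skin_tone) <= 6:
            raise ValueError(f"skin_tone must be 1-6, got {self.skin_tone}")
        if self.tumor_location not in ("none", "middle", "posterior"):
            raise ValueError(f"unknown tumor_location {self.tumor_location!r}")
        half_xy = min(self.grid.extent_mm[0], self.grid.extent_mm[1]) / 2.0
        need = self.breast_radius_mm + 2.0 * self.grid.voxel_size
        if need > half_xy or need > self.grid.extent_mm[2]:
            raise ValueError(
                f"grid {self.grid.shape} at {self.grid.voxel_size} mm cannot contain a "
                f"breast of radius {self.breast_radius_mm} mm plus skin; enlarge the grid "
                f"or shrink the breast"
            )


@dataclass
class FunctionalMaps:
    so2: np.ndarray
    blood_vf: np.ndarray
    water_vf: np.ndarray
    fat_vf: np.ndarray
    melanosome_vf: np.ndarray
    thb: np.ndarray  # total hemoglobin, mM


@dataclass
class OpticalMaps:
    """Per-wavelength absorption/scattering plus anisotropy and index maps."""

    mua: dict[float, np.ndarray]  # mm^-1
    mus: dict[float, np.ndarray]  # mm^-1
    g: np.ndarray
    n: np.ndarray


@dataclass
class AcousticMaps:
    c: np.ndarray  # m/s
    rho: np.ndarray  # kg/m^3
    alpha0: np.ndarray  # dB MHz^-y cm^-1
    y: np.ndarray


@dataclass
class Phantom:
    grid: GridSpec
    labels: np.ndarray
    functional: FunctionalMaps
    optical: OpticalMaps
    acoustic: AcousticMaps
    metadata: dict

    @property
    def breast_mask(self) -> np.ndarray:
        return self.labels != LABELS["water"]

    @property
    def target_mask(self) -> np.ndarray:
        """Ground-truth target structures: arteries, veins, viable tumor."""
        return np.isin(
            self.labels, [LABELS["artery"], LABELS["vein"], LABELS["tumor_viable"]]
        )

    @property
    def vessel_mask(self) -> np.ndarray:
        return np.isin(self.labels, [LABELS["artery"], LABELS["vein"]])

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels == LABELS["tumor_viable"]


# ---------------------------------------------------------------- anatomy


def _radial_coords(grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x, y, z = grid.meshgrid()
    r = np.sqrt(x**2 + y**2 + z**2)
    return x, y, z, r


def _base_anatomy(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Water bath, skin shells and the fat/fibroglandular interior."""
    grid = config.grid
    _, _, z, r = _radial_coords(grid)
    R = config.breast_radius_mm
    t_epi, t_derm = config.epidermis_thickness_mm, config.dermis_thickness_mm

    labels = np.full(grid.shape, LABELS["water"], dtype=np.int16)
    # hemisphere: z >= 0 measured from the chest-wall plane (z index 0)
    breast = (r <= R) & (z >= 0)
    # voxelized shells; epidermis occupies at least one voxel layer
    epi = breast & (r > R - max(t_epi, grid.voxel_size))
    derm = breast & ~epi & (r > R - t_epi - t_derm)
    interior = breast & ~epi & ~derm

    # fibroglandular / fat partition: smoothed Gaussian field thresholded at
    # the density-type quantile, weighted toward the central cone where
    # glandular tissue concentrates
    frac = _DENSITY_FRACTION[config.density_type]
    noise = rng.standard_normal(grid.shape)
    sigma_vox = max(1.0, 2.0 / grid.voxel_size)
    fieldv = ndimage.gaussian_filter(noise, sigma_vox)
    rho_xy = np.sqrt(r**2 - np.minimum(z, r) ** 2 + 1e-9)
    central = 1.0 - np.clip(rho_xy / max(R, 1e-9), 0, 1)  # 1 at the axis
    fieldv = fieldv + 1.2 * central
    vals = fieldv[interior]
    if vals.size:
        thr = np.quantile(vals, 1.0 - frac)
        fibro = interior & (fieldv > thr)
    else:
        fibro = np.zeros_like(interior)
    labels[interior] = LABELS["fat"]
    labels[fibro] = LABELS["fibroglandular"]
    labels[derm] = LABELS["dermis"]
    labels[epi] = LABELS["epidermis"]
    return labels


def _grow_tree(
    config: PhantomConfig,
    rng: np.random.Generator,
    interior: np.ndarray,
    label_volume: np.ndarray,
    label: int,
) -> None:
    """Rasterize one stochastic bifurcating vessel tree into label_volume.

    Segments random-walk from a chest-wall entry point into the breast,
    radii shrink at each bifurcation (Murray-like factor), and branches stop
    below the minimum radius, at maximum depth, or on leaving the interior.
    """
    grid = config.grid
    R = config.breast_radius_mm
    # entry on the chest-wall plane, within 60% of the breast radius
    ang = rng.uniform(0, 2 * np.pi)
    rad = R * 0.6 * np.sqrt(rng.uniform())
    start = np.array([rad * np.cos(ang), rad * np.sin(ang), 0.5 * grid.voxel_size])
    d0 = np.array([0.3 * rng.standard_normal(), 0.3 * rng.standard_normal(), 1.0])
    stack = [(start, d0 / np.linalg.norm(d0), config.vessel_root_radius_mm, 0)]
    step = grid.voxel_size * 0.5

    while stack:
        pos, direction, radius, depth = stack.pop()
        if radius < config.vessel_min_radius_mm or depth > config.vessel_max_depth:
            continue
        n_steps = max(2, int(config.vessel_segment_length_mm / step))
        for _ in range(n_steps):
            pos = pos + direction * step
            if np.linalg.norm(pos) > R - config.dermis_thickness_mm - radius:
                break
            _stamp_sphere(label_volume, grid, pos, radius, label, interior)
            # gentle meander
            direction = direction + 0.15 * rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
        else:
            # segment completed inside the breast: bifurcate or continue
            if rng.uniform() < config.vessel_branch_prob:
                for _ in range(2):
                    child = direction + 0.8 * rng.standard_normal(3)
                    child /= np.linalg.norm(child)
                    shrink = rng.uniform(0.6, 0.85)
                    stack.append((pos.copy(), child, radius * shrink, depth + 1))
            else:
                stack.append((pos.copy(), direction, radius * rng.uniform(0.85, 0.98), depth + 1))


def _stamp_sphere(
    volume: np.ndarray,
    grid: GridSpec,
    center: np.ndarray,
    radius_mm: float,
    label: int,
    allowed: np.ndarray,
) -> None:
    """Mark voxels within radius of center, restricted to the allowed mask."""
    vs = grid.voxel_size
    rad_vox = int(np.ceil(radius_mm / vs)) + 1
    idx = grid.index_of(center)
    sl = tuple(
        slice(max(i - rad_vox, 0), min(i + rad_vox + 1, s))
        for i, s in zip(idx, grid.shape)
    )
    coords = np.meshgrid(
        *[grid.axis_coords(a)[sl[a]] for a in range(3)], indexing="ij"
    )
    d2 = sum((c - cc) ** 2 for c, cc in zip(coords, center))
    inside = (d2 <= radius_mm**2) & allowed[sl]
    volume[sl][inside] = label


def _tumor_center(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample a tumor center for the requested location class."""
    R = config.breast_radius_mm
    margin = config.tumor_radius_mm * config.tumor_angio_fraction + config.dermis_thickness_mm
    if config.tumor_location == "posterior":
        # adjacent to the chest wall, where fluence is weakest
        z = max(config.tumor_radius_mm * 1.05, config.posterior_depth_fraction * R)
    else:  # middle region of the breast
        z = 0.5 * R
    for _ in range(200):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.4 * R)
        center = np.array([rad * np.cos(ang), rad * np.sin(ang), z])
        if np.linalg.norm(center) + margin < R:
            return center
    raise ValueError(
        f"cannot place a {config.tumor_location!r} tumor of radius "
        f"{config.tumor_radius_mm} mm inside a breast of radius {R} mm"
    )


def _insert_tumor(
    labels: np.ndarray, config: PhantomConfig, rng: np.random.Generator
) -> np.ndarray:
    """Spiculated viable rim + necrotic core + angiogenesis shell.

    Returns the bounding-region mask that was (potentially) modified, so a
    paired phantom can assert equality outside it.
    """
    grid = config.grid
    center = _tumor_center(config, rng)
    r0 = config.tumor_radius_mm
    x, y, z = grid.meshgrid()
    d = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)

    # procedural spiculation: smooth multiplicative noise on the viable radius
    noise = ndimage.gaussian_filter(
        rng.standard_normal(grid.shape), max(1.0, 1.0 / grid.voxel_size)
    )
    noise = noise / (np.abs(noise).max() + 1e-12)
    r_viable = r0 * (1.0 + config.tumor_spiculation * noise)

    interiorish = ~np.isin(labels, [LABELS["water"], LABELS["epidermis"], LABELS["dermis"]])
    angio = (d <= r0 * config.tumor_angio_fraction) & interiorish
    viable = (d <= r_viable) & interiorish
    core = (d <= r0 * config.tumor_necrotic_fraction) & interiorish

    labels[angio] = LABELS["tumor_angiogenesis"]
    labels[viable] = LABELS["tumor_viable"]
    labels[core] = LABELS["tumor_necrotic"]
    return d <= r0 * (config.tumor_angio_fraction + config.tumor_spiculation)


# ----------------------------------------------------- property assignment


def _sample_tissue_draws(
    config: PhantomConfig, rng: np.random.Generator, table: dict
) -> dict:
    """Resolve every ranged entry of the tissue table to one per-phantom value.

    Draw order is fixed (sorted tissue names, fixed key order) so identical
    seeds give identical draws.
    """

    def resolve(v):
        if isinstance(v, list) and len(v) == 2 and all(isinstance(x, (int, float)) for x in v):
            return float(rng.uniform(v[0], v[1]))
        return v

    draws: dict = {"tissues": {}}
    for name in sorted(table["tissues"]):
        entry = table["tissues"][name]
        out = {"optical": dict(entry["optical"]), "acoustic": {}, "functional": {}}
        for key in ("c", "rho", "alpha0", "y"):
            out["acoustic"][key] = resolve(entry["acoustic"][key])
        for key in ("blood_vf", "water_vf", "fat_vf", "so2"):
            if key in entry["functional"]:
                out["functional"][key] = resolve(entry["functional"][key])
        draws["tissues"][name] = out
    mel_range = table["melanosome_vf_by_fitzpatrick"][int(config.skin_tone)]
    draws["melanosome_vf"] = float(rng.uniform(mel_range[0], mel_range[1]))
    draws["whole_blood_thb_mM"] = float(table["whole_blood_thb_mM"])
    # enforce the artery > vein invariant by construction: the configured
    # ranges are disjoint, but guard against a user-edited table
    art = draws["tissues"]["artery"]["functional"]["so2"]
    ven = draws["tissues"]["vein"]["functional"]["so2"]
    if not art > ven:
        draws["tissues"]["vein"]["functional"]["so2"] = art - 0.05
    return draws


def _functional_from_labels(labels: np.ndarray, draws: dict) -> FunctionalMaps:
    shape = labels.shape
    so2 = np.zeros(shape)
    blood = np.zeros(shape)
    water = np.zeros(shape)
    fat = np.zeros(shape)
    mel = np.zeros(shape)
    for name, lab in LABELS.items():
        mask = labels == lab
        if not mask.any():
            continue
        f = draws["tissues"][name]["functional"]
        blood[mask] = f.get("blood_vf", 0.0)
        water[mask] = f.get("water_vf", 0.0)
        fat[mask] = f.get("fat_vf", 0.0)
        so2[mask] = f.get("so2", 0.0)
    mel[labels == LABELS["epidermis"]] = draws["melanosome_vf"]
    # volume fractions must not exceed 1 per voxel
    total = blood + water + fat + mel
    over = total > 1.0
    if over.any():
        scale = np.ones(shape)
        scale[over] = 1.0 / total[over]
        blood, water, fat, mel = blood * scale, water * scale, fat * scale, mel * scale
    thb = blood * draws["whole_blood_thb_mM"]
    return FunctionalMaps(so2, blood, water, fat, mel, thb)


def assign_optical_properties(
    labels: np.ndarray,
    functional: FunctionalMaps,
    spectra: SpectraSet | None = None,
    wavelengths=DEFAULT_WAVELENGTHS_NM,
    tissue_table: dict | None = None,
) -> OpticalMaps:
    """Voxelwise optical maps: chromophore-sum mu_a plus tabulated mus/g/n.

    mu_a is the exact chromophore linear combination; scattering, anisotropy
    and refractive index come from the per-label literature table (water
    voxels carry water optical properties).
    """
    spectra = spectra or load_default_spectra()
    table = tissue_table or load_tissue_table()
    for name in ("HbO2", "Hb", "water", "fat", "melanin"):
        if name not in spectra:
            raise ValueError(f"missing spectrum for chromophore {name!r}")
        for wl in wavelengths:
            spectra[name].at(wl)  # raises with chromophore+wavelength if absent

    mua: dict[float, np.ndarray] = {}
    mus: dict[float, np.ndarray] = {}
    table_wls = [float(w) for w in DEFAULT_WAVELENGTHS_NM]
    for wl in wavelengths:
        mua[wl] = (
            functional.thb * functional.so2 * spectra["HbO2"].at(wl)
            + functional.thb * (1.0 - functional.so2) * spectra["Hb"].at(wl)
            + functional.water_vf * spectra["water"].at(wl)
            + functional.fat_vf * spectra["fat"].at(wl)
            + functional.melanosome_vf * spectra["melanin"].at(wl)
        )
        mus_vol = np.zeros(labels.shape)
        for name, lab in LABELS.items():
            mask = labels == lab
            if not mask.any():
                continue
            mus_tab = table["tissues"][name]["optical"]["mus"]
            mus_vol[mask] = float(np.interp(wl, table_wls, mus_tab))
        mus[wl] = mus_vol

    g = np.zeros(labels.shape)
    n = np.ones(labels.shape)
    for name, lab in LABELS.items():
        mask = labels == lab
        if not mask.any():
            continue
        g[mask] = table["tissues"][name]["optical"]["g"]
        n[mask] = table["tissues"][name]["optical"]["n"]
    return OpticalMaps(mua=mua, mus=mus, g=g, n=n)


def assign_acoustic_properties(labels: np.ndarray, draws: dict) -> AcousticMaps:
    c = np.zeros(labels.shape)
    rho = np.zeros(labels.shape)
    alpha0 = np.zeros(labels.shape)
    yexp = np.ones(labels.shape)
    for name, lab in LABELS.items():
        mask = labels == lab
        if not mask.any():
            continue
        a = draws["tissues"][name]["acoustic"]
        c[mask] = a["c"]
        rho[mask] = a["rho"]
        alpha0[mask] = a["alpha0"]
        yexp[mask] = a["y"]
    return AcousticMaps(c=c, rho=rho, alpha0=alpha0, y=yexp)


# ------------------------------------------------------------- generators


def make_breast_phantom(config: PhantomConfig, seed: int) -> Phantom:
    """Generate one phantom; identical (config, seed) pairs are bit-identical."""
    rng = np.random.default_rng(seed)
    labels = _base_anatomy(config, rng)
    interior = np.isin(labels, [LABELS["fat"], LABELS["fibroglandular"]])
    for _ in range(config.n_arteries):
        _grow_tree(config, rng, interior, labels, LABELS["artery"])
    for _ in range(config.n_veins):
        _grow_tree(config, rng, interior, labels, LABELS["vein"])

    table = load_tissue_table()
    draws = _sample_tissue_draws(config, rng, table)

    if config.tumor_location != "none":
        # dedicated stream so tumor insertion never perturbs base-anatomy draws
        tumor_rng = np.random.default_rng([seed, 0x7A])
        _insert_tumor(labels, config, tumor_rng)

    functional = _functional_from_labels(labels, draws)
    optical = assign_optical_properties(labels, functional, tissue_table=table)
    acoustic = assign_acoustic_properties(labels, draws)
    metadata = {
        "density_type": config.density_type,
        "skin_tone": int(config.skin_tone),
        "tumor_location": config.tumor_location,
        "seed": int(seed),
        "tissue_draws": draws,
        "config": config,
    }
    return Phantom(config.grid, labels, functional, optical, acoustic, metadata)


def paired_phantom(
    base: Phantom, tumor_location: str, config: PhantomConfig | None = None
) -> Phantom:
    """Tumor-bearing twin of a tumor-free phantom, identical outside the tumor.

    The tumor stream is seeded from the base phantom's seed, so the pair is
    reproducible, and property maps are recomputed from the stored per-tissue
    draws, so voxels outside the inserted region are bit-identical.
    """
    if base.metadata["tumor_location"] != "none":
        raise ValueError("paired_phantom requires a tumor-free base phantom")
    if config is None:
        config = base.metadata.get("config") or PhantomConfig(
            grid=base.grid,
            density_type=base.metadata["density_type"],
            skin_tone=base.metadata["skin_tone"],
        )
    config = replace(config, tumor_location=tumor_location)
    labels = base.labels.copy()
    tumor_rng = np.random.default_rng([base.metadata["seed"], 0x7A])
    _insert_tumor(labels, config, tumor_rng)

    draws = copy.deepcopy(base.metadata["tissue_draws"])
    functional = _functional_from_labels(labels, draws)
    optical = assign_optical_properties(labels, functional)
    acoustic = assign_acoustic_properties(labels, draws)
    metadata = dict(base.metadata)
    metadata["tumor_location"] = tumor_location
    metadata["tissue_draws"] = draws
    return Phantom(base.grid, labels, functional, optical, acoustic, metadata)


def sample_cohort(
    n: int,
    density_distribution: tuple[float, float, float, float] = (0.1, 0.4, 0.4, 0.1),
    seed: int = 0,
    config: PhantomConfig | None = None,
) -> list[Phantom]:
    """Cohort with BI-RADS density counts matching the given proportions.

    Counts follow the largest-remainder rule so they match the proportions as
    closely as integers allow; per-phantom seeds derive deterministically from
    the master seed.
    """
    if n <= 0:
        raise ValueError(f"cohort size must be positive, got {n}")
    props = np.asarray(density_distribution, dtype=float)
    if props.shape != (4,) or not np.isclose(props.sum(), 1.0):
        raise ValueError("density_distribution must be 4 proportions summing to 1")
    raw = props * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1

    config = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    cohort = []
    k = 0
    for dtype, cnt in zip("ABCD", counts):
        for _ in range(cnt):
            cfg = replace(config, density_type=dtype)
            cohort.append(make_breast_phantom(cfg, int(child_seeds[k])))
            k += 1
    return cohort
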