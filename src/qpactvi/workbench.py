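"""End-to-end orchestration of the two virtual-imaging study designs.

Study 1 is the idealized design: the true initial-pressure volumes are
corrupted directly with colored image-domain noise (iid sensor noise mapped
through homogeneous time reversal), so noise is the only degradation.
Study 2 is the realistic design: heterogeneous acoustic forward simulation
on the fine grid, sensor-domain noise, then time-reversal reconstruction on
a coarser grid under mismatched homogeneous assumptions (water sound speed,
uniform density, no attenuation), introducing aberration, blurring and
grid-mismatch artifacts.

Both studies share the phantom cohort, the Monte Carlo fluence stage, the
unmixing baselines (the compensated baseline uses cohort ensemble-average
properties) and the evaluation protocol. Everything derives from a single
master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .acoustics import (TransducerArray, add_sensor_noise, colored_noise_image,
                        ensemble_noise_sigma, induced_pressure,
                        simulate_acoustics, study1_input, time_reversal)
from .depth import shell_mask, surface_depth_map
from .evaluate import EvaluationReport, evaluate_estimate
from .grids import GridSpec
from .io import array_checksum, save_phantom
from .optics import SourceModel, ensemble_average_props, homogeneous_fluence, mc_fluence
from .phantom import LABELS, Phantom, PhantomConfig, paired_phantom, sample_cohort
from .spectra import DEFAULT_WAVELENGTHS_NM
from .unmix import fluence_compensated_unmix, linear_unmix

__all__ = ["StudyConfig", "StudyResult", "run_study", "aggregate_depth_tables"]


@dataclass(frozen=True)
class StudyConfig:
    """Desk-scale configuration of one study run."""

    study: int = 1
    n_phantoms: int = 4
    density_distribution: tuple = (0.1, 0.4, 0.4, 0.1)
    skin_tone: int = 1
    tumor_locations: tuple = ("middle", "posterior")  # alternated across cohort
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    wavelengths: tuple = DEFAULT_WAVELENGTHS_NM
    n_photons: int = 100_000
    gamma: float = 1.0
    # acoustics (desk-scale rotating arc)
    array_views: int = 8
    array_elements: int = 24
    array_span_deg: float = 80.0
    noise_fraction: float = 0.01
    noise_sigma: float | None = None  # overrides the ensemble rule
    recon_voxel_ratio: float = 1.2  # recon voxel / forward voxel (0.3 / 0.25)
    matched_reconstruction: bool = False
    # evaluation
    shell_depth_mm: float = 15.0
    depth_bin_mm: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.study not in (1, 2):
            raise ValueError("study must be 1 or 2")


@dataclass
class StudyResult:
    config: StudyConfig
    reports: dict  # estimator name -> list of EvaluationReport
    inputs: list  # per phantom: dict wavelength -> input volume (recon grid)
    phantoms: list
    truth: list  # per phantom: dict with so2/vessel/tumor/depth on recon grid
    summary: dict


def _desk_array(config: StudyConfig, grid: GridSpec) -> TransducerArray:
    """Rotating-arc array scaled into the desk grid, CFL-compatible sampling."""
    radius = config.phantom.breast_radius_mm + 1.5
    c_max = 1650.0  # above any tabulated tissue sound speed
    dt = 0.3 * grid.voxel_size * 1e-3 / c_max
    # enough samples for a two-way domain crossing
    t_cross = 2.0 * max(grid.extent_mm) * 1e-3 / 1400.0
    n_samples = int(np.ceil(t_cross / dt))
    return TransducerArray.rotating_arc(
        n_elements=config.array_elements, radius_mm=radius,
        span_deg=config.array_span_deg, n_views=config.array_views,
        sampling_rate=1.0 / dt, n_samples=n_samples)


def _recon_grid(config: StudyConfig) -> GridSpec:
    fwd = config.phantom.grid
    if config.study == 1 or config.recon_voxel_ratio == 1.0:
        return fwd
    vs = fwd.voxel_size * config.recon_voxel_ratio
    shape = tuple(int(np.floor(e / vs)) for e in fwd.extent_mm)
    origin = tuple(o - fwd.voxel_size / 2 + vs / 2 for o in fwd.origin)
    return GridSpec(shape, vs, origin)


def _resample(vol: np.ndarray, src: GridSpec, dst: GridSpec, order: int = 1):
    if src.shape == dst.shape and np.isclose(src.voxel_size, dst.voxel_size):
        return np.asarray(vol)
    factors = [d / s for d, s in zip(dst.shape, src.shape)]
    out = ndimage.zoom(np.asarray(vol, dtype=float), factors, order=order,
                       mode="nearest", grid_mode=True)
    return out


def _water_sound_speed(phantom: Phantom) -> float:
    water = phantom.labels == LABELS["water"]
    return float(phantom.acoustic.c[water].mean())


def run_study(config: StudyConfig, model=None, output_dir=None) -> StudyResult:
    """Run one study end to end over a paired cohort.

    Tumor-free base phantoms are drawn with the configured density mix; each
    is paired with a tumor-bearing twin (locations alternate through
    ``tumor_locations``), and the twins are imaged. With ``model`` given,
    the learned estimator is applied alongside the unmixing baselines.
    """
    rng = np.random.default_rng(config.seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    seed_cohort, seed_optics, seed_noise = sub(), sub(), sub()

    base_cfg = replace(config.phantom, skin_tone=config.skin_tone,
                       tumor_location="none")
    bases = sample_cohort(config.n_phantoms, config.density_distribution,
                          seed=seed_cohort, config=base_cfg)
    phantoms = [
        paired_phantom(b, config.tumor_locations[i % len(config.tumor_locations)],
                       config=replace(base_cfg, grid=b.grid))
        for i, b in enumerate(bases)
    ]

    grid = config.phantom.grid
    recon_grid = _recon_grid(config)
    source = SourceModel(shell_radius_mm=None)
    array = _desk_array(config, recon_grid if config.study == 1 else grid)

    # stage 1: fluence and true initial pressure per phantom
    p0_all, fluence_all = [], []
    for i, ph in enumerate(phantoms):
        p0_wl, phi_wl = {}, {}
        for wl in config.wavelengths:
            fv = mc_fluence(ph.optical, grid, source, wl, config.n_photons,
                            seed=(seed_optics + 31 * i + int(wl)) % 2**31)
            phi_wl[wl] = fv
            p0_wl[wl] = induced_pressure(ph.optical.mua[wl], fv.phi,
                                         gamma=config.gamma, grid=grid,
                                         wavelength=wl)
        p0_all.append(p0_wl)
        fluence_all.append(phi_wl)

    # stage 2: study-specific image formation
    inputs_all = []
    if config.study == 1:
        sigma = config.noise_sigma
        if sigma is None:
            # reference signal level from one forward simulation (desk-scale
            # stand-in for the full simulated-measurement ensemble)
            ref = {wl: simulate_acoustics(p0_all[0][wl], phantoms[0].acoustic,
                                          array, grid, apply_attenuation=False)
                   for wl in config.wavelengths}
            sigma = ensemble_noise_sigma([ref], config.noise_fraction)
        c_water = _water_sound_speed(phantoms[0])
        for i in range(len(phantoms)):
            noise = {wl: colored_noise_image(
                array, recon_grid, sigma, c_water,
                seed=(seed_noise + 97 * i + int(wl)) % 2**31)
                for wl in config.wavelengths}
            inputs_all.append(study1_input(p0_all[i], noise))
    else:
        sensors_all = [
            {wl: simulate_acoustics(p0_all[i][wl], phantoms[i].acoustic, array,
                                    grid, apply_attenuation=True)
             for wl in config.wavelengths}
            for i in range(len(phantoms))
        ]
        sigma = (config.noise_sigma if config.noise_sigma is not None
                 else ensemble_noise_sigma(sensors_all, config.noise_fraction))
        for i, sensors in enumerate(sensors_all):
            noisy = add_sensor_noise(sensors, seed=(seed_noise + i) % 2**31,
                                     sigma=sigma)
            if config.matched_reconstruction:
                breast = phantoms[i].breast_mask
                c_assumed = float(phantoms[i].acoustic.c[breast].mean())
            else:
                c_assumed = _water_sound_speed(phantoms[i])
            recons = {wl: time_reversal(noisy[wl], array, c_assumed, 1000.0,
                                        recon_grid)
                      for wl in config.wavelengths}
            inputs_all.append({wl: r.volume for wl, r in recons.items()})

    # stage 3: truth on the reconstruction grid
    truth_all = []
    for ph in phantoms:
        breast_r = _resample(ph.breast_mask.astype(float), grid, recon_grid,
                             order=0) > 0.5
        truth_all.append({
            "so2": _resample(ph.functional.so2, grid, recon_grid, order=1),
            "vessel": _resample(ph.vessel_mask.astype(float), grid, recon_grid,
                                order=0) > 0.5,
            "tumor": (_resample(ph.tumor_mask.astype(float), grid, recon_grid,
                                order=0) > 0.5).astype(int),
            "target": _resample(ph.target_mask.astype(float), grid, recon_grid,
                                order=0) > 0.5,
            "breast": breast_r,
            "depth": surface_depth_map(breast_r, recon_grid.voxel_size),
            "shell": shell_mask(breast_r, recon_grid, config.shell_depth_mm),
        })

    # stage 4: estimators + evaluation
    avg_props = ensemble_average_props(phantoms, config.wavelengths)
    reports: dict[str, list[EvaluationReport]] = {"linear_unmix": [],
                                                  "fluence_compensated": []}
    if model is not None:
        reports["dl"] = []
    for i, (ph, inputs, truth) in enumerate(zip(phantoms, inputs_all, truth_all)):
        mask = truth["target"] & truth["shell"]
        vols = {wl: np.asarray(v) for wl, v in inputs.items()}
        lin = linear_unmix(vols, mask=mask)
        phi_est = {wl: homogeneous_fluence(
            truth["breast"], avg_props, source, wl, config.n_photons,
            seed=(seed_optics + 7919 * (i + 1) + int(wl)) % 2**31,
            grid=recon_grid)
            for wl in config.wavelengths}
        comp = fluence_compensated_unmix(vols, phi_est, mask=mask)
        for name, res in (("linear_unmix", lin), ("fluence_compensated", comp)):
            reports[name].append(evaluate_estimate(
                res.so2, mask, truth["so2"], truth["vessel"], truth["tumor"],
                truth["depth"], bin_width_mm=config.depth_bin_mm,
                location_tags={1: ph.metadata["tumor_location"]}))
        if model is not None:
            from .dl import predict

            x = np.stack([vols[wl] for wl in sorted(vols)])
            est = predict(model, x, truth["shell"])
            reports["dl"].append(evaluate_estimate(
                est.so2, est.seg_mask, truth["so2"], truth["vessel"],
                truth["tumor"], truth["depth"], bin_width_mm=config.depth_bin_mm,
                location_tags={1: ph.metadata["tumor_location"]}))

    summary = _summarize(config, reports, inputs_all)
    result = StudyResult(config=config, reports=reports, inputs=inputs_all,
                         phantoms=phantoms, truth=truth_all, summary=summary)
    if output_dir is not None:
        _write_outputs(result, Path(output_dir))
    return result


def aggregate_depth_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Voxel-weighted pooling of per-phantom depth-binned MAE tables."""
    cat = pd.concat(tables, ignore_index=True)
    rows = []
    for (lo, hi), gdf in cat.groupby(["depth_lo_mm", "depth_hi_mm"]):
        n = int(gdf["n_voxels"].sum())
        if n:
            w = gdf["n_voxels"] / n
            mae = float((gdf["mae"].fillna(0) * w).sum())
            var = float((w * (gdf["std"].fillna(0) ** 2
                              + (gdf["mae"].fillna(0) - mae) ** 2)).sum())
            rows.append({"depth_lo_mm": lo, "depth_hi_mm": hi, "mae": mae,
                         "std": np.sqrt(var), "n_voxels": n})
        else:
            rows.append({"depth_lo_mm": lo, "depth_hi_mm": hi, "mae": np.nan,
                         "std": np.nan, "n_voxels": 0})
    return pd.DataFrame(rows).sort_values("depth_lo_mm").reset_index(drop=True)


def _summarize(config: StudyConfig, reports: dict, inputs_all: list) -> dict:
    summary: dict = {"study": config.study, "seed": config.seed,
                     "n_phantoms": config.n_phantoms}
    for name, reps in reports.items():
        dices = [r.dice_mean for r in reps]
        det = {k: int(sum(r.detection[k] for r in reps)) for k in ("tp", "fp", "fn")}
        table = aggregate_depth_tables([r.depth_mae for r in reps])
        pairs = [p for r in reps for p in r.tumor_so2_pairs]
        summary[name] = {
            "dice_mean": float(np.mean(dices)),
            "dice_std": float(np.std(dices)),
            "detection": det,
            "depth_mae": table.to_dict(orient="records"),
            "tumor_so2_pairs": pairs,
        }
    summary["input_checksum"] = array_checksum(
        *[np.asarray(v) for inp in inputs_all for v in
          (inp[wl] for wl in sorted(inp))])
    return summary


def _write_outputs(result: StudyResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for i, ph in enumerate(result.phantoms):
        save_phantom(ph, outdir / f"phantom_{i:03d}.h5")
    for name, reps in result.reports.items():
        for i, r in enumerate(reps):
            r.depth_mae.to_csv(outdir / f"depth_mae_{name}_{i:03d}.csv", index=False)
            with open(outdir / f"report_{name}_{i:03d}.json", "w") as fh:
                json.dump({"dice": r.dice_mean, "detection": r.detection,
                           "tumor_so2_pairs": r.tumor_so2_pairs}, fh, indent=2)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2)
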