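"""Study-1-style training/evaluation datasets at desk scale.

Builds small phantom cohorts, runs Monte Carlo fluence at the three
wavelengths, forms the true initial pressure, and corrupts it with
spatially smoothed Gaussian image-domain noise (a cheap stand-in for the
time-reversal colored noise of the full Study-1 pipeline, keeping its two
salient features: zero mean and spatial correlation). Inputs are
normalized per sample by the pooled multiwavelength maximum, which is the
network's input normalization convention throughout this package.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from .acoustics import induced_pressure
from .depth import shell_mask, surface_depth_map
from .grids import GridSpec
from .optics import SourceModel, mc_fluence
from .phantom import PhantomConfig, paired_phantom, sample_cohort
from .spectra import DEFAULT_WAVELENGTHS_NM

__all__ = ["make_study1_dataset"]


def make_study1_dataset(
    n_samples: int,
    size: int = 24,
    seed: int = 0,
    n_photons: int = 20_000,
    noise_fraction: float = 0.01,
    with_tumors: bool = True,
    extent_mm: float = 22.0,
    breast_radius_mm: float = 8.5,
    vessel_root_radius_mm: float | None = None,
    vessel_min_radius_mm: float | None = None,
    tumor_radius_mm: float = 2.0,
    wavelengths=DEFAULT_WAVELENGTHS_NM,
) -> tuple[list[dict], list[dict]]:
    """(training samples, auxiliary truth) for a small Study-1-style cohort.

    Each training sample is ``{"input": (3, D, H, W), "so2": (D, H, W),
    "seg": binary}``; the auxiliary list carries the matching vessel mask,
    depth map, shell and p0 volumes for evaluation. Density types follow
    the 1:4:4:1 clinical mix.
    """
    voxel = extent_mm / size
    cfg = PhantomConfig(
        grid=GridSpec((size, size, size), voxel),
        breast_radius_mm=breast_radius_mm,
        vessel_root_radius_mm=(vessel_root_radius_mm if vessel_root_radius_mm
                               is not None else max(1.0, 2.2 * voxel)),
        vessel_min_radius_mm=(vessel_min_radius_mm if vessel_min_radius_mm
                              is not None else max(0.4, 0.8 * voxel)),
        tumor_radius_mm=tumor_radius_mm,
    )
    rng = np.random.default_rng(seed)
    bases = sample_cohort(n_samples, (0.1, 0.4, 0.4, 0.1),
                          seed=int(rng.integers(2**31)), config=cfg)
    source = SourceModel(shell_radius_mm=None)
    samples, aux = [], []
    for i, base in enumerate(bases):
        ph = base
        if with_tumors:
            loc = "middle" if i % 2 == 0 else "posterior"
            try:
                ph = paired_phantom(base, loc, config=replace(cfg, grid=base.grid))
            except ValueError:
                ph = base  # breast too small for this placement; keep tumor-free
        p0 = {}
        for wl in wavelengths:
            fv = mc_fluence(ph.optical, ph.grid, source, wl, n_photons,
                            seed=int(rng.integers(2**31)))
            p0[wl] = induced_pressure(ph.optical.mua[wl], fv.phi).p0
        pooled_max = max(v.max() for v in p0.values())
        noisy = {}
        for wl in wavelengths:
            noise = rng.standard_normal(ph.grid.shape)
            noise = ndimage.gaussian_filter(noise, 1.0)
            noise *= noise_fraction * pooled_max / max(noise.std(), 1e-12)
            noisy[wl] = (p0[wl] + noise) / pooled_max
        breast = ph.breast_mask
        shell = shell_mask(breast, ph.grid)
        seg = (ph.target_mask & shell).astype(float)
        samples.append({
            "input": np.stack([noisy[wl] for wl in sorted(noisy)]),
            "so2": ph.functional.so2.astype(float),
            "seg": seg,
        })
        aux.append({
            "phantom": ph,
            "p0": p0,
            "vessel": ph.vessel_mask,
            "tumor": ph.tumor_mask.astype(int),
            "target": ph.target_mask,
            "shell": shell,
            "depth": surface_depth_map(breast, voxel),
            "pooled_max": pooled_max,
        })
    return samples, aux
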