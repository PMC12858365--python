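"""Spectral-unmixing baselines for blood-oxygenation estimation.

Linear spectral unmixing assumes wavelength-invariant optical fluence: the
multiwavelength initial-pressure spectrum of a voxel is fit by least squares
to a nonnegative combination of the HbO2 and Hb extinction spectra, and sO2
is the ratio c_HbO2 / (c_HbO2 + c_Hb). Any common positive scale (Grueneisen
parameter, delivered energy, fluence magnitude) cancels in the ratio, which
is why only relative concentrations are recovered. Spectral coloring —
wavelength-dependent fluence attenuation with depth — biases this estimator;
the fluence-compensated variant divides each wavelength's image by an
estimated fluence map before unmixing to partially remove that bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectraSet, load_default_spectra

__all__ = ["UnmixResult", "linear_unmix", "fluence_compensated_unmix"]


@dataclass
class UnmixResult:
    """Relative hemoglobin concentrations and the derived sO2 map.

    ``so2`` is only defined where ``valid_mask`` is True (voxels inside the
    requested mask whose total-hemoglobin estimate exceeds the denominator
    floor); elsewhere it is 0. Values are clipped to [0, 1].
    """

    c_hbo2: np.ndarray
    c_hb: np.ndarray
    so2: np.ndarray
    valid_mask: np.ndarray


def linear_unmix(
    p_volumes: dict,
    spectra: SpectraSet | None = None,
    mask: np.ndarray | None = None,
    nonnegative: bool = False,
    denom_floor_frac: float = 1e-12,
) -> UnmixResult:
    """Joint least-squares unmixing of all wavelengths.

    Parameters
    ----------
    p_volumes : dict
        Wavelength (nm) -> initial-pressure volume. At least two wavelengths.
    mask : bool array, optional
        Voxels where estimation is attempted (default: everywhere).
    nonnegative : bool
        Solve with nonnegativity enforced by active-set projection instead
        of clipping the unconstrained solution at zero. For a 2-component
        fit the projection is exact: if one concentration goes negative the
        optimum lies on the corresponding axis.
    """
    wavelengths = sorted(p_volumes)
    if len(wavelengths) < 2:
        raise ValueError("need at least two wavelengths to unmix")
    spectra = spectra or load_default_spectra()
    E = spectra.extinction_matrix(wavelengths)  # raises if singular

    shape = p_volumes[wavelengths[0]].shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    P = np.stack([np.asarray(p_volumes[wl])[mask] for wl in wavelengths])  # (nwl, nvox)

    # unconstrained least squares for every voxel at once
    C, *_ = np.linalg.lstsq(E, P, rcond=None)  # (2, nvox)
    if nonnegative:
        # exact 2-component nonnegative solution: project onto each axis
        neg = (C < 0).any(axis=0)
        if neg.any():
            Pn = P[:, neg]
            cands = np.empty((2, 2, neg.sum()))
            resid = np.empty((2, neg.sum()))
            for j in range(2):
                e = E[:, j]
                cj = np.maximum(e @ Pn / (e @ e), 0.0)
                cands[j] = 0.0
                cands[j, j] = cj
                resid[j] = ((Pn - np.outer(e, cj)) ** 2).sum(axis=0)
            pick = resid.argmin(axis=0)
            C[:, neg] = cands[pick, :, np.arange(neg.sum())].T
    else:
        C = np.clip(C, 0.0, None)

    denom = C.sum(axis=0)
    floor = denom_floor_frac * (denom.max() if denom.size else 0.0)
    ok = denom > floor
    so2_flat = np.zeros_like(denom)
    so2_flat[ok] = np.clip(C[0, ok] / denom[ok], 0.0, 1.0)

    c_hbo2 = np.zeros(shape)
    c_hb = np.zeros(shape)
    so2 = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    c_hbo2[mask] = C[0]
    c_hb[mask] = C[1]
    so2[mask] = so2_flat
    valid[mask] = ok
    return UnmixResult(c_hbo2=c_hbo2, c_hb=c_hb, so2=so2, valid_mask=valid)


def fluence_compensated_unmix(
    p_volumes: dict,
    phi_est: dict,
    spectra: SpectraSet | None = None,
    mask: np.ndarray | None = None,
    **kwargs,
) -> UnmixResult:
    """Rescale each wavelength by its estimated fluence, then unmix.

    ``phi_est`` maps wavelength to a fluence volume (or an object with a
    ``phi`` attribute). Fluence must be strictly positive on the mask —
    apply the flooring of the fluence estimator upstream.
    """
    wavelengths = sorted(p_volumes)
    shape = np.asarray(p_volumes[wavelengths[0]]).shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    rescaled = {}
    for wl in wavelengths:
        phi = phi_est[wl]
        phi = getattr(phi, "phi", phi)
        if np.any(phi[mask] <= 0):
            raise ValueError(
                f"fluence estimate at {wl} nm is not strictly positive inside the "
                f"mask; apply a floor before compensation"
            )
        rescaled[wl] = np.where(phi > 0, np.asarray(p_volumes[wl]) / np.where(phi > 0, phi, 1.0), 0.0)
    return linear_unmix(rescaled, spectra=spectra, mask=mask, **kwargs)
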