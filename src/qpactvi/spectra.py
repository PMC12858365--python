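"""Chromophore absorption spectra and the extinction matrix for unmixing.

The absorption coefficient of soft tissue in the near infrared is a linear
combination of chromophore contributions,

    mu_a(r, lambda) = sum_k c_k(r) * eps_k(lambda),

with oxyhemoglobin (HbO2), deoxyhemoglobin (Hb), water, fat (lipid) and
melanin as the chromophores that matter for breast imaging between 700 and
900 nm. Hemoglobin spectra are stored per mM of hemoglobin; water, fat and
melanin per unit volume fraction (see ``data/chromophores.yaml``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "ChromophoreSpectrum",
    "SpectraSet",
    "load_default_spectra",
    "DEFAULT_WAVELENGTHS_NM",
]

logger = logging.getLogger(__name__)

#: Illumination wavelengths of the emulated imager (nm).
DEFAULT_WAVELENGTHS_NM: tuple[int, ...] = (757, 800, 850)

_KNOWN = ("HbO2", "Hb", "water", "fat", "melanin")


@dataclass(frozen=True)
class ChromophoreSpectrum:
    """Specific absorption of one chromophore on a wavelength support.

    ``epsilon`` is in mm^-1 per mM for HbO2/Hb and mm^-1 per unit volume
    fraction for water/fat/melanin; all values use the natural-log
    (Napierian) convention so that mu_a multiplies path length directly.
    """

    name: str
    wavelengths: tuple[float, ...]
    epsilon: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.name not in _KNOWN:
            raise ValueError(f"unknown chromophore {self.name!r}; expected one of {_KNOWN}")
        if len(self.wavelengths) != len(self.epsilon):
            raise ValueError("wavelengths and epsilon must have equal length")
        if any(e < 0 for e in self.epsilon):
            raise ValueError(f"negative epsilon in spectrum {self.name!r}")

    def at(self, wavelength: float) -> float:
        """Epsilon at one wavelength; raises if the wavelength is missing."""
        for wl, eps in zip(self.wavelengths, self.epsilon):
            if np.isclose(wl, wavelength):
                return float(eps)
        raise KeyError(
            f"chromophore {self.name!r} has no tabulated value at {wavelength} nm "
            f"(available: {list(self.wavelengths)})"
        )


class SpectraSet:
    """Collection of chromophore spectra sharing a wavelength support."""

    def __init__(self, spectra: dict[str, ChromophoreSpectrum]):
        self.spectra = dict(spectra)

    def __getitem__(self, name: str) -> ChromophoreSpectrum:
        return self.spectra[name]

    def __contains__(self, name: str) -> bool:
        return name in self.spectra

    def extinction_matrix(self, wavelengths=DEFAULT_WAVELENGTHS_NM) -> np.ndarray:
        """(n_wavelengths, 2) matrix of [HbO2, Hb] epsilons.

        The condition number is logged: unmixing is only well posed when the
        two hemoglobin spectra are linearly independent over the support.
        """
        E = np.array(
            [[self["HbO2"].at(wl), self["Hb"].at(wl)] for wl in wavelengths],
            dtype=float,
        )
        cond = np.linalg.cond(E)
        if not np.isfinite(cond):
            raise ValueError("HbO2/Hb extinction matrix is singular on this wavelength support")
        logger.info("extinction matrix condition number: %.3f", cond)
        return E


def load_default_spectra() -> SpectraSet:
    """Load the packaged chromophore table (``data/chromophores.yaml``)."""
    with resources.files("qpactvi.data").joinpath("chromophores.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    wavelengths = tuple(float(w) for w in raw["wavelengths_nm"])
    spectra = {
        name: ChromophoreSpectrum(name, wavelengths, tuple(float(v) for v in values))
        for name, values in raw["epsilon"].items()
    }
    return SpectraSet(spectra)
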