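"""Core spectral value types shared by every module.

An :class:`EmissionSpectrum` pairs a strictly increasing wavelength grid (nm)
with nonnegative intensities (arbitrary units / photon counts). It is the
common currency between the synthetic generator, the I/O layer and the GP
computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["EmissionSpectrum"]


@dataclass(frozen=True)
class EmissionSpectrum:
    """One emission spectrum: intensity sampled on a wavelength grid.

    Parameters
    ----------
    wavelengths : array-like
        Sample wavelengths in nm, strictly increasing.
    intensities : array-like
        Nonnegative, finite intensities, same length as ``wavelengths``.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation_nm: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise ValidationError(
                f"wavelengths and intensities must be 1-D of equal length, "
                f"got shapes {wl.shape} and {it.shape}"
            )
        if wl.size == 0:
            raise ValidationError("spectrum must contain at least one sample")
        if not np.all(np.isfinite(wl)) or not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths must be finite and strictly increasing")
        if not np.all(np.isfinite(it)):
            raise ValidationError("intensities must be finite")
        if np.any(it < 0):
            raise ValidationError("intensities must be nonnegative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def total(self) -> float:
        """Summed intensity over all samples."""
        return float(self.intensities.sum())

    def scaled(self, factor: float) -> "EmissionSpectrum":
        """Return a copy with intensities multiplied by ``factor`` (>= 0)."""
        if factor < 0:
            raise ValidationError("scale factor must be nonnegative")
        return EmissionSpectrum(
            self.wavelengths, self.intensities * float(factor), self.excitation_nm
        )

    def __add__(self, other: "EmissionSpectrum") -> "EmissionSpectrum":
        if not np.array_equal(self.wavelengths, other.wavelengths):
            raise ValidationError("cannot add spectra on different wavelength grids")
        return EmissionSpectrum(
            self.wavelengths, self.intensities + other.intensities, self.excitation_nm
        )
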