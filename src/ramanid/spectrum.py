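"""Core containers for Raman measurements.

A :class:`RamanSpectrum` is a single measurement: a strictly increasing
wavenumber axis (cm^-1), an intensity axis of the same length (arbitrary
units, possibly negative before baseline correction), and light metadata.
A :class:`SpectrumSet` is an ordered, labelled collection of spectra that
the preprocessing, feature-extraction and chemometrics stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .errors import ValidationError

MIN_POINTS = 8

__all__ = ["RamanSpectrum", "SpectrumSet", "MIN_POINTS"]


@dataclass(frozen=True)
class RamanSpectrum:
    """One Raman measurement on its own wavenumber grid.

    Parameters
    ----------
    wavenumbers : array-like of float
        Raman shift axis in cm^-1, strictly increasing, all finite.
    intensities : array-like of float
        Counts (arbitrary units), same length as ``wavenumbers``; negative
        values are legal before baseline correction.
    label : str
        Analyte name, or ``"unknown"``.
    excitation_nm : float or None
        Laser excitation wavelength (e.g. 785 or 532).
    replicate_id : str
        Identifier distinguishing technical replicates of one analyte.
    source_path : str
        Provenance of the data, when read from disk.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    label: str = "unknown"
    excitation_nm: float | None = None
    replicate_id: str = ""
    source_path: str = ""

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        iy = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", iy)
        if wn.ndim != 1 or iy.ndim != 1:
            raise ValidationError("wavenumbers and intensities must be 1-D arrays")
        if wn.size != iy.size:
            raise ValidationError(
                f"axis length mismatch: {wn.size} wavenumbers vs {iy.size} intensities"
            )
        if wn.size < MIN_POINTS:
            raise ValidationError(
                f"spectrum has {wn.size} points; at least {MIN_POINTS} required"
            )
        if not np.all(np.isfinite(wn)):
            raise ValidationError("wavenumbers contain non-finite values")
        if not np.all(np.isfinite(iy)):
            raise ValidationError("intensities contain non-finite values")
        if np.any(np.diff(wn) <= 0):
            if np.any(np.diff(wn) == 0):
                raise ValidationError("duplicate wavenumbers present")
            raise ValidationError("wavenumbers must be strictly increasing")

    # -- basic geometry -------------------------------------------------

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def with_intensities(self, intensities: np.ndarray) -> "RamanSpectrum":
        """Copy of this spectrum with a new intensity axis on the same grid."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))

    def crop(self, lo: float, hi: float) -> "RamanSpectrum":
        """Restrict to the closed wavenumber interval [lo, hi].

        Metadata is preserved.  Raises :class:`ValidationError` when the
        interval is empty or selects no points.
        """
        if not lo < hi:
            raise ValidationError(f"crop interval invalid: lo={lo} >= hi={hi}")
        mask = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        if not np.any(mask):
            raise ValidationError(
                f"crop [{lo}, {hi}] does not overlap spectrum support {self.support}"
            )
        return replace(
            self, wavenumbers=self.wavenumbers[mask], intensities=self.intensities[mask]
        )

    def regrid(self, grid: Sequence[float]) -> "RamanSpectrum":
        """Linearly interpolate intensities onto ``grid`` (must lie within support)."""
        g = np.asarray(grid, dtype=float)
        if g.ndim != 1 or np.any(np.diff(g) <= 0):
            raise ValidationError("target grid must be 1-D and strictly increasing")
        lo, hi = self.support
        if g[0] < lo or g[-1] > hi:
            raise ValidationError(
                f"target grid [{g[0]}, {g[-1]}] outside spectrum support [{lo}, {hi}]"
            )
        iy = np.interp(g, self.wavenumbers, self.intensities)
        return replace(self, wavenumbers=g, intensities=iy)


@dataclass
class SpectrumSet:
    """Ordered collection of spectra plus the ordered set of class names.

    Iteration order is insertion order, so downstream results are
    deterministic for a fixed input.
    """

    spectra: list[RamanSpectrum] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.class_names)) != len(self.class_names):
            raise ValidationError("class_names must be unique")
        known = set(self.class_names)
        for s in self.spectra:
            if s.label != "unknown" and s.label not in known:
                raise ValidationError(
                    f"spectrum label {s.label!r} not in class_names and not 'unknown'"
                )

    @classmethod
    def from_spectra(cls, spectra: Sequence[RamanSpectrum]) -> "SpectrumSet":
        """Build a set whose class names are the labels in first-seen order."""
        names: list[str] = []
        for s in spectra:
            if s.label != "unknown" and s.label not in names:
                names.append(s.label)
        return cls(spectra=list(spectra), class_names=names)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[RamanSpectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> RamanSpectrum:
        return self.spectra[i]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.spectra]
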