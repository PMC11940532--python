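"""Seeded generator of labelled synthetic Raman spectra.

The generator emulates the statistical structure of replicate powder
measurements: each pesticide class contributes Lorentzian (optionally
Gaussian / pseudo-Voigt) peaks at its library fingerprint positions, on
top of a smooth fluorescence-like baseline (random cubic polynomial or
decaying exponential, one family drawn per spectrum), with additive white
noise, occasional one-point cosmic spikes, and small replicate-to-replicate
position and height jitter.

Class archetypes (base peak heights and widths) are derived from a stream
keyed by ``(seed, class name)``, and replicate-level randomness from a
stream keyed by ``(seed, class name, replicate index)``, so spectra are
reproducible one by one and adding a class never perturbs existing ones.

A "spiked extract" mode mimics dried QuEChERS extracts measured on a
silicon wafer by adding the sharp crystalline Si band at 521 cm^-1 and a
broad second-order Si band across 900-1000 cm^-1.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .library import FingerprintRecord, load_library
from .spectrum import RamanSpectrum, SpectrumSet

__all__ = ["SyntheticConfig", "simulate_spectrum", "simulate_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs; defaults describe the study conditions emulated."""

    grid_lo: float = 400.0
    grid_hi: float = 1700.0
    grid_step: float = 1.0
    peak_shape: str = "lorentzian"  # lorentzian | gaussian | pseudo_voigt
    fwhm_range: tuple[float, float] = (8.0, 15.0)
    major_height_range: tuple[float, float] = (0.6, 1.0)
    minor_height_range: tuple[float, float] = (0.1, 0.5)
    position_jitter_sd: float = 1.5
    height_jitter_cv: float = 0.1
    baseline_families: tuple[str, ...] = ("poly3", "exp_decay")
    baseline_amplitude_range: tuple[float, float] = (0.2, 0.8)
    noise_sd: float = 0.02
    spike_prob_per_spectrum: float = 0.3
    spike_height_range: tuple[float, float] = (5.0, 20.0)  # x max peak height
    spiked_extract_mode: bool = False
    n_per_class: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ConfigError("grid_step must be > 0")
        if self.grid_lo >= self.grid_hi:
            raise ConfigError("grid_lo must be < grid_hi")
        if self.peak_shape not in ("lorentzian", "gaussian", "pseudo_voigt"):
            raise ConfigError(f"unknown peak_shape {self.peak_shape!r}")
        for name in ("fwhm_range", "major_height_range", "minor_height_range",
                     "baseline_amplitude_range", "spike_height_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ConfigError(f"{name} must satisfy 0 < lo < hi, got ({lo}, {hi})")
        if self.position_jitter_sd < 0 or self.height_jitter_cv < 0:
            raise ConfigError("jitter parameters must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 <= self.spike_prob_per_spectrum <= 1:
            raise ConfigError("spike_prob_per_spectrum must be in [0, 1]")
        if self.n_per_class < 1:
            raise ConfigError("n_per_class must be >= 1")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.grid_lo, self.grid_hi + self.grid_step / 2, self.grid_step)


def _stream(*keys: object) -> np.random.Generator:
    """Deterministic RNG substream keyed by seed / strings / ints (crc32-hashed)."""
    entropy = [k if isinstance(k, int) else zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _kernel(nu: np.ndarray, center: float, fwhm: float, shape: str) -> np.ndarray:
    if shape == "lorentzian":
        gamma = fwhm / 2.0
        return gamma**2 / ((nu - center) ** 2 + gamma**2)
    if shape == "gaussian":
        sd = fwhm / 2.3548200450309493  # FWHM -> sigma
        return np.exp(-0.5 * ((nu - center) / sd) ** 2)
    # pseudo-Voigt: equal-weight mix
    return 0.5 * _kernel(nu, center, fwhm, "lorentzian") + 0.5 * _kernel(
        nu, center, fwhm, "gaussian"
    )


def _class_archetype(record: FingerprintRecord, cfg: SyntheticConfig):
    """Base (position, height, fwhm) per peak, fixed per (seed, class)."""
    rng = _stream(cfg.seed, record.name, "archetype")
    peaks = []
    for pos in record.major_peaks:
        peaks.append((float(pos), rng.uniform(*cfg.major_height_range),
                      rng.uniform(*cfg.fwhm_range)))
    for pos in record.minor_peaks:
        peaks.append((float(pos), rng.uniform(*cfg.minor_height_range),
                      rng.uniform(*cfg.fwhm_range)))
    return peaks


def _baseline(nu: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    family = cfg.baseline_families[rng.integers(len(cfg.baseline_families))]
    u = (nu - nu[0]) / (nu[-1] - nu[0])
    amp = rng.uniform(*cfg.baseline_amplitude_range)
    if family == "poly3":
        coeffs = rng.uniform(-1.0, 1.0, size=4)
        raw = coeffs[0] + coeffs[1] * u + coeffs[2] * u**2 + coeffs[3] * u**3
        raw = raw - raw.min()
        peak_to_peak = raw.max() if raw.max() > 0 else 1.0
        return amp * raw / peak_to_peak
    if family == "exp_decay":
        tau = rng.uniform(0.3, 1.0)
        return amp * np.exp(-u / tau)
    raise ConfigError(f"unknown baseline family {family!r}")


def simulate_spectrum(
    record: FingerprintRecord,
    cfg: SyntheticConfig | None = None,
    replicate: int = 0,
) -> RamanSpectrum:
    """One synthetic replicate spectrum of ``record``; reproducible from
    ``(cfg.seed, record.name, replicate)``."""
    cfg = cfg or SyntheticConfig()
    nu = cfg.grid
    rng = _stream(cfg.seed, record.name, replicate)
    y = np.zeros_like(nu)
    max_height = 0.0
    for pos, height, fwhm in _class_archetype(record, cfg):
        delta = rng.normal(0.0, cfg.position_jitter_sd) if cfg.position_jitter_sd else 0.0
        h = height * max(0.0, 1.0 + rng.normal(0.0, cfg.height_jitter_cv))
        y += h * _kernel(nu, pos + delta, fwhm, cfg.peak_shape)
        max_height = max(max_height, h)
    if cfg.spiked_extract_mode:
        # crystalline Si first-order band: sharp and dominant on wafer substrates
        si_h = rng.uniform(1.5, 3.0) * max(max_height, 1.0)
        y += si_h * _kernel(nu, 521.0, 6.0, "lorentzian")
        # broad second-order Si band across 900-1000 cm^-1
        band_h = rng.uniform(0.2, 0.5) * max(max_height, 1.0)
        y += band_h * np.exp(-0.5 * ((nu - 950.0) / 40.0) ** 2)
    y += _baseline(nu, cfg, rng)
    if cfg.noise_sd:
        y += rng.normal(0.0, cfg.noise_sd, size=nu.size)
    if cfg.spike_prob_per_spectrum and rng.uniform() < cfg.spike_prob_per_spectrum:
        i = int(rng.integers(nu.size))
        y[i] += rng.uniform(*cfg.spike_height_range) * max(max_height, 1.0)
    return RamanSpectrum(
        wavenumbers=nu,
        intensities=y,
        label=record.name,
        excitation_nm=785.0,
        replicate_id=str(replicate),
    )


def simulate_dataset(
    library: Sequence[FingerprintRecord] | None = None,
    cfg: SyntheticConfig | None = None,
) -> SpectrumSet:
    """``cfg.n_per_class`` replicates for every library record, in record order."""
    cfg = cfg or SyntheticConfig()
    if library is None:
        library = load_library()
    if not library:
        raise ConfigError("library must be non-empty")
    spectra = [
        simulate_spectrum(rec, cfg, replicate=r)
        for rec in library
        for r in range(cfg.n_per_class)
    ]
    return SpectrumSet.from_spectra(spectra)
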