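"""Spectral pre-processing: despiking, baseline correction, denoising, scaling.

The pipeline applied to every spectrum is, in fixed order:

1. crop to the fingerprint window (default 400-1700 cm^-1),
2. Whittaker-Hayes cosmic-spike removal (modified z-score of the first
   difference),
3. IARPLS baseline correction (improved asymmetrically reweighted
   penalized least squares, Ye et al. 2020),
4. Savitzky-Golay denoising,
5. min-max scaling to [0, 1].

Cropping precedes despiking so that edge spikes outside the fingerprint
window never influence the robust statistics.

IARPLS
------
At iteration ``t`` the baseline ``z`` solves the weighted Whittaker problem

    minimize  sum_i w_i (y_i - z_i)^2  +  lam * sum_i (D2 z)_i^2

with ``D2`` the second-difference operator (natural boundaries).  With
residual ``d = y - z`` and ``sigma`` the standard deviation of the negative
residuals, the weights are updated by the algebraic-sigmoid rule

    u_i = exp(t) * (d_i - 2 sigma) / sigma
    w_i = 0.5 * (1 - u_i / sqrt(1 + u_i^2))

so points far above the running baseline (Raman peaks) are driven to
weight 0 while points at or below it keep weight near 1; the sigmoid
sharpens as ``exp(t)`` grows.  Iteration stops when the relative change of
the weight vector drops below ``tol`` or after ``max_iter`` rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded
from scipy.signal import savgol_filter

from .errors import ConfigError, ValidationError
from .spectrum import RamanSpectrum, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "BaselineResult",
    "PipelineResult",
    "despike_whitaker_hayes",
    "baseline_iarpls",
    "denoise_savgol",
    "normalize_minmax",
    "run_pipeline",
]


@dataclass
class PreprocessConfig:
    """All pipeline knobs.

    Defaults follow common chemometric practice: a modified-z cutoff of 6
    for spike detection, a Whittaker penalty ``iarpls_lambda = 1e5`` suited
    to a ~1 cm^-1 grid, and a 9-point cubic Savitzky-Golay filter.
    """

    despike_z_threshold: float = 6.0
    despike_window: int = 5
    iarpls_lambda: float = 1e5
    iarpls_max_iter: int = 50
    iarpls_tol: float = 1e-3
    savgol_window: int = 9
    savgol_order: int = 3
    crop_lo: float = 400.0
    crop_hi: float = 1700.0
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise ConfigError(
                f"savgol_window must be odd and > savgol_order "
                f"(got window={self.savgol_window}, order={self.savgol_order})"
            )
        if self.iarpls_lambda <= 0:
            raise ConfigError("iarpls_lambda must be > 0")
        if self.iarpls_max_iter < 1:
            raise ConfigError("iarpls_max_iter must be >= 1")
        if self.iarpls_tol <= 0:
            raise ConfigError("iarpls_tol must be > 0")
        if self.despike_z_threshold <= 0:
            raise ConfigError("despike_z_threshold must be > 0")
        if self.despike_window < 1:
            raise ConfigError("despike_window must be >= 1")
        if not self.crop_lo < self.crop_hi:
            raise ConfigError("crop_lo must be < crop_hi")


@dataclass
class BaselineResult:
    """Baseline estimate on the input grid; ``corrected + baseline == input`` exactly."""

    baseline: np.ndarray
    corrected: np.ndarray
    iterations_used: int
    converged: bool


@dataclass
class StageLog:
    source_path: str
    label: str
    spikes_removed: int = 0
    iarpls_iterations: int = 0
    iarpls_converged: bool = True


@dataclass
class PipelineResult:
    """Processed spectra plus per-spectrum stage logs and per-spectrum errors."""

    spectra: SpectrumSet
    logs: list[StageLog] = field(default_factory=list)
    errors: list[tuple[str, str]] = field(default_factory=list)  # (source, message)


# ---------------------------------------------------------------------------
# despiking
# ---------------------------------------------------------------------------

def despike_whitaker_hayes(
    s: RamanSpectrum, z_threshold: float = 6.0, window: int = 5
) -> tuple[RamanSpectrum, np.ndarray]:
    """Remove cosmic-ray spikes via the modified z-score of the differenced signal.

    The first difference ``dy[j] = y[j+1] - y[j]`` is scored with the
    median/MAD modified z-score.  Point ``j+1`` becomes a candidate when
    ``z[j] > z_threshold`` (jump up into a spike) and point ``j`` when
    ``z[j] < -z_threshold`` (jump down out of one).  Because a cosmic
    spike is a narrow artifact entered by an up-jump and left by a
    down-jump, a run of candidates is confirmed only if it is at most
    ``window`` points wide and contains both jump directions (a run at the
    spectrum edge needs only the inward-facing one); this keeps the steep
    flanks of genuine Raman peaks, whose large differences all share one
    sign over a wide run, from being mistaken for spikes.  Each flagged
    intensity is replaced by the mean of the non-flagged neighbours within
    ``window`` points; no other point is modified.

    Returns the despiked spectrum and the boolean flag array.
    """
    if window < 1:
        raise ConfigError("despike window must be >= 1")
    if z_threshold <= 0:
        raise ConfigError("z_threshold must be > 0")
    y = s.intensities
    n = y.size
    dy = np.diff(y)
    med = np.median(dy)
    mad = np.median(np.abs(dy - med))
    flags = np.zeros(n, dtype=bool)
    if mad == 0:  # constant differences: nothing scorable, return unchanged
        return s, flags
    z = 0.6745 * (dy - med) / mad
    up = np.zeros(n, dtype=bool)
    down = np.zeros(n, dtype=bool)
    up[1:] = z > z_threshold
    down[:-1] = z < -z_threshold
    cand = up | down
    # confirm only narrow runs bounded by an up-entry and a down-exit
    i = 0
    while i < n:
        if not cand[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and cand[j + 1]:
            j += 1
        width = j - i + 1
        has_up = bool(up[i:j + 1].any()) or i == 0
        has_down = bool(down[i:j + 1].any()) or j == n - 1
        if width <= window and has_up and has_down:
            flags[i:j + 1] = True
        i = j + 1
    if not np.any(flags):
        return s, flags

    fixed = y.copy()
    idx = np.nonzero(flags)[0]
    for i in idx:
        lo, hi = max(0, i - window), min(n, i + window + 1)
        neigh = np.arange(lo, hi)
        good = neigh[~flags[neigh]]
        if good.size:
            fixed[i] = y[good].mean()
        # else: an implausible all-flagged window; leave the point as-is
    return s.with_intensities(fixed), flags


# ---------------------------------------------------------------------------
# IARPLS baseline
# ---------------------------------------------------------------------------

def _whittaker_banded(lam: float, n: int) -> np.ndarray:
    """Upper+lower banded representation of lam * D2^T D2 (pentadiagonal)."""
    # second-difference penalty stencil with natural (unpadded) boundaries
    d2 = np.zeros((5, n))
    # main diagonal of D2^T D2
    main = np.full(n, 6.0)
    main[0] = main[-1] = 1.0
    main[1] = main[-2] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[0] = off1[-1] = -2.0
    off2 = np.full(n - 2, 1.0)
    d2[0, 2:] = lam * off2
    d2[1, 1:] = lam * off1
    d2[2, :] = lam * main
    d2[3, :-1] = lam * off1
    d2[4, :-2] = lam * off2
    return d2


def baseline_iarpls(
    s: RamanSpectrum,
    lam: float = 1e5,
    max_iter: int = 50,
    tol: float = 1e-3,
) -> BaselineResult:
    """Estimate a fluorescence-like baseline by IARPLS (see module docstring).

    Non-convergence within ``max_iter`` is reported through
    ``BaselineResult.converged``, not raised.
    """
    if lam <= 0:
        raise ConfigError("iarpls lambda must be > 0")
    y = s.intensities.astype(float)
    n = y.size
    penalty = _whittaker_banded(lam, n)
    w = np.ones(n)
    z = y.copy()
    converged = False
    t = 0
    for t in range(1, max_iter + 1):
        ab = penalty.copy()
        ab[2, :] += w
        z = solve_banded((2, 2), ab, w * y)
        d = y - z
        neg = d[d < 0]
        if neg.size < 2:
            converged = True
            break
        sigma = neg.std()
        if sigma == 0 or not np.isfinite(sigma):
            converged = True
            break
        u = np.exp(min(t, 500)) * (d - 2.0 * sigma) / sigma
        w_new = 0.5 * (1.0 - u / np.sqrt(1.0 + u * u))
        denom = np.linalg.norm(w)
        if denom > 0 and np.linalg.norm(w_new - w) / denom < tol:
            w = w_new
            converged = True
            break
        w = w_new
    return BaselineResult(
        baseline=z, corrected=y - z, iterations_used=t, converged=converged
    )


def baseline_iarpls_cfg(s: RamanSpectrum, cfg: PreprocessConfig) -> BaselineResult:
    """:func:`baseline_iarpls` driven by a :class:`PreprocessConfig`."""
    return baseline_iarpls(
        s, lam=cfg.iarpls_lambda, max_iter=cfg.iarpls_max_iter, tol=cfg.iarpls_tol
    )


# ---------------------------------------------------------------------------
# denoise + scale
# ---------------------------------------------------------------------------

def denoise_savgol(s: RamanSpectrum, window: int = 9, order: int = 3) -> RamanSpectrum:
    """Savitzky-Golay local-polynomial smoothing; the grid is unchanged."""
    if window % 2 == 0:
        raise ConfigError(f"savgol window must be odd, got {window}")
    if window <= order:
        raise ConfigError(f"savgol window ({window}) must exceed order ({order})")
    if window > len(s):
        raise ConfigError(f"savgol window ({window}) exceeds spectrum length ({len(s)})")
    return s.with_intensities(savgol_filter(s.intensities, window, order))


def normalize_minmax(s: RamanSpectrum) -> RamanSpectrum:
    """Affine map of intensities onto [0, 1]; constant spectra are rejected."""
    y = s.intensities
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise ValidationError("cannot min-max normalize a constant spectrum")
    return s.with_intensities((y - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# composed pipeline
# ---------------------------------------------------------------------------

def preprocess_spectrum(
    s: RamanSpectrum, cfg: PreprocessConfig | None = None
) -> tuple[RamanSpectrum, StageLog]:
    """Run crop -> despike -> IARPLS -> SavGol -> min-max on one spectrum."""
    cfg = cfg or PreprocessConfig()
    log = StageLog(source_path=s.source_path, label=s.label)
    out = s.crop(cfg.crop_lo, cfg.crop_hi)
    out, flags = despike_whitaker_hayes(out, cfg.despike_z_threshold, cfg.despike_window)
    log.spikes_removed = int(flags.sum())
    bl = baseline_iarpls_cfg(out, cfg)
    log.iarpls_iterations = bl.iterations_used
    log.iarpls_converged = bl.converged
    out = out.with_intensities(bl.corrected)
    out = denoise_savgol(out, cfg.savgol_window, cfg.savgol_order)
    if cfg.normalize:
        out = normalize_minmax(out)
    return out, log


def run_pipeline(sset: SpectrumSet, cfg: PreprocessConfig | None = None) -> PipelineResult:
    """Apply the full pipeline to every spectrum in a set.

    A failure in one spectrum is recorded in ``errors`` (with its source
    path) and does not abort the remaining spectra.
    """
    cfg = cfg or PreprocessConfig()
    result = PipelineResult(spectra=SpectrumSet(class_names=list(sset.class_names)))
    for s in sset:
        try:
            out, log = preprocess_spectrum(s, cfg)
        except Exception as exc:  # per-spectrum isolation is the contract
            result.errors.append((s.source_path or s.label, str(exc)))
            continue
        result.spectra.spectra.append(out)
        result.logs.append(log)
    return result
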