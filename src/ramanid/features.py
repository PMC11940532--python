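"""Peak detection and fixed-length windowed peak features.

The classifier input for each spectrum is the three highest-intensity
peaks (position and intensity) within every 200 cm^-1 window of the
fingerprint range.  For the default 400-1700 cm^-1 range this yields
seven windows — [400,600), [600,800), ..., [1400,1600), [1600,1700] —
and hence a 7 x 3 x 2 = 42-dimensional vector.  Windows holding fewer
than three detected peaks are zero-padded, so the layout is identical
for every spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ConfigError
from .spectrum import RamanSpectrum, SpectrumSet

__all__ = [
    "Peak",
    "FeatureVector",
    "detect_peaks",
    "extract_window_features",
    "top_k_peaks",
    "peak_concordance",
    "feature_matrix",
    "feature_names",
]

DEFAULT_MIN_PROMINENCE = 0.02  # on the 0-1 normalized intensity scale


@dataclass(frozen=True)
class Peak:
    """A detected local maximum: position (cm^-1), intensity, topographic prominence."""

    position: float
    intensity: float
    prominence: float


@dataclass
class FeatureVector:
    """Fixed-length windowed-peak encoding of one spectrum.

    ``values`` holds, per window in ascending order, three
    ``(position, intensity)`` pairs sorted by descending intensity;
    missing peaks are zero-filled.
    """

    values: np.ndarray
    label: str = "unknown"
    names: list[str] = field(default_factory=list)


def detect_peaks(s: RamanSpectrum, min_prominence: float = DEFAULT_MIN_PROMINENCE) -> list[Peak]:
    """All strict local maxima with topographic prominence >= ``min_prominence``.

    Prominence follows the standard lowest-saddle definition
    (scipy.signal.peak_prominences).  Peaks are returned sorted by position.
    """
    idx, props = find_peaks(s.intensities, prominence=min_prominence)
    return [
        Peak(
            position=float(s.wavenumbers[i]),
            intensity=float(s.intensities[i]),
            prominence=float(p),
        )
        for i, p in zip(idx, props["prominences"])
    ]


def _windows(lo: float, hi: float, width: float) -> list[tuple[float, float]]:
    """Half-open windows [a, a+width) from lo; the final window is truncated to hi
    and closed so every datum belongs to exactly one window."""
    edges = []
    a = lo
    while a < hi:
        edges.append((a, min(a + width, hi)))
        a += width
    return edges


def feature_names(lo: float = 400.0, hi: float = 1700.0, window_width: float = 200.0,
                  k: int = 3) -> list[str]:
    """Column names ``w<i>_p<j>_pos / w<i>_p<j>_int`` for the feature layout."""
    names = []
    for w in range(len(_windows(lo, hi, window_width))):
        for j in range(k):
            names.append(f"w{w + 1}_p{j + 1}_pos")
            names.append(f"w{w + 1}_p{j + 1}_int")
    return names


def extract_window_features(
    s: RamanSpectrum,
    window_width: float = 200.0,
    k: int = 3,
    lo: float = 400.0,
    hi: float = 1700.0,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> FeatureVector:
    """Windowed top-k peak features for one (pre-processed) spectrum.

    Within each window the ``k`` detected peaks of highest intensity are
    kept, ordered by descending intensity (ties: lower wavenumber first),
    and emitted as (position, intensity) pairs; empty slots are zeros.
    """
    if window_width <= 0:
        raise ConfigError("window_width must be > 0")
    if k < 1:
        raise ConfigError("k must be >= 1")
    peaks = detect_peaks(s, min_prominence=min_prominence)
    wins = _windows(lo, hi, window_width)
    values = np.zeros(len(wins) * k * 2)
    for w, (a, b) in enumerate(wins):
        last = w == len(wins) - 1
        inside = [
            p for p in peaks
            if (a <= p.position < b) or (last and a <= p.position <= b)
        ]
        inside.sort(key=lambda p: (-p.intensity, p.position))
        for j, p in enumerate(inside[:k]):
            values[(w * k + j) * 2] = p.position
            values[(w * k + j) * 2 + 1] = p.intensity
    return FeatureVector(values=values, label=s.label,
                         names=feature_names(lo, hi, window_width, k))


def top_k_peaks(s: RamanSpectrum, k: int = 5,
                min_prominence: float = DEFAULT_MIN_PROMINENCE) -> list[Peak]:
    """The ``k`` most prominent peaks, by descending prominence (ties: lower
    wavenumber first); fewer are returned if fewer exist."""
    peaks = detect_peaks(s, min_prominence=min_prominence)
    peaks.sort(key=lambda p: (-p.prominence, p.position))
    return peaks[:k]


def peak_concordance(a: Sequence[Peak | float], b: Sequence[Peak | float],
                     tol: float = 5.0) -> float:
    """Fraction of ``a``'s peaks matched one-to-one to a peak of ``b`` within ``tol`` cm^-1.

    Greedy nearest-neighbour matching: each peak of ``a`` (ascending
    position) claims its nearest unmatched peak of ``b`` within tolerance.
    An empty ``a`` scores 0 by definition.
    """
    if tol <= 0:
        raise ConfigError("tol must be > 0")
    pos_a = sorted(p.position if isinstance(p, Peak) else float(p) for p in a)
    pos_b = [p.position if isinstance(p, Peak) else float(p) for p in b]
    if not pos_a:
        return 0.0
    available = list(pos_b)
    matched = 0
    for pa in pos_a:
        if not available:
            break
        j = int(np.argmin([abs(pa - pb) for pb in available]))
        if abs(pa - available[j]) <= tol:
            available.pop(j)
            matched += 1
    return matched / len(pos_a)


def feature_matrix(
    sset: SpectrumSet,
    window_width: float = 200.0,
    k: int = 3,
    lo: float = 400.0,
    hi: float = 1700.0,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> pd.DataFrame:
    """Feature vectors of a whole set as a DataFrame with a trailing ``label`` column."""
    names = feature_names(lo, hi, window_width, k)
    rows = []
    for s in sset:
        fv = extract_window_features(s, window_width, k, lo, hi, min_prominence)
        rows.append(list(fv.values) + [fv.label])
    return pd.DataFrame(rows, columns=names + ["label"])
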