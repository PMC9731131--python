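"""Rotation- and size-invariant fuzzy intensity histograms.

A lesion's texture feature is the distribution of its voxel intensities:
after discarding the dimmest fraction (segmentation false positives cluster
at lesion boundaries), intensities are min-max normalised to [0, 1] and
soft-binned — each value splits its unit mass linearly between the two
nearest bin centres ``(2j + 1) / (2 n_bins)`` — then the histogram is
normalised to unit sum so lesions of different sizes are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lesions import Lesion3D

__all__ = ["FuzzyHistogram", "normalize_intensities", "fuzzy_histogram", "fuzzy_masses"]


class DegenerateIntensityError(ValueError):
    """Raised when a lesion has constant intensity after discarding."""


@dataclass
class FuzzyHistogram:
    n_bins: int
    frequencies: np.ndarray
    lesion_id: str = ""


def normalize_intensities(
    lesion: Lesion3D | np.ndarray, discard_fraction: float = 0.01
) -> np.ndarray:
    """Min-max normalise lesion intensities after dropping the lowest tail.

    Voxels below the ``discard_fraction`` quantile (linear-interpolation
    definition) are removed; the survivors are mapped through
    ``s = (clip(f, gMin, gMax) - gMin) / (gMax - gMin)``.
    """
    f = np.asarray(lesion.intensities if isinstance(lesion, Lesion3D) else lesion, dtype=float)
    if discard_fraction > 0:
        cut = np.quantile(f, discard_fraction)
        f = f[f >= cut]
    g_min, g_max = f.min(), f.max()
    if g_max == g_min:
        raise DegenerateIntensityError("constant intensity after discarding")
    return (np.clip(f, g_min, g_max) - g_min) / (g_max - g_min)


def fuzzy_masses(s_values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Per-value fuzzy bin masses, shape ``(len(s), n_bins)``; rows sum to 1.

    Bin centres sit at ``(2j + 1) / (2n)``.  A value below the first centre
    (or above the last) gives its whole mass to the edge bin; in between the
    mass splits linearly between the bracketing centres, so a value exactly
    at a centre loads that bin fully.
    """
    s = np.asarray(s_values, dtype=float)
    if s.size == 0:
        raise ValueError("empty input")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("normalized intensities must lie in [0, 1]")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    out = np.zeros((s.size, n_bins))
    t = s * n_bins - 0.5  # position in bin-centre units
    low = t <= 0
    high = t >= n_bins - 1
    mid = ~(low | high)
    out[low, 0] = 1.0
    out[high, n_bins - 1] = 1.0
    j = np.floor(t[mid]).astype(int)
    frac = t[mid] - j
    rows = np.nonzero(mid)[0]
    np.add.at(out, (rows, j), 1.0 - frac)
    np.add.at(out, (rows, j + 1), frac)
    return out


def fuzzy_histogram(
    s_values: np.ndarray, n_bins: int = 10, lesion_id: str = ""
) -> FuzzyHistogram:
    """Unit-sum fuzzy histogram of normalised intensities."""
    masses = fuzzy_masses(s_values, n_bins)
    freq = masses.sum(axis=0) / masses.shape[0]
    return FuzzyHistogram(n_bins=n_bins, frequencies=freq, lesion_id=lesion_id)
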