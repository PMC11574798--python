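"""Evaluation metrics: overlap, histogram intersection, repeatability.

- DICE coefficient 2|A∩B|/(|A|+|B|) scores contour propagation.
- Histogram intersection (Minter): for two normalized intensity histograms on
  shared bins, sum of per-bin minima — 1 for identical distributions.
  Computed between every unordered pair of subjects, it measures how well a
  normalization aligns intensity scales across a cohort.
- Histogram equalization is the comparator normalizer: a rank-based monotone
  map to a uniform target on [0, 1500].
- Repeatability of a paired repeat-measurement design: within-subject SD
  sw = sqrt(sum d_i^2 / (2n)), repeatability coefficient RC = 2*1.96*sw,
  Pearson r, and Bland–Altman mean difference with 95% limits of agreement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import Volume

__all__ = [
    "dice",
    "histogram_intersection",
    "minter_from_histograms",
    "pairwise_minter",
    "histogram_equalize",
    "RepeatabilityReport",
    "repeatability",
]


def _as_bool(a) -> np.ndarray:
    data = getattr(a, "data", a)
    return np.asarray(data).astype(bool)


def dice(a, b) -> float:
    """Overlap 2|A∩B|/(|A|+|B|); two empty masks score 1 with a warning."""
    geom_a, geom_b = getattr(a, "geometry", None), getattr(b, "geometry", None)
    if geom_a is not None and geom_b is not None and not geom_a.close_to(geom_b):
        raise ValueError("dice: masks are on different grids")
    a_arr, b_arr = _as_bool(a), _as_bool(b)
    if a_arr.shape != b_arr.shape:
        raise ValueError(f"dice: shape mismatch {a_arr.shape} vs {b_arr.shape}")
    denom = int(a_arr.sum()) + int(b_arr.sum())
    if denom == 0:
        warnings.warn("dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * float(np.logical_and(a_arr, b_arr).sum()) / denom


def minter_from_histograms(h1: np.ndarray, h2: np.ndarray) -> float:
    """Histogram intersection of two already-normalized histograms."""
    h1, h2 = np.asarray(h1, dtype=float), np.asarray(h2, dtype=float)
    if h1.shape != h2.shape:
        raise ValueError("histograms must share bins")
    return float(np.minimum(h1, h2).sum())


def _shared_edges(a: np.ndarray, b: np.ndarray, n_bins: int, range_policy: str) -> np.ndarray:
    pooled = np.concatenate([a, b])
    if range_policy == "pooled_percentile":
        lo, hi = np.percentile(pooled, [1.0, 99.0])
    elif range_policy == "pooled_full":
        lo, hi = pooled.min(), pooled.max()
    else:
        raise ValueError(f"unknown range policy {range_policy!r}")
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_bins + 1)


def histogram_intersection(
    intensities_a: Sequence[float],
    intensities_b: Sequence[float],
    n_bins: int = 64,
    range_policy: str = "pooled_percentile",
) -> float:
    """Minter between two intensity samples on shared bin edges.

    Bins span the pooled 1st–99th percentile range by default
    (``range_policy='pooled_full'`` uses the full pooled range).  Each
    histogram is normalized by its own in-range count.
    """
    a = np.asarray(intensities_a, dtype=float).ravel()
    b = np.asarray(intensities_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("histogram intersection of an empty sample")
    edges = _shared_edges(a, b, n_bins, range_policy)
    h1, _ = np.histogram(a, bins=edges)
    h2, _ = np.histogram(b, bins=edges)
    if h1.sum() == 0 or h2.sum() == 0:
        return 0.0
    return minter_from_histograms(h1 / h1.sum(), h2 / h2.sum())


def pairwise_minter(
    cohort_intensities: Mapping[str, Sequence[float]],
    n_bins: int = 64,
    range_policy: str = "pooled_percentile",
) -> dict:
    """Minter for every unordered subject pair; C(n,2) values plus the median."""
    keys = list(cohort_intensities)
    if len(keys) < 2:
        raise ValueError("pairwise Minter needs at least 2 subjects")
    pairs = {}
    for ka, kb in combinations(keys, 2):
        pairs[(ka, kb)] = histogram_intersection(
            cohort_intensities[ka], cohort_intensities[kb], n_bins, range_policy
        )
    values = np.asarray(list(pairs.values()))
    return {
        "pairs": pairs,
        "values": values,
        "n_pairs": len(pairs),
        "median": float(np.median(values)),
    }


def histogram_equalize(volume: Volume, output_max: float = 1500.0) -> Volume:
    """Rank-based equalization to a uniform target on [0, output_max].

    Comparator normalizer only.  The map v -> output_max * CDF(v) is monotone
    non-decreasing by construction; a constant image maps to itself with a
    warning (equalization undefined).
    """
    flat = volume.data.ravel()
    uniq, counts = np.unique(flat, return_counts=True)
    if uniq.size == 1:
        warnings.warn("constant image: histogram equalization is the identity", stacklevel=2)
        return volume.with_data(volume.data.copy())
    cdf = np.cumsum(counts).astype(float)
    cdf /= cdf[-1]
    out = np.interp(flat, uniq, cdf) * output_max
    return volume.with_data(out.reshape(volume.data.shape))


@dataclass
class RepeatabilityReport:
    """Agreement of paired per-subject means across two repeat timepoints."""

    values_a: np.ndarray
    values_b: np.ndarray
    n: int
    sw: float
    rc: float
    pearson_r: float
    pearson_p: float
    bland_altman_mean_diff: float
    bland_altman_loa: tuple[float, float]
    r_defined: bool

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "sw": self.sw,
            "rc": self.rc,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "ba_mean_diff": self.bland_altman_mean_diff,
            "ba_loa_low": self.bland_altman_loa[0],
            "ba_loa_high": self.bland_altman_loa[1],
            "r_defined": self.r_defined,
        }


def repeatability(values_a: Sequence[float], values_b: Sequence[float]) -> RepeatabilityReport:
    """Within-subject SD, RC = 2*1.96*sw, Pearson r and Bland–Altman stats.

    For the paired duplicate design sw^2 = sum(d_i^2) / (2n) with
    d_i = a_i - b_i.  Zero variance in either arm leaves r undefined
    (flagged, reported as NaN).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1D value arrays")
    n = a.size
    if n < 3:
        raise ValueError(f"repeatability needs >= 3 paired subjects, got {n}")
    d = a - b
    sw = math.sqrt(float(np.sum(d**2)) / (2.0 * n))
    rc = 2.0 * 1.96 * sw
    r_defined = bool(np.std(a) > 0 and np.std(b) > 0)
    if r_defined:
        r, p = stats.pearsonr(a, b)
    else:
        warnings.warn("zero variance in one arm: Pearson r undefined", stacklevel=2)
        r, p = float("nan"), float("nan")
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1)) if n > 1 else 0.0
    loa = (mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff)
    return RepeatabilityReport(
        values_a=a,
        values_b=b,
        n=n,
        sw=sw,
        rc=rc,
        pearson_r=float(r),
        pearson_p=float(p),
        bland_altman_mean_diff=mean_diff,
        bland_altman_loa=loa,
        r_defined=r_defined,
    )
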