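"""Reference-tissue intensity harmonization.

Raw T2-weighted intensities are scanner- and visit-dependent.  Harmonization
maps them onto a fixed standard scale using three reference tissues whose
signal is stable and far from the treated region: gluteus maximus muscle (GM),
femur and bladder, pinned to 330, 660 and 990 a.u. respectively, with boundary
anchors 0 -> 0 and the volume's intensity ceiling -> 1500 a.u.

The map is built in two steps.  The five anchor pairs are piecewise-linearly
interpolated to a dense target over [0, input_max]; that target is then fitted
by a penalized cubic B-spline (P-spline: second-order difference penalty on
the coefficients) under a non-decreasing-coefficient constraint — a sufficient
condition for a monotone, non-negative spline.  The constrained least squares
problem is solved exactly by NNLS after reparameterizing the coefficients as
cumulative sums of non-negative increments.

A fit is refused ("fit impeded") when anchors are inverted relative to the
reference ordering or closer together than a separation threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import nnls

from .core import LabelMask, Volume

__all__ = [
    "OUTPUT_ANCHORS_AU",
    "AnchorSet",
    "IntensityMap",
    "AnchorFitError",
    "extract_anchor_means",
    "fit_intensity_map",
    "apply_intensity_map",
    "harmonize_volume",
]

#: Standard-scale values for (minimum, GM, femur, bladder, maximum).
OUTPUT_ANCHORS_AU = (0.0, 330.0, 660.0, 990.0, 1500.0)
OUTPUT_MAX_AU = 1500.0

REFERENCE_STRUCTURES = ("GM", "femur", "bladder")


class AnchorFitError(ValueError):
    """Fit impeded: anchors inverted or too close to each other."""


@dataclass
class AnchorSet:
    """Input/output anchor pairs with per-structure provenance."""

    input_anchors: tuple[float, float, float, float, float]
    output_anchors: tuple[float, float, float, float, float] = OUTPUT_ANCHORS_AU
    structure_means: dict[str, float] = field(default_factory=dict)
    structure_counts: dict[str, int] = field(default_factory=dict)

    @property
    def input_max(self) -> float:
        return self.input_anchors[-1]

    def validate(self, separation_fraction: float = 0.02) -> None:
        anchors = np.asarray(self.input_anchors, dtype=float)
        diffs = np.diff(anchors)
        if np.any(diffs < 0):
            raise AnchorFitError(
                f"fit impeded: inverted anchors {tuple(np.round(anchors, 2))}"
            )
        threshold = separation_fraction * self.input_max
        if np.any(diffs < threshold):
            raise AnchorFitError(
                f"fit impeded: anchors too close (min gap {diffs.min():.3g} < "
                f"{threshold:.3g} = {separation_fraction:.0%} of input max "
                f"{self.input_max:.3g})"
            )


def extract_anchor_means(
    volume: Volume,
    mask: LabelMask,
    max_percentile: float = 99.9,
    use_literal_max: bool = False,
    separation_fraction: float = 0.02,
) -> AnchorSet:
    """Anchor intensities from reference-tissue means.

    ``input_max`` (the raw value pinned to 1500 a.u.) defaults to the volume's
    99.9th-percentile intensity so a handful of hot pixels cannot stretch the
    scale; ``use_literal_max`` restores the literal maximum.
    """
    mask.check_companion(volume)
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for name in REFERENCE_STRUCTURES:
        sel = mask.binary(name)
        counts[name] = int(sel.sum())
        if counts[name] == 0:
            raise AnchorFitError(f"reference structure {name!r} is empty in the mask")
        means[name] = float(volume.data[sel].mean())
    if use_literal_max:
        input_max = float(volume.data.max())
    else:
        input_max = float(np.percentile(volume.data, max_percentile))
    anchors = AnchorSet(
        input_anchors=(0.0, means["GM"], means["femur"], means["bladder"], input_max),
        structure_means=means,
        structure_counts=counts,
    )
    anchors.validate(separation_fraction)
    return anchors


@dataclass
class IntensityMap:
    """Monotone non-decreasing map from raw intensity to harmonized a.u.

    Evaluation uses a dense lookup table (linear interpolation); inputs above
    the fitted domain clamp to 1500 a.u., below zero to 0.
    """

    grid: np.ndarray
    values: np.ndarray
    coefficients: np.ndarray | None = None
    knots: np.ndarray | None = None
    max_anchor_residual: float = float("nan")
    anchors: AnchorSet | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be equal-length 1D arrays")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(self.values) < -1e-9):
            raise ValueError("intensity map must be non-decreasing")

    @property
    def input_max(self) -> float:
        return float(self.grid[-1])

    def __call__(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        out = np.interp(v, self.grid, self.values)
        out[v >= self.input_max] = OUTPUT_MAX_AU
        return np.clip(out, 0.0, OUTPUT_MAX_AU)

    @classmethod
    def from_lookup(cls, grid: np.ndarray, values: np.ndarray) -> "IntensityMap":
        return cls(grid, np.clip(values, 0.0, OUTPUT_MAX_AU))


def _second_difference_matrix(n: int) -> np.ndarray:
    d = np.zeros((n - 2, n))
    for i in range(n - 2):
        d[i, i : i + 3] = (1.0, -2.0, 1.0)
    return d


def fit_intensity_map(
    anchors: AnchorSet,
    lambda_penalty: float = 0.1,
    n_knots: int = 50,
    grid_points: int = 1024,
) -> IntensityMap:
    """Fit the monotone non-negative P-spline through the anchor points.

    The dense piecewise-linear interpolant of the anchors is the regression
    target; cubic B-spline coefficients are constrained non-decreasing (hence
    the spline is monotone and, with the first coefficient >= 0, non-negative).
    Knots are spread uniformly over [0, input_max] with extra knots at the
    anchor positions, where the piecewise-linear target has slope kinks.
    """
    anchors.validate()
    xa = np.asarray(anchors.input_anchors, dtype=float)
    ya = np.asarray(anchors.output_anchors, dtype=float)
    x = np.linspace(0.0, anchors.input_max, grid_points)
    y = np.interp(x, xa, ya)

    degree = 3
    interior = np.unique(
        np.concatenate([np.linspace(0.0, anchors.input_max, n_knots), xa])
    )
    knots = np.concatenate(
        [np.full(degree, 0.0), interior, np.full(degree, anchors.input_max)]
    )
    n_coef = len(knots) - degree - 1
    design = BSpline.design_matrix(x, knots, degree).toarray()

    # reparameterize: c = L u with u >= 0  =>  coefficients non-decreasing, >= 0
    lower = np.tril(np.ones((n_coef, n_coef)))
    d2 = _second_difference_matrix(n_coef)
    # scale the penalty so lambda is dimensionless w.r.t. grid density
    pen_scale = np.sqrt(lambda_penalty * grid_points / n_coef)
    a_mat = np.vstack([design @ lower, pen_scale * (d2 @ lower)])
    b_vec = np.concatenate([y, np.zeros(d2.shape[0])])
    u, _ = nnls(a_mat, b_vec)
    coef = lower @ u

    spline = BSpline(knots, coef, degree, extrapolate=False)
    dense_grid = np.linspace(0.0, anchors.input_max, 2048)
    dense_vals = np.clip(spline(dense_grid), 0.0, OUTPUT_MAX_AU)
    dense_vals = np.maximum.accumulate(dense_vals)  # guard float round-off

    residual = float(np.max(np.abs(np.interp(xa, dense_grid, dense_vals) - ya)))
    if residual > 0.01 * OUTPUT_MAX_AU:
        warnings.warn(
            f"anchor residual {residual:.1f} a.u. exceeds 1% of the output scale; "
            "consider lowering lambda_penalty or adding knots",
            stacklevel=2,
        )
    return IntensityMap(
        grid=dense_grid,
        values=dense_vals,
        coefficients=coef,
        knots=knots,
        max_anchor_residual=residual,
        anchors=anchors,
    )


def apply_intensity_map(volume: Volume, imap: IntensityMap) -> Volume:
    """Voxelwise evaluation of the map; output lies in [0, 1500] a.u."""
    return volume.with_data(imap(volume.data))


def harmonize_volume(
    volume: Volume,
    reference_mask: LabelMask,
    lambda_penalty: float = 0.1,
    max_percentile: float = 99.9,
    use_literal_max: bool = False,
    separation_fraction: float = 0.02,
) -> tuple[Volume, IntensityMap]:
    """Fit-and-apply convenience wrapper: one map per volume."""
    anchors = extract_anchor_means(
        volume,
        reference_mask,
        max_percentile=max_percentile,
        use_literal_max=use_literal_max,
        separation_fraction=separation_fraction,
    )
    imap = fit_intensity_map(anchors, lambda_penalty=lambda_penalty)
    return apply_intensity_map(volume, imap), imap
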