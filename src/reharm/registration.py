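"""Longitudinal registration: rigid pre-alignment, multi-scale symmetric-forces
demons, mutual-information B-spline refinement near the prostate, and
displacement-field composition.

A follow-up volume is mapped into baseline (reference) space in three stages:

1. a 6-DOF rigid transform absorbing patient repositioning;
2. a coarse-to-fine demons run (symmetric forces, which keeps the update
   consistent between the time-forward and time-backward directions and
   favours invertible fields) over shrink factors [4, 2] with image-pyramid
   smoothing sigmas [8, 4] mm;
3. an optional B-spline free-form refinement driven by mutual information,
   restricted to the prostate neighbourhood where treatment-induced signal
   change defeats the intensity-difference force of demons.  Increased
   smoothness in this stage comes from a coarse control-point grid, and the
   refinement displacement is feathered to exactly zero away from the region.

The deformable stages are concatenated by composition into a single field on
the reference grid; the rigid part is folded in analytically, so one
resampling maps a follow-up (image or contours) into reference space.

Convention: ``warp(image, field)(x) = image(x + field(x))`` at physical point
x, i.e. fields map reference points toward moving-image points, matching what
resampling needs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .core import (
    DisplacementField,
    GeometryError,
    LabelMask,
    Volume,
    require_same_geometry,
)
from .maskproc import BinaryShape

__all__ = [
    "RegistrationParams",
    "RigidResult",
    "RegistrationResult",
    "RegistrationDivergenceError",
    "register_rigid",
    "register_demons",
    "refine_near_prostate",
    "compose",
    "warp",
    "invert_field",
    "register_longitudinal",
    "jacobian_positive_fraction",
    "body_mask",
]


class RegistrationDivergenceError(RuntimeError):
    """Demons mean-squared error increased over a scale; result unusable."""

    def __init__(self, message: str, trace: list):
        super().__init__(message + f" (trace: {trace})")
        self.trace = trace


@dataclass
class RegistrationParams:
    """Tunable registration settings; defaults follow the method's stated scheme."""

    shrink_factors: Sequence[int] = (4, 2)
    smoothing_sigmas: Sequence[float] = (8.0, 4.0)  # image-pyramid sigmas, mm
    demons_iterations: Sequence[int] = (50, 25)
    field_smoothing_voxels: float = 1.0  # demons regularisation, voxels
    histogram_match: bool = True
    rigid_metric: str = "mattes"  # mattes | mean_squares | correlation
    rigid_sampling: float = 0.2
    rigid_iterations: int = 200
    control_point_spacing_mm: float = 16.0
    dilation_radius_mm: float = 10.0
    refine_iterations: int = 50
    mi_bins: int = 32
    divergence_factor: float = 1.5  # MSE increase beyond this flags divergence
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shrink_factors) != len(self.smoothing_sigmas):
            raise ValueError("shrink_factors and smoothing_sigmas must have equal length")


def _as_euler(transform: sitk.Transform) -> sitk.Euler3DTransform:
    tx = transform.Downcast() if hasattr(transform, "Downcast") else transform
    if isinstance(tx, sitk.CompositeTransform):
        tx = tx.GetNthTransform(tx.GetNumberOfTransforms() - 1).Downcast()
    return sitk.Euler3DTransform(tx)


@dataclass
class RigidResult:
    transform: sitk.Transform
    resampled: Volume
    converged: bool
    stop_condition: str
    final_metric: float

    @property
    def matrix_offset(self) -> tuple[np.ndarray, np.ndarray]:
        """Affine form: p_moving = M @ p_ref + offset."""
        tx = _as_euler(self.transform)
        m = np.asarray(tx.GetMatrix()).reshape(3, 3)
        c = np.asarray(tx.GetCenter())
        t = np.asarray(tx.GetTranslation())
        return m, c + t - m @ c

    @property
    def translation_of_center(self) -> np.ndarray:
        """Displacement of the rotation centre — a centre-referenced translation."""
        tx = _as_euler(self.transform)
        c = np.asarray(tx.GetCenter())
        return np.asarray(self.transform.TransformPoint(tuple(c))) - c

    @property
    def rotation_angles_deg(self) -> np.ndarray:
        tx = _as_euler(self.transform)
        return np.rad2deg([tx.GetAngleX(), tx.GetAngleY(), tx.GetAngleZ()])


@dataclass
class RegistrationResult:
    rigid: RigidResult
    demons_field: DisplacementField
    refinement_field: DisplacementField
    composed_field: DisplacementField  # includes the rigid part
    warped: Volume
    trace: list
    qc: dict


# ---------------------------------------------------------------------------
# Rigid


def _reference_image(geometry) -> sitk.Image:
    img = sitk.Image(list(geometry.shape), sitk.sitkFloat64)
    img.SetSpacing(geometry.spacing)
    img.SetOrigin(geometry.origin)
    img.SetDirection(geometry.direction)
    return img


def register_rigid(
    reference: Volume, moving: Volume, params: RegistrationParams | None = None
) -> RigidResult:
    """Estimate a 6-DOF transform mapping reference points to moving points."""
    params = params or RegistrationParams()
    fixed = reference.to_sitk()
    mov = moving.to_sitk()
    initial = sitk.CenteredTransformInitializer(
        fixed, mov, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    if params.rigid_metric == "mattes":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=params.mi_bins)
    elif params.rigid_metric == "mean_squares":
        reg.SetMetricAsMeanSquares()
    elif params.rigid_metric == "correlation":
        reg.SetMetricAsCorrelation()
    else:
        raise ValueError(f"unknown rigid metric {params.rigid_metric!r}")
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(params.rigid_sampling, params.seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0,
        minStep=1e-4,
        numberOfIterations=params.rigid_iterations,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2, 1, 0])
    reg.SetInitialTransform(initial, inPlace=False)
    final = reg.Execute(fixed, mov)
    stop = reg.GetOptimizerStopConditionDescription()
    converged = "maximum number of iterations" not in stop.lower()
    if not converged:
        warnings.warn(f"rigid registration did not converge: {stop}", stacklevel=2)
    resampled = sitk.Resample(mov, fixed, final, sitk.sitkLinear, 0.0)
    return RigidResult(
        transform=final,
        resampled=Volume.from_sitk(resampled),
        converged=converged,
        stop_condition=stop,
        final_metric=float(reg.GetMetricValue()),
    )


# ---------------------------------------------------------------------------
# Demons


def _pyramid_level(img: sitk.Image, shrink: int, sigma_mm: float) -> sitk.Image:
    out = img
    if sigma_mm > 0:
        out = sitk.SmoothingRecursiveGaussian(out, sigma_mm)
    if shrink > 1:
        out = sitk.Shrink(out, [int(shrink)] * 3)
    return out


def _mse(a: sitk.Image, b: sitk.Image) -> float:
    diff = sitk.GetArrayViewFromImage(a) - sitk.GetArrayViewFromImage(b)
    return float(np.mean(diff**2))


def register_demons(
    reference: Volume, moving: Volume, params: RegistrationParams | None = None
) -> tuple[DisplacementField, list]:
    """Multi-scale symmetric-forces demons; returns the field and a trace.

    The moving volume must already be rigidly aligned.  Because demons drives
    on intensity differences, the moving image is histogram-matched to the
    reference first (registration-internal only; harmonization proper is a
    separate stage).
    """
    params = params or RegistrationParams()
    require_same_geometry(reference, moving, "demons registration")
    fixed = sitk.Cast(reference.to_sitk(), sitk.sitkFloat64)
    mov = sitk.Cast(moving.to_sitk(), sitk.sitkFloat64)
    if params.histogram_match:
        matcher = sitk.HistogramMatchingImageFilter()
        matcher.SetNumberOfHistogramLevels(1024)
        matcher.SetNumberOfMatchPoints(7)
        # no mean-intensity threshold: when the image mean falls inside a
        # large tissue plateau, thresholding includes the plateau in one
        # histogram but not the other and the quantile map derails
        matcher.ThresholdAtMeanIntensityOff()
        mov = matcher.Execute(mov, fixed)

    trace: list = []
    field_img: sitk.Image | None = None
    for shrink, sigma, iters in zip(
        params.shrink_factors, params.smoothing_sigmas, params.demons_iterations
    ):
        f_level = _pyramid_level(fixed, shrink, sigma)
        m_level = _pyramid_level(mov, shrink, sigma)
        if field_img is None:
            field_img = sitk.Image(f_level.GetSize(), sitk.sitkVectorFloat64, 3)
            field_img.CopyInformation(f_level)
        else:
            field_img = sitk.Resample(field_img, f_level, sitk.Transform(), sitk.sitkLinear)
        mse_before = _mse(
            f_level,
            sitk.Resample(
                m_level,
                f_level,
                sitk.DisplacementFieldTransform(sitk.Image(field_img)),
                sitk.sitkLinear,
            ),
        )
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(iters))
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(params.field_smoothing_voxels)
        field_img = demons.Execute(f_level, m_level, field_img)
        mse_after = _mse(
            f_level,
            sitk.Resample(
                m_level,
                f_level,
                sitk.DisplacementFieldTransform(sitk.Image(field_img)),
                sitk.sitkLinear,
            ),
        )
        trace.append(
            {
                "shrink": int(shrink),
                "sigma_mm": float(sigma),
                "iterations": int(iters),
                "mse_before": mse_before,
                "mse_after": mse_after,
                "rms_change": float(demons.GetRMSChange()),
            }
        )
        # near the noise floor the MSE fluctuates; only a substantial rise to a
        # non-trivial level (RMS > 0.5% of the intensity range) marks divergence
        f_arr = sitk.GetArrayViewFromImage(f_level)
        floor = (0.005 * (float(f_arr.max()) - float(f_arr.min()))) ** 2
        if mse_after > mse_before * params.divergence_factor and mse_after > floor:
            raise RegistrationDivergenceError(
                f"demons diverged at shrink factor {shrink}: "
                f"MSE {mse_before:.4g} -> {mse_after:.4g}",
                trace,
            )
    field_img = sitk.Resample(field_img, fixed, sitk.Transform(), sitk.sitkLinear)
    return DisplacementField.from_sitk(field_img), trace


# ---------------------------------------------------------------------------
# Refinement near the prostate


def _as_bool_array(mask, geometry) -> np.ndarray:
    if isinstance(mask, BinaryShape):
        if not mask.geometry.close_to(geometry):
            raise GeometryError("prostate mask geometry differs from reference")
        return mask.data
    if isinstance(mask, LabelMask):
        if not mask.geometry.close_to(geometry):
            raise GeometryError("prostate mask geometry differs from reference")
        return mask.data > 0
    arr = np.asarray(mask).astype(bool)
    if arr.shape != geometry.shape:
        raise GeometryError("prostate mask shape differs from reference grid")
    return arr


def refine_near_prostate(
    reference: Volume,
    moving_warped: Volume,
    prostate_mask,
    params: RegistrationParams | None = None,
) -> DisplacementField:
    """Mutual-information B-spline refinement restricted to the prostate region.

    The metric only sees voxels inside the prostate mask dilated by
    ``dilation_radius_mm``; the resulting displacement is feathered linearly to
    exactly zero over one control-point spacing outside that region.
    """
    params = params or RegistrationParams()
    require_same_geometry(reference, moving_warped, "refinement")
    geom = reference.geometry
    mask_arr = _as_bool_array(prostate_mask, geom)
    if not mask_arr.any():
        raise ValueError("prostate mask is empty")
    radius_vox = [
        max(1, int(math.ceil(params.dilation_radius_mm / s))) for s in geom.spacing
    ]
    dilated = ndimage.binary_dilation(
        mask_arr, iterations=1, structure=_ellipsoid_structuring(radius_vox)
    )
    extent_mm = [
        (np.ptp(np.nonzero(dilated)[ax]) + 1) * geom.spacing[ax] for ax in range(3)
    ]
    if min(extent_mm) < params.control_point_spacing_mm:
        raise ValueError(
            f"refinement region extent {extent_mm} mm is smaller than one "
            f"control-point cell ({params.control_point_spacing_mm} mm)"
        )

    fixed = reference.to_sitk()
    mov = moving_warped.to_sitk()
    mask_img = sitk.GetImageFromArray(dilated.transpose(2, 1, 0).astype(np.uint8))
    mask_img.CopyInformation(fixed)

    physical_extent = [sz * sp for sz, sp in zip(geom.shape, geom.spacing)]
    mesh = [max(1, int(round(e / params.control_point_spacing_mm))) for e in physical_extent]
    bspline = sitk.BSplineTransformInitializer(fixed, mesh)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=params.mi_bins)
    # dense sampling: the metric region is already restricted to the mask, and
    # dense evaluation makes the refinement deterministic
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetMetricFixedMask(mask_img)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7, numberOfIterations=params.refine_iterations
    )
    reg.SetInitialTransform(bspline, inPlace=True)
    reg.Execute(fixed, mov)

    field_img = sitk.TransformToDisplacementField(
        bspline,
        sitk.sitkVectorFloat64,
        list(geom.shape),
        geom.origin,
        geom.spacing,
        geom.direction,
    )
    fld = DisplacementField.from_sitk(field_img)

    # feather the displacement to zero over one control-point spacing
    dist_out = ndimage.distance_transform_edt(~dilated, sampling=geom.spacing)
    weight = np.clip(1.0 - dist_out / params.control_point_spacing_mm, 0.0, 1.0)
    return fld.with_data(fld.data * weight[..., None])


def _ellipsoid_structuring(radius_vox: Sequence[int]) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(-r, r + 1) / max(r, 1) for r in radius_vox], indexing="ij"
    )
    return sum(g**2 for g in grids) <= 1.0


# ---------------------------------------------------------------------------
# Composition and warping


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Concatenate two fields: ``result(x) = inner(x) + outer(x + inner(x))``.

    Warping with the result equals warping by ``outer`` first, then ``inner``:
    ``warp(img, compose(outer, inner)) == warp(warp(img, outer), inner)``
    within interpolation tolerance.
    """
    require_same_geometry(outer, inner, "field composition")
    geom = inner.geometry
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in geom.shape], indexing="ij"), axis=-1
    )
    pts = geom.index_to_physical(idx.reshape(-1, 3))
    target = pts + inner.data.reshape(-1, 3)
    target_idx = geom.physical_to_index(target).T  # (3, N)
    sampled = np.stack(
        [
            ndimage.map_coordinates(
                outer.data[..., c], target_idx, order=1, mode="nearest"
            )
            for c in range(3)
        ],
        axis=-1,
    )
    return inner.with_data(inner.data + sampled.reshape(geom.shape + (3,)))


def warp(obj, fld: DisplacementField, interpolation: str | None = None):
    """Resample a volume or mask through a displacement field.

    Images use linear interpolation, masks nearest-neighbour (labels are never
    blended); out-of-field voxels become 0 / background.
    """
    is_mask = isinstance(obj, LabelMask)
    if interpolation is None:
        interpolation = "nearest" if is_mask else "linear"
    interps = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}
    if interpolation not in interps:
        raise ValueError(f"unknown interpolation mode {interpolation!r}")
    ref = _reference_image(fld.geometry)
    out = sitk.Resample(
        obj.to_sitk(), ref, fld.to_sitk_transform(), interps[interpolation], 0.0
    )
    if is_mask:
        return LabelMask.from_sitk(sitk.Cast(out, sitk.sitkUInt16), obj.label_table)
    return Volume.from_sitk(out)


def invert_field(fld: DisplacementField, n_iter: int = 30) -> DisplacementField:
    """Fixed-point displacement inversion: ``v(x) = -u(x + v(x))``."""
    geom = fld.geometry
    inv = DisplacementField.zeros(geom)
    for _ in range(n_iter):
        sampled = compose(fld, inv).data - inv.data  # u evaluated at x + v(x)
        inv = inv.with_data(-sampled)
    return inv


def jacobian_positive_fraction(fld: DisplacementField, mask: np.ndarray | None = None) -> float:
    """Fraction of voxels (optionally within a mask) with positive Jacobian."""
    det = fld.jacobian_determinant()
    if mask is not None:
        det = det[np.asarray(mask, dtype=bool)]
    if det.size == 0:
        return float("nan")
    return float(np.mean(det > 0))


def body_mask(volume: Volume) -> np.ndarray:
    """Foreground (patient body) mask by Otsu thresholding + hole filling."""
    img = volume.to_sitk()
    otsu = sitk.OtsuThreshold(img, 0, 1)
    arr = sitk.GetArrayFromImage(otsu).transpose(2, 1, 0).astype(bool)
    arr = ndimage.binary_fill_holes(arr)
    labeled, n = ndimage.label(arr)
    if n > 1:
        counts = np.bincount(labeled.ravel())[1:]
        arr = labeled == (int(np.argmax(counts)) + 1)
    return arr


# ---------------------------------------------------------------------------
# Full longitudinal pipeline


def _rigid_into_field(rigid: RigidResult, deformable: DisplacementField) -> DisplacementField:
    """Fold the rigid transform into a deformable field: total(x) = R(x+d(x)) - x."""
    m, off = rigid.matrix_offset
    geom = deformable.geometry
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in geom.shape], indexing="ij"), axis=-1
    )
    pts = geom.index_to_physical(idx.reshape(-1, 3))
    target = pts + deformable.data.reshape(-1, 3)
    total = target @ m.T + off - pts
    return deformable.with_data(total.reshape(geom.shape + (3,)))


def register_longitudinal(
    reference: Volume,
    moving: Volume,
    prostate_mask=None,
    params: RegistrationParams | None = None,
) -> RegistrationResult:
    """Rigid -> demons -> optional prostate refinement -> composed field.

    The composed field (rigid folded in) lives on the reference grid; a single
    ``warp`` with it maps the original follow-up image or its contours into
    reference space.
    """
    params = params or RegistrationParams()
    rigid = register_rigid(reference, moving, params)
    demons_field, trace = register_demons(reference, rigid.resampled, params)
    if prostate_mask is not None:
        warped_after_demons = warp(rigid.resampled, demons_field)
        refinement = refine_near_prostate(reference, warped_after_demons, prostate_mask, params)
    else:
        refinement = DisplacementField.zeros(reference.geometry)
    deformable = compose(outer=demons_field, inner=refinement)
    composed = _rigid_into_field(rigid, deformable)
    warped = warp(moving, composed)
    body = body_mask(reference)
    qc = {
        "jacobian_positive_fraction": jacobian_positive_fraction(composed, body),
        "rigid_converged": rigid.converged,
        "final_mse": float(np.mean((warped.data - reference.data) ** 2)),
    }
    return RegistrationResult(
        rigid=rigid,
        demons_field=demons_field,
        refinement_field=refinement,
        composed_field=composed,
        warped=warped,
        trace=trace,
        qc=qc,
    )
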