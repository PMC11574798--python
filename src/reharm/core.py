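"""Core image containers: scalar volumes, label masks and displacement fields.

All containers carry physical geometry (spacing, origin, direction) so every
spatial statement downstream is in millimetres.  Array axes are ordered
``(x, y, z)`` — i.e. the same index order SimpleITK uses for ``GetPixel`` —
and the axial (slice) axis is axis 2.  Conversion to/from SimpleITK images is
lossless; SimpleITK's numpy bridge uses ``(z, y, x)`` order, so the adapters
transpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Geometry",
    "Volume",
    "LabelMask",
    "DisplacementField",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised when two objects that must share a grid do not."""


@dataclass(frozen=True)
class Geometry:
    """Physical layout of a 3D voxel grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError(f"expected 3D geometry, got shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix is not orthonormal")

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def index_to_physical_matrix(self) -> np.ndarray:
        """3x3 matrix A with physical = A @ index + origin."""
        return self.direction_matrix @ np.diag(self.spacing)

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        idx = np.asarray(index, dtype=float)
        return idx @ self.index_to_physical_matrix.T + np.asarray(self.origin)

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        p = np.asarray(point, dtype=float) - np.asarray(self.origin)
        return p @ np.linalg.inv(self.index_to_physical_matrix).T

    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def close_to(self, other: "Geometry", tol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


def _require_same_geometry(a: "Geometry", b: "Geometry", what: str) -> None:
    if not a.close_to(b):
        raise GeometryError(f"{what}: geometries differ ({a} vs {b})")


@dataclass
class Volume:
    """A 3D scalar image with physical geometry.

    ``data`` is indexed ``[x, y, z]`` with z the axial slice axis.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D data")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = tuple(float(d) for d in np.ravel(self.direction))
        self.geometry  # validate

    @property
    def geometry(self) -> Geometry:
        return Geometry(tuple(self.data.shape), self.spacing, self.origin, self.direction)

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.spacing, self.origin, self.direction)

    # -- SimpleITK bridge ---------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(self.data.transpose(2, 1, 0).astype(np.float64))
        )
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(self.direction)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        arr = sitk.GetArrayFromImage(img)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D volume, got {arr.ndim}D image")
        return cls(
            arr.transpose(2, 1, 0),
            tuple(img.GetSpacing()),
            tuple(img.GetOrigin()),
            tuple(img.GetDirection()),
        )


@dataclass
class LabelMask:
    """Integer-labeled volume sharing a companion :class:`Volume`'s grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)
    label_table: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {data.ndim}D data")
        if not np.issubdtype(data.dtype, np.integer):
            if not np.all(data == np.round(data)):
                raise ValueError("mask contains non-integral voxel values")
            data = data.astype(np.int64)
        if data.min() < 0:
            raise ValueError("mask labels must be nonnegative")
        self.data = data.astype(np.uint16)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = tuple(float(d) for d in np.ravel(self.direction))
        self.label_table = dict(self.label_table)
        self.geometry  # validate

    @property
    def geometry(self) -> Geometry:
        return Geometry(tuple(self.data.shape), self.spacing, self.origin, self.direction)

    @property
    def name_to_label(self) -> dict[str, int]:
        return {v: k for k, v in self.label_table.items()}

    def labels_present(self) -> list[int]:
        out = np.unique(self.data)
        return [int(v) for v in out if v != 0]

    def binary(self, which: int | str | list) -> np.ndarray:
        """Boolean array of the voxels carrying the given label(s) or name(s)."""
        if isinstance(which, (int, np.integer, str)):
            which = [which]
        ids = []
        for w in which:
            if isinstance(w, str):
                try:
                    ids.append(self.name_to_label[w])
                except KeyError:
                    raise KeyError(
                        f"label name {w!r} not in table {sorted(self.name_to_label)}"
                    ) from None
            else:
                ids.append(int(w))
        return np.isin(self.data, ids)

    def voxel_count(self, which: int | str | list) -> int:
        return int(self.binary(which).sum())

    def with_data(self, data: np.ndarray) -> "LabelMask":
        return LabelMask(data, self.spacing, self.origin, self.direction, self.label_table)

    def check_companion(self, volume: Volume) -> None:
        _require_same_geometry(self.geometry, volume.geometry, "mask/volume pairing")

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(self.data.transpose(2, 1, 0).astype(np.uint16))
        )
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(self.direction)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, label_table: Mapping[int, str] | None = None) -> "LabelMask":
        arr = sitk.GetArrayFromImage(img)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got {arr.ndim}D image")
        return cls(
            arr.transpose(2, 1, 0),
            tuple(img.GetSpacing()),
            tuple(img.GetOrigin()),
            tuple(img.GetDirection()),
            label_table or {},
        )


@dataclass
class DisplacementField:
    """Per-voxel 3D displacement (mm, physical x/y/z components) on a reference grid.

    Warping convention: ``warp(image, field)(x) = image(x + field(x))`` with x a
    physical point on the reference grid.
    """

    data: np.ndarray  # (nx, ny, nz, 3)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(
                f"expected (nx, ny, nz, 3) displacement data, got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = tuple(float(d) for d in np.ravel(self.direction))
        self.geometry  # validate

    @property
    def geometry(self) -> Geometry:
        return Geometry(tuple(self.data.shape[:3]), self.spacing, self.origin, self.direction)

    @classmethod
    def zeros(cls, geometry: Geometry) -> "DisplacementField":
        return cls(
            np.zeros(geometry.shape + (3,)),
            geometry.spacing,
            geometry.origin,
            geometry.direction,
        )

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=-1)

    def with_data(self, data: np.ndarray) -> "DisplacementField":
        return DisplacementField(data, self.spacing, self.origin, self.direction)

    # -- SimpleITK bridge ---------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(self.data.transpose(2, 1, 0, 3)), isVector=True
        )
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(self.direction)
        return img

    def to_sitk_transform(self) -> sitk.DisplacementFieldTransform:
        # DisplacementFieldTransform takes ownership of the image, so pass a copy.
        return sitk.DisplacementFieldTransform(sitk.Image(self.to_sitk()))

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "DisplacementField":
        arr = sitk.GetArrayFromImage(img)
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError(f"expected 3-component vector image, got shape {arr.shape}")
        return cls(
            arr.transpose(2, 1, 0, 3),
            tuple(img.GetSpacing()),
            tuple(img.GetOrigin()),
            tuple(img.GetDirection()),
        )

    def jacobian_determinant(self) -> np.ndarray:
        """Jacobian determinant of (identity + field) per voxel."""
        jac = sitk.DisplacementFieldJacobianDeterminant(self.to_sitk())
        return sitk.GetArrayFromImage(jac).transpose(2, 1, 0)


def require_same_geometry(a, b, what: str = "operation") -> None:
    """Raise :class:`GeometryError` unless the two carriers share a grid."""
    _require_same_geometry(a.geometry, b.geometry, what)
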