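"""NIfTI and manifest I/O.

Volumes, masks and displacement fields are stored as NIfTI-1 (``.nii`` /
``.nii.gz``); displacement fields as 3-component vector images with values in
millimetres on the reference grid.  Intensity maps are stored as two-column
TSV lookup tables.  A cohort is described by a YAML manifest::

    subjects:
      - id: subj01
        timepoints:
          - {tag: baseline, volume: t1.nii.gz, mask: t1_mask.nii.gz}
          - {tag: planning, volume: t2.nii.gz, mask: t2_mask.nii.gz}

The first timepoint of every subject is the registration reference.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import SimpleITK as sitk
import yaml

from .core import DisplacementField, LabelMask, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_field",
    "write_field",
    "read_intensity_map",
    "write_intensity_map",
    "TimepointEntry",
    "SubjectEntry",
    "CohortManifest",
    "load_manifest",
    "save_manifest",
    "ManifestError",
]

TIMEPOINT_TAGS = ("baseline", "planning", "3mo", "9mo", "24mo")


def _read_image(path: str | os.PathLike) -> sitk.Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    return sitk.ReadImage(str(path))


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a 3D scalar NIfTI volume, preserving geometry losslessly."""
    img = _read_image(path)
    if img.GetDimension() != 3:
        raise ValueError(f"expected 3D volume, got {img.GetDimension()}D: {path}")
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError(f"expected scalar volume, got vector image: {path}")
    arr = sitk.GetArrayFromImage(img)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"volume contains non-finite voxels: {path}")
    return Volume.from_sitk(img)


def write_volume(volume: Volume, path: str | os.PathLike, dtype=np.float32) -> None:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(volume.data.transpose(2, 1, 0).astype(dtype))
    )
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    img.SetDirection(volume.direction)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


def read_mask(path: str | os.PathLike, label_table: Mapping[int, str] | None = None) -> LabelMask:
    """Read an integer label mask; labels must appear in ``label_table`` if given."""
    img = _read_image(path)
    if img.GetDimension() != 3:
        raise ValueError(f"expected 3D mask, got {img.GetDimension()}D: {path}")
    arr = sitk.GetArrayFromImage(img)
    if not np.all(arr == np.round(arr)):
        raise ValueError(f"mask contains non-integral voxel values: {path}")
    mask = LabelMask.from_sitk(sitk.Cast(img, sitk.sitkUInt16), label_table)
    if label_table is not None:
        unknown = sorted(set(mask.labels_present()) - set(label_table))
        if unknown:
            raise ValueError(f"mask {path} contains labels absent from table: {unknown}")
    return mask


def write_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(mask.to_sitk(), str(path))


def read_field(path: str | os.PathLike) -> DisplacementField:
    img = _read_image(path)
    if img.GetNumberOfComponentsPerPixel() != 3:
        raise ValueError(
            f"expected 3-component displacement field, got "
            f"{img.GetNumberOfComponentsPerPixel()} components: {path}"
        )
    return DisplacementField.from_sitk(img)


def write_field(fld: DisplacementField, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(fld.to_sitk(), str(path))


def write_intensity_map(imap, path: str | os.PathLike) -> None:
    """Persist an intensity map as a dense two-column lookup (raw, harmonized)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table = np.column_stack([imap.grid, imap.values])
    np.savetxt(
        path,
        table,
        fmt="%.6f",
        delimiter="\t",
        header="input_intensity\tharmonized_au",
        comments="",
    )


def read_intensity_map(path: str | os.PathLike):
    from .harmonization import IntensityMap  # noqa: PLC0415 — avoid import cycle

    table = np.loadtxt(path, delimiter="\t", skiprows=1)
    return IntensityMap.from_lookup(table[:, 0], table[:, 1])


# ---------------------------------------------------------------------------
# Cohort manifest


class ManifestError(ValueError):
    """Aggregated manifest validation failure."""


@dataclass
class TimepointEntry:
    tag: str
    volume: Path
    mask: Path | None = None


@dataclass
class SubjectEntry:
    subject_id: str
    timepoints: list[TimepointEntry]

    @property
    def baseline(self) -> TimepointEntry:
        return self.timepoints[0]

    @property
    def followups(self) -> list[TimepointEntry]:
        return self.timepoints[1:]


@dataclass
class CohortManifest:
    subjects: list[SubjectEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.subjects)

    def subject(self, subject_id: str) -> SubjectEntry:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def load_manifest(path: str | os.PathLike, check_files: bool = True) -> CohortManifest:
    """Parse and validate a cohort manifest; all problems reported together."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "subjects" not in raw:
        raise ManifestError(f"{path}: manifest must have a top-level 'subjects' list")
    root = path.parent
    errors: list[str] = []
    subjects: list[SubjectEntry] = []
    for sub in raw["subjects"]:
        sid = str(sub.get("id", "<missing id>"))
        tps_raw = sub.get("timepoints", [])
        if len(tps_raw) < 2:
            errors.append(f"subject {sid}: has {len(tps_raw)} timepoints, need >= 2")
        tps: list[TimepointEntry] = []
        for i, tp in enumerate(tps_raw):
            tag = str(tp.get("tag", i))
            vol = tp.get("volume")
            if vol is None:
                errors.append(f"subject {sid}, timepoint {tag}: missing volume path")
                continue
            vol = root / vol
            mask = tp.get("mask")
            mask = root / mask if mask is not None else None
            if check_files and not vol.exists():
                errors.append(f"subject {sid}, timepoint {tag}: volume not found: {vol}")
            if check_files and mask is not None and not mask.exists():
                errors.append(f"subject {sid}, timepoint {tag}: mask not found: {mask}")
            tps.append(TimepointEntry(tag, vol, mask))
        subjects.append(SubjectEntry(sid, tps))
    if errors:
        raise ManifestError(f"{path}: invalid manifest:\n  " + "\n  ".join(errors))
    return CohortManifest(subjects)


def save_manifest(manifest: CohortManifest, path: str | os.PathLike) -> None:
    path = Path(path)
    root = path.parent

    def rel(p: Path | None):
        if p is None:
            return None
        try:
            return os.path.relpath(p, root)
        except ValueError:
            return str(p)

    doc = {
        "subjects": [
            {
                "id": s.subject_id,
                "timepoints": [
                    {
                        "tag": tp.tag,
                        "volume": rel(tp.volume),
                        **({"mask": rel(tp.mask)} if tp.mask is not None else {}),
                    }
                    for tp in s.timepoints
                ],
            }
            for s in manifest.subjects
        ]
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
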