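"""Synthetic multi-timepoint pelvis phantoms with known ground truth.

The phantom emulates the variability a longitudinal T2-weighted prostate MRI
pipeline must undo: per-visit patient repositioning (rigid motion), soft-tissue
deformation (smooth Gaussian-bump displacement fields), scanner/sequence signal
scaling (monotone gain/offset/gamma transforms), and acquisition noise — all
with analytic ground truth, so registration and harmonization can be scored
exactly.

Anatomy is a set of ellipsoids on a body cross-section: bilateral gluteus
maximus (GM) and femur, bladder, prostate with a posterior peripheral zone (PZ)
sub-region and a small tumor (GTV) inside the PZ, plus a subcutaneous fat rim
that carries the brightest signal.  Default tissue means sit on the
standardized harmonization scale (GM 330, femur 660, bladder 990, fat 1500
a.u.), so with no scanner distortion the correct harmonization map is the
identity; a gain g makes it v -> v / g.

Generation convention: a follow-up samples the reference anatomy through an
analytic pull-back map ``psi`` — ``F(x) = A(psi(x))`` — where ``psi`` first
undoes the rigid content motion (rotation ``theta`` about the volume centre,
then translation ``t``) and then adds the deformation ``w`` (sum of Gaussian
bumps).  Masks are rendered through the same map, so follow-up contours are
exact warped copies of the baseline contours.  Noise is Gaussian; at the
signal-to-noise ratios exercised here the Rician magnitude-MRI correction is
negligible and deliberately omitted.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DisplacementField, Geometry, LabelMask, Volume
from .io import (
    TIMEPOINT_TAGS,
    CohortManifest,
    SubjectEntry,
    TimepointEntry,
    save_manifest,
    write_mask,
    write_volume,
)

__all__ = [
    "PHANTOM_LABELS",
    "STRUCTURE_CHILDREN",
    "Ellipsoid",
    "GaussianBump",
    "TimepointDistortion",
    "PhantomSpec",
    "CohortVariability",
    "TimepointTruth",
    "SubjectTimepoint",
    "generate_subject",
    "generate_cohort",
    "PhantomSpecError",
]

PHANTOM_LABELS = {
    1: "body",
    2: "prostate",
    3: "PZ",
    4: "GTV",
    5: "GM",
    6: "femur",
    7: "bladder",
    8: "fat",
}

# ROI containment: the stored label is the most specific one; a structure's
# full mask is the union of its own label and its children's.
STRUCTURE_CHILDREN = {
    "prostate": ["PZ", "GTV"],
    "PZ": ["GTV"],
}


def structure_mask(mask: LabelMask, name: str) -> np.ndarray:
    """Boolean mask of a structure including contained sub-structures."""
    return mask.binary([name] + STRUCTURE_CHILDREN.get(name, []))


class PhantomSpecError(ValueError):
    """Raised when a phantom specification violates its invariants."""


@dataclass
class Ellipsoid:
    center: tuple[float, float, float]  # mm
    semi_axes: tuple[float, float, float]  # mm

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = (np.asarray(points) - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (p**2).sum(axis=-1) <= 1.0

    def boundary_points(self, n: int = 200, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return v * np.asarray(self.semi_axes) + np.asarray(self.center)

    def jitter(self, rng: np.random.Generator, center_mm: float, scale_frac: float) -> "Ellipsoid":
        c = np.asarray(self.center) + rng.uniform(-center_mm, center_mm, 3)
        s = np.asarray(self.semi_axes) * rng.uniform(1 - scale_frac, 1 + scale_frac, 3)
        return Ellipsoid(tuple(c), tuple(s))


@dataclass
class GaussianBump:
    """One compact displacement bump: ``amp * exp(-|x-c|^2 / (2 sigma^2))``."""

    center: tuple[float, float, float]  # mm
    sigma: float  # mm
    amplitude: tuple[float, float, float]  # mm, physical components

    def displacement(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points) - np.asarray(self.center)
        r2 = (d**2).sum(axis=-1, keepdims=True)
        return np.exp(-r2 / (2.0 * self.sigma**2)) * np.asarray(self.amplitude)

    @property
    def max_gradient(self) -> float:
        # peak |d(amp * gauss)/dx| for a 1D Gaussian: |amp| * exp(-1/2) / sigma
        return float(np.linalg.norm(self.amplitude)) * np.exp(-0.5) / self.sigma


@dataclass
class TimepointDistortion:
    """Everything that separates a follow-up acquisition from the reference."""

    gain: float = 1.0
    offset: float = 0.0
    gamma: float = 1.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # content shift, mm
    rotation_deg: float = 0.0  # content rotation about z through volume centre
    bumps: list[GaussianBump] = field(default_factory=list)
    tissue_scale: dict[str, float] = field(default_factory=dict)
    noise_sd: float | None = None  # overrides the spec default when set

    @classmethod
    def identity(cls) -> "TimepointDistortion":
        return cls()


def _default_structures() -> dict[str, list[Ellipsoid]]:
    return {
        "body": [Ellipsoid((48, 48, 48), (44, 38, 60))],
        "prostate": [Ellipsoid((48, 56, 48), (13, 10, 12))],
        "PZ": [Ellipsoid((48, 60, 48), (10, 5, 9))],
        "GTV": [Ellipsoid((51, 60, 46), (4, 3.5, 4))],
        "GM": [
            Ellipsoid((18, 66, 48), (8, 9, 26)),
            Ellipsoid((78, 66, 48), (8, 9, 26)),
        ],
        "femur": [
            Ellipsoid((16, 36, 48), (7, 7, 30)),
            Ellipsoid((80, 36, 48), (7, 7, 30)),
        ],
        "bladder": [Ellipsoid((48, 30, 56), (12, 9, 13))],
    }


def _default_tissue_means() -> dict[str, float]:
    return {
        "background": 0.0,
        "body": 250.0,
        "prostate": 480.0,
        "PZ": 590.0,
        "GTV": 380.0,
        "GM": 330.0,
        "femur": 660.0,
        "bladder": 990.0,
        "fat": 1500.0,
    }


@dataclass
class PhantomSpec:
    """Geometry, tissue intensities and per-timepoint distortions of one subject."""

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    structures: dict[str, list[Ellipsoid]] = field(default_factory=_default_structures)
    fat_rim_mm: float = 3.5  # fat shell thickness inside the body surface
    tissue_means: dict[str, float] = field(default_factory=_default_tissue_means)
    noise_sd: float = 15.0
    distortions: list[TimepointDistortion] = field(default_factory=list)
    # intensity-only scanner state at baseline (no spatial part): emulates
    # inter-subject scanner/sequence differences present from the first visit
    baseline_distortion: TimepointDistortion | None = None
    seed: int = 0

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.shape, self.spacing)

    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    def scaled(self, shape: tuple[int, int, int]) -> "PhantomSpec":
        """Same anatomy on a different grid covering the same ~96 mm FOV."""
        spec = copy.deepcopy(self)
        old_fov = np.asarray(self.shape) * np.asarray(self.spacing)
        new_spacing = old_fov / np.asarray(shape)
        spec.shape = tuple(int(s) for s in shape)
        spec.spacing = tuple(float(s) for s in new_spacing)
        return spec

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        errors: list[str] = []
        means = self.tissue_means
        if not means["GM"] < means["femur"] < means["bladder"]:
            errors.append(
                "tissue means must satisfy GM < femur < bladder, got "
                f"{means['GM']}/{means['femur']}/{means['bladder']}"
            )
        # containment chain GTV ⊂ PZ ⊂ prostate (boundary sampling)
        chain = [("GTV", "PZ"), ("PZ", "prostate")]
        for inner_name, outer_name in chain:
            for inner in self.structures[inner_name]:
                pts = inner.boundary_points()
                outer_hits = np.zeros(len(pts), dtype=bool)
                for outer in self.structures[outer_name]:
                    outer_hits |= outer.contains(pts)
                if not outer_hits.all():
                    errors.append(f"{inner_name} not contained in {outer_name}")
        # pairwise disjointness of top-level organs
        top = ["prostate", "GM", "femur", "bladder"]
        for i, a in enumerate(top):
            for b in top[i + 1 :]:
                for ea in self.structures[a]:
                    pts = np.concatenate(
                        [ea.boundary_points(), [np.asarray(ea.center)]]
                    )
                    for eb in self.structures[b]:
                        if eb.contains(pts).any():
                            errors.append(f"structures {a} and {b} overlap")
        if self.baseline_distortion is not None:
            bd = self.baseline_distortion
            if bd.bumps or bd.rotation_deg != 0 or any(t != 0 for t in bd.translation):
                errors.append("baseline distortion must be intensity-only")
        for dist in self.distortions:
            grad = sum(b.max_gradient for b in dist.bumps)
            if grad >= 0.9:
                errors.append(
                    f"deformation too strong to stay invertible (sum of bump "
                    f"gradients {grad:.2f} >= 0.9)"
                )
            if dist.gain <= 0 or dist.gamma <= 0:
                errors.append("gain and gamma must be positive")
        if errors:
            raise PhantomSpecError("invalid phantom spec:\n  " + "\n  ".join(errors))


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class TimepointTruth:
    """Analytic provenance of one generated timepoint."""

    distortion: TimepointDistortion
    center_mm: tuple[float, float, float]
    intensity_max: float  # reference anatomy maximum (gamma normalisation)

    # -- spatial ------------------------------------------------------------
    def rigid_pullback(self, points: np.ndarray) -> np.ndarray:
        """psi_rigid: scanner point -> content point before deformation."""
        t = np.asarray(self.distortion.translation)
        c = np.asarray(self.center_mm)
        theta = np.deg2rad(self.distortion.rotation_deg)
        rot = np.array(
            [
                [np.cos(-theta), -np.sin(-theta), 0.0],
                [np.sin(-theta), np.cos(-theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        return (np.asarray(points) - t - c) @ rot.T + c

    def deformation(self, points: np.ndarray) -> np.ndarray:
        w = np.zeros_like(np.asarray(points, dtype=float))
        for b in self.distortion.bumps:
            w += b.displacement(points)
        return w

    def pullback(self, points: np.ndarray) -> np.ndarray:
        """Full psi: scanner point -> reference anatomy point."""
        q = self.rigid_pullback(points)
        return q + self.deformation(q)

    def expected_registration_translation(self) -> np.ndarray:
        """Translation a rigid registration (follow-up -> reference) should find."""
        return np.asarray(self.distortion.translation, dtype=float)

    def recovery_field(self, geometry: Geometry, n_iter: int = 30) -> DisplacementField:
        """Ground-truth deformable field a registration should recover.

        After exact rigid alignment the residual image is ``A(x + w(x))``; the
        field ``g`` with ``warp(moving, g) = A`` satisfies ``g(x) = -w(x+g(x))``
        — the displacement inverse of ``w``, computed by fixed-point iteration
        on analytic evaluations of ``w``.
        """
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in geometry.shape], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        pts = geometry.index_to_physical(idx)
        g = np.zeros_like(pts)
        for _ in range(n_iter):
            g = -self.deformation(pts + g)
        return DisplacementField(
            g.reshape(geometry.shape + (3,)),
            geometry.spacing,
            geometry.origin,
            geometry.direction,
        )

    # -- intensity ----------------------------------------------------------
    def scanner_transform(self, values: np.ndarray) -> np.ndarray:
        """Monotone raw-scale distortion applied at acquisition time."""
        d = self.distortion
        v = np.asarray(values, dtype=float)
        vmax = self.intensity_max
        if d.gamma != 1.0:
            v = vmax * np.clip(v / vmax, 0.0, None) ** d.gamma
        return d.offset + d.gain * v

    def scanner_inverse(self, values: np.ndarray) -> np.ndarray:
        """Inverse of the scanner transform — the ideal harmonization map."""
        d = self.distortion
        v = (np.asarray(values, dtype=float) - d.offset) / d.gain
        vmax = self.intensity_max
        if d.gamma != 1.0:
            v = vmax * np.clip(v / vmax, 0.0, None) ** (1.0 / d.gamma)
        return v

    def to_json(self) -> str:
        d = self.distortion
        return json.dumps(
            {
                "gain": d.gain,
                "offset": d.offset,
                "gamma": d.gamma,
                "translation": list(d.translation),
                "rotation_deg": d.rotation_deg,
                "bumps": [
                    {"center": list(b.center), "sigma": b.sigma, "amplitude": list(b.amplitude)}
                    for b in d.bumps
                ],
                "tissue_scale": d.tissue_scale,
                "noise_sd": d.noise_sd,
            },
            sort_keys=True,
        )


@dataclass
class SubjectTimepoint:
    tag: str
    volume: Volume
    mask: LabelMask
    truth: TimepointTruth


# ---------------------------------------------------------------------------
# Rendering

_RENDER_PRIORITY = ["body", "fat", "GM", "femur", "bladder", "prostate", "PZ", "GTV"]


def _render(spec: PhantomSpec, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate anatomy labels and noiseless intensities at physical points."""
    labels = np.zeros(len(points), dtype=np.uint16)
    label_of = {v: k for k, v in PHANTOM_LABELS.items()}
    body = spec.structures["body"][0]
    inner_body = Ellipsoid(
        body.center, tuple(np.asarray(body.semi_axes) - spec.fat_rim_mm)
    )
    member = {"body": inner_body.contains(points)}
    member["fat"] = body.contains(points) & ~member["body"]
    for name in ["GM", "femur", "bladder", "prostate", "PZ", "GTV"]:
        hit = np.zeros(len(points), dtype=bool)
        for ell in spec.structures[name]:
            hit |= ell.contains(points)
        member[name] = hit
    for name in _RENDER_PRIORITY:
        labels[member[name]] = label_of[name]
    intensities = np.zeros(len(points), dtype=float)
    for lab, name in PHANTOM_LABELS.items():
        intensities[labels == lab] = spec.tissue_means[name]
    return labels, intensities


def _grid_points(geometry: Geometry) -> np.ndarray:
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in geometry.shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    return geometry.index_to_physical(idx)


def generate_timepoint(
    spec: PhantomSpec,
    distortion: TimepointDistortion,
    tag: str,
    rng: np.random.Generator,
) -> SubjectTimepoint:
    spec_t = spec
    if distortion.tissue_scale:
        means = dict(spec.tissue_means)
        # a scale on an ROI applies to its contained sub-structures too,
        # unless the sub-structure is scaled explicitly
        expanded = dict(distortion.tissue_scale)
        for name, factor in distortion.tissue_scale.items():
            for child in STRUCTURE_CHILDREN.get(name, []):
                expanded.setdefault(child, factor)
        for name, factor in expanded.items():
            means[name] = means[name] * factor
        spec_t = replace(copy.copy(spec), tissue_means=means)
    geom = spec.geometry
    truth = TimepointTruth(
        distortion,
        tuple(spec.center_mm),
        intensity_max=max(spec.tissue_means.values()),
    )
    pts = _grid_points(geom)
    anatomy_pts = truth.pullback(pts)
    labels, intensities = _render(spec_t, anatomy_pts)
    intensities = truth.scanner_transform(intensities)
    # background stays at the scanner floor, not at `offset` + 0 gain artifacts
    noise_sd = spec.noise_sd if distortion.noise_sd is None else distortion.noise_sd
    if noise_sd > 0:
        intensities = intensities + rng.normal(0.0, noise_sd, size=intensities.shape)
    intensities = np.clip(intensities, 0.0, None)
    volume = Volume(intensities.reshape(geom.shape), spec.spacing)
    mask = LabelMask(labels.reshape(geom.shape), spec.spacing, label_table=PHANTOM_LABELS)
    return SubjectTimepoint(tag, volume, mask, truth)


def generate_subject(spec: PhantomSpec, n_timepoints: int = 2) -> list[SubjectTimepoint]:
    """Generate one subject: an undistorted reference plus distorted follow-ups.

    ``spec.distortions[i]`` applies to timepoint ``i+1``; missing entries
    default to the identity distortion.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tags = [
        TIMEPOINT_TAGS[i] if i < len(TIMEPOINT_TAGS) else f"tp{i}"
        for i in range(n_timepoints)
    ]
    base_dist = spec.baseline_distortion or TimepointDistortion.identity()
    out = [generate_timepoint(spec, base_dist, tags[0], rng)]
    for i in range(1, n_timepoints):
        dist = (
            spec.distortions[i - 1]
            if i - 1 < len(spec.distortions)
            else TimepointDistortion.identity()
        )
        out.append(generate_timepoint(spec, dist, tags[i], rng))
    return out


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortVariability:
    """Per-subject / per-timepoint jitter ranges for cohort generation.

    Scanner gain/offset are drawn independently for every visit, baseline
    included: longitudinal studies mix magnets and sequences, so each
    acquisition carries its own intensity scale.
    """

    gain_range: tuple[float, float] = (0.6, 1.6)
    offset_range: tuple[float, float] = (0.0, 40.0)
    gamma_range: tuple[float, float] = (1.0, 1.0)
    translation_mm: float = 3.0
    rotation_deg: float = 2.0
    n_bumps: int = 2
    bump_amplitude_mm: tuple[float, float] = (1.0, 3.5)
    bump_sigma_mm: tuple[float, float] = (12.0, 20.0)
    geometry_center_jitter_mm: float = 2.0
    geometry_scale_jitter: float = 0.08
    # inter-subject habitus: body cross-section, subcutaneous fat thickness
    # and bladder filling vary far more than organ positions do
    body_scale_jitter: float = 0.08
    fat_rim_range_mm: tuple[float, float] = (2.0, 6.0)
    bladder_scale_jitter: float = 0.18
    post_tissue_scale: dict[str, float] = field(default_factory=dict)

    @classmethod
    def none(cls) -> "CohortVariability":
        return cls(
            gain_range=(1.0, 1.0),
            offset_range=(0.0, 0.0),
            translation_mm=0.0,
            rotation_deg=0.0,
            n_bumps=0,
            geometry_center_jitter_mm=0.0,
            geometry_scale_jitter=0.0,
        )


_POST_TAGS = {"3mo", "9mo", "24mo"}


def _draw_distortion(
    var: CohortVariability,
    rng: np.random.Generator,
    spec: PhantomSpec,
    tag: str,
) -> TimepointDistortion:
    bumps = []
    body = spec.structures["body"][0]
    for _ in range(var.n_bumps):
        center = np.asarray(body.center) + rng.uniform(-0.5, 0.5, 3) * np.asarray(
            body.semi_axes
        )
        sigma = rng.uniform(*var.bump_sigma_mm)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        amp = rng.uniform(*var.bump_amplitude_mm)
        bumps.append(GaussianBump(tuple(center), float(sigma), tuple(direction * amp)))
    tissue_scale = dict(var.post_tissue_scale) if tag in _POST_TAGS else {}
    return TimepointDistortion(
        gain=float(rng.uniform(*var.gain_range)),
        offset=float(rng.uniform(*var.offset_range)),
        gamma=float(rng.uniform(*var.gamma_range)),
        translation=tuple(rng.uniform(-var.translation_mm, var.translation_mm, 3)),
        rotation_deg=float(rng.uniform(-var.rotation_deg, var.rotation_deg)),
        bumps=bumps,
        tissue_scale=tissue_scale,
    )


def _jitter_spec(
    base: PhantomSpec, var: CohortVariability, rng: np.random.Generator, seed: int
) -> PhantomSpec:
    spec = copy.deepcopy(base)
    spec.seed = seed
    if var.geometry_center_jitter_mm > 0 or var.geometry_scale_jitter > 0:
        body = spec.structures["body"][0]
        body_scale = rng.uniform(1 - var.body_scale_jitter, 1 + var.body_scale_jitter, 2)
        new_body = Ellipsoid(
            body.center,
            (
                body.semi_axes[0] * body_scale[0],
                body.semi_axes[1] * body_scale[1],
                body.semi_axes[2],
            ),
        )
        spec.fat_rim_mm = float(rng.uniform(*var.fat_rim_range_mm))
        jittered: dict[str, list[Ellipsoid]] = {"body": [new_body]}
        # the prostate family moves and scales as a unit so containment holds
        family_shift = rng.uniform(
            -var.geometry_center_jitter_mm, var.geometry_center_jitter_mm, 3
        )
        family_scale = rng.uniform(
            1 - var.geometry_scale_jitter, 1 + var.geometry_scale_jitter, 3
        )
        anchor = np.asarray(spec.structures["prostate"][0].center)
        for name in ("prostate", "PZ", "GTV"):
            jittered[name] = [
                Ellipsoid(
                    tuple(anchor + (np.asarray(e.center) - anchor) * family_scale + family_shift),
                    tuple(np.asarray(e.semi_axes) * family_scale),
                )
                for e in spec.structures[name]
            ]
        for name in ("GM", "femur"):
            jittered[name] = [
                e.jitter(rng, var.geometry_center_jitter_mm, var.geometry_scale_jitter)
                for e in spec.structures[name]
            ]
        jittered["bladder"] = [
            e.jitter(rng, var.geometry_center_jitter_mm, var.bladder_scale_jitter)
            for e in spec.structures["bladder"]
        ]
        spec.structures = jittered
    return spec


def generate_cohort(
    base_spec: PhantomSpec,
    n_subjects: int,
    variability: CohortVariability,
    out_dir: str | Path,
    n_timepoints: int = 2,
    seed: int = 0,
    overwrite: bool = False,
) -> CohortManifest:
    """Generate a cohort on disk: subject dirs, manifest and ground-truth log."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out_dir} is not empty (use overwrite)")
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    subjects: list[SubjectEntry] = []
    log_rows = []
    for si in range(n_subjects):
        sid = f"subj{si + 1:02d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = _jitter_spec(base_spec, variability, rng, sub_seed)
        tags = [
            TIMEPOINT_TAGS[i] if i < len(TIMEPOINT_TAGS) else f"tp{i}"
            for i in range(n_timepoints)
        ]
        spec.baseline_distortion = TimepointDistortion(
            gain=float(rng.uniform(*variability.gain_range)),
            offset=float(rng.uniform(*variability.offset_range)),
            gamma=float(rng.uniform(*variability.gamma_range)),
        )
        spec.distortions = [
            _draw_distortion(variability, rng, spec, tags[i])
            for i in range(1, n_timepoints)
        ]
        tps = generate_subject(spec, n_timepoints)
        entries = []
        for tp in tps:
            vpath = out_dir / sid / f"{tp.tag}_t2w.nii.gz"
            mpath = out_dir / sid / f"{tp.tag}_mask.nii.gz"
            write_volume(tp.volume, vpath)
            write_mask(tp.mask, mpath)
            entries.append(TimepointEntry(tp.tag, vpath, mpath))
            log_rows.append(
                {
                    "subject": sid,
                    "timepoint": tp.tag,
                    "seed": sub_seed,
                    "gain": tp.truth.distortion.gain,
                    "offset": tp.truth.distortion.offset,
                    "gamma": tp.truth.distortion.gamma,
                    "noise_sd": spec.noise_sd
                    if tp.truth.distortion.noise_sd is None
                    else tp.truth.distortion.noise_sd,
                    "tissue_means": json.dumps(spec.tissue_means, sort_keys=True),
                    "distortion": tp.truth.to_json(),
                }
            )
        subjects.append(SubjectEntry(sid, entries))
    manifest = CohortManifest(subjects)
    save_manifest(manifest, out_dir / "manifest.yaml")
    pd.DataFrame(log_rows).to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    return manifest
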