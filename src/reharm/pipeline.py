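"""Per-subject and cohort orchestration.

For each subject: register every follow-up to the baseline, propagate the
baseline contours as automatic ROIs, post-process reference-tissue masks,
harmonize every timepoint in baseline space, and collect a longitudinal table
of ROI mean intensities (raw and harmonized) plus registration QC.  Cohort
runs add the evaluation battery: per-ROI pairwise histogram intersection
(raw vs harmonized vs histogram-equalized), repeatability between the two
pre-treatment timepoints, and pre/post percent change of median ROI means.

A subject that fails any stage produces a structured failure record; the rest
of the cohort completes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .core import LabelMask, Volume
from .harmonization import apply_intensity_map, harmonize_volume
from .maskproc import postprocess_mask
from .metrics import histogram_equalize, pairwise_minter, repeatability
from .phantom import PHANTOM_LABELS, structure_mask
from .registration import RegistrationParams, register_longitudinal, warp

__all__ = ["RunConfig", "SubjectOutput", "CohortResult", "run_subject", "run_cohort"]

log = logging.getLogger("reharm")

ROI_NAMES = ("prostate", "PZ", "GTV")
PRE_TAGS = ("baseline", "planning")
POST_TAGS = ("3mo", "9mo", "24mo")


@dataclass
class RunConfig:
    """Fully serializable description of a run; run = config + inputs + seed."""

    manifest: Path
    output_dir: Path
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    register: bool = True  # False = harmonize in original space (ablation)
    lambda_penalty: float = 0.1
    max_percentile: float = 99.9
    use_literal_max: bool = False
    separation_fraction: float = 0.02
    maskproc_enabled: bool = True
    maskproc_sigma_mm: float | None = None
    maskproc_impute: bool = True
    n_bins: int = 64
    save_volumes: bool = True
    seed: int = 0
    log_level: str = "INFO"
    label_table: dict[int, str] = field(default_factory=lambda: dict(PHANTOM_LABELS))

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.output_dir = Path(self.output_dir)
        if isinstance(self.registration, dict):
            self.registration = RegistrationParams(**self.registration)
        self.registration.seed = self.seed
        self.label_table = {int(k): v for k, v in self.label_table.items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["manifest"] = str(self.manifest)
        d["output_dir"] = str(self.output_dir)
        d["registration"]["shrink_factors"] = list(self.registration.shrink_factors)
        d["registration"]["smoothing_sigmas"] = list(self.registration.smoothing_sigmas)
        d["registration"]["demons_iterations"] = list(self.registration.demons_iterations)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SubjectOutput:
    subject_id: str
    rows: list[dict]
    roi_samples: dict  # tag -> variant -> roi -> 1D intensity array
    qc: dict
    failure: dict | None = None


@dataclass
class CohortResult:
    table: pd.DataFrame
    minter: dict
    repeatability: dict
    prepost: dict
    failures: list[dict]
    summary: dict


def _roi_stats(volume: Volume, mask: LabelMask, roi: str) -> tuple[float, float]:
    sel = structure_mask(mask, roi)
    if not sel.any():
        return float("nan"), 0.0
    vol_ml = float(sel.sum()) * mask.geometry.voxel_volume_ml()
    return float(volume.data[sel].mean()), vol_ml


def _reference_mask(mask: LabelMask, config: RunConfig) -> LabelMask:
    if not config.maskproc_enabled:
        return mask
    names = [n for n in ("GM", "femur", "bladder") if mask.voxel_count(n) > 0]
    if not names:
        return mask
    return postprocess_mask(
        mask, labels=names, sigma_mm=config.maskproc_sigma_mm, impute=config.maskproc_impute
    )


def run_subject(config: RunConfig, subject: rio.SubjectEntry) -> SubjectOutput:
    """Process one subject end to end; exceptions become a failure record."""
    sid = subject.subject_id
    out_dir = config.output_dir / sid
    try:
        baseline_vol = rio.read_volume(subject.baseline.volume)
        if subject.baseline.mask is None:
            raise ValueError(f"subject {sid}: baseline timepoint has no mask")
        baseline_mask = rio.read_mask(subject.baseline.mask, config.label_table)
        baseline_mask.check_companion(baseline_vol)
        ref_mask = _reference_mask(baseline_mask, config)
        prostate = structure_mask(baseline_mask, "prostate")

        rows: list[dict] = []
        roi_samples: dict[str, dict[str, dict[str, np.ndarray]]] = {}
        qc: dict[str, Any] = {}

        def record(tag, vol_raw, vol_harm, vol_eq, mask, dice_by_roi=None, manual_means=None):
            samples = {"raw": {}, "harmonized": {}, "equalized": {}}
            for roi in ROI_NAMES:
                sel = structure_mask(mask, roi)
                mean_raw, vol_ml = _roi_stats(vol_raw, mask, roi)
                mean_harm, _ = _roi_stats(vol_harm, mask, roi)
                samples["raw"][roi] = vol_raw.data[sel].copy()
                samples["harmonized"][roi] = vol_harm.data[sel].copy()
                samples["equalized"][roi] = vol_eq.data[sel].copy()
                rows.append(
                    {
                        "subject": sid,
                        "timepoint": tag,
                        "roi": roi,
                        "mean_raw": mean_raw,
                        "mean_harmonized": mean_harm,
                        "mean_raw_manual": (manual_means or {}).get(roi, mean_raw),
                        "volume_ml": vol_ml,
                        "dice": (dice_by_roi or {}).get(roi, float("nan")),
                    }
                )
            roi_samples[tag] = samples

        # -- baseline (the reference: automatic == manual) --------------------
        base_harm, base_map = harmonize_volume(
            baseline_vol,
            ref_mask,
            lambda_penalty=config.lambda_penalty,
            max_percentile=config.max_percentile,
            use_literal_max=config.use_literal_max,
            separation_fraction=config.separation_fraction,
        )
        base_eq = histogram_equalize(baseline_vol)
        record(
            subject.baseline.tag,
            baseline_vol,
            base_harm,
            base_eq,
            baseline_mask,
            dice_by_roi={roi: 1.0 for roi in ROI_NAMES},
        )
        if config.save_volumes:
            rio.write_volume(base_harm, out_dir / f"{subject.baseline.tag}_harmonized.nii.gz")
            rio.write_intensity_map(base_map, out_dir / f"{subject.baseline.tag}_map.tsv")

        # -- follow-ups --------------------------------------------------------
        from .metrics import dice as dice_fn

        for tp in subject.followups:
            vol = rio.read_volume(tp.volume)
            manual_mask = (
                rio.read_mask(tp.mask, config.label_table) if tp.mask is not None else None
            )
            manual_means = {}
            if manual_mask is not None:
                for roi in ROI_NAMES:
                    manual_means[roi], _ = _roi_stats(vol, manual_mask, roi)

            if config.register:
                result = register_longitudinal(
                    baseline_vol, vol, prostate_mask=prostate, params=config.registration
                )
                vol_reg = result.warped
                dice_by_roi = {}
                if manual_mask is not None:
                    warped_manual = warp(manual_mask, result.composed_field)
                    for roi in ROI_NAMES:
                        dice_by_roi[roi] = dice_fn(
                            structure_mask(baseline_mask, roi),
                            structure_mask(warped_manual, roi),
                        )
                qc[tp.tag] = result.qc
                eval_mask = baseline_mask
                if config.save_volumes:
                    rio.write_field(result.composed_field, out_dir / f"{tp.tag}_field.nii.gz")
                    rio.write_volume(vol_reg, out_dir / f"{tp.tag}_registered.nii.gz")
            else:
                if manual_mask is None:
                    raise ValueError(
                        f"subject {sid}, timepoint {tp.tag}: --no-register mode "
                        "requires per-timepoint masks"
                    )
                vol_reg, eval_mask, dice_by_roi = vol, manual_mask, {}

            # the intensity map is fitted on the follow-up's own acquisition
            # using its own reference-structure segmentation when available
            # (mirroring per-scan reference segmentation); a monotone pointwise
            # map commutes with resampling, so it applies to the registered
            # volume unchanged.  Without per-timepoint masks, fall back to the
            # propagated baseline reference masks on the registered volume.
            if manual_mask is not None:
                _, imap = harmonize_volume(
                    vol,
                    _reference_mask(manual_mask, config),
                    lambda_penalty=config.lambda_penalty,
                    max_percentile=config.max_percentile,
                    use_literal_max=config.use_literal_max,
                    separation_fraction=config.separation_fraction,
                )
            else:
                _, imap = harmonize_volume(
                    vol_reg,
                    _reference_mask(eval_mask, config),
                    lambda_penalty=config.lambda_penalty,
                    max_percentile=config.max_percentile,
                    use_literal_max=config.use_literal_max,
                    separation_fraction=config.separation_fraction,
                )
            harm = apply_intensity_map(vol_reg, imap)
            eq = histogram_equalize(vol_reg)
            record(tp.tag, vol_reg, harm, eq, eval_mask, dice_by_roi, manual_means)
            if config.save_volumes:
                rio.write_volume(harm, out_dir / f"{tp.tag}_harmonized.nii.gz")
                rio.write_intensity_map(imap, out_dir / f"{tp.tag}_map.tsv")

        return SubjectOutput(sid, rows, roi_samples, qc)
    except Exception as exc:  # noqa: BLE001 — failure isolation is the contract
        log.error("subject %s failed: %s", sid, exc)
        return SubjectOutput(
            sid,
            rows=[],
            roi_samples={},
            qc={},
            failure={"subject": sid, "error": f"{type(exc).__name__}: {exc}"},
        )


def _cohort_minter(outputs: list[SubjectOutput], tag: str, n_bins: int) -> dict:
    result: dict[str, dict] = {}
    for variant in ("raw", "harmonized", "equalized"):
        result[variant] = {}
        for roi in ROI_NAMES:
            cohort = {
                o.subject_id: o.roi_samples[tag][variant][roi]
                for o in outputs
                if tag in o.roi_samples and o.roi_samples[tag][variant][roi].size > 0
            }
            if len(cohort) >= 2:
                mm = pairwise_minter(cohort, n_bins=n_bins)
                result[variant][roi] = {"median": mm["median"], "n_pairs": mm["n_pairs"]}
    return result


def _cohort_repeatability(table: pd.DataFrame) -> dict:
    out: dict[str, dict] = {}
    pre = table[table.timepoint.isin(PRE_TAGS)]
    for column, variant in [
        ("mean_raw_manual", "raw_manual"),
        ("mean_raw", "raw_automatic"),
        ("mean_harmonized", "harmonized_automatic"),
    ]:
        out[variant] = {}
        for roi in ROI_NAMES:
            sub = pre[pre.roi == roi].pivot_table(
                index="subject", columns="timepoint", values=column
            )
            if not set(PRE_TAGS).issubset(sub.columns):
                continue
            sub = sub.dropna(subset=list(PRE_TAGS))
            if len(sub) < 3:
                continue
            rep = repeatability(sub["baseline"].to_numpy(), sub["planning"].to_numpy())
            out[variant][roi] = rep.as_dict()
    return out


def _prepost_change(table: pd.DataFrame) -> dict:
    out = {}
    for roi in ROI_NAMES:
        sub = table[table.roi == roi]
        pre = sub[sub.timepoint.isin(PRE_TAGS)]["mean_harmonized"].median()
        post = sub[sub.timepoint.isin(POST_TAGS)]["mean_harmonized"].median()
        if np.isfinite(pre) and np.isfinite(post) and pre != 0:
            out[roi] = {"pct_change": float((pre - post) / pre * 100.0)}
    return out


def run_cohort(config: RunConfig) -> CohortResult:
    """Run every subject, then the cohort evaluation battery."""
    logging.basicConfig(level=config.log_level)
    manifest = rio.load_manifest(config.manifest)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    outputs = [run_subject(config, s) for s in manifest.subjects]
    failures = [o.failure for o in outputs if o.failure is not None]
    ok = [o for o in outputs if o.failure is None]

    rows = [r for o in ok for r in o.rows]
    table = pd.DataFrame(
        rows,
        columns=[
            "subject",
            "timepoint",
            "roi",
            "mean_raw",
            "mean_harmonized",
            "mean_raw_manual",
            "volume_ml",
            "dice",
        ],
    )

    minter: dict = {}
    repeat: dict = {}
    prepost: dict = {}
    if len(ok) >= 2:
        minter = _cohort_minter(ok, "baseline", config.n_bins)
        repeat = _cohort_repeatability(table)
        prepost = _prepost_change(table)
    else:
        log.warning("fewer than 2 usable subjects: cohort metrics skipped")

    summary = {
        "config_hash": config.config_hash(),
        "manifest": str(config.manifest),
        "n_subjects": len(manifest.subjects),
        "n_failed": len(failures),
        "seed": config.seed,
    }
    table.to_csv(
        config.output_dir / "longitudinal.tsv", sep="\t", index=False, float_format="%.6f"
    )
    with open(config.output_dir / "run_summary.json", "w") as fh:
        json.dump(
            {
                "summary": summary,
                "minter": minter,
                "repeatability": repeat,
                "prepost": prepost,
                "failures": failures,
                "qc": {o.subject_id: o.qc for o in ok},
            },
            fh,
            indent=2,
            default=float,
        )
    return CohortResult(table, minter, repeat, prepost, failures, summary)
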