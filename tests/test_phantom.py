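"""Phantom generator: ground-truth fidelity, determinism, validation."""

import json

import numpy as np
import pandas as pd
import pytest

from reharm.phantom import (
    CohortVariability,
    Ellipsoid,
    GaussianBump,
    PhantomSpec,
    PhantomSpecError,
    TimepointDistortion,
    generate_cohort,
    generate_subject,
    structure_mask,
)


def centroid_mm(mask, name):
    geom = mask.geometry
    idx = np.argwhere(structure_mask(mask, name))
    return geom.index_to_physical(idx).mean(axis=0)


class TestGenerateSubject:
    def test_identity_distortion_reproduces_reference(self):
        spec = PhantomSpec(noise_sd=0.0, seed=1).scaled((48, 48, 24))
        t1, t2 = generate_subject(spec, 2)
        np.testing.assert_array_equal(t1.volume.data, t2.volume.data)
        np.testing.assert_array_equal(t1.mask.data, t2.mask.data)

    def test_pure_translation_shifts_prostate_centroid(self):
        shift = (3.0, 0.0, 0.0)  # 3 voxels along x at 1 mm spacing
        spec = PhantomSpec(
            noise_sd=0.0, seed=1, distortions=[TimepointDistortion(translation=shift)]
        )
        t1, t2 = generate_subject(spec, 2)
        delta = centroid_mm(t2.mask, "prostate") - centroid_mm(t1.mask, "prostate")
        np.testing.assert_allclose(delta, shift, atol=0.05)

    def test_gain_scales_tissue_means_exactly(self):
        spec = PhantomSpec(
            noise_sd=0.0, seed=2, distortions=[TimepointDistortion(gain=1.3)]
        ).scaled((48, 48, 24))
        t1, t2 = generate_subject(spec, 2)
        gm1 = t1.volume.data[t1.mask.binary("GM")].mean()
        gm2 = t2.volume.data[t2.mask.binary("GM")].mean()
        assert gm2 / gm1 == pytest.approx(1.3, abs=1e-9)

    def test_tissue_scale_applies_to_contained_structures(self):
        spec = PhantomSpec(
            noise_sd=0.0,
            seed=2,
            distortions=[TimepointDistortion(tissue_scale={"PZ": 0.86})],
        ).scaled((48, 48, 24))
        t1, t2 = generate_subject(spec, 2)
        roi1 = t1.volume.data[structure_mask(t1.mask, "PZ")].mean()
        roi2 = t2.volume.data[structure_mask(t2.mask, "PZ")].mean()
        assert roi2 / roi1 == pytest.approx(0.86, abs=1e-9)

    def test_scanner_inverse_undoes_transform(self):
        spec = PhantomSpec(
            noise_sd=0.0,
            seed=3,
            distortions=[TimepointDistortion(gain=1.4, offset=25.0, gamma=1.2)],
        ).scaled((48, 48, 24))
        _, t2 = generate_subject(spec, 2)
        v = np.linspace(0, 1500, 64)
        np.testing.assert_allclose(
            t2.truth.scanner_inverse(t2.truth.scanner_transform(v)), v, atol=1e-8
        )

    def test_recovery_field_inverts_deformation(self):
        spec = PhantomSpec(
            noise_sd=0.0,
            seed=4,
            distortions=[
                TimepointDistortion(bumps=[GaussianBump((48, 50, 48), 18.0, (3.0, -2.0, 1.0))])
            ],
        ).scaled((48, 48, 24))
        t1, t2 = generate_subject(spec, 2)
        fld = t2.truth.recovery_field(t1.volume.geometry)
        geom = t1.volume.geometry
        idx = np.argwhere(np.ones(geom.shape, bool))
        pts = geom.index_to_physical(idx)
        # psi(x + g(x)) == x: the field undoes the generative pull-back
        round_trip = t2.truth.pullback(pts + fld.data.reshape(-1, 3))
        np.testing.assert_allclose(round_trip, pts, atol=1e-6)


class TestValidation:
    def test_inverted_tissue_means_rejected(self):
        spec = PhantomSpec(noise_sd=0.0)
        spec.tissue_means["GM"] = 2000.0
        with pytest.raises(PhantomSpecError, match="GM < femur < bladder"):
            generate_subject(spec, 2)

    def test_broken_containment_rejected(self):
        spec = PhantomSpec(noise_sd=0.0)
        spec.structures["GTV"] = [Ellipsoid((20, 20, 20), (4, 4, 4))]
        with pytest.raises(PhantomSpecError, match="GTV not contained"):
            generate_subject(spec, 2)

    def test_non_invertible_deformation_rejected(self):
        spec = PhantomSpec(
            noise_sd=0.0,
            distortions=[
                TimepointDistortion(bumps=[GaussianBump((48, 48, 48), 3.0, (9.0, 0, 0))])
            ],
        )
        with pytest.raises(PhantomSpecError, match="invertible"):
            generate_subject(spec, 2)

    def test_baseline_distortion_must_be_intensity_only(self):
        spec = PhantomSpec(noise_sd=0.0)
        spec.baseline_distortion = TimepointDistortion(translation=(1, 0, 0))
        with pytest.raises(PhantomSpecError, match="intensity-only"):
            generate_subject(spec, 2)


class TestGenerateCohort:
    def test_seeded_cohort_reproducible_bytewise(self, tmp_path):
        spec = PhantomSpec(noise_sd=5.0).scaled((32, 32, 16))
        var = CohortVariability()
        for d in ("a", "b"):
            generate_cohort(spec, 2, var, tmp_path / d, n_timepoints=2, seed=42)
        log_a = (tmp_path / "a" / "ground_truth.tsv").read_bytes()
        log_b = (tmp_path / "b" / "ground_truth.tsv").read_bytes()
        assert log_a == log_b
        va = (tmp_path / "a" / "subj01" / "baseline_t2w.nii.gz").read_bytes()
        vb = (tmp_path / "b" / "subj01" / "baseline_t2w.nii.gz").read_bytes()
        assert va == vb

    def test_output_collision_requires_overwrite(self, tmp_path):
        spec = PhantomSpec(noise_sd=0.0).scaled((32, 32, 16))
        generate_cohort(spec, 1, CohortVariability.none(), tmp_path / "c", seed=1)
        with pytest.raises(FileExistsError):
            generate_cohort(spec, 1, CohortVariability.none(), tmp_path / "c", seed=1)
        generate_cohort(spec, 1, CohortVariability.none(), tmp_path / "c", seed=1, overwrite=True)

    def test_logged_gains_respect_requested_range(self, tmp_path):
        spec = PhantomSpec(noise_sd=0.0).scaled((32, 32, 16))
        var = CohortVariability(gain_range=(0.6, 1.6))
        generate_cohort(spec, 6, var, tmp_path / "g", n_timepoints=2, seed=3)
        log = pd.read_csv(tmp_path / "g" / "ground_truth.tsv", sep="\t")
        assert log.gain.min() >= 0.6 and log.gain.max() <= 1.6
        assert log.gain.max() - log.gain.min() > 0.3  # actually spread out

    def test_ground_truth_log_has_full_provenance(self, tmp_path):
        spec = PhantomSpec(noise_sd=2.0).scaled((32, 32, 16))
        man = generate_cohort(spec, 2, CohortVariability(), tmp_path / "p", seed=9)
        log = pd.read_csv(tmp_path / "p" / "ground_truth.tsv", sep="\t")
        assert len(log) == 2 * 2  # subjects x timepoints
        dist = json.loads(log.distortion.iloc[1])
        assert {"gain", "offset", "translation", "rotation_deg", "bumps"} <= set(dist)
        assert len(man) == 2

    def test_zero_variability_cohort_matches_generate_subject(self, tmp_path):
        from reharm import io as rio

        spec = PhantomSpec(noise_sd=0.0, seed=0).scaled((32, 32, 16))
        man = generate_cohort(
            spec, 1, CohortVariability.none(), tmp_path / "z", n_timepoints=2, seed=0
        )
        vol = rio.read_volume(man.subjects[0].baseline.volume)
        direct = generate_subject(spec, 2)[0]
        np.testing.assert_allclose(vol.data, direct.volume.data, atol=1e-4)
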