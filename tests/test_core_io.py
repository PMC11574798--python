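"""Containers, geometry validation and NIfTI / manifest round-trips."""

import numpy as np
import pytest
import SimpleITK as sitk

from reharm import io as rio
from reharm.core import DisplacementField, Geometry, GeometryError, LabelMask, Volume
from reharm.harmonization import AnchorSet, fit_intensity_map


class TestContainers:
    def test_volume_rejects_bad_input(self):
        with pytest.raises(ValueError, match="3D"):
            Volume(np.zeros((4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="spacing"):
            Volume(np.zeros((4, 4, 4)), (1, 0, 1))
        with pytest.raises(ValueError, match="finite"):
            Volume(np.full((4, 4, 4), np.nan), (1, 1, 1))
        with pytest.raises(ValueError, match="orthonormal"):
            Volume(np.zeros((4, 4, 4)), (1, 1, 1), direction=tuple(np.ones(9)))

    def test_mask_rejects_non_integral_and_negative(self):
        with pytest.raises(ValueError, match="non-integral"):
            LabelMask(np.full((4, 4, 4), 0.5), (1, 1, 1))
        with pytest.raises(ValueError, match="nonnegative"):
            LabelMask(np.full((4, 4, 4), -1), (1, 1, 1))

    def test_geometry_physical_index_round_trip(self):
        geom = Geometry((8, 8, 4), (1.0, 1.5, 3.0), origin=(10.0, -5.0, 2.0))
        idx = np.array([[3, 4, 1], [0, 0, 0], [7, 7, 3]], dtype=float)
        back = geom.physical_to_index(geom.index_to_physical(idx))
        np.testing.assert_allclose(back, idx, atol=1e-10)

    def test_mask_companion_geometry_enforced(self):
        vol = Volume(np.zeros((4, 4, 4)), (1, 1, 1))
        mask = LabelMask(np.zeros((4, 4, 4), dtype=np.uint8), (2, 2, 2))
        with pytest.raises(GeometryError):
            mask.check_companion(vol)

    def test_sitk_round_trip_preserves_layout(self):
        data = np.arange(4 * 5 * 6, dtype=float).reshape(4, 5, 6)
        vol = Volume(data, (1.0, 2.0, 3.0), origin=(1, 2, 3))
        img = vol.to_sitk()
        assert img.GetSize() == (4, 5, 6)
        assert img.GetPixel(1, 2, 3) == data[1, 2, 3]
        back = Volume.from_sitk(img)
        np.testing.assert_array_equal(back.data, data)
        assert back.spacing == vol.spacing


class TestNiftiIO:
    def test_volume_round_trip_lossless(self, tmp_path, rng):
        vol = Volume(
            rng.normal(100, 10, (8, 8, 8)).astype(np.float32),
            (1.0, 1.0, 2.0),
            origin=(5.0, -3.0, 0.0),
        )
        rio.write_volume(vol, tmp_path / "v.nii.gz")
        back = rio.read_volume(tmp_path / "v.nii.gz")
        np.testing.assert_array_equal(back.data.astype(np.float32), vol.data)
        assert back.spacing == vol.spacing
        assert back.origin == vol.origin

    def test_constant_volume_round_trip(self, tmp_path):
        vol = Volume(np.full((8, 8, 8), 7.0), (1, 1, 1))
        rio.write_volume(vol, tmp_path / "c.nii")
        assert np.abs(rio.read_volume(tmp_path / "c.nii").data - 7.0).max() == 0

    def test_read_4d_rejected(self, tmp_path):
        img4d = sitk.GetImageFromArray(np.zeros((2, 4, 4, 4)))
        sitk.WriteImage(img4d, str(tmp_path / "x.nii.gz"))
        with pytest.raises(ValueError, match="expected (3D|scalar) volume"):
            rio.read_volume(tmp_path / "x.nii.gz")

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.nii"):
            rio.read_volume(tmp_path / "nope.nii")

    def test_mask_round_trip_per_label_counts(self, tmp_path, rng):
        table = {1: "prostate", 2: "PZ", 3: "GTV", 4: "GM", 5: "femur", 6: "bladder"}
        data = rng.integers(0, 7, (12, 12, 6))
        mask = LabelMask(data, (1, 1, 2), label_table=table)
        rio.write_mask(mask, tmp_path / "m.nii.gz")
        back = rio.read_mask(tmp_path / "m.nii.gz", table)
        for lab in table:
            assert back.voxel_count(lab) == mask.voxel_count(lab)

    def test_mask_unknown_label_listed(self, tmp_path):
        mask = LabelMask(np.full((4, 4, 4), 7, dtype=np.uint8), (1, 1, 1))
        rio.write_mask(mask, tmp_path / "m.nii.gz")
        with pytest.raises(ValueError, match=r"\[7\]"):
            rio.read_mask(tmp_path / "m.nii.gz", {1: "prostate"})

    def test_field_round_trip(self, tmp_path, rng):
        fld = DisplacementField(rng.normal(0, 1, (6, 6, 6, 3)), (1, 1, 2))
        rio.write_field(fld, tmp_path / "f.nii.gz")
        back = rio.read_field(tmp_path / "f.nii.gz")
        np.testing.assert_allclose(back.data, fld.data, atol=1e-6)

    def test_intensity_map_round_trip(self, tmp_path):
        imap = fit_intensity_map(AnchorSet(input_anchors=(0, 200, 500, 900, 1000)))
        rio.write_intensity_map(imap, tmp_path / "map.tsv")
        back = rio.read_intensity_map(tmp_path / "map.tsv")
        x = np.linspace(0, 1000, 77)
        np.testing.assert_allclose(back(x), imap(x), atol=0.01)


class TestManifest:
    def _write(self, tmp_path, doc):
        import yaml

        p = tmp_path / "manifest.yaml"
        p.write_text(yaml.safe_dump(doc))
        return p

    def _touch_volumes(self, tmp_path, names):
        vol = Volume(np.zeros((4, 4, 4)), (1, 1, 1))
        for n in names:
            rio.write_volume(vol, tmp_path / n)

    def test_parse_ordered_timepoints(self, tmp_path):
        self._touch_volumes(tmp_path, ["a1.nii.gz", "a2.nii.gz", "b1.nii.gz", "b2.nii.gz"])
        doc = {
            "subjects": [
                {
                    "id": "s1",
                    "timepoints": [
                        {"tag": "baseline", "volume": "a1.nii.gz"},
                        {"tag": "planning", "volume": "a2.nii.gz"},
                    ],
                },
                {
                    "id": "s2",
                    "timepoints": [
                        {"tag": "baseline", "volume": "b1.nii.gz"},
                        {"tag": "planning", "volume": "b2.nii.gz"},
                    ],
                },
            ]
        }
        man = rio.load_manifest(self._write(tmp_path, doc))
        assert len(man) == 2
        assert man.subject("s1").baseline.tag == "baseline"
        assert [tp.tag for tp in man.subject("s2").timepoints] == ["baseline", "planning"]

    def test_single_timepoint_rejected(self, tmp_path):
        self._touch_volumes(tmp_path, ["a1.nii.gz"])
        doc = {"subjects": [{"id": "s1", "timepoints": [{"volume": "a1.nii.gz"}]}]}
        with pytest.raises(rio.ManifestError, match="need >= 2"):
            rio.load_manifest(self._write(tmp_path, doc))

    def test_missing_file_names_subject_and_timepoint(self, tmp_path):
        self._touch_volumes(tmp_path, ["a1.nii.gz"])
        doc = {
            "subjects": [
                {
                    "id": "s1",
                    "timepoints": [
                        {"tag": "baseline", "volume": "a1.nii.gz"},
                        {"tag": "planning", "volume": "gone.nii.gz"},
                    ],
                }
            ]
        }
        with pytest.raises(rio.ManifestError, match="subject s1, timepoint planning"):
            rio.load_manifest(self._write(tmp_path, doc))

    def test_save_load_round_trip(self, tmp_path):
        self._touch_volumes(tmp_path, ["a1.nii.gz", "a2.nii.gz"])
        doc = {
            "subjects": [
                {
                    "id": "s1",
                    "timepoints": [
                        {"tag": "baseline", "volume": "a1.nii.gz"},
                        {"tag": "planning", "volume": "a2.nii.gz"},
                    ],
                }
            ]
        }
        man = rio.load_manifest(self._write(tmp_path, doc))
        rio.save_manifest(man, tmp_path / "copy.yaml")
        back = rio.load_manifest(tmp_path / "copy.yaml")
        assert [s.subject_id for s in back.subjects] == ["s1"]
        assert back.subject("s1").timepoints[1].volume.name == "a2.nii.gz"
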