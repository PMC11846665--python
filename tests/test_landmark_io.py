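"""Point-file, mask and config I/O: round-trips and structural validation."""

import numpy as np
import pytest
import yaml
from PIL import Image

from kneedxa import (
    ConfigError,
    GraderConfig,
    PtsParseError,
    Site,
    read_config,
    read_mask,
    read_pts,
    write_config,
    write_pts,
)
from kneedxa.io import read_area_table

from conftest import random_landmarks


class TestPtsRoundTrip:
    def test_read_back_equals_original(self, tmp_path, rng):
        lm = random_landmarks(rng)
        write_pts(lm, tmp_path / "a.pts")
        back = read_pts(tmp_path / "a.pts")
        assert back.subject_id == lm.subject_id
        assert back.side == lm.side
        assert back.pixel_spacing_mm == pytest.approx(lm.pixel_spacing_mm, abs=1e-6)
        np.testing.assert_allclose(back.points, lm.points, atol=1e-6)

    def test_write_read_write_is_byte_identical(self, tmp_path, rng):
        # canonical form is a fixed point of the writer, across many files
        for i in range(50):
            lm = random_landmarks(rng, subject_id=f"S{i:04d}")
            p1, p2 = tmp_path / "one.pts", tmp_path / "two.pts"
            write_pts(lm, p1)
            write_pts(read_pts(p1), p2)
            assert p1.read_bytes() == p2.read_bytes()

    def test_point_order_preserved(self, tmp_path, rng):
        lm = random_landmarks(rng)
        write_pts(lm, tmp_path / "a.pts")
        back = read_pts(tmp_path / "a.pts")
        # order matters: reversing would break equality for random points
        assert not np.allclose(back.points, lm.points[::-1])


class TestPtsErrors:
    def test_wrong_point_count_names_expected_and_found(self, tmp_path):
        lines = ["version: 1", "n_points: 128", "{"]
        lines += ["1.0 2.0"] * 128 + ["}"]
        f = tmp_path / "short.pts"
        f.write_text("\n".join(lines) + "\n")
        with pytest.raises(PtsParseError, match="expected 129.*found 128"):
            read_pts(f, pixel_spacing_mm=0.25)

    def test_declared_count_mismatch(self, tmp_path):
        lines = ["version: 1", "n_points: 129", "{", "1.0 2.0", "}"]
        f = tmp_path / "bad.pts"
        f.write_text("\n".join(lines) + "\n")
        with pytest.raises(PtsParseError, match="declares 129"):
            read_pts(f, pixel_spacing_mm=0.25)

    def test_non_numeric_coordinate_reports_line(self, tmp_path):
        lines = ["version: 1", "n_points: 129", "{"]
        lines += ["1.0 2.0"] * 64 + ["1.0 oops"] + ["1.0 2.0"] * 64 + ["}"]
        f = tmp_path / "nan.pts"
        f.write_text("\n".join(lines) + "\n")
        with pytest.raises(PtsParseError, match=":68:"):
            read_pts(f, pixel_spacing_mm=0.25)

    def test_missing_spacing_rejected(self, tmp_path):
        lines = ["version: 1", "n_points: 129", "{"] + ["1.0 2.0"] * 129 + ["}"]
        f = tmp_path / "nospacing.pts"
        f.write_text("\n".join(lines) + "\n")
        with pytest.raises(PtsParseError, match="pixel_spacing_mm"):
            read_pts(f)
        assert read_pts(f, pixel_spacing_mm=0.3).pixel_spacing_mm == 0.3


class TestMaskReading:
    def _save(self, tmp_path, arr):
        p = tmp_path / "mask.png"
        Image.fromarray(arr).save(p)
        return p

    def test_all_background_is_empty(self, tmp_path, cfg):
        p = self._save(tmp_path, np.zeros((32, 32, 3), dtype=np.uint8))
        assert read_mask(p, cfg, 0.25) == []

    def test_single_red_blob_is_medial_femur(self, tmp_path, cfg):
        arr = np.zeros((32, 32, 3), dtype=np.uint8)
        arr[5:15, 5:15] = (255, 0, 0)
        anns = read_mask(self._save(tmp_path, arr), cfg, 0.25)
        assert [a.site for a in anns] == [Site.MEDIAL_FEMUR]
        assert anns[0].mask.sum() == 100

    def test_disjoint_blobs_of_one_colour_sum(self, tmp_path, cfg):
        arr = np.zeros((64, 64, 3), dtype=np.uint8)
        arr[2:7, 2:7] = (255, 0, 0)     # 25 px
        arr[40:50, 40:52] = (255, 0, 0)  # 120 px
        anns = read_mask(self._save(tmp_path, arr), cfg, 0.5)
        assert anns[0].mask.sum() == 145  # pixel-count oracle

    def test_unmapped_colour_ignored_with_warning(self, tmp_path, cfg, caplog):
        arr = np.zeros((16, 16, 3), dtype=np.uint8)
        arr[0:4, 0:4] = (12, 34, 56)
        arr[8:10, 8:10] = (0, 0, 255)
        with caplog.at_level("WARNING"):
            anns = read_mask(self._save(tmp_path, arr), cfg, 0.25)
        assert [a.site for a in anns] == [Site.LATERAL_TIBIA]
        assert "16 pixels" in caplog.text


class TestConfigIO:
    def test_empty_document_gives_defaults(self, tmp_path):
        f = tmp_path / "empty.yaml"
        f.write_text("")
        assert read_config(f) == GraderConfig()

    def test_non_decreasing_jsn_thresholds_rejected(self, tmp_path):
        f = tmp_path / "bad.yaml"
        f.write_text(yaml.safe_dump({"jsn_thresholds_mm": [2.0, 2.5, 3.0]}))
        with pytest.raises(ConfigError, match="decreasing"):
            read_config(f)

    def test_overlapping_subset_ranges_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            GraderConfig(femur_medial_idx=(15, 30))

    def test_round_trip_identity_over_randomised_configs(self, tmp_path, rng):
        for _ in range(20):
            t1 = float(rng.uniform(2, 15))
            cfg = GraderConfig(
                osteophyte_area_thresholds_mm2=(t1, t1 + float(rng.uniform(1, 20))),
                jsn_thresholds_mm=(3.5, 2.4, 1.9),
                jsn_boundary_grade=int(rng.choice([2, 3])),
                distance_mode=str(rng.choice(["segment", "point"])),
            )
            write_config(cfg, tmp_path / "c.yaml")
            assert read_config(tmp_path / "c.yaml") == cfg

    def test_unknown_keys_rejected(self, tmp_path):
        f = tmp_path / "extra.yaml"
        f.write_text(yaml.safe_dump({"jsn_threshold": [3, 2.5, 2]}))
        with pytest.raises(ConfigError, match="unknown config keys"):
            read_config(f)


def test_area_table_maps_subjects_to_annotations(tmp_path):
    f = tmp_path / "areas.csv"
    f.write_text(
        "subject_id,site,area_mm2\n"
        "S1,medial_femur,12.5\nS1,lateral_tibia,3.0\nS2,medial_tibia,40.0\n"
    )
    table = read_area_table(f)
    assert set(table) == {"S1", "S2"}
    assert {a.site for a in table["S1"]} == {Site.MEDIAL_FEMUR, Site.LATERAL_TIBIA}
    assert table["S2"][0].area_mm2 == 40.0
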