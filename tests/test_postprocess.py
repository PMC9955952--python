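"""Channel selection, lesion splitting/localization, dimensions, reports."""

import json

import numpy as np
import pytest

from piradscaps.encoding import encode_label_map
from piradscaps.phantom import ZONE_PZ, ZONE_TZ
from piradscaps.postprocess import (
    LesionFinding,
    generate_report,
    lesion_dimensions,
    locate_lesion,
    select_final_channel,
    split_lesions,
)


def _stack_with_counts(counts):
    """Build an (S,4,H,W) stack whose channel voxel counts equal ``counts``."""
    probs = np.zeros((1, 4, 16, 16), np.float32)
    for k, n in enumerate(counts):
        flat = probs[0, k].reshape(-1)
        flat[:n] = 1.0
    return probs


class TestChannelSelection:
    def test_argmax_of_stated_counts(self):
        mask, scope = select_final_channel(_stack_with_counts((120, 118, 115, 3)))
        assert scope == 1  # channel 1 of 4 -> class >= 1 (any lesion)
        assert mask.sum() == 120

    def test_all_zero_channels_yield_no_lesion(self):
        mask, scope = select_final_channel(np.zeros((2, 4, 8, 8), np.float32))
        assert scope == 0
        assert mask.sum() == 0

    @pytest.mark.parametrize("cls", [1, 2, 3, 4])
    def test_exact_encoding_recovers_class_via_tie_break(self, cls):
        """Nested GT channels tie; the higher-channel tie-break restores
        the encoded class and the exact mask."""
        lm = np.zeros((3, 12, 12), np.int64)
        lm[1, 4:8, 4:8] = cls
        stack = encode_label_map(lm).transpose(1, 0, 2, 3).astype(np.float32)
        mask, scope = select_final_channel(stack)
        assert scope == cls
        np.testing.assert_array_equal(mask, lm > 0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            select_final_channel(np.zeros((4, 8, 8), np.float32))
        with pytest.raises(ValueError):
            select_final_channel(np.full((1, 4, 4, 4), 1.5, np.float32))


class TestSplitLesions:
    def test_two_disjoint_blobs_become_two_findings(self):
        vol = np.zeros((3, 20, 20), bool)
        vol[0:2, 2:6, 2:6] = True
        vol[1:3, 12:16, 12:16] = True
        comps = split_lesions(vol)
        assert len(comps) == 2
        assert sum(c.sum() for c in comps) == vol.sum()

    def test_empty_mask_gives_empty_list(self):
        assert split_lesions(np.zeros((2, 5, 5), bool)) == []

    def test_speckle_below_threshold_discarded(self):
        vol = np.zeros((2, 10, 10), bool)
        vol[0, 0, 0] = True  # 1 voxel < 5
        vol[1, 4:7, 4:7] = True  # 9 voxels
        comps = split_lesions(vol)
        assert len(comps) == 1
        assert sum(c.sum() for c in comps) == vol.sum() - 1


class TestLocateLesion:
    def _zonal(self):
        z = np.zeros((2, 20, 20), np.uint8)
        z[:, 5:15, 2:10] = ZONE_TZ
        z[:, 5:15, 10:18] = ZONE_PZ
        return z

    def test_fully_inside_pz(self):
        lesion = np.zeros((2, 20, 20), bool)
        lesion[:, 6:9, 12:15] = True
        zone, side = locate_lesion(lesion, self._zonal())
        assert zone == "PZ" and side == "right"

    def test_majority_intersection_wins(self):
        lesion = np.zeros((2, 20, 20), bool)
        lesion[0, 6:8, 7:12] = True  # columns 7..11: 3 in TZ, 2 in PZ per row
        zone, _ = locate_lesion(lesion, self._zonal())
        assert zone == "TZ"

    def test_side_by_centroid_with_documented_midline_tie(self):
        zonal = np.full((1, 10, 10), ZONE_PZ, np.uint8)
        left = np.zeros((1, 10, 10), bool)
        left[0, 4, 3:5] = True  # centroid column 3.5 < 5
        assert locate_lesion(left, zonal)[1] == "left"
        tie = np.zeros((1, 10, 10), bool)
        tie[0, 4, 5] = True  # centroid exactly at width/2 -> right
        assert locate_lesion(tie, zonal)[1] == "right"

    def test_extraprostatic_flag(self):
        lesion = np.zeros((1, 10, 10), bool)
        lesion[0, 0, 0] = True
        zone, _ = locate_lesion(lesion, np.zeros((1, 10, 10), np.uint8))
        assert zone == "extraprostatic"

    def test_radiological_convention_swaps_sides(self):
        lesion = np.zeros((1, 10, 10), bool)
        lesion[0, 4, 1] = True
        zonal = np.full((1, 10, 10), ZONE_TZ, np.uint8)
        assert locate_lesion(lesion, zonal)[1] == "left"
        assert locate_lesion(lesion, zonal, radiological=True)[1] == "right"


class TestDimensions:
    def test_fifty_pixels_at_t2_resolution(self):
        mask = np.zeros((1, 10, 10), bool)
        mask.reshape(1, -1)[0, :50] = True
        dims = lesion_dimensions(mask, 0.68, 3.0)
        assert dims["area_mm2"] == pytest.approx(50 * 0.68 ** 2)  # 23.12 mm²
        assert dims["area_mm2"] == pytest.approx(23.12, abs=1e-6)
        assert dims["volume_mm3"] == pytest.approx(50 * 0.68 ** 2 * 3.0)

    def test_area_is_max_over_slices(self):
        mask = np.zeros((2, 8, 8), bool)
        mask[0, :2, :2] = True  # 4 px
        mask[1, :4, :4] = True  # 16 px
        dims = lesion_dimensions(mask, 1.0, 1.0)
        assert dims["area_mm2"] == 16.0
        assert dims["volume_mm3"] == 20.0

    def test_doubling_resolution_quadruples_area(self):
        mask = np.zeros((1, 6, 6), bool)
        mask[0, :3, :3] = True
        a1 = lesion_dimensions(mask, 1.0, 1.0)["area_mm2"]
        a2 = lesion_dimensions(mask, 2.0, 1.0)["area_mm2"]
        assert a2 == 4 * a1

    def test_equivalent_diameter_closed_form(self):
        mask = np.zeros((1, 20, 20), bool)
        mask[0, :10, :10] = True  # 100 px at 1 mm -> d = 2*sqrt(100/pi)
        d = lesion_dimensions(mask, 1.0, 1.0)["equiv_diameter_mm"]
        assert d == pytest.approx(2 * np.sqrt(100 / np.pi))

    def test_invalid_inputs_rejected(self):
        mask = np.zeros((1, 4, 4), bool)
        with pytest.raises(ValueError):
            lesion_dimensions(mask, 1.0, 1.0)  # empty
        mask[0, 0, 0] = True
        with pytest.raises(ValueError):
            lesion_dimensions(mask, -1.0, 1.0)


class TestReport:
    def _finding(self):
        mask = np.zeros((2, 10, 10), bool)
        mask[0, 2:5, 2:5] = True
        return LesionFinding(
            finding_id="finding_1", mask=mask, pirads_scope=3, grade="high",
            grade_probs=(0.2, 0.8), zone="PZ", side="left",
            area_mm2=9.0, volume_mm3=27.0, equiv_diameter_mm=3.39,
            slice_range=(1, 1),
        )

    def test_json_round_trips_losslessly(self, tmp_path):
        paths = generate_report([self._finding()], "case_x", str(tmp_path))
        with open(paths["json"]) as fh:
            payload = json.load(fh)
        assert payload == json.loads(json.dumps(payload))
        assert payload["n_findings"] == 1
        assert payload["findings"][0]["pirads_scope"] == 3

    def test_zero_findings_reports_no_lesion(self, tmp_path):
        paths = generate_report([], "case_y", str(tmp_path))
        with open(paths["json"]) as fh:
            payload = json.load(fh)
        assert payload["no_lesion_detected"] is True
        with open(paths["markdown"]) as fh:
            assert "No lesion detected" in fh.read()

    def test_report_count_matches_findings_and_overlays_written(self, tmp_path):
        findings = [self._finding(), self._finding()]
        t2 = np.random.default_rng(0).uniform(size=(2, 10, 10)).astype(np.float32)
        paths = generate_report(findings, "case_z", str(tmp_path), t2=t2, adc=t2)
        with open(paths["json"]) as fh:
            payload = json.load(fh)
        assert payload["n_findings"] == len(findings)
        assert "overlay_t2" in paths and "overlay_adc" in paths
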