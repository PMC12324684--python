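"""Tests for quantitative immunofluorescence measurement rules."""

import numpy as np
import pytest

from ciliaquant import imaging
from ciliaquant.simulate import SimConfig, simulate_images, roi_from_mask


@pytest.fixture(scope="module")
def clean_field():
    """Noiseless, background-free field of 6 ciliated cells."""
    config = SimConfig(seed=21, image_shape=(512, 512), pixel_size_um=0.1)
    return simulate_images(config, n_cells=6)


class TestMaxProject:
    def test_single_plane_is_identity(self, rng):
        img = rng.uniform(size=(32, 32))
        stack = imaging.ImageStack({"c": img}, pixel_size_um=0.1)
        out = imaging.max_project(stack)
        assert np.array_equal(out.channel("c"), img)

    def test_disjoint_bright_pixels_union(self):
        z = np.zeros((2, 8, 8))
        z[0, 1, 1] = 5.0
        z[1, 6, 6] = 7.0
        out = imaging.max_project(imaging.ImageStack({"c": z}, 0.1))
        assert out.channel("c")[1, 1] == 5.0
        assert out.channel("c")[6, 6] == 7.0

    def test_matches_brute_force_max(self, rng):
        z = rng.uniform(size=(5, 16, 16))
        out = imaging.max_project(imaging.ImageStack({"c": z}, 0.1))
        expected = np.array([[z[:, i, j].max() for j in range(16)] for i in range(16)])
        assert np.allclose(out.channel("c"), expected)


class TestSegmentCilia:
    def test_blank_image_yields_nothing(self):
        stack = imaging.ImageStack({"cilium": np.zeros((64, 64))}, 0.1)
        assert imaging.segment_cilia(stack) == []

    def test_two_disjoint_rods_give_two_rois(self):
        img = np.zeros((128, 128))
        img[20:23, 20:60] = 100.0
        img[90:93, 30:80] = 100.0
        stack = imaging.ImageStack({"cilium": img}, 0.1)
        rois = imaging.segment_cilia(stack, max_px=1000)
        assert len(rois) == 2

    def test_axis_aligned_rod_length_within_one_pixel(self):
        # 40 px end-to-end at 0.1 µm/px -> 4.0 µm
        img = np.zeros((96, 96))
        img[48:51, 20:61] = 100.0
        stack = imaging.ImageStack({"cilium": img}, 0.1)
        rois = imaging.segment_cilia(stack)
        assert len(rois) == 1
        assert 3.9 <= rois[0].skeleton_length_um <= 4.1

    def test_generator_rod_lengths_reasonable(self, clean_field):
        stack, truth = clean_field
        rois = imaging.segment_cilia(stack)
        assert len(rois) == len(truth.image_objects)
        seg = sorted(r.skeleton_length_um for r in rois)
        true = sorted(truth.image_objects["length_um"])
        # 8-connected chain-code lengths carry a known orientation bias of
        # up to ~8% for oblique rods
        for measured, expected in zip(seg, true):
            assert measured == pytest.approx(expected, abs=0.1 + 0.09 * expected)

    def test_base_assigned_to_endpoint_near_nucleus(self, clean_field):
        stack, truth = clean_field
        rois = imaging.segment_cilia(stack)
        for roi in rois:
            assert roi.base_defined
            row = truth.image_objects.iloc[
                ((truth.image_objects["base_y"] - roi.base_yx[0]) ** 2
                 + (truth.image_objects["base_x"] - roi.base_yx[1]) ** 2).idxmin()
                if hasattr((truth.image_objects["base_y"] - roi.base_yx[0]), "idxmin")
                else 0]
            d_base = np.hypot(row["base_y"] - roi.base_yx[0],
                              row["base_x"] - roi.base_yx[1])
            d_tip = np.hypot(row["tip_y"] - roi.base_yx[0],
                             row["tip_x"] - roi.base_yx[1])
            assert d_base < d_tip

    def test_without_nucleus_channel_base_undefined(self):
        img = np.zeros((64, 64))
        img[30:33, 10:50] = 100.0
        stack = imaging.ImageStack({"cilium": img}, 0.1)
        rois = imaging.segment_cilia(stack)
        assert len(rois) == 1
        assert not rois[0].base_defined


class TestMeasureCiliary:
    def test_uniform_image_gives_zero_concentration(self):
        img = np.full((96, 96), 37.0)
        mask = np.zeros((96, 96), bool)
        mask[40:43, 30:60] = True
        roi = roi_from_mask(mask, 0.1)
        stack = imaging.ImageStack({"c": img}, 0.1)
        rec = imaging.measure_ciliary(roi, stack, "c")
        assert rec.concentration == pytest.approx(0.0)

    def test_zero_noise_recovery_is_exact(self, clean_field):
        stack, truth = clean_field
        rois = imaging.segment_cilia(stack)
        for roi in rois:
            rec = imaging.measure_ciliary(roi, stack, "poi")
            assert rec.concentration == pytest.approx(120.0, abs=1e-9)

    def test_linearity_in_channel_scaling(self, clean_field):
        stack, _ = clean_field
        roi = imaging.segment_cilia(stack)[0]
        rec1 = imaging.measure_ciliary(roi, stack, "poi")
        scaled = imaging.ImageStack({"poi": stack.channel("poi") * 3.0},
                                    stack.pixel_size_um)
        rec3 = imaging.measure_ciliary(roi, scaled, "poi")
        assert rec3.concentration == pytest.approx(3.0 * rec1.concentration)

    def test_roi_at_border_is_skipped_with_flag(self):
        img = np.full((40, 40), 10.0)
        mask = np.zeros((40, 40), bool)
        mask[1:38, 1:38] = True  # fills nearly everything: nowhere to shift
        roi = roi_from_mask(mask, 0.1)
        rec = imaging.measure_ciliary(roi, imaging.ImageStack({"c": img}, 0.1), "c")
        assert "no-background" in rec.flags
        assert np.isnan(rec.concentration)

    def test_both_density_conventions_recorded(self, clean_field):
        stack, _ = clean_field
        roi = imaging.segment_cilia(stack)[0]
        rec = imaging.measure_ciliary(roi, stack, "poi")
        assert rec.integrated_density == pytest.approx(
            rec.concentration * roi.area_um2)
        assert rec.mean_over_area == pytest.approx(
            rec.concentration / roi.area_um2)


class TestMeasurePericiliary:
    @pytest.mark.parametrize("pixel_size", [0.05, 0.1])
    def test_disc_area_within_two_percent_of_5um2(self, pixel_size):
        shape = (256, 256)
        disc = imaging.disc_mask(shape, (128, 128),
                                 imaging.PERICILIARY_RADIUS_UM, pixel_size)
        area = disc.sum() * pixel_size ** 2
        assert area == pytest.approx(5.0, rel=0.02)

    def test_uniform_image_measures_zero(self):
        img = np.full((128, 128), 55.0)
        mask = np.zeros((128, 128), bool)
        mask[60:63, 60:90] = True
        roi = roi_from_mask(mask, 0.1, base_yx=(61, 60))
        rec = imaging.measure_periciliary(roi, imaging.ImageStack({"c": img}, 0.1), "c")
        assert rec.periciliary_mean == pytest.approx(0.0)

    def test_known_basal_blob_recovered(self, clean_field):
        stack, truth = clean_field
        row = truth.image_objects.iloc[0]
        mask = stack.channel("cilium") > 0
        roi = roi_from_mask(mask, stack.pixel_size_um,
                            base_yx=(int(row["base_y"]), int(row["base_x"])))
        rec = imaging.measure_periciliary(roi, stack, "basal")
        assert rec.periciliary_mean == pytest.approx(80.0, abs=1e-9)

    def test_disc_outside_image_flagged(self):
        img = np.zeros((64, 64))
        mask = np.zeros((64, 64), bool)
        mask[2:5, 2:30] = True
        roi = roi_from_mask(mask, 0.1, base_yx=(3, 2))
        rec = imaging.measure_periciliary(roi, imaging.ImageStack({"c": img}, 0.1), "c")
        assert "disc-out-of-bounds" in rec.flags


class TestCiliationPercentage:
    @pytest.mark.parametrize("cilia, nuclei, expected",
                             [(5, 10, 50.0), (0, 7, 0.0), (12, 10, 100.0)])
    def test_basic_percentages(self, cilia, nuclei, expected):
        assert imaging.ciliation_percentage(cilia, nuclei) == pytest.approx(expected)

    def test_zero_nuclei_rejected(self):
        with pytest.raises(ValueError):
            imaging.ciliation_percentage(3, 0)

    def test_planted_ciliation_recovered_by_sampling(self):
        rng = np.random.default_rng(31)
        n_cells, p = 500, 0.8
        ciliated = rng.uniform(size=n_cells) < p
        estimate = imaging.ciliation_percentage(int(ciliated.sum()), n_cells)
        assert estimate == pytest.approx(80.0, abs=3.0)


class TestDepleteGate:
    def _records(self, intensities, condition="kd"):
        records = []
        for i, v in enumerate(intensities):
            rec = imaging.MeasurementRecord(cell_id=f"c{i}", condition=condition)
            rec.depletion_intensity = float(v)
            records.append(rec)
        return records

    def test_quartile_gate_flags_upper_three_quarters(self):
        records = self._records(range(1, 101))
        imaging.deplete_gate(records, {"kd"})
        flagged = [r for r in records if "insufficient-depletion" in r.flags]
        assert len(flagged) == 75

    def test_all_equal_intensities_flag_nothing(self):
        records = self._records([5.0] * 10)
        imaging.deplete_gate(records, {"kd"})
        assert not any("insufficient-depletion" in r.flags for r in records)

    def test_control_condition_never_flagged(self):
        records = self._records(range(100), condition="control")
        imaging.deplete_gate(records, {"kd"})
        assert not any(r.flags for r in records)


class TestRoutOutliers:
    def test_gross_outlier_removed(self):
        kept, removed = imaging.rout_outliers([1.0, 1.1, 0.9, 50.0], q_pct=1.0)
        assert list(removed) == [False, False, False, True]

    def test_tight_cluster_all_kept(self, rng):
        values = rng.normal(1.0, 0.05, size=30)
        kept, removed = imaging.rout_outliers(values, q_pct=1.0)
        assert removed.sum() == 0

    def test_q_zero_keeps_everything(self):
        kept, removed = imaging.rout_outliers([1.0, 1.0, 1.0, 99.0], q_pct=0.0)
        assert kept.all()

    def test_small_samples_are_noops(self):
        kept, removed = imaging.rout_outliers([1.0, 99.0], q_pct=1.0)
        assert kept.all()

    def test_reference_grubbs_agreement_on_single_outlier(self, rng):
        # independent check: a single planted outlier that Grubbs' test
        # flags at alpha=0.01 should also be flagged by ROUT at Q=1%
        from scipy import stats as sps
        values = np.concatenate([rng.normal(0, 1, size=20), [15.0]])
        n = len(values)
        g = np.max(np.abs(values - values.mean())) / values.std(ddof=1)
        t2 = sps.t.ppf(1 - 0.01 / (2 * n), n - 2) ** 2
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))
        assert g > g_crit  # Grubbs agrees it is an outlier
        _, removed = imaging.rout_outliers(values, q_pct=1.0)
        assert removed[-1]


class TestNormalizeToControl:
    def _records(self, values, condition, replicate="r1"):
        out = []
        for i, v in enumerate(values):
            rec = imaging.MeasurementRecord(cell_id=f"{condition}{i}",
                                            condition=condition, replicate=replicate)
            rec.concentration = float(v)
            out.append(rec)
        return out

    def test_control_mean_becomes_one(self):
        records = self._records([2.0, 4.0], "control") + self._records([1.5], "kd")
        imaging.normalize_to_control(records, "control")
        control_norm = [r.normalized for r in records if r.condition == "control"]
        assert np.mean(control_norm) == pytest.approx(1.0, abs=1e-9)
        assert records[2].normalized == pytest.approx(0.5)

    def test_idempotent_after_first_application(self):
        records = self._records([2.0, 4.0, 3.0], "control")
        imaging.normalize_to_control(records, "control")
        first = [r.normalized for r in records]
        for r in records:
            r.concentration = r.normalized
        imaging.normalize_to_control(records, "control")
        assert [r.normalized for r in records] == pytest.approx(first)

    def test_per_replicate_normalization(self):
        records = (self._records([2.0], "control", "r1")
                   + self._records([8.0], "control", "r2")
                   + self._records([1.0], "kd", "r1")
                   + self._records([1.0], "kd", "r2"))
        imaging.normalize_to_control(records, "control")
        assert records[2].normalized == pytest.approx(0.5)
        assert records[3].normalized == pytest.approx(0.125)

    def test_zero_control_mean_rejected(self):
        records = self._records([0.0, 0.0], "control")
        with pytest.raises(ValueError):
            imaging.normalize_to_control(records, "control")
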