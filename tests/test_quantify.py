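"""Per-cell measurement engines, QC and marker calls."""

import numpy as np
import pytest

from somaquant.imaging import MultiChannelImage
from somaquant.postprocess import estimate_background
from somaquant.quantify import (CellRecord, MarkerThreshold, QCCriteria,
                                classify_marker, count_dots, measure_bf,
                                measure_rf, qc_filter, segment_cells)
from somaquant.synth import ImageSpec, generate_cell_image


def records_from_truth(truth, pixel_size_um=1.0):
    """Geometry records built directly from generator truth masks."""
    recs = []
    for cell in truth.cells:
        cid = cell["id"]
        body = truth.body_labels.labels == cid
        nuc = truth.nucleus_labels.labels == cid
        rec = CellRecord(cell_id=cid, body_mask=body,
                         nucleus_mask=nuc if nuc.any() else None,
                         pixel_size_um=pixel_size_um,
                         centroid=cell["center"])
        rec.area_um2["body"] = float(body.sum()) * pixel_size_um ** 2
        recs.append(rec)
    return recs


class TestSegmentCells:
    def test_disjoint_cells_found_with_nuclei_inside(self, cell_model):
        spec = ImageSpec(shape=(192, 192), n_cells=8, seed=55)
        img, truth = generate_cell_image(spec)
        records = segment_cells(img, cell_model)
        assert len(records) == 8
        for rec in records:
            assert rec.nucleus_mask is not None
            assert np.all(rec.body_mask[rec.nucleus_mask])

    def test_blank_image_gives_empty_list(self, cell_model, rng):
        blank = MultiChannelImage(
            np.clip(rng.normal(0.05, 0.01, (96, 96, 3)), 0, 1),
            ["marker", "nuclear", "target"])
        assert segment_cells(blank, cell_model) == []

    def test_touching_cells_separated_by_watershed(self, cell_model):
        spec = ImageSpec(shape=(160, 160), n_cells=2, overlap_fraction=1.0,
                         cell_radius=(12, 14), seed=21)
        img, truth = generate_cell_image(spec)
        assert len(truth.cells) == 2
        records = segment_cells(img, cell_model)
        assert len(records) == 2


class TestCountDots:
    def test_zero_planted_dots_counts_zero(self):
        spec = ImageSpec(shape=(96, 96), n_cells=3, dots_per_cell=0, seed=2)
        img, truth = generate_cell_image(spec)
        recs = count_dots(img, records_from_truth(truth), truth.dot_mask)
        assert all(r.dot_count == 0 for r in recs)

    def test_well_separated_dots_counted_exactly(self):
        spec = ImageSpec(shape=(256, 256), n_cells=6, dots_per_cell=25,
                         cell_radius=(16, 20), dot_min_separation=9.0, seed=4)
        img, truth = generate_cell_image(spec)
        recs = count_dots(img, records_from_truth(truth), truth.dot_mask,
                          min_dot_area=2)
        for rec in recs:
            assert rec.dot_count == truth.dot_count(rec.cell_id)

    def test_fused_dot_pair_split_by_watershed(self):
        # two dots 5 px apart form one connected component with two EDT peaks
        img = MultiChannelImage(np.zeros((40, 40, 1)), ["target"])
        dot_mask = np.zeros((40, 40), bool)
        yy, xx = np.ogrid[:40, :40]
        for cx in (18, 23):
            dot_mask |= (xx - cx) ** 2 + (yy - 20) ** 2 <= 3 ** 2
        body = np.zeros((40, 40), bool)
        body[5:35, 5:35] = True
        rec = CellRecord(cell_id=1, body_mask=body)
        count_dots(img, [rec], dot_mask, min_dot_area=2, min_peak_distance=3)
        assert rec.dot_count == 2

    def test_dots_outside_cells_ignored(self):
        img = MultiChannelImage(np.zeros((30, 30, 1)), ["target"])
        dot_mask = np.zeros((30, 30), bool)
        dot_mask[2:5, 2:5] = True  # far from the body
        body = np.zeros((30, 30), bool)
        body[15:25, 15:25] = True
        rec = CellRecord(cell_id=1, body_mask=body)
        count_dots(img, [rec], dot_mask)
        assert rec.dot_count == 0

    def test_total_counts_never_exceed_planted(self):
        spec = ImageSpec(shape=(192, 192), n_cells=5, seed=6)
        img, truth = generate_cell_image(spec)
        recs = count_dots(img, records_from_truth(truth), truth.dot_mask)
        planted = sum(len(c["dot_centers"]) for c in truth.cells)
        assert sum(r.dot_count for r in recs) <= planted


class TestMeasureBf:
    def test_planted_transmission_recovered(self):
        spec = ImageSpec(shape=(128, 128), n_cells=4,
                         transmission=(0.5, 0.5), noise_sd=0.005,
                         background_level=0.0, seed=8)
        img, truth = generate_cell_image(spec)
        recs = measure_bf(img, records_from_truth(truth))
        for rec in recs:
            assert rec.bf_transmission == pytest.approx(0.5, abs=0.05)
            assert 0 < rec.bf_transmission <= 1.0

    def test_blank_region_cell_has_zero_attenuation(self):
        bf = np.full((40, 40), 0.9)
        img = MultiChannelImage(bf[:, :, None], ["brightfield"])
        body = np.zeros((40, 40), bool)
        body[10:20, 10:20] = True
        rec = CellRecord(cell_id=1, body_mask=body)
        measure_bf(img, [rec])
        assert rec.bf_intensity == pytest.approx(0.0, abs=1e-9)
        assert rec.bf_transmission == pytest.approx(1.0)

    def test_missing_channel_raises(self, rng):
        img = MultiChannelImage(rng.random((10, 10, 1)), ["marker"])
        with pytest.raises(KeyError):
            measure_bf(img, [])


class TestMeasureRf:
    def make_scene(self, signal, bg_value=0.1):
        pixels = np.full((40, 40, 1), bg_value)
        body = np.zeros((40, 40), bool)
        body[10:25, 10:25] = True
        pixels[body, 0] = signal
        img = MultiChannelImage(pixels, ["target"])
        rec = CellRecord(cell_id=1, body_mask=body)
        bg = estimate_background(img, exclude_mask=body,
                                 threshold=40 / 255)
        return img, rec, bg

    def test_ratio_of_five(self):
        img, rec, bg = self.make_scene(signal=0.5)
        measure_rf(img, [rec], bg)
        assert rec.rf["target"]["body"] == pytest.approx(5.0, rel=1e-6)

    def test_background_equal_compartment_gives_one(self):
        img, rec, bg = self.make_scene(signal=0.1)
        measure_rf(img, [rec], bg)
        assert rec.rf["target"]["body"] == pytest.approx(1.0, rel=1e-6)

    def test_global_gain_invariance(self):
        img1, rec1, bg1 = self.make_scene(signal=0.08, bg_value=0.04)
        measure_rf(img1, [rec1], bg1)
        img2, rec2, bg2 = self.make_scene(signal=0.16, bg_value=0.08)
        measure_rf(img2, [rec2], bg2)
        assert rec1.rf["target"]["body"] == \
            pytest.approx(rec2.rf["target"]["body"], rel=1e-6)

    def test_saturated_compartment_flagged(self):
        img, rec, bg = self.make_scene(signal=1.0)
        measure_rf(img, [rec], bg)
        assert rec.rf_unreliable["target"]["body"]


class TestQcFilter:
    def base_record(self, shape=(60, 60)):
        body = np.zeros(shape, bool)
        body[20:40, 20:40] = True
        nuc = np.zeros(shape, bool)
        nuc[25:35, 25:35] = True
        rec = CellRecord(cell_id=1, body_mask=body, nucleus_mask=nuc)
        rec.area_um2["body"] = float(body.sum())
        return rec

    def test_clean_cell_included(self):
        rec = self.base_record()
        qc_filter([rec])
        assert rec.qc_included and rec.exclusion_reasons == []

    def test_border_contact_excluded(self):
        rec = self.base_record()
        rec.body_mask[0, 25:30] = True
        qc_filter([rec])
        assert not rec.qc_included
        assert "border" in rec.exclusion_reasons

    def test_missing_nucleus_excluded(self):
        rec = self.base_record()
        rec.nucleus_mask = None
        qc_filter([rec])
        assert "no_nucleus" in rec.exclusion_reasons

    def test_size_bounds_enforced(self):
        rec = self.base_record()
        qc_filter([rec], QCCriteria(min_area_um2=1000.0, max_area_um2=2000.0))
        assert "size" in rec.exclusion_reasons

    def test_planted_violations_among_clean_cells(self):
        records = [self.base_record() for _ in range(10)]
        for rec, cid in zip(records, range(1, 11)):
            rec.cell_id = cid
        records[1].body_mask[:, 0] = True       # border
        records[4].nucleus_mask = None          # no nucleus
        records[7].area_um2["body"] = 10.0      # too small
        qc_filter(records)
        excluded = {r.cell_id for r in records if not r.qc_included}
        assert excluded == {2, 5, 8}


class TestClassifyMarker:
    def record_with_rf(self, rf):
        rec = CellRecord(cell_id=1, body_mask=np.ones((4, 4), bool))
        rec.rf["DAT"] = {"body": rf}
        return rec

    def test_rf_at_background_mean_is_negative(self):
        thr = MarkerThreshold("DAT", k=2.0, bg_mean=1.0, bg_sd=0.2)
        rec = self.record_with_rf(1.0)
        classify_marker([rec], thr)
        assert rec.marker_calls["DAT"] == "negative"

    def test_three_sd_above_with_k25_is_positive(self):
        thr = MarkerThreshold("DAT", k=2.5, bg_mean=1.0, bg_sd=0.2)
        rec = self.record_with_rf(1.0 + 3 * 0.2)
        classify_marker([rec], thr)
        assert rec.marker_calls["DAT"] == "positive"

    def test_exactly_at_threshold_is_negative(self):
        thr = MarkerThreshold("DAT", k=2.0, bg_mean=1.0, bg_sd=0.25)
        rec = self.record_with_rf(thr.threshold)
        classify_marker([rec], thr)
        assert rec.marker_calls["DAT"] == "negative"

    def test_missing_rf_raises(self):
        thr = MarkerThreshold("DAT", k=2.0, bg_mean=1.0, bg_sd=0.2)
        rec = CellRecord(cell_id=1, body_mask=np.ones((4, 4), bool))
        with pytest.raises(ValueError, match="not computed"):
            classify_marker([rec], thr)

    def test_planted_negative_fraction_recovered_within_ci(self, rng):
        # synthetic cohort: 5% of cells at background-level RF
        n = 2000
        negative = rng.random(n) < 0.05
        rf = np.where(negative, 1.0 + np.abs(rng.normal(0, 0.05, n)),
                      3.0 + rng.normal(0, 0.3, n))
        thr = MarkerThreshold("DAT", k=2.0, bg_mean=1.0, bg_sd=0.15)
        records = []
        for i, v in enumerate(rf):
            rec = CellRecord(cell_id=i, body_mask=np.ones((2, 2), bool))
            rec.rf["DAT"] = {"body": float(v)}
            records.append(rec)
        classify_marker(records, thr)
        called_neg = np.array([r.marker_calls["DAT"] == "negative"
                               for r in records])
        p_hat = called_neg.mean()
        se = np.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(p_hat - negative.mean()) < 2 * se + 0.01
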