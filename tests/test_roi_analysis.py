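"""Stepwise ROI funnel: exclusion, detection, classification, profiles."""

import numpy as np
import pytest

import goldsip as g
from goldsip.imaging import ratio_map
from goldsip.model import RoiCategory, SpeciesLabel
from goldsip.roi_analysis import (
    RoiConfig,
    detect_candidates,
    early_window,
    exclusion_mask,
    first_detection_cycle,
    funnel_counts,
    roi_cycle_profile,
)


def iou(mask_a, mask_b):
    return (mask_a & mask_b).sum() / (mask_a | mask_b).sum()


class TestExclusionMask:
    def test_planted_trench_is_excluded(self):
        cfg = g.ScenarioConfig(pixel_shape=(128, 128), n_cycles=6, n_cells=6,
                               n_trenches=1, trench_size_px=(25, 30), seed=11)
        session, truth = g.simulate_session(cfg)
        excl = exclusion_mask(session, RoiConfig())
        overlap = (excl & truth.excluded_region_mask).sum()
        assert overlap / truth.excluded_region_mask.sum() >= 0.95

    def test_session_without_se_uses_c_rule_only(self):
        cfg = g.ScenarioConfig(pixel_shape=(64, 64), n_cycles=3, n_cells=2,
                               n_trenches=0, seed=12)
        session, _ = g.simulate_session(cfg)
        del session.stacks[SpeciesLabel.SE]
        excl = exclusion_mask(session, RoiConfig())
        assert excl.shape == (64, 64)  # runs on the C12 rule alone


class TestDetectCandidates:
    def test_blank_map_gives_empty_list(self):
        m = g.RatioMap(values=np.zeros((32, 32)), numerator="AU197_1",
                       denominator="C12", cycle_range=(1, 1),
                       validity=np.ones((32, 32), bool))
        assert detect_candidates(m, np.zeros((32, 32), bool), RoiConfig()) == []

    def test_planted_cells_recovered_without_background_junk(self):
        cfg = g.ScenarioConfig(pixel_shape=(256, 256), n_cycles=12, n_cells=20,
                               n_gold_specks=0, n_trenches=0, seed=13)
        session, truth = g.simulate_session(cfg)
        processed, _ = g.preprocess(session)
        rc = RoiConfig()
        excl = exclusion_mask(processed, rc)
        am = ratio_map(processed, "AU197_1", "C12", early_window(processed, rc))
        rois = detect_candidates(am, excl, rc)
        shape = session.pixel_shape
        cell_masks = [c.mask(shape) for c in truth.cells]
        matched = sum(
            any(iou(cm, r.mask(shape)) >= 0.3 for r in rois) for cm in cell_masks
        )
        assert matched >= 18
        # detections not matching any planted cell = false positives
        fp = sum(
            not any(iou(cm, r.mask(shape)) >= 0.3 for cm in cell_masks)
            for r in rois
        )
        assert fp <= 1

    def test_large_cluster_is_omitted(self):
        vals = np.zeros((64, 64))
        vals[10:40, 10:40] = 1.0  # 900 px blob, above max_area_px
        vals[50:54, 50:54] = 1.0  # cell-sized blob
        m = g.RatioMap(values=vals, numerator="AU197_1", denominator="C12",
                       cycle_range=(1, 1), validity=np.ones((64, 64), bool))
        rc = RoiConfig(au_ratio_threshold=0.5, au_min_counts=0, trim_radius=0,
                       closing_radius=0)
        rois = detect_candidates(m, np.zeros((64, 64), bool), rc)
        assert len(rois) == 1
        assert rois[0].area_px == 16

    def test_ordering_is_deterministic_top_left_first(self):
        vals = np.zeros((32, 32))
        vals[20:24, 2:6] = 1.0
        vals[2:6, 20:24] = 1.0
        m = g.RatioMap(values=vals, numerator="AU197_1", denominator="C12",
                       cycle_range=(1, 1), validity=np.ones((32, 32), bool))
        rc = RoiConfig(au_ratio_threshold=0.5, au_min_counts=0, trim_radius=0,
                       closing_radius=0)
        rois = detect_candidates(m, np.zeros((32, 32), bool), rc)
        assert [r.bbox_key() for r in rois] == sorted(r.bbox_key() for r in rois)
        assert rois[0].id == "roi_0001"

    def test_translation_equivariance(self):
        cfg = g.ScenarioConfig(pixel_shape=(128, 128), n_cycles=6, n_cells=5,
                               n_trenches=0, n_gold_specks=0, drift_max_step=0,
                               seed=14)
        session, _ = g.simulate_session(cfg)
        rc = RoiConfig()
        shift = (5, 3)
        shifted = session.copy()
        for lab in shifted.stacks:
            shifted.stacks[lab].planes = np.roll(
                shifted.stacks[lab].planes, shift, axis=(1, 2)
            )

        def detect(s):
            excl = exclusion_mask(s, rc)
            am = ratio_map(s, "AU197_1", "C12", early_window(s, rc))
            return detect_candidates(am, excl, rc)

        base = detect(session)
        moved = detect(shifted)
        assert len(base) == len(moved)
        for rb, rm in zip(base, moved):
            expected = {(r + shift[0], c + shift[1]) for r, c in map(tuple, rb.pixels)}
            assert expected == set(map(tuple, rm.pixels))


class TestClassification:
    def test_zero_phosphorus_stays_au_only(self, processed):
        # specks carry gold but no biomass: they must not pass the P screen
        result, truth = processed
        speck_rois = [r for r in result.rois
                      if not any(
                          iou(c.mask(result.session.pixel_shape),
                              r.mask(result.session.pixel_shape)) >= 0.3
                          for c in truth.cells)]
        assert speck_rois, "scenario should produce non-cell gold candidates"
        assert all(r.category is RoiCategory.AU_ONLY for r in speck_rois)

    def test_enriched_cells_reach_top_category(self):
        cfg = g.ScenarioConfig(pixel_shape=(256, 256), n_cycles=12, n_cells=20,
                               enrichment_dist="point", enrichment_point_atpct=3.0,
                               fraction_unlabeled=0.0, n_gold_specks=0,
                               n_trenches=0, seed=15)
        session, truth = g.simulate_session(cfg)
        control = g.ControlStats(0.362, 0.045)
        result = g.process_session(session, control)
        shape = session.pixel_shape
        matched = [
            r for r in result.rois
            if any(iou(c.mask(shape), r.mask(shape)) >= 0.3 for c in truth.cells)
        ]
        top = sum(r.category is RoiCategory.AU_P_N15 for r in matched)
        assert top / len(matched) >= 0.95

    def test_funnel_monotone(self, processed):
        result, _ = processed
        f = result.funnel
        assert f["au_p_n15"] <= f["au_p"] <= f["candidates"]

    def test_funnel_counts_consistent_with_categories(self, processed):
        result, _ = processed
        assert funnel_counts(result.rois) == result.funnel


class TestCycleProfiles:
    def test_all_zero_roi_gives_zero_series(self):
        cfg = g.ScenarioConfig(pixel_shape=(32, 32), n_cycles=4, n_cells=0,
                               n_trenches=0, n_gold_specks=0, seed=16,
                               background_rates={"C12": 0.0, "CN": 0.0, "AU": 0.0,
                                                 "C12_2": 0.0, "P31": 0.0, "SE": 0.0})
        session, _ = g.simulate_session(cfg)
        roi = g.Roi(id="r", pixels=np.array([[5, 5], [5, 6]]))
        prof = roi_cycle_profile(roi, session)
        assert prof["AU197_1"].sum() == 0
        assert np.isnan(prof["atpct"]).all()

    def test_gold_detected_before_n15(self, paper_like, control):
        cfg, session, truth = paper_like
        processed, _ = g.preprocess(session)
        late_onset = [c for c in truth.cells
                      if c.n15_onset_cycle >= 4 and c.true_atpct > 2.0]
        assert late_onset
        cell = late_onset[0]
        roi = g.Roi(id="t", pixels=cell.pixels)
        prof = roi_cycle_profile(roi, processed)
        au_first = first_detection_cycle(
            prof["AU197_1"], threshold=prof["AU197_1"].max() * 0.2)
        n15_first = first_detection_cycle(
            prof["atpct"], threshold=control.threshold_atpct)
        assert au_first is not None and n15_first is not None
        assert au_first <= n15_first

    def test_onset_cycle_recovered_within_two_cycles(self, paper_like, control):
        _, session, truth = paper_like
        processed, _ = g.preprocess(session)
        for cell in truth.cells:
            if cell.true_atpct < 2.0:
                continue
            roi = g.Roi(id="t", pixels=cell.pixels)
            prof = roi_cycle_profile(roi, processed)
            onset = first_detection_cycle(prof["atpct"], control.threshold_atpct)
            assert onset is not None
            assert abs(onset - cell.n15_onset_cycle) <= 2


class TestFirstDetection:
    def test_never_exceeding_returns_none(self):
        assert first_detection_cycle(np.array([1.0, 2.0, 3.0]), 5.0) is None

    def test_m_consecutive_rule(self):
        assert first_detection_cycle(np.array([0, 0, 5, 6, 7]), 4.0, 2) == 3

    def test_single_spike_does_not_trigger_m2(self):
        assert first_detection_cycle(np.array([0, 9, 0, 0]), 4.0, 2) is None
        assert first_detection_cycle(np.array([0, 9, 0, 0]), 4.0, 1) == 2
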