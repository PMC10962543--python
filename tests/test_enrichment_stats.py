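"""Isotope statistics: at%, Poisson error, 6σ rule, dilution, summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import goldsip as g
from goldsip.enrichment_stats import (
    atpercent,
    compare_areas,
    correct_dilution,
    dilution_factor,
    estimate_label_loss,
    fit_control,
    is_enriched,
    poisson_sigma,
    roi_enrichment,
    summarize_area,
)
from goldsip.model import ControlStats, EnrichmentResult


class TestAtPercent:
    def test_equal_counts_give_fifty(self):
        assert atpercent(100, 100) == 50.0

    def test_zero_n15_gives_zero(self):
        assert atpercent(0, 1000) == 0.0

    def test_natural_abundance_counts(self):
        assert atpercent(366, 99634) == pytest.approx(0.366)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            atpercent(0, 0)

    @given(st.integers(1, 10**6), st.integers(1, 10**6))
    def test_monotone_in_n15(self, n15, n14):
        assert atpercent(n15 + 1, n14) > atpercent(n15, n14)


class TestPoissonSigma:
    def test_closed_form_at_symmetric_counts(self):
        assert poisson_sigma(100, 100) == pytest.approx(100 * np.sqrt(1e4 / 8e6))

    def test_zero_count_boundary(self):
        assert poisson_sigma(0, 500) == 0.0

    @pytest.mark.parametrize("n15,n14", [(50, 10_000), (100, 100), (500, 50_000)])
    def test_matches_monte_carlo_sd(self, n15, n14, rng):
        draws15 = rng.poisson(n15, size=100_000)
        draws14 = rng.poisson(n14, size=100_000)
        total = draws15 + draws14
        ok = total > 0
        mc_sd = (100.0 * draws15[ok] / total[ok]).std()
        assert poisson_sigma(n15, n14) == pytest.approx(mc_sd, rel=0.05)


class TestControlFit:
    def test_threshold_arithmetic(self):
        c = ControlStats(mean_atpct=0.362, sd_atpct=0.045, k_sigma=6.0)
        assert c.threshold_atpct == pytest.approx(0.632)
        assert f"{c.threshold_atpct:.2f}" == "0.63"

    def test_identical_values_have_zero_sd(self):
        c = fit_control([0.36, 0.36, 0.36])
        assert c.sd_atpct == 0.0
        assert c.threshold_atpct == pytest.approx(0.36)

    def test_rejects_fewer_than_two(self):
        with pytest.raises(ValueError):
            fit_control([0.362])

    def test_synthetic_unlabeled_cells_recover_natural_abundance(self, rng):
        vals = g.simulate_single_cells(60, g.NATURAL_ABUNDANCE_ATPCT, 18_000, rng)
        c = fit_control(vals)
        se = c.sd_atpct / np.sqrt(c.n_cells)
        assert abs(c.mean_atpct - g.NATURAL_ABUNDANCE_ATPCT) < 3 * se


class TestSignificanceRule:
    def test_value_at_control_mean_is_not_enriched(self, control):
        assert not is_enriched(0.362, 0.001, control)

    def test_high_enrichment_with_small_sigma(self, control):
        assert is_enriched(4.82, 0.05, control)

    def test_clause_two_can_veto(self, control):
        # 0.70 > 0.632 passes clause 1, but 6σ = 0.6 exceeds 0.70−0.362
        assert not is_enriched(0.70, 0.10, control)

    def test_increasing_n15_never_flips_to_not_enriched(self, control):
        n14 = 50_000
        flags = []
        for n15 in range(200, 4000, 100):
            flags.append(is_enriched(atpercent(n15, n14),
                                     poisson_sigma(n15, n14), control))
        # once enriched, more 15N keeps it enriched
        first_true = flags.index(True)
        assert all(flags[first_true:])


class TestRoiEnrichment:
    def test_planted_cell_recovered_within_three_sigma(self, paper_like, control):
        _, session, truth = paper_like
        processed, _ = g.preprocess(session)
        cell = max(truth.cells, key=lambda c: c.true_atpct)
        roi = g.Roi(id="t", pixels=cell.pixels)
        res = roi_enrichment(roi, processed, (1, session.n_cycles), control)
        expected = cell.expected_atpct((1, session.n_cycles))
        assert abs(res.atpct_raw - expected) < 3 * res.sigma_poisson

    def test_cycle_range_restricts_contribution(self, paper_like, control):
        _, session, _ = paper_like
        processed, _ = g.preprocess(session)
        roi = g.Roi(id="t", pixels=np.array([[100, 100], [100, 101]]))
        res_sub = roi_enrichment(roi, processed, (2, 4), control)
        n14 = g.enrichment_stats.roi_counts(roi, processed, "C12N14", (1, processed.n_cycles))
        assert res_sub.n14_counts == pytest.approx(n14[1:4].sum())

    def test_zero_count_roi_flagged_invalid(self):
        cfg = g.ScenarioConfig(pixel_shape=(32, 32), n_cycles=2, n_cells=0,
                               n_trenches=0, n_gold_specks=0, seed=2,
                               background_rates={"C12": 1.0, "CN": 0.0, "AU": 0.1,
                                                 "C12_2": 1.0, "P31": 0.0, "SE": 1.0})
        session, _ = g.simulate_session(cfg)
        roi = g.Roi(id="r", pixels=np.array([[3, 3]]))
        res = roi_enrichment(roi, session, (1, 2), ControlStats(0.362, 0.045))
        assert not res.valid and not res.enriched

    def test_sum_and_cycle_mean_agree_for_homogeneous_signal(self, control, rng):
        n14 = rng.poisson(5000, size=(10, 4, 4))
        n15 = rng.poisson(150, size=(10, 4, 4))
        from goldsip.model import (AcquisitionSession, IonImageStack,
                                   SpeciesLabel, default_species_table)
        table = {sp.label: sp for sp in default_species_table()}
        s = AcquisitionSession(stacks={
            SpeciesLabel.C12N14: IonImageStack(table[SpeciesLabel.C12N14], n14),
            SpeciesLabel.C15N: IonImageStack(table[SpeciesLabel.C15N], n15),
        })
        roi = g.Roi(id="r", pixels=np.array([[r, c] for r in range(4) for c in range(4)]))
        a = roi_enrichment(roi, s, (1, 10), control, method="sum")
        b = roi_enrichment(roi, s, (1, 10), control, method="cycle_mean")
        assert a.atpct_raw == pytest.approx(b.atpct_raw, rel=0.02)


class TestDilution:
    def test_factor_full_precision(self):
        m = dilution_factor(0.39)
        assert m.factor == pytest.approx(1 / 0.61)

    def test_boundary_values(self):
        assert dilution_factor(0.0).factor == 1.0
        assert dilution_factor(0.5).factor == 2.0
        with pytest.raises(ValueError):
            dilution_factor(1.0)

    @pytest.mark.parametrize("raw,display", [
        (2.05, "3.36"), (7.36, "12.07"), (1.77, "2.90"), (2.16, "3.54"),
    ])
    def test_corrected_display_values(self, raw, display):
        model = dilution_factor(0.39)
        res = EnrichmentResult(roi_id="r", atpct_raw=raw, sigma_poisson=0.01,
                               enriched=True, cycle_range=(1, 95))
        out = correct_dilution(res, model)
        assert f"{np.round(out.atpct_corrected, 2):.2f}" == display

    def test_factor_one_is_identity(self):
        res = EnrichmentResult(roi_id="r", atpct_raw=1.5, sigma_poisson=0.01,
                               enriched=True, cycle_range=(1, 1))
        assert correct_dilution(res, dilution_factor(0.0)).atpct_corrected == 1.5

    def test_nonphysical_correction_raises(self):
        res = EnrichmentResult(roi_id="r", atpct_raw=80.0, sigma_poisson=0.01,
                               enriched=True, cycle_range=(1, 1))
        with pytest.raises(ValueError):
            correct_dilution(res, dilution_factor(0.5))

    def test_correction_commutes_with_averaging(self, rng):
        raws = rng.uniform(0.5, 5.0, size=20)
        model = dilution_factor(0.39)
        results = [
            correct_dilution(
                EnrichmentResult(roi_id=str(i), atpct_raw=v, sigma_poisson=0.01,
                                 enriched=True, cycle_range=(1, 1)), model)
            for i, v in enumerate(raws)
        ]
        mean_of_corrected = np.mean([r.atpct_corrected for r in results])
        assert mean_of_corrected == pytest.approx(raws.mean() * model.factor)


class TestLabelLoss:
    def test_direct_arithmetic(self):
        assert estimate_label_loss([6.1], [10.0]) == pytest.approx(0.39)

    def test_identical_lists_give_zero(self):
        assert estimate_label_loss([2.0, 3.0], [2.0, 3.0]) == 0.0

    def test_planted_forty_percent_loss_recovered(self, rng):
        true = 10.0
        untreated = g.simulate_single_cells(40, true, 20_000, rng)
        treated = g.simulate_single_cells(40, true * 0.6, 20_000, rng)
        loss = estimate_label_loss(treated, untreated)
        se_t = treated.std(ddof=1) / np.sqrt(len(treated))
        se_u = untreated.std(ddof=1) / np.sqrt(len(untreated))
        ratio = treated.mean() / untreated.mean()
        se_loss = ratio * np.hypot(se_t / treated.mean(), se_u / untreated.mean())
        assert abs(loss - 0.40) < 3 * se_loss

    def test_zero_untreated_mean_raises(self):
        with pytest.raises(ValueError):
            estimate_label_loss([1.0], [0.0])


class TestSummaries:
    def test_single_roi_degenerate_summary(self):
        r = EnrichmentResult(roi_id="a", atpct_raw=2.0, sigma_poisson=0.01,
                             enriched=True, cycle_range=(1, 1))
        s = summarize_area([r], "AA1")
        assert s.mean == s.median == s.max == 2.0 and s.n_rois == 1

    def test_three_values(self):
        rs = [EnrichmentResult(roi_id=str(v), atpct_raw=float(v), sigma_poisson=0.01,
                               enriched=True, cycle_range=(1, 1)) for v in (1, 2, 3)]
        s = summarize_area(rs, "AA1")
        assert (s.mean, s.median, s.max) == (2.0, 2.0, 3.0)
        assert s.q1 <= s.median <= s.q3 <= s.max

    def test_pooled_mean_is_weighted_mean_of_area_means(self, rng):
        groups = {a: rng.uniform(1, 4, size=n)
                  for a, n in [("AA1", 30), ("AA2", 17), ("AA3", 26)]}
        summaries = {}
        for a, vals in groups.items():
            rs = [EnrichmentResult(roi_id=f"{a}{i}", atpct_raw=float(v),
                                   sigma_poisson=0.01, enriched=True,
                                   cycle_range=(1, 1))
                  for i, v in enumerate(vals)]
            summaries[a] = summarize_area(rs, a)
        pooled = np.concatenate(list(groups.values())).mean()
        weighted = (sum(s.mean * s.n_rois for s in summaries.values())
                    / sum(s.n_rois for s in summaries.values()))
        assert pooled == pytest.approx(weighted)

    def test_no_valid_results_raises(self):
        bad = EnrichmentResult(roi_id="x", atpct_raw=0.0, sigma_poisson=0.0,
                               enriched=False, cycle_range=(1, 1), valid=False)
        with pytest.raises(ValueError):
            summarize_area([bad], "AA9")


class TestCompareAreas:
    def test_identical_groups_give_f_near_zero(self):
        rep = compare_areas({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert rep["anova"]["F"] == pytest.approx(0.0, abs=1e-12)
        assert rep["anova"]["p"] > 0.99

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)  # 5σ shift
        rep = compare_areas({"a": a.tolist(), "b": b.tolist()})
        assert rep["anova"]["p"] < 0.001
        assert rep["tukey"][0]["p_adj"] < 0.001

    def test_type_one_error_calibration(self, rng):
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            gs = {k: rng.normal(0, 1, 10) for k in ("a", "b", "c")}
            if compare_areas(gs)["anova"]["p"] < 0.05:
                hits += 1
        assert 0.03 <= hits / n_rep <= 0.07

    def test_degenerate_group_raises(self):
        with pytest.raises(ValueError):
            compare_areas({"a": [1.0], "b": [1.0, 2.0]})
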