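"""Tests for the quartile-restricted cutoff scan and its selection rule."""

import json

import numpy as np
import pytest

import exprsurv as es
from exprsurv.cutscan import CutoffResult, EmptyScanError, select_cutoff
from exprsurv.survival import ValidationError, bh_fdr, cox_fit


class TestCandidateCutoffs:
    def test_interquartile_candidates_linear_convention(self):
        # Q1 = 2.75, Q3 = 6.25 under linear interpolation
        cands = es.candidate_cutoffs(
            [1, 2, 3, 4, 5, 6, 7, 8], es.ScanConfig(min_group_size=1)
        )
        np.testing.assert_array_equal(cands, [3, 4, 5, 6])

    def test_all_identical_values_unscannable(self):
        with pytest.raises(EmptyScanError):
            es.candidate_cutoffs([2.0] * 10, es.ScanConfig(min_group_size=1))

    def test_duplicates_collapse_to_single_candidates(self):
        cands = es.candidate_cutoffs(
            [1, 3, 3, 3, 4, 4, 5, 8], es.ScanConfig(min_group_size=1)
        )
        assert np.unique(cands).size == cands.size

    def test_min_group_size_prunes_tail_strata(self):
        expr = np.arange(1.0, 21.0)
        wide = es.candidate_cutoffs(expr, es.ScanConfig(min_group_size=1))
        narrow = es.candidate_cutoffs(expr, es.ScanConfig(min_group_size=8))
        assert set(narrow) <= set(wide)
        for v in narrow:
            assert (expr <= v).sum() >= 8 and (expr > v).sum() >= 8


def _row(cutoff, hr, p, q):
    return CutoffResult(cutoff=cutoff, n_low=10, n_high=10, hazard_ratio=hr, p_value=p, fdr_q=q)


class TestSelectionRule:
    def test_tied_fdr_resolved_by_highest_hazard_ratio(self):
        rows = [
            _row(0.1, 1.5, 0.010, 0.20),
            _row(0.2, 2.0, 0.002, 0.05),
            _row(0.3, 3.0, 0.002, 0.05),
        ]
        selected, reason = select_cutoff(rows)
        assert selected.cutoff == 0.3
        assert reason == "hr_tiebreak"

    def test_unique_minimum_needs_no_tiebreak(self):
        rows = [_row(0.1, 1.5, 0.01, 0.03), _row(0.2, 9.0, 0.02, 0.06)]
        selected, reason = select_cutoff(rows)
        assert selected.cutoff == 0.1
        assert reason == "unique_min_fdr"

    def test_residual_ties_fall_back_to_lower_p_then_smaller_cutoff(self):
        rows = [
            _row(0.3, 2.0, 0.004, 0.05),
            _row(0.1, 2.0, 0.002, 0.05),
            _row(0.2, 2.0, 0.002, 0.05),
        ]
        selected, _ = select_cutoff(rows)
        assert selected.cutoff == 0.1

    def test_nonconverged_rows_excluded(self):
        rows = [
            CutoffResult(0.1, 5, 15, float("nan"), float("nan"), float("nan"), converged=False),
            _row(0.2, 2.0, 0.01, 0.04),
        ]
        selected, _ = select_cutoff(rows)
        assert selected.cutoff == 0.2


class TestScan:
    def test_scan_fdr_column_is_bh_of_p_column(self, small_cohort):
        out = es.scan(small_cohort)
        p = np.array([r.p_value for r in out.results])
        q = np.array([r.fdr_q for r in out.results])
        np.testing.assert_allclose(q, bh_fdr(p), atol=1e-12)

    def test_selection_optimality_bruteforce(self, small_cohort):
        out = es.scan(small_cohort)
        qs = [r.fdr_q for r in out.results if r.converged]
        assert out.selected.fdr_q <= min(qs) + 1e-15
        tied = [r for r in out.results if np.isclose(r.fdr_q, out.selected.fdr_q, rtol=1e-12)]
        assert out.selected.hazard_ratio == max(r.hazard_ratio for r in tied)

    def test_group_sizes_partition_cohort(self, small_cohort):
        out = es.scan(small_cohort)
        for r in out.results:
            assert r.n_low + r.n_high == out.n
            assert r.hazard_ratio > 0

    def test_low_high_flip_inverts_hazard_ratios(self, small_cohort):
        tab = small_cohort.table
        expr = tab.relative_expression.to_numpy()
        t = tab.os_months.to_numpy()
        e = tab.os_event.to_numpy().astype(bool)
        out = es.scan(small_cohort)
        for r in out.results[:5]:
            low = expr <= r.cutoff
            flipped = cox_fit(t, e, (~low).astype(float))
            assert flipped.hazard_ratio == pytest.approx(1.0 / r.hazard_ratio, rel=1e-8)
            assert flipped.p_value == pytest.approx(r.p_value, abs=1e-10)

    def test_recovers_true_cutoff_on_stepped_cohort(self):
        spec = es.CohortSpec(n_patients=2000, seed=21)
        out = es.scan(es.generate_cohort(spec))
        # central 20% band of the expression distribution around the cutoff
        assert abs(out.selected.cutoff - spec.true_cutoff) < 0.1 * spec.true_cutoff
        assert out.selected.fdr_q < 0.01

    def test_attached_km_curves_describe_selected_strata(self, small_cohort):
        out = es.scan(small_cohort)
        assert out.km_low.n_total == out.selected.n_low
        assert out.km_high.n_total == out.selected.n_high

    def test_too_few_events_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "relative_expression": np.linspace(0.1, 1.0, 20),
                "os_months": np.linspace(1, 20, 20),
                "os_event": [0] * 20,
            }
        )
        with pytest.raises(ValidationError):
            es.scan(df, es.ScanConfig(min_group_size=2))


class TestSubgroupScan:
    def test_effect_confined_to_one_mutation_stratum(self):
        spec = es.CohortSpec(
            n_patients=1600,
            true_log_hr_low=0.0,
            subgroup_log_hr_low={"flt3_itd": np.log(2.5)},
            seed=31,
        )
        cohort = es.generate_cohort(spec)
        outcomes = es.subgroup_scan(cohort, ["flt3_itd"], es.ScanConfig())
        by_label = {o.subgroup: o for o in outcomes}
        assert by_label["flt3_itd+"].selected.fdr_q < 0.05
        assert by_label["flt3_itd-"].selected.fdr_q > 0.05

    def test_undersized_subgroup_skipped_with_warning(self, caplog):
        spec = es.CohortSpec(n_patients=300, subgroup_fractions={"cebpa": 0.02}, seed=5)
        cohort = es.generate_cohort(spec)
        import logging

        with caplog.at_level(logging.WARNING, logger="exprsurv.cutscan"):
            outcomes = es.subgroup_scan(cohort, ["cebpa"], es.ScanConfig())
        labels = [o.subgroup for o in outcomes]
        assert "cebpa+" not in labels
        assert any("skipped" in r.message or "not scannable" in r.message for r in caplog.records)

    def test_single_level_flag_is_one_stratum(self):
        spec = es.CohortSpec(n_patients=300, subgroup_fractions={"npm1": 0.0}, seed=6)
        cohort = es.generate_cohort(spec)
        outcomes = es.subgroup_scan(cohort, ["npm1"], es.ScanConfig())
        assert [o.subgroup for o in outcomes] == ["npm1"]

    def test_efs_endpoint_selectable(self, small_cohort):
        outcomes = es.subgroup_scan(small_cohort, ["npm1"], es.ScanConfig(), endpoint="efs")
        assert all(o.endpoint == "efs" for o in outcomes)

    def test_missing_flag_rejected(self, small_cohort):
        with pytest.raises(ValidationError):
            es.subgroup_scan(small_cohort, ["nonexistent_flag"])


class TestReport:
    def test_report_roundtrips_and_is_deterministic(self, small_cohort):
        out = es.scan(small_cohort)
        rep1 = json.dumps(es.report(out, seed=7), sort_keys=True)
        rep2 = json.dumps(es.report(out, seed=7), sort_keys=True)
        assert rep1 == rep2
        assert json.loads(rep1) == json.loads(rep2)

    def test_report_medians_match_attached_curves(self, small_cohort):
        out = es.scan(small_cohort)
        rep = es.report(out)
        entry = rep["outcomes"][0]
        assert entry["median_survival_low"] == out.km_low.median
        assert entry["median_survival_high"] == out.km_high.median

    def test_write_report_emits_expected_files(self, small_cohort, tmp_path):
        out = es.scan(small_cohort)
        es.write_report(out, tmp_path, seed=3)
        for name in ("scan_table.tsv", "selection.json", "km_low.tsv", "km_high.tsv"):
            assert (tmp_path / name).exists()
        sel = json.loads((tmp_path / "selection.json").read_text())
        assert sel["seed"] == 3
        assert sel["outcomes"][0]["config"]["quantile_convention"] == "linear"
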