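"""Preprocessing: exclusions, log decisions, drift removal, normalization."""
import numpy as np
import pandas as pd
import pytest

import pushpull as pp
from pushpull.errors import ConfigurationError, DegenerateInputError


def make_table(rows):
    return pd.DataFrame(rows, columns=["animal_id", "sex", "age_years",
                                       "biomarker", "value", "lab_code"])


class TestExclusions:
    def test_threshold_rules_remove_out_of_range_records(self):
        table = make_table([
            ("d1", "F", 10.0, "Albumin", 1.9, ""),
            ("d1", "F", 11.0, "Albumin", 2.1, ""),
            ("d1", "F", 12.0, "RDW", 41.0, ""),
            ("d1", "F", 13.0, "RDW", 39.0, ""),
            ("d1", "F", 14.0, "GFR", 1.0, ""),
            ("d1", "F", 15.0, "Iron", 100.0, ""),
        ])
        out, removals = pp.apply_exclusions(table, pp.PanelConfig())
        assert removals["Albumin below 2.0"] == 1
        assert removals["RDW above 40.0"] == 1
        assert removals["drop GFR"] == 1
        kept = set(zip(out["biomarker"], out["value"]))
        assert ("Albumin", 2.1) in kept and ("Albumin", 1.9) not in kept
        assert ("RDW", 39.0) in kept and ("RDW", 41.0) not in kept
        assert "GFR" not in set(out["biomarker"])

    def test_no_matching_rule_leaves_table_unchanged(self):
        table = make_table([("d1", "M", 5.0, "Iron", 50.0, "")])
        out, _ = pp.apply_exclusions(table, pp.PanelConfig())
        pd.testing.assert_frame_equal(out, table)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        table = make_table([
            ("d1", "F", float(a), b, float(v), "")
            for a, b, v in zip(rng.uniform(0, 30, 50),
                               rng.choice(["Albumin", "RDW", "Iron"], 50),
                               rng.uniform(0, 60, 50))])
        once, _ = pp.apply_exclusions(table, pp.PanelConfig())
        twice, removals = pp.apply_exclusions(once, pp.PanelConfig())
        pd.testing.assert_frame_equal(once, twice)
        assert all(v == 0 for v in removals.values())

    def test_unknown_biomarker_in_rule_rejected(self):
        with pytest.raises(ConfigurationError):
            pp.PanelConfig(exclusion_rules=(
                pp.ExclusionRule("NotAMarker", 1.0, "below"),))


class TestSmallestIncrement:
    @pytest.mark.parametrize("values,expected", [
        ([1.0, 1.2, 1.4], 0.2),
        ([0, 5, 10, 12], 2.0),
        ([3.0, 3.0, 3.5, 3.0], 0.5),
    ])
    def test_minimum_positive_gap(self, values, expected):
        assert pp.smallest_increment(values) == pytest.approx(expected)

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            pp.smallest_increment([3.0, 3.0])


class TestLogTransform:
    def test_lognormal_gets_log(self, rng):
        vals = np.exp(rng.standard_normal(10_000))
        delta = pp.smallest_increment(vals)
        applied, s_raw, s_log = pp.choose_log_transform(vals, delta)
        assert applied and abs(s_log) < abs(s_raw)

    def test_gaussian_stays_raw(self, rng):
        vals = rng.standard_normal(10_000) + 10.0
        applied, s_raw, s_log = pp.choose_log_transform(
            vals, pp.smallest_increment(vals))
        assert not applied and abs(s_raw) <= abs(s_log)

    def test_constant_values_stay_raw(self):
        applied, s_raw, s_log = pp.choose_log_transform(
            np.full(10, 7.0), 0.5)
        assert not applied and s_raw == 0.0

    def test_scale_invariance_of_raw_skewness(self, rng):
        vals = np.exp(rng.standard_normal(500))
        _, s1, _ = pp.choose_log_transform(vals, 0.1)
        _, s2, _ = pp.choose_log_transform(37.0 * vals, 3.7)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_nonpositive_shifted_values_block_log(self):
        applied, _, s_log = pp.choose_log_transform(
            np.array([-5.0, -1.0, 2.0]), 0.5)
        assert not applied and np.isnan(s_log)


class TestAgeDrift:
    def test_exact_line_recovered(self):
        ages = np.arange(6.0, 21.0)
        slope, intercept, n, fb = pp.fit_age_drift(ages, 2 + 0.1 * ages)
        assert slope == pytest.approx(0.1, abs=1e-12)
        assert intercept == pytest.approx(2.0, abs=1e-10)
        # interpolated 1st/99th percentiles may trim the two endpoints
        assert not fb and ages.size - 2 <= n <= ages.size

    def test_points_before_age_five_ignored(self):
        ages = np.concatenate([[1.0, 3.0], np.arange(6.0, 21.0)])
        vals = 2 + 0.1 * ages
        vals[0] = 99.0
        vals[1] = -55.0
        slope, _, _, _ = pp.fit_age_drift(ages, vals)
        assert slope == pytest.approx(0.1, abs=1e-12)

    def test_percentile_filter_excludes_planted_outlier(self):
        # >= 101 clean points guarantee the 99th percentile excludes the spike
        rng = np.random.default_rng(7)
        ages = np.linspace(6.0, 30.0, 120)
        vals = 1.0 + 0.05 * ages + rng.normal(0, 0.01, ages.size)
        clean_slope = np.polyfit(ages, vals, 1)[0]
        ages2 = np.append(ages, 18.0)
        vals2 = np.append(vals, 1e4)
        clean_intercept = np.polyfit(ages, vals, 1)[1]
        # unfiltered fit: the mid-range spike shifts the intercept by ~82
        corrupted_intercept = np.polyfit(ages2, vals2, 1)[1]
        assert abs(corrupted_intercept - clean_intercept) > 50
        slope, intercept, n, _ = pp.fit_age_drift(ages2, vals2)
        # the spike is excluded (a few boundary points may be trimmed too)
        assert 110 <= n <= 120
        assert slope == pytest.approx(clean_slope, rel=1e-2)
        assert intercept == pytest.approx(clean_intercept, abs=1e-2)

    def test_short_series_falls_back_to_pooled_slope(self):
        slope, _, n, fb = pp.fit_age_drift([6.0, 7.0], [1.0, 2.0],
                                           pooled=(0.33, 0.0))
        assert fb and slope == 0.33 and n < 3


class TestDetrendNormalize:
    def test_output_mean_zero_variance_one(self, rng):
        rows = []
        for d in ("d1", "d2"):
            ages = np.sort(rng.uniform(5, 30, 40))
            vals = rng.normal(3, 2, 40) + 0.2 * ages
            rows += [(d, "F", float(a), "Iron", float(v), "")
                     for a, v in zip(ages, vals)]
        table = pd.DataFrame(rows, columns=["animal_id", "sex", "age_years",
                                            "biomarker", "value", "lab_code"])
        drift = pp.compute_drift(table)
        out = pp.detrend_normalize(table, drift)
        for _, grp in out.groupby("animal_id"):
            v = grp["value"].to_numpy()
            assert abs(v.mean()) < 1e-12
            assert abs(v.var(ddof=1) - 1.0) < 1e-12

    def test_constant_series_dropped_with_warning(self, caplog):
        table = make_table([("d1", "F", float(a), "Iron", 4.0, "")
                            for a in range(6, 16)])
        drift = pp.compute_drift(table)
        with caplog.at_level("WARNING", logger="pushpull"):
            out = pp.detrend_normalize(table, drift)
        assert len(out) == 0
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_two_point_series_normalized_with_unbiased_variance(self):
        table = make_table([("d1", "F", 6.0, "Iron", 1.0, ""),
                            ("d1", "F", 9.0, "Iron", 2.0, "")])
        drift = pd.DataFrame([("d1", "Iron", 0.0, 0.0, 2, True)],
                             columns=["animal_id", "biomarker", "slope",
                                      "intercept", "n_points_used",
                                      "fallback_used"])
        out = pp.detrend_normalize(table, drift)
        v = out["value"].to_numpy()
        assert v == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])


class TestIncrementDiagnostics:
    def test_twelve_bins_reported(self, small_null_cohort):
        _, _, pre = small_null_cohort
        diag = pp.increment_diagnostics(pre.normalized, "B0")
        assert diag.bin_count.size == 12
        assert diag.bin_edges.size == 13
        assert diag.histogram.shape == (12, 18)
        nonempty = diag.bin_count > 0
        assert np.allclose(diag.histogram[nonempty].max(axis=1), 1.0)
        assert diag.histogram.min() >= 0.0

    def test_brownian_variance_grows_linearly(self):
        # pure Brownian observations: slope ~ Q, intercept ~ 0
        rng = np.random.default_rng(5)
        rows = []
        for d in range(40):
            t = np.cumsum(rng.uniform(0.05, 1.0, 130))
            x = np.cumsum(np.sqrt(np.diff(np.concatenate([[0], t])))
                          * rng.standard_normal(130))
            rows += [(f"d{d}", "F", float(a), "X", float(v), "")
                     for a, v in zip(t, x)]
        table = pd.DataFrame(rows, columns=["animal_id", "sex", "age_years",
                                            "biomarker", "value", "lab_code"])
        diag = pp.increment_diagnostics(table, "X")
        assert diag.slope_vs_dt == pytest.approx(1.0, abs=0.15)
        assert diag.intercept_at_dt0 == pytest.approx(0.0, abs=0.1)

    def test_pure_noise_intercept_is_twice_noise_variance(self):
        rng = np.random.default_rng(6)
        rows = []
        for d in range(40):
            t = np.cumsum(rng.uniform(0.05, 1.0, 130))
            v = rng.normal(0, np.sqrt(0.5), 130)
            rows += [(f"d{d}", "F", float(a), "X", float(x), "")
                     for a, x in zip(t, v)]
        table = pd.DataFrame(rows, columns=["animal_id", "sex", "age_years",
                                            "biomarker", "value", "lab_code"])
        diag = pp.increment_diagnostics(table, "X")
        assert diag.slope_vs_dt == pytest.approx(0.0, abs=0.15)
        assert diag.intercept_at_dt0 == pytest.approx(1.0, abs=0.15)

    def test_too_few_increments_rejected(self):
        table = make_table([("d1", "F", float(a), "Iron", float(a), "")
                            for a in range(5)])
        with pytest.raises(DegenerateInputError):
            pp.increment_diagnostics(table, "Iron")


def test_preprocess_cohort_end_to_end(small_null_cohort):
    spec, cohort, pre = small_null_cohort
    assert set(pre.normalized["biomarker"]) <= set(spec.biomarkers)
    # log-scale biomarkers should have been detected and log-transformed
    rep = pre.transform_report.set_index("biomarker")
    for b, is_log in zip(spec.biomarkers, spec.log_scale):
        assert rep.loc[b, "log_applied"] == is_log
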