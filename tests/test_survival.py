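"""Cohort filtering, Youden dichotomization, KM/log-rank, subtype expression."""

import itertools

import numpy as np
import pandas as pd
import pytest

from subtypescreen import synthetic
from subtypescreen.survival import (
    filter_cohort,
    km_fit,
    logrank,
    marker_correlations,
    stratify_by_marker,
    subtype_differential_expression,
    youden_cutoff,
)


class TestFilterCohort:
    def test_flagged_rows_removed(self):
        n, n_bad = 411, 25
        raw = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "time_months": [np.nan] * n_bad + list(np.arange(n - n_bad) + 1.0),
            "event": 1,
            "marker": 0.5,
        })
        filtered, excluded = filter_cohort(raw)
        assert len(filtered) == 386 and excluded == 25

    def test_complete_table_identity(self):
        raw = pd.DataFrame({"time_months": [1.0, 2.0], "event": [1, 0], "marker": [0.1, 0.2]})
        filtered, excluded = filter_cohort(raw)
        assert excluded == 0
        pd.testing.assert_frame_equal(filtered, raw)

    def test_all_missing_empty(self):
        raw = pd.DataFrame({"time_months": [np.nan], "event": [np.nan], "marker": [np.nan]})
        filtered, excluded = filter_cohort(raw)
        assert len(filtered) == 0 and excluded == 1

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="required"):
            filter_cohort(pd.DataFrame({"time_months": [1.0]}))


def brute_force_youden(marker, event):
    """Exhaustive threshold scan, ties toward the larger cutoff."""
    marker, event = np.asarray(marker, float), np.asarray(event, int)
    best = (-np.inf, -np.inf)
    for c in np.unique(marker):
        high = marker >= c
        sens = event[high].sum() / event.sum()
        spec = (1 - event[~high]).sum() / (1 - event).sum()
        j = sens + spec - 1
        if (j, c) >= best:
            best = (j, c)
    return best[1], best[0]


class TestYouden:
    def test_textbook_example(self):
        cut = youden_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
        assert cut.cutoff == 3.0 and cut.j == pytest.approx(1.0)

    def test_perfect_marker(self):
        cut = youden_cutoff([0, 0, 1, 1, 1], [0, 0, 1, 1, 1])
        assert cut.j == pytest.approx(1.0) and not cut.uninformative

    def test_independent_marker_flagged_uninformative(self):
        rng = np.random.default_rng(0)
        marker = rng.normal(size=400)
        event = rng.integers(0, 2, size=400)
        assert youden_cutoff(marker, event).uninformative

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both event classes"):
            youden_cutoff([1.0, 2.0], [1, 1])

    def test_matches_exhaustive_scan_small_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(4, 13))
            marker = np.round(rng.normal(size=n), 1)
            event = rng.integers(0, 2, size=n)
            if event.sum() in (0, n):
                continue
            cut = youden_cutoff(marker, event)
            exp_cut, exp_j = brute_force_youden(marker, event)
            assert cut.j == pytest.approx(exp_j)
            assert cut.cutoff == pytest.approx(exp_cut)


class TestKmFit:
    def test_distinct_event_times_steps_of_tenth(self):
        times = np.arange(1.0, 11.0)
        est = km_fit(times, np.ones(10, dtype=int))
        # survival drops by 1/10 at each event; median = 5th event time
        drops = -np.diff(np.concatenate([[1.0], est.survival[est.times > 0]]))
        np.testing.assert_allclose(drops, 0.1)
        assert est.median == pytest.approx(5.0)

    def test_all_censored_median_undefined(self):
        est = km_fit([5.0, 6.0, 7.0], [0, 0, 0])
        assert np.all(est.survival == 1.0)
        assert np.isnan(est.median)

    def test_censoring_time_beyond_last_event_is_immaterial(self):
        # a patient censored after the last event is at risk throughout
        # either way; moving that censoring time changes no survival value
        early = km_fit([1.0, 2.0, 3.0, 3.5], [1, 1, 1, 0])
        late = km_fit([1.0, 2.0, 3.0, 9.0], [1, 1, 1, 0])
        for t in (1.0, 2.0, 3.0):
            s_early = early.survival[early.times == t]
            s_late = late.survival[late.times == t]
            assert s_early == pytest.approx(s_late)


def brute_force_logrank(time_a, time_b):
    """O−E chi-square for fully observed (uncensored) groups."""
    times = np.sort(np.unique(np.concatenate([time_a, time_b])))
    o_minus_e, var = 0.0, 0.0
    for t in times:
        n_a = np.sum(time_a >= t)
        n_b = np.sum(time_b >= t)
        d_a = np.sum(time_a == t)
        d_b = np.sum(time_b == t)
        n, d = n_a + n_b, d_a + d_b
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups(self):
        chi2, p = logrank([1.0, 2.0, 3.0], [1, 1, 1], [1.0, 2.0, 3.0], [1, 1, 1])
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_full_separation_matches_hand_computation(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([10.0, 20.0, 30.0])
        chi2, _ = logrank(a, [1, 1, 1], b, [1, 1, 1])
        assert chi2 == pytest.approx(brute_force_logrank(a, b))

    def test_label_swap_symmetry(self):
        a, ea = [1.0, 4.0, 6.0, 9.0], [1, 0, 1, 1]
        b, eb = [2.0, 3.0, 8.0, 12.0], [1, 1, 0, 1]
        c1, p1 = logrank(a, ea, b, eb)
        c2, p2 = logrank(b, eb, a, ea)
        assert c1 == pytest.approx(c2) and p1 == pytest.approx(p2)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            logrank([1.0, 2.0], [0, 0], [3.0], [0])


class TestStratification:
    def test_marker_effect_recovered(self):
        coh = synthetic.simulate_cohort(synthetic.SimulationConfig(seed=31))
        out = stratify_by_marker(coh)
        assert out["median_high"] < out["median_low"]
        assert out["p"] < 0.05
        assert out["n_high"] + out["n_low"] == len(coh)

    def test_null_logrank_p_roughly_uniform(self):
        ps = []
        for seed in range(60):
            cfg = synthetic.SimulationConfig(seed=seed, marker_log_hazard=0.0, cohort_size=150)
            coh = synthetic.simulate_cohort(cfg)
            high = coh["marker"] > 0
            _, p = logrank(
                coh.loc[high, "time_months"], coh.loc[high, "event"],
                coh.loc[~high, "time_months"], coh.loc[~high, "event"],
            )
            ps.append(p)
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01


class TestExpressionStatistics:
    def test_perfect_monotone_and_antimonotone(self):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4, 5], [2, 4, 6, 8, 10], [5, 4, 3, 2, 1]],
            index=["ITGAV", "VIM", "CDH1"], columns=[f"p{i}" for i in range(5)],
        )
        table = marker_correlations(expr, "ITGAV", ["VIM", "CDH1"]).set_index("partner")
        assert table.loc["VIM", "rho"] == pytest.approx(1.0)
        assert table.loc["CDH1", "rho"] == pytest.approx(-1.0)

    def test_independent_markers_low_rho(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(
                rng.normal(size=(2, 386)), index=["A", "B"],
                columns=[f"p{i}" for i in range(386)],
            )
            rho = marker_correlations(expr, "A", ["B"])["rho"].iloc[0]
            hits += abs(rho) < 0.15
        assert hits / 20 >= 0.95

    def test_subtype_differential_expression_planted_shift(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(30)]
        labels = pd.Series(["basal"] * 10 + ["luminal"] * 10 + ["mesenchymal-like"] * 10,
                           index=ids)
        values = rng.normal(5, 1, 30)
        values[20:] += 3.0  # mesenchymal shift
        expr = pd.DataFrame([values], index=["ITGAV"], columns=ids)
        out = subtype_differential_expression(expr, "ITGAV", labels)
        assert out["p"] < 0.001
        pw = out["pairwise"].set_index(["subtype_a", "subtype_b"])
        assert pw.loc[("basal", "mesenchymal-like"), "stars"] != "ns"
        assert pw.loc[("luminal", "mesenchymal-like"), "stars"] != "ns"
        assert pw.loc[("basal", "luminal"), "stars"] == "ns"

    def test_identical_groups_h_zero(self):
        ids = [f"s{i}" for i in range(8)]
        labels = pd.Series(["basal"] * 4 + ["luminal"] * 4, index=ids)
        expr = pd.DataFrame([[1.0] * 8], index=["g"], columns=ids)
        out = subtype_differential_expression(expr, "g", labels)
        assert out["H"] == 0.0 and out["p"] == 1.0
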