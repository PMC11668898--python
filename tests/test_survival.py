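"""Product-limit, log-rank, Cox PH, and cutoff scanning, cross-checked
against lifelines as the independent implementation."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.statistics import multivariate_logrank_test

from radres.survival import (
    SCHEMES,
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
    read_clinical,
    reverse_km_followup,
    scan_cutoffs,
    write_clinical,
)
from radres.synth import CohortTruth, sim_cohort


def sim_two_groups(rng, n=60, hr=1.0, censor_frac=0.3):
    x = (rng.random(n) < 0.5).astype(float)
    lam = (np.log(2) / 24) * np.exp(np.log(hr) * x)
    te = rng.exponential(1 / lam)
    tc = rng.exponential(1 / (lam * censor_frac / (1 - censor_frac)))
    return np.minimum(te, tc), (te <= tc).astype(int), x


class TestKaplanMeier:
    def test_three_events_hand_example(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([5, 6, 7], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 40)
        km = km_estimate(t, np.ones(40, int))
        for tt in km.times:
            assert km.survival_at(tt) == pytest.approx((t > tt).mean())

    def test_matches_lifelines(self, rng):
        t = rng.exponential(10, 50)
        e = (rng.random(50) < 0.6).astype(int)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        expected = kmf.survival_function_.loc[km.times].to_numpy().ravel()
        np.testing.assert_allclose(km.survival, expected, atol=1e-12)


class TestReverseKm:
    def test_all_censored_at_five(self):
        assert reverse_km_followup([5, 5, 5], [0, 0, 0]) == pytest.approx(5.0)

    def test_no_censoring_is_not_reached(self):
        assert np.isnan(reverse_km_followup([1, 2, 3], [1, 1, 1]))

    def test_hand_computed_flipped_median(self):
        # censorings at 2,4,6 (flipped events), events at 1,3,5: the flipped
        # curve steps 1 -> 4/5 (t=2) -> 8/15 (t=4) -> 0 (t=6); median = 6
        time = [1, 2, 3, 4, 5, 6]
        event = [1, 0, 1, 0, 1, 0]
        assert reverse_km_followup(time, event) == pytest.approx(6.0)


class TestLogRank:
    def test_identical_groups_statistic_zero(self, rng):
        t = rng.exponential(10, 20)
        e = (rng.random(20) < 0.7).astype(int)
        res = logrank_test([(t, e), (t, e)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_subject_hand_example(self):
        res = logrank_test([(np.array([1.0]), np.array([1])),
                            (np.array([2.0]), np.array([0]))])
        assert res.statistic == pytest.approx(1.0)
        assert res.p == pytest.approx(0.3173, abs=1e-4)

    def test_group_label_swap_invariant(self, rng):
        t, e, x = sim_two_groups(rng)
        a = logrank_test([(t[x == 1], e[x == 1]), (t[x == 0], e[x == 0])])
        b = logrank_test([(t[x == 0], e[x == 0]), (t[x == 1], e[x == 1])])
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_matches_lifelines_two_and_three_groups(self, rng):
        t, e, x = sim_two_groups(rng, n=80)
        ours = logrank_test([(t[x == 1], e[x == 1]), (t[x == 0], e[x == 0])])
        ref = ll_logrank(t[x == 1], t[x == 0], e[x == 1], e[x == 0])
        assert ours.statistic == pytest.approx(ref.test_statistic, abs=1e-9)

        g = rng.integers(0, 3, 80)
        ours3 = logrank_test([(t[g == k], e[g == k]) for k in range(3)])
        ref3 = multivariate_logrank_test(t, g, e)
        assert ours3.statistic == pytest.approx(ref3.test_statistic, abs=1e-9)
        assert ours3.df == 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([(np.array([1.0]), np.array([1])),
                          (np.array([]), np.array([]))])


class TestCox:
    def test_three_subject_analytic_estimate(self):
        fit = cox_fit([1.0, 2.0, 3.0], [1, 1, 1], [1.0, 0.0, 1.0])
        assert fit.converged
        assert fit.beta == pytest.approx(-0.5 * np.log(2), abs=1e-7)
        assert fit.hr == pytest.approx(np.exp(fit.beta))
        lo, hi = fit.ci95
        assert lo < fit.hr < hi

    def test_monotone_likelihood_flagged(self):
        fit = cox_fit([1.0, 2.0], [1, 1], [1.0, 0.0])
        assert not fit.converged

    def test_matches_lifelines_with_ties(self, rng):
        t = np.round(rng.exponential(10, 60)) + 1  # force ties
        e = (rng.random(60) < 0.7).astype(int)
        x = rng.normal(size=60)
        fit = cox_fit(t, e, x)
        cph = CoxPHFitter().fit(pd.DataFrame({"T": t, "E": e, "x": x}), "T", "E")
        assert fit.beta == pytest.approx(float(cph.params_.iloc[0]), abs=1e-5)
        assert fit.se == pytest.approx(float(cph.standard_errors_.iloc[0]), abs=1e-5)

    def test_score_test_equals_logrank_without_ties(self, rng):
        for _ in range(10):
            t, e, x = sim_two_groups(rng, n=40)
            if e.sum() == 0 or x.sum() in (0, len(x)):
                continue
            lr = logrank_test([(t[x == 1], e[x == 1]), (t[x == 0], e[x == 0])])
            score = cox_score_test(t, e, x)
            assert score.statistic == pytest.approx(lr.statistic, abs=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1.0, 2.0], [1, 1], [1.0, 1.0])


class TestCutoffScan:
    def test_selected_is_minimal_p_among_valid(self, rng):
        _, clinical, _ = sim_cohort(n_patients=100, seed=4)
        scan = scan_cutoffs(
            clinical["time_months"], clinical["event"], clinical["score"]
        )
        valid = scan.candidates[scan.candidates["valid"]]
        assert scan.selected_row["logrank_p"] == pytest.approx(valid["logrank_p"].min())

    def test_every_interior_quantile_is_a_candidate(self, rng):
        _, clinical, _ = sim_cohort(n_patients=80, seed=5)
        scan = scan_cutoffs(
            clinical["time_months"], clinical["event"], clinical["score"]
        )
        levels = set(scan.candidates["quantile_level"])
        # the 40th percentile makes the "top 3 quintiles" split representable
        assert {0.5, 0.25, 0.75, 0.2, 0.4, 0.6, 0.8} <= levels

    def test_recovers_planted_threshold_in_most_cohorts(self):
        hits = 0
        for seed in range(10):
            _, clinical, _ = sim_cohort(n_patients=400, seed=100 + seed)
            scan = scan_cutoffs(
                clinical["time_months"], clinical["event"], clinical["score"]
            )
            hits += scan.selected_row["quantile_level"] in (0.5, 0.6, 2 / 3)
        assert hits >= 8

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            scan_cutoffs([1.0, 2.0, 3.0], [1, 1, 1], [5.0, 5.0, 5.0])

    def test_group_size_constraint_marks_invalid(self, rng):
        t = rng.exponential(10, 30)
        e = np.ones(30, int)
        s = rng.normal(size=30)
        # strict fraction: only near-median splits stay valid
        scan = scan_cutoffs(t, e, s, min_group_frac=0.45)
        assert (~scan.candidates["valid"]).any()
        assert scan.candidates["valid"].any()

    def test_degenerate_scores_leave_no_valid_split(self, rng):
        t = rng.exponential(10, 30)
        e = np.ones(30, int)
        s = np.concatenate([np.zeros(28), [1.0, 2.0]])
        with pytest.raises(ValueError, match="valid split"):
            scan_cutoffs(t, e, s, min_group_frac=0.2)


class TestCohortSimulation:
    def test_zero_censoring_gives_all_events(self):
        truth = CohortTruth(censoring_fraction=0.0)
        _, clinical, _ = sim_cohort(n_patients=50, truth=truth, seed=1)
        assert (clinical["event"] == 1).all()

    def test_censoring_fraction_calibrated(self):
        truth = CohortTruth(censoring_fraction=0.4)
        _, clinical, _ = sim_cohort(n_patients=2000, truth=truth, seed=2)
        assert (clinical["event"] == 0).mean() == pytest.approx(0.4, abs=0.05)

    def test_clinical_roundtrip(self, tmp_path):
        _, clinical, _ = sim_cohort(n_patients=30, seed=3)
        write_clinical(clinical, tmp_path / "clin.tsv")
        back = read_clinical(tmp_path / "clin.tsv")
        np.testing.assert_allclose(back["time_months"], clinical["time_months"])
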