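"""Each statistic is checked against hand computations, brute-force
oracles, and an independent library implementation."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from desep.survival_stats import (CoxResult, SurvivalRecord, TwoByTwo,
                                  bootstrap_c_se, cox_hr_binary, cramers_phi,
                                  harrells_c, km_curve, km_survival_at,
                                  logrank, restricted_mean_survival)


def recs(times, events, scores=None):
    scores = scores if scores is not None else [0.0] * len(times)
    return [SurvivalRecord(t, e, s) for t, e, s in zip(times, events, scores)]


def random_records(rng, n, score=True):
    t = rng.exponential(2.0, n).round(3) + 0.001
    e = (rng.uniform(size=n) < 0.7).astype(int)
    s = rng.standard_normal(n) if score else np.zeros(n)
    return recs(t, e, s)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = dict(km_curve(recs([1, 2, 3], [1, 1, 0])))
        assert curve[1.0] == pytest.approx(2 / 3)
        assert curve[2.0] == pytest.approx(1 / 3)
        assert km_survival_at(recs([1, 2, 3], [1, 1, 0]), 3.0) == pytest.approx(1 / 3)

    def test_all_censored_stays_at_one(self):
        assert km_curve(recs([1, 2, 3], [0, 0, 0])) == [(0.0, 1.0)]

    def test_no_censoring_reduces_to_ecdf(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1.0, 25)
        curve = km_curve(recs(t, [1] * 25))
        for ti, si in curve[1:]:
            assert si == pytest.approx(np.mean(t > ti))

    def test_monotone_non_increasing_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            s = [si for _, si in km_curve(random_records(rng, 30))]
            assert all(0 <= x <= 1 for x in s)
            assert all(a >= b for a, b in zip(s, s[1:]))

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(2)
        r = random_records(rng, 40)
        kmf = lifelines.KaplanMeierFitter().fit(
            [x.time for x in r], [x.event for x in r])
        for ti, si in km_curve(r)[1:]:
            assert si == pytest.approx(
                float(kmf.survival_function_at_times(ti).iloc[0]), abs=1e-10)

    def test_restricted_mean_is_km_area(self):
        r = recs([1, 2, 4], [1, 1, 1])
        # S=1 on [0,1), 2/3 on [1,2), 1/3 on [2,4)
        assert restricted_mean_survival(r, tau=4) == pytest.approx(
            1 + 2 / 3 + 2 / 3)


class TestLogrank:
    def test_identical_groups_null(self):
        a = recs([1, 2, 3], [1, 0, 1])
        chi2, p = logrank(a, list(a))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_table(self):
        # A: 1 censored, 2 event, 3 event; B: 2 event, 4 event, 5 censored
        a = recs([1, 2, 3], [0, 1, 1])
        b = recs([2, 4, 5], [1, 1, 0])
        # independent accumulation of O-E and hypergeometric variance
        o_minus_e, var = 0.0, 0.0
        for ti in [2, 3, 4]:
            na = sum(1 for x in a if x.time >= ti)
            nb = sum(1 for x in b if x.time >= ti)
            da = sum(1 for x in a if x.time == ti and x.event)
            db = sum(1 for x in b if x.time == ti and x.event)
            n, d = na + nb, da + db
            o_minus_e += da - d * na / n
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
        chi2, p = logrank(a, b)
        assert chi2 == pytest.approx(o_minus_e ** 2 / var, abs=1e-9)
        assert p == pytest.approx(float(sps.chi2.sf(chi2, 1)), abs=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = random_records(rng, 20), random_records(rng, 25)
        assert logrank(a, b)[0] == pytest.approx(logrank(b, a)[0], abs=1e-12)

    def test_zero_events_overall(self):
        chi2, p = logrank(recs([1, 2], [0, 0]), recs([3], [0]))
        assert (chi2, p) == (0.0, 1.0)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(4)
        a, b = random_records(rng, 30), random_records(rng, 30)
        res = lifelines.logrank_test(
            [x.time for x in a], [x.time for x in b],
            [x.event for x in a], [x.event for x in b])
        chi2, p = logrank(a, b)
        assert chi2 == pytest.approx(res.test_statistic, abs=1e-8)
        assert p == pytest.approx(res.p_value, abs=1e-8)


def _partial_loglik(beta, records):
    """Explicit Breslow partial log-likelihood, independent of the
    implementation under test."""
    ll = 0.0
    for r in records:
        if not r.event:
            continue
        risk = [x for x in records if x.time >= r.time]
        ll += beta * r.group_or_score - np.log(
            sum(np.exp(beta * x.group_or_score) for x in risk))
    return ll


class TestCox:
    def test_null_hr_is_one(self):
        base = [(1, 1), (2, 1), (3, 0), (4, 1)]
        r = [SurvivalRecord(t, e, g) for g in (0.0, 1.0) for t, e in base]
        # identical experience in both groups except tied times; shift group B
        # times by epsilon-free amounts is unnecessary: Breslow handles ties
        assert cox_hr_binary(r).hr == pytest.approx(1.0, abs=1e-6)

    def test_matches_direct_likelihood_maximization(self):
        r = recs([1.1, 2.3, 3.7, 4.2, 5.9, 7.4], [1, 1, 0, 1, 1, 1],
                 [1, 0, 1, 0, 1, 0])
        res = minimize_scalar(lambda b: -_partial_loglik(b, r),
                              bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert cox_hr_binary(r).beta == pytest.approx(res.x, abs=1e-6)

    def test_relabel_inverts_hr(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 30); e = (rng.uniform(size=30) < 0.8).astype(int)
        g = (rng.uniform(size=30) < 0.5).astype(float)
        hr1 = cox_hr_binary(recs(t, e, g)).hr
        hr2 = cox_hr_binary(recs(t, e, 1 - g)).hr
        assert hr1 == pytest.approx(1 / hr2, rel=1e-6)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        rng = np.random.default_rng(6)
        t = rng.exponential(1, 60).round(4) + 1e-3
        g = (rng.uniform(size=60) < 0.5).astype(float)
        e = (rng.uniform(size=60) < 0.75).astype(int)
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "g": g}), "t", "e")
        ours = cox_hr_binary(recs(t, e, g))
        assert ours.beta == pytest.approx(cph.params_["g"], abs=1e-5)
        assert ours.se == pytest.approx(cph.standard_errors_["g"], abs=1e-4)

    def test_recovers_hr_two_on_exponential_simulation(self):
        rng = np.random.default_rng(7)
        n = 1000
        g = (np.arange(n) % 2).astype(float)
        t = rng.exponential(1.0 / (0.5 * np.exp(np.log(2) * g)))
        c = rng.exponential(5.0, n)
        r = recs(np.minimum(t, c) + 1e-9, (t <= c).astype(int), g)
        assert cox_hr_binary(r).hr == pytest.approx(2.0, rel=0.15)

    def test_monotone_likelihood_flagged(self):
        r = recs([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0],
                 [1, 1, 1, 0, 0, 0])
        res = cox_hr_binary(r)
        assert res.monotone_likelihood
        assert res.ci_high == np.inf


class TestHarrellsC:
    def test_perfect_concordance(self):
        # higher score = higher risk = earlier event
        r = recs([1, 2, 3, 4], [1, 1, 1, 1], [4, 3, 2, 1])
        assert harrells_c(r) == 1.0

    def test_all_tied_scores(self):
        r = recs([1, 2, 3], [1, 1, 1], [5, 5, 5])
        assert harrells_c(r) == 0.5

    def test_brute_force_oracle_censored(self):
        rng = np.random.default_rng(8)
        r = random_records(rng, 12)
        conc = usable = 0
        for i in range(12):
            for j in range(12):
                if i == j or r[i].time >= r[j].time or not r[i].event:
                    continue
                usable += 1
                if r[i].group_or_score > r[j].group_or_score:
                    conc += 1
                elif r[i].group_or_score == r[j].group_or_score:
                    conc += 0.5
        assert harrells_c(r) == pytest.approx(conc / usable, abs=1e-12)

    def test_score_negation_complement_without_ties(self):
        rng = np.random.default_rng(9)
        r = random_records(rng, 15)
        flipped = [SurvivalRecord(x.time, x.event, -x.group_or_score)
                   for x in r]
        assert harrells_c(r) + harrells_c(flipped) == pytest.approx(1.0)

    def test_matches_scikit_survival(self):
        sksurv = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(10)
        r = random_records(rng, 40)
        c = sksurv.concordance_index_censored(
            np.array([bool(x.event) for x in r]),
            np.array([x.time for x in r]),
            np.array([x.group_or_score for x in r]))[0]
        assert harrells_c(r) == pytest.approx(c, abs=1e-10)

    def test_undefined_without_usable_pairs(self):
        with pytest.raises(ValueError, match="c undefined"):
            harrells_c(recs([1, 2], [0, 0], [1, 2]))

    def test_bootstrap_se_positive(self):
        rng = np.random.default_rng(11)
        se = bootstrap_c_se(random_records(rng, 30), n_boot=50, seed=1)
        assert 0 < se < 0.5


class TestCramersPhi:
    def test_perfect_agreement(self):
        assert cramers_phi(TwoByTwo(10, 0, 0, 10))[0] == pytest.approx(1.0)

    def test_independence(self):
        assert cramers_phi(TwoByTwo(5, 5, 5, 5))[0] == pytest.approx(0.0)

    def test_closed_form(self):
        phi, p = cramers_phi(TwoByTwo(8, 2, 3, 7))
        assert phi == pytest.approx(50 / np.sqrt(9900), abs=1e-12)
        # cross-check via chi2 = n phi^2 against scipy's chi-square test
        chi2 = sps.chi2_contingency([[8, 2], [3, 7]], correction=False)[0]
        assert phi == pytest.approx(np.sqrt(chi2 / 20), abs=1e-12)

    def test_sign_flips_with_label_swap(self):
        phi1, _ = cramers_phi(TwoByTwo(8, 2, 3, 7))
        phi2, _ = cramers_phi(TwoByTwo(2, 8, 7, 3))
        assert phi1 == pytest.approx(-phi2)

    def test_bounded_by_one(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 20, 4)
            phi, _ = cramers_phi(TwoByTwo(int(a), int(b), int(c), int(d)))
            assert -1 <= phi <= 1

    def test_zero_margin_undefined(self):
        with pytest.raises(ValueError, match="zero margin"):
            cramers_phi(TwoByTwo(5, 5, 0, 0))


def test_record_validation():
    with pytest.raises(ValueError):
        SurvivalRecord(0.0, 1)
    with pytest.raises(ValueError):
        SurvivalRecord(1.0, 2)
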