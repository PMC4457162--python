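import numpy as np
import pytest

from aposcan.survival import (
    SeparationError,
    _breslow_loglik,
    attack_rate,
    cox_fit_matrix,
    fit_cox,
    kaplan_meier,
    pairwise_survival,
)
from aposcan.synthetic import simulate_field_predation
from aposcan.types import PredationRecord


def rec(i, colour, time, event, block="T01", reason=None):
    return PredationRecord(f"M{i:04d}", colour, block, time, event,
                           "none" if event else (reason or "administrative"))


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        curve = kaplan_meier([(10.0, False), (20.0, False)])
        assert curve.event_times.size == 0
        assert curve.at(48.0) == 1.0

    def test_hand_computed_product_limit(self):
        # oracle: 4 subjects, events at 1,2,3 and a later event at 5
        curve = kaplan_meier([(1.0, True), (2.0, True), (3.0, True),
                              (5.0, True)])
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        assert curve.at(2.5) == pytest.approx(0.5)
        assert curve.at(0.5) == 1.0

    def test_duplication_invariance(self):
        data = [(1.0, True), (2.0, False), (3.0, True), (4.0, True)]
        c1 = kaplan_meier(data)
        c2 = kaplan_meier(data + data)
        np.testing.assert_allclose(c1.survival, c2.survival)

    def test_equals_empirical_survival_without_censoring(self, rng):
        for _ in range(10):
            t = rng.integers(1, 20, 15).astype(float)
            curve = kaplan_meier([(ti, True) for ti in t])
            for ti in np.unique(t):
                empirical = np.mean(t > ti)
                assert curve.at(ti) == pytest.approx(empirical)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        t = rng.exponential(10, 80)
        e = rng.random(80) < 0.7
        curve = kaplan_meier(list(zip(t, e)))
        kmf = KaplanMeierFitter().fit(t, e)
        for ti, si in zip(curve.event_times, curve.survival):
            assert si == pytest.approx(
                float(kmf.survival_function_at_times(ti).iloc[0]), abs=1e-9)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([(0.0, True)])

    def test_greenwood_variance_nonnegative_monotone_accumulation(self):
        curve = kaplan_meier([(1.0, True), (2.0, True), (3.0, False),
                              (4.0, True), (5.0, False)])
        assert np.all(curve.variance >= 0)


class TestCox:
    def test_matches_lifelines(self, rng):
        # library oracle; continuous times so tie conventions cannot differ
        import pandas as pd
        from lifelines import CoxPHFitter
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.5 * x)))
        e = t <= 48
        t = np.minimum(t, 48.0)
        fit = cox_fit_matrix(x[:, None], t, e, names=["x"])
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        ll = CoxPHFitter().fit(df, "t", "e")
        assert fit.coef[0] == pytest.approx(float(ll.params_.iloc[0]),
                                            abs=1e-5)
        assert fit.se[0] == pytest.approx(float(ll.standard_errors_.iloc[0]),
                                          abs=1e-5)

    def test_identical_groups_near_zero_coefficient(self, rng):
        zs = []
        for _ in range(100):
            t = rng.exponential(20, 60)
            e = t <= 48
            t = np.minimum(t, 48.0)
            x = (np.arange(60) % 2).astype(float)
            fit = cox_fit_matrix(x[:, None], t, e)
            zs.append(fit.z[0])
        # null z-scores: standard normal; ~5% exceed 1.96
        assert abs(np.mean(zs)) < 0.2
        assert np.mean(np.abs(zs) > 1.96) < 0.12

    def test_hazard_ratio_recovery_single_large_sample(self, rng):
        n = 2000
        x = (np.arange(n) % 2).astype(float)
        lam = 0.02 * np.exp(np.log(2.0) * x)
        t = rng.exponential(1 / lam)
        e = t <= 48
        t = np.minimum(t, 48.0)
        fit = cox_fit_matrix(x[:, None], t, e)
        assert np.exp(fit.coef[0]) == pytest.approx(2.0, abs=0.35)

    def test_time_rescaling_leaves_hr_unchanged(self, rng):
        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.4 * x)))
        e = t <= 30
        t = np.minimum(t, 30.0)
        f1 = cox_fit_matrix(x[:, None], t, e)
        f2 = cox_fit_matrix(x[:, None], t * 7.3, e)
        assert f1.coef[0] == pytest.approx(f2.coef[0], rel=1e-8)

    def test_score_unbiased_at_truth(self, rng):
        beta_true = np.array([0.5])
        grads = []
        for _ in range(50):
            n = 100
            x = rng.normal(size=(n, 1))
            t = rng.exponential(1 / (0.05 * np.exp(x[:, 0] * beta_true)))
            e = np.ones(n, dtype=bool)
            _, g, _ = _breslow_loglik(beta_true, x, t, e, np.zeros(n))
            grads.append(g[0])
        assert abs(np.mean(grads)) < 2 * np.std(grads) / np.sqrt(len(grads)) + 1.0

    def test_separation_raises(self):
        # failure order perfectly follows the covariate
        x = np.arange(10, dtype=float)[:, None]
        t = np.arange(10, 0, -1, dtype=float)
        e = np.ones(10, dtype=bool)
        with pytest.raises(SeparationError):
            cox_fit_matrix(x, t, e)

    def test_stratified_fit_handles_block_baselines(self, rng):
        n = 600
        block = np.repeat(np.arange(6), n // 6)
        base = np.array([0.005, 0.01, 0.02, 0.04, 0.08, 0.16])[block]
        x = (np.arange(n) % 2).astype(float)
        t = rng.exponential(1 / (base * np.exp(np.log(2) * x)))
        e = t <= 48
        t = np.minimum(t, 48.0)
        fit = cox_fit_matrix(x[:, None], t, e, strata=block)
        assert np.exp(fit.coef[0]) == pytest.approx(2.0, abs=0.6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_fit_matrix(np.ones((3, 1)), np.ones(3),
                           np.zeros(3, dtype=bool))


class TestFitCoxRecords:
    @staticmethod
    def records(rng, n=400, hr=2.0):
        models = [("dull", 0.0)] * (n // 2) + [("bright", 1.0)] * (n // 2)
        return simulate_field_predation(models,
                                        hazard_coefficient=-np.log(hr),
                                        baseline_hazard=0.015, seed=rng)

    def test_recovers_hazard_ratio(self, rng):
        fit = fit_cox(self.records(rng, n=2000))
        # bright (jnd=1) has hazard ratio ~2 relative to reference "bright"?
        assert fit.reference_level == "bright"
        hr = np.exp(fit.coef[fit.names.index("colour[dull]")])
        assert hr == pytest.approx(0.5, abs=0.15)

    def test_level_without_events_rejected(self):
        recs = [rec(0, "a", 4.0, True), rec(1, "a", 8.0, True),
                rec(2, "b", 48.0, False), rec(3, "b", 48.0, False)]
        with pytest.raises(ValueError, match="no events"):
            fit_cox(recs, stratify_by_block=False)

    def test_ambiguous_censored_excluded_by_default(self, rng):
        recs = self.records(rng) + [rec(9000, "dull", 8.0, False,
                                        reason="slime")]
        fit_excl = fit_cox(recs)
        fit_incl = fit_cox(recs, include_ambiguous_censored=True)
        assert fit_incl.n == fit_excl.n + 1

    def test_jnd_covariate(self, rng):
        recs = self.records(rng, n=1000)
        # jittered so the covariate is not collinear with the colour dummy
        jnd = {r.model_id: (0.0 if r.colour_label == "dull" else 1.0)
               + rng.uniform(0, 0.5) for r in recs}
        fit = fit_cox(recs, jnd_by_model=jnd)
        assert "jnd" in fit.names

    def test_missing_jnd_rejected(self, rng):
        recs = self.records(rng, n=20)
        with pytest.raises(ValueError, match="without JND"):
            fit_cox(recs, jnd_by_model={})


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(77)
    models = [("a", 0.0)] * 150 + [("b", 0.5)] * 150 + [("c", 1.5)] * 150
    recs = simulate_field_predation(models, hazard_coefficient=-0.5,
                                    baseline_hazard=0.01, seed=rng)
    return fit_cox(recs)


class TestPairwise:
    def test_antisymmetry(self, fitted):
        ab = pairwise_survival(fitted, [("a", "b")]).iloc[0]
        ba = pairwise_survival(fitted, [("b", "a")]).iloc[0]
        assert ab["coef"] == pytest.approx(-ba["coef"])
        assert ab["p"] == pytest.approx(ba["p"])

    def test_self_pair_zero(self, fitted):
        aa = pairwise_survival(fitted, [("b", "b")]).iloc[0]
        assert aa["coef"] == 0.0

    def test_unknown_level_rejected(self, fitted):
        with pytest.raises(ValueError, match="unknown"):
            pairwise_survival(fitted, [("a", "zebra")])

    def test_all_pairs_by_default(self, fitted):
        out = pairwise_survival(fitted)
        assert len(out) == 3


class TestAttackRate:
    def test_paper_scale_numbers(self):
        recs = [rec(i, "red", 4.0 * (1 + i % 12), i < 50) for i in range(750)]
        r = attack_rate(recs)
        assert r.n_attacked == 50 and r.n_total == 750
        assert r.rate == pytest.approx(50 / 750)
        assert r.ci[0] < 50 / 750 < r.ci[1]

    def test_zero_events(self):
        recs = [rec(i, "red", 48.0, False) for i in range(20)]
        r = attack_rate(recs)
        assert r.rate == 0.0 and r.ci[0] == 0.0

    def test_shuffle_invariance(self, rng):
        recs = [rec(i, "red", 4.0, i % 3 == 0) for i in range(30)]
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert attack_rate(recs).rate == attack_rate(shuffled).rate
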