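"""Model-comparison metrics, group BMS, compatibility, goodness of fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import betaln, logsumexp
from scipy.stats import beta as beta_dist

import multicause as mc
from multicause.model_comparison import (
    default_alpha0,
    factor_balanced_weights,
    grassberger_entropy,
)


class TestInfoCriteria:
    def test_closed_form_values(self):
        aicc, _ = mc.info_criteria(-100.0, 5, 500)
        assert aicc == pytest.approx(210.0 + 60.0 / 494.0)
        _, bic = mc.info_criteria(0.0, 2, 100)
        assert bic == pytest.approx(2.0 * np.log(100.0))

    def test_correction_vanishes_for_large_samples(self):
        aicc, _ = mc.info_criteria(-100.0, 5, 10**7)
        assert aicc == pytest.approx(210.0, abs=1e-4)
        assert aicc > 210.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            mc.info_criteria(-10.0, 5, 6)


def _beta_bernoulli(n=20, k_succ=13, a=1.0, b=1.0, S=4000, seed=0):
    """Posterior draws and per-trial log-lik matrix for a conjugate toy."""
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=bool)
    y[:k_succ] = True
    theta = rng.beta(a + k_succ, b + n - k_succ, size=S)
    loglik = np.where(y[None, :], np.log(theta)[:, None],
                      np.log1p(-theta)[:, None])
    return y, theta, loglik


class TestPSISLoo:
    def test_single_draw_degenerates_to_plugin(self):
        _, _, ll = _beta_bernoulli(S=1)
        res = mc.psis_loo(ll)
        assert res.loo == pytest.approx(ll[0].sum())

    def test_pointwise_sums_to_total(self):
        _, _, ll = _beta_bernoulli()
        res = mc.psis_loo(ll)
        assert res.loo == pytest.approx(res.pointwise.sum())
        assert res.pareto_k.shape == (ll.shape[1],)

    def test_matches_exact_leave_one_out_on_conjugate_toy(self):
        n, k_succ, a, b = 20, 13, 1.0, 1.0
        y, _, ll = _beta_bernoulli(n, k_succ, a, b, S=4000, seed=1)
        # exact refits: leave-one-out predictive is analytic for the
        # Beta-Bernoulli model
        exact = 0.0
        for i in range(n):
            k_i = k_succ - int(y[i])
            a_i, b_i = a + k_i, b + (n - 1) - k_i
            p_pred = a_i / (a_i + b_i)
            exact += np.log(p_pred if y[i] else 1.0 - p_pred)
        res = mc.psis_loo(ll)
        assert abs(res.loo - exact) < 0.1

    def test_penalization_is_nonnegative(self):
        _, _, ll = _beta_bernoulli(seed=2)
        res = mc.psis_loo(ll)
        in_sample = logsumexp(ll, axis=0) - np.log(ll.shape[0])
        assert res.loo <= in_sample.sum() + 1e-9


class TestMarginalLikelihood:
    def test_conjugate_toy_within_tenth_nat(self):
        n, k_succ, a, b = 20, 13, 1.0, 1.0
        _, theta, ll = _beta_bernoulli(n, k_succ, a, b, S=4000, seed=3)
        lml = mc.marginal_likelihood_whm(theta[:, None], log_prior=np.zeros(len(theta)),
                                         log_lik=ll.sum(axis=1), seed=0)
        exact = betaln(a + k_succ, b + n - k_succ) - betaln(a, b)
        assert abs(lml - exact) < 0.1

    def test_shift_invariance(self):
        _, theta, ll = _beta_bernoulli(S=4000, seed=4)
        tot = ll.sum(axis=1)
        lml = mc.marginal_likelihood_whm(theta[:, None], log_lik=tot, seed=0)
        lml_shift = mc.marginal_likelihood_whm(theta[:, None],
                                               log_lik=tot + 7.5, seed=0)
        assert lml_shift - lml == pytest.approx(7.5, abs=1e-9)

    def test_gaussian_likelihood_uniform_prior(self):
        # 1-D Gaussian likelihood x uniform prior on [0, 1]
        rng = np.random.default_rng(5)
        mu, sd = 0.4, 0.05
        draws = np.clip(rng.normal(mu, sd, 5000), 1e-4, 1 - 1e-4)[:, None]

        def loglik(x):
            return float(-0.5 * ((x[0] - mu) / sd) ** 2
                         - np.log(sd * np.sqrt(2 * np.pi)))

        lml = mc.marginal_likelihood_whm(draws, log_lik=loglik, seed=1)
        assert abs(lml - 0.0) < 0.1  # evidence = integral of N over ~[0,1] = 1


class TestGroupBMS:
    def test_dirichlet_count_update(self):
        rng = np.random.default_rng(0)
        ev = pd.DataFrame(rng.normal(size=(11, 4)))
        res = mc.group_bms(ev, alpha0=0.5, n_draws=10_000, seed=0)
        assert res.alpha.sum() == pytest.approx(res.alpha0.sum() + 11)
        assert res.phi.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.phi_tilde.sum() == pytest.approx(1.0, abs=1e-9)
        k = len(res.phi)
        assert np.allclose(res.phi_tilde,
                           (1 - res.bor) * res.phi + res.bor / k)

    def test_identical_evidence_is_protected_to_chance(self):
        ev = pd.DataFrame(np.zeros((11, 2)), columns=["m1", "m2"])
        res = mc.group_bms(ev, n_draws=50_000, seed=1)
        assert res.bor > 0.5
        assert res.phi_tilde["m1"] == pytest.approx(0.5, abs=0.01)
        big = mc.group_bms(pd.DataFrame(np.zeros((200, 2))), n_draws=50_000,
                          seed=1)
        assert big.bor > res.bor > 0.5
        assert big.bor > 0.9

    def test_dominant_model_wins(self):
        ev = pd.DataFrame(np.zeros((11, 7)))
        ev[3] = 100.0
        res = mc.group_bms(ev, n_draws=100_000, seed=2)
        assert res.phi_tilde[3] > 0.99
        assert res.bor < 0.01

    def test_frequency_recovery_with_many_subjects(self):
        # subjects drawn from a known model-frequency vector
        rng = np.random.default_rng(3)
        freqs = np.array([0.6, 0.3, 0.1])
        z = rng.choice(3, p=freqs, size=200)
        ev = np.full((200, 3), 0.0)
        ev[np.arange(200), z] = 8.0  # strong per-subject evidence
        res = mc.group_bms(pd.DataFrame(ev), n_draws=20_000, seed=3)
        assert np.max(np.abs(res.freq_mean.to_numpy() - freqs)) < 0.07


class TestFactorBMS:
    def test_agglomeration_sums_member_concentrations(self):
        rng = np.random.default_rng(4)
        ev = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        factors = {"f": {"left": ["a", "b"], "right": ["c", "d"]}}
        full, per = mc.factor_level_bms(ev, factors, n_draws=10_000, seed=4)
        got = per["f"].alpha
        assert got["left"] == pytest.approx(full.alpha[["a", "b"]].sum())
        assert got["right"] == pytest.approx(full.alpha[["c", "d"]].sum())

    def test_explicit_space_strategy_balancing(self):
        models = ["Bay-C-E", "Bay-C-I", "Bay-X-E", "Bay-X-I", "Fix-C",
                  "Fix-X", "SFu"]
        factors = {
            "strategy": {"Bay": models[:4], "Fix": models[4:6],
                         "SFu": ["SFu"]},
            "noise": {"C": ["Bay-C-E", "Bay-C-I", "Fix-C"],
                      "X": ["Bay-X-E", "Bay-X-I", "Fix-X"]},
            "prior": {"E": ["Bay-C-E", "Bay-X-E"],
                      "I": ["Bay-C-I", "Bay-X-I"]},
        }
        w = factor_balanced_weights(models, {"strategy": factors["strategy"]})
        assert np.allclose(w[models[:4]], 1.0)
        assert np.allclose(w[["Fix-C", "Fix-X"]], 2.0)
        assert w["SFu"] == pytest.approx(4.0)

    def test_alpha0_scale_gives_order_one_factor_concentrations(self):
        models = [m.name for m in mc.joint_model_space()]
        factors = {
            "strategy": {s: [m for m in models if m.startswith(s)]
                         for s in ("Bay/Bay", "Fix/Fix", "Bay/FFu", "Fix/FFu")},
            "noise": {n: [m for m in models if f"-{n}-" in m] for n in "CX"},
            "prior": {p: [m for m in models if m.endswith(p)] for p in "EI"},
        }
        a0 = default_alpha0(models, factors)
        assert a0 == pytest.approx((4 + 2 + 2) / 3 / 16)
        for comps in factors.values():
            for ms in comps.values():
                assert 0.3 < a0 * len(ms) < 3.0

    def test_partition_must_cover(self):
        ev = pd.DataFrame(np.zeros((3, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            mc.factor_level_bms(ev, {"f": {"x": ["a"], "y": ["b"]}})


class TestCompatibility:
    def test_single_task_hypotheses_coincide(self):
        rng = np.random.default_rng(6)
        draws = {f"s{i}": {"t1": rng.normal(0.3, 0.05, 500)} for i in range(4)}
        res = mc.compatibility_probability(draws, seed=0, n_draws=20_000)
        assert np.allclose(res.likelihoods["H0"], res.likelihoods["H1"],
                           atol=1e-9)

    def test_identical_task_posteriors_favor_shared_parameter(self):
        rng = np.random.default_rng(7)
        draws = {
            f"s{i}": {t: rng.normal(0.5, 0.03, 400) for t in ("a", "b", "c")}
            for i in range(6)
        }
        res = mc.compatibility_probability(draws, seed=1, n_draws=50_000)
        assert np.all(res.likelihoods["H0"] > res.likelihoods["H1"])
        assert res.c_p > 0.5

    def test_separated_task_posteriors_favor_distinct_parameters(self):
        rng = np.random.default_rng(8)
        draws = {
            f"s{i}": {"a": rng.normal(0.2, 0.02, 400),
                      "b": rng.normal(0.8, 0.02, 400)}
            for i in range(6)
        }
        res = mc.compatibility_probability(draws, seed=2, n_draws=50_000)
        assert np.all(res.likelihoods["H1"] > res.likelihoods["H0"])
        assert res.c_p < 0.5


class TestGoodnessOfFit:
    def _data(self, n_cond=30, n_rep=40, p=0.5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for c in range(n_cond):
            for _ in range(n_rep):
                rows.append({
                    "task": "unity", "s_vis": float(c), "s_vest": float(c + 5),
                    "coherence": "med",
                    "response": "unity" if rng.uniform() < p else "separate"})
        return pd.DataFrame(rows)

    def test_chance_predictions_give_zero(self):
        data = self._data()
        n = len(data)
        gof = mc.absolute_goodness_of_fit(data, -n * np.log(2.0))
        assert gof.g == pytest.approx(0.0, abs=1e-12)

    def test_entropy_matching_predictions_give_one(self):
        data = self._data(seed=1)
        h = grassberger_entropy(
            np.array([[20, 20]] * 10, dtype=float))
        gof = mc.absolute_goodness_of_fit(data, -1.0)
        g1 = mc.absolute_goodness_of_fit(data, -gof.entropy)
        assert g1.g == pytest.approx(1.0, abs=1e-12)

    def test_linear_in_loo(self):
        data = self._data(seed=2)
        g_vals = [mc.absolute_goodness_of_fit(data, loo).g
                  for loo in (-900.0, -800.0, -700.0)]
        assert np.diff(g_vals, 2) == pytest.approx(0.0, abs=1e-9)

    def test_grassberger_approaches_plugin_for_balanced_counts(self):
        # fair-coin conditions: per-trial entropy -> log 2 as counts grow
        for n in (10, 50, 200):
            h = grassberger_entropy(np.array([[n, n]], dtype=float))
            assert abs(h / (2 * n) - np.log(2.0)) < 0.3 / n
        h50 = grassberger_entropy(np.array([[50, 50]], dtype=float))
        assert h50 / 100 == pytest.approx(np.log(2.0), abs=2e-3)

    def test_sparse_conditions_flagged(self):
        data = self._data(n_cond=100, n_rep=1, seed=3)
        gof = mc.absolute_goodness_of_fit(data, -50.0)
        assert gof.high_variance
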