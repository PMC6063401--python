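"""Measurement-conditional observer-model behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import multicause as mc
from multicause.models import NoiseParams, PriorParams, StrategyParams, step


def _noise(sigma0_vest=6.49, sigma0_vis=(4.08, 6.32, 11.57), w_vest=0.0,
           w_vis=0.0, shape="C"):
    return NoiseParams(sigma0_vest, tuple(sigma0_vis), w_vest, w_vis, shape)


class TestNoise:
    def test_eccentricity_vanishes_at_zero(self):
        npz = _noise(w_vest=0.04, w_vis=0.07, shape="X")
        assert mc.noise_sd(0.0, "vest", None, npz) == pytest.approx(6.49)

    def test_zero_coefficient_reduces_to_constant(self):
        nx = _noise(w_vest=0.0, w_vis=0.0, shape="X")
        nc = _noise(shape="C")
        s = np.linspace(-45, 45, 7)
        assert np.allclose(nx.sd(s, "vest"), nc.sd(s, "vest"), atol=1e-12)
        assert np.allclose(nx.sd(s, "vis", "low"), nc.sd(s, "vis", "low"),
                           atol=1e-12)

    def test_quadratic_form_value(self):
        npz = _noise(sigma0_vest=5.0, w_vest=0.05, shape="X")
        # sigma0 * sqrt(1 + (w s)^2) at s=20: 5*sqrt(2)
        assert npz.sd(20.0, "vest") == pytest.approx(7.0710678, abs=1e-5)

    def test_even_and_monotone_in_eccentricity(self):
        npz = _noise(w_vest=0.1, w_vis=0.1, shape="X")
        s = np.linspace(0, 80, 30)
        sd = npz.sd(s, "vest")
        assert np.all(np.diff(sd) >= 0)
        assert np.allclose(npz.sd(-s, "vest"), sd)

    def test_missing_reliability_rejected(self):
        with pytest.raises(ValueError):
            _noise().sd(0.0, "vis", None)


class TestMeasurementDensity:
    def test_normalized_and_centered(self):
        npz = _noise()
        x = np.linspace(-90, 90, 4001)
        for s in (0.0, 17.5, -40.0):
            d = mc.measurement_density(x, s, "vest", None, npz)
            assert np.trapezoid(d, x) == pytest.approx(1.0, abs=1e-6)
            assert x[np.argmax(d)] == pytest.approx(s, abs=0.1)

    def test_wrapped_matches_plain_for_narrow_noise(self):
        npz = _noise(sigma0_vest=6.0)
        x = np.linspace(-180, 180, 201)
        pw = mc.measurement_density(x, 0.0, "vest", None, npz,
                                    domain=(-180, 180), variant="wrapped")
        pp = mc.measurement_density(x, 0.0, "vest", None, npz,
                                    domain=(-180, 180), variant="plain")
        assert np.max(np.abs(pw - pp)) < 1e-10


class TestPrior:
    def test_independent_factorizes(self):
        pp = PriorParams(sigma_prior=40.0, kind="I")
        d2 = mc.prior_density(10.0, -20.0, 2, pp)
        d_a = mc.prior_density(10.0, 10.0, 1, pp)
        d_b = mc.prior_density(-20.0, -20.0, 1, pp)
        assert d2 == pytest.approx(d_a * d_b, rel=1e-12)

    @pytest.mark.parametrize("kind,dp", [("I", None), ("E", 23.5)])
    def test_sign_flip_symmetry(self, kind, dp):
        pp = PriorParams(sigma_prior=40.0, delta_prior=dp, kind=kind)
        pairs = [(10.0, -20.0), (22.5, 2.5)] if kind == "E" else \
            [(10.0, -20.0), (3.3, 7.7)]
        for sv, se in pairs:
            assert mc.prior_density(sv, se, 2, pp) == pytest.approx(
                mc.prior_density(-sv, -se, 2, pp), rel=1e-12)

    def test_narrow_disparity_prior_concentrates_on_smallest_disparity(self):
        pp = PriorParams(sigma_prior=50.0, delta_prior=1.0, kind="E")
        from multicause.models import empirical_support
        sv, se, w = empirical_support(pp, 2)
        mass_small = w[np.isclose(np.abs(se - sv), 5.0)].sum()
        assert mass_small > 0.999

    def test_empirical_c2_excludes_zero_disparity(self):
        pp = PriorParams(sigma_prior=50.0, delta_prior=20.0, kind="E")
        from multicause.models import empirical_support
        sv, se, w = empirical_support(pp, 2)
        assert np.all(np.abs(se - sv) > 0)
        assert w.sum() == pytest.approx(1.0)


def _observer(explicit=None, implicit=None, noise="C", prior="I", p_c=0.56,
              kappa_c=26.5, eta=None, lapse=0.0, sigma_prior=49.77,
              delta_prior=23.51, n_s=201, **noise_kw):
    tasks = tuple(t for t, s in (("unity", explicit), ("inertial", implicit))
                  if s is not None)
    spec = mc.ModelSpec(explicit=explicit, implicit=implicit, noise=noise,
                        prior=prior, tasks=tasks)
    needs_pc = {explicit, implicit} & {"Bay", "BayPM"}
    strat = StrategyParams(
        explicit=explicit, implicit=implicit,
        p_c=p_c if needs_pc else None,
        kappa_c=kappa_c if "Fix" in (explicit, implicit) else None,
        eta=eta, lapse=lapse)
    pr = None
    if spec.uses_prior:
        pr = PriorParams(sigma_prior=sigma_prior,
                         delta_prior=delta_prior if prior == "E" else None,
                         kind=prior)
    return mc.Observer(spec, _noise(shape=noise, **noise_kw), pr, strat, n_s=n_s)


class TestPosteriorCommonCause:
    def test_degenerate_prior_probability(self):
        xv, xe = np.array([3.0, -12.0]), np.array([8.0, 30.0])
        for p_c, want in ((1.0, 1.0), (0.0, 0.0)):
            obs = _observer(explicit="Bay", p_c=p_c)
            assert np.allclose(obs.posterior_common_cause(xv, xe, "med"), want)

    def test_monotone_in_prior_probability(self):
        xv, xe = np.array([5.0]), np.array([-15.0])
        vals = [float(_observer(explicit="Bay", p_c=p).posterior_common_cause(
            xv, xe, "med")[0]) for p in np.linspace(0.05, 0.95, 8)]
        assert np.all(np.diff(vals) > 0)

    def test_posterior_odds_algebra(self):
        # Pr(C=1|x) = p_c p(x|C=1) / [p_c p(x|C=1) + (1-p_c) p(x|C=2)];
        # in particular equal scenario likelihoods and p_c=1/2 give 1/2.
        xv, xe = np.array([4.0, -25.0]), np.array([-9.0, 11.0])
        for p_c in (0.25, 0.5, 0.8):
            obs = _observer(explicit="Bay", p_c=p_c)
            p1, p2 = obs.scenario_likelihoods(xv, xe, "low")
            want = p_c * p1 / (p_c * p1 + (1 - p_c) * p2)
            got = obs.posterior_common_cause(xv, xe, "low")
            assert np.allclose(got, want, atol=1e-12)
            assert np.allclose(p_c * 1.0 / (p_c + (1 - p_c)), p_c)

    @pytest.mark.parametrize("prior", ["I", "E"])
    def test_matches_finer_quadrature(self, prior):
        # refinement oracle: 10x finer heading grid
        xv = np.array([-30.0, 0.0, 12.0, 44.0])
        xe = np.array([10.0, 4.0, -12.0, 41.0])
        coarse = _observer(explicit="Bay", prior=prior, n_s=201)
        fine = _observer(explicit="Bay", prior=prior, n_s=2001)
        a = coarse.posterior_common_cause(xv, xe, "low")
        b = fine.posterior_common_cause(xv, xe, "low")
        assert np.max(np.abs(a - b)) < 1e-4


class TestChoiceRules:
    def test_fix_reports_unity_within_criterion(self):
        obs = _observer(explicit="Fix", kappa_c=20.0)
        p = obs.choice_prob_unity(np.array([0.0, 0.0]), np.array([10.0, 30.0]),
                                  "med")
        assert np.allclose(p, [1.0, 0.0])

    def test_full_lapse_yields_chance(self):
        for obs in (_observer(explicit="Bay", lapse=1.0),
                    _observer(explicit="Fix", lapse=1.0),
                    _observer(implicit="Bay", lapse=1.0)):
            xv, xe = np.array([7.0]), np.array([-22.0])
            if obs.strategy.explicit:
                assert obs.choice_prob_unity(xv, xe, "low")[0] == 0.5
            else:
                assert obs.choice_prob_right(xv, xe, "low")[0] == 0.5

    def test_stochastic_fusion_ignores_measurements(self):
        obs = _observer(explicit="SFu", eta=(0.75, 0.65, 0.55), p_c=None,
                        kappa_c=None, prior="I")
        xv = np.linspace(-80, 80, 9)
        assert np.allclose(obs.choice_prob_unity(xv, -xv, "high"), 0.75)
        assert np.allclose(obs.choice_prob_unity(xv, xv, "low"), 0.55)

    def test_stochastic_fusion_rejects_lapse(self):
        with pytest.raises(ValueError, match="lapse"):
            StrategyParams(explicit="SFu", eta=(0.5, 0.5, 0.5), lapse=0.1)

    def test_implicit_weight_forced_fusion_is_one(self):
        obs = _observer(implicit="FFu", p_c=None, kappa_c=None)
        xv = np.linspace(-60, 60, 5)
        assert np.allclose(obs.implicit_causal_weight(xv, -xv, "med"), 1.0)

    def test_implicit_weight_fix_at_max_criterion(self):
        obs = _observer(implicit="Fix", kappa_c=180.0, p_c=None)
        xv = np.array([-85.0, 0.0, 60.0])
        xe = np.array([85.0, -85.0, -80.0])
        assert np.allclose(obs.implicit_causal_weight(xv, xe, "med"), 1.0)

    def test_implicit_weight_bayes_certain_common_cause(self):
        obs = _observer(implicit="Bay", p_c=1.0)
        assert np.allclose(obs.implicit_causal_weight(
            np.array([-40.0]), np.array([40.0]), "low"), 1.0)

    def test_unisensory_sign_rule(self):
        obs = _observer(implicit="Bay")
        assert obs.choice_prob_right(None, np.array([10.0]), task="unisensory")[0] == 1.0
        assert obs.choice_prob_right(np.array([-0.3]), None, "med",
                                     task="unisensory")[0] == 0.0

    def test_forced_fusion_equals_bayes_with_certain_common_cause(self):
        ffu = _observer(implicit="FFu", p_c=None, kappa_c=None)
        bay = _observer(implicit="Bay", p_c=1.0)
        rng = np.random.default_rng(0)
        xv = rng.uniform(-80, 80, 50)
        xe = rng.uniform(-80, 80, 50)
        for c in ("high", "med", "low"):
            a = ffu.choice_prob_right(xv, xe, c)
            b = bay.choice_prob_right(xv, xe, c)
            assert np.max(np.abs(a - b)) < 1e-10


class TestInvariants:
    @pytest.mark.parametrize("prior", ["I", "E"])
    def test_sign_flip_antisymmetry_of_left_right(self, prior):
        for strat in ("Bay", "BayPM", "Fix", "FFu"):
            obs = _observer(implicit=strat, prior=prior, lapse=0.1)
            rng = np.random.default_rng(3)
            xv = rng.uniform(-80, 80, 40)
            xe = rng.uniform(-80, 80, 40)
            p = obs.choice_prob_right(xv, xe, "med")
            q = obs.choice_prob_right(-xv, -xe, "med")
            assert np.max(np.abs(p + q - 1.0)) < 1e-10

    @pytest.mark.parametrize("prior", ["I", "E"])
    def test_sign_flip_symmetry_of_unity(self, prior):
        for strat in ("Bay", "BayPM", "Fix"):
            obs = _observer(explicit=strat, prior=prior, lapse=0.05)
            rng = np.random.default_rng(4)
            xv = rng.uniform(-80, 80, 40)
            xe = rng.uniform(-80, 80, 40)
            p = obs.choice_prob_unity(xv, xe, "low")
            q = obs.choice_prob_unity(-xv, -xe, "low")
            assert np.max(np.abs(p - q)) < 1e-10

    def test_lapse_envelope(self):
        lam = 0.2
        grid = np.linspace(-85, 85, 21)
        XV, XE = np.meshgrid(grid, grid)
        for kind in ("unity", "inertial"):
            obs = _observer(explicit="Bay" if kind == "unity" else None,
                            implicit="Bay" if kind == "inertial" else None,
                            lapse=lam)
            if kind == "unity":
                p = obs.choice_prob_unity(XV.ravel(), XE.ravel(), "med")
            else:
                p = obs.choice_prob_right(XV.ravel(), XE.ravel(), "med")
            assert np.all(p >= lam / 2 - 1e-12)
            assert np.all(p <= 1 - lam / 2 + 1e-12)

    def test_eccentric_with_zero_coefficients_matches_constant(self):
        xc = _observer(implicit="Bay", noise="C")
        xx = _observer(implicit="Bay", noise="X", w_vest=0.0, w_vis=0.0)
        rng = np.random.default_rng(5)
        xv = rng.uniform(-80, 80, 30)
        xe = rng.uniform(-80, 80, 30)
        assert np.max(np.abs(xc.choice_prob_right(xv, xe, "low")
                             - xx.choice_prob_right(xv, xe, "low"))) < 1e-12


@given(x=st.floats(-89, 89), s=st.floats(-44, 44))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_measurement_density_positive_and_even_noise(x, s):
    npz = _noise(w_vest=0.07, shape="X", w_vis=0.07)
    d = mc.measurement_density(x, s, "vest", None, npz)
    assert d >= 0.0
    assert npz.sd(s, "vest") == pytest.approx(npz.sd(-s, "vest"))


def test_step_tie_convention():
    assert step(np.array([-1.0, 0.0, 1.0])).tolist() == [0.0, 0.5, 1.0]


class TestModelSpaces:
    def test_explicit_space_has_seven_models(self):
        names = [m.name for m in mc.explicit_model_space()]
        assert len(names) == 7 and len(set(names)) == 7
        assert "SFu" in names and "Fix-C" in names and "Bay-X-E" in names

    def test_joint_space_has_sixteen_models(self):
        names = [m.name for m in mc.joint_model_space()]
        assert len(names) == 16 and len(set(names)) == 16
        strategies = {n.split("-")[0] for n in names}
        assert strategies == {"Bay/Bay", "Fix/Fix", "Bay/FFu", "Fix/FFu"}

    def test_name_round_trip(self):
        for m in mc.joint_model_space() + mc.explicit_model_space():
            again = mc.ModelSpec.from_name(m.name, tasks=m.tasks)
            assert again == m
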