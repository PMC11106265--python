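"""Choice-model acceptance probabilities, likelihoods, and simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from riskreact.models import (
    ChoiceObservation,
    ModelParams,
    SamplingConfig,
    loglik,
    ordered_probit_pmf,
    p_accept,
    p_accept_additive,
    p_accept_ev,
    p_accept_prospect,
    p_accept_sampling,
    simulate_choices,
    utility,
    weight_logodds,
)
from riskreact.task import generate_task

from .oracles import (
    ordered_probit_pmf_oracle,
    sampling_accept_monte_carlo,
    sampling_accept_oracle,
)
from .test_task import make_trial


def additive_params(bg=0.0, bl=0.0, bp=0.0, bw=0.0):
    return ModelParams(
        "additive", {"beta_gain": bg, "beta_loss": bl, "beta_prob": bp, "beta_rew": bw}
    )


class TestEV:
    def test_hand_example(self):
        # p_O1=.8, r_O1=75, r_O2=0, r_OS=40 -> EV diff 20, beta .1 -> logistic(2)
        t = make_trial(base_trig=75.0, base_safe=40.0, noises=(0, 0, 0), stim="P4")
        assert p_accept_ev(t, ModelParams("ev", {"beta": 0.1})) == pytest.approx(
            expit(2.0)
        )

    def test_zero_beta_and_zero_ev_diff(self, design):
        flat = ModelParams("ev", {"beta": 0.0})
        for t in design.decision_trials[:10]:
            assert p_accept_ev(t, flat) == 0.5
        # EV difference exactly zero: p(.5) impossible with 4 stimuli, craft one
        t = make_trial(base_trig=80.0, base_safe=48.0, noises=(0, 0, 0), stim="P3")
        # EV = .6*80 = 48 = safe (up to float rounding of .6)
        assert p_accept_ev(t, ModelParams("ev", {"beta": 2.0})) == pytest.approx(0.5)

    def test_catch_trial_rejected(self):
        with pytest.raises(ValueError):
            p_accept_ev(make_trial(catch=True), ModelParams("ev", {"beta": 1.0}))


class TestAdditive:
    def test_all_betas_zero(self, design):
        flat = additive_params()
        assert all(p_accept_additive(t, flat) == 0.5 for t in design.decision_trials[:20])

    def test_hand_example(self):
        # P_better - P_worse = .6-.4 = .2... use P4 for .8-.2=.6; R* midpoint 40 = safe
        t = make_trial(base_trig=80.0, base_safe=40.0, noises=(9, 9, 9), stim="P4")
        p = p_accept_additive(t, additive_params(bp=1.0, bw=0.05))
        assert p == pytest.approx(expit(0.6))

    def test_monotone_in_probability_weight(self, design):
        t = next(tr for tr in design.decision_trials if tr.prob_stim.p_O1 == 0.8)
        ps = [p_accept_additive(t, additive_params(bp=b)) for b in (0.0, 0.5, 1.0, 2.0)]
        better_is_O1 = t.r_O1 > t.r_O2
        if (t.p_O1 > 0.5) == better_is_O1:
            assert ps == sorted(ps)
        else:
            assert ps == sorted(ps, reverse=True)

    def test_frame_specific_intercept(self):
        gain = make_trial(frame="gain")
        loss = make_trial(frame="loss", base_trig=-80.0, base_safe=-40.0,
                          noises=(-9, -9, -9))
        params = additive_params(bg=1.0, bl=-1.0)
        assert p_accept_additive(gain, params) == pytest.approx(expit(1.0))
        assert p_accept_additive(loss, params) == pytest.approx(expit(-1.0))


class TestWeightingAndUtility:
    def test_weighting_example(self):
        assert weight_logodds(0.2, 1.0, 0.5) == pytest.approx(1.0 / 3.0)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_identity_parameters(self, p):
        assert weight_logodds(p, 1.0, 1.0) == pytest.approx(p)

    def test_endpoints_and_domain(self):
        assert weight_logodds(0.0, 0.7, 1.3) == 0.0
        assert weight_logodds(1.0, 0.7, 1.3) == 1.0
        with pytest.raises(ValueError):
            weight_logodds(0.5, 0.0, 1.0)

    @given(st.floats(0.01, 0.99), st.floats(0.1, 5.0), st.floats(0.1, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_weighting_in_unit_interval(self, p, delta, gamma):
        assert 0.0 < weight_logodds(p, delta, gamma) < 1.0

    def test_utility(self):
        assert utility(-4.0, 1.0, 0.5) == pytest.approx(-2.0)
        assert utility(0.0, 0.8, 0.9) == 0.0
        assert utility(9.0, 1.0, 1.0) == 9.0


class TestProspect:
    def test_reduces_to_ev(self, design):
        beta = 0.07
        pt = ModelParams("prospect", {"beta": beta, "alpha_gain": 1.0,
                                      "alpha_loss": 1.0, "delta": 1.0, "gamma": 1.0})
        ev = ModelParams("ev", {"beta": beta})
        for t in design.decision_trials:
            assert p_accept_prospect(t, pt) == pytest.approx(p_accept_ev(t, ev), abs=1e-12)

    def test_compositional_oracle(self):
        t = make_trial(base_trig=75.0, base_safe=40.0, noises=(3, 3, 3), stim="P2")
        params = ModelParams("prospect", {"beta": 0.05, "alpha_gain": 0.8,
                                          "alpha_loss": 0.8, "delta": 1.0, "gamma": 0.6})
        z = (
            weight_logodds(t.p_O1, 1.0, 0.6) * utility(t.r_O1, 0.8, 0.8)
            + weight_logodds(t.p_O2, 1.0, 0.6) * utility(t.r_O2, 0.8, 0.8)
            - utility(t.r_OS, 0.8, 0.8)
        )
        assert p_accept_prospect(t, params) == pytest.approx(expit(0.05 * z))


class TestOrderedProbit:
    @given(st.floats(-2.0, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_normalized_and_positive(self, n):
        pmf = ordered_probit_pmf(n)
        assert pmf.sum() == pytest.approx(1.0)
        assert np.all(pmf >= 0)

    def test_symmetry_at_center(self):
        pmf = ordered_probit_pmf(4.0, SamplingConfig(S_max=7, c=2.0))
        assert np.allclose(pmf, pmf[::-1])

    def test_limit_and_mode_monotonicity(self):
        assert ordered_probit_pmf(100.0)[-1] == pytest.approx(1.0)
        modes = [int(np.argmax(ordered_probit_pmf(n))) for n in (1, 2, 3, 4, 5, 6, 7)]
        assert modes == sorted(modes)

    def test_matches_independent_binning(self):
        for n in (0.5, 2.7, 6.1):
            assert np.allclose(
                ordered_probit_pmf(n), ordered_probit_pmf_oracle(n, 2.0, 7)
            )


def sampling_params(n=3.0, ag=1.0, al=1.0, model="prob_sampling"):
    return ModelParams(model, {"n": n, "alpha_gain": ag, "alpha_loss": al})


class TestSampling:
    def test_dominant_cases(self):
        # both gamble outcomes better than safe -> every episode accepts
        t = make_trial(base_trig=75.0, base_safe=20.0, noises=(0, 30, 0))
        assert p_accept_sampling(t, sampling_params()) == 1.0
        # both worse -> never accepts
        t2 = make_trial(base_trig=80.0, base_safe=70.0, noises=(0, 0, 15.0))
        # r_O1=80, r_O2=0, r_OS=85: both gamble outcomes below safe
        assert p_accept_sampling(t2, sampling_params()) == 0.0

    @pytest.mark.parametrize("variant", ["probability", "utility_weighted"])
    def test_matches_sequence_enumeration_oracle(self, design, variant):
        """Marginal acceptance equals exhaustive 2^S sequence enumeration."""
        rng = np.random.default_rng(1)
        trials = [design.decision_trials[i]
                  for i in rng.choice(288, size=12, replace=False)]
        model = "prob_sampling" if variant == "probability" else "utility_sampling"
        for t in trials:
            n = rng.uniform(0.5, 7.5)
            ag = rng.uniform(0.6, 1.2)
            al = rng.uniform(0.6, 1.2)
            params = sampling_params(n, ag, al, model)
            mine = p_accept_sampling(t, params)
            if variant == "probability":
                q1 = t.p_O1
            else:
                def v(x):
                    return x**ag if x >= 0 else -(abs(x) ** al)
                a1 = t.p_O1 * abs(v(t.r_O1) - v(t.r_OS))
                a2 = t.p_O2 * abs(v(t.r_O2) - v(t.r_OS))
                q1 = a1 / (a1 + a2)
            oracle = sampling_accept_oracle(
                t.p_O1, t.r_O1, t.r_O2, t.r_OS, n, ag, al, q1
            )
            assert mine == pytest.approx(oracle, abs=1e-12)

    def test_matches_monte_carlo(self, design):
        t = design.decision_trials[5]
        params = sampling_params(3.0)
        exact = p_accept_sampling(t, params)
        mc, se = sampling_accept_monte_carlo(
            t.p_O1, t.r_O1, t.r_O2, t.r_OS, 3.0, 1.0, 1.0, t.p_O1,
            n_episodes=200_000, seed=0,
        )
        assert abs(exact - mc) < 3 * max(se, 1e-4)

    def test_utility_weighted_fallback_to_probability_proposal(self):
        # both gamble rewards equal the safe reward -> utility proposal undefined
        t = make_trial(base_trig=40.0, base_safe=40.0 - 1e-9, noises=(0, 40, 0))
        t.r_OS = 40.0
        t.r_O2 = 40.0
        params = sampling_params(model="utility_sampling")
        assert p_accept_sampling(t, params) == 0.5


class TestLoglikAndSimulation:
    def test_loglik_basics(self):
        assert loglik(additive_params(), []) == 0.0
        obs = ChoiceObservation(make_trial(), 1)
        assert loglik(additive_params(), [obs]) == pytest.approx(np.log(0.5))

    def test_loglik_per_trial_oracle(self, design):
        params = additive_params(bg=0.3, bp=2.0, bw=0.03)
        data = simulate_choices(params, design, seed=4)[:50]
        expected = 0.0
        for o in data:
            p = p_accept(o.trial, params)
            expected += np.log(p) if o.accept else np.log(1 - p)
        assert loglik(params, data) == pytest.approx(expected)

    def test_simulation_rates(self, design):
        # flat model: acceptance rate ~ .5 within 3 s.e. over 288 trials
        flat = simulate_choices(additive_params(), design, seed=0)
        rate = np.mean([o.accept for o in flat])
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / 288)
        # saturated intercepts: always accept
        greedy = simulate_choices(additive_params(bg=50.0, bl=50.0), design, seed=0)
        assert all(o.accept for o in greedy)

    def test_simulation_deterministic(self, design):
        params = additive_params(bp=3.0, bw=0.05)
        a = [o.accept for o in simulate_choices(params, design, seed=7)]
        b = [o.accept for o in simulate_choices(params, design, seed=7)]
        assert a == b

    def test_cell_frequencies_match_probabilities(self):
        # Monte-Carlo: empirical acceptance matches p_accept within binomial error
        t = make_trial(base_trig=75.0, base_safe=40.0, noises=(2, 2, 2), stim="P3")
        params = additive_params(bg=0.2, bp=2.0, bw=0.04)
        p = p_accept(t, params)
        rng = np.random.default_rng(11)
        n = 10_000
        hits = int((rng.random(n) < p).sum())
        assert abs(hits / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_probabilities_strictly_within_unit_interval(self, design):
        params = additive_params(bg=1.0, bl=-1.0, bp=5.0, bw=0.1)
        for t in design.decision_trials[:50]:
            assert 0.0 < p_accept(t, params) < 1.0
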