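"""Model-family tests: update rules, decision variables, likelihoods."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracle import oracle_nll
from conftest import random_session, session_frame
from bmprl import bmp_task, rl_models as rl, synthetic_data as sd

ALL_FAMILIES = list(rl.BASELINE_FAMILIES) + list(rl.K_FAMILIES)

BASELINE_Y = sd.saline_baseline("Y")


def random_params(rng) -> rl.ParamSet:
    return rl.ParamSet(
        alpha_F=rng.uniform(0, 1), alpha_F_C=rng.uniform(0, 1),
        alpha_F_UC=rng.uniform(0, 1), alpha_L=rng.uniform(0, 1),
        delta_gain=rng.uniform(-2, 2), delta_neutral=rng.uniform(-2, 2),
        delta_loss=rng.uniform(-3, 1), beta=rng.uniform(0.2, 3),
        lambda_=rng.uniform(-0.5, 0.5), epsilon=rng.uniform(0, 1),
        omega1=rng.uniform(-1, 1), omega2=rng.uniform(-1, 1),
        omega3=rng.uniform(-1, 1), rho=rng.uniform(0, 1),
        tau=rng.uniform(0, 2), phi=rng.uniform(0, 1),
        k=rng.uniform(-1, 1), k1=rng.uniform(-1, 1), k2=rng.uniform(-1, 1))


def make_spec(family: str) -> rl.ModelSpec:
    if family.startswith("K"):
        return rl.ModelSpec(family, baseline=dict(BASELINE_Y))
    return rl.ModelSpec(family)


class TestUpdateValues:
    def test_df_update_published_arithmetic(self):
        """With the P-saline DF parameters, a right gain from zero state gives
        Q(R) = 0.72*0 + (-0.57) and Q(L) = 0.09*0."""
        state = rl.ValueState()
        new = rl.update_values(state, "R", "gain", 3, rl.ModelSpec("DF"),
                               sd.saline_paramset("P"))
        assert new.q_right == pytest.approx(-0.57, abs=1e-12)
        assert new.q_left == 0.0

    def test_df_update_from_nonzero_state(self):
        params = sd.saline_paramset("P")
        state = rl.ValueState(q_right=0.5, q_left=-0.4)
        new = rl.update_values(state, "R", "loss", 0, rl.ModelSpec("DF"), params)
        assert new.q_right == pytest.approx(0.72 * 0.5 - 2.31)
        assert new.q_left == pytest.approx(0.09 * -0.4)

    def test_zero_params_zero_state_fixed_point(self):
        for family in ALL_FAMILIES:
            spec = make_spec(family)
            if spec.baseline is not None:
                spec = rl.ModelSpec(family, baseline={k: 0.0 for k in BASELINE_Y})
            new = rl.update_values(rl.ValueState(), "R", "gain", 2, spec,
                                   rl.ParamSet())
            assert new.q_right == 0.0 and new.q_left == 0.0

    def test_ndf_nested_in_df(self):
        """With equal chosen/unchosen rates the DF and NDF trajectories agree
        on any shared input sequence."""
        rng = np.random.default_rng(0)
        p_df = rl.ParamSet(alpha_F_C=0.6, alpha_F_UC=0.6, delta_gain=0.4,
                           delta_neutral=-0.1, delta_loss=-1.2)
        p_ndf = dataclasses.replace(p_df, alpha_F=0.6)
        s_df, s_ndf = rl.ValueState(), rl.ValueState()
        for c, o, a in random_session(1, 100):
            s_df = rl.update_values(s_df, c, o, a, rl.ModelSpec("DF"), p_df)
            s_ndf = rl.update_values(s_ndf, c, o, a, rl.ModelSpec("NDF"), p_ndf)
            assert s_df.q_right == pytest.approx(s_ndf.q_right, abs=1e-14)
            assert s_df.q_left == pytest.approx(s_ndf.q_left, abs=1e-14)

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError):
            rl.update_values(rl.ValueState(), "R", "draw", 0,
                             rl.ModelSpec("DF"), rl.ParamSet())


class TestDecisionVariable:
    def test_perseveration_gate_closed(self):
        state = rl.ValueState(q_right=0.8, q_left=-0.3, recent_choices=(1.0,))
        spec = rl.ModelSpec("K6", baseline=dict(BASELINE_Y))
        x = rl.decision_variable(state, spec, rl.ParamSet(epsilon=0.0))
        assert x == pytest.approx(1.1)

    def test_pure_perseveration(self):
        state = rl.ValueState(q_right=-5.0, q_left=3.0, recent_choices=(1.0,))
        spec = rl.ModelSpec("K6", baseline=dict(BASELINE_Y))
        x = rl.decision_variable(state, spec, rl.ParamSet(epsilon=1.0))
        assert x == 1.0

    def test_statistical_learning_threshold_gate(self):
        spec = rl.ModelSpec("K10", baseline=dict(BASELINE_Y))
        params = rl.ParamSet(omega1=2.0, tau=1.0, rho=0.9, phi=0.9)
        state = rl.ValueState(q_right=0.2, q_left=0.1, freq_right=0.6,
                              freq_left=0.2, avg_delta=-1.0)
        # |rFreq| = 0.4 < tau: the statistical-learning term contributes 0
        assert rl.decision_variable(state, spec, params) == pytest.approx(0.1)
        above = dataclasses.replace(state, freq_right=1.5)
        x = rl.decision_variable(above, spec, params)
        assert x == pytest.approx(0.1 + 2.0 * 1.3 * -1.0)


class TestChoiceProbability:
    @pytest.mark.parametrize("x,beta,expected", [
        (0.0, 1.0, 0.5),
        (0.0, 7.3, 0.5),
        (1.0, 1.0, 1 / (1 + math.exp(-1))),
        (1e6, 1.0, 1.0),
        (-1e6, 1.0, 0.0),
    ])
    def test_values(self, x, beta, expected):
        assert rl.choice_probability(x, beta) == pytest.approx(expected, abs=1e-9)

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            rl.choice_probability(0.0, 0.0)


class TestSessionNll:
    def test_single_trial_is_log_two(self):
        frame = session_frame([("R", "gain", 2)])
        for family in ("DF", "Q", "K4"):
            nll = rl.session_nll(frame, make_spec(family), rl.ParamSet())
            assert nll == pytest.approx(math.log(2), abs=1e-12)

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_matches_independent_oracle(self, family):
        """Package likelihood (object path and vectorised path) equals a
        brute-force history-based recomputation."""
        rng = np.random.default_rng(sum(ord(c) for c in family))
        for rep in range(3):
            params = random_params(rng)
            spec = make_spec(family)
            triples = random_session(100 + rep, 150)
            frame = session_frame(triples)
            expected = oracle_nll(triples, family, dataclasses.asdict(params),
                                  baseline=spec.baseline)
            got = rl.session_nll(frame, spec, params)
            pooled = rl.pooled_nll(rl.pack_sessions([frame]), spec, params)
            assert got == pytest.approx(expected, abs=1e-10)
            assert pooled == pytest.approx(expected, abs=1e-10)

    def test_relabeling_symmetry(self):
        """Swapping L and R jointly across choices leaves the likelihood
        unchanged."""
        rng = np.random.default_rng(11)
        triples = random_session(3, 200)
        flipped = [("L" if c == "R" else "R", o, a) for c, o, a in triples]
        for family in ("DF", "QSE", "K6", "K10"):
            params = random_params(rng)
            spec = make_spec(family)
            a = rl.session_nll(session_frame(triples), spec, params)
            b = rl.session_nll(session_frame(flipped), spec, params)
            assert a == pytest.approx(b, abs=1e-10)

    def test_nan_params_rejected(self):
        with pytest.raises(ValueError):
            rl.session_nll(session_frame(random_session(0, 5)),
                           rl.ModelSpec("DF"),
                           rl.ParamSet(delta_gain=float("nan")))


class TestNestingIdentities:
    def test_k1_with_zero_shift_equals_baseline(self):
        frame = session_frame(random_session(5, 300))
        base_spec = rl.ModelSpec("DF")
        base_params = sd.saline_paramset("Y")
        nll_df = rl.session_nll(frame, base_spec, base_params)
        k1 = rl.session_nll(frame, make_spec("K1"), rl.ParamSet(k=0.0))
        assert k1 == pytest.approx(nll_df, abs=1e-12)

    def test_k2_reduces_to_k1_with_equal_shifts(self):
        frame = session_frame(random_session(6, 300))
        a = rl.session_nll(frame, make_spec("K1"), rl.ParamSet(k=0.37))
        b = rl.session_nll(frame, make_spec("K2"), rl.ParamSet(k1=0.37, k2=0.37))
        assert a == pytest.approx(b, abs=1e-12)

    @pytest.mark.parametrize("family,params", [
        ("K3", rl.ParamSet()),
        ("K4", rl.ParamSet(delta_gain=-0.54, delta_neutral=-1.91,
                           delta_loss=-3.15)),
        ("K5", rl.ParamSet(alpha_F_C=0.65, alpha_F_UC=0.20)),
        ("K6", rl.ParamSet(epsilon=0.0)),
        ("K8", rl.ParamSet()),
        ("K9", rl.ParamSet()),
        ("K10", rl.ParamSet(rho=0.5, tau=0.1, phi=0.5)),
    ])
    def test_kmodels_reduce_to_baseline(self, family, params):
        """Every K-model collapses onto the frozen saline DF model when its
        deviation parameters vanish (or reproduce the saline values)."""
        frame = session_frame(random_session(7, 300))
        nll_df = rl.session_nll(frame, rl.ModelSpec("DF"), sd.saline_paramset("Y"))
        nll_k = rl.session_nll(frame, make_spec(family), params)
        assert nll_k == pytest.approx(nll_df, abs=1e-12)

    def test_qse_r_nested_in_qse(self):
        frame = session_frame(random_session(8, 300))
        p = rl.ParamSet(alpha_F=0.7, delta_gain=0.5, delta_neutral=0.0,
                        delta_loss=-1.0)
        a = rl.session_nll(frame, rl.ModelSpec("QSE"), p)
        b = rl.session_nll(frame, rl.ModelSpec("QSE-R"), p)
        assert a == pytest.approx(b, abs=1e-12)


class TestValueBoundedness:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_df_values_bounded_by_geometric_sum(self, seed):
        """|Q| <= max(|Q0|, D/(1-alpha)) for forgetting rates in (0,1)."""
        rng = np.random.default_rng(seed)
        alpha = rng.uniform(0.05, 0.95)
        params = rl.ParamSet(alpha_F_C=alpha, alpha_F_UC=rng.uniform(0, alpha),
                             delta_gain=rng.uniform(-2, 2),
                             delta_neutral=rng.uniform(-2, 2),
                             delta_loss=rng.uniform(-2, 2))
        d_max = max(abs(params.delta_gain), abs(params.delta_neutral),
                    abs(params.delta_loss))
        bound = d_max / (1 - alpha) + 1e-9
        state = rl.ValueState()
        for c, o, a in random_session(seed % 1000, 200):
            state = rl.update_values(state, c, o, a, rl.ModelSpec("DF"), params)
            assert abs(state.q_right) <= bound and abs(state.q_left) <= bound

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_standard_q_confined_to_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        params = rl.ParamSet(alpha_L=rng.uniform(0.01, 1.0))
        state = rl.ValueState()
        for c, o, a in random_session(seed % 1000, 200):
            state = rl.update_values(state, c, o, a, rl.ModelSpec("Q"), params)
            assert -1.0 <= state.q_right <= 1.0
            assert -1.0 <= state.q_left <= 1.0


class TestSimulateAgent:
    def test_deterministic_given_seed(self, task_p, uniform_opponent, df_spec,
                                      p_saline):
        a = rl.simulate_agent(task_p, uniform_opponent, df_spec, p_saline, 300, 42)
        b = rl.simulate_agent(task_p, uniform_opponent, df_spec, p_saline, 300, 42)
        assert a.equals(b)

    def test_indifferent_agent_chooses_uniformly(self, task_p, uniform_opponent):
        frame = rl.simulate_agent(task_p, uniform_opponent, rl.ModelSpec("DF"),
                                  rl.ParamSet(), 6000, 9)
        frac_r = (frame.animal_choice == "R").mean()
        assert abs(frac_r - 0.5) < 3 * np.sqrt(0.25 / 6000)

    def test_switch_probability_ordering(self, task_p, uniform_opponent,
                                         df_spec, p_saline):
        """Loss is the most aversive outcome: P(switch | loss) >
        P(switch | neutral) > P(switch | gain)."""
        frame = rl.simulate_agent(task_p, uniform_opponent, df_spec, p_saline,
                                  10_000, 10)
        prev_choice = frame.animal_choice.shift(1)
        prev_out = frame.outcome_class.shift(1)
        switched = frame.animal_choice != prev_choice
        p = {o: switched[prev_out == o].mean()
             for o in ("gain", "neutral", "loss")}
        assert p["loss"] > p["neutral"] > p["gain"]
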