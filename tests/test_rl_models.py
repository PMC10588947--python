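import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import example_params, frame_to_trial_dicts, random_block
from oracles import straight_line_loglik, straight_line_trial_probs
from unchosen._likelihoods import cohort_rowwise_logp, pack_cohort
from unchosen.rl_models import (
    MODEL_IDS,
    ModelParams,
    QState,
    choice_prob,
    init_state,
    sequence_loglik,
    simulate_agent,
    truncate_q,
    update_state,
)
from unchosen.synthetic_task import CohortDataset, RewardSchedule, TaskConfig, generate_offers


class TestInitState:
    def test_baseline_all_half(self):
        state = init_state("baseline", 4)
        assert np.array_equal(state.q, [0.5, 0.5, 0.5, 0.5])

    def test_select_reject_eight_values(self):
        state = init_state("select_reject", 4)
        assert len(state.values()) == 8
        assert np.all(state.values() == 0.5)

    def test_zero_arms_rejected(self):
        with pytest.raises(ValueError):
            init_state("baseline", 0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            init_state("epsilon_greedy", 4)


class TestChoiceProb:
    def test_equal_values_symmetric(self):
        state = init_state("baseline", 4)
        pa, pb = choice_prob("baseline", state, (0, 1), example_params("baseline"))
        assert pa == pytest.approx(0.5)
        assert pa + pb == pytest.approx(1.0)

    def test_zero_beta_uniform(self):
        state = init_state("baseline", 4)
        state.q[:] = [0.9, 0.1, 0.5, 0.5]
        params = ModelParams(model="baseline", alpha_chosen=0.3, beta=0.0)
        pa, pb = choice_prob("baseline", state, (0, 1), params)
        assert pa == pytest.approx(0.5)

    def test_baseline_softmax_value(self):
        # beta * (0.6 - 0.4) = 0.8 -> p = 1 / (1 + e^-0.8)
        state = init_state("baseline", 4)
        state.q[0], state.q[1] = 0.6, 0.4
        params = ModelParams(model="baseline", alpha_chosen=0.3, beta=4.0)
        pa, _ = choice_prob("baseline", state, (0, 1), params)
        assert pa == pytest.approx(1.0 / (1.0 + np.exp(-0.8)), abs=1e-12)

    def test_select_reject_net_value_mixing(self):
        state = init_state("select_reject", 4)
        state.q_select[0] = 0.6
        state.q_reject[1] = 0.4
        params = ModelParams(model="select_reject", alpha_chosen=0.3, omega=0.7, beta=1.0)
        # v(offer0) = 0.7 * 0.6 + 0.3 * 0.4 = 0.54
        pa, _ = choice_prob("select_reject", state, (0, 1), params)
        v0 = 0.7 * 0.6 + 0.3 * 0.4
        v1 = 0.7 * 0.5 + 0.3 * 0.5
        assert pa == pytest.approx(1.0 / (1.0 + np.exp(-(v0 - v1))), abs=1e-12)

    @given(
        q=st.lists(st.floats(0, 1), min_size=4, max_size=4),
        beta=st.floats(0, 20),
    )
    @settings(max_examples=50, deadline=None)
    def test_probabilities_sum_to_one_and_positive(self, q, beta):
        state = init_state("baseline", 4)
        state.q[:] = q
        params = ModelParams(model="baseline", alpha_chosen=0.5, beta=beta)
        pa, pb = choice_prob("baseline", state, (2, 3), params)
        assert pa + pb == pytest.approx(1.0)
        assert pa > 0 and pb > 0

    @given(
        q_low=st.floats(0, 1), q_high=st.floats(0, 1), bump=st.floats(0, 0.5)
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_own_value(self, q_low, q_high, bump):
        params = ModelParams(model="baseline", alpha_chosen=0.5, beta=5.0)
        state = init_state("baseline", 4)
        state.q[0], state.q[1] = q_low, q_high
        p_before, _ = choice_prob("baseline", state, (0, 1), params)
        state.q[0] = min(1.0, q_low + bump)
        p_after, _ = choice_prob("baseline", state, (0, 1), params)
        assert p_after >= p_before - 1e-12


class TestUpdateState:
    def test_baseline_update(self):
        state = init_state("baseline", 4)
        params = ModelParams(model="baseline", alpha_chosen=0.3, beta=1.0)
        new, pes = update_state("baseline", state, (0, 1), 0, 1, params)
        assert pes.delta_chosen == pytest.approx(0.5)
        assert new.q[0] == pytest.approx(0.65)
        assert np.all(new.q[1:] == 0.5)

    def test_double_two_pe_inverted_outcome(self):
        state = init_state("double_two_pe", 4)
        params = ModelParams(
            model="double_two_pe", alpha_chosen=0.3, alpha_unchosen=0.1, beta=1.0
        )
        new, pes = update_state("double_two_pe", state, (0, 1), 0, 1, params)
        assert pes.delta_unchosen == pytest.approx(-0.5)
        assert new.q[1] == pytest.approx(0.45)

    def test_double_one_pe_shared_error(self):
        state = init_state("double_one_pe", 4)
        params = ModelParams(
            model="double_one_pe", alpha_chosen=0.3, alpha_unchosen=0.1, beta=1.0
        )
        new, pes = update_state("double_one_pe", state, (0, 1), 0, 1, params)
        assert pes.delta_chosen == pytest.approx(0.5)
        assert new.q[1] == pytest.approx(0.5 - 0.1 * 0.5)

    def test_select_reject_reject_value_moves_toward_reward(self):
        state = init_state("select_reject", 4)
        params = ModelParams(model="select_reject", alpha_chosen=0.3, omega=0.7, beta=1.0)
        new, pes = update_state("select_reject", state, (0, 1), 0, 1, params)
        assert pes.delta_unchosen == pytest.approx(0.5)
        assert new.q_reject[1] == pytest.approx(0.65)  # toward reward, not inverse
        assert new.q_select[0] == pytest.approx(0.65)
        assert new.q_select[1] == 0.5 and new.q_reject[0] == 0.5

    def test_unoffered_arms_untouched(self):
        for model in MODEL_IDS:
            state = init_state(model, 4)
            new, _ = update_state(model, state, (0, 1), 0, 1, example_params(model))
            assert np.all(new.values()[[2, 3]] == 0.5) or np.all(
                np.asarray(new.values())[[2, 3, 6, 7]] == 0.5
            )

    def test_raw_payoff_rejected(self):
        state = init_state("baseline", 4)
        with pytest.raises(ValueError, match="recode"):
            update_state("baseline", state, (0, 1), 0, -1, example_params("baseline"))

    @given(
        rewards=st.lists(st.integers(0, 1), min_size=5, max_size=30),
        alpha=st.floats(0.01, 0.99),
        alpha_u=st.floats(0.01, 0.99),
    )
    @settings(max_examples=30, deadline=None)
    def test_values_stay_bounded_and_errors_bounded(self, rewards, alpha, alpha_u):
        params = ModelParams(
            model="double_one_pe", alpha_chosen=alpha, alpha_unchosen=alpha_u, beta=1.0
        )
        state = init_state("double_one_pe", 4)
        for i, r in enumerate(rewards):
            offer = ((i % 3), ((i % 3) + 1))
            state, pes = update_state("double_one_pe", state, offer, offer[0], r, params)
            assert -1.0 <= pes.delta_chosen <= 1.0
            assert np.all(state.q >= 0.0) and np.all(state.q <= 1.0)


class TestTruncate:
    def test_clamps_and_preserves(self):
        state = QState("baseline", q=np.array([1.08, -0.03, 0.5, 1.0]))
        out = truncate_q(state)
        assert np.array_equal(out.q, [1.0, 0.0, 0.5, 1.0])


class TestSequenceLoglik:
    def test_first_trial_symmetric(self):
        rng = np.random.default_rng(0)
        block = random_block(rng, n_trials=1)
        total, per_trial = sequence_loglik("baseline", example_params("baseline"), block)
        assert total == pytest.approx(np.log(0.5))
        assert len(per_trial) == 1

    def test_zero_beta_pure_noise(self):
        rng = np.random.default_rng(1)
        block = random_block(rng, n_trials=20)
        params = ModelParams(model="baseline", alpha_chosen=0.3, beta=0.0)
        total, _ = sequence_loglik("baseline", params, block)
        assert total == pytest.approx(20 * np.log(0.5))

    def test_no_response_trials_skipped(self):
        rng = np.random.default_rng(2)
        block = random_block(rng, n_trials=10)
        block.loc[4, "choice"] = pd.NA
        _, per_trial = sequence_loglik("baseline", example_params("baseline"), block)
        assert len(per_trial) == 9

    def test_multi_block_frame_rejected(self):
        rng = np.random.default_rng(3)
        b1 = random_block(rng, block=1)
        b2 = random_block(rng, block=2)
        with pytest.raises(ValueError, match="one block"):
            sequence_loglik("baseline", example_params("baseline"), pd.concat([b1, b2]))

    def test_unsorted_rejected(self):
        rng = np.random.default_rng(4)
        block = random_block(rng).iloc[::-1]
        with pytest.raises(ValueError, match="sorted"):
            sequence_loglik("baseline", example_params("baseline"), block)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_omega_one_reduces_to_baseline(self, seed):
        rng = np.random.default_rng(seed)
        block = random_block(rng)
        sr = ModelParams(model="select_reject", alpha_chosen=0.3, omega=1.0, beta=4.0)
        bl = ModelParams(model="baseline", alpha_chosen=0.3, beta=4.0)
        _, lp_sr = sequence_loglik("select_reject", sr, block)
        _, lp_bl = sequence_loglik("baseline", bl, block)
        assert np.max(np.abs(lp_sr - lp_bl)) <= 1e-10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_unchosen_rate_reduces_to_baseline(self, seed):
        rng = np.random.default_rng(seed)
        block = random_block(rng)
        d1 = ModelParams(model="double_one_pe", alpha_chosen=0.3, alpha_unchosen=0.0, beta=4.0)
        bl = ModelParams(model="baseline", alpha_chosen=0.3, beta=4.0)
        _, lp_d1 = sequence_loglik("double_one_pe", d1, block)
        _, lp_bl = sequence_loglik("baseline", bl, block)
        assert np.max(np.abs(lp_d1 - lp_bl)) <= 1e-10

    @pytest.mark.parametrize("model", MODEL_IDS)
    def test_matches_straight_line_oracle(self, model):
        rng = np.random.default_rng(17)
        block = random_block(rng)
        params = example_params(model)
        total, _ = sequence_loglik(model, params, block)
        oracle = straight_line_loglik(model, params.to_dict(), frame_to_trial_dicts(block))
        assert total == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("model", MODEL_IDS)
    def test_compiled_kernels_match_oracle(self, model):
        rng = np.random.default_rng(23)
        block = random_block(rng)
        data = CohortDataset(block)
        packed = pack_cohort(data)
        params = example_params(model)
        logp = cohort_rowwise_logp(model, packed, params.as_array()[None, :].repeat(1, 0))
        oracle = straight_line_trial_probs(model, params.to_dict(), frame_to_trial_dicts(block))
        assert np.max(np.abs(logp - np.log(oracle))) <= 1e-10


class TestSimulateAgent:
    def _static_schedule(self, p_values, n_trials=200):
        p = np.tile(np.asarray(p_values, float), (1, n_trials, 1))
        return RewardSchedule(p)

    def test_greedy_limit_prefers_better_arm(self):
        cfg = TaskConfig(n_blocks=1, trials_per_block=200, drift_sd=0.0)
        schedule = self._static_schedule([[[0.9, 0.1, 0.9, 0.1]]])
        offers = np.tile([0, 1], (1, 200, 1))
        params = ModelParams(model="baseline", alpha_chosen=0.5, beta=50.0)
        df = simulate_agent("baseline", params, schedule, offers, cfg, seed=0)
        late = df[df["trial"] > 50]
        assert (late["choice"] == 0).mean() > 0.9

    def test_zero_beta_uniform_choice(self):
        cfg = TaskConfig(n_blocks=1, trials_per_block=2000, drift_sd=0.0)
        schedule = self._static_schedule([[[0.9, 0.1, 0.5, 0.5]]], n_trials=2000)
        offers = np.tile([0, 1], (1, 2000, 1))
        params = ModelParams(model="baseline", alpha_chosen=0.3, beta=0.0)
        df = simulate_agent("baseline", params, schedule, offers, cfg, seed=1)
        assert abs((df["choice"] == 0).mean() - 0.5) < 0.03

    def test_double_one_pe_degenerate_matches_baseline(self, small_task_config):
        from unchosen.synthetic_task import generate_reward_schedule

        schedule = generate_reward_schedule(small_task_config, 5)
        offers = generate_offers(small_task_config, 6)
        d1 = ModelParams(model="double_one_pe", alpha_chosen=0.3, alpha_unchosen=0.0, beta=4.0)
        bl = ModelParams(model="baseline", alpha_chosen=0.3, beta=4.0)
        df1 = simulate_agent("double_one_pe", d1, schedule, offers, small_task_config, seed=7)
        df2 = simulate_agent("baseline", bl, schedule, offers, small_task_config, seed=7)
        pd.testing.assert_frame_equal(df1, df2)

    def test_seed_determinism(self, small_task_config):
        from unchosen.synthetic_task import generate_reward_schedule

        schedule = generate_reward_schedule(small_task_config, 5)
        offers = generate_offers(small_task_config, 6)
        params = example_params("select_reject")
        a = simulate_agent("select_reject", params, schedule, offers, small_task_config, seed=3)
        b = simulate_agent("select_reject", params, schedule, offers, small_task_config, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestModelParams:
    def test_field_configuration_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(model="baseline", alpha_chosen=0.3, beta=1.0, omega=0.5)
        with pytest.raises(ValueError):
            ModelParams(model="select_reject", alpha_chosen=0.3, beta=1.0)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(model="baseline", alpha_chosen=1.2, beta=1.0)
        with pytest.raises(ValueError):
            ModelParams(model="baseline", alpha_chosen=0.3, beta=-1.0)

    def test_array_round_trip(self):
        p = example_params("select_reject")
        q = ModelParams.from_array("select_reject", p.as_array())
        assert p == q
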