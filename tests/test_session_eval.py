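"""Alternating training/testing sessions, metrics and model comparison."""

import numpy as np
import pytest

from neurostim import (
    NetworkParams,
    Outcome,
    SessionSchedule,
    StimulationEnv,
    TrialRecord,
    compare_distributions,
    compute_metrics,
    evaluate_vs_model,
    run_cohort,
    run_session,
    recovery_strength,
    sample_network_params,
    trials_to_frame,
)
from neurostim.model_fit import FitResult, IbiFit, RecoveryFit


def _rec(i, outcome, spikes, reward):
    return TrialRecord(
        trial_index=i, start_time=float(i), chosen_state=1,
        outcome=outcome, response_spikes=spikes, reward=reward,
    )


class TestComputeMetrics:
    def test_hand_built_round(self):
        records = [
            _rec(0, Outcome.STIMULATED, 5, 5.0),
            _rec(1, Outcome.INTERRUPTED, 0, 0.0),
            _rec(2, Outcome.STIMULATED, 3, 3.0),
            _rec(3, Outcome.STIMULATED, 2, 2.0),
        ]
        m = compute_metrics(records)
        assert m.rs_per_sb == pytest.approx(2.5)          # 10 spikes / 4 trials
        assert m.interruption_fraction == pytest.approx(0.25)
        assert m.mean_reward == pytest.approx(2.5)
        assert m.rs_per_stimulus_mean == pytest.approx(10 / 3)
        assert m.n_stimulated == 3

    def test_all_interrupted(self):
        records = [_rec(i, Outcome.INTERRUPTED, 0, 0.0) for i in range(5)]
        m = compute_metrics(records)
        assert m.rs_per_sb == 0.0
        assert m.interruption_fraction == 1.0
        assert m.n_stimulated == 0

    def test_order_invariance(self, rng):
        records = [
            _rec(i, Outcome.STIMULATED if i % 3 else Outcome.INTERRUPTED,
                 i % 3 * 4, float(i % 3 * 4))
            for i in range(30)
        ]
        m1 = compute_metrics(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        m2 = compute_metrics(shuffled)
        assert m1.rs_per_sb == m2.rs_per_sb
        assert m1.interruption_fraction == m2.interruption_fraction
        assert m1.rs_per_stimulus_sd == m2.rs_per_stimulus_sd

    def test_empty_round_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([])


class TestRunSession:
    def test_default_schedule_logs_exactly_1000_trials(self, canonical):
        env = StimulationEnv(canonical, rng=np.random.default_rng(0))
        log = run_session(env, rng=np.random.default_rng(1))
        assert len(log.trials) == 1000
        kinds = [k for k, _ in log.round_of_trial]
        assert kinds.count("train") == 800
        assert kinds.count("test") == 200
        assert len(log.rounds) == 8
        assert log.learned_latency in set(env.state_latencies)

    def test_zero_hazard_deterministic_session_learns_last_state(self):
        # no interruptions + monotone deterministic rewards: wait to the end
        p = NetworkParams(A=20, B=6.67, lam=0.2, mu=50.0, sigma=1.0)
        env = StimulationEnv(p, noise_model="deterministic",
                             rng=np.random.default_rng(1))
        log = run_session(env, rng=np.random.default_rng(2))
        assert log.learned_state == env.n_states
        assert log.learned_latency == pytest.approx(10.0)

    def test_session_log_replays_to_same_metrics(self, canonical):
        env = StimulationEnv(canonical, rng=np.random.default_rng(3))
        log = run_session(env, rng=np.random.default_rng(4))
        df = trials_to_frame(log)
        round_idx = 0
        for pair in range(4):
            for kind, n in (("train", 200), ("test", 50)):
                sel = df[(df.round_kind == kind) & (df.round_pair == pair)]
                assert len(sel) == n
                m = log.rounds[round_idx]
                assert sel.response_spikes.sum() / n == pytest.approx(m.rs_per_sb)
                assert (sel.outcome == "interrupted").mean() == pytest.approx(
                    m.interruption_fraction
                )
                assert sel.reward.mean() == pytest.approx(m.mean_reward)
                round_idx += 1

    def test_testing_rounds_freeze_the_policy(self, canonical):
        # within one testing round every stimulated trial uses one state
        env = StimulationEnv(canonical, rng=np.random.default_rng(5))
        log = run_session(env, rng=np.random.default_rng(6))
        df = trials_to_frame(log)
        for pair in range(4):
            sel = df[(df.round_kind == "test") & (df.round_pair == pair)]
            assert sel.chosen_state.nunique() == 1


@pytest.fixture(scope="module")
def canonical_sessions():
    p = NetworkParams.canonical()
    logs = []
    for run in range(30):
        env = StimulationEnv(p, rng=np.random.default_rng(3000 + run))
        logs.append(run_session(env, rng=np.random.default_rng(4000 + run)))
    return logs


class TestSessionStatistics:
    def test_testing_beats_training_efficacy_in_most_sessions(
        self, canonical_sessions
    ):
        wins = 0
        for log in canonical_sessions:
            tr = [m for m in log.rounds if m.kind == "train"][-1]
            te = [m for m in log.rounds if m.kind == "test"][-1]
            wins += te.rs_per_sb > tr.rs_per_sb
        assert wins >= int(0.7 * len(canonical_sessions))

    def test_response_variability_drops_while_mean_is_preserved(
        self, canonical_sessions
    ):
        sd_tr, sd_te, mean_tr, mean_te = [], [], [], []
        for log in canonical_sessions:
            tr = [m for m in log.rounds if m.kind == "train"][-1]
            te = [m for m in log.rounds if m.kind == "test"][-1]
            sd_tr.append(tr.rs_per_stimulus_sd)
            sd_te.append(te.rs_per_stimulus_sd)
            mean_tr.append(tr.rs_per_stimulus_mean)
            mean_te.append(te.rs_per_stimulus_mean)
        assert np.median(sd_te) < np.median(sd_tr)
        assert np.median(mean_te) == pytest.approx(np.median(mean_tr), rel=0.25)

    def test_reward_distribution_shifts_after_learning(self, canonical_sessions):
        log = canonical_sessions[0]
        df = trials_to_frame(log)
        pre = df[(df.round_kind == "train") & (df.round_pair == 3)].reward
        post = df[(df.round_kind == "test") & (df.round_pair == 3)].reward
        stat, p_val = compare_distributions(pre, post, test="KS")
        assert stat > 0.0
        assert p_val < 0.05


class TestEvaluateVsModel:
    def test_deterministic_no_interruption_efficacy_equals_model(self):
        p = NetworkParams(A=20, B=6.67, lam=0.2, mu=50.0, sigma=1.0)
        env = StimulationEnv(p, noise_model="deterministic",
                             rng=np.random.default_rng(1))
        log = run_session(env, rng=np.random.default_rng(2))
        fit = FitResult(
            recovery=RecoveryFit(A=p.A, B=p.B, lam=p.lam, cov=np.zeros((3, 3)),
                                 residual_ss=0.0, n_points=100, mode="per-trial"),
            ibi=IbiFit(mu=p.mu, sigma=p.sigma, n=10**18),
        )
        report = evaluate_vs_model(log, fit, n_boot=100,
                                   rng=np.random.default_rng(0))
        # survival ~ 1 everywhere: achieved RS/SB = R(learned latency) exactly
        assert report.achieved_efficacy == pytest.approx(
            recovery_strength(log.learned_latency, p), abs=0.51
        )
        assert report.latency_error == pytest.approx(
            log.learned_latency - report.predicted_t_star
        )
        assert report.ci_lower_at_learned <= report.achieved_efficacy
        assert report.baseline_efficacy <= report.predicted_f_star

    def test_missing_fit_rejected(self, canonical):
        env = StimulationEnv(canonical, rng=np.random.default_rng(0))
        log = run_session(
            env, SessionSchedule(n_pairs=1, train_trials=20, test_trials=5),
            rng=np.random.default_rng(1),
        )
        with pytest.raises(ValueError):
            evaluate_vs_model(log, None)


class TestCompareDistributions:
    def test_identical_samples_have_zero_ks_statistic(self):
        x = np.arange(10.0)
        stat, _ = compare_distributions(x, x)
        assert stat == 0.0

    def test_disjoint_support_has_unit_ks_statistic(self):
        stat, p = compare_distributions(np.zeros(20), np.ones(20) * 5)
        assert stat == 1.0
        assert p < 1e-6

    def test_t_test_variant_and_sample_size_guard(self):
        stat, p = compare_distributions(
            np.random.default_rng(0).normal(0, 1, 50),
            np.random.default_rng(1).normal(2, 1, 50),
            test="t",
        )
        assert p < 1e-6
        with pytest.raises(ValueError):
            compare_distributions([1, 2, 3], [1, 2, 3, 4, 5])


class TestCohort:
    def test_sampled_parameters_respect_printed_ranges(self):
        root = np.random.default_rng(0)
        for _ in range(200):
            p = sample_network_params(root)
            assert 5 <= p.A <= 40
            assert -10 <= p.B <= 20
            assert p.A + p.B > 0
            assert 0.2 <= p.lam <= 1.2
            assert 0.6 <= p.mu <= 2.0
            assert 0.5 <= p.sigma <= 1.5

    def test_small_cohort_structure(self):
        res = run_cohort(
            n_networks=3, sessions_per_network=2, seed=1,
            schedule=SessionSchedule(n_pairs=2, train_trials=50, test_trials=20),
        )
        assert len(res.params) == 3
        assert len(res.sessions) == 6
        assert res.network_of_session == [0, 0, 1, 1, 2, 2]
        assert all(0 < t <= 10 for t in res.t_star_true)
        for log in res.sessions:
            assert len(log.trials) == 140
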