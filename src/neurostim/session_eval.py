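"""Closed-loop learning sessions and their evaluation.

A session alternates training rounds (episode-wise uniform exploration,
online Q updates) with testing rounds (frozen Q, greedy policy), by
default 4 pairs of 200 training and 50 testing trials = 1000 trials.  A
trial is every spontaneous-burst-initiated episode, including interrupted
ones.  Per round the paper's performance metrics are computed:

* RS/SB — total evoked response spikes divided by the number of trials,
  the stimulation efficacy being maximized;
* interruption fraction — share of trials ended by the next burst;
* RS/stimulus — mean and sd of the response over stimulated trials only;
* mean reward over all trials.

Evaluation compares the learned latency and achieved efficacy against the
phenomenological model's predictions (optimal latency, efficacy with its
99% bootstrap CI, and the random-latency baseline used to normalize the
performance plane).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_fit import FitResult, predict_objective
from .phenomodel import (
    LatencyGrid,
    NetworkParams,
    PARAM_RANGES,
    baseline_efficacy,
    objective_curve,
)
from .rl_control import (
    QTable,
    greedy_stimulate_state,
    run_greedy_episode,
    run_training_episode,
)
from .simulator import Action, Outcome, StimulationEnv, TrialRecord


@dataclass(frozen=True)
class SessionSchedule:
    n_pairs: int = 4
    train_trials: int = 200
    test_trials: int = 50

    def __post_init__(self) -> None:
        if min(self.n_pairs, self.train_trials, self.test_trials) < 1:
            raise ValueError("schedule counts must be positive")

    @property
    def total_trials(self) -> int:
        return self.n_pairs * (self.train_trials + self.test_trials)


@dataclass
class RoundMetrics:
    kind: str                 # "train" | "test"
    n_trials: int
    rs_per_sb: float
    interruption_fraction: float
    mean_reward: float
    rs_per_stimulus_mean: float
    rs_per_stimulus_sd: float
    n_stimulated: int


@dataclass
class SessionLog:
    trials: list[TrialRecord]
    round_of_trial: list[tuple[str, int]]   # (kind, round index) per trial
    rounds: list[RoundMetrics]
    learned_state: int
    learned_latency: float
    q_table: QTable
    error: str | None = None


def compute_metrics(records: list[TrialRecord], kind: str = "") -> RoundMetrics:
    """Round metrics from its trial records (order-invariant)."""
    if not records:
        raise ValueError("empty round")
    n = len(records)
    spikes = np.array([r.response_spikes for r in records], dtype=float)
    rewards = np.array([r.reward for r in records], dtype=float)
    stim = np.array([r.outcome is Outcome.STIMULATED for r in records])
    interrupted = sum(r.outcome is Outcome.INTERRUPTED for r in records)
    n_stim = int(stim.sum())
    return RoundMetrics(
        kind=kind,
        n_trials=n,
        rs_per_sb=float(spikes.sum() / n),
        interruption_fraction=interrupted / n,
        mean_reward=float(rewards.mean()),
        rs_per_stimulus_mean=float(spikes[stim].mean()) if n_stim else 0.0,
        rs_per_stimulus_sd=float(spikes[stim].std()) if n_stim else 0.0,
        n_stimulated=n_stim,
    )


def _trial_record(
    idx: int, start: float, chosen: int, transitions, n_states: int
) -> TrialRecord:
    last_s, last_a, r, s_next = transitions[-1]
    if last_a == Action.STIMULATE:
        outcome, spikes = Outcome.STIMULATED, int(round(r))
    elif last_s == n_states:
        outcome, spikes = Outcome.TIMEOUT, 0
    else:
        outcome, spikes = Outcome.INTERRUPTED, 0
    return TrialRecord(
        trial_index=idx, start_time=start, chosen_state=chosen,
        outcome=outcome, response_spikes=spikes, reward=float(r),
    )


def run_session(
    env: StimulationEnv,
    schedule: SessionSchedule | None = None,
    rng: np.random.Generator | None = None,
    q_table: QTable | None = None,
) -> SessionLog:
    """Run one alternating training/testing session against the environment.

    Training rounds explore (uniform target state per episode) and update
    Q online; testing rounds follow the greedy policy with Q frozen.  The
    learned latency is the greedy stimulation state of the final testing
    round converted to seconds.
    """
    schedule = schedule or SessionSchedule()
    rng = rng if rng is not None else np.random.default_rng()
    table = q_table or QTable(env.n_states)

    trials: list[TrialRecord] = []
    round_of_trial: list[tuple[str, int]] = []
    rounds: list[RoundMetrics] = []
    idx = 0
    clock = 0.0
    learned_state = greedy_stimulate_state(table)
    for pair in range(schedule.n_pairs):
        for kind, n_trials in (("train", schedule.train_trials),
                               ("test", schedule.test_trials)):
            records: list[TrialRecord] = []
            for _ in range(n_trials):
                if kind == "train":
                    target, transitions = run_training_episode(env, table, rng)
                    chosen = target
                else:
                    transitions = run_greedy_episode(env, table)
                    chosen = greedy_stimulate_state(table)
                rec = _trial_record(idx, clock, chosen, transitions, env.n_states)
                records.append(rec)
                trials.append(rec)
                round_of_trial.append((kind, pair))
                clock += env.latency_of_state(max(t[0] for t in transitions))
                idx += 1
            rounds.append(compute_metrics(records, kind))
            if kind == "test":
                learned_state = greedy_stimulate_state(table)
    return SessionLog(
        trials=trials,
        round_of_trial=round_of_trial,
        rounds=rounds,
        learned_state=learned_state,
        learned_latency=env.latency_of_state(learned_state),
        q_table=table,
    )


def trials_to_frame(log: SessionLog) -> pd.DataFrame:
    """Flat per-trial table (round kind/index, state, outcome, reward)."""
    return pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in log.trials],
            "round_kind": [k for k, _ in log.round_of_trial],
            "round_pair": [p for _, p in log.round_of_trial],
            "chosen_state": [t.chosen_state for t in log.trials],
            "outcome": [t.outcome.value for t in log.trials],
            "response_spikes": [t.response_spikes for t in log.trials],
            "reward": [t.reward for t in log.trials],
        }
    )


@dataclass
class EvaluationReport:
    learned_latency: float
    predicted_t_star: float
    latency_error: float
    achieved_efficacy: float
    predicted_f_star: float
    ci_lower_at_learned: float
    ci_upper_at_learned: float
    inside_ci: bool
    baseline_efficacy: float
    baseline_interruption: float
    norm_rs_per_stimulus: float
    norm_interruption: float


def evaluate_vs_model(
    log: SessionLog,
    fit: FitResult,
    grid: LatencyGrid | None = None,
    rng: np.random.Generator | None = None,
    n_boot: int = 2000,
) -> EvaluationReport:
    """Compare a finished session with the fitted model's predictions.

    Reports the learned latency against the predicted optimum t*, the
    achieved final-testing efficacy (RS/SB) against the predicted optimal
    efficacy with its 99% bootstrap CI evaluated at the learned latency,
    and the normalized performance-plane coordinates (RS/stimulus and
    interruption fraction, each relative to the model's random-latency
    baseline).
    """
    if fit is None:
        raise ValueError("a FitResult is required")
    grid = grid or LatencyGrid()
    curve, lower, upper = predict_objective(fit, grid, n_boot=n_boot, rng=rng)
    base_eff = baseline_efficacy(curve)
    # random-latency interruption probability: mean of 1 - Ibar over the grid
    base_intr = float(np.mean(1.0 - curve.survival_values))

    final_test = [m for m in log.rounds if m.kind == "test"][-1]
    final_train = [m for m in log.rounds if m.kind == "train"][-1]

    t = grid.values
    i_learned = int(np.argmin(np.abs(t - log.learned_latency)))
    base_rs_per_stim = base_eff / (1.0 - base_intr) if base_intr < 1 else np.nan
    return EvaluationReport(
        learned_latency=log.learned_latency,
        predicted_t_star=curve.t_star,
        latency_error=log.learned_latency - curve.t_star,
        achieved_efficacy=final_test.rs_per_sb,
        predicted_f_star=curve.f_at_t_star,
        ci_lower_at_learned=float(lower[i_learned]),
        ci_upper_at_learned=float(upper[i_learned]),
        inside_ci=bool(
            lower[i_learned] <= final_test.rs_per_sb <= upper[i_learned]
        ),
        baseline_efficacy=base_eff,
        baseline_interruption=base_intr,
        norm_rs_per_stimulus=(
            final_test.rs_per_stimulus_mean / base_rs_per_stim
            if np.isfinite(base_rs_per_stim) and base_rs_per_stim > 0
            else np.nan
        ),
        norm_interruption=(
            final_test.interruption_fraction / base_intr if base_intr > 0 else np.nan
        ),
    )


def compare_distributions(pre, post, test: str = "KS"):
    """Two-sample comparison of reward or IBI samples.

    ``test`` is "KS" (Kolmogorov-Smirnov) or "t" (Welch t-test); returns
    ``(statistic, p_value)``.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size < 5 or post.size < 5:
        raise ValueError("need at least 5 samples per group")
    if test.upper() == "KS":
        res = stats.ks_2samp(pre, post)
    elif test.lower() == "t":
        res = stats.ttest_ind(pre, post, equal_var=False)
    else:
        raise ValueError(f"unknown test: {test!r}")
    return float(res.statistic), float(res.pvalue)


def sample_network_params(rng: np.random.Generator) -> NetworkParams:
    """One network drawn uniformly from the experimentally observed ranges.

    A in [5, 40], B in [-10, 20] (rejecting A + B <= 0), lambda in
    [0.2, 1.2], mu in [0.6, 2], sigma in [0.5, 1.5].
    """
    while True:
        A = rng.uniform(*PARAM_RANGES["A"])
        B = rng.uniform(*PARAM_RANGES["B"])
        if A + B > 0:
            break
    return NetworkParams(
        A=A,
        B=B,
        lam=rng.uniform(*PARAM_RANGES["lam"]),
        mu=rng.uniform(*PARAM_RANGES["mu"]),
        sigma=rng.uniform(*PARAM_RANGES["sigma"]),
    )


@dataclass
class CohortResult:
    params: list[NetworkParams]
    sessions: list[SessionLog]
    network_of_session: list[int]
    t_star_true: list[float]          # dense-grid optimum per network


def cohort_statistics(res: "CohortResult") -> dict:
    """Learning statistics across a cohort, in the units reported per figure.

    Efficacy and interruption changes are counted over alternating
    training/testing round pairs (each pair is one observation); the
    learned-latency accuracy is counted per session against the dense-grid
    optimum of the network's true generative parameters.
    """
    n_pairs = n_up = n_down = 0
    n_sessions = n_close = 0
    for i, log in enumerate(res.sessions):
        trains = [m for m in log.rounds if m.kind == "train"]
        tests = [m for m in log.rounds if m.kind == "test"]
        for tr, te in zip(trains, tests):
            n_pairs += 1
            n_up += te.rs_per_sb > tr.rs_per_sb
            n_down += te.interruption_fraction < tr.interruption_fraction
        n_sessions += 1
        t_star = res.t_star_true[res.network_of_session[i]]
        n_close += abs(log.learned_latency - t_star) <= 0.5
    return {
        "n_pairs": n_pairs,
        "n_sessions": n_sessions,
        "pct_efficacy_increase": 100.0 * n_up / n_pairs,
        "pct_interruption_decrease": 100.0 * n_down / n_pairs,
        "pct_learned_within_half_s": 100.0 * n_close / n_sessions,
    }


def predicted_efficacy_coverage(
    n_networks: int = 11,
    seed: int = 0,
    n_ibis: int = 200,
    n_probes: int = 100,
    n_boot: int = 2000,
    schedule: SessionSchedule | None = None,
) -> tuple[int, list[dict]]:
    """Closed-loop efficacy vs the 99% CI of the open-loop prediction.

    For each random network: fit the lognormal IBI model to ``n_ibis``
    spontaneous intervals and the recovery model to an open-loop probe
    table, build the predicted objective with its parametric-bootstrap 99%
    band, run one closed-loop session, and test whether the final-testing
    RS/SB lies inside the band at the learned latency.

    Returns the count of covered networks and a per-network detail list.
    """
    from .io import open_loop_probe
    from .model_fit import fit_ibi_lognormal, fit_recovery

    schedule = schedule or SessionSchedule()
    root = np.random.default_rng(seed)
    grid = LatencyGrid()
    inside = 0
    details = []
    for _ in range(n_networks):
        p = sample_network_params(root)
        rng = np.random.default_rng(root.integers(2**31))
        ibis = rng.lognormal(p.mu, p.sigma, size=n_ibis)
        fit = FitResult(
            recovery=fit_recovery(open_loop_probe(p, n_probes, rng)),
            ibi=fit_ibi_lognormal(ibis),
        )
        _, lower, upper = predict_objective(fit, grid, n_boot=n_boot, rng=rng)

        env = StimulationEnv(p, rng=np.random.default_rng(root.integers(2**31)))
        log = run_session(env, schedule,
                          rng=np.random.default_rng(root.integers(2**31)))
        final_test = [m for m in log.rounds if m.kind == "test"][-1]
        k = int(np.argmin(np.abs(grid.values - log.learned_latency)))
        ok = bool(lower[k] <= final_test.rs_per_sb <= upper[k])
        inside += ok
        details.append(
            {
                "achieved": final_test.rs_per_sb,
                "ci_lower": float(lower[k]),
                "ci_upper": float(upper[k]),
                "inside": ok,
            }
        )
    return inside, details


def run_cohort(
    n_networks: int = 11,
    sessions_per_network: int = 5,
    seed: int = 0,
    schedule: SessionSchedule | None = None,
    neutral_reward: float = 0.0,
) -> CohortResult:
    """Closed-loop sessions across a cohort of random synthetic networks."""
    schedule = schedule or SessionSchedule()
    root = np.random.default_rng(seed)
    params_list: list[NetworkParams] = []
    sessions: list[SessionLog] = []
    network_of_session: list[int] = []
    t_stars: list[float] = []
    grid = LatencyGrid()
    for i in range(n_networks):
        p = sample_network_params(root)
        params_list.append(p)
        t_stars.append(objective_curve(p, grid).t_star)
        for _ in range(sessions_per_network):
            env = StimulationEnv(
                p, neutral_reward=neutral_reward,
                rng=np.random.default_rng(root.integers(2**31)),
            )
            log = run_session(
                env, schedule, rng=np.random.default_rng(root.integers(2**31))
            )
            sessions.append(log)
            network_of_session.append(i)
    return CohortResult(
        params=params_list,
        sessions=sessions,
        network_of_session=network_of_session,
        t_star_true=t_stars,
    )
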