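"""Tabular Q-learning for the latency-optimization task.

The task is a finite-horizon optimal-stopping problem: the controller
moves through latency states 1..N (0.5 s apart) after each burst end and
at each state either WAITs — risking interruption by the next spontaneous
burst — or STIMULATEs, collecting a terminal reward equal to the evoked
spike count.  Action values are learned online,

    Q(s, a) <- Q(s, a) + alpha * [r + gamma * max_a' Q(s', a') - Q(s, a)],

with alpha = 0.5 and gamma = 1 (finite horizon, no discounting); terminal
states bootstrap with value 0.  Training uses an episode-wise uniform
exploration policy (draw a target state, wait until it, stimulate) and
testing follows the greedy policy.  A backward-induction value-iteration
oracle, fed the exact hazards and expected rewards, provides the ground
truth the learned policy is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulator import Action, StimulationEnv

DEFAULT_ALPHA = 0.5
DEFAULT_GAMMA = 1.0


@dataclass
class QTable:
    """Action values over latency states 1..N x {WAIT, STIMULATE}.

    Terminal states carry no entries; their bootstrap value is 0 by
    contract.  Initialized to zeros.
    """

    n_states: int
    alpha: float = DEFAULT_ALPHA
    gamma: float = DEFAULT_GAMMA
    values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        self.values = np.zeros((self.n_states, 2))

    def q(self, state: int, action: Action) -> float:
        return float(self.values[state - 1, int(action)])

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "gamma": self.gamma,
            "wait": self.values[:, int(Action.WAIT)].tolist(),
            "stimulate": self.values[:, int(Action.STIMULATE)].tolist(),
        }


def q_update(
    table: QTable, s: int, a: Action, r: float, s_next: int | None
) -> QTable:
    """One temporal-difference backup; ``s_next`` is None for terminals."""
    boot = 0.0 if s_next is None else float(np.max(table.values[s_next - 1]))
    idx = (s - 1, int(a))
    td = r + table.gamma * boot - table.values[idx]
    table.values[idx] += table.alpha * td
    return table


def explore_target(n_states: int, rng: np.random.Generator) -> int:
    """Uniform draw of the state at which this training episode stimulates."""
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    return int(rng.integers(1, n_states + 1))


def greedy_action(table: QTable, s: int) -> Action:
    """argmax over {WAIT, STIMULATE}; exact ties break toward WAIT."""
    w = table.values[s - 1, int(Action.WAIT)]
    st = table.values[s - 1, int(Action.STIMULATE)]
    return Action.STIMULATE if st > w else Action.WAIT


def greedy_stimulate_state(table: QTable) -> int:
    """State at which an uninterrupted greedy rollout stimulates.

    Walks states 1..N taking greedy actions.  A WAIT at the last state
    would end the episode with the neutral reward; when the last state's
    actions are exactly tied (e.g. an untrained all-zero table) the
    rollout stimulates there instead of timing out, so a stimulation
    state is always defined.
    """
    N = table.n_states
    for s in range(1, N):
        if greedy_action(table, s) == Action.STIMULATE:
            return s
    # a WAIT-preferring last state would time out; the rollout state is
    # still N, and exact ties there stimulate rather than deadlock
    return N


def run_training_episode(
    env: StimulationEnv, table: QTable, rng: np.random.Generator
) -> tuple[int, list[tuple[int, Action, float, int | None]]]:
    """One exploration episode: commit to a uniform target state, then act.

    Returns the intended target and the transition list; Q is updated in
    place after every transition.
    """
    target = explore_target(env.n_states, rng)
    s = env.reset()
    transitions: list[tuple[int, Action, float, int | None]] = []
    while True:
        a = Action.STIMULATE if s >= target else Action.WAIT
        s_next, r, done, _ = env.step(a)
        transitions.append((s, a, r, s_next))
        q_update(table, s, a, r, s_next)
        if done:
            return target, transitions
        s = s_next


def run_greedy_episode(
    env: StimulationEnv, table: QTable
) -> list[tuple[int, Action, float, int | None]]:
    """One frozen-Q test episode under the greedy policy."""
    stim_state = greedy_stimulate_state(table)
    s = env.reset()
    transitions: list[tuple[int, Action, float, int | None]] = []
    while True:
        a = Action.STIMULATE if s >= stim_state else Action.WAIT
        s_next, r, done, _ = env.step(a)
        transitions.append((s, a, r, s_next))
        if done:
            return transitions
        s = s_next


@dataclass
class OraclePolicy:
    stimulate_state: int
    state_values: np.ndarray      # V*(k), k = 1..N
    q_wait: np.ndarray
    q_stim: np.ndarray


def value_iteration_oracle(
    hazards: np.ndarray,
    expected_rewards: np.ndarray,
    neutral_reward: float = 0.0,
) -> OraclePolicy:
    """Exact solution of the stopping problem by backward induction.

    Parameters
    ----------
    hazards : per-state interruption probability h_k while waiting from
        state k to k+1 (h_N is the unused last entry or omitted).
    expected_rewards : mean stimulation reward at each state,
        Rbar(t_k) (the clamped recovery model).

    The optimal first stimulation state equals the argmax over k of
    [conditional survival to t_k] * Rbar(t_k) — the state-grid restriction
    of the objective function — with ties broken toward the earliest
    state.
    """
    R = np.asarray(expected_rewards, dtype=float)
    h = np.asarray(hazards, dtype=float)
    N = R.size
    q_stim = R.copy()
    q_wait = np.empty(N)
    V = np.empty(N)
    V[N - 1] = max(R[N - 1], neutral_reward)
    q_wait[N - 1] = neutral_reward
    for k in range(N - 2, -1, -1):
        q_wait[k] = (1.0 - h[k]) * V[k + 1] + h[k] * neutral_reward
        V[k] = max(q_stim[k], q_wait[k])
    # roll the optimal policy forward; stop at the first state where
    # stopping is at least as good as continuing (earliest-latency tie rule)
    stim_state = N
    for k in range(N):
        if q_stim[k] >= q_wait[k]:
            stim_state = k + 1
            break
    return OraclePolicy(
        stimulate_state=stim_state, state_values=V, q_wait=q_wait, q_stim=q_stim
    )


def oracle_for_env(env: StimulationEnv) -> OraclePolicy:
    """Value-iteration oracle using the environment's exact quantities."""
    R = np.array([env.expected_reward(s) for s in range(1, env.n_states + 1)])
    return value_iteration_oracle(env.hazards, R, env.neutral_reward)
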