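"""Generative model of one cultured network on a microelectrode array.

Two faces of the same stochastic model:

* a spike-event generator producing network-wide spontaneous bursts
  (lognormal inter-burst intervals), intra-burst spiking and sparse
  background activity on every channel — input to the burst-detection and
  model-fitting path; and
* an episodic environment for the controller, where a trial starts at the
  end of a spontaneous burst, time advances in discrete 0.5-s states, a
  WAIT action risks interruption by the next burst, and a STIMULATE action
  terminates the trial with a reward equal to the evoked spike count.

Interruptions are sampled state-by-state through the conditional hazard of
the lognormal inter-burst-interval distribution, which is distributionally
equivalent to drawing one interval per episode but keeps WAIT transitions
Markov.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phenomodel import NetworkParams, interruption_cdf, recovery_strength


class Action(enum.IntEnum):
    WAIT = 0
    STIMULATE = 1


class Outcome(enum.Enum):
    STIMULATED = "stimulated"
    INTERRUPTED = "interrupted"
    TIMEOUT = "timeout"


@dataclass
class TrialRecord:
    """One inter-burst episode: what was chosen and how it ended."""

    trial_index: int
    start_time: float
    chosen_state: int | None
    outcome: Outcome
    response_spikes: int
    reward: float

    def __post_init__(self) -> None:
        if self.response_spikes < 0:
            raise ValueError("response_spikes must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic network recording.

    Defaults reflect the qualitative features of mature cortical cultures:
    burst durations of a few hundred milliseconds up to a couple of
    seconds, dense intra-burst firing (~100 spikes/s per channel) and
    sparse background activity.
    """

    params: NetworkParams
    burst_duration_mu: float = -0.8   # lognormal log-location, median ~0.45 s
    burst_duration_sigma: float = 0.5
    burst_duration_min: float = 0.1
    burst_duration_max: float = 2.0
    in_burst_rate: float = 100.0      # spikes/s per channel within a burst
    background_rate: float = 0.2      # spikes/s per channel, always on
    n_channels: int = 8
    onset_jitter: float = 0.05        # max per-channel burst-onset jitter (s)
    response_window: float = 0.5      # s, post-stimulus spike-count window
    response_noise: str = "poisson"   # "poisson" | "deterministic"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.in_burst_rate < 0 or self.background_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.response_window <= 0:
            raise ValueError("response_window must be positive")
        if self.n_channels < 3:
            raise ValueError("need at least 3 channels (offline detector minimum)")


def draw_ibi(mu: float, sigma: float, rng: np.random.Generator, size=None):
    """Draw inter-burst interval(s) from the lognormal renewal process."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return rng.lognormal(mean=mu, sigma=sigma, size=size)


def evoke_response(
    latency: float,
    params: NetworkParams,
    rng: np.random.Generator,
    noise_model: str = "poisson",
):
    """Stimulus-evoked spike count at the given latency after a burst end.

    The mean follows the recovery model clamped at zero; under the default
    Poisson noise model the count is an integer draw with that mean, while
    the deterministic mode returns the clamped mean itself (for oracle
    tests).
    """
    if latency <= 0:
        raise ValueError("latency must be positive")
    mean = max(recovery_strength(latency, params), 0.0)
    if noise_model == "deterministic":
        return mean
    if noise_model == "poisson":
        return int(rng.poisson(mean))
    raise ValueError(f"unknown noise model: {noise_model!r}")


def generate_spontaneous_recording(
    config: SimConfig, duration: float, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate spontaneous activity for ``duration`` seconds.

    Alternates quiescent gaps (lognormal IBIs measured burst-end to next
    burst-onset) and network bursts.  During a burst, each channel fires a
    homogeneous Poisson train at ``in_burst_rate`` starting at the burst
    onset plus a channel-specific jitter (<= ``onset_jitter``).  Background
    spikes form a sparse homogeneous process on every channel throughout.

    Returns
    -------
    spikes : DataFrame with columns ``time_s`` (float) and ``channel``
        (int), sorted by time.
    bursts : DataFrame with ground-truth columns ``onset_s``, ``offset_s``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    p = config.params

    times: list[np.ndarray] = []
    chans: list[np.ndarray] = []
    onsets: list[float] = []
    offsets: list[float] = []

    t = 0.0
    while True:
        gap = float(draw_ibi(p.mu, p.sigma, rng))
        onset = t + gap
        if onset >= duration:
            break
        d = float(
            np.clip(
                rng.lognormal(config.burst_duration_mu, config.burst_duration_sigma),
                config.burst_duration_min,
                config.burst_duration_max,
            )
        )
        offset = min(onset + d, duration)
        for ch in range(config.n_channels):
            start = onset + rng.uniform(0.0, config.onset_jitter)
            if start >= offset:
                continue
            n = rng.poisson(config.in_burst_rate * (offset - start))
            if n:
                times.append(rng.uniform(start, offset, size=n))
                chans.append(np.full(n, ch, dtype=int))
        onsets.append(onset)
        offsets.append(offset)
        t = offset

    if config.background_rate > 0:
        for ch in range(config.n_channels):
            n = rng.poisson(config.background_rate * duration)
            if n:
                times.append(rng.uniform(0.0, duration, size=n))
                chans.append(np.full(n, ch, dtype=int))

    if times:
        time_arr = np.concatenate(times)
        chan_arr = np.concatenate(chans)
        order = np.argsort(time_arr, kind="stable")
        spikes = pd.DataFrame({"time_s": time_arr[order], "channel": chan_arr[order]})
    else:
        spikes = pd.DataFrame({"time_s": pd.Series(dtype=float),
                               "channel": pd.Series(dtype=int)})
    bursts = pd.DataFrame({"onset_s": onsets, "offset_s": offsets})
    return spikes.reset_index(drop=True), bursts


@dataclass
class StimulationEnv:
    """Episodic environment for the latency-optimization task.

    An episode begins at the detected end of a spontaneous burst.  The
    latency since burst end is discretized into ``n_states`` states of
    ``state_width`` seconds; being in state k means the latency t_k =
    t_first + (k - 1) * state_width has elapsed.  ``t_first`` honours the
    online detector's dead time: a burst end is only known one ISI
    threshold after the last spike, so the earliest available state sits at
    max(state_width, dead_time) after the true burst end.

    WAIT in state k survives to state k+1 with probability 1 - h_k, where
    h_k = [F(t_{k+1}) - F(t_k)] / [1 - F(t_k)] is the conditional hazard of
    the lognormal IBI distribution; otherwise the episode terminates as
    INTERRUPTED with the neutral reward.  WAIT in the last state times out
    with the neutral reward.  STIMULATE terminates with reward equal to the
    evoked spike count at t_k.
    """

    params: NetworkParams
    state_width: float = 0.5
    n_states: int = 20
    neutral_reward: float = 0.0
    dead_time: float | None = None     # default: one state width
    noise_model: str = "poisson"
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def __post_init__(self) -> None:
        if self.state_width <= 0 or self.n_states < 2:
            raise ValueError("state_width > 0 and n_states >= 2 required")
        dead = self.state_width if self.dead_time is None else self.dead_time
        t_first = max(self.state_width, dead)
        self.state_latencies = t_first + self.state_width * np.arange(self.n_states)
        edges = np.concatenate([self.state_latencies,
                                [self.state_latencies[-1] + self.state_width]])
        F = interruption_cdf(edges, self.params.mu, self.params.sigma)
        # h_k: interruption hazard while waiting from state k to k+1
        self.hazards = (F[1:] - F[:-1]) / (1.0 - F[:-1])
        self._state: int | None = None

    # -- contract -----------------------------------------------------------

    def latency_of_state(self, state: int) -> float:
        return float(self.state_latencies[state - 1])

    def expected_reward(self, state: int) -> float:
        """Mean STIMULATE reward at a state (recovery model clamped at 0)."""
        return max(recovery_strength(self.latency_of_state(state), self.params), 0.0)

    def reset(self) -> int:
        """Start a new trial at a burst end; returns the initial state (1)."""
        self._state = 1
        return 1

    def step(self, action: Action) -> tuple[int | None, float, bool, Outcome | None]:
        """Advance one decision point.

        Returns ``(next_state, reward, terminated, outcome)``; next_state is
        None on termination and outcome is None while the episode runs.
        """
        if self._state is None:
            raise RuntimeError("step() called on a terminated episode; call reset()")
        s = self._state
        if action == Action.STIMULATE:
            count = evoke_response(
                self.latency_of_state(s), self.params, self.rng, self.noise_model
            )
            self._state = None
            return None, float(count), True, Outcome.STIMULATED
        if action == Action.WAIT:
            if s == self.n_states:
                self._state = None
                return None, self.neutral_reward, True, Outcome.TIMEOUT
            if self.rng.random() < self.hazards[s - 1]:
                self._state = None
                return None, self.neutral_reward, True, Outcome.INTERRUPTED
            self._state = s + 1
            return self._state, 0.0, False, None
        raise ValueError(f"unknown action: {action!r}")

    def with_rng(self, rng: np.random.Generator) -> "StimulationEnv":
        return replace(self, rng=rng)
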