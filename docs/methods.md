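# Methods

## The trade-off model

A cultured cortical network alternates between network-wide spontaneous
bursts (SBs) and quiescent periods. Two processes, both functions only of
the latency *t* since the last burst end, define the stimulation problem:

- **Recovery of excitability.** The expected response strength (spikes at
  the recording site in a post-stimulus window, 0.5 s by default) is
  *R(t) = A·(1 − e^(−λt)) + B*. *A* (spikes) is the gain, *B* (spikes) the
  y-intercept — interpretable as the excitability floor at burst
  termination, and possibly negative — and *λ* (1/s) the recovery rate.
  *A + B > 0* is required so the saturated response is positive.
- **Burst initiation.** Quiescent periods are lognormal, with location *μ*
  (log-seconds) and scale *σ*. The probability that no SB has occurred by
  latency *t* is the survival function *Ī(t) = 1 − Φ((ln t − μ)/σ)*,
  implemented through the complementary error function for stability at
  large |z|.

A fixed-latency strategy "always stimulate at *t*" earns, per SB-initiated
trial, the objective *f(t) = Ī(t)·R(t)* expected spikes. Its maximizer
*t\** on the 0–10 s domain is the network-specific optimal latency. The
grid argmax breaks ties toward the smallest latency (equal modeled
efficacy, fewer interruption opportunities); quasiconcavity of *f* is
checked empirically (a single sign change of discrete differences at
tolerance 1e−9), not assumed. When *B* < 0, *R* and hence *f* may be
negative at small *t*; the analytic module leaves them negative and takes
the argmax over the full grid, while the simulator clamps expected spike
counts at zero. The random-latency baseline efficacy is the arithmetic
mean of *f* over the grid.

The default analysis grid spans 0.01–10 s at 0.01 s; it is deliberately
finer than the controller's 0.5-s state width so that discretization error
of the controller can be measured against a near-continuous optimum.

## The simulator

One synthetic network is the parameter vector (A, B, λ, μ, σ) plus
plumbing parameters. The spike-level generator alternates lognormal
quiescent gaps (measured burst end → next burst onset) with bursts whose
durations are lognormal (median ≈ 0.45 s, clamped to 0.1–2 s). During a
burst each of the 8 default channels fires a homogeneous 100 spikes/s
train starting at the burst onset plus an up-to-50-ms channel jitter;
background activity is a sparse 0.2 spikes/s homogeneous process per
channel throughout. These defaults reproduce the qualitative features the
detection chain relies on — bimodal per-channel inter-spike-interval (ISI)
distributions, sub-second network bursts, seconds-scale IBIs — and the
burst-duration and rate values are free choices documented here, since
only qualitative ranges are known for them.

What the generator does *not* emulate: spatial electrode geometry, burst
propagation structure ("burst leaders"), stimulation artifacts,
activity-dependent drift of any parameter, and serial correlations between
successive IBIs. Passing tests therefore demonstrate correctness of the
algorithms under stationary renewal dynamics, not robustness to the
non-stationarity of real cultures.

Evoked responses are Poisson counts with mean max(R(t), 0); only the mean
relationship is empirically constrained, and Poisson is the natural
minimal choice for a spike count. A deterministic mode (count = clamped
mean) exists for oracle tests.

## The episodic environment

A trial starts at a detected burst end. Latency is discretized into N = 20
states of 0.5 s; state k sits at t_k = t_first + (k−1)·0.5 s, where
t_first = max(state width, online-detector dead time) — a burst end is
only known one ISI threshold after the last spike. WAIT in state k is
interrupted with the conditional hazard
h_k = [F(t_{k+1}) − F(t_k)] / [1 − F(t_k)] of the lognormal IBI CDF F;
state-by-state hazard sampling keeps WAIT transitions Markov and is
distributionally identical to drawing one IBI per episode (the telescoping
product of (1 − h_k) equals the conditional survival exactly, and is
unit-tested). STIMULATE ends the trial with reward equal to the evoked
spike count; interruption and timeout (WAIT in state N) end it with the
neutral reward (0 by default, configurable to −10⁻³). After any terminal
event the next trial re-arms at the following burst end with a fresh IBI.
Whether an evoked response can itself be interrupted is not modeled; the
response window is atomic once the stimulus is delivered.

## Burst detection

Offline (multi-channel): per-channel burstlets are maximal runs of ISIs
≤ 100 ms, extended once by a trailing interval ≤ 200 ms, with ≥ 3 spikes;
burstlets whose onsets chain within 100 ms across ≥ 3 sites — with at most
one larger inter-onset gap ≤ 200 ms per chain — form a network burst
spanning to the latest constituent offset. Overlapping events are merged,
so detected intervals are disjoint and sorted. The "one larger onset
interval" rule is an interpretation of an ambiguous prescription;
alternative readings move only borderline groupings.

Online (single channel): the ISI threshold is estimated from spontaneous
activity as the valley between the two modes of a Gaussian-smoothed
(0.15-decade bandwidth) log-ISI histogram; the candidate valley must dip
below half the smaller mode, otherwise the estimator raises an explicit
failure and a manual threshold is required. A burst end is declared one
threshold after the last spike of a ≥ 3-spike sub-threshold run; that lag
is the detector dead time that offsets the first controller state.

## Model fitting and uncertainty

The recovery model is fitted by nonlinear least squares with multi-start
initialization (λ₀ ∈ {0.2, 0.6, 1.2}, the experimentally observed range;
A₀ = response span; B₀ = minimum response), keeping the start with the
lowest residual sum of squares. Open-loop data are fitted per trial;
closed-loop data, which exist only on the 0.5-s state grid, are collapsed
to per-state medians first. A flat fit (A ≈ 0) is accepted but flagged
degenerate. The IBI model is fitted by maximum likelihood: μ̂ and σ̂ are
the mean and (biased, MLE) standard deviation of the log intervals.

Uncertainty on the predicted objective is propagated by a parametric
bootstrap: 2000 replicate parameter vectors are drawn from the Gaussian
approximation at the fitted values — (A, B, λ) with the least-squares
covariance, (μ, σ) with the asymptotic ML covariance σ²/n and σ²/(2n) —
and *f(t)* is rebuilt per replicate; the 99 % band is the 0.5/99.5
percentile envelope per grid point, with the point estimate included in
the replicate set so the band always brackets it. An ill-conditioned
least-squares covariance is replaced by an inflated diagonal (10 % of each
parameter, floor 0.1) with a warning — a deliberately wide band rather
than a hard failure. The paper trail for this choice: the confidence
construction of the original analysis is not recorded, and a parametric
bootstrap from the fit covariance is the standard reconstruction.

## Learning and evaluation

Tabular Q-learning with α = 0.5, γ = 1 (finite horizon), zero-initialized
values, and terminal bootstrap 0. Training explores episode-wise: a target
state is drawn uniformly from 1..N, the episode WAITs until it and
STIMULATEs (unless interrupted first), and every transition updates Q
online. Testing rounds freeze Q and follow the greedy policy; exact ties
break toward WAIT, except that an all-tied last state stimulates so a
stimulation state is always defined (a WAIT tie-break alone would deadlock
a zero-initialized table into timeouts). Updating Q during greedy testing
was evaluated and rejected: with α = 0.5 a single interruption halves
Q(s, WAIT), ratcheting the policy toward state 1 irreversibly, since the
greedy policy never revisits later states to recover.

A session is 4 alternating pairs of 200 training and 50 testing trials
(1000 trials); the learned latency is the greedy stimulation state after
the final round. A finite-horizon value-iteration oracle, fed the exact
hazards and expected rewards, solves the stopping problem by backward
induction; its stimulation state provably equals the state-grid argmax of
*f* (ties toward the earliest state), which links the MDP solution to the
closed-form objective and is verified exactly over random parameter sets.

Session metrics follow the experimental definitions: RS/SB (total evoked
spikes over all trials, interrupted ones included), interruption fraction,
RS/stimulus mean and sd over stimulated trials, and mean reward.
Model-based evaluation reports the learned-vs-predicted latency error, the
achieved final-testing RS/SB against the 99 % band at the learned latency,
and performance-plane coordinates normalized by the model's
random-latency baselines. Cohorts draw parameters uniformly from
A ∈ [5, 40], B ∈ [−10, 20] (rejecting A + B ≤ 0), λ ∈ [0.2, 1.2],
μ ∈ [0.6, 2], σ ∈ [0.5, 1.5]; efficacy and interruption improvements are
counted per training/testing round pair, learned-latency accuracy per
session.

## Known limitations

The fixed learning rate α = 0.5 leaves a stationary noise floor on the
action values: Q(s, STIMULATE) fluctuates with sd ≈ √(Var[r]/3) (≈ 2.5
spikes for Poisson rewards near 20), and Q(s, WAIT) — hit by occasional
halving on interruptions and inflated by the max-operator bias compounding
across states — fluctuates more. For networks whose objective is flat
within a spike or two across neighboring states (common at large μ, where
hazards are small), the learned state therefore scatters by several states
around the optimum and does not concentrate further with more episodes.
The learned policy still outperforms the random-latency baseline in nearly
all runs, and efficacy reliably rises from training to testing rounds, but
exact agreement with the value-iteration oracle is limited by this noise
floor, not by training duration. Annealing α or double estimators would
tighten it; both are deliberately out of scope because the controller
under study is the fixed-α tabular learner.

Problem sizes used by the test suite and the acceptance script — 11
networks × 5 sessions for cohort statistics, 50 replicate runs of 2000
episodes for convergence checks, 30 replications for CI coverage — were
chosen to give stable statistics at interactive runtimes; all randomness
flows from explicit seeds, so every reported number is exactly
reproducible.
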