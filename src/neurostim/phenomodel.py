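"""Phenomenological model of the stimulus-timing trade-off.

In cultured cortical networks, the expected strength of a stimulus-evoked
response grows with the period of inactivity since the last spontaneous
burst (SB), following a saturating exponential

    R(t) = A * (1 - exp(-lambda * t)) + B,

while the probability that the quiescent period survives to latency ``t``
without being interrupted by the next SB decays according to the lognormal
inter-burst-interval (IBI) distribution,

    Ibar(t) = 1 - Phi((ln t - mu) / sigma).

The product f(t) = Ibar(t) * R(t) is the expected number of evoked spikes
per SB for a fixed-latency stimulation strategy; its maximizer t* is the
network-specific optimal stimulus latency.  This module evaluates these
curves, locates t*, computes the random-latency baseline efficacy, and
sweeps the model parameters over their experimentally observed ranges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

logger = logging.getLogger(__name__)

#: Canonical parameter set used throughout the analyses and the tests.
CANONICAL = dict(A=20.0, B=6.67, lam=1.0, mu=0.6, sigma=1.0)

#: Experimentally observed parameter ranges used by the sweeps and cohorts.
PARAM_RANGES = {
    "A": (5.0, 40.0),
    "B": (-10.0, 20.0),
    "lam": (0.2, 1.2),
    "mu": (0.6, 2.0),
    # The sigma sweep brackets the fixed value sigma = 1 used elsewhere.
    "sigma": (0.5, 1.5),
}


@dataclass(frozen=True)
class NetworkParams:
    """The five parameters defining one network.

    Attributes
    ----------
    A : float
        Response gain (spikes): amplitude of the saturating recovery.
    B : float
        Response offset / y-intercept (spikes); may be negative.
    lam : float
        Recovery rate (1/s) of post-burst excitability.
    mu : float
        Lognormal location of the IBI distribution (log-seconds).
    sigma : float
        Lognormal scale of the IBI distribution (dimensionless).
    """

    A: float
    B: float
    lam: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.A + self.B > 0:
            raise ValueError(
                f"A + B must be strictly positive (maximal response), "
                f"got A={self.A}, B={self.B}"
            )
        if not self.lam > 0:
            raise ValueError(f"lambda must be positive, got {self.lam}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @classmethod
    def canonical(cls) -> "NetworkParams":
        return cls(**CANONICAL)


@dataclass(frozen=True)
class LatencyGrid:
    """Dense latency grid (seconds) over the domain of interest, 0-10 s."""

    t_min: float = 0.01
    t_max: float = 10.0
    step: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.t_min < self.t_max:
            raise ValueError("require 0 < t_min < t_max")
        if not self.step > 0:
            raise ValueError("step must be positive")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.t_max - self.t_min) / self.step)) + 1
        return self.t_min + self.step * np.arange(n)


@dataclass
class ObjectiveCurve:
    """Tabulated objective f(t) = Ibar(t) * R(t) with its maximizer."""

    grid: LatencyGrid
    R_values: np.ndarray
    survival_values: np.ndarray
    f_values: np.ndarray
    t_star: float
    f_at_t_star: float
    params: NetworkParams | None = field(default=None)


def recovery_strength(t, params: NetworkParams):
    """Expected response strength R(t) = A(1 - e^(-lambda t)) + B (spikes).

    Monotone non-decreasing in ``t`` (for A > 0) and bounded by A + B.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("latency t must be non-negative")
    out = params.A * (1.0 - np.exp(-params.lam * t)) + params.B
    return out.item() if out.ndim == 0 else out


def ibi_density(t, mu: float, sigma: float):
    """Lognormal probability density of the IBI at time ``t`` (1/s)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("ibi_density requires t > 0")
    z = (np.log(t) - mu) / sigma
    out = np.exp(-0.5 * z * z) / (t * sigma * math.sqrt(2.0 * math.pi))
    return out.item() if out.ndim == 0 else out


def _norm_cdf(z):
    # Phi via the complementary error function for stability at large |z|.
    return 0.5 * erfc(-np.asarray(z, dtype=float) / math.sqrt(2.0))


def survival_prob(t, mu: float, sigma: float):
    """Probability Ibar(t) of NOT being interrupted by an SB up to latency t.

    One minus the lognormal CDF: 1 - Phi((ln t - mu) / sigma).  Monotone
    non-increasing with limits 1 at t -> 0+ and 0 at t -> infinity.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("survival_prob requires t > 0")
    z = (np.log(t) - mu) / sigma
    out = 0.5 * erfc(z / math.sqrt(2.0))
    return out.item() if out.ndim == 0 else out


def interruption_cdf(t, mu: float, sigma: float):
    """Lognormal CDF: probability an SB has occurred by latency ``t``."""
    t = np.asarray(t, dtype=float)
    out = np.where(t > 0, 1.0 - survival_prob(np.maximum(t, 1e-300), mu, sigma), 0.0)
    return out.item() if out.ndim == 0 else out


def objective_curve(params: NetworkParams, grid: LatencyGrid | None = None) -> ObjectiveCurve:
    """Tabulate f(t) = Ibar(t) * R(t) on the grid and locate its maximizer t*.

    Ties in the discrete argmax are broken toward the smallest latency:
    at equal modeled efficacy, shorter waits risk fewer interruptions.
    """
    grid = grid or LatencyGrid()
    t = grid.values
    R = recovery_strength(t, params)
    surv = survival_prob(t, params.mu, params.sigma)
    f = surv * R
    i_star = int(np.argmax(f))  # np.argmax returns the first (smallest-t) maximum
    return ObjectiveCurve(
        grid=grid,
        R_values=R,
        survival_values=surv,
        f_values=f,
        t_star=float(t[i_star]),
        f_at_t_star=float(f[i_star]),
        params=params,
    )


def baseline_efficacy(curve: ObjectiveCurve) -> float:
    """Efficacy of a random-latency strategy: the mean of f over the grid.

    Always <= f(t*); equality only for a constant objective.
    """
    if curve.f_values.size == 0:
        raise ValueError("empty objective curve")
    return float(np.mean(curve.f_values))


def is_quasiconcave(f: np.ndarray, tol: float = 1e-9) -> bool:
    """Check that a sampled curve rises to a single maximum then falls.

    Discrete differences may change sign at most once (+ to -) up to ``tol``.
    """
    d = np.diff(np.asarray(f, dtype=float))
    sign = np.where(d > tol, 1, np.where(d < -tol, -1, 0))
    sign = sign[sign != 0]
    if sign.size == 0:
        return True
    # strip leading +1 run, then the remainder must be all -1
    i = 0
    while i < sign.size and sign[i] == 1:
        i += 1
    return bool(np.all(sign[i:] == -1))


def parameter_sweep(
    base: NetworkParams,
    vary: Mapping[str, Sequence[float] | Iterable[float]],
    grid: LatencyGrid | None = None,
) -> pd.DataFrame:
    """Objective-function summary over a grid of parameter combinations.

    Parameters
    ----------
    base : NetworkParams
        Values for the parameters held constant.
    vary : mapping of parameter name -> sequence of values
        Cartesian product of these values is swept.  Combinations that
        violate A + B > 0 are skipped with a logged warning.

    Returns
    -------
    DataFrame with one row per valid combination and columns
    ``A, B, lambda, mu, sigma, t_star, f_star, baseline, gain``.
    """
    grid = grid or LatencyGrid()
    names = list(vary.keys())
    valid = {"A", "B", "lam", "mu", "sigma"}
    unknown = set(names) - valid
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    rows = []
    for combo in product(*(list(vary[n]) for n in names)):
        kw = {
            "A": base.A, "B": base.B, "lam": base.lam,
            "mu": base.mu, "sigma": base.sigma,
        }
        kw.update(dict(zip(names, combo)))
        if kw["A"] + kw["B"] <= 0:
            logger.warning("skipping combination with A + B <= 0: %s", kw)
            continue
        p = NetworkParams(**kw)
        curve = objective_curve(p, grid)
        base_eff = baseline_efficacy(curve)
        rows.append(
            {
                "A": kw["A"], "B": kw["B"], "lambda": kw["lam"],
                "mu": kw["mu"], "sigma": kw["sigma"],
                "t_star": curve.t_star,
                "f_star": curve.f_at_t_star,
                "baseline": base_eff,
                "gain": curve.f_at_t_star / base_eff if base_eff != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
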