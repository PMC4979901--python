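"""Estimating network parameters from data.

Two independent fits define a network: a nonlinear least-squares fit of
the saturating-exponential recovery model A(1 - e^(-lambda t)) + B to
(latency, response-strength) pairs, and a maximum-likelihood lognormal fit
to inter-burst intervals.  The fitted parameters feed the phenomenological
objective f(t) = Ibar(t) * R(t); uncertainty is propagated to the
objective by a parametric bootstrap, yielding a 99% confidence band on the
predicted efficacy at every latency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .phenomodel import (
    LatencyGrid,
    NetworkParams,
    ObjectiveCurve,
    objective_curve,
    survival_prob,
)


class FitError(RuntimeError):
    """Nonlinear fit failed to converge from every starting point."""


@dataclass
class RecoveryFit:
    A: float
    B: float
    lam: float
    cov: np.ndarray          # 3x3 covariance of (A, B, lam)
    residual_ss: float
    n_points: int
    mode: str
    degenerate: bool = False  # flat fit (A ~ 0): responses carry no latency signal


@dataclass
class IbiFit:
    mu: float
    sigma: float
    n: int
    degenerate: bool = False

    @property
    def cov(self) -> np.ndarray:
        """Asymptotic ML covariance of (mu, sigma)."""
        return np.diag([self.sigma**2 / self.n, self.sigma**2 / (2 * self.n)])


@dataclass
class FitResult:
    """Joint description of one fitted network."""

    recovery: RecoveryFit
    ibi: IbiFit
    params: NetworkParams = field(init=False)

    def __post_init__(self) -> None:
        self.params = NetworkParams(
            A=self.recovery.A,
            B=self.recovery.B,
            lam=self.recovery.lam,
            mu=self.ibi.mu,
            sigma=max(self.ibi.sigma, 1e-9),
        )


def _recovery_model(t, A, B, lam):
    return A * (1.0 - np.exp(-lam * t)) + B


def fit_recovery(
    table: pd.DataFrame,
    mode: str = "per-trial",
) -> RecoveryFit:
    """Least-squares fit of the recovery model to stimulus-response data.

    Parameters
    ----------
    table : DataFrame with columns ``latency_s`` and ``response_spikes``.
    mode : "per-trial" fits all points (open-loop data); "per-state-median"
        first collapses the responses at each distinct latency to their
        median (closed-loop data, where responses exist only on the state
        grid).

    Multi-start initialization covers the experimentally observed range of
    the rate constant (lambda in {0.2, 0.6, 1.2}); the start with the
    lowest residual sum of squares wins.
    """
    if mode not in ("per-trial", "per-state-median"):
        raise ValueError(f"unknown mode: {mode!r}")
    lat = np.asarray(table["latency_s"], dtype=float)
    resp = np.asarray(table["response_spikes"], dtype=float)
    if np.any(lat <= 0):
        raise ValueError("latencies must be positive")
    if np.any(resp < 0):
        raise ValueError("response counts must be non-negative")
    if mode == "per-state-median":
        df = pd.DataFrame({"latency_s": lat, "response_spikes": resp})
        med = df.groupby("latency_s")["response_spikes"].median()
        lat, resp = med.index.to_numpy(), med.to_numpy()
    if np.unique(lat).size < 3:
        raise ValueError("need at least 3 distinct latencies")

    span = float(resp.max() - resp.min())
    A0 = span if span > 0 else 1.0
    B0 = float(resp.min())
    best = None
    for lam0 in (0.2, 0.6, 1.2):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    _recovery_model, lat, resp, p0=(A0, B0, lam0),
                    maxfev=20000,
                )
            rss = float(np.sum((resp - _recovery_model(lat, *popt)) ** 2))
            if np.any(~np.isfinite(popt)):
                continue
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
        except (RuntimeError, ValueError):
            continue
    if best is None:
        raise FitError(
            "recovery fit did not converge from any start "
            f"(n={lat.size}, latency range {lat.min():.3g}-{lat.max():.3g} s)"
        )
    popt, pcov, rss = best
    A, B, lam = (float(v) for v in popt)
    degenerate = abs(A) < 1e-6 * max(1.0, abs(B)) or span == 0
    if not np.all(np.isfinite(pcov)):
        pcov = np.full((3, 3), np.nan)
    return RecoveryFit(
        A=A, B=B, lam=lam, cov=np.asarray(pcov), residual_ss=rss,
        n_points=int(lat.size), mode=mode, degenerate=degenerate,
    )


def fit_ibi_lognormal(ibis) -> IbiFit:
    """Maximum-likelihood lognormal fit: mean and sd of the log intervals."""
    x = np.asarray(ibis, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 inter-burst intervals")
    if np.any(x <= 0):
        raise ValueError("inter-burst intervals must be positive")
    logs = np.log(x)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs))
    if sigma < 1e-12:
        sigma = 0.0
    return IbiFit(mu=mu, sigma=sigma, n=int(x.size), degenerate=sigma == 0.0)


def predict_objective(
    fit: FitResult,
    grid: LatencyGrid | None = None,
    n_boot: int = 2000,
    ci: float = 0.99,
    rng: np.random.Generator | None = None,
) -> tuple[ObjectiveCurve, np.ndarray, np.ndarray]:
    """Predicted objective curve with a parametric-bootstrap CI band on f.

    Parameter vectors (A, B, lambda) and (mu, sigma) are resampled from
    the Gaussian approximation at the fitted values with the least-squares
    / ML covariances; f(t) is rebuilt per replicate and the band is the
    (1-ci)/2 .. 1-(1-ci)/2 percentile envelope per grid point.  The point
    estimate itself is included in the replicate set, so the band always
    contains the point curve.  An ill-conditioned recovery covariance is
    replaced by an inflated diagonal (10% of each parameter, floor 0.1)
    with a warning — a deliberately widened band rather than a failure.

    Returns ``(curve, lower, upper)``.
    """
    grid = grid or LatencyGrid()
    rng = rng if rng is not None else np.random.default_rng()
    curve = objective_curve(fit.params, grid)
    t = grid.values

    rcov = np.asarray(fit.recovery.cov, dtype=float)
    theta = np.array([fit.recovery.A, fit.recovery.B, fit.recovery.lam])
    if not np.all(np.isfinite(rcov)) or np.any(np.diag(rcov) < 0):
        warnings.warn(
            "ill-conditioned recovery covariance; widening the CI band",
            RuntimeWarning,
        )
        rcov = np.diag(np.maximum(0.1 * np.abs(theta), 0.1) ** 2)
    # symmetrize (+ jitter for factorization robustness, unless exactly zero)
    rcov = 0.5 * (rcov + rcov.T)
    if np.any(rcov):
        rcov = rcov + 1e-12 * np.eye(3)

    icov = fit.ibi.cov
    ith = np.array([fit.ibi.mu, fit.ibi.sigma])

    fs = np.empty((n_boot + 1, t.size))
    fs[0] = curve.f_values
    draws_r = rng.multivariate_normal(theta, rcov, size=n_boot, method="eigh")
    draws_i = rng.multivariate_normal(ith, icov, size=n_boot)
    for b in range(n_boot):
        A, B, lam = draws_r[b]
        mu, sigma = draws_i[b]
        lam = max(lam, 1e-6)
        sigma = max(sigma, 1e-6)
        R = A * (1.0 - np.exp(-lam * t)) + B
        fs[b + 1] = survival_prob(t, mu, sigma) * R
    alpha = 100.0 * (1.0 - ci) / 2.0
    lower = np.percentile(fs, alpha, axis=0)
    upper = np.percentile(fs, 100.0 - alpha, axis=0)
    return curve, lower, upper
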