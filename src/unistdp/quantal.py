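"""Binomial quantal release model and (P, q, N) estimators.

Transmitter release is modelled as N independent release sites, each
releasing with probability P; a released quantum contributes an
amplitude q.  The response mean and variance are then

    mu  = P * q * N
    s2  = q**2 * N * P * (1 - P)

Inverting these moments yields the in vitro estimators used to extract
P and q from plasticity recordings (with N held fixed, default 5.5,
the literature value for this connection type).  The in vivo
parameterization works with the variability measure ``v = q * (1 - P)``
and the response mean, with sign-insensitive means (|mu|) to absorb
current-sign conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "QuantalParams",
    "QuantalObservation",
    "binomial_pmf",
    "forward_stats",
    "estimate_invitro",
    "estimate_invivo_baseline",
    "estimate_invivo_after",
    "estimation_error",
    "sample_responses",
]

DEFAULT_N_SITES = 5.5


@dataclass(frozen=True)
class QuantalParams:
    """Release probability P, quantal amplitude q and site count N.

    N is a positive real at the moment-equation level; the stochastic
    sampler rounds it to the nearest integer.
    """

    P: float
    q: float
    N: float = DEFAULT_N_SITES

    def __post_init__(self) -> None:
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("P must lie in [0, 1]")
        if self.q < 0:
            raise ValueError("q must be non-negative")
        if self.N <= 0:
            raise ValueError("N must be positive")


@dataclass(frozen=True)
class QuantalObservation:
    """Mean and variance (or variability v = q(1-P)) of synaptic responses."""

    mean: float
    variance: float = 0.0
    v: float | None = None

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")
        if self.v is not None and self.v < 0:
            raise ValueError("v must be non-negative")


def binomial_pmf(k: int, N: int, P: float) -> float:
    """Probability of ``k`` successful releases out of ``N`` sites."""
    if k < 0 or k > N:
        raise ValueError("k must lie in [0, N]")
    return float(stats.binom.pmf(k, N, P))


def forward_stats(params: QuantalParams) -> QuantalObservation:
    """Moments of the scaled binomial response."""
    P, q, N = params.P, params.q, params.N
    return QuantalObservation(
        mean=P * q * N,
        variance=q * q * N * P * (1.0 - P),
        v=q * (1.0 - P),
    )


def estimate_invitro(obs: QuantalObservation, N: float = DEFAULT_N_SITES) -> tuple[float, float]:
    """Moment estimators of (P, q) at known N.

    q = variance/mean + mean/N and P = mean/(N q); the exact inverse of
    :func:`forward_stats` on its valid domain.
    """
    if obs.mean <= 0:
        raise ValueError("the in vitro estimator requires a positive mean response")
    q = obs.variance / obs.mean + obs.mean / N
    P = obs.mean / (N * q)
    return P, q


def estimate_invivo_baseline(mean: float, v: float, P0: float = 0.5) -> tuple[float, float]:
    """Baseline (N, q) from mean and variability v, assuming P = P0.

    q = v / (1 - P0) and N = |mean| / (q * P0).  A zero mean yields the
    degenerate N = 0, which is returned as-is for the caller to flag.
    """
    if v <= 0:
        raise ValueError("v must be positive for the baseline estimator")
    if not 0.0 < P0 < 1.0:
        raise ValueError("P0 must lie strictly inside (0, 1)")
    q = v / (1.0 - P0)
    N = abs(mean) / (q * P0)
    return N, q


def estimate_invivo_after(mean: float, v: float, N: float) -> tuple[float, float]:
    """After-pairing (P, q) at N fixed from the baseline estimate.

    q = v + |mean|/N and P = |mean|/(N q); P is guaranteed in (0, 1]
    whenever v >= 0 and mean != 0.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if v < 0:
        raise ValueError("v must be non-negative")
    q = v + abs(mean) / N
    P = abs(mean) / (N * q) if q > 0 else 0.0
    return P, q


def estimation_error(v_real: np.ndarray, v_est: np.ndarray) -> float:
    """Mean squared error between true and estimated variability sequences."""
    v_real = np.asarray(v_real, dtype=float)
    v_est = np.asarray(v_est, dtype=float)
    if v_real.size == 0 or v_real.shape != v_est.shape:
        raise ValueError("sequences must be non-empty and of equal length")
    return float(np.mean((v_real - v_est) ** 2))


def sample_responses(
    params: QuantalParams,
    noise_var: float = 0.0,
    n_trials: int = 1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw synthetic response amplitudes: q * Binomial(round(N), P) + noise.

    Additive Gaussian background of variance ``noise_var``; reproducible
    under an integer seed (or an existing Generator).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if noise_var < 0:
        raise ValueError("noise_var must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_int = max(int(round(params.N)), 0)
    k = rng.binomial(n_int, params.P, size=n_trials)
    noise = rng.normal(0.0, np.sqrt(noise_var), size=n_trials) if noise_var > 0 else 0.0
    return params.q * k + noise
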