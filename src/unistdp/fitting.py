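"""Fitting the six rule constants to protocol-level plasticity ratios.

The observable for each pairing protocol is the pair of before/after
ratios of the presynaptic factor P and the postsynaptic factor q
(initial P = 0.5, q = 1).  The fit minimizes the mean squared error

    MSE(theta) = (1/N) * sum_protocols [ (P_ratio_model - P_ratio_data)^2
                                         + (q_ratio_model - q_ratio_data)^2 ]

over theta = (d_minus, tau_y_minus, d_plus, tau_y_plus, c_plus,
tau_x_plus).  The canonical protocol set pairs five frequencies
{0.1, 10, 20, 40, 50} Hz with relative timings of +10 and -10 ms (ten
protocols); high-frequency protocols use bursts of five spikes paired
15 times at 0.1 Hz, the 0.1 Hz protocols a single pre/post pair per
repetition.

The optimizer (unstated in the source data's original analysis and
declared here) is multi-start Nelder-Mead in log-parameter space:
positivity comes for free and amplitudes/time constants live on very
different scales.  Synthetic targets with lognormal ratio noise
support parameter-recovery experiments in place of the experimental
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .plasticity import (
    PlasticityParams,
    ProtocolSpec,
    load_preset,
    run_pairing_protocol,
)

__all__ = [
    "FitTargets",
    "FitResult",
    "canonical_protocols",
    "objective",
    "fit",
    "synth_targets",
]

PARAM_NAMES = ("d_minus", "tau_y_minus", "d_plus", "tau_y_plus", "c_plus", "tau_x_plus")
CANONICAL_FREQS = (0.1, 10.0, 20.0, 40.0, 50.0)
TAU_BOUNDS = (1.0, 1.0e4)
AMP_BOUNDS = (1.0e-5, 1.0e-1)


@dataclass(frozen=True)
class FitTargets:
    """Target P/q ratios per protocol."""

    protocols: tuple[ProtocolSpec, ...]
    p_ratios: np.ndarray
    q_ratios: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p_ratios, dtype=float)
        q = np.asarray(self.q_ratios, dtype=float)
        object.__setattr__(self, "p_ratios", p)
        object.__setattr__(self, "q_ratios", q)
        if not (len(self.protocols) == p.size == q.size):
            raise ValueError("protocols and ratio arrays must have equal length")
        if np.any(p <= 0) or np.any(q <= 0):
            raise ValueError("target ratios must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq_hz": [s.pairing_freq for s in self.protocols],
                "delta_t_ms": [s.delta_t for s in self.protocols],
                "p_ratio": self.p_ratios,
                "q_ratio": self.q_ratios,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FitTargets":
        protocols = tuple(
            _protocol_for(float(row.freq_hz), float(row.delta_t_ms))
            for row in frame.itertuples()
        )
        return cls(
            protocols=protocols,
            p_ratios=frame["p_ratio"].to_numpy(),
            q_ratios=frame["q_ratio"].to_numpy(),
        )


@dataclass(frozen=True)
class FitResult:
    """Best parameters, objective value and optimizer diagnostics."""

    params: PlasticityParams
    objective: float
    n_starts: int
    n_iterations: int
    converged: bool
    seed: int

    @property
    def theta(self) -> np.ndarray:
        p = self.params
        return np.array(
            [p.d_minus, p.tau_y_minus, p.d_plus, p.tau_y_plus, p.c_plus, p.tau_x_plus]
        )


def _protocol_for(freq: float, delta_t: float) -> ProtocolSpec:
    n_spikes = 1 if freq < 10.0 else 5
    return ProtocolSpec(
        pairing_freq=freq,
        delta_t=delta_t,
        n_spikes_per_burst=n_spikes,
        n_pairings=15,
        repetition_rate=0.1,
    )


def canonical_protocols() -> list[ProtocolSpec]:
    """The ten-protocol set: five frequencies at +-10 ms relative timing."""
    return [
        _protocol_for(freq, dt) for freq in CANONICAL_FREQS for dt in (10.0, -10.0)
    ]


def _with_theta(base: PlasticityParams, theta: np.ndarray) -> PlasticityParams:
    return replace(base, **dict(zip(PARAM_NAMES, map(float, theta))))


def objective(params: PlasticityParams, targets: FitTargets) -> float:
    """Mean squared error of the model P/q ratios against the targets."""
    err = 0.0
    for spec, p_t, q_t in zip(targets.protocols, targets.p_ratios, targets.q_ratios):
        out = run_pairing_protocol(spec, params)
        err += (out.P_ratio - p_t) ** 2 + (out.q_ratio - q_t) ** 2
    return err / len(targets.protocols)


def synth_targets(
    params: PlasticityParams,
    noise_sd: float = 0.0,
    seed: int | None = None,
    protocols: list[ProtocolSpec] | None = None,
) -> FitTargets:
    """Targets generated by the model itself, with lognormal ratio noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    protocols = protocols if protocols is not None else canonical_protocols()
    rng = np.random.default_rng(seed)
    p_ratios, q_ratios = [], []
    for spec in protocols:
        out = run_pairing_protocol(spec, params)
        p_ratios.append(out.P_ratio)
        q_ratios.append(out.q_ratio)
    p = np.asarray(p_ratios)
    q = np.asarray(q_ratios)
    if noise_sd > 0:
        p = p * rng.lognormal(0.0, noise_sd, p.size)
        q = q * rng.lognormal(0.0, noise_sd, q.size)
    return FitTargets(protocols=tuple(protocols), p_ratios=p, q_ratios=q)


def fit(
    targets: FitTargets,
    init: PlasticityParams | None = None,
    n_starts: int = 20,
    seed: int = 0,
    ftol: float = 1.0e-8,
    max_iter: int = 4000,
) -> FitResult:
    """Multi-start Nelder-Mead minimization of the protocol MSE.

    Each start draws log-uniform parameters within the bounds
    (amplitudes in [1e-5, 1e-1], time constants in [1, 1e4] ms); the
    simplex runs in log space so parameters stay positive.  The best
    start is polished by a restarted simplex.  Deterministic under
    ``seed``.
    """
    base = init if init is not None else load_preset()
    rng = np.random.default_rng(seed)

    def loss(log_theta: np.ndarray) -> float:
        theta = np.exp(log_theta)
        if np.any(theta[[1, 3, 5]] < TAU_BOUNDS[0]) or np.any(theta[[1, 3, 5]] > TAU_BOUNDS[1]):
            return 1.0e6
        return objective(_with_theta(base, theta), targets)

    # theta layout alternates amplitude/time-constant: (d-, ty-, d+, ty+, c+, tx+)
    lo = np.log(np.array([AMP_BOUNDS[0], TAU_BOUNDS[0]] * 3))
    hi = np.log(np.array([AMP_BOUNDS[1], TAU_BOUNDS[1]] * 3))

    best = None
    total_iters = 0
    for _ in range(n_starts):
        x0 = rng.uniform(lo, hi)
        res = optimize.minimize(
            loss,
            x0,
            method="Nelder-Mead",
            options={"fatol": ftol, "xatol": 1.0e-6, "maxiter": max_iter, "adaptive": True},
        )
        total_iters += res.nit
        if best is None or res.fun < best.fun:
            best = res
    # polish: restart the simplex at the best point
    polish = optimize.minimize(
        loss,
        best.x,
        method="Nelder-Mead",
        options={"fatol": ftol * 1e-2, "xatol": 1.0e-8, "maxiter": max_iter, "adaptive": True},
    )
    total_iters += polish.nit
    if polish.fun < best.fun:
        best = polish
    theta = np.exp(best.x)
    return FitResult(
        params=_with_theta(base, theta),
        objective=float(best.fun),
        n_starts=n_starts,
        n_iterations=int(total_iters),
        converged=bool(best.success),
        seed=seed,
    )
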