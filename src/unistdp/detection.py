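"""Signal-detection analysis of synaptic responses.

A synaptic response is discriminated against a Gaussian background of
variance ``noise_var``.  Under the Gaussian approximation to the
binomial release model the response is distributed as
``Normal(P q N, q^2 N P (1-P) + noise_var)``, giving closed-form SNR,
ROC and AUC expressions.  The number of release sites N defaults to 1
here (it only rescales the mean), and the background variance defaults
to 0.5 on the dimensionless q scale.

The SNR of the first response is

    SNR = 2 (P q N)^2 / (q^2 N P (1 - P) + 2 noise_var),

the key quantity behind the observation that postsynaptic-only
potentiation is penalized: the response variance grows quadratically
in q, whereas raising P both raises the mean and *reduces* the
binomial variance, so at matched mean the high-P synapse is always the
more reliable one.

Responses later in a train depress; their SNR uses the short-term
release fraction ``r_k p_k`` in place of P.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc, ndtr

from .stp import STPParams, stp_advance, stp_init

__all__ = [
    "DetectionConfig",
    "ROCCurve",
    "snr_first",
    "snr_kth",
    "snr_sum",
    "roc_curve",
    "auc",
    "discriminability",
    "default_thresholds",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Background noise level, site count and threshold grid."""

    noise_var: float = 0.5
    N: float = 1.0
    n_thresholds: int = 512

    def __post_init__(self) -> None:
        if self.noise_var < 0:
            raise ValueError("noise_var must be non-negative")
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.n_thresholds < 2:
            raise ValueError("need at least two thresholds")


@dataclass(frozen=True)
class ROCCurve:
    """False-alarm and detection probabilities over a threshold grid."""

    thresholds: np.ndarray
    false_alarm: np.ndarray
    detection: np.ndarray


def _release_fractions(K: int, rate: float, P: float, stp_params: STPParams) -> np.ndarray:
    """r_k * p_k for the first K responses of a regular train at ``rate`` Hz."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    params = STPParams(D=stp_params.D, F=stp_params.F, P_baseline=P)
    dt = 1000.0 / rate
    out = np.empty(K)
    state = stp_init(params)
    for k in range(K):
        if k > 0:
            state = stp_advance(state, dt, params)
        out[k] = state.r * state.p
    return out


def snr_first(P: float, q: float, N: float = 1.0, noise_var: float = 0.5) -> float:
    """SNR of the first response; 0 when the mean response is 0."""
    mean = P * q * N
    denom = q * q * N * P * (1.0 - P) + 2.0 * noise_var
    if mean == 0.0:
        return 0.0
    if denom == 0.0:
        return np.inf
    return 2.0 * mean * mean / denom


def snr_kth(
    k: int,
    rate: float,
    P: float,
    q: float,
    N: float = 1.0,
    noise_var: float = 0.5,
    stp_params: STPParams = STPParams(),
) -> float:
    """SNR of the k-th response (k = 0 is the first) of a regular train.

    Uses the depressed release fraction ``u_k = r_k p_k`` in both the
    mean and the binomial variance term.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    u = _release_fractions(k + 1, rate, P, stp_params)[-1]
    mean = u * q * N
    denom = q * q * N * u * (1.0 - u) + 2.0 * noise_var
    if mean == 0.0:
        return 0.0
    return 2.0 * mean * mean / denom


def snr_sum(
    K: int,
    rate: float,
    P: float,
    q: float,
    N: float = 1.0,
    noise_var: float = 0.5,
    stp_params: STPParams = STPParams(),
) -> float:
    """SNR of the summed first K responses, independent noise per pulse."""
    if K < 1:
        raise ValueError("K must be at least 1")
    u = _release_fractions(K, rate, P, stp_params)
    mean = float(np.sum(u)) * q * N
    var = float(np.sum(q * q * N * u * (1.0 - u))) + 2.0 * K * noise_var
    if mean == 0.0:
        return 0.0
    return 2.0 * mean * mean / var


def default_thresholds(P: float, q: float, N: float, noise_var: float, n: int = 512) -> np.ndarray:
    """Grid spanning the pooled signal/noise range +- 6 combined SD."""
    mean = P * q * N
    sd = np.sqrt(q * q * N * P * (1.0 - P) + noise_var + noise_var) + 1e-12
    lo = min(0.0, mean) - 6.0 * sd
    hi = max(0.0, mean) + 6.0 * sd
    return np.linspace(lo, hi, n)


def roc_curve(
    P: float,
    q: float,
    N: float = 1.0,
    noise_var: float = 0.5,
    thresholds: np.ndarray | None = None,
) -> ROCCurve:
    """Analytic ROC under the Gaussian approximation.

    p_fa(T) = erfc(T / sqrt(2 noise_var)) / 2 and
    p_d(T) = erfc((T - P q N) / sqrt(2 (q^2 N P (1-P) + noise_var))) / 2.
    A zero noise variance degenerates to step functions, handled via the
    erfc limits of +-inf arguments.
    """
    if thresholds is None:
        thresholds = default_thresholds(P, q, N, noise_var)
    T = np.asarray(thresholds, dtype=float)
    if T.size == 0:
        raise ValueError("thresholds must be non-empty")
    mean = P * q * N
    sig_var = q * q * N * P * (1.0 - P) + noise_var
    with np.errstate(divide="ignore", invalid="ignore"):
        if noise_var > 0:
            p_fa = 0.5 * erfc(T / np.sqrt(2.0 * noise_var))
        else:
            p_fa = np.where(T < 0, 1.0, np.where(T > 0, 0.0, 0.5))
        if sig_var > 0:
            p_d = 0.5 * erfc((T - mean) / np.sqrt(2.0 * sig_var))
        else:
            p_d = np.where(T < mean, 1.0, np.where(T > mean, 0.0, 0.5))
    return ROCCurve(thresholds=T, false_alarm=p_fa, detection=p_d)


def auc(curve: ROCCurve) -> float:
    """Area under the ROC curve by the trapezoid rule, clamped to [0, 1]."""
    fa = np.asarray(curve.false_alarm, dtype=float)
    pd = np.asarray(curve.detection, dtype=float)
    if fa.size < 2:
        raise ValueError("need at least two ROC points")
    order = np.argsort(fa)
    value = float(np.trapezoid(pd[order], fa[order]))
    return min(1.0, max(0.0, value))


def discriminability(P: float, q: float, N: float = 1.0, noise_var: float = 0.5) -> float:
    """Probability of discrimination: trapezoid AUC on the default grid.

    For two Gaussians this converges (dense grid) to the closed form
    ``Phi(mean / sqrt(sig_var + noise_var))``.
    """
    curve = roc_curve(P, q, N, noise_var)
    return auc(curve)


def gaussian_auc_closed_form(P: float, q: float, N: float = 1.0, noise_var: float = 0.5) -> float:
    """Closed-form two-Gaussian AUC, the independent oracle for :func:`auc`."""
    mean = P * q * N
    total_sd = np.sqrt(q * q * N * P * (1.0 - P) + 2.0 * noise_var)
    if total_sd == 0:
        return 1.0 if mean > 0 else 0.5
    return float(ndtr(mean / total_sd))
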