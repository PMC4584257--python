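"""Tsodyks-Markram short-term plasticity with facilitation.

The model tracks two per-synapse variables between presynaptic spikes:
``r``, the normalized pool of release-ready vesicles, and ``p``, the
instantaneous release factor.  Between spikes ``r`` recovers towards 1
with time constant ``D`` (depression recovery) and ``p`` decays towards
the baseline release factor ``P`` with time constant ``F``
(facilitation).  At each presynaptic spike a fraction ``p*r`` of the
pool is released, ``r`` drops by that amount, and ``p`` jumps by
``P*(1 - p)``.

Two integration paths are provided:

* :func:`stp_advance` -- the exact event-based recursion (the jumps are
  folded into the closed-form inter-spike solution), used everywhere in
  the package.
* :func:`stp_ode_oracle` -- a dense fixed-step Euler integration of the
  underlying ODEs with instantaneous jumps, kept as an independent
  cross-check of the event recursion.

All times in this module are in milliseconds; :class:`SpikeTrain`
carries seconds (the package-wide I/O convention) and is converted at
the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STPParams",
    "STPState",
    "SpikeTrain",
    "stp_init",
    "stp_advance",
    "stp_ode_oracle",
    "release_sequence",
    "epsp_train",
]


@dataclass(frozen=True)
class STPParams:
    """Short-term plasticity constants.

    Parameters
    ----------
    D : float
        Depression (vesicle recovery) time constant, ms.
    F : float
        Facilitation time constant, ms.
    P_baseline : float
        Baseline presynaptic release factor, dimensionless probability.
        This is the quantity modified by long-term plasticity.
    """

    D: float = 200.0
    F: float = 50.0
    P_baseline: float = 0.5

    def __post_init__(self) -> None:
        if self.D <= 0 or self.F <= 0:
            raise ValueError("time constants D and F must be positive")
        if not 0.0 <= self.P_baseline <= 1.0:
            raise ValueError("P_baseline must lie in [0, 1]")


@dataclass(frozen=True)
class STPState:
    """Vesicle availability ``r`` and instantaneous release factor ``p``."""

    r: float = 1.0
    p: float = 0.5


@dataclass(frozen=True)
class SpikeTrain:
    """A strictly increasing sequence of spike times in seconds."""

    times: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if times.size and times[0] < 0:
            raise ValueError("spike times must be non-negative")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError(f"spike times of train {self.id!r} must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def times_ms(self) -> np.ndarray:
        return self.times * 1000.0


def stp_init(params: STPParams) -> STPState:
    """Rested state: full vesicle pool, release factor at baseline."""
    return STPState(r=1.0, p=params.P_baseline)


def stp_advance(state: STPState, dt_pre: float, params: STPParams) -> STPState:
    """Advance the state across one inter-spike interval of ``dt_pre`` ms.

    Implements the event recursion

    .. math::

        r_{k+1} = 1 - [1 - r_k (1 - p_k)]\\, e^{-\\Delta t / D},
        \\qquad
        p_{k+1} = P + p_k (1 - P)\\, e^{-\\Delta t / F},

    where the per-spike jumps (release ``p_k r_k`` and facilitation
    ``P (1 - p_k)``) are already folded in.  The released fraction at
    the arriving spike is ``r_{k+1} * p_{k+1}``; callers must not apply
    the jumps again.
    """
    if dt_pre < 0:
        raise ValueError("inter-spike interval must be non-negative")
    P = params.P_baseline
    r = 1.0 - (1.0 - state.r * (1.0 - state.p)) * math.exp(-dt_pre / params.D)
    p = P + state.p * (1.0 - P) * math.exp(-dt_pre / params.F)
    return STPState(r=r, p=p)


def release_sequence(spikes: SpikeTrain, params: STPParams) -> np.ndarray:
    """Released fraction ``r_k * p_k`` at each spike of a train.

    The first spike releases from the rested state (``r0 = 1``,
    ``p0 = P``); subsequent spikes follow :func:`stp_advance`.
    """
    t = spikes.times_ms
    out = np.empty(t.size)
    state = stp_init(params)
    for k in range(t.size):
        if k > 0:
            state = stp_advance(state, t[k] - t[k - 1], params)
        out[k] = state.r * state.p
    return out


def stp_ode_oracle(
    spikes: SpikeTrain, params: STPParams, step: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Dense Euler integration of the depletion/facilitation ODEs.

    Integrates ``dr/dt = (1 - r)/D`` and ``dp/dt = (P - p)/F`` with an
    explicit Euler scheme of step ``step`` ms, applying the release and
    facilitation jumps instantaneously at spike times.  Because both
    ODEs are linear and autonomous between spikes, ``n`` Euler steps
    compose exactly to a multiplication by ``(1 - step/tau)**n``; that
    closed composition is used so the oracle stays cheap at
    microsecond steps without changing its numerics.

    Returns the pair of arrays ``(r_k, p_k)`` sampled at the spike
    times, *after* folding each spike's jump into the next interval --
    i.e. directly comparable with iterating :func:`stp_advance`.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    t = spikes.times_ms
    P = params.P_baseline
    r, p = 1.0, P
    rs = np.empty(t.size)
    ps = np.empty(t.size)
    for k in range(t.size):
        if k > 0:
            dt = t[k] - t[k - 1]
            # n whole Euler steps plus one remainder step to land exactly on
            # the spike time (avoids quantizing the inter-spike interval)
            n = int(dt / step)
            rem = dt - n * step
            decay_r = (1.0 - step / params.D) ** n * (1.0 - rem / params.D)
            decay_p = (1.0 - step / params.F) ** n * (1.0 - rem / params.F)
            r = 1.0 - (1.0 - r) * decay_r
            p = P + (p - P) * decay_p
        rs[k] = r
        ps[k] = p
        # jump: release p*r, facilitate by P*(1-p)
        r = r * (1.0 - p)
        p = p + P * (1.0 - p)
    return rs, ps


def epsp_train(
    spikes: SpikeTrain,
    params: STPParams,
    q: float = 1.0,
    tau_m: float = 25.0,
) -> np.ndarray:
    """Per-spike EPSP peak amplitudes through a passive membrane.

    Each spike injects a synaptic drive ``q * r_k * p_k`` into a
    first-order low-pass filter with membrane time constant ``tau_m``
    (ms).  The filtered trace jumps at the spike and decays between
    spikes, so the peak within each inter-spike interval is the value
    right after the jump; the array of those peaks is returned.  This
    reproduces how paired-pulse ratios are read from voltage traces:
    lower baseline release (after presynaptic LTD) gives less
    short-term depression, i.e. a peak2/peak1 ratio closer to one.
    """
    if tau_m <= 0:
        raise ValueError("tau_m must be positive")
    t = spikes.times_ms
    release = release_sequence(spikes, params)
    peaks = np.empty(t.size)
    v = 0.0
    for k in range(t.size):
        if k > 0:
            v *= math.exp(-(t[k] - t[k - 1]) / tau_m)
        v += q * release[k]
        peaks[k] = v
    return peaks
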