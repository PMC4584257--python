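"""Unified long-term plasticity rule acting on P (presynaptic) and q (postsynaptic).

The rule is a triplet-style trace model.  Three exponentially decaying
traces filter the spike trains: the presynaptic trace ``x_plus``
(incremented at presynaptic spikes; NMDA-receptor-like), and two
postsynaptic traces ``y_plus`` (nitric-oxide-like) and ``y_minus``
(endocannabinoid-like), both incremented at postsynaptic spikes.

At a postsynaptic spike the quantal amplitude grows:

    dq = c_plus * x_plus * y_minus          (postsynaptic LTP, triplet)

At a presynaptic spike the release probability changes:

    dP = -d_minus * y_minus * y_plus        (presynaptic LTD)
         + d_plus * y_plus * x_plus         (presynaptic LTP)

Traces are read out *before* the increment contributed by the spike
that triggers the update, so a spike never potentiates through its own
trace.  P is hard-bounded to [0, 1]; q is clipped to a configurable
range (upper bound 2 in dimensionless protocol units, 20 nA in the
network context).  Slow subtractive homeostasis on q applies only in
network simulations: :func:`apply_homeostasis` is the per-update form
(``dq_i - alpha * mean_j dq_j``), while the network scheduler bleeds
off the accumulated mean q drift on its normalization interval (see
the network module).

All times are milliseconds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np

from .stp import STPParams, STPState, stp_advance, stp_init

__all__ = [
    "PlasticityParams",
    "TraceState",
    "SynapseState",
    "ProtocolSpec",
    "PlasticityOutcome",
    "load_preset",
    "decay_and_increment_trace",
    "on_pre_spike",
    "on_post_spike",
    "synaptic_weight",
    "apply_homeostasis",
    "apply_blockade",
    "build_protocol_trains",
    "run_pairing_protocol",
    "trace_ode_oracle",
]

BLOCKADE_MODES = ("none", "eCB", "NO")


@dataclass(frozen=True)
class PlasticityParams:
    """Constants of the unified rule.

    ``d_minus``/``d_plus`` scale presynaptic LTD/LTP, ``c_plus``
    postsynaptic LTP; the three ``tau_*`` are the trace time constants
    in ms.  ``alpha`` is the subtractive-homeostasis rate per
    normalization step (network context only).  ``lr_scale``
    multiplies the three amplitudes (1.0 for pairing protocols, 0.15
    for network development).  ``no_blockade`` forces the y_plus trace
    to read as zero, emulating blocked nitric-oxide signalling.
    """

    d_minus: float
    tau_y_minus: float
    d_plus: float
    tau_y_plus: float
    c_plus: float
    tau_x_plus: float
    alpha: float = 0.075
    q_bounds: tuple[float, float] = (0.0, 2.0)
    lr_scale: float = 1.0
    no_blockade: bool = False
    stp: STPParams = field(default_factory=STPParams)

    def __post_init__(self) -> None:
        if min(self.d_minus, self.d_plus, self.c_plus) < 0:
            raise ValueError("plasticity amplitudes must be non-negative")
        if min(self.tau_y_minus, self.tau_y_plus, self.tau_x_plus) <= 0:
            raise ValueError("trace time constants must be positive")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if self.q_bounds[0] >= self.q_bounds[1]:
            raise ValueError("q_bounds must be an increasing pair")

    @property
    def effective(self) -> tuple[float, float, float]:
        """(d_minus, d_plus, c_plus) scaled by lr_scale."""
        s = self.lr_scale
        return (s * self.d_minus, s * self.d_plus, s * self.c_plus)


def load_preset(name: str = "young_rat_visual_cortex", **overrides) -> PlasticityParams:
    """Load a named parameter preset shipped with the package."""
    ref = resources.files("unistdp.data").joinpath(f"{name}.json")
    try:
        payload = json.loads(ref.read_text())
    except FileNotFoundError as exc:
        raise KeyError(f"unknown preset {name!r}") from exc
    stp_cfg = payload.get("stp", {})
    kwargs = dict(
        d_minus=payload["d_minus"],
        tau_y_minus=payload["tau_y_minus_ms"],
        d_plus=payload["d_plus"],
        tau_y_plus=payload["tau_y_plus_ms"],
        c_plus=payload["c_plus"],
        tau_x_plus=payload["tau_x_plus_ms"],
        alpha=payload.get("alpha", 0.075),
        stp=STPParams(D=stp_cfg.get("D_ms", 200.0), F=stp_cfg.get("F_ms", 50.0)),
    )
    kwargs.update(overrides)
    return PlasticityParams(**kwargs)


@dataclass(frozen=True)
class TraceState:
    """Values of the three traces together with last pre/post spike times.

    Trace values are stored as of their own last update; reading a trace
    at a later time requires decaying it by the elapsed interval.
    ``t_last_pre``/``t_last_post`` are ``-inf`` until the first spike of
    the corresponding kind, which makes the decayed readouts exactly 0.
    """

    x_plus: float = 0.0
    y_plus: float = 0.0
    y_minus: float = 0.0
    t_last_pre: float = -math.inf
    t_last_post: float = -math.inf


@dataclass(frozen=True)
class SynapseState:
    """Full per-synapse state: long-term factors, traces and STP."""

    P: float = 0.5
    q: float = 1.0
    traces: TraceState = field(default_factory=TraceState)
    stp: STPState = field(default_factory=lambda: STPState(r=1.0, p=0.5))


def decay_and_increment_trace(trace: float, dt: float, tau: float, increment: float = 0.0) -> float:
    """Exact inter-spike trace update: ``trace * exp(-dt/tau) + increment``."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    return trace * math.exp(-dt / tau) + increment


def _decayed(value: float, t_last: float, t: float, tau: float) -> float:
    if not math.isfinite(t_last):
        return 0.0
    return value * math.exp(-(t - t_last) / tau)


def synaptic_weight(state: SynapseState) -> float:
    """Instantaneous synaptic strength ``w = q * p * r``.

    For a rested synapse (r = 1, p = P) this reduces to ``w = P * q``.
    """
    return state.q * state.stp.p * state.stp.r


def on_pre_spike(state: SynapseState, t: float, params: PlasticityParams) -> SynapseState:
    """Process a presynaptic spike at time ``t`` ms.

    Reads the postsynaptic traces (decayed to ``t``) and the
    presynaptic trace (value before this spike's increment), applies
    dP, clips P to [0, 1], increments x_plus, and advances the
    short-term state across the presynaptic inter-spike interval using
    the updated P as the STP baseline.
    """
    tr = state.traces
    if t < max(tr.t_last_pre, tr.t_last_post):
        raise ValueError("events must be processed in non-decreasing time order")
    d_minus, d_plus, _ = params.effective
    y_m = _decayed(tr.y_minus, tr.t_last_post, t, params.tau_y_minus)
    y_p = 0.0 if params.no_blockade else _decayed(tr.y_plus, tr.t_last_post, t, params.tau_y_plus)
    x_val = _decayed(tr.x_plus, tr.t_last_pre, t, params.tau_x_plus)
    P = min(1.0, max(0.0, state.P + (-d_minus * y_m * y_p + d_plus * y_p * x_val)))

    stp_params = replace(params.stp, P_baseline=P)
    if math.isfinite(tr.t_last_pre):
        stp_state = stp_advance(state.stp, t - tr.t_last_pre, stp_params)
    else:
        stp_state = stp_init(stp_params)
    traces = replace(tr, x_plus=x_val + 1.0, t_last_pre=t)
    return SynapseState(P=P, q=state.q, traces=traces, stp=stp_state)


def on_post_spike(state: SynapseState, t: float, params: PlasticityParams) -> SynapseState:
    """Process a postsynaptic spike at time ``t`` ms.

    Applies dq = c_plus * x_plus * y_minus with y_minus read *before*
    this spike's increment (a postsynaptic spike therefore needs both a
    preceding presynaptic and a preceding postsynaptic spike to trigger
    LTP), clips q to bounds, then increments both postsynaptic traces.
    """
    tr = state.traces
    if t < max(tr.t_last_pre, tr.t_last_post):
        raise ValueError("events must be processed in non-decreasing time order")
    _, _, c_plus = params.effective
    x_val = _decayed(tr.x_plus, tr.t_last_pre, t, params.tau_x_plus)
    y_m = _decayed(tr.y_minus, tr.t_last_post, t, params.tau_y_minus)
    y_p = _decayed(tr.y_plus, tr.t_last_post, t, params.tau_y_plus)
    lo, hi = params.q_bounds
    q = min(hi, max(lo, state.q + c_plus * x_val * y_m))
    traces = replace(tr, y_minus=y_m + 1.0, y_plus=y_p + 1.0, t_last_post=t)
    return SynapseState(P=state.P, q=q, traces=traces, stp=state.stp)


def apply_homeostasis(delta_q: Sequence[float], alpha: float) -> np.ndarray:
    """Subtractive normalization: ``dq_i - alpha * mean_j(dq_j)``.

    Applied across all synapses of one postsynaptic neuron; conserves
    ``sum(adjusted) = (1 - alpha) * sum(raw)`` exactly.
    """
    dq = np.asarray(delta_q, dtype=float)
    if dq.size == 0:
        raise ValueError("delta_q must be non-empty")
    return dq - alpha * dq.mean()


def apply_blockade(params: PlasticityParams, mode: str) -> PlasticityParams:
    """Pharmacological-blockade variants of the rule.

    ``eCB`` (endocannabinoid receptor blockade) disables presynaptic
    LTD by setting d_minus = 0; ``NO`` (nitric-oxide blockade) forces
    the y_plus trace to zero, removing both presynaptic terms.
    ``none`` returns the parameters unchanged.
    """
    if mode == "none":
        return params
    if mode == "eCB":
        return replace(params, d_minus=0.0)
    if mode == "NO":
        return replace(params, no_blockade=True)
    raise ValueError(f"unknown blockade mode {mode!r}; expected one of {BLOCKADE_MODES}")


@dataclass(frozen=True)
class ProtocolSpec:
    """A pairing experiment.

    ``delta_t`` follows the convention dt = t_post - t_pre (ms): positive
    means the postsynaptic spike trails the presynaptic one.  High
    frequency protocols use bursts of ``n_spikes_per_burst`` pre/post
    pairs at ``pairing_freq``, repeated ``n_pairings`` times at
    ``repetition_rate``.
    """

    pairing_freq: float
    delta_t: float
    n_spikes_per_burst: int = 5
    n_pairings: int = 15
    repetition_rate: float = 0.1
    blockade: str = "none"

    def __post_init__(self) -> None:
        if self.pairing_freq <= 0:
            raise ValueError("pairing_freq must be positive")
        if self.n_spikes_per_burst < 1 or self.n_pairings < 1:
            raise ValueError("spike and pairing counts must be at least 1")
        if self.blockade not in BLOCKADE_MODES:
            raise ValueError(f"blockade must be one of {BLOCKADE_MODES}")
        if self.n_pairings > 1:
            burst_ms = (self.n_spikes_per_burst - 1) * 1000.0 / self.pairing_freq + abs(self.delta_t)
            if burst_ms > 1000.0 / self.repetition_rate:
                raise ValueError("burst duration exceeds the repetition interval")

    @property
    def id(self) -> str:
        sign = "+" if self.delta_t >= 0 else ""
        tag = "" if self.blockade == "none" else f"_{self.blockade}"
        return f"{self.pairing_freq:g}Hz_{sign}{self.delta_t:g}ms{tag}"


@dataclass(frozen=True)
class PlasticityOutcome:
    """Before/after ratios of the two factors and of the rested weight."""

    P_ratio: float
    q_ratio: float
    w_ratio: float


def build_protocol_trains(spec: ProtocolSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic pre/post spike times (ms) for a pairing protocol.

    Within repetition ``m`` (period ``1/repetition_rate``), pre spikes
    sit at ``k / pairing_freq`` for ``k = 0..n-1`` and post spikes at
    the same positions shifted by ``delta_t``.  A negative ``delta_t``
    may place the first post spike before the first pre spike; event
    times are later shifted so all are non-negative.
    """
    period = 1000.0 / spec.repetition_rate
    burst = np.arange(spec.n_spikes_per_burst) * 1000.0 / spec.pairing_freq
    reps = np.arange(spec.n_pairings) * period
    pre = (reps[:, None] + burst[None, :]).ravel()
    post = pre + spec.delta_t
    return pre, post


def run_pairing_protocol(
    spec: ProtocolSpec,
    params: PlasticityParams,
    initial_P: float = 0.5,
    initial_q: float = 1.0,
) -> PlasticityOutcome:
    """Simulate a pairing protocol and return P/q/w before-after ratios.

    Events are processed in time order with the documented tie rule
    (a presynaptic event precedes a simultaneous postsynaptic one).
    Homeostasis is not applied in this context.  The rested weight is
    ``w = P * q``.
    """
    if initial_P <= 0 or initial_q <= 0:
        raise ValueError("initial P and q must be positive to form ratios")
    params = apply_blockade(params, spec.blockade)
    pre, post = build_protocol_trains(spec)
    shift = min(pre.min(), post.min())
    events = sorted(
        [(t - shift, 0) for t in pre] + [(t - shift, 1) for t in post]
    )  # kind 0 = pre, 1 = post; pre wins ties

    # plain-float replay of on_pre_spike / on_post_spike (the protocol loop
    # sits inside the fitting objective, so it avoids per-event dataclass
    # allocation; equivalence with the event API is covered by tests)
    d_minus, d_plus, c_plus = params.effective
    tau_ym, tau_yp, tau_xp = params.tau_y_minus, params.tau_y_plus, params.tau_x_plus
    q_lo, q_hi = params.q_bounds
    no_block = params.no_blockade
    exp = math.exp
    P, q = initial_P, initial_q
    x_plus = y_plus = y_minus = 0.0
    t_pre = t_post = -math.inf
    for t, kind in events:
        if kind == 0:
            y_m = y_minus * exp(-(t - t_post) / tau_ym) if t_post > -math.inf else 0.0
            y_p = 0.0 if (no_block or t_post == -math.inf) else (
                y_plus * exp(-(t - t_post) / tau_yp)
            )
            x_val = x_plus * exp(-(t - t_pre) / tau_xp) if t_pre > -math.inf else 0.0
            P = min(1.0, max(0.0, P - d_minus * y_m * y_p + d_plus * y_p * x_val))
            x_plus = x_val + 1.0
            t_pre = t
        else:
            x_val = x_plus * exp(-(t - t_pre) / tau_xp) if t_pre > -math.inf else 0.0
            if t_post > -math.inf:
                y_m = y_minus * exp(-(t - t_post) / tau_ym)
                y_p = y_plus * exp(-(t - t_post) / tau_yp)
            else:
                y_m = y_p = 0.0
            q = min(q_hi, max(q_lo, q + c_plus * x_val * y_m))
            y_minus = y_m + 1.0
            y_plus = y_p + 1.0
            t_post = t
    return PlasticityOutcome(
        P_ratio=P / initial_P,
        q_ratio=q / initial_q,
        w_ratio=(P * q) / (initial_P * initial_q),
    )


def trace_ode_oracle(
    pre_times: np.ndarray,
    post_times: np.ndarray,
    params: PlasticityParams,
    step: float = 1e-3,
) -> dict[str, np.ndarray]:
    """Dense Euler integration of the three trace ODEs.

    Integrates ``d(trace)/dt = -trace/tau`` with explicit Euler at step
    ``step`` ms and unit increments at the driving spikes, sampling each
    trace *just before* each spike of its own driving train (matching
    the read-before-increment convention of the event updates).  As in
    the STP oracle, the Euler steps between events compose exactly to
    ``(1 - step/tau)**n`` which is evaluated in closed form.

    Returns readouts at every event of the merged (pre + post) stream:
    arrays ``x_plus``, ``y_plus``, ``y_minus`` aligned with the sorted
    merged event times ``t`` and kinds ``kind`` (0 pre / 1 post).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    events = sorted([(t, 0) for t in pre_times] + [(t, 1) for t in post_times])
    taus = (params.tau_x_plus, params.tau_y_plus, params.tau_y_minus)
    vals = [0.0, 0.0, 0.0]  # x_plus, y_plus, y_minus
    t_prev = events[0][0] if events else 0.0
    out = {k: [] for k in ("t", "kind", "x_plus", "y_plus", "y_minus")}
    for t, kind in events:
        dt = t - t_prev
        n = int(dt / step)
        rem = dt - n * step
        for i, tau in enumerate(taus):
            vals[i] *= (1.0 - step / tau) ** n * (1.0 - rem / tau)
        t_prev = t
        out["t"].append(t)
        out["kind"].append(kind)
        out["x_plus"].append(vals[0])
        out["y_plus"].append(vals[1])
        out["y_minus"].append(vals[2])
        if kind == 0:
            vals[0] += 1.0
        else:
            vals[1] += 1.0
            vals[2] += 1.0
    return {k: np.asarray(v) for k, v in out.items()}
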