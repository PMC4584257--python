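"""Receptive-field development and memory-savings simulations.

A single adaptive exponential integrate-and-fire (AdEx) neuron receives
100 Poisson inputs whose rates follow a Gaussian profile over the input
index (peak ``rho_max`` = 50 Hz, floor ``rho_min`` = 3 Hz, spread
``sigma`` = 5 index units).  Every synapse carries the full unified
plasticity state (P, q, traces, short-term dynamics); each input spike
injects a current pulse of amplitude ``q_j * p_j * r_j`` nA through an
exponential kernel.  Plasticity amplitudes are scaled by ``lr_scale``
(default 0.15) and a subtractive homeostasis on q (rate ``alpha`` =
0.075 per 10 ms normalization step) keeps postsynaptic potentiation in
check.  q is bounded to [0, 20] nA in this context.

For memory savings, two receptive-field positions alternate in blocks;
learning time is the time for the performance measure (the mean rested
weight ``w_j = P_j q_j`` over the active stimulus's on-region,
affinely rescaled per block between its block-start value and the
converged single-stimulus value) to reach the 0.99 threshold.
Relearning of a previously seen stimulus is fast because its q-profile
persists as a hidden trace -- only P has to be rebuilt -- whereas
initial learning must grow q from baseline, which is the slow
component of the rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .detection import snr_first, discriminability
from .plasticity import PlasticityParams

__all__ = [
    "RateProfile",
    "AdExParams",
    "NetworkConfig",
    "Trajectory",
    "SavingsResult",
    "gaussian_rates",
    "adex_step",
    "NetworkState",
    "run_development",
    "run_savings",
    "savings_experiment",
    "profile_correlation",
    "probe_response",
    "preference",
    "on_region_weight",
    "performance",
    "half_rise_time",
    "on_off_masks",
    "evaluate_snr_map",
]


@dataclass(frozen=True)
class RateProfile:
    """Gaussian rate profile over the input index.

    ``rate_j = rho_min + (rho_max - rho_min) * exp(-(j - center)^2 / (2 sigma^2))``
    with ``j = 1..n_inputs``.  ``spread`` is in input-index units.
    """

    center: float
    spread: float = 5.0
    rho_min: float = 3.0
    rho_max: float = 50.0
    n_inputs: int = 100

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if not 0.0 <= self.rho_min <= self.rho_max:
            raise ValueError("need 0 <= rho_min <= rho_max")
        if not 1 <= self.center <= self.n_inputs:
            raise ValueError("center must lie within the input range")


def gaussian_rates(profile: RateProfile) -> np.ndarray:
    """Per-input Poisson rates (Hz) for a profile."""
    j = np.arange(1, profile.n_inputs + 1, dtype=float)
    bump = np.exp(-((j - profile.center) ** 2) / (2.0 * profile.spread**2))
    return profile.rho_min + (profile.rho_max - profile.rho_min) * bump


@dataclass(frozen=True)
class AdExParams:
    """Adaptive exponential integrate-and-fire constants (standard set)."""

    C_pF: float = 281.0
    g_L_nS: float = 30.0
    E_L_mV: float = -70.6
    V_T_mV: float = -50.4
    Delta_T_mV: float = 2.0
    a_nS: float = 4.0
    b_nA: float = 0.0805
    tau_w_ms: float = 144.0
    V_reset_mV: float = -70.6
    V_cut_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.C_pF <= 0 or self.g_L_nS <= 0 or self.tau_w_ms <= 0:
            raise ValueError("capacitance, leak conductance and tau_w must be positive")


def adex_step(
    V: float, w_adapt: float, I_nA: float, params: AdExParams, dt_ms: float = 0.1
) -> tuple[float, float, bool]:
    """One forward-Euler AdEx update; returns (V, w_adapt, spiked).

    ``w_adapt`` is in pA, ``V`` in mV.  On crossing the cutoff the
    voltage resets and the adaptation current jumps by b.
    """
    ex = min((V - params.V_T_mV) / params.Delta_T_mV, 30.0)
    I_pA = I_nA * 1000.0
    dV = (
        dt_ms
        * (
            -params.g_L_nS * (V - params.E_L_mV)
            + params.g_L_nS * params.Delta_T_mV * math.exp(ex)
            - w_adapt
            + I_pA
        )
        / params.C_pF
    )
    dw = dt_ms * (params.a_nS * (V - params.E_L_mV) - w_adapt) / params.tau_w_ms
    V, w_adapt = V + dV, w_adapt + dw
    if not (math.isfinite(V) and math.isfinite(w_adapt)):
        raise FloatingPointError("AdEx state became non-finite")
    if V >= params.V_cut_mV:
        return params.V_reset_mV, w_adapt + params.b_nA * 1000.0, True
    return V, w_adapt, False


@dataclass(frozen=True)
class NetworkConfig:
    """Simulation constants for the feedforward network."""

    n_inputs: int = 100
    dt_ms: float = 0.1
    q_init_nA: float = 2.0
    q_bounds: tuple[float, float] = (0.0, 20.0)
    lr_scale: float = 0.15
    alpha: float = 0.075
    homeo_interval_ms: float = 10.0
    tau_syn_ms: float = 2.5
    record_interval_ms: float = 50.0
    adex: AdExParams = field(default_factory=AdExParams)

    def __post_init__(self) -> None:
        if self.dt_ms <= 0 or self.dt_ms > 0.1 + 1e-12:
            raise ValueError("dt_ms must be positive and at most 0.1 ms")
        if self.q_bounds[0] >= self.q_bounds[1]:
            raise ValueError("q_bounds must be increasing")


class NetworkState:
    """Mutable per-synapse and neuron state, chained across blocks."""

    def __init__(self, config: NetworkConfig, initial_P: float = 0.5):
        n = config.n_inputs
        self.config = config
        self.P = np.full(n, initial_P)
        self.q = np.full(n, config.q_init_nA)
        self.r = np.ones(n)
        self.p = np.full(n, initial_P)
        self.x_plus = np.zeros(n)
        self.t_pre = np.full(n, _kernel.NEG_INF)
        self.q_target_mean = float(config.q_init_nA)
        self.misc = np.zeros(7)
        self.misc[_kernel.T_POST] = _kernel.NEG_INF
        self.misc[_kernel.V_MEMB] = config.adex.E_L_mV

    def copy(self) -> "NetworkState":
        dup = NetworkState.__new__(NetworkState)
        dup.config = self.config
        for name in ("P", "q", "r", "p", "x_plus", "t_pre", "misc"):
            setattr(dup, name, getattr(self, name).copy())
        dup.q_target_mean = self.q_target_mean
        return dup

    @property
    def weights(self) -> np.ndarray:
        """Rested synaptic weights w_j = P_j * q_j."""
        return self.P * self.q


@dataclass(frozen=True)
class Trajectory:
    """Sampled P/q time courses and postsynaptic spikes of one run."""

    times_s: np.ndarray
    P: np.ndarray  # (n_samples, n_inputs)
    q: np.ndarray
    post_spikes_s: np.ndarray
    rates_hz: np.ndarray
    status: int = 0


def _derived_seed(seed: int, *salt: int) -> int:
    return int(np.random.SeedSequence([int(seed), *map(int, salt)]).generate_state(1)[0] % (2**31))


def _run_block(
    state: NetworkState,
    profile: RateProfile,
    duration_s: float,
    params: PlasticityParams,
    seed: int,
    freeze_P: bool = False,
) -> Trajectory:
    cfg = state.config
    rates = gaussian_rates(profile)
    d_minus, d_plus, c_plus = (
        cfg.lr_scale * params.d_minus,
        cfg.lr_scale * params.d_plus,
        cfg.lr_scale * params.c_plus,
    )
    n_steps = int(round(duration_s * 1000.0 / cfg.dt_ms))
    adex = cfg.adex
    rec_t, rec_P, rec_q, post, n_post, status = _kernel.run_block(
        seed,
        n_steps,
        cfg.dt_ms,
        rates,
        state.P,
        state.q,
        state.r,
        state.p,
        state.x_plus,
        state.t_pre,
        state.q_target_mean,
        state.misc,
        d_minus,
        d_plus,
        c_plus,
        params.tau_y_minus,
        params.tau_y_plus,
        params.tau_x_plus,
        params.no_blockade,
        freeze_P,
        params.stp.D,
        params.stp.F,
        cfg.q_bounds[0],
        cfg.q_bounds[1],
        cfg.alpha,
        max(int(round(cfg.homeo_interval_ms / cfg.dt_ms)), 1),
        adex.C_pF,
        adex.g_L_nS,
        adex.E_L_mV,
        adex.V_T_mV,
        adex.Delta_T_mV,
        adex.a_nS,
        adex.b_nA,
        adex.tau_w_ms,
        adex.V_reset_mV,
        adex.V_cut_mV,
        cfg.tau_syn_ms,
        max(int(round(cfg.record_interval_ms / cfg.dt_ms)), 1),
    )
    if status == 1:
        raise RuntimeError("runaway firing: postsynaptic rate exceeded 500 Hz sustained")
    if status == 2:
        raise FloatingPointError("membrane state became non-finite")
    return Trajectory(
        times_s=rec_t / 1000.0,
        P=rec_P,
        q=rec_q,
        post_spikes_s=post / 1000.0,
        rates_hz=rates,
        status=status,
    )


def run_development(
    profile: RateProfile,
    params: PlasticityParams,
    config: NetworkConfig | None = None,
    duration_s: float = 100.0,
    seed: int = 0,
    initial_P: float = 0.5,
    freeze_P: bool = False,
) -> tuple[Trajectory, NetworkState]:
    """Single-stimulus receptive-field development.

    ``freeze_P`` runs the postsynaptic-only ablation: P stays at its
    initial value and only q develops (with homeostasis).
    """
    config = config or NetworkConfig()
    state = NetworkState(config, initial_P=initial_P)
    traj = _run_block(state, profile, duration_s, params, _derived_seed(seed, 0), freeze_P)
    return traj, state


def profile_correlation(P: np.ndarray, q: np.ndarray, rates: np.ndarray) -> float:
    """Pearson correlation between rested weights P*q and a rate profile."""
    w = np.asarray(P) * np.asarray(q)
    if np.std(w) == 0 or np.std(rates) == 0:
        return 0.0
    return float(np.corrcoef(w, rates)[0, 1])


def probe_response(
    state: NetworkState,
    profile: RateProfile,
    params: PlasticityParams,
    seed: int,
    duration_s: float = 2.0,
) -> float:
    """Postsynaptic firing rate (Hz) when presenting a stimulus alone.

    Runs a copy of the state with long-term plasticity inactive (all
    amplitudes zero, P frozen, homeostasis off), so probing never
    perturbs learning.  The copy starts rested -- full vesicle pools,
    facilitation at baseline, traces and adaptation decayed -- as if
    the stimulus arrived after a quiet period, so the response is
    carried by the rested weights P*q.
    """
    frozen = state.copy()
    frozen.config = replace(state.config, alpha=0.0)
    frozen.r[:] = 1.0
    frozen.p[:] = frozen.P
    frozen.x_plus[:] = 0.0
    frozen.t_pre[:] = _kernel.NEG_INF
    frozen.misc[_kernel.Y_PLUS] = frozen.misc[_kernel.Y_MINUS] = 0.0
    frozen.misc[_kernel.T_POST] = _kernel.NEG_INF
    frozen.misc[_kernel.V_MEMB] = frozen.config.adex.E_L_mV
    frozen.misc[_kernel.W_ADAPT] = 0.0
    frozen.misc[_kernel.I_SYN] = 0.0
    probe_params = replace(params, d_minus=0.0, d_plus=0.0, c_plus=0.0)
    traj = _run_block(frozen, profile, duration_s, probe_params, seed, freeze_P=True)
    return traj.post_spikes_s.size / duration_s


def preference(f_own: float, f_other: float) -> float:
    """Stimulus-preference index of probe responses, in [-1, 1]."""
    total = f_own + f_other
    if total <= 0:
        return 0.0
    return (f_own - f_other) / total


def on_region_weight(P: np.ndarray, q: np.ndarray, profile: RateProfile) -> float:
    """Mean rested weight P*q over the stimulus's on-region inputs."""
    on, _ = on_off_masks(profile)
    return float((np.asarray(P)[on] * np.asarray(q)[on]).mean())


def performance(value: float, start: float, ref: float) -> float:
    """Tuning performance: affinely rescaled on-region weight, in [0, 1].

    0 at the block-start value, 1 at the converged single-stimulus
    reference (end of pre-training); clamped, so strengthening beyond
    the reference still reads as 1.  Learning time is the time to
    cross 0.99.
    """
    span = ref - start
    if span <= 0:
        return 1.0 if value >= ref else 0.0
    return min(1.0, max(0.0, (value - start) / span))


def half_rise_time(times: np.ndarray, series: np.ndarray) -> float:
    """First time at which a series crosses halfway from start to end."""
    target = 0.5 * (series[0] + series[-1])
    rising = series[-1] >= series[0]
    hit = np.nonzero(series >= target if rising else series <= target)[0]
    return float(times[hit[0]]) if hit.size else float(times[-1])


def on_off_masks(profile: RateProfile) -> tuple[np.ndarray, np.ndarray]:
    """Input classification: on = within one spread of the peak, off = beyond three."""
    j = np.arange(1, profile.n_inputs + 1, dtype=float)
    dist = np.abs(j - profile.center)
    return dist <= profile.spread, dist >= 3.0 * profile.spread


@dataclass(frozen=True)
class SavingsResult:
    """Learning times of the alternating-stimulus schedule.

    ``block_stimuli`` labels each post-pretraining block ('A'/'B');
    ``learning_times_s`` holds the time to 0.99 performance in each
    block (block length if never reached, mirrored in ``reached``).
    ``perf_times_s``/``perf_curves`` hold the per-block performance
    curves (block-relative times).  The savings ratio compares the
    first and second B blocks.
    """

    block_stimuli: tuple[str, ...]
    learning_times_s: np.ndarray
    reached: np.ndarray
    weight_ref: float
    perf_times_s: tuple[np.ndarray, ...]
    perf_curves: tuple[np.ndarray, ...]
    trajectories: tuple[Trajectory, ...]

    @property
    def savings_ratio(self) -> float:
        b_blocks = [i for i, s in enumerate(self.block_stimuli) if s == "B"]
        first, second = b_blocks[0], b_blocks[1]
        return float(self.learning_times_s[first] / self.learning_times_s[second])


def run_savings(
    profile_a: RateProfile,
    profile_b: RateProfile,
    params: PlasticityParams,
    config: NetworkConfig | None = None,
    seed: int = 0,
    pretrain_s: float = 100.0,
    block_s: float = 150.0,
    block_stimuli: tuple[str, ...] = ("B", "A", "B"),
) -> SavingsResult:
    """Alternating two-stimulus schedule with per-block learning times.

    The network first converges on stimulus A; the mean on-region
    rested weight reached there is the converged single-stimulus
    reference (B is a translate of A, so the reference transfers).
    Within each block, performance is the on-region weight of the
    active stimulus rescaled between its block-start value and that
    reference; the learning time is the first sample crossing 0.99
    (block length, flagged, if never crossed).  Because the readout is
    built from the rested weights ``w = P q`` it needs no extra
    probing and does not penalize the hidden q-trace of the inactive
    stimulus -- the memory the schedule is designed to expose.
    """
    if block_stimuli.count("B") < 2:
        raise ValueError("schedule must expose stimulus B at least twice")
    config = config or NetworkConfig()
    state = NetworkState(config)
    profiles = {"A": profile_a, "B": profile_b}

    pre = _run_block(state, profile_a, pretrain_s, params, _derived_seed(seed, 0))
    weight_ref = on_region_weight(state.P, state.q, profile_a)

    times = np.empty(len(block_stimuli))
    reached = np.zeros(len(block_stimuli), dtype=bool)
    trajs = [pre]
    perf_times: list[np.ndarray] = []
    perf_curves: list[np.ndarray] = []
    for i, stim in enumerate(block_stimuli):
        prof = profiles[stim]
        start = on_region_weight(state.P, state.q, prof)
        t0 = state.misc[_kernel.T_NOW] / 1000.0
        traj = _run_block(state, prof, block_s, params, _derived_seed(seed, i + 1))
        trajs.append(traj)
        on, _ = on_off_masks(prof)
        w_on = (traj.P[:, on] * traj.q[:, on]).mean(axis=1)
        perf = np.array([performance(v, start, weight_ref) for v in w_on])
        hit = np.nonzero(perf >= 0.99)[0]
        if hit.size:
            times[i] = traj.times_s[hit[0]] - t0
            reached[i] = True
        else:
            times[i] = block_s
        perf_times.append(traj.times_s - t0)
        perf_curves.append(perf)
    return SavingsResult(
        block_stimuli=block_stimuli,
        learning_times_s=times,
        reached=reached,
        weight_ref=weight_ref,
        perf_times_s=tuple(perf_times),
        perf_curves=tuple(perf_curves),
        trajectories=tuple(trajs),
    )


def savings_experiment(
    params: PlasticityParams,
    config: NetworkConfig | None = None,
    n_seeds: int = 10,
    seed: int = 0,
    center_a: float = 30.0,
    center_b: float = 70.0,
    pretrain_s: float = 100.0,
    block_s: float = 150.0,
) -> dict:
    """Savings ratio (initial learning time / relearning time) over seeds."""
    profile_a = RateProfile(center=center_a)
    profile_b = RateProfile(center=center_b)
    ratios = np.empty(n_seeds)
    initial = np.empty(n_seeds)
    relearn = np.empty(n_seeds)
    for i in range(n_seeds):
        res = run_savings(
            profile_a,
            profile_b,
            params,
            config,
            seed=_derived_seed(seed, 100 + i),
            pretrain_s=pretrain_s,
            block_s=block_s,
        )
        b_blocks = [k for k, s in enumerate(res.block_stimuli) if s == "B"]
        initial[i] = res.learning_times_s[b_blocks[0]]
        relearn[i] = res.learning_times_s[b_blocks[1]]
        ratios[i] = res.savings_ratio
    return {
        "ratios": ratios,
        "mean_ratio": float(np.mean(ratios)),
        "initial_times_s": initial,
        "relearning_times_s": relearn,
        "n_seeds": n_seeds,
    }


def evaluate_snr_map(
    P: np.ndarray,
    q: np.ndarray,
    q_init: float,
    noise_var: float = 0.5,
    N: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-input SNR and discrimination AUC of the first response.

    q is normalized by its initial value so that the dimensionless
    background variance applies.
    """
    qn = np.asarray(q) / q_init
    snr = np.array([snr_first(Pj, qj, N, noise_var) for Pj, qj in zip(P, qn)])
    aucs = np.array([discriminability(Pj, qj, N, noise_var) for Pj, qj in zip(P, qn)])
    return snr, aucs
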