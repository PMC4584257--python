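# Methods

## The synapse model

Synaptic strength is the product of a presynaptic factor `P` (release
probability, hard-bounded to [0, 1]) and a postsynaptic factor `q`
(quantal amplitude, lower-bounded at 0 with a configurable upper
bound): the rested weight is `w = P q`, and the instantaneous weight is
`w(t) = q p(t) r(t)` once short-term dynamics are engaged.

### Short-term plasticity

Between presynaptic spikes the normalized vesicle pool `r` recovers to
1 with time constant `D` (default 200 ms) and the instantaneous release
factor `p` decays to the baseline `P` with time constant `F` (50 ms);
at each spike a fraction `p r` of the pool is released and `p` jumps by
`P (1 - p)`.  The defaults are typical for pyramidal-to-pyramidal
connections.  We integrate this exactly between spikes using the
event recursion

    r_{k+1} = 1 - [1 - r_k (1 - p_k)] e^{-dt/D}
    p_{k+1} = P + p_k (1 - P) e^{-dt/F}

with `r_0 = 1`, `p_0 = P` — the per-spike jumps are folded into the
recursion, and the release at spike k is `r_k p_k`.  A dense
explicit-Euler integrator with instantaneous jumps serves as an
independent oracle in the tests.  Because both ODEs are linear between
spikes, the oracle composes its Euler steps in closed form
(`(1 - h/tau)^n` plus one remainder step to land exactly on each spike
time); this is bit-equivalent to literal stepping but cheap enough to
run at nanosecond steps.  The oracle's own truncation error is
`~dt·h/(2 tau^2)` relative, which sets the comparison tolerances used
in the tests (1e-4 relative with a 1e-5 absolute floor for STP at a
1 µs step; 1e-6 relative for the traces at a 2.5 ns step).

### Long-term plasticity

Three exponentially decaying spike traces drive the rule: a
presynaptic trace `x+` (time constant 48.6 ms; NMDA-receptor-like) and
two postsynaptic traces, `y+` (417.8 ms; nitric-oxide-like) and `y-`
(12.5 ms; endocannabinoid-like).  At each postsynaptic spike

    dq = c+ · x+ · y-          (triplet postsynaptic LTP)

and at each presynaptic spike

    dP = -d- · y- · y+  +  d+ · y+ · x+   (presynaptic LTD and LTP).

Traces are read out *before* the increment contributed by the
triggering spike, implemented as read-then-increment ordering rather
than a finite time offset.  Simultaneous pre/post events are processed
pre-first (a deterministic, documented tie rule; the shipped protocols
never produce exact ties).  The triplet structure means postsynaptic
LTP requires a preceding postsynaptic spike (through `y-`), so low
pairing frequencies produce no LTP in `q`, while presynaptic LTD
(driven by `y-·y+` at presynaptic spikes) survives at low frequency.

The six constants `(d-, tau_y-, d+, tau_y+, c+, tau_x+)` are shipped
as the `young_rat_visual_cortex` preset
(0.00389, 12.5 ms, 0.002483, 417.8 ms, 0.013706, 48.6 ms), stored as
package data rather than code.  With these constants, one diagnostic
worth recording: at 50 Hz with +10 ms timing the first paired spikes
produce a slightly *negative* net dP; potentiation builds up only as
`y+` accumulates across the burst.  This is the mechanism behind the
frequency threshold for presynaptic LTP.

### Pairing protocols

A protocol is (pairing frequency, dt = t_post - t_pre, spikes per
burst, number of pairings, repetition rate, blockade mode).  High
frequency (>= 10 Hz) protocols use five pre/post pairs per burst,
repeated 15 times at 0.1 Hz; the 0.1 Hz protocols use a single
pre/post pair per repetition.  The number of repetitions of the 0.1 Hz
protocols is not pinned down by the source data; we default to 15 to
match the high-frequency protocols.  Protocols start from P = 0.5,
q = 1 and report before/after ratios of P, q and w = Pq.  Homeostasis
is not applied in protocol simulations.

Pharmacological blockade modes: `eCB` sets d- = 0 (endocannabinoid
receptor blockade disables presynaptic LTD, revealing stronger
presynaptic LTP); `NO` forces the `y+` readout to zero (nitric-oxide
blockade removes both presynaptic terms, leaving purely postsynaptic
potentiation).

## Quantal analysis

Release follows a binomial model with `N` sites: mean `P q N`,
variance `q^2 N P (1-P)`, variability `v = q (1 - P)`.  `N` is treated
as a positive real at the moment level (default 5.5, the literature
value for this connection type); the stochastic response sampler
rounds it to the nearest integer, since sampling needs integer trials.
The in vitro estimator inverts the moments at known N
(`q = var/mean + mean/N`, `P = mean/(Nq)`); the in vivo estimators use
`|mean|` and `v`, with `P0 = 0.5` assumed at baseline and `N` then
held fixed for after-pairing estimates.  All four maps are exact
algebraic inverses of the forward moments on their valid domains,
which the tests exercise as round-trip identities.

## Signal detection

Detection of a synaptic response against Gaussian background noise of
variance 0.5 (dimensionless q units) uses the Gaussian approximation
to the binomial: the first-response SNR is
`2 (PqN)^2 / (q^2 N P(1-P) + 2 sigma_n^2)` with N = 1 by default.
Because the response variance grows quadratically in `q` but *falls*
in `P` (at fixed mean), reliability requires presynaptic potentiation
— the core comparative claim.  Later responses substitute the
depressed release fraction `r_k p_k` for `P`; the summed-response SNR
assumes independent noise per pulse (the `2K sigma_n^2` term), exactly
as the closed form prescribes — no noise-correlation model is
introduced.  ROC curves are analytic erfc expressions evaluated on a
default grid of 512 thresholds spanning ±6 combined standard
deviations, and the AUC is the trapezoid integral, which matches the
closed-form two-Gaussian AUC to better than 1e-3 on that grid.

One measured caveat: at *matched rested weight*, a high-P/low-q state
does **not** dominate a low-P/high-q state in summed-response SNR for
every pulse count — deeper short-term depression can lose at K >= 2
at 30 Hz.  The dominance of the unified rule holds for the states the
two rules actually *learn* (the unified protocol outcome vs its
NO-blockade, postsynaptic-only counterpart, where the unified rule
attains both higher P and higher w); the tests implement that
comparison.

## Receptive-field network

One AdEx neuron (standard parameter set: C = 281 pF, g_L = 30 nS,
E_L = -70.6 mV, V_T = -50.4 mV, Delta_T = 2 mV, a = 4 nS,
b = 0.0805 nA, tau_w = 144 ms, reset -70.6 mV, cutoff 0 mV; forward
Euler at dt = 0.1 ms) receives 100 Poisson inputs whose rates follow
`rho(j) = 3 + 47 exp(-(j-p)^2/50)` Hz — spread sigma = 5 interpreted
in input-index units.  Plasticity is handled event-wise at spike times
with the exact exponential updates, so dt affects only the membrane
integration.  Each input spike injects a current `q_j p_j r_j` nA
through an exponential kernel (tau_syn = 2.5 ms).  Plasticity
amplitudes are scaled by 0.15 in this context; q is bounded to
[0, 20] nA and initialized at q_init = 2 nA.

**Drive calibration.**  q_init and tau_syn are free design constants
(only their product sets the mean drive).  They were chosen so the
postsynaptic rate sits near 20–25 Hz: in this regime the receptive
field converges within 100 s, q changes stay moderate, and alternating
stimulation is stable.  Both presynaptic depression of off-inputs and
growth of q scale as the square of the postsynaptic rate, so at twice
the drive the network ratchets to 70–125 Hz across stimulus switches
and q saturates its bound — outside the regime the model describes.

**Homeostasis.**  The subtractive normalization is scheduled: every
10 ms each synapse loses `alpha · (mean(q) - q_init)` with
alpha = 0.075, i.e. the *accumulated* mean q drift is bled off on a
~133 ms timescale, softly conserving total postsynaptic weight.  The
per-increment form (subtracting alpha times the mean of the latest dq
batch) removes only a fixed fraction of the LTP influx, stabilizes
nothing, and makes alpha a dimensionless fraction rather than a rate —
incompatible with comparing alpha against the (much slower) timescale
of experimental homeostatic scaling.  Under the drift form the decay
of any *inactive* synapse's q is driven by the LTP influx to the
active ones (mass conservation); this is exactly the slow decay of the
hidden memory trace, and it stops when homeostasis is disabled.  A
consequence worth noting: the savings ratio is insensitive to the
magnitude of alpha itself (alpha sets clamp tightness, the influx sets
the drain), which the tests assert in that form.

**Performance and learning time.**  Tuning performance for a stimulus
is the mean rested weight `P_j q_j` over that stimulus's on-region
(inputs within one spread of the peak), affinely rescaled to be 0 at
the block start and 1 at the value reached by converged
single-stimulus development (measured at the end of pre-training; the
two stimuli are translates, so the reference transfers), clamped to
[0, 1].  Learning time is the first trajectory sample (50 ms
resolution) at which performance crosses 0.99.  Alternatives were
implemented and measured before settling on this definition: Pearson
correlation of the full weight profile against the rate profile is
non-monotone (it decays as the developing profile grows sharper than
the Gaussian) and penalizes the retained q-bump of the inactive
stimulus — the very trace that carries the memory; probe-based
readouts (frozen-plasticity presentations of each stimulus) are
faithful to how tuning is assessed experimentally and are provided as
`probe_response`, but steady-state response rates are nearly
untuned (short-term depression almost exactly cancels the rate
advantage of the preferred stimulus) and transient-response probes
carry too much Poisson noise to resolve a 99% threshold.

**Savings experiment.**  Pre-train on stimulus A (center 30) for
100 s, then alternate B (center 70), A, B in 150-s blocks.  Block
length exceeds the spec of a single development run so that the
*initial* learning of B completes within its block.  The savings
ratio is (learning time of B, first exposure) / (learning time of B,
second exposure), averaged over 10 seeded runs.  Initial learning is
rate-limited by growth of q (tens of seconds); relearning only
requires P to recover onto the retained q-profile (seconds).
Measured: initial ≈ 115–125 s, relearning ≈ 5–6 s, ratio ≈ 20.

## Fitting

The objective is the mean squared error of model P- and q-ratios
against targets over the canonical ten protocols ({0.1, 10, 20, 40,
50} Hz × ±10 ms).  The optimizer is multi-start Nelder-Mead in
log-parameter space (20 seeded log-uniform starts within amplitude
bounds [1e-5, 0.1] and time-constant bounds [1, 1e4] ms; adaptive
simplex, objective tolerance 1e-8, followed by a polishing restart at
the best point).  On noiseless synthetic targets generated from the
shipped preset this recovers all six constants to machine precision.
Synthetic targets for recovery experiments multiply the model ratios
by lognormal noise of configurable standard deviation.

## What the synthetic conditions do and do not show

All network inputs are homogeneous Poisson processes with stationary
Gaussian rate profiles, synapses are current-based with a single
exponential kernel, and there is no inhibition, no conductance
saturation, no trial-to-trial variation in N, and no structural
plasticity.  Passing tests therefore demonstrate the internal
consistency of the rule and its functional consequences under these
idealized conditions — improved first-response discriminability and
savings through the pre/post decomposition — not quantitative
agreement with any particular recorded dataset.  The estimators
(quantal module) accept experimental response tables in the documented
CSV schema, but no experimental data ships with, or is required by,
the package.

## Numerical and degenerate-input conventions

Times are milliseconds inside the library and seconds at file
boundaries.  Traces and STP use exact exponential updates, so no
integration error accrues at the synapse level.  Trace readouts before
any spike of the relevant kind are exactly zero (last-spike times are
initialized to -inf).  Zero-mean observations make the in vitro
estimator undefined (rejected) and the in vivo baseline degenerate
(N = 0, returned for the caller to flag).  Zero noise variance in the
ROC degenerates to step functions, handled analytically.  The network
kernel aborts with a diagnostic on sustained firing above 500 Hz or
non-finite membrane state.  All stochastic entry points take explicit
integer seeds; derived seeds are produced with SeedSequence and stay
below 2^31.
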