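# unistdp

Simulation and analysis tools for spike-timing-dependent plasticity
(STDP) that is expressed **both pre- and postsynaptically**.  Synaptic
strength is the product of a presynaptic factor — the release
probability `P` — and a postsynaptic factor — the quantal amplitude
`q` — and long-term plasticity moves the two factors separately:

* postsynaptic LTP at each postsynaptic spike, `Δq = c₊ x₊ y₋`,
* presynaptic LTD and LTP at each presynaptic spike,
  `ΔP = −d₋ y₋ y₊ + d₊ y₊ x₊`,

where `x₊` (48.6 ms), `y₊` (417.8 ms) and `y₋` (12.5 ms) are
exponentially filtered traces of the pre- and postsynaptic spike
trains.  `P` also sets the baseline of Tsodyks–Markram short-term
dynamics (depression `D` = 200 ms, facilitation `F` = 50 ms), so
long-term changes in `P` visibly reshape paired-pulse behaviour.  The
shipped `young_rat_visual_cortex` preset reproduces the timing and
frequency dependence of plasticity in layer-5 pyramidal cell pairs,
including pharmacological blockade of the nitric-oxide and
endocannabinoid retrograde pathways.

The package is for computational neuroscientists who want to simulate
this unified rule (pairing protocols, feedforward receptive-field
development with an adaptive exponential integrate-and-fire neuron,
memory-savings experiments), estimate `(P, q, N)` from response
statistics with the binomial quantal model, and quantify synaptic
discriminability with SNR/ROC analysis.

## Worked example

Simulate the canonical pairing experiment — five pre/post spike pairs
at 50 Hz with the postsynaptic spike 10 ms after the presynaptic one,
repeated 15 times at 0.1 Hz — and inspect how the two factors change:

```python
from unistdp import ProtocolSpec, load_preset, run_pairing_protocol

params = load_preset("young_rat_visual_cortex")
out = run_pairing_protocol(ProtocolSpec(pairing_freq=50, delta_t=10), params)
print(f"P: x{out.P_ratio:.3f}  q: x{out.q_ratio:.3f}  w: x{out.w_ratio:.3f}")
```

prints

```
P: x1.332  q: x1.351  w: x1.800
```

— both factors potentiate, i.e. LTP at this synapse is expressed on
both sides (P +33%, q +35%, total weight +80%).  Reversing the timing
(`delta_t=-10`, 20 Hz) gives `P: x0.759  q: x1.009  w: x0.766`:
timing-dependent LTD here is presynaptic — `P` weakens while `q` even
gains slightly.  Simulated nitric-oxide blockade
(`ProtocolSpec(pairing_freq=50, delta_t=10, blockade="NO")`) yields
`P: x1.000  q: x1.351`: without the retrograde `y₊` signal only the
postsynaptic component of LTP remains.

The same rule, embedded in a 100-input feedforward network
(`unistdp.network`), develops receptive fields in which both `P` and
`q` follow the input profile, with `P` converging in ~1 s of
simulated time and `q` over tens of seconds — and that separation of
timescales is what produces memory savings when stimuli alternate.

A command-line interface mirrors the library:

```bash
unistdp protocol --freq 50 --delta-t 10 --out run/
unistdp detect --p 0.73 --q 1.16 --noise-var 0.5 --out roc/
unistdp savings --runs 10 --seed 1 --out savings/
```

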