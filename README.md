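# vplast — voltage-based synaptic plasticity

`vplast` simulates, fits and criticises a phenomenological voltage-based
rule of Hebbian synaptic plasticity.  It is aimed at computational
neuroscientists who want to predict long-term potentiation (LTP) and
depression (LTD) directly from the *dendritic voltage time course* near a
stimulated synapse — clamp experiments, spike-timing (STDP) pairings,
bursts, subthreshold protocols, dendritic spikes — without committing to a
biophysical neuron model.

## The rule

A presynaptic spike train X(t) leaves a glutamate trace x̄ at the synapse;
the local voltage u(t) (mV relative to rest) is low-pass filtered twice:

    τ_x dx̄/dt  = −x̄ + X(t)
    τ_± dū_±/dt = −ū_± + u(t)

    dw_LTP/dt = A_LTP · x̄ · [ū₊ − θ₊]₊
    dw_LTD/dt = A_LTD · x̄ · [ū₋ − θ₋(t)]₊ ,   θ₋(t) = θ₀ + θ(t)
    τ_θ dθ/dt = −θ + b_θ · dw_LTP/dt

with [y]₊ = max(y, 0) and dw/dt = dw_LTP/dt − dw_LTD/dt.  The last
equation is the **veto**: ongoing potentiation transiently raises the LTD
threshold, so concentrated LTP suppresses depression.  Nine parameters
(τ_x, τ₊, τ₋, θ₊, θ₀, A_LTP, A_LTD, b_θ, τ_θ) characterise a synapse type;
five reference sets ship in `vplast.PRESETS`.

The package provides, as both a Python library and a `vplast` CLI:

* explicit-Euler integration of the rule over voltage traces (dt = 0.1 ms),
* synthetic protocol generation (clamps, square pulses, pairings, bursts,
  dendritic-spike trial mixtures) and labelled synthetic datasets,
* closed-form and fine-grid oracles validating the integrator,
* bounded multi-start least-squares fitting of the nine parameters,
* leave-one-out cross-validation, ±5% sensitivity analysis, veto ablation,
  clamp-voltage regime scans and spike pair/triplet predictions.

## Worked example

Pairing 100 presynaptic stimulations at 2 Hz with a constant voltage clamp
(the `clamp-demo-linear` preset) exposes the rule's three regimes:

```python
import vplast as vp

params = vp.PRESETS["clamp-demo-linear"]   # θ₀ = 5 mV, θ₊ = 10 mV
for u0 in (4.0, 8.0, 30.0):
    trace, spikes = vp.make_clamp_protocol(u0, 100, 2.0)
    res = vp.integrate_protocol(trace, spikes, params)
    print(f"clamp {u0:4.1f} mV: w {res.w_initial} -> {res.w_final:.4f} "
          f"({100*(1+res.relative_change):.1f}% of initial)")
```

prints

```
clamp  4.0 mV: w 0.5 -> 0.5000 (100.0% of initial)
clamp  8.0 mV: w 0.5 -> 0.3514 (70.3% of initial)
clamp 30.0 mV: w 0.5 -> 0.6594 (131.9% of initial)
```

— no plasticity below θ₀, depression just above it, potentiation at high
depolarisation.  The same scan from the shell, with automatic detection of
the regime boundaries (depression onset at θ₀ = 5 mV; LTD→LTP crossover):

```sh
$ vplast scan-voltage --params clamp-demo-linear --out curve.csv
no_change_upper=5.0 ltd_ltp_crossing=22.192344614956305 curve=curve.csv
```

Other subcommands: `simulate` (one trace + spike train → weight change),
`synth` (synthetic manifest dataset), `fit`, `crossval`, `sensitivity`,
`triplets`.  Traces are plain delimited text (time, voltage); datasets are
YAML manifests pairing protocols with measured relative weight changes
(fractions or percent, declared per entry).

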