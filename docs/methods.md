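# Methods

## The plasticity rule

`vplast` implements a phenomenological, voltage-based rule for Hebbian
plasticity at a single glutamatergic synapse.  The synapse sees two signals:
the presynaptic spike train X(t) (a sum of Dirac pulses) and the local
dendritic voltage u(t), measured in mV relative to rest (rest ≡ 0).  The
state of the rule is

* a glutamate trace, τ_x dx̄/dt = −x̄ + X(t) — each spike increments x̄ by
  exactly +1 and the trace decays with τ_x; x̄ stands for transmitter bound
  to postsynaptic receptors,
* two low-pass-filtered voltages, τ_± dū_±/dt = −ū_± + u(t),
* a dynamic LTD-threshold component θ(t) (the "veto", below).

Weight changes accumulate separately for potentiation and depression,

    dw_LTP/dt = A_LTP · x̄ · [ū₊ − θ₊]₊
    dw_LTD/dt = A_LTD · x̄ · [ū₋ − (θ₀ + θ(t))]₊
    dw/dt     = dw_LTP/dt − dw_LTD/dt,          [y]₊ = max(y, 0)

and the veto couples LTP onto the LTD threshold,

    τ_θ dθ/dt = −θ + b_θ · dw_LTP/dt ,

so a strong potentiation signal transiently raises θ₋ = θ₀ + θ(t) and
suppresses depression.  The weight w is purely accumulative: it never feeds
back into the dynamics, hence w(T) − w(0) = w_LTP(T) − w_LTD(T) to machine
precision, and protocols can be composed additively
(`simulate_trial_mixture`).  No hard bounds are applied to w during
induction; an optional clip-at-zero switch exists on `integrate_protocol`
but is off by default.

### Parameters

| name | meaning | units | demo value |
|------|---------|-------|-----------|
| τ_x | glutamate-trace decay | ms | 5 |
| τ₊, τ₋ | LTP / LTD voltage filters | ms | 6, 15 |
| θ₊ | LTP threshold | mV | 10 |
| θ₀ | fixed part of LTD threshold | mV | 5 |
| A_LTP, A_LTD | plasticity amplitudes | mV⁻¹·ms⁻¹ | 10⁻⁴ |
| b_θ | veto strength | mV·ms | 3.1·10⁴ |
| τ_θ | veto decay | ms | 14 |

θ₊ > θ₀ is enforced as an invariant.  Five reference sets ship in
`vplast.PRESETS`: two clamp-demo sets that illustrate the three-regime
voltage dependence, and the best-fit sets for hippocampal CA3 recurrent
synapses, neocortical L2/3→L5 synapses and neocortical L5→L5 synapses.

## Numerical integration

Differential equations are integrated with explicit (forward) Euler at
dt = 0.1 ms.  Within one step the order is fixed: (1) x̄ decays by
(1 − dt/τ_x), then gains +1 per spike arriving in (t, t+dt] (a spike at the
very start of a trace joins the first step); (2) ū₊, ū₋ relax toward the
step's voltage sample (the right endpoint of the step); (3) the LTP and
LTD rates are evaluated with the just-updated traces, the LTD threshold
still using the veto state of the previous step; (4) w_LTP, w_LTD
accumulate; (5) θ decays and gains b_θ·r₊·dt/τ_θ — the explicit-Euler
discretisation of the veto equation.  All state variables start at 0 and
the weight at w_i = 0.5; filters are *not* reset between pairings within a
continuous trace, which is precisely what carries the frequency dependence
of pairing protocols (residual depolarisation between pairings).

Because nothing feeds back into the filters, the whole system is
feed-forward and is integrated with vectorised IIR filters
(`scipy.signal.lfilter`); a scalar per-step implementation with identical
arithmetic (`model.step`, `model.integrate_protocol_loop`) is kept and
cross-checked to ~1e-12.

### Accuracy

Against exact closed forms (first-order filters under piecewise-constant
drive; the single-spike LTP integral A_LTP·(u₀−θ₊)·τ_x under equilibrated
clamp) and against a fine-grid reference (dt = 10⁻³ ms, trace linearly
interpolated), the dt = 0.1 ms integrator is first-order accurate: errors
roughly halve when dt halves.  On well-conditioned piecewise-constant
protocols the net weight change agrees with the fine grid to < 0.5%.  Two
caveats, both measured and deliberate:

* when a protocol's outcome is a deep cancellation of comparable LTP and
  LTD totals, the *relative* error of the net change is inflated by the
  cancellation even though each accumulated component stays first-order
  accurate; the convergence experiment (`oracle.random_convergence_protocols`)
  therefore draws protocols whose outcome is dominated by one component or
  has a solid threshold margin;
* with the veto engaged the observed coarse-grid accuracy on kernel-built
  pairing protocols is ~1% (still first-order); the veto-coupled system has
  no closed form and is validated by grid refinement only.

Querying a filter exactly at a voltage discontinuity is ambiguous at finite
dt (the right-endpoint convention assigns the sample to the new segment);
comparisons against the analytic filter are made inside segments.

## Synthetic protocols

`synth` builds voltage traces from an additive, idealised kernel family:
double-exponential EPSPs (default 0.5 ms rise, 10 ms decay, 4 mV peak),
triangular bAPs (2 ms wide, 35 mV) with an exponential after-depolarisation
(amplitude fixed at 0.2 of the bAP peak; decay 20 ms), and a plateau with
raised-cosine edges (20 mV, 30 ms) standing in for supralinear dendritic
(NMDA/calcium) spikes.  Amplitudes are nominal dendritic values; real
recordings differ in shape, noise and nonlinearity, so tests built on these
kernels demonstrate properties of the *rule* for this surrogate family, not
quantitative agreement with any particular preparation.  Protocol classes:
constant clamp with repeated presynaptic stimulation, square voltage pulses
with one spike at a configurable offset, repeated pre/post pairings
(intervals signed: positive = pre leads; bursts; optional supralinear trial
fraction), and arbitrary spike sequences (used for pair/triplet
predictions).  Pairing traces are continuous by default (so depolarisation
accumulates across pairings); `per_trial=True` instead integrates one trial
and multiplies, valid at repetition rates slow enough for the membrane to
rest between trials.

`make_synthetic_dataset` labels each protocol with the model prediction
under known parameters plus N(0, σ²) noise — ground truth for the fitting
and validation studies.  σ = 0.05 (5% of the initial weight) is used for
the noisy studies, matching the scale of cell-to-cell scatter in plasticity
experiments; noise-free datasets (σ = 0) are used for recovery tests.

## Fitting

The objective is SE = Σ_pp (Δw_model − Δw_exp)² over protocols, with Δw as
fractions of the initial weight; the normalised error divides by the number
of protocols.  Minimisation is multi-start bounded least squares:

* box bounds per parameter (τ_x ∈ [2,30], τ₊ ∈ [2,60], θ₊ ∈ [8.5,30],
  θ₀ ∈ [2.5,15], A_LTP, A_LTD ∈ [10⁻⁵,10⁻²], τ₋ ∈ [2,60], b_θ ∈ [0,5·10⁵],
  τ_θ ∈ [1,100]);
* a seeded Latin-hypercube design of start points (25 by default);
* from each start, `scipy.optimize.least_squares` (trust-region reflective,
  2-point numerical Jacobian) in an internal unit-box parameterisation:
  log10 scale for A_LTP, A_LTD and τ_θ (bounds spanning decades), square-root
  scale for b_θ (lower bound 0), θ₀ expressed as a fraction of
  [lo, min(hi, θ₊ − 0.1 mV)] so θ₊ > θ₀ holds by construction;
* the best run is reported; runs that raise are recorded as failed.

An optional early stop ends the multi-start once the best SE falls below a
target (used in recovery studies where the global optimum is zero).
Parameters may be pinned (`fixed={"b_theta": 0}`) to ablate the veto; the
ablated optimum is re-used as an extra start of the free fit, so the nested
inequality error(with veto) ≤ error(without veto) holds by construction
(the local optimiser is monotone from its start).

## Validation studies and problem sizes

* **Leave-one-out cross-validation** fits on n−1 protocols and scores the
  squared prediction error on the held-out one; reported are per-fold
  results, medians (training error normalised by fold size; median chosen
  for both aggregates) and per-parameter coefficients of variation across
  folds (100·sd/mean, population sd).  The noisy LOO study runs an
  8-protocol battery with 5 starts and a capped evaluation budget per fit,
  repeated over ≥20 noise seeds — sizes chosen to keep hundreds of fits
  cheap while the qualitative statistics (test > train; veto parameters far
  less stable than τ_x, θ₊) are already unambiguous at this scale.
* **Sensitivity analysis** perturbs each parameter ±5%, one at a time, and
  reports ΔSE (18 entries); perturbations that would break θ₊ > θ₀ are
  clipped to the feasible margin and flagged.
* **Veto ablation** compares the free fit against b_θ = 0.  A dataset can
  only distinguish them if the veto's signature is not mimicable: matched
  clamp levels at different stimulation rates are the clean instrument,
  since without the veto the equilibrated-clamp outcome is rate-invariant
  (apart from filter ramp-in, which short protocols let the optimiser
  exploit — the ablation test uses protocols long relative to the filters).
* **Voltage–plasticity scans** run repeated presynaptic stimulation under
  clamp over a grid of levels (default 0.5 mV resolution) and report the
  percent-of-initial weight plus detected regime boundaries: the largest
  level with exactly zero change, and the LTD→LTP zero crossing by linear
  interpolation between grid levels.
* **Pair/triplet predictions** integrate pre-post, post-pre, pre-post-pre
  and post-pre-post sequences on surrogate kernel traces; outcomes are
  qualitative by construction (the numbers depend on the dendritic
  waveforms).

The recovery study uses a 15-protocol battery (`default_battery`) spanning
clamp levels at 2 and 40 Hz, square pulses around the pulse, ±10 ms
pairings at two rates, a burst pairing and a supralinear mixture, with
small repetition counts (5–10) so one SE evaluation stays ~10 ms.  On
noise-free data from in-bounds parameters, the multi-start fit reaches
SE < 10⁻⁶ and recovers the seven well-identified parameters to ≪10%;
b_θ and τ_θ are weakly identified in general (large CoV under LOO), though
this battery pins them too.

## Known limitations

* Surrogate kernels are idealised; no measured-trace reader ships beyond
  the delimited-text loader (`io.read_trace`, with baseline shift and
  linear-interpolation resampling to the model grid).
* The spike-reset alternative (x̄ ← 1 instead of x̄ += 1) is not
  implemented; both conventions coincide for all shipped protocols, whose
  inter-spike intervals are long against τ_x, but would differ for
  presynaptic bursts at ≳200 Hz.
* Multi-start local search carries no global-optimality guarantee; on
  ill-conditioned datasets different starts can win under different seeds.
* The weight is unbounded during induction; network-level use would need
  bounds or a stabilising extension, which is out of scope here.
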