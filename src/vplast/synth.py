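"""Synthetic dendritic voltage traces and protocol batteries.

The plasticity rule consumes the voltage time course at the synapse; for
testing and for synthetic fitting studies we emulate the waveforms that
dominate real dendritic recordings with an idealised additive kernel family:

* EPSP — double-exponential ``e^{-t/τ_decay} − e^{-t/τ_rise}``, peak-normalised;
* backpropagating action potential (bAP) — narrow triangular spike followed
  by an exponential after-depolarisation (ADP) whose amplitude is a fixed
  fraction (0.2) of the bAP peak; the ADP tail is what lets depolarisation
  accumulate across pairings at high repetition rates;
* dendritic (NMDA/calcium) spike — plateau with raised-cosine edges,
  standing in for the supralinear events of the hippocampal protocols;
* constant voltage clamp and square voltage pulses.

All traces are in mV relative to rest (rest = 0) on a uniform grid,
``dt = 0.1 ms`` by default, and all kernels superpose linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    DEFAULT_DT,
    DEFAULT_W_INIT,
    PlasticityParams,
    SpikeTrain,
    VoltageTrace,
    simulate_trial_mixture,
)

__all__ = [
    "KernelParams",
    "ProtocolSpec",
    "ProtocolRecord",
    "make_clamp_trace",
    "make_clamp_protocol",
    "make_square_pulse_protocol",
    "make_pairing_protocol",
    "make_spike_sequence_protocol",
    "realize_protocol",
    "predict_record",
    "make_synthetic_dataset",
    "default_battery",
]

#: fraction of the bAP peak carried over into the after-depolarisation
ADP_FRACTION = 0.2
#: raised-cosine edge width of the dendritic-spike plateau, ms
DSPIKE_EDGE = 1.0


@dataclass(frozen=True)
class KernelParams:
    """Shape parameters of the synthetic voltage kernels (mV, ms)."""

    epsp_amp: float = 4.0
    epsp_tau_rise: float = 0.5
    epsp_tau_decay: float = 10.0
    bap_amp: float = 35.0
    bap_width: float = 2.0
    adp_tau: float = 20.0
    dspike_amp: float = 20.0
    dspike_duration: float = 30.0

    def __post_init__(self) -> None:
        for name in ("epsp_amp", "bap_amp", "dspike_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("epsp_tau_rise", "epsp_tau_decay", "bap_width",
                     "adp_tau", "dspike_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.epsp_tau_rise < self.epsp_tau_decay:
            raise ValueError("epsp_tau_rise must be smaller than epsp_tau_decay")

    @property
    def max_tau(self) -> float:
        """Slowest relaxation scale of any kernel, ms."""
        return max(self.epsp_tau_decay, self.adp_tau, self.dspike_duration)


@dataclass(frozen=True)
class ProtocolSpec:
    """Declarative description of one plasticity-induction protocol.

    Exactly one protocol class applies: a constant clamp when ``clamp_mv``
    is set, a square voltage pulse when ``pulse`` is set, otherwise a
    pre/post pairing protocol.  ``interval_ms > 0`` means the presynaptic
    spike precedes the (first) postsynaptic event; negative intervals mean
    the postsynaptic event comes first.  ``post_pattern = (n, f)`` pairs the
    presynaptic stimulus with ``n`` action potentials at intra-burst
    frequency ``f`` Hz; ``n = 0`` pairs it with an EPSP-like depolarisation
    instead (subthreshold pairing).  ``composition`` splits the repetitions
    into trial kinds ``"linear"`` / ``"supralinear"``.
    """

    label: str = ""
    interval_ms: float = 10.0
    repetitions: int = 1
    frequency_hz: float = 1.0
    post_pattern: tuple[int, float] = (1, 200.0)
    composition: dict[str, float] = field(default_factory=lambda: {"linear": 1.0})
    clamp_mv: Optional[float] = None
    pulse: Optional[tuple[float, float, float]] = None  # (Δu mV, T ms, spike offset ms)
    per_trial: bool = False

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be > 0")
        total = sum(self.composition.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(f"composition fractions must sum to 1, got {total}")
        for kind in self.composition:
            if kind not in ("linear", "supralinear"):
                raise ValueError(f"unknown trial kind {kind!r}")


@dataclass(frozen=True)
class ProtocolRecord:
    """One protocol with its (synthetic or measured) plasticity outcome.

    ``components`` are ``(trace, spikes, repetitions)`` trial types;
    ``dw_exp`` is the relative weight change as a fraction (+0.22 means the
    synapse ends at 122% of its initial strength).
    """

    id: str
    components: tuple[tuple[VoltageTrace, SpikeTrain, int], ...]
    dw_exp: float
    spec: Optional[ProtocolSpec] = None


# ---------------------------------------------------------------------------
# kernel waveforms

def _epsp_kernel(k: KernelParams, dt: float) -> np.ndarray:
    if k.epsp_amp == 0:
        return np.zeros(1)
    span = 5.0 * k.epsp_tau_decay
    t = dt * np.arange(int(round(span / dt)) + 1)
    shape = np.exp(-t / k.epsp_tau_decay) - np.exp(-t / k.epsp_tau_rise)
    return k.epsp_amp * shape / shape.max()


def _bap_kernel(k: KernelParams, dt: float) -> np.ndarray:
    if k.bap_amp == 0:
        return np.zeros(1)
    adp0 = ADP_FRACTION * k.bap_amp
    span = k.bap_width + 5.0 * k.adp_tau
    t = dt * np.arange(int(round(span / dt)) + 1)
    half = k.bap_width / 2.0
    out = np.zeros_like(t)
    rise = t <= half
    out[rise] = k.bap_amp * t[rise] / half
    fall = (t > half) & (t <= k.bap_width)
    out[fall] = k.bap_amp + (adp0 - k.bap_amp) * (t[fall] - half) / half
    tail = t > k.bap_width
    out[tail] = adp0 * np.exp(-(t[tail] - k.bap_width) / k.adp_tau)
    return out


def _dspike_kernel(k: KernelParams, dt: float) -> np.ndarray:
    if k.dspike_amp == 0:
        return np.zeros(1)
    edge = min(DSPIKE_EDGE, k.dspike_duration / 2.0)
    t = dt * np.arange(int(round(k.dspike_duration / dt)) + 1)
    out = np.full_like(t, k.dspike_amp)
    rise = t < edge
    out[rise] = k.dspike_amp * 0.5 * (1.0 - np.cos(np.pi * t[rise] / edge))
    fall = t > k.dspike_duration - edge
    out[fall] = k.dspike_amp * 0.5 * (
        1.0 - np.cos(np.pi * (k.dspike_duration - t[fall]) / edge))
    return out


def _add_at(values: np.ndarray, kernel: np.ndarray, t_event: float, dt: float) -> None:
    i0 = int(round(t_event / dt))
    if i0 < 0 or i0 >= values.size:
        raise ValueError(f"event at t = {t_event:g} ms outside trace")
    n = min(kernel.size, values.size - i0)
    values[i0:i0 + n] += kernel[:n]


# ---------------------------------------------------------------------------
# protocol constructors

def make_clamp_trace(u0: float, duration: float, dt: float = DEFAULT_DT) -> VoltageTrace:
    """Constant voltage-clamp trace at ``u0`` mV relative to rest."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration / dt)) + 1
    return VoltageTrace(dt=dt, values=np.full(n, float(u0)))


def make_clamp_protocol(u0: float, n_pulses: int, frequency_hz: float,
                        dt: float = DEFAULT_DT, lead: float = 10.0,
                        tail: float = 100.0) -> tuple[VoltageTrace, SpikeTrain]:
    """Presynaptic stimulation at a fixed rate under constant postsynaptic clamp."""
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    period = 1000.0 / frequency_hz
    spikes = lead + period * np.arange(n_pulses)
    duration = spikes[-1] + tail
    return make_clamp_trace(u0, duration, dt), SpikeTrain(times=spikes)


def make_square_pulse_protocol(delta_u: float, T: float, spike_offset: float,
                               dt: float = DEFAULT_DT, lead: float = 50.0,
                               tail: float = 200.0) -> tuple[VoltageTrace, SpikeTrain]:
    """Square voltage pulse of height ``Δu`` and duration ``T`` paired with one
    presynaptic spike at ``spike_offset`` ms relative to pulse onset (negative
    = before the pulse, ``> T`` = after its end)."""
    if T <= 0:
        raise ValueError("pulse duration T must be > 0")
    spike_t = lead + spike_offset
    duration = lead + T + tail
    if not 0.0 <= spike_t <= duration:
        raise ValueError(
            f"spike offset {spike_offset:g} ms places the spike at t = {spike_t:g} ms, "
            f"outside the trace [0, {duration:g}] ms")
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    values = np.where((t >= lead) & (t < lead + T), float(delta_u), 0.0)
    return VoltageTrace(dt=dt, values=values), SpikeTrain(times=np.array([spike_t]))


def make_spike_sequence_protocol(pre_times: Sequence[float],
                                 post_times: Sequence[float],
                                 kernels: KernelParams,
                                 dt: float = DEFAULT_DT,
                                 supralinear_times: Sequence[float] = (),
                                 subthreshold_post: bool = False,
                                 lead: float = 20.0,
                                 ) -> tuple[VoltageTrace, SpikeTrain]:
    """Render an arbitrary pre/post spike sequence into a voltage trace.

    Presynaptic spikes contribute EPSP kernels; postsynaptic events
    contribute bAP kernels (or EPSP kernels when ``subthreshold_post``);
    ``supralinear_times`` add a dendritic-spike plateau.  Event times may be
    negative: everything is shifted so the earliest event sits at ``lead``.
    """
    pre = np.asarray(pre_times, dtype=float)
    post = np.asarray(post_times, dtype=float)
    supra = np.asarray(supralinear_times, dtype=float)
    all_t = np.concatenate([pre, post, supra])
    if all_t.size == 0:
        raise ValueError("protocol must contain at least one event")
    shift = lead - all_t.min()
    duration = all_t.max() + shift + 5.0 * kernels.max_tau
    n = int(round(duration / dt)) + 1
    values = np.zeros(n)
    epsp = _epsp_kernel(kernels, dt)
    post_kernel = epsp if subthreshold_post else _bap_kernel(kernels, dt)
    dsp = _dspike_kernel(kernels, dt)
    for t in pre:
        _add_at(values, epsp, t + shift, dt)
    for t in post:
        _add_at(values, post_kernel, t + shift, dt)
    for t in supra:
        _add_at(values, dsp, t + shift, dt)
    return VoltageTrace(dt=dt, values=values), SpikeTrain(times=np.sort(pre) + shift)


def _allocate(composition: dict[str, float], repetitions: int) -> dict[str, int]:
    """Largest-remainder split of repetitions across trial kinds."""
    kinds = sorted(composition)
    raw = {k: composition[k] * repetitions for k in kinds}
    counts = {k: int(math.floor(raw[k])) for k in kinds}
    leftover = repetitions - sum(counts.values())
    for k in sorted(kinds, key=lambda k: raw[k] - counts[k], reverse=True)[:leftover]:
        counts[k] += 1
    return {k: c for k, c in counts.items() if c > 0}


def make_pairing_protocol(spec: ProtocolSpec, kernels: KernelParams,
                          dt: float = DEFAULT_DT,
                          ) -> list[tuple[VoltageTrace, SpikeTrain, int]]:
    """Build the trial-type components of a repeated pairing protocol.

    Each trial kind in ``spec.composition`` yields one component.  By default
    the component is a single continuous trace holding that kind's share of
    the repetitions at ``spec.frequency_hz`` (so residual depolarisation can
    accumulate between pairings) with component repetitions 1; with
    ``spec.per_trial`` each component holds one pairing and the share is
    carried in the repetition count — appropriate for rates low enough for
    the membrane to repolarise between trials.
    """
    n_post, burst_hz = spec.post_pattern
    subthreshold = n_post == 0
    n_events = max(n_post, 1)
    post_rel = spec.interval_ms + (1000.0 / burst_hz) * np.arange(n_events)
    span = max(float(post_rel.max()), 0.0) - min(float(post_rel.min()), 0.0)
    period = 1000.0 / spec.frequency_hz
    counts = _allocate(spec.composition, spec.repetitions)
    components: list[tuple[VoltageTrace, SpikeTrain, int]] = []
    for kind, n_trials in sorted(counts.items()):
        if spec.per_trial:
            onsets = np.zeros(1)
            reps = n_trials
        else:
            if n_trials > 1 and period < span:
                raise ValueError(
                    f"inter-pairing period {period:g} ms is shorter than the "
                    f"pairing pattern span {span:g} ms")
            onsets = period * np.arange(n_trials)
            reps = 1
        pre = onsets
        post = (onsets[:, None] + post_rel[None, :]).ravel()
        supra = onsets + spec.interval_ms if kind == "supralinear" else ()
        trace, spikes = make_spike_sequence_protocol(
            pre, post, kernels, dt=dt, supralinear_times=supra,
            subthreshold_post=subthreshold)
        components.append((trace, spikes, reps))
    return components


def realize_protocol(spec: ProtocolSpec, kernels: KernelParams,
                     dt: float = DEFAULT_DT,
                     ) -> list[tuple[VoltageTrace, SpikeTrain, int]]:
    """Turn a :class:`ProtocolSpec` into simulatable components."""
    if spec.clamp_mv is not None:
        trace, spikes = make_clamp_protocol(
            spec.clamp_mv, spec.repetitions, spec.frequency_hz, dt=dt)
        return [(trace, spikes, 1)]
    if spec.pulse is not None:
        delta_u, T, offset = spec.pulse
        trace, spikes = make_square_pulse_protocol(delta_u, T, offset, dt=dt)
        return [(trace, spikes, spec.repetitions)]
    return make_pairing_protocol(spec, kernels, dt=dt)


def predict_record(record: ProtocolRecord, params: PlasticityParams,
                   w_init: float = DEFAULT_W_INIT) -> float:
    """Model-predicted relative weight change for one protocol record."""
    return simulate_trial_mixture(record.components, params, w_init=w_init).relative_change


def make_synthetic_dataset(true_params: PlasticityParams,
                           protocol_battery: Sequence[ProtocolSpec],
                           noise_sd: float, seed: int,
                           kernels: Optional[KernelParams] = None,
                           dt: float = DEFAULT_DT,
                           predictions: Optional[Sequence[float]] = None,
                           ) -> list[ProtocolRecord]:
    """Labelled dataset with ground-truth outcomes plus Gaussian noise.

    ``dw_exp`` for each protocol is the model prediction under
    ``true_params`` plus ``N(0, noise_sd²)`` noise; reproducible for a fixed
    ``seed``.  ``predictions`` may carry precomputed noise-free outcomes
    (e.g. when sweeping seeds for the same battery) — they are trusted as-is.
    """
    if not protocol_battery:
        raise ValueError("protocol battery must not be empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    kernels = kernels or KernelParams()
    rng = np.random.default_rng(seed)
    records: list[ProtocolRecord] = []
    for i, spec in enumerate(protocol_battery):
        components = tuple(realize_protocol(spec, kernels, dt=dt))
        if predictions is not None:
            pred = float(predictions[i])
        else:
            pred = simulate_trial_mixture(components, true_params).relative_change
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        label = spec.label or f"protocol-{i:02d}"
        records.append(ProtocolRecord(
            id=f"{i:02d}-{label}", components=components,
            dw_exp=pred + noise, spec=spec))
    return records


def compact_battery() -> list[ProtocolSpec]:
    """An 8-protocol battery with short traces, for cross-validation studies
    where hundreds of fits must stay cheap (clamp at three levels and two
    rates, two square pulses, pre/post pairings at ±10 ms)."""
    return [
        ProtocolSpec(label="clamp-4mV-5Hz", clamp_mv=4.0, repetitions=5, frequency_hz=5.0),
        ProtocolSpec(label="clamp-8mV-5Hz", clamp_mv=8.0, repetitions=5, frequency_hz=5.0),
        ProtocolSpec(label="clamp-25mV-5Hz", clamp_mv=25.0, repetitions=5, frequency_hz=5.0),
        ProtocolSpec(label="clamp-20mV-40Hz", clamp_mv=20.0, repetitions=8, frequency_hz=40.0),
        ProtocolSpec(label="pulse-25mV-T5-center", pulse=(25.0, 5.0, 2.5), repetitions=10),
        ProtocolSpec(label="pulse-30mV-T20-after", pulse=(30.0, 20.0, 30.0), repetitions=10),
        ProtocolSpec(label="stdp-plus10ms-5Hz", interval_ms=10.0, repetitions=3,
                     frequency_hz=5.0, post_pattern=(1, 200.0)),
        ProtocolSpec(label="stdp-minus10ms-5Hz", interval_ms=-10.0, repetitions=3,
                     frequency_hz=5.0, post_pattern=(1, 200.0)),
    ]


def default_battery() -> list[ProtocolSpec]:
    """A diverse 15-protocol battery for synthetic fitting studies.

    Spans the protocol classes the rule is sensitive to: constant clamp at
    several levels and two stimulation rates (thresholds, amplitudes, veto),
    square pulses around the pulse (LTD filter time constant), pre/post
    pairings at ±10 ms and two repetition rates (glutamate-trace and filter
    timing), a burst pairing and a supralinear trial mixture.  Repetition
    counts are kept small so the battery stays cheap to integrate.
    """
    return [
        ProtocolSpec(label="clamp-4mV-2Hz", clamp_mv=4.0, repetitions=10, frequency_hz=2.0),
        ProtocolSpec(label="clamp-8mV-2Hz", clamp_mv=8.0, repetitions=10, frequency_hz=2.0),
        ProtocolSpec(label="clamp-14mV-2Hz", clamp_mv=14.0, repetitions=10, frequency_hz=2.0),
        ProtocolSpec(label="clamp-25mV-2Hz", clamp_mv=25.0, repetitions=10, frequency_hz=2.0),
        ProtocolSpec(label="clamp-8mV-40Hz", clamp_mv=8.0, repetitions=10, frequency_hz=40.0),
        ProtocolSpec(label="clamp-20mV-40Hz", clamp_mv=20.0, repetitions=10, frequency_hz=40.0),
        ProtocolSpec(label="pulse-15mV-T5-center", pulse=(15.0, 5.0, 2.5), repetitions=10),
        ProtocolSpec(label="pulse-25mV-T5-center", pulse=(25.0, 5.0, 2.5), repetitions=10),
        ProtocolSpec(label="pulse-30mV-T20-after", pulse=(30.0, 20.0, 30.0), repetitions=10),
        ProtocolSpec(label="pulse-20mV-T15-before", pulse=(20.0, 15.0, -10.0), repetitions=10),
        ProtocolSpec(label="stdp-plus10ms-1Hz", interval_ms=10.0, repetitions=5,
                     frequency_hz=1.0, post_pattern=(1, 200.0)),
        ProtocolSpec(label="stdp-minus10ms-1Hz", interval_ms=-10.0, repetitions=5,
                     frequency_hz=1.0, post_pattern=(1, 200.0)),
        ProtocolSpec(label="stdp-plus10ms-20Hz", interval_ms=10.0, repetitions=5,
                     frequency_hz=20.0, post_pattern=(1, 200.0)),
        ProtocolSpec(label="burst-plus10ms-1Hz", interval_ms=10.0, repetitions=5,
                     frequency_hz=1.0, post_pattern=(3, 200.0)),
        ProtocolSpec(label="mixture-supralinear", interval_ms=10.0, repetitions=5,
                     frequency_hz=1.0, post_pattern=(0, 200.0),
                     composition={"linear": 0.4, "supralinear": 0.6}, per_trial=True),
    ]
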