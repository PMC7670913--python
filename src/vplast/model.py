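"""Core voltage-based plasticity rule.

The rule is phenomenological and Hebbian: each presynaptic spike leaves a
glutamate trace ``x̄`` at the synapse that decays with time constant ``τ_x``;
the local dendritic voltage ``u(t)`` (in mV relative to rest) is low-pass
filtered twice, with time constants ``τ_+`` and ``τ_-``.  Potentiation is
driven at rate ``A_LTP · x̄ · [ū₊ − θ₊]₊`` and depression at rate
``A_LTD · x̄ · [ū₋ − θ₋(t)]₊`` where ``[y]₊ = max(y, 0)``.  The depression
threshold ``θ₋(t) = θ₀ + θ(t)`` has a dynamic part that is charged by the
momentary LTP rate (``τ_θ dθ/dt = −θ + b_θ dw_LTP/dt``): ongoing potentiation
transiently raises the LTD threshold and thereby *vetoes* depression.

Integration is explicit (forward) Euler on a fixed grid, by default
``dt = 0.1 ms``.  Within one step the update order is fixed:

1. ``x̄`` decays by ``(1 − dt/τ_x)`` and gains +1 per spike in ``(t, t+dt]``;
2. ``ū₊`` and ``ū₋`` relax toward the step's voltage sample;
3. LTP/LTD rates are evaluated with the just-updated traces — the LTD
   threshold still uses the veto state from the *previous* step;
4. ``w_LTP`` and ``w_LTD`` accumulate, ``w = w_init + w_LTP − w_LTD``;
5. the veto variable ``θ`` decays with ``τ_θ`` and gains ``b_θ·r₊·dt/τ_θ``.

All of this is feed-forward (no state feeds back into the filters), so the
whole protocol can be integrated with vectorised IIR filters; a scalar
``step`` function implementing the identical arithmetic is kept for
inspection and cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "PlasticityParams",
    "VoltageTrace",
    "SpikeTrain",
    "ModelState",
    "SimulationResult",
    "Trajectory",
    "PRESETS",
    "PARAM_NAMES",
    "step",
    "integrate_protocol",
    "simulate_trial_mixture",
    "DEFAULT_DT",
    "DEFAULT_W_INIT",
]

DEFAULT_DT = 0.1  # ms, integration step of the reference fits
DEFAULT_W_INIT = 0.5  # dimensionless initial weight

#: canonical parameter ordering used by the fitting layer and serialisation
PARAM_NAMES = (
    "tau_x",
    "tau_plus",
    "theta_plus",
    "theta_0",
    "A_LTP",
    "A_LTD",
    "tau_minus",
    "b_theta",
    "tau_theta",
)


@dataclass(frozen=True)
class PlasticityParams:
    """The nine parameters of the plasticity rule.

    Attributes
    ----------
    tau_x : float
        Decay time constant of the presynaptic glutamate trace, ms.
    tau_plus, tau_minus : float
        Time constants of the LTP / LTD voltage filters, ms.
    theta_plus : float
        LTP voltage threshold, mV (relative to rest).
    theta_0 : float
        Fixed part of the LTD threshold, mV; must satisfy
        ``theta_plus > theta_0``.
    A_LTP, A_LTD : float
        Potentiation / depression amplitudes, mV⁻¹·ms⁻¹.
    b_theta : float
        Veto interaction strength, mV·ms (``0`` disables the veto).
    tau_theta : float
        Decay time constant of the veto variable, ms.
    """

    tau_x: float
    tau_plus: float
    tau_minus: float
    theta_plus: float
    theta_0: float
    A_LTP: float
    A_LTD: float
    b_theta: float
    tau_theta: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v!r}")
        for name in ("tau_x", "tau_plus", "tau_minus", "theta_plus",
                     "theta_0", "A_LTP", "A_LTD", "tau_theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0, got {getattr(self, name)!r}")
        if self.b_theta < 0:
            raise ValueError(f"b_theta must be >= 0, got {self.b_theta!r}")
        if not self.theta_plus > self.theta_0:
            raise ValueError(
                f"theta_plus must exceed theta_0 (got {self.theta_plus!r} <= {self.theta_0!r})"
            )

    def as_array(self) -> np.ndarray:
        """Parameters as a vector in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "PlasticityParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (9,):
            raise ValueError(f"expected 9 parameter values, got shape {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values)))

    def replace(self, **kwargs) -> "PlasticityParams":
        return replace(self, **kwargs)


#: Reference parameter sets.  The two ``clamp-demo`` sets illustrate the
#: three-regime voltage dependence under constant clamp (linear and
#: non-linear variants); the remaining three are the best-fit sets for the
#: hippocampal CA3 recurrent synapses (subthreshold + burst STDP protocols),
#: the L2/3→L5 neocortical synapses (distance-dependent burst STDP) and the
#: L5→L5 neocortical synapses (frequency-dependent STDP).
PRESETS: dict[str, PlasticityParams] = {
    "clamp-demo-linear": PlasticityParams(
        tau_x=5.0, tau_plus=6.0, tau_minus=15.0, theta_plus=10.0, theta_0=5.0,
        A_LTP=1e-4, A_LTD=1e-4, b_theta=31000.0, tau_theta=14.0),
    "clamp-demo-nonlinear": PlasticityParams(
        tau_x=5.0, tau_plus=7.0, tau_minus=15.0, theta_plus=13.0, theta_0=7.0,
        A_LTP=1e-4, A_LTD=1e-4, b_theta=45000.0, tau_theta=5.0),
    "ca3-hippocampus": PlasticityParams(
        tau_x=14.3, tau_plus=7.80, tau_minus=53.3, theta_plus=9.94, theta_0=4.04,
        A_LTP=225e-5, A_LTD=691e-5, b_theta=9.91e-1, tau_theta=1.99),
    "l23-l5-neocortex": PlasticityParams(
        tau_x=22.4, tau_plus=2.00, tau_minus=60.0, theta_plus=27.1, theta_0=6.20,
        A_LTP=4.27e-5, A_LTD=16.5e-5, b_theta=1.00e4, tau_theta=29.1),
    "l5-l5-neocortex": PlasticityParams(
        tau_x=5.08, tau_plus=17.8, tau_minus=24.9, theta_plus=11.8, theta_0=6.50,
        A_LTP=37.2e-5, A_LTD=31.2e-5, b_theta=24.7e4, tau_theta=2.49),
}


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled dendritic voltage, mV relative to rest (rest = 0)."""

    dt: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not (math.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be a positive finite number, got {self.dt!r}")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("voltage trace must be a non-empty 1-D array")
        bad = np.flatnonzero(~np.isfinite(self.values))
        if bad.size:
            raise ValueError(
                f"non-finite voltage sample at index {bad[0]} "
                f"(t = {self.t0 + bad[0] * self.dt:g} ms)"
            )

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Trace span in ms: ``dt × (n_samples − 1)``."""
        return self.dt * (self.n_samples - 1)

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing presynaptic spike times, ms."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        if t.ndim != 1:
            raise ValueError("spike times must be 1-D")
        if t.size and not np.isfinite(t).all():
            raise ValueError("spike times must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return self.times.size

    @classmethod
    def empty(cls) -> "SpikeTrain":
        return cls(times=np.empty(0))


@dataclass
class ModelState:
    """Dynamic variables of the rule at one instant.

    ``theta_var`` is the dynamic part of the LTD threshold,
    ``θ₋(t) = theta_0 + theta_var``.  ``w`` always equals
    ``w_init + w_ltp − w_ltd``.
    """

    x_bar: float = 0.0
    u_bar_plus: float = 0.0
    u_bar_minus: float = 0.0
    theta_var: float = 0.0
    w_ltp: float = 0.0
    w_ltd: float = 0.0
    w: float = DEFAULT_W_INIT


@dataclass(frozen=True)
class Trajectory:
    """Per-step record of the state variables (index 0 = initial state)."""

    times: np.ndarray
    u: np.ndarray
    x_bar: np.ndarray
    u_bar_plus: np.ndarray
    u_bar_minus: np.ndarray
    theta_var: np.ndarray
    w_ltp: np.ndarray
    w_ltd: np.ndarray
    w: np.ndarray


@dataclass(frozen=True)
class SimulationResult:
    """Outcome of integrating one protocol."""

    w_initial: float
    w_final: float
    relative_change: float
    w_ltp: float
    w_ltd: float
    trajectory: Optional[Trajectory] = None


def step(state: ModelState, u_t: float, n_spikes_in_step: int, dt: float,
         params: PlasticityParams) -> ModelState:
    """Apply one explicit-Euler step and return the new state.

    ``u_t`` is the voltage sample at the end of the step; spikes arriving in
    ``(t, t+dt]`` are counted in this step.  The update order is the one
    documented in the module docstring.
    """
    if not (dt > 0):
        raise ValueError(f"dt must be positive, got {dt!r}")
    if not math.isfinite(u_t):
        raise ValueError(f"non-finite voltage sample {u_t!r}")
    p = params
    x = state.x_bar * (1.0 - dt / p.tau_x) + n_spikes_in_step
    up = state.u_bar_plus + (dt / p.tau_plus) * (u_t - state.u_bar_plus)
    um = state.u_bar_minus + (dt / p.tau_minus) * (u_t - state.u_bar_minus)
    r_ltp = p.A_LTP * x * max(up - p.theta_plus, 0.0)
    r_ltd = p.A_LTD * x * max(um - (p.theta_0 + state.theta_var), 0.0)
    w_ltp = state.w_ltp + r_ltp * dt
    w_ltd = state.w_ltd + r_ltd * dt
    w = state.w + r_ltp * dt - r_ltd * dt
    theta = state.theta_var * (1.0 - dt / p.tau_theta) + p.b_theta * r_ltp * dt / p.tau_theta
    return ModelState(x_bar=x, u_bar_plus=up, u_bar_minus=um, theta_var=theta,
                      w_ltp=w_ltp, w_ltd=w_ltd, w=w)


def _spike_counts(trace: VoltageTrace, spikes: SpikeTrain) -> np.ndarray:
    """Spikes per step; step n covers (t_{n-1}, t_n], a spike at t0 joins step 1."""
    n_steps = trace.n_samples - 1
    counts = np.zeros(n_steps)
    if spikes.n_spikes == 0:
        return counts
    rel = (spikes.times - trace.t0) / trace.dt
    # snap spike times sitting on a grid point to it despite float fuzz
    idx = np.ceil(rel - 1e-9).astype(int)
    if np.any(rel < -1e-9) or np.any(idx > n_steps):
        off = spikes.times[(rel < -1e-9) | (idx > n_steps)][0]
        raise ValueError(
            f"spike at t = {off:g} ms lies outside the trace span "
            f"[{trace.t0:g}, {trace.t_end:g}] ms"
        )
    np.add.at(counts, np.maximum(idx, 1) - 1, 1.0)
    return counts


def _first_order_filter(drive: np.ndarray, gain: float, decay: float) -> np.ndarray:
    """y_n = decay·y_{n-1} + gain·drive_n with y_0 = 0 (state before drive[0])."""
    return lfilter([gain], [1.0, -decay], drive)


def integrate_protocol(trace: VoltageTrace, spikes: SpikeTrain,
                       params: PlasticityParams, w_init: float = DEFAULT_W_INIT,
                       record_trajectory: bool = False,
                       clip_at_zero: bool = False) -> SimulationResult:
    """Integrate the rule over a full protocol and return the weight change.

    All state variables start at 0 (rest); the weight starts at ``w_init``
    (0.5 by default) and is read out at the end of the trace.  The weight is
    purely accumulative — it does not feed back into the dynamics — so
    ``w_final − w_init = w_ltp − w_ltd`` holds to machine precision.

    With ``clip_at_zero`` the final weight is floored at 0 (off by default;
    the induction-protocol fits use unbounded weights).
    """
    if trace.n_samples < 2:
        raise ValueError("trace must contain at least two samples")
    dt = trace.dt
    p = params
    counts = _spike_counts(trace, spikes)
    u_in = trace.values[1:]

    x = _first_order_filter(counts, 1.0, 1.0 - dt / p.tau_x)
    up = _first_order_filter(u_in, dt / p.tau_plus, 1.0 - dt / p.tau_plus)
    um = _first_order_filter(u_in, dt / p.tau_minus, 1.0 - dt / p.tau_minus)

    r_ltp = p.A_LTP * x * np.maximum(up - p.theta_plus, 0.0)
    k_th = dt / p.tau_theta
    theta = _first_order_filter(r_ltp, p.b_theta * k_th, 1.0 - k_th)
    theta_prev = np.concatenate(([0.0], theta[:-1]))  # veto updates after plasticity
    r_ltd = p.A_LTD * x * np.maximum(um - (p.theta_0 + theta_prev), 0.0)

    w_ltp = float(r_ltp.sum() * dt)
    w_ltd = float(r_ltd.sum() * dt)
    w_final = w_init + w_ltp - w_ltd
    if clip_at_zero:
        w_final = max(w_final, 0.0)

    trajectory = None
    if record_trajectory:
        pad = lambda a: np.concatenate(([0.0], a))  # noqa: E731
        cum_p = pad(np.cumsum(r_ltp) * dt)
        cum_d = pad(np.cumsum(r_ltd) * dt)
        trajectory = Trajectory(
            times=trace.times(), u=trace.values.copy(),
            x_bar=pad(x), u_bar_plus=pad(up), u_bar_minus=pad(um),
            theta_var=pad(theta), w_ltp=cum_p, w_ltd=cum_d,
            w=w_init + cum_p - cum_d,
        )
    return SimulationResult(
        w_initial=w_init, w_final=w_final,
        relative_change=(w_final - w_init) / w_init,
        w_ltp=w_ltp, w_ltd=w_ltd, trajectory=trajectory,
    )


def integrate_protocol_loop(trace: VoltageTrace, spikes: SpikeTrain,
                            params: PlasticityParams,
                            w_init: float = DEFAULT_W_INIT) -> SimulationResult:
    """Reference integration using the scalar :func:`step` (slow; cross-checks
    the vectorised path)."""
    counts = _spike_counts(trace, spikes)
    state = ModelState(w=w_init)
    for n in range(1, trace.n_samples):
        state = step(state, float(trace.values[n]), int(counts[n - 1]),
                     trace.dt, params)
    return SimulationResult(
        w_initial=w_init, w_final=state.w,
        relative_change=(state.w - w_init) / w_init,
        w_ltp=state.w_ltp, w_ltd=state.w_ltd,
    )


def simulate_trial_mixture(components: Sequence[tuple[VoltageTrace, SpikeTrain, int]],
                           params: PlasticityParams,
                           w_init: float = DEFAULT_W_INIT) -> SimulationResult:
    """Weight change of a protocol whose repetitions split into trial types.

    Each component ``(trace, spikes, repetitions)`` is integrated
    independently from a fresh resting state and its weight change is counted
    ``repetitions`` times.  This models protocols repeated at rates low
    enough for the synapse to return to rest between trials — e.g. pairings
    at 0.1 Hz of which a stated fraction evoke a supralinear dendritic event.
    """
    if not components:
        raise ValueError("mixture must contain at least one component")
    dts = {c[0].dt for c in components}
    if len(dts) > 1:
        raise ValueError(f"components must share dt, got {sorted(dts)}")
    w_ltp = 0.0
    w_ltd = 0.0
    for trace, spikes, reps in components:
        if reps < 0 or int(reps) != reps:
            raise ValueError(f"repetitions must be a non-negative integer, got {reps!r}")
        if reps == 0:
            continue
        res = integrate_protocol(trace, spikes, params, w_init=w_init)
        w_ltp += reps * res.w_ltp
        w_ltd += reps * res.w_ltd
    w_final = w_init + w_ltp - w_ltd
    return SimulationResult(
        w_initial=w_init, w_final=w_final,
        relative_change=(w_final - w_init) / w_init,
        w_ltp=w_ltp, w_ltd=w_ltd,
    )
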