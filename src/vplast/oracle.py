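"""Independent reference solutions for validating the Euler integrator.

Two kinds of oracle are provided: exact closed forms for the pieces of the
rule that admit them (first-order low-pass filters driven by
piecewise-constant voltage; the time-integrated LTP of a single spike under
equilibrated clamp), and a brute-force fine-grid integration (default
``dt = 10⁻³ ms``, trace linearly interpolated) for everything else.  The
production integrator must agree with these before any fitted parameters
are trusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    PlasticityParams,
    SimulationResult,
    SpikeTrain,
    VoltageTrace,
    integrate_protocol,
)

__all__ = [
    "PiecewiseConstantInput",
    "analytic_filter",
    "analytic_single_spike_ltp",
    "fine_grid_reference",
    "random_convergence_protocols",
]


@dataclass(frozen=True)
class PiecewiseConstantInput:
    """Voltage held at ``levels[i]`` on ``[breakpoints[i], breakpoints[i+1])``."""

    breakpoints: np.ndarray  # len = n_segments + 1, strictly increasing, ms
    levels: np.ndarray       # len = n_segments, mV
    spike_times: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        lv = np.asarray(self.levels, dtype=float)
        st = np.asarray([] if self.spike_times is None else self.spike_times, dtype=float)
        if bp.size < 2 or not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly increasing with >= 2 entries")
        if lv.size != bp.size - 1:
            raise ValueError("need exactly one level per segment")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "spike_times", st)

    def to_trace(self, dt: float) -> tuple[VoltageTrace, SpikeTrain]:
        """Sample the input on a uniform grid starting at the first breakpoint."""
        t0, t1 = self.breakpoints[0], self.breakpoints[-1]
        n = int(round((t1 - t0) / dt)) + 1
        t = t0 + dt * np.arange(n)
        seg = np.clip(np.searchsorted(self.breakpoints, t, side="right") - 1,
                      0, self.levels.size - 1)
        return (VoltageTrace(dt=dt, values=self.levels[seg], t0=t0),
                SpikeTrain(times=self.spike_times))


def analytic_filter(inp: PiecewiseConstantInput, tau: float, t_query: float) -> float:
    """Exact response of ``τ dy/dt = −y + u`` to a piecewise-constant drive.

    The filter starts at 0 at the first breakpoint; within a segment of
    level ``L`` entered with value ``v`` at ``t_s`` the response is
    ``L + (v − L)·exp(−(t − t_s)/τ)``, composed segment by segment.
    """
    bp, lv = inp.breakpoints, inp.levels
    if not bp[0] <= t_query <= bp[-1]:
        raise ValueError(
            f"t_query = {t_query:g} ms outside input span [{bp[0]:g}, {bp[-1]:g}] ms")
    v = 0.0
    for i, level in enumerate(lv):
        t_end = min(bp[i + 1], t_query)
        v = level + (v - level) * np.exp(-(t_end - bp[i]) / tau)
        if t_query <= bp[i + 1]:
            break
    return float(v)


def analytic_single_spike_ltp(u0: float, params: PlasticityParams) -> float:
    """Exact total LTP from one spike under equilibrated supra-threshold clamp.

    With both filters pre-equilibrated at ``u0`` and the veto disabled, the
    LTP rate after a single spike at ``t = 0`` is
    ``A_LTP·(u0 − θ₊)₊·e^{−t/τ_x}``, whose time integral is
    ``A_LTP·(u0 − θ₊)₊·τ_x`` (the glutamate trace integrates to ``τ_x``
    per unit jump).
    """
    if params.b_theta != 0:
        raise ValueError("closed form requires the veto disabled (b_theta = 0)")
    return params.A_LTP * max(u0 - params.theta_plus, 0.0) * params.tau_x


def fine_grid_reference(trace: VoltageTrace, spikes: SpikeTrain,
                        params: PlasticityParams, dt_fine: float = 1e-3,
                        w_init: float = 0.5) -> SimulationResult:
    """Integrate the rule on a refined grid (trace linearly interpolated).

    Serves as a convergence reference for the production step
    (first-order accuracy: halving ``dt`` should roughly halve the error).
    """
    if not 0 < dt_fine < trace.dt:
        raise ValueError("dt_fine must be positive and smaller than the trace dt")
    n = int(round(trace.duration / dt_fine)) + 1
    t_fine = trace.t0 + dt_fine * np.arange(n)
    values = np.interp(t_fine, trace.times(), trace.values)
    fine = VoltageTrace(dt=dt_fine, values=values, t0=trace.t0)
    return integrate_protocol(fine, spikes, params, w_init=w_init)


def random_convergence_protocols(params: PlasticityParams, seed: int,
                                 n: int = 21, dt: float = 0.1,
                                 ) -> list[tuple[VoltageTrace, SpikeTrain]]:
    """Random piecewise-constant protocols for the convergence experiment.

    Draws ``n`` protocols, cycling through three stratified classes with
    well-conditioned outcomes (thresholds crossed with solid margins, so the
    net change is not a near-cancellation of potentiation and depression —
    near the LTD/LTP crossover the *relative* accuracy of the net change is
    limited by cancellation even though each accumulated component stays
    first-order accurate):

    1. depression-regime square waves — random multi-level voltage between
       ``θ₀ + 2`` and ``θ₊ − 0.5`` mV with random spikes placed after the
       initial filter ramp-in (≥ 50 ms);
    2. high constant clamp (24–29 mV) with repeated presynaptic stimulation
       at 2 or 40 Hz;
    3. square-pulse LTD — 20–35 mV pulse of 15–25 ms with the spike 10 ms
       after pulse end.

    All voltages are piecewise constant, the regime where the analytic
    filter composition is exact; spike and breakpoint times sit on the
    coarse grid so refined grids subdivide them exactly.
    """
    from .synth import make_clamp_protocol, make_square_pulse_protocol

    rng = np.random.default_rng(seed)
    out: list[tuple[VoltageTrace, SpikeTrain]] = []
    for i in range(n):
        cls = i % 3
        if cls == 0:
            nseg = int(rng.integers(3, 7))
            bp = np.round(np.concatenate([[0.0], np.cumsum(rng.uniform(30, 120, nseg))]), 1)
            levels = rng.uniform(params.theta_0 + 2.0, params.theta_plus - 0.5, nseg)
            nsp = int(rng.integers(4, 10))
            grid = np.arange(int(50 / dt), int(bp[-1] / dt) - 10, dtype=int)
            sp_t = np.sort(rng.choice(grid, nsp, replace=False)) * dt
            out.append(PiecewiseConstantInput(bp, levels, sp_t).to_trace(dt))
        elif cls == 1:
            out.append(make_clamp_protocol(
                float(rng.uniform(24, 29)), int(rng.integers(5, 12)),
                float(rng.choice([2.0, 40.0])), dt=dt))
        else:
            du = float(rng.uniform(20, 35))
            T = float(np.round(rng.uniform(15, 25), 1))
            out.append(make_square_pulse_protocol(du, T, T + 10.0, dt=dt))
    return out
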