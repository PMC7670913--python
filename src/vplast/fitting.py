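"""Least-squares fitting of the plasticity parameters.

The objective is the plain sum of squared residuals between predicted and
measured relative weight changes (both as fractions),

    SE = Σ_pp ( [w_f − w_i]/w_i |_pp − Δw_exp_pp )²,

minimised over the nine parameters inside fixed box bounds with the
constraint ``θ₊ > θ₀``.  The landscape has flat regions (rectifier
thresholds that no trace crosses) and local minima, so the search is
multi-start: a seeded Latin-hypercube design provides ``n_starts`` initial
points (25 by default) and a bounded trust-region least-squares run is
launched from each; the best run is reported.

Numerical choices: the optimiser works in an internal unit-box
parameterisation — amplitudes ``A_LTP``/``A_LTD`` and ``τ_θ`` on a log10
scale (their bounds span decades), ``b_θ`` on a square-root scale (its
lower bound is 0), time constants and ``θ₊`` linear, and ``θ₀`` as a
fraction of the feasible interval ``[lo, min(hi, θ₊ − 0.1 mV)]``, which
enforces ``θ₊ > θ₀`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import PARAM_NAMES, PlasticityParams
from .synth import ProtocolRecord, predict_record

__all__ = [
    "DEFAULT_BOUNDS",
    "FitConfig",
    "FitResult",
    "compute_se",
    "normalized_error",
    "generate_initial_points",
    "fit_parameters",
    "se_of_params",
]

#: search box for each parameter (units as in :class:`PlasticityParams`)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "tau_x": (2.0, 30.0),
    "tau_plus": (2.0, 60.0),
    "theta_plus": (8.5, 30.0),
    "theta_0": (2.5, 15.0),
    "A_LTP": (1e-5, 1e-2),
    "A_LTD": (1e-5, 1e-2),
    "tau_minus": (2.0, 60.0),
    "b_theta": (0.0, 5e5),
    "tau_theta": (1.0, 100.0),
}

#: strict-inequality margin enforced between θ₊ and θ₀, mV
THETA_MARGIN = 0.1

_LOG_PARAMS = ("A_LTP", "A_LTD", "tau_theta")


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the multi-start bounded least-squares search."""

    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_starts: int = 25
    seed: int = 0
    max_iterations: Optional[int] = None  # max residual evaluations per start
    tolerance: float = 1e-12              # ftol/xtol of each local run
    target_lse: Optional[float] = None    # stop the multi-start early below this
    extra_starts: tuple[PlasticityParams, ...] = ()
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = self.bounds[name]
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass(frozen=True)
class FitResult:
    params: PlasticityParams
    lse: float
    per_protocol: tuple[tuple[float, float], ...]  # (predicted, experimental)
    start_index: int
    all_runs: tuple[float, ...]  # final SE per start (NaN = failed run)

    @property
    def normalized_lse(self) -> float:
        return normalized_error(self.lse, len(self.per_protocol))


def compute_se(predicted: Sequence[float], experimental: Sequence[float]) -> float:
    """Sum of squared differences of relative weight changes (fractions)."""
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(experimental, dtype=float)
    if p.shape != e.shape or p.ndim != 1 or p.size == 0:
        raise ValueError(
            f"predicted and experimental must be equal-length non-empty vectors, "
            f"got shapes {p.shape} and {e.shape}")
    return float(np.sum((p - e) ** 2))


def normalized_error(se: float, n_protocols: int) -> float:
    """SE divided by the number of protocol outcomes."""
    if n_protocols < 1:
        raise ValueError("n_protocols must be >= 1")
    return se / n_protocols


def se_of_params(params: PlasticityParams, dataset: Sequence[ProtocolRecord]) -> float:
    """SE of a parameter set on a dataset (no fitting)."""
    preds = [predict_record(r, params) for r in dataset]
    return compute_se(preds, [r.dw_exp for r in dataset])


# ---------------------------------------------------------------------------
# internal unit-box parameterisation

def _theta0_cap(theta_plus: float, bounds: Mapping[str, tuple[float, float]]) -> float:
    lo, hi = bounds["theta_0"]
    return max(min(hi, theta_plus - THETA_MARGIN), lo + 1e-9)


def _from_internal(z: np.ndarray, bounds: Mapping[str, tuple[float, float]],
                   fixed: Mapping[str, float] = {}) -> PlasticityParams:
    """Map a unit-box vector to parameters; entries named in ``fixed`` ignore
    their ``z`` coordinate and take the given value verbatim."""
    values: dict[str, float] = {}
    zmap = dict(zip(PARAM_NAMES, z))
    for name in PARAM_NAMES:
        lo, hi = bounds[name]
        if name in fixed:
            values[name] = float(fixed[name])
        elif name == "theta_0":
            continue  # resolved below, needs theta_plus
        elif name in _LOG_PARAMS:
            values[name] = 10.0 ** (np.log10(lo) + zmap[name] * (np.log10(hi) - np.log10(lo)))
        elif name == "b_theta":
            values[name] = lo + (hi - lo) * zmap[name] ** 2
        else:
            values[name] = lo + (hi - lo) * zmap[name]
    if "theta_0" not in values:
        lo0 = bounds["theta_0"][0]
        cap = _theta0_cap(values["theta_plus"], bounds)
        values["theta_0"] = lo0 + zmap["theta_0"] * (cap - lo0)
    return PlasticityParams(**values)


def _to_internal(params: PlasticityParams, bounds: Mapping[str, tuple[float, float]]
                 ) -> np.ndarray:
    z = np.empty(len(PARAM_NAMES))
    for i, name in enumerate(PARAM_NAMES):
        lo, hi = bounds[name]
        v = float(np.clip(getattr(params, name), lo, hi))
        if name == "theta_0":
            lo0 = bounds["theta_0"][0]
            cap = _theta0_cap(float(np.clip(params.theta_plus, *bounds["theta_plus"])),
                              bounds)
            z[i] = (min(v, cap) - lo0) / (cap - lo0)
        elif name in _LOG_PARAMS:
            z[i] = (np.log10(v) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))
        elif name == "b_theta":
            z[i] = np.sqrt((v - lo) / (hi - lo))
        else:
            z[i] = (v - lo) / (hi - lo)
    return np.clip(z, 0.0, 1.0)


def generate_initial_points(bounds: Mapping[str, tuple[float, float]],
                            n: int, seed: int) -> list[PlasticityParams]:
    """Seeded Latin-hypercube design of start points, all strictly inside the
    bounds and feasible (``θ₊ > θ₀`` holds by construction)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=len(PARAM_NAMES), seed=seed)
    zs = np.clip(sampler.random(n), 1e-3, 1.0 - 1e-3)
    return [_from_internal(z, bounds) for z in zs]


def fit_parameters(dataset: Sequence[ProtocolRecord], config: FitConfig) -> FitResult:
    """Multi-start bounded least-squares fit; returns the best run.

    Parameters listed in ``config.fixed`` are pinned to the given value and
    excluded from the search (used e.g. to ablate the veto by fixing
    ``b_theta = 0``).  Deterministic for a fixed config; a start whose local
    run raises is recorded as failed (SE = NaN) rather than aborting.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset must not be empty")
    bounds = dict(config.bounds)
    dw_exp = np.array([r.dw_exp for r in dataset])
    free = [i for i, name in enumerate(PARAM_NAMES) if name not in config.fixed]
    if not free:
        raise ValueError("at least one parameter must remain free")

    def embed(z_free: np.ndarray) -> PlasticityParams:
        z = np.full(len(PARAM_NAMES), 0.5)
        z[free] = np.clip(z_free, 0.0, 1.0)
        return _from_internal(z, bounds, fixed=config.fixed)

    def residuals(z_free: np.ndarray) -> np.ndarray:
        params = embed(z_free)
        preds = np.array([predict_record(r, params) for r in dataset])
        return preds - dw_exp

    starts = list(generate_initial_points(bounds, config.n_starts, config.seed))
    starts += list(config.extra_starts)
    best: Optional[tuple[float, np.ndarray, int]] = None
    all_runs: list[float] = []
    for idx, start in enumerate(starts):
        z0 = _to_internal(start, bounds)[free]
        z0 = np.clip(z0, 1e-6, 1.0 - 1e-6)
        try:
            sol = least_squares(
                residuals, z0, bounds=(0.0, 1.0), method="trf",
                ftol=config.tolerance, xtol=config.tolerance, gtol=config.tolerance,
                max_nfev=config.max_iterations)
            se = float(np.sum(sol.fun ** 2))
            z_best = sol.x
        except Exception:
            all_runs.append(float("nan"))
            continue
        all_runs.append(se)
        if best is None or se < best[0]:
            best = (se, z_best, idx)
        if config.target_lse is not None and best[0] < config.target_lse:
            break
    if best is None:
        raise RuntimeError("every optimisation start failed")
    se, z_best, idx = best
    params = embed(z_best)
    preds = tuple((float(predict_record(r, params)), float(r.dw_exp)) for r in dataset)
    return FitResult(params=params, lse=se, per_protocol=preds,
                     start_index=idx, all_runs=tuple(all_runs))
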