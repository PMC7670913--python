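"""Model criticism: cross-validation, sensitivity, ablation and predictions.

These routines interrogate a fitted rule rather than extend it: leave-one-out
cross-validation quantifies predictive power and per-parameter
identifiability (coefficient of variation across folds); a ±5% one-at-a-time
sensitivity analysis probes the error landscape around a parameter set;
the veto ablation refits with ``b_θ = 0`` to measure what the LTP-on-LTD
veto buys; the voltage–plasticity scan maps the three clamp regimes
(no change / depression / potentiation); and the spike-triplet tables give
qualitative predictions for pair and triplet protocols on surrogate traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import (
    THETA_MARGIN,
    FitConfig,
    FitResult,
    fit_parameters,
    normalized_error,
    se_of_params,
)
from .model import DEFAULT_DT, PARAM_NAMES, PlasticityParams, integrate_protocol, \
    simulate_trial_mixture
from .synth import KernelParams, ProtocolRecord, make_clamp_protocol, \
    make_spike_sequence_protocol, predict_record

__all__ = [
    "FoldResult",
    "CrossValReport",
    "leave_one_out",
    "sensitivity_analysis",
    "VetoAblationResult",
    "veto_ablation",
    "RegimeBoundaries",
    "voltage_plasticity_curve",
    "triplet_prediction",
]


@dataclass(frozen=True)
class FoldResult:
    held_out_id: str
    train_norm: float      # training SE / (n − 1)
    test_se: float         # squared error on the held-out protocol
    params: Optional[PlasticityParams]
    error: Optional[str] = None


@dataclass(frozen=True)
class CrossValReport:
    per_fold: tuple[FoldResult, ...]
    median_train_norm: float
    median_test: float
    param_cov: dict[str, float]  # 100·sd/mean over fold-wise fitted values


def leave_one_out(dataset: Sequence[ProtocolRecord], config: FitConfig) -> CrossValReport:
    """Leave-one-out cross-validation: n fits of size n−1.

    Each fold fits on all records but one and scores the squared prediction
    error on the held-out record.  Aggregates are medians over folds (both
    the training error — normalised by fold size — and the test error);
    parameter spread is summarised as a coefficient of variation,
    100·(population sd)/mean over the fold-wise fitted values.  A fold whose
    fit fails is recorded with NaN errors rather than aborting the report.
    """
    dataset = list(dataset)
    if len(dataset) < 3:
        raise ValueError("leave-one-out needs at least 3 records")
    folds: list[FoldResult] = []
    for i, held in enumerate(dataset):
        train = dataset[:i] + dataset[i + 1:]
        try:
            fit = fit_parameters(train, config)
        except Exception as exc:  # fold failure is data, not a crash
            folds.append(FoldResult(held.id, float("nan"), float("nan"),
                                    None, error=str(exc)))
            continue
        pred = predict_record(held, fit.params)
        folds.append(FoldResult(
            held_out_id=held.id,
            train_norm=normalized_error(fit.lse, len(train)),
            test_se=(pred - held.dw_exp) ** 2,
            params=fit.params))
    ok = [f for f in folds if f.params is not None]
    cov: dict[str, float] = {}
    for name in PARAM_NAMES:
        vals = np.array([getattr(f.params, name) for f in ok])
        mean = vals.mean() if vals.size else np.nan
        cov[name] = float(100.0 * vals.std() / mean) if vals.size and mean != 0 \
            else float("nan")
    return CrossValReport(
        per_fold=tuple(folds),
        median_train_norm=float(np.median([f.train_norm for f in ok])) if ok else float("nan"),
        median_test=float(np.median([f.test_se for f in ok])) if ok else float("nan"),
        param_cov=cov)


def sensitivity_analysis(params: PlasticityParams,
                         dataset: Sequence[ProtocolRecord],
                         delta: float = 0.05) -> pd.DataFrame:
    """ΔSE from increasing / decreasing each parameter by ``delta`` (±5%).

    Returns a 9×2 table (rows = parameters, columns ``increase`` /
    ``decrease``) of SE(perturbed) − SE(params).  A perturbation that would
    break ``θ₊ > θ₀`` is clipped to the feasible margin; the affected cells
    are listed in ``df.attrs["clipped"]``.
    """
    base = se_of_params(params, dataset)
    out = pd.DataFrame(index=list(PARAM_NAMES),
                       columns=["increase", "decrease"], dtype=float)
    clipped: list[tuple[str, str]] = []
    for name in PARAM_NAMES:
        for direction, factor in (("increase", 1.0 + delta), ("decrease", 1.0 - delta)):
            value = getattr(params, name) * factor
            kwargs = {name: value}
            if name == "theta_0" and value >= params.theta_plus - THETA_MARGIN:
                kwargs[name] = params.theta_plus - THETA_MARGIN
                clipped.append((name, direction))
            if name == "theta_plus" and value <= params.theta_0 + THETA_MARGIN:
                kwargs[name] = params.theta_0 + THETA_MARGIN
                clipped.append((name, direction))
            perturbed = params.replace(**kwargs)
            out.loc[name, direction] = se_of_params(perturbed, dataset) - base
    out.attrs["clipped"] = clipped
    out.attrs["base_se"] = base
    return out


@dataclass(frozen=True)
class VetoAblationResult:
    error_with_veto: float
    error_without_veto: float
    ratio: float  # with / without
    fit_with: FitResult
    fit_without: FitResult


def veto_ablation(dataset: Sequence[ProtocolRecord], config: FitConfig
                  ) -> VetoAblationResult:
    """Best fit with the veto free versus pinned off (``b_θ = 0``).

    The veto-free model nests the ablated one, so the free fit reuses the
    ablated optimum (with ``b_θ = 0``) as an extra start; its error can
    therefore never exceed the ablated error.
    """
    fixed = dict(config.fixed)
    fixed["b_theta"] = 0.0
    fit_without = fit_parameters(dataset, FitConfig(
        bounds=config.bounds, n_starts=config.n_starts, seed=config.seed,
        max_iterations=config.max_iterations, tolerance=config.tolerance,
        target_lse=config.target_lse, extra_starts=config.extra_starts,
        fixed=fixed))
    fit_with = fit_parameters(dataset, FitConfig(
        bounds=config.bounds, n_starts=config.n_starts, seed=config.seed,
        max_iterations=config.max_iterations, tolerance=config.tolerance,
        target_lse=config.target_lse,
        extra_starts=tuple(config.extra_starts) + (fit_without.params,),
        fixed=config.fixed))
    e_with = min(fit_with.lse, fit_without.lse)  # guard against optimiser jitter
    return VetoAblationResult(
        error_with_veto=e_with, error_without_veto=fit_without.lse,
        ratio=e_with / fit_without.lse if fit_without.lse > 0 else 1.0,
        fit_with=fit_with, fit_without=fit_without)


@dataclass(frozen=True)
class RegimeBoundaries:
    """Detected boundaries of the clamp-voltage plasticity regimes, mV."""

    no_change_upper: Optional[float]    # largest clamp level with Δw = 0
    ltd_ltp_crossing: Optional[float]   # interpolated zero-crossing LTD → LTP


def voltage_plasticity_curve(params: PlasticityParams,
                             n_pulses: int = 100,
                             frequency_hz: float = 2.0,
                             clamp_levels: Optional[Sequence[float]] = None,
                             dt: float = DEFAULT_DT,
                             ) -> tuple[pd.DataFrame, RegimeBoundaries]:
    """Final weight (percent of initial) versus constant clamp voltage.

    Repeated presynaptic stimulation under clamp maps out the three regimes:
    no plasticity near rest, net depression above ``θ₀``, and net
    potentiation at high clamp once the veto and LTP terms dominate.
    ``clamp_levels`` defaults to a 0.5 mV grid from 0 to 30 mV.
    """
    if clamp_levels is None:
        clamp_levels = np.arange(0.0, 30.0 + 1e-9, 0.5)
    levels = np.asarray(clamp_levels, dtype=float)
    if np.any(np.diff(levels) <= 0):
        raise ValueError("clamp levels must be sorted increasing")
    dw = np.empty(levels.size)
    for i, u0 in enumerate(levels):
        trace, spikes = make_clamp_protocol(u0, n_pulses, frequency_hz, dt=dt)
        dw[i] = integrate_protocol(trace, spikes, params).relative_change
    df = pd.DataFrame({"u_mv": levels, "dw_percent": 100.0 * (1.0 + dw)})

    zero = np.abs(dw) <= 1e-14
    no_change = float(levels[zero].max()) if zero.any() else None
    crossing = None
    sign = np.sign(dw)
    for i in range(levels.size - 1):
        if sign[i] < 0 and sign[i + 1] > 0:
            # linear interpolation between grid levels
            crossing = float(levels[i] - dw[i] * (levels[i + 1] - levels[i])
                             / (dw[i + 1] - dw[i]))
            break
    return df, RegimeBoundaries(no_change_upper=no_change, ltd_ltp_crossing=crossing)


_TRIPLET_PROTOCOLS = ("pre-post", "post-pre", "pre-post-pre", "post-pre-post")


def triplet_prediction(params: PlasticityParams,
                       kernels: Optional[KernelParams] = None,
                       intervals: Sequence[float] = (5.0, 10.0),
                       repetitions: int = 60,
                       dt: float = DEFAULT_DT) -> pd.DataFrame:
    """Predicted weight (percent of initial) for spike pairs and triplets.

    Protocols: ``pre-post`` / ``post-pre`` pairs at interval Δt and
    ``pre-post-pre`` / ``post-pre-post`` triplets where the middle spike sits
    Δt after the first and Δt before the last.  Trials are assumed far
    enough apart for the synapse to rest between repetitions, so one
    sequence is integrated and its weight change counted ``repetitions``
    times.  Predictions on synthetic kernel traces are qualitative — real
    dendritic waveforms shape the exact numbers.
    """
    kernels = kernels or KernelParams()
    rows = {}
    for name in _TRIPLET_PROTOCOLS:
        row = {}
        for delta_t in intervals:
            if name == "pre-post":
                pre, post = [0.0], [delta_t]
            elif name == "post-pre":
                pre, post = [delta_t], [0.0]
            elif name == "pre-post-pre":
                pre, post = [0.0, 2 * delta_t], [delta_t]
            else:  # post-pre-post
                pre, post = [delta_t], [0.0, 2 * delta_t]
            trace, spikes = make_spike_sequence_protocol(pre, post, kernels, dt=dt)
            res = simulate_trial_mixture([(trace, spikes, repetitions)], params)
            row[delta_t] = 100.0 * (1.0 + res.relative_change)
        rows[name] = row
    df = pd.DataFrame(rows).T
    df.index.name = "protocol"
    df.columns.name = "interval_ms"
    return df
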