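"""File formats: delimited voltage traces, spike trains, dataset manifests.

Electrophysiology exports are heterogeneous, so traces travel as plain
delimited text (comma, tab or whitespace; ``#`` comments and a single header
line tolerated) with a time and a voltage column.  On load a trace is
baseline-shifted so rest = 0 (explicit rest value, or the mean over a
declared rest window) and resampled to the target grid by linear
interpolation.  A dataset manifest (YAML) pairs protocols — trace files,
presynaptic spike times, per-trial-type repetitions — with their measured
relative weight change, declared either as a fraction (+0.22) or a percent
change (+22).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .model import PARAM_NAMES, PRESETS, PlasticityParams, SpikeTrain, VoltageTrace
from .fitting import FitResult
from .synth import ProtocolRecord

__all__ = [
    "read_trace",
    "write_trace",
    "read_spikes",
    "write_spikes",
    "load_params",
    "save_params",
    "load_manifest",
    "save_dataset",
    "save_fit_result",
]

PathLike = Union[str, Path]


def _parse_columns(path: Path) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Read the first two numeric columns; returns (col0, col1, line numbers)."""
    t, v, lines = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.replace(",", " ").replace("\t", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {text!r}")
            try:
                a, b = float(parts[0]), float(parts[1])
            except ValueError:
                if not t:  # tolerate one header line
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric row {text!r}") from None
            t.append(a)
            v.append(b)
            lines.append(lineno)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two data rows")
    return np.array(t), np.array(v), lines


def read_trace(path: PathLike, dt_target: float = 0.1, *,
               time_unit: str = "ms", rest: Optional[float] = None,
               rest_window: Optional[tuple[float, float]] = None) -> VoltageTrace:
    """Load a (time, voltage) file as a rest-referenced uniform trace.

    ``time_unit`` is ``"ms"`` or ``"s"``; voltages are mV.  Baseline: if
    ``rest`` is given it is subtracted; else if ``rest_window`` (ms) is
    given, the mean voltage over that window is subtracted; else samples are
    assumed to be rest-referenced already.
    """
    path = Path(path)
    if time_unit not in ("ms", "s"):
        raise ValueError(f"time_unit must be 'ms' or 's', got {time_unit!r}")
    t, v, lines = _parse_columns(path)
    if time_unit == "s":
        t = t * 1000.0
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}:{lines[bad[0] + 1]}: time column not strictly increasing")
    if rest is not None:
        v = v - rest
    elif rest_window is not None:
        w0, w1 = rest_window
        mask = (t >= w0) & (t <= w1)
        if not mask.any():
            raise ValueError(f"rest window [{w0}, {w1}] ms contains no samples")
        v = v - v[mask].mean()
    n = int(np.floor((t[-1] - t[0]) / dt_target + 1e-9)) + 1
    grid = t[0] + dt_target * np.arange(n)
    return VoltageTrace(dt=dt_target, values=np.interp(grid, t, v), t0=float(t[0]))


def write_trace(path: PathLike, trace: VoltageTrace, delimiter: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(f"time_ms{delimiter}voltage_mv\n")
        for t, v in zip(trace.times(), trace.values):
            fh.write(f"{t:.17g}{delimiter}{v:.17g}\n")


def read_spikes(path: PathLike) -> SpikeTrain:
    """One spike time (ms) per line; ``#`` comments tolerated."""
    times = []
    with open(path) as fh:
        for raw in fh:
            text = raw.split("#", 1)[0].strip()
            if text:
                times.append(float(text))
    return SpikeTrain(times=np.array(times))


def write_spikes(path: PathLike, spikes: SpikeTrain) -> None:
    with open(path, "w") as fh:
        for t in spikes.times:
            fh.write(f"{t:.17g}\n")


def load_params(source: PathLike) -> PlasticityParams:
    """Load parameters from a preset name or a YAML/JSON mapping file."""
    if str(source) in PRESETS:
        return PRESETS[str(source)]
    with open(source) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{source}: expected a mapping of parameter names")
    unknown = set(data) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"{source}: unknown parameter(s) {sorted(unknown)}")
    return PlasticityParams(**{k: float(v) for k, v in data.items()})


def save_params(path: PathLike, params: PlasticityParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({n: float(getattr(params, n)) for n in PARAM_NAMES},
                       fh, sort_keys=False)


def load_manifest(path: PathLike, dt_target: float = 0.1) -> list[ProtocolRecord]:
    """Load a dataset manifest and all referenced traces/spike trains.

    Manifest schema (YAML)::

        entries:
          - id: "00-clamp-8mV"
            dw_exp: 22.0
            dw_unit: percent      # percent change; or fraction (default)
            components:
              - trace: traces/00.csv
                spikes: [10.0, 510.0]   # inline times or a file path
                repetitions: 1
                rest: 0.0             # optional baseline, passed to read_trace
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = (doc or {}).get("entries")
    if not entries:
        raise ValueError(f"{path}: manifest has no entries")
    root = path.parent
    records: list[ProtocolRecord] = []
    seen: set[str] = set()
    for entry in entries:
        pid = str(entry["id"])
        if pid in seen:
            raise ValueError(f"{path}: duplicate protocol id {pid!r}")
        seen.add(pid)
        unit = entry.get("dw_unit", "fraction")
        if unit not in ("fraction", "percent"):
            raise ValueError(f"{path}: entry {pid!r}: unknown dw_unit {unit!r}")
        dw = float(entry["dw_exp"]) / (100.0 if unit == "percent" else 1.0)
        components = []
        for comp in entry["components"]:
            reps = int(comp.get("repetitions", 1))
            if reps < 1:
                raise ValueError(f"{path}: entry {pid!r}: repetitions must be >= 1")
            trace_path = root / comp["trace"]
            if not trace_path.exists():
                raise FileNotFoundError(f"{path}: entry {pid!r}: missing trace file "
                                        f"{trace_path}")
            trace = read_trace(trace_path, dt_target=dt_target,
                               rest=comp.get("rest"))
            spikes_field = comp.get("spikes", [])
            if isinstance(spikes_field, (str, Path)):
                spike_path = root / spikes_field
                if not spike_path.exists():
                    raise FileNotFoundError(f"{path}: entry {pid!r}: missing spike "
                                            f"file {spike_path}")
                spikes = read_spikes(spike_path)
            else:
                spikes = SpikeTrain(times=np.array(spikes_field, dtype=float))
            components.append((trace, spikes, reps))
        records.append(ProtocolRecord(id=pid, components=tuple(components), dw_exp=dw))
    return records


def save_dataset(directory: PathLike, records: Sequence[ProtocolRecord]) -> Path:
    """Write records as trace files plus a manifest; returns the manifest path."""
    directory = Path(directory)
    (directory / "traces").mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in records:
        comps = []
        for j, (trace, spikes, reps) in enumerate(rec.components):
            rel = f"traces/{rec.id}-{j}.csv"
            write_trace(directory / rel, trace)
            comps.append({"trace": rel,
                          "spikes": [float(t) for t in spikes.times],
                          "repetitions": int(reps)})
        entries.append({"id": rec.id, "dw_exp": float(rec.dw_exp),
                        "dw_unit": "fraction", "components": comps})
    manifest = directory / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"entries": entries}, fh, sort_keys=False)
    return manifest


def save_fit_result(path: PathLike, fit: FitResult,
                    ids: Optional[Sequence[str]] = None) -> None:
    """Serialise a fit as a flat JSON report."""
    report = {f"param_{n}": float(getattr(fit.params, n)) for n in PARAM_NAMES}
    report["lse"] = float(fit.lse)
    report["normalized_lse"] = float(fit.normalized_lse)
    report["start_index"] = int(fit.start_index)
    report["per_protocol"] = [
        {"id": (ids[i] if ids is not None else str(i)),
         "predicted": pred, "experimental": exp}
        for i, (pred, exp) in enumerate(fit.per_protocol)]
    report["all_runs_se"] = [None if np.isnan(v) else float(v) for v in fit.all_runs]
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
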