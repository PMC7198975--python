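"""File round-tripping: trajectory CSV + JSON sidecar, result tables.

CSV dialect: comma-separated, '.' decimal, UTF-8, mandatory header; floats
are written with 17 significant digits so that reloading reproduces values
bit-for-bit.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .dde import Trajectory
from .model import STATE_NAMES
from .parameters import ParameterSet
from .scenarios import ScenarioSpec

__all__ = ["write_trajectory", "read_trajectory", "write_json"]


def _fmt(x: float) -> str:
    return format(x, ".17g")


def _scenario_dict(s: ScenarioSpec) -> dict:
    return {
        "genotype": s.genotype,
        "treatment": s.treatment,
        "bin_on_arf": s.bin_on_arf,
        "pils_feedback": s.pils_feedback,
        "reporters": [
            {"kind": getattr(r, "kind", r), "overrides": dict(getattr(r, "overrides", {}))}
            for r in s.reporters
        ],
        "overrides": dict(s.overrides),
    }


def _scenario_from_dict(d: dict) -> ScenarioSpec:
    from .reporters import ReporterSpec

    return ScenarioSpec(
        genotype=d["genotype"],
        treatment=d["treatment"],
        bin_on_arf=d["bin_on_arf"],
        pils_feedback=d["pils_feedback"],
        reporters=tuple(
            ReporterSpec(kind=r["kind"], overrides=r.get("overrides", {}))
            for r in d.get("reporters", [])
        ),
        overrides=d.get("overrides", {}),
    )


def write_trajectory(traj: Trajectory, csv_path: str | Path,
                     sidecar_path: str | Path | None = None) -> None:
    """Write the sampled trajectory as CSV plus a JSON provenance sidecar."""
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    header = ["time_h", *STATE_NAMES, *traj.reporter_names]
    cols = [traj.times, *(traj.states[:, j] for j in range(traj.states.shape[1]))]
    if traj.reporter_states is not None:
        cols += [traj.reporter_states[:, j] for j in range(traj.reporter_states.shape[1])]
    lines = [",".join(header)]
    for i in range(len(traj.times)):
        lines.append(",".join(_fmt(c[i]) for c in cols))
    csv_path.write_text("\n".join(lines) + "\n")

    sidecar = {
        "scenario": _scenario_dict(traj.scenario) if traj.scenario else None,
        "parameters": traj.params.to_dict() if traj.params else None,
        "bin2_ref": traj.params.bin2_ref if traj.params else None,
        "bin2_eps": traj.params.bin2_eps if traj.params else None,
        "history": [float(v) for v in traj.history] if traj.history is not None else None,
        "rtol": traj.rtol,
        "atol": traj.atol,
        "output_dt": float(traj.times[1] - traj.times[0]) if len(traj.times) > 1 else None,
        "t_end": float(traj.times[-1]),
        "reporter_names": list(traj.reporter_names),
        "solver_stats": traj.solver_stats,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2) + "\n")


def read_trajectory(csv_path: str | Path,
                    sidecar_path: str | Path | None = None) -> Trajectory:
    """Reload a trajectory written by :func:`write_trajectory`.

    Grid values are restored exactly; dense-output queries on a reloaded
    trajectory fall back to linear interpolation between grid points.
    """
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    lines = csv_path.read_text().strip().splitlines()
    header = lines[0].split(",")
    if header[0] != "time_h" or tuple(header[1:11]) != STATE_NAMES:
        raise ValueError(f"unexpected trajectory header in {csv_path}")
    data = np.array([[float(v) for v in line.split(",")] for line in lines[1:]])
    rep_names = tuple(header[11:])

    meta = {}
    if Path(sidecar_path).exists():
        meta = json.loads(Path(sidecar_path).read_text())
    params = None
    if meta.get("parameters"):
        params = ParameterSet.from_dict(meta["parameters"])
        if meta.get("bin2_ref") is not None:
            params = params.replace(bin2_ref=meta["bin2_ref"])
    scenario = _scenario_from_dict(meta["scenario"]) if meta.get("scenario") else None
    return Trajectory(
        times=data[:, 0],
        states=data[:, 1:11],
        reporter_states=data[:, 11:] if rep_names else None,
        reporter_names=rep_names,
        scenario=scenario,
        params=params,
        history=np.array(meta["history"]) if meta.get("history") else None,
        rtol=meta.get("rtol", 1e-8),
        atol=meta.get("atol", 1e-10),
        solver_stats=meta.get("solver_stats", {}),
        _dense=None,
    )


def write_json(obj, path: str | Path) -> None:
    """Write a dict (or dataclass with to_dict) as pretty JSON."""
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    elif dataclasses.is_dataclass(obj):
        obj = dataclasses.asdict(obj)
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
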