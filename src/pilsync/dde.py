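"""User-facing DDE integration: histories, trajectories, dense queries."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _solver
from .model import N_STATES, STATE_NAMES, model_rhs_jit, pack_pvec
from .parameters import ParameterSet
from .scenarios import ScenarioSpec, compile_scenario

__all__ = ["HistorySpec", "Trajectory", "IntegrationError", "integrate", "query"]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_OUTPUT_DT = 0.1


class IntegrationError(RuntimeError):
    """Integration failed; carries the failure time."""

    def __init__(self, message: str, time: float):
        super().__init__(f"{message} at t = {time:.6g} h")
        self.time = time


@dataclass(frozen=True)
class HistorySpec:
    """Constant history y(t) = values for all t <= 0."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("history values must be a 1-D vector")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("history values must be finite and non-negative")
        object.__setattr__(self, "values", v)

    @classmethod
    def zeros(cls) -> "HistorySpec":
        return cls(np.zeros(N_STATES))

    @classmethod
    def constant(cls, level: float) -> "HistorySpec":
        return cls(np.full(N_STATES, float(level)))


@dataclass
class Trajectory:
    """Solution sampled on a uniform output grid.

    ``states`` has one row per time and one column per core species (order
    :data:`pilsync.model.STATE_NAMES`); reporter channels, when present,
    follow in ``reporter_states`` with names in ``reporter_names``.
    """

    times: np.ndarray
    states: np.ndarray
    reporter_states: np.ndarray | None = None
    reporter_names: tuple = ()
    scenario: ScenarioSpec | None = None
    params: ParameterSet | None = None
    history: np.ndarray | None = None
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    solver_stats: dict = field(default_factory=dict)
    _dense: tuple | None = None

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def signal(self, name: str) -> np.ndarray:
        """Column by core-species or reporter name."""
        if name in STATE_NAMES:
            return self.states[:, STATE_NAMES.index(name)]
        if name in self.reporter_names:
            return self.reporter_states[:, self.reporter_names.index(name)]
        raise KeyError(f"unknown signal {name!r}")


def _mesh(tau: float, t_end: float) -> np.ndarray:
    k = int(np.floor(t_end / tau + 1e-12))
    pts = np.arange(0, k + 1, dtype=float) * tau
    if pts[-1] < t_end - 1e-12:
        pts = np.append(pts, t_end)
    else:
        pts[-1] = t_end
    return pts


def integrate(
    params: ParameterSet,
    scenario: ScenarioSpec | None = None,
    history: HistorySpec | None = None,
    t_end: float = 300.0,
    output_dt: float = DEFAULT_OUTPUT_DT,
    rel_tol: float = DEFAULT_RTOL,
    abs_tol: float = DEFAULT_ATOL,
    max_steps: int = 20_000_000,
    compiled: bool = False,
) -> Trajectory:
    """Integrate the model under a scenario and sample it uniformly.

    ``params`` is the base parameter set; the scenario is compiled against
    it unless ``compiled=True`` (then ``params`` is used as-is and the
    scenario only carries flags/reporters).  The history may have 10
    components (core; attached reporters start at 0) or 10 + n_reporters.
    Fixed inputs give bit-identical results.
    """
    if t_end <= 0 or output_dt <= 0 or rel_tol <= 0 or abs_tol <= 0:
        raise ValueError("t_end, output_dt and tolerances must be positive")
    if scenario is None:
        scenario = ScenarioSpec()
    p = params if compiled else compile_scenario(params, scenario)

    from .reporters import build_reporter_matrix

    rep, rep_names = build_reporter_matrix(p, scenario.reporters)
    n = N_STATES + rep.shape[0]

    if history is None:
        history = HistorySpec.zeros()
    hist = history.values
    if hist.shape[0] == N_STATES and n > N_STATES:
        hist = np.concatenate([hist, np.zeros(n - N_STATES)])
    if hist.shape[0] != n:
        raise ValueError(f"history must have {N_STATES} or {n} components")

    pvec = pack_pvec(p, bin_on_arf=scenario.bin_on_arf)
    mesh = _mesh(p.tau, float(t_end))
    status, fail_t, nacc, ts, hs, y0s, Qs, na, nr = _solver.solve_dde(
        model_rhs_jit, pvec, rep, hist, p.tau, mesh, rel_tol, abs_tol, max_steps
    )
    if status == _solver.STATUS_UNDERFLOW:
        raise IntegrationError("step-size underflow", fail_t)
    if status == _solver.STATUS_MAXSTEPS:
        raise IntegrationError("maximum step count exceeded", fail_t)
    if status == _solver.STATUS_NONFINITE:
        raise IntegrationError("non-finite state", fail_t)

    n_out = int(round(t_end / output_dt))
    tq = np.linspace(0.0, float(t_end), n_out + 1)
    Y = _solver.dense_sample(tq, hist, 0.0, nacc, ts, hs, y0s, Qs)

    return Trajectory(
        times=tq,
        states=Y[:, :N_STATES],
        reporter_states=Y[:, N_STATES:] if rep.shape[0] else None,
        reporter_names=rep_names,
        scenario=scenario,
        params=p,
        history=hist,
        rtol=rel_tol,
        atol=abs_tol,
        solver_stats={"n_accepted": int(na), "n_rejected": int(nr)},
        _dense=(hist, nacc, ts, hs, y0s, Qs),
    )


def query(trajectory: Trajectory, t: float) -> np.ndarray:
    """State (core + reporters) at any time within the trajectory span,
    interpolated consistently with the solver's dense output."""
    if t < 0 or t > trajectory.t_end:
        raise ValueError(f"query time {t} outside [0, {trajectory.t_end}]")
    if trajectory._dense is not None:
        hist, nacc, ts, hs, y0s, Qs = trajectory._dense
        return _solver.dense_sample(np.array([float(t)]), hist, 0.0, nacc, ts, hs, y0s, Qs)[0]
    # reloaded trajectories fall back to linear interpolation of the grid
    full = (
        trajectory.states
        if trajectory.reporter_states is None
        else np.hstack([trajectory.states, trajectory.reporter_states])
    )
    out = np.empty(full.shape[1])
    for j in range(full.shape[1]):
        out[j] = np.interp(t, trajectory.times, full[:, j])
    return out


def solve_test_dde(
    rhs_jit,
    history: Sequence[float],
    tau: float,
    t_end: float,
    output_dt: float = 0.01,
    rel_tol: float = DEFAULT_RTOL,
    abs_tol: float = DEFAULT_ATOL,
    pvec: np.ndarray | None = None,
):
    """Integrate an arbitrary jitted constant-lag DDE (testing hook).

    ``rhs_jit(t, y, ylag, pvec, rep)`` must be numba-compiled with the same
    signature as the model kernel.
    """
    hist = np.asarray(history, dtype=float)
    if pvec is None:
        pvec = np.zeros(1)
    rep = np.zeros((0, 7))
    mesh = _mesh(tau, t_end)
    status, fail_t, nacc, ts, hs, y0s, Qs, na, nr = _solver.solve_dde(
        rhs_jit, pvec, rep, hist, tau, mesh, rel_tol, abs_tol, 20_000_000
    )
    if status != _solver.STATUS_OK:
        raise IntegrationError("test DDE integration failed", fail_t)
    n_out = int(round(t_end / output_dt))
    tq = np.linspace(0.0, t_end, n_out + 1)
    Y = _solver.dense_sample(tq, hist, 0.0, nacc, ts, hs, y0s, Qs)
    return tq, Y
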