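"""The four experimental observables as passive auxiliary states.

Each reporter adds one extra state co-integrated with the core model but
never feeding back into it:

* ``pPILS_transcription`` - transcriptional PILS reporter: the PILS
  equation with BR-dependent protein degradation removed (delta_PBR = 0),
  so it tracks promoter activity only.
* ``PILS_protein_35S`` - PILS protein expressed from a constitutive
  promoter: strong basal production (alpha_bP = 100) with all regulated
  transcription removed (alpha_pAF = k_AF = k_BZ = 0) but BR-dependent
  degradation retained.
* ``DR5`` - synthetic auxin-response transcriptional reporter: the Aux/IAA
  equation with auxin-dependent degradation removed (delta_aux = 0) and
  basal turnover delta_bx = 0.075.
* ``DII`` - auxin-input degron reporter: the Aux/IAA equation with
  transcriptional activation removed (alpha = 0) and strong basal
  production alpha_bx = 75; its level falls as nuclear auxin rises.

Readout ratios between two scenarios are evaluated, by default, at the
fixed point of the lag-collapsed system ("steady_state" statistic), which
emulates quasi-steady reporter measurements after short treatments.  A
"window_mean" statistic (time average of the co-integrated reporter over a
late window) is available for studying the oscillatory regime.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .parameters import ParameterSet
from .scenarios import REPORTER_KINDS, ScenarioSpec, ScenarioError, compile_scenario
from .steady import steady_state

__all__ = [
    "ReporterSpec",
    "RatioReadout",
    "build_reporter_matrix",
    "attach_reporters",
    "reporter_steady_value",
    "predict_ratio",
    "DegenerateSignalError",
]

# template ids used by the jitted kernel
_TPL_PILS = 0.0   # params: a_bP, a_pAF, k_AF, k_BZ, d_PIL, d_PBR
_TPL_AUXIAA = 1.0  # params: a_bx, alpha, k_ARF, d_bx, d_aux


class DegenerateSignalError(ZeroDivisionError):
    """Denominator readout indistinguishable from zero."""


@dataclass(frozen=True)
class ReporterSpec:
    """A reporter kind plus optional overrides of its recipe constants.

    Override keys are the recipe-local names (``a_bP``, ``a_pAF``, ``k_AF``,
    ``k_BZ``, ``d_PIL``, ``d_PBR`` for the PILS-equation reporters;
    ``a_bx``, ``alpha``, ``k_ARF``, ``d_bx``, ``d_aux`` for the
    Aux/IAA-equation reporters).
    """

    kind: str
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in REPORTER_KINDS:
            raise ScenarioError(f"unknown reporter kind {self.kind!r}")
        valid = _RECIPE_FIELDS[_TEMPLATE_OF[self.kind]]
        for k in self.overrides:
            if k not in valid:
                raise ScenarioError(
                    f"unknown reporter override {k!r} for {self.kind}; valid: {valid}"
                )


_PILS_FIELDS = ("a_bP", "a_pAF", "k_AF", "k_BZ", "d_PIL", "d_PBR")
_AUXIAA_FIELDS = ("a_bx", "alpha", "k_ARF", "d_bx", "d_aux")
_RECIPE_FIELDS = {_TPL_PILS: _PILS_FIELDS, _TPL_AUXIAA: _AUXIAA_FIELDS}
_TEMPLATE_OF = {
    "pPILS_transcription": _TPL_PILS,
    "PILS_protein_35S": _TPL_PILS,
    "DR5": _TPL_AUXIAA,
    "DII": _TPL_AUXIAA,
}


def _recipe(kind: str, p: ParameterSet) -> dict[str, float]:
    if kind == "pPILS_transcription":
        return dict(a_bP=p.alpha_bP, a_pAF=p.alpha_pAF, k_AF=p.k_AF, k_BZ=p.k_BZ,
                    d_PIL=p.delta_PIL, d_PBR=0.0)
    if kind == "PILS_protein_35S":
        return dict(a_bP=100.0, a_pAF=0.0, k_AF=0.0, k_BZ=0.0,
                    d_PIL=p.delta_PIL, d_PBR=p.delta_PBR)
    if kind == "DR5":
        return dict(a_bx=p.alpha_bx, alpha=p.alpha, k_ARF=p.k_ARF,
                    d_bx=0.075, d_aux=0.0)
    if kind == "DII":
        return dict(a_bx=75.0, alpha=0.0, k_ARF=p.k_ARF,
                    d_bx=p.delta_bx, d_aux=p.delta_aux)
    raise ScenarioError(f"unknown reporter kind {kind!r}")


def _as_spec(rep) -> ReporterSpec:
    return rep if isinstance(rep, ReporterSpec) else ReporterSpec(kind=rep)


def build_reporter_matrix(
    params: ParameterSet, reporters: Sequence
) -> tuple[np.ndarray, tuple]:
    """Compile reporter specs into the (n_rep, 7) row matrix the kernel reads.

    Applying the recipe is idempotent: the rows depend only on the compiled
    parameter set and the spec, never on previous attachments.  Duplicate
    kinds are rejected.
    """
    specs = [_as_spec(r) for r in reporters]
    kinds = [s.kind for s in specs]
    if len(set(kinds)) != len(kinds):
        raise ScenarioError(f"duplicate reporter kinds in {kinds}")
    rep = np.zeros((len(specs), 7))
    for i, spec in enumerate(specs):
        tpl = _TEMPLATE_OF[spec.kind]
        vals = _recipe(spec.kind, params)
        vals.update(spec.overrides)
        rep[i, 0] = tpl
        for j, name in enumerate(_RECIPE_FIELDS[tpl]):
            rep[i, 1 + j] = vals[name]
    return rep, tuple(kinds)


def attach_reporters(scenario: ScenarioSpec, reporters: Sequence) -> ScenarioSpec:
    """Return the scenario with the given reporters attached (passively)."""
    specs = tuple(_as_spec(r) for r in reporters)
    kinds = [s.kind for s in specs]
    if len(set(kinds)) != len(kinds):
        raise ScenarioError(f"duplicate reporter kinds in {kinds}")
    import dataclasses

    return dataclasses.replace(scenario, reporters=specs)


def reporter_steady_value(spec: ReporterSpec | str, core_state: np.ndarray,
                          params: ParameterSet) -> float:
    """Quasi-steady reporter level given the core fixed point.

    Reporters are linear in their own state, so the fixed-point level is
    production / loss with the driving species held at the core fixed point.
    """
    spec = _as_spec(spec)
    vals = _recipe(spec.kind, params)
    vals.update(spec.overrides)
    BR, A = core_state[0], core_state[5]
    BZRD, ARFD = core_state[3], core_state[8]
    if _TEMPLATE_OF[spec.kind] == _TPL_PILS:
        prod = vals["a_bP"] + vals["a_pAF"] * vals["k_AF"] * ARFD / (
            1.0 + vals["k_AF"] * ARFD + vals["k_BZ"] * BZRD
        )
        loss = vals["d_PIL"] + vals["d_PBR"] * BR
    else:
        prod = vals["a_bx"] + vals["alpha"] * vals["k_ARF"] * ARFD / (
            1.0 + vals["k_ARF"] * ARFD
        )
        loss = vals["d_bx"] + vals["d_aux"] * A
    return prod / loss


@dataclass(frozen=True)
class RatioReadout:
    observable: str
    numerator_scenario: str
    denominator_scenario: str
    statistic: str
    window: tuple[float, float] | None
    value: float


DEFAULT_WINDOW = (250.0, 300.0)


def predict_ratio(
    observable: ReporterSpec | str,
    numerator: ScenarioSpec,
    denominator: ScenarioSpec,
    params: ParameterSet,
    statistic: str = "steady_state",
    window: tuple[float, float] = DEFAULT_WINDOW,
    **integrate_kwargs,
) -> RatioReadout:
    """Model-predicted reporter ratio between two scenarios.

    ``statistic='steady_state'`` (default) evaluates the reporter at each
    scenario's fixed point; ``statistic='window_mean'`` time-averages the
    co-integrated reporter over ``window`` of a transient simulation.
    Deterministic for fixed inputs.
    """
    spec = _as_spec(observable)
    if statistic == "steady_state":
        num = _steady_readout(spec, numerator, params)
        den = _steady_readout(spec, denominator, params)
    elif statistic == "window_mean":
        num = _window_readout(spec, numerator, params, window, **integrate_kwargs)
        den = _window_readout(spec, denominator, params, window, **integrate_kwargs)
    else:
        raise ValueError(f"unknown readout statistic {statistic!r}")
    if abs(den) < 1e-12:
        raise DegenerateSignalError(
            f"denominator readout of {spec.kind} is degenerate ({den:.3e})"
        )
    return RatioReadout(
        observable=spec.kind,
        numerator_scenario=numerator.scenario_id,
        denominator_scenario=denominator.scenario_id,
        statistic=statistic,
        window=window if statistic == "window_mean" else None,
        value=float(num / den),
    )


def _steady_readout(spec: ReporterSpec, scenario: ScenarioSpec, params: ParameterSet) -> float:
    compiled = compile_scenario(params, scenario)
    core = steady_state(compiled, bin_on_arf=scenario.bin_on_arf)
    return reporter_steady_value(spec, core, compiled)


def _window_readout(spec, scenario, params, window, **kwargs) -> float:
    from .dde import integrate

    w0, w1 = window
    if not 0 <= w0 < w1:
        raise ValueError(f"invalid readout window {window}")
    scen = attach_reporters(scenario, [spec])
    traj = integrate(params, scen, t_end=w1, **kwargs)
    mask = traj.times >= w0
    return float(traj.reporter_states[mask, 0].mean())
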