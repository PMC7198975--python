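"""Genotype / treatment / model-variant scenarios.

A :class:`ScenarioSpec` names the condition to simulate; compiling it
against a base :class:`ParameterSet` yields the parameter set actually
integrated.  Substitution order: genotype, treatment, variant flags,
explicit overrides last.  Compilation is a pure function and never mutates
its inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .parameters import ParameterError, ParameterSet, PARAMETER_NAMES

__all__ = ["ScenarioSpec", "compile_scenario", "GENOTYPES", "TREATMENTS", "ScenarioError"]


class ScenarioError(ValueError):
    """Unknown genotype, treatment, reporter or override name."""


#: genotype -> parameter substitutions (experimentally fitted mutant values;
#: pils_overexpression adds strong constitutive PILS production on top of
#: the regulated transcription)
GENOTYPES: dict[str, dict[str, float]] = {
    "wild_type": {},
    "bri1_6": {"delta_brb": 0.55},
    "bzr1_d": {"delta_bzb": 0.3},
    "pils_triple": {"alpha_pAF": 10.0},
    "pils_overexpression": {"alpha_bP": 100.0},
}

#: treatment -> substitutions; BL adds a constant external BR source
TREATMENTS: dict[str, dict[str, float]] = {
    "control": {},
    "BL": {"phi": 0.05},
}

REPORTER_KINDS = ("pPILS_transcription", "PILS_protein_35S", "DR5", "DII")


@dataclass(frozen=True)
class ScenarioSpec:
    genotype: str = "wild_type"
    treatment: str = "control"
    bin_on_arf: bool = False
    pils_feedback: bool = True
    reporters: tuple = ()
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ScenarioError(
                f"unknown genotype {self.genotype!r}; known: {sorted(GENOTYPES)}"
            )
        if self.treatment not in TREATMENTS:
            raise ScenarioError(
                f"unknown treatment {self.treatment!r}; known: {sorted(TREATMENTS)}"
            )
        for name in self.overrides:
            if name not in PARAMETER_NAMES and name not in ("bin2_ref", "bin2_eps"):
                raise ScenarioError(f"unknown override parameter {name!r}")
        for rep in self.reporters:
            kind = getattr(rep, "kind", rep)
            if kind not in REPORTER_KINDS:
                raise ScenarioError(f"unknown reporter kind {kind!r}")

    @property
    def scenario_id(self) -> str:
        """Compact identifier used in CSV outputs, e.g. ``pils_triple+BL``."""
        parts = [self.genotype]
        if self.treatment != "control":
            parts.append(self.treatment)
        if self.bin_on_arf:
            parts.append("bin_on_arf")
        if not self.pils_feedback:
            parts.append("no_pils_feedback")
        return "+".join(parts)

    @classmethod
    def from_id(cls, scenario_id: str, **kwargs) -> "ScenarioSpec":
        genotype = "wild_type"
        treatment = "control"
        bin_on_arf = False
        pils_feedback = True
        for part in scenario_id.split("+"):
            if part in GENOTYPES:
                genotype = part
            elif part in TREATMENTS:
                treatment = part
            elif part == "bin_on_arf":
                bin_on_arf = True
            elif part == "no_pils_feedback":
                pils_feedback = False
            else:
                raise ScenarioError(f"cannot parse scenario id component {part!r}")
        return cls(genotype=genotype, treatment=treatment, bin_on_arf=bin_on_arf,
                   pils_feedback=pils_feedback, **kwargs)


def compile_scenario(base: ParameterSet, scenario: ScenarioSpec) -> ParameterSet:
    """Apply the scenario's substitutions to ``base`` and return the result.

    Disabling the PILS feedback zeroes both arms of the BR -> PILS coupling
    (transcriptional repression ``k_BZ`` and BR-dependent degradation
    ``delta_PBR``).  For the BIN-on-ARF variant the reference BIN2 level is
    filled, when unset, with the compiled system's own fixed-point BIN2 so
    that ``theta_eff = theta`` at the operating point.
    """
    changes: dict[str, float] = {}
    changes.update(GENOTYPES[scenario.genotype])
    changes.update(TREATMENTS[scenario.treatment])
    if not scenario.pils_feedback:
        changes["k_BZ"] = 0.0
        changes["delta_PBR"] = 0.0
    try:
        compiled = base.replace(**changes) if changes else base
        compiled = compiled.replace(**dict(scenario.overrides)) if scenario.overrides else compiled
    except ParameterError as exc:
        raise ScenarioError(str(exc)) from exc
    if scenario.bin_on_arf and compiled.bin2_ref is None:
        from .steady import steady_state

        ref = float(steady_state(compiled, bin_on_arf=False)[1])
        compiled = compiled.replace(bin2_ref=ref)
    return compiled
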