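"""Kinetic parameter set of the brassinosteroid-auxin crosstalk model.

The model couples the brassinosteroid (BR) signaling branch
(BR -> BIN2 -> BZR -> BZR homodimer) to the auxin signaling branch
(auxin -> Aux/IAA -> ARF -> ARF homodimer) through PILS auxin-transport
facilitators.  PILS transcription is activated by ARF dimers, repressed
by BZR dimers, and PILS protein is degraded in a BR-dependent manner;
PILS in turn restricts nuclear auxin.  All concentrations are in uM and
all times in hours.

:class:`ParameterSet` is an immutable record of the 33 rate/affinity/delay
constants plus the external BR source ``phi`` used to emulate
24-epibrassinolide (BL) treatment.  The defaults are the experimentally
fitted wild-type reference values.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = ["ParameterSet", "PARAMETER_NAMES", "ParameterError"]


class ParameterError(ValueError):
    """Raised for unknown parameter names or invalid parameter values."""


@dataclass(frozen=True)
class ParameterSet:
    # --- brassinosteroid branch ---
    alpha_BR: float = 10.0      # BR production rate, uM/h
    k_BR: float = 5.0           # BZR-dimer repression constant of BR synthesis, 1/uM
    delta_BR: float = 0.3       # BR turnover, 1/h
    alpha_bin: float = 10.0     # BIN2 production, uM/h
    delta_bin: float = 0.01     # BIN2 basal degradation, 1/h
    delta_brb: float = 0.7      # BR-dependent BIN2 de-phosphorylation, 1/(uM h)
    alpha_BZR: float = 10.0     # BZR production, uM/h
    delta_bzr: float = 0.01     # BZR basal degradation, 1/h
    delta_bzb: float = 0.5      # BIN2-dependent BZR repression, 1/(uM h)
    # --- dimerization ---
    gamma_dB: float = 0.5       # BZR homodimer dissociation, 1/h
    gamma_dAB: float = 0.5      # BZR-ARF heterodimer dissociation, 1/h
    gamma_dAF: float = 0.5      # ARF homodimer dissociation, 1/h
    gamma_aB: float = 1.0       # BZR homodimer association, 1/(uM h)
    gamma_aAB: float = 1.0      # BZR-ARF heterodimer association, 1/(uM h)
    gamma_aAF: float = 1.0      # ARF homodimer association, 1/(uM h)
    # --- auxin branch ---
    alpha_A: float = 1.0        # auxin production, uM/h
    delta_A: float = 0.01       # auxin basal degradation, 1/h
    T: float = 10.0             # PILS transport coefficient, 1/(uM h)
    alpha_bx: float = 0.001     # Aux/IAA basal production, uM/h
    delta_bx: float = 0.01      # Aux/IAA basal degradation, 1/h
    delta_aux: float = 0.5      # auxin-dependent Aux/IAA degradation, 1/(uM h)
    k_ARF: float = 0.01         # ARF-dimer promoter association constant, 1/uM
    alpha: float = 1000.0       # ARF-dependent Aux/IAA transcription rate, uM/h
    alpha_ARF: float = 10.0     # ARF production, uM/h
    delta_ARF: float = 0.01     # ARF basal degradation, 1/h
    theta: float = 0.5          # Aux/IAA-dependent ARF sequestering, 1/(uM h)
    # --- PILS ---
    alpha_bP: float = 0.001     # PILS basal production, uM/h
    delta_PIL: float = 0.01     # PILS basal degradation, 1/h
    alpha_pAF: float = 1000.0   # ARF-dependent PILS transcription, uM/h
    delta_PBR: float = 0.75     # BR-dependent PILS degradation, 1/(uM h)
    k_AF: float = 0.01          # ARF-dimer / PILS-promoter association, 1/uM
    k_BZ: float = 10.0          # BZR-dimer-mediated PILS repression constant, 1/uM
    # --- delay and treatment ---
    tau: float = 10.0           # signaling delay of the dimer-mediated feedbacks, h
    phi: float = 0.0            # external BR source under BL treatment, uM/h
    # --- BIN-on-ARF variant plumbing (not part of the reference table) ---
    bin2_ref: float | None = field(default=None, compare=True)
    # reference BIN2 level for inverse theta scaling, uM; None = fill at
    # scenario compilation from the parameter set's own fixed point
    bin2_eps: float = 1e-6      # floor for BIN2 in the inverse scaling, uM

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            v = getattr(self, name)
            if not isinstance(v, (int, float)):
                raise ParameterError(f"parameter {name!r} must be a number, got {v!r}")
            if v < 0:
                raise ParameterError(f"parameter {name!r} must be >= 0, got {v}")
        if self.tau <= 0:
            raise ParameterError(f"delay tau must be > 0, got {self.tau}")
        if self.bin2_ref is not None and self.bin2_ref <= 0:
            raise ParameterError("bin2_ref must be positive")
        if self.bin2_eps <= 0:
            raise ParameterError("bin2_eps must be positive")

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the named parameters replaced.

        Unknown names are rejected rather than silently ignored.
        """
        for name in changes:
            if name not in _ALL_FIELD_NAMES:
                raise ParameterError(f"unknown parameter {name!r}")
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        """Flat name -> value mapping of the kinetic parameters."""
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ParameterSet":
        """Build from a flat mapping; missing keys take the reference defaults,
        unknown keys are rejected."""
        for name in data:
            if name not in _ALL_FIELD_NAMES:
                raise ParameterError(f"unknown parameter {name!r}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterSet":
        """Read a flat key -> number mapping from a JSON or YAML file."""
        text = Path(path).read_text()
        suffix = Path(path).suffix.lower()
        if suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ParameterError(f"parameter file {path} must contain a mapping")
        return cls.from_dict(data)


#: Names of the tabulated model parameters, in declaration order
#: (excludes the BIN-on-ARF plumbing fields).
PARAMETER_NAMES: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(ParameterSet) if f.name not in ("bin2_ref", "bin2_eps")
)

_ALL_FIELD_NAMES = {f.name for f in dataclasses.fields(ParameterSet)}
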