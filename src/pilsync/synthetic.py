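"""Synthetic observation sets with the statistical structure of the real data.

Real calibration data are treatment/genotype ratios of fluorescence
readouts, measured in triplicate.  The generator produces such tables from
model-predicted ratios with multiplicative log-normal noise (ratios of
positive fluorescence signals), replicate_i = ratio * exp(eps_i) with
eps_i ~ N(0, sigma^2).  An additive Gaussian mode exists for robustness
checks.  Everything is seeded and byte-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .fitting import Observation
from .parameters import ParameterSet
from .reporters import predict_ratio
from .scenarios import ScenarioSpec
from .steady import SteadyStateError

__all__ = ["GenerationSpec", "generate_observations", "default_panel",
           "observations_to_csv", "observations_from_csv"]


def default_panel() -> list[tuple[str, ScenarioSpec, ScenarioSpec]]:
    """The comparisons the calibration experiments cover: BL/control for all
    four observables in the three PILS-dosage genotypes, auxin-reporter
    comparisons between the PILS-dosage mutants and wild type, and
    mutant/wild-type PILS-transcription ratios for the BR-signaling mutants.

    Cross-genotype comparisons are oriented as fold-changes above one (the
    convention for reporting such measurements), which also keeps the
    plain-MSE fitting objective comparably weighted across observables.
    """
    panel = []
    wt = ScenarioSpec()
    for genotype in ("wild_type", "pils_triple", "pils_overexpression"):
        ctl = ScenarioSpec(genotype=genotype)
        bl = ScenarioSpec(genotype=genotype, treatment="BL")
        for obs in ("pPILS_transcription", "PILS_protein_35S", "DR5", "DII"):
            panel.append((obs, bl, ctl))
    pils = ScenarioSpec(genotype="pils_triple")
    oe = ScenarioSpec(genotype="pils_overexpression")
    panel.append(("DR5", pils, wt))   # loss of PILS raises auxin signaling
    panel.append(("DII", wt, pils))
    panel.append(("DII", oe, wt))     # extra PILS lowers nuclear auxin
    panel.append(("DR5", wt, oe))
    for genotype in ("bri1_6", "bzr1_d"):
        panel.append(("pPILS_transcription", ScenarioSpec(genotype=genotype), wt))
    return panel


@dataclass(frozen=True)
class GenerationSpec:
    true_parameters: ParameterSet
    panel: Sequence[tuple[str, ScenarioSpec, ScenarioSpec]] = field(
        default_factory=default_panel
    )
    noise_sd: float = 0.05
    n_replicates: int = 3
    seed: int | None = None
    noise_model: str = "lognormal"  # or "gaussian"
    statistic: str = "steady_state"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("a seed is required when noise_sd > 0")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def generate_observations(spec: GenerationSpec) -> list[Observation]:
    """Simulate the panel under the true parameters and add replicate noise."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for observable, num, den in spec.panel:
        try:
            ratio = predict_ratio(
                observable, num, den, spec.true_parameters, statistic=spec.statistic
            ).value
        except SteadyStateError as exc:
            raise RuntimeError(
                f"generation aborted: scenario {num.scenario_id} vs "
                f"{den.scenario_id} failed ({exc})"
            ) from exc
        eps = rng.normal(0.0, spec.noise_sd, spec.n_replicates)
        if spec.noise_model == "lognormal":
            reps = ratio * np.exp(eps)
        else:
            reps = ratio * (1.0 + eps)
        out.append(
            Observation(
                observable=observable,
                numerator=num,
                denominator=den,
                replicates=tuple(float(r) for r in reps),
            )
        )
    return out


_CSV_HEADER = "observable,numerator_scenario,denominator_scenario,replicate_index,value"


def observations_to_csv(observations: Sequence[Observation], path: str | Path) -> None:
    lines = [_CSV_HEADER]
    for obs in observations:
        for i, v in enumerate(obs.replicates):
            lines.append(
                f"{obs.observable},{obs.numerator.scenario_id},"
                f"{obs.denominator.scenario_id},{i},{format(v, '.17g')}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def observations_from_csv(path: str | Path) -> list[Observation]:
    lines = Path(path).read_text().strip().splitlines()
    if not lines or lines[0].strip() != _CSV_HEADER:
        raise ValueError(f"unexpected observations CSV header in {path}")
    groups: dict[tuple[str, str, str], list[tuple[int, float]]] = {}
    for line in lines[1:]:
        obs_name, num_id, den_id, idx, value = line.split(",")
        groups.setdefault((obs_name, num_id, den_id), []).append(
            (int(idx), float(value))
        )
    out = []
    for (obs_name, num_id, den_id), rows in groups.items():
        rows.sort()
        out.append(
            Observation(
                observable=obs_name,
                numerator=ScenarioSpec.from_id(num_id),
                denominator=ScenarioSpec.from_id(den_id),
                replicates=tuple(v for _, v in rows),
            )
        )
    return out
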