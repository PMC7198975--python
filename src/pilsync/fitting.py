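"""Parameter estimation against observed reporter ratios, and robustness.

The estimation procedure is the one used to calibrate the model: an
exhaustive grid search over the free parameters followed by Monte-Carlo
refinement, minimizing the mean squared error between model-predicted and
observed treatment/genotype ratios.  The robustness scan perturbs the key
kinetic rates uniformly within a fraction of their reference values and
checks how often the oscillation and the coupled-beats-uncoupled synchrony
ordering survive.

Free parameters may be *scoped* to a genotype, written ``genotype:name``
(e.g. ``bri1_6:delta_brb``): the value then replaces that genotype's
compiled parameter only, leaving the wild type at its reference value.
Unscoped names apply to the base parameter set shared by all scenarios.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np

from .parameters import ParameterError, ParameterSet
from .reporters import DegenerateSignalError, predict_ratio
from .scenarios import GENOTYPES, ScenarioSpec, ScenarioError
from .steady import SteadyStateError

logger = logging.getLogger(__name__)

__all__ = [
    "Observation",
    "FreeParameter",
    "FitResult",
    "SensitivityReport",
    "objective",
    "grid_search",
    "monte_carlo_refine",
    "sensitivity_scan",
    "FIT_PRESETS",
    "KEY_RATE_NAMES",
]


@dataclass(frozen=True)
class Observation:
    """Replicate ratio measurements of one observable between two scenarios."""

    observable: str
    numerator: ScenarioSpec
    denominator: ScenarioSpec
    replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise ValueError("an observation needs at least one replicate")

    @property
    def n(self) -> int:
        return len(self.replicates)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicates, ddof=1)) if self.n > 1 else 0.0


@dataclass(frozen=True)
class FreeParameter:
    name: str            # plain ParameterSet field or "genotype:field"
    bounds: tuple[float, float]
    points: int = 9      # grid nodes along this axis

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError(f"bounds for {self.name} must satisfy lo < hi")
        if self.points < 1:
            raise ValueError("grid needs at least one point")
        _split_scope(self.name)  # validates

    def grid(self) -> np.ndarray:
        lo, hi = self.bounds
        if self.points == 1:
            return np.array([0.5 * (lo + hi)])
        return np.linspace(lo, hi, self.points)


def _split_scope(name: str) -> tuple[str | None, str]:
    if ":" in name:
        scope, base = name.split(":", 1)
        if scope not in GENOTYPES:
            raise ScenarioError(f"unknown genotype scope {scope!r} in {name!r}")
        return scope, base
    return None, name


def _apply_free(
    base: ParameterSet, free_names: Sequence[str], free_values: Sequence[float]
) -> tuple[ParameterSet, dict[str, dict[str, float]]]:
    """Split free parameters into base replacements and per-genotype overrides."""
    base_changes: dict[str, float] = {}
    scoped: dict[str, dict[str, float]] = {}
    for name, value in zip(free_names, free_values):
        scope, pname = _split_scope(name)
        if scope is None:
            base_changes[pname] = float(value)
        else:
            scoped.setdefault(scope, {})[pname] = float(value)
    return base.replace(**base_changes), scoped


def _scenario_with(scen: ScenarioSpec, scoped: dict[str, dict[str, float]]) -> ScenarioSpec:
    extra = scoped.get(scen.genotype)
    if not extra:
        return scen
    merged = dict(scen.overrides)
    merged.update(extra)
    return dc_replace(scen, overrides=merged)


def objective(
    free_values: Sequence[float],
    free_names: Sequence[str],
    base: ParameterSet,
    observations: Sequence[Observation],
    statistic: str = "steady_state",
    _cache: dict | None = None,
) -> float:
    """Mean squared error between predicted and observed mean ratios.

    Always >= 0; exactly 0 iff every predicted ratio equals the observed
    mean.  Scenarios that fail to integrate or equilibrate yield an
    infinite-cost sentinel (with a logged warning) instead of an exception.
    """
    if len(free_values) != len(free_names):
        raise ValueError("free_values and free_names must have equal length")
    try:
        base_mod, scoped = _apply_free(base, free_names, free_values)
    except (ParameterError, ScenarioError):
        raise
    except ValueError as exc:  # negative value drawn against a bound, etc.
        logger.warning("invalid free values %s: %s", list(free_values), exc)
        return math.inf
    errs = []
    for obs in observations:
        try:
            pred = predict_ratio(
                obs.observable,
                _scenario_with(obs.numerator, scoped),
                _scenario_with(obs.denominator, scoped),
                base_mod,
                statistic=statistic,
            ).value
        except (SteadyStateError, DegenerateSignalError, ParameterError) as exc:
            logger.warning("prediction failed for %s: %s", obs.observable, exc)
            return math.inf
        errs.append((pred - obs.mean) ** 2)
    return float(np.mean(errs))


@dataclass
class FitResult:
    free_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    best_values: tuple[float, ...]
    best_mse: float
    trace: list = field(default_factory=list)  # (values tuple, mse) per evaluation
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "free_names": list(self.free_names),
            "bounds": [list(b) for b in self.bounds],
            "best_values": list(self.best_values),
            "best_mse": self.best_mse,
            "n_evaluations": len(self.trace),
            "seed": self.seed,
            "trace": [{"values": list(v), "mse": m} for v, m in self.trace],
        }


def grid_search(
    free: Sequence[FreeParameter],
    base: ParameterSet,
    observations: Sequence[Observation],
    statistic: str = "steady_state",
    max_grid: int = 100_000,
) -> FitResult:
    """Exhaustive search of the Cartesian grid.

    Nodes are visited in lexicographic order of the free-parameter axes;
    ties keep the first-encountered node.
    """
    if not free:
        raise ValueError("grid_search needs at least one free parameter")
    axes = [fp.grid() for fp in free]
    total = int(np.prod([len(a) for a in axes]))
    if total == 0:
        raise ValueError("empty grid")
    if total > max_grid:
        raise ValueError(f"grid of {total} nodes exceeds cap {max_grid}")
    names = tuple(fp.name for fp in free)
    trace = []
    best_values = None
    best_mse = math.inf
    for values in itertools.product(*axes):
        mse = objective(values, names, base, observations, statistic=statistic)
        trace.append((tuple(float(v) for v in values), mse))
        if mse < best_mse:
            best_mse = mse
            best_values = values
    return FitResult(
        free_names=names,
        bounds=tuple(fp.bounds for fp in free),
        best_values=tuple(float(v) for v in best_values),
        best_mse=best_mse,
        trace=trace,
    )


def monte_carlo_refine(
    start: FitResult,
    base: ParameterSet,
    observations: Sequence[Observation],
    n_samples: int = 200,
    proposal_width: float = 0.1,
    seed: int | None = None,
    statistic: str = "steady_state",
) -> FitResult:
    """Refine a fit by seeded uniform proposals around the incumbent.

    Each proposal perturbs every free parameter by U(-w, w) times its bound
    span, clipped to the bounds; the incumbent moves on improvement.  The
    same seed reproduces the trace exactly.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    if seed is None:
        raise ValueError("monte_carlo_refine requires an explicit seed")
    rng = np.random.default_rng(seed)
    names = start.free_names
    bounds = np.asarray(start.bounds, dtype=float)
    spans = bounds[:, 1] - bounds[:, 0]
    incumbent = np.asarray(start.best_values, dtype=float)
    best_mse = start.best_mse
    trace = list(start.trace)
    for _ in range(n_samples):
        step = rng.uniform(-proposal_width, proposal_width, len(names)) * spans
        cand = np.clip(incumbent + step, bounds[:, 0], bounds[:, 1])
        mse = objective(cand, names, base, observations, statistic=statistic)
        trace.append((tuple(float(v) for v in cand), mse))
        if mse < best_mse:
            best_mse = mse
            incumbent = cand
    return FitResult(
        free_names=names,
        bounds=start.bounds,
        best_values=tuple(float(v) for v in incumbent),
        best_mse=best_mse,
        trace=trace,
        seed=seed,
    )


#: kinetic rates perturbed by the robustness scan: every non-zero rate or
#: affinity constant of the reference table (delay and treatment excluded)
KEY_RATE_NAMES: tuple[str, ...] = (
    "alpha_BR", "k_BR", "delta_BR", "alpha_bin", "delta_bin", "delta_brb",
    "alpha_BZR", "delta_bzr", "delta_bzb", "gamma_dB", "gamma_dAB", "gamma_dAF",
    "gamma_aB", "gamma_aAB", "gamma_aAF", "alpha_A", "delta_A", "T",
    "alpha_bx", "delta_bx", "delta_aux", "k_ARF", "alpha",
    "alpha_ARF", "delta_ARF", "theta",
    "alpha_bP", "delta_PIL", "alpha_pAF", "delta_PBR", "k_AF", "k_BZ",
)


@dataclass
class SensitivityReport:
    fraction: float
    n_draws: int
    seed: int
    key_names: tuple[str, ...]
    reference_dispersion: float
    uncoupled_reference_dispersion: float
    draws: list = field(default_factory=list)  # per-draw dicts
    fraction_oscillating: float = 0.0
    fraction_ordering_preserved: float = 0.0

    def to_dict(self) -> dict:
        return {
            "fraction": self.fraction,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "key_names": list(self.key_names),
            "reference_dispersion": self.reference_dispersion,
            "uncoupled_reference_dispersion": self.uncoupled_reference_dispersion,
            "fraction_oscillating": self.fraction_oscillating,
            "fraction_ordering_preserved": self.fraction_ordering_preserved,
            "draws": self.draws,
        }


def sensitivity_scan(
    reference: ParameterSet,
    key_names: Sequence[str] = KEY_RATE_NAMES,
    fraction: float = 0.25,
    n_draws: int = 100,
    seed: int | None = None,
    scenario: ScenarioSpec | None = None,
    protocol=None,
) -> SensitivityReport:
    """Perturb the key rates uniformly within +/- ``fraction`` and rescore.

    Each seeded draw perturbs every listed parameter independently,
    re-simulates the coupled model under the onset protocol, and records
    whether the oscillation persists and whether its ARF/BZR dispersion
    stays below the unperturbed *uncoupled* model's reference dispersion
    (the coupled-beats-uncoupled ordering).  Individual failed draws are
    recorded, not fatal.
    """
    from .protocols import ONSET, score_dispersion

    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if seed is None:
        raise ValueError("sensitivity_scan requires an explicit seed")
    if scenario is None:
        scenario = ScenarioSpec()
    if protocol is None:
        protocol = ONSET
    uncoupled = dc_replace(scenario, pils_feedback=False)

    ref_disp = score_dispersion(reference, scenario, protocol)
    unc_disp = score_dispersion(reference, uncoupled, protocol)

    rng = np.random.default_rng(seed)
    draws = []
    n_osc = 0
    n_ord = 0
    for i in range(n_draws):
        factors = rng.uniform(1.0 - fraction, 1.0 + fraction, len(key_names))
        changes = {
            name: getattr(reference, name) * f for name, f in zip(key_names, factors)
        }
        entry: dict = {"draw": i, "factors": {n: float(f) for n, f in zip(key_names, factors)}}
        try:
            disp = score_dispersion(reference.replace(**changes), scenario, protocol)
        except Exception as exc:  # noqa: BLE001 - individual draws must not abort the scan
            logger.warning("draw %d failed: %s", i, exc)
            entry["status"] = "failed"
            entry["error"] = str(exc)
            draws.append(entry)
            continue
        oscillating = math.isfinite(disp)
        ordered = oscillating and math.isfinite(unc_disp) and disp < unc_disp
        n_osc += oscillating
        n_ord += ordered
        entry.update(
            status="ok",
            dispersion=disp if oscillating else None,
            oscillating=bool(oscillating),
            ordering_preserved=bool(ordered),
        )
        draws.append(entry)
    return SensitivityReport(
        fraction=fraction,
        n_draws=n_draws,
        seed=seed,
        key_names=tuple(key_names),
        reference_dispersion=ref_disp,
        uncoupled_reference_dispersion=unc_disp,
        draws=draws,
        fraction_oscillating=n_osc / n_draws,
        fraction_ordering_preserved=n_ord / n_draws,
    )


def _preset_panels() -> dict:
    wt = ScenarioSpec()
    oe = ScenarioSpec(genotype="pils_overexpression")
    pils = ScenarioSpec(genotype="pils_triple")
    return {
        # BR-dependent PILS degradation, constrained by how strongly PILS
        # abundance differs across PILS-dosage genotypes (auxin-signaling
        # readouts; comparisons oriented as fold-changes above one so the
        # plain-MSE objective weights both reporters comparably)
        "delta_PBR": {
            "free": [FreeParameter("delta_PBR", (0.15, 1.35), points=9)],
            "observations": [("DII", oe, wt), ("DR5", wt, oe)],
            "truth": 0.75,
        },
        # bri1-6: weakened BR-dependent BIN2 inactivation
        "bri1_6": {
            "free": [FreeParameter("bri1_6:delta_brb", (0.3, 0.7), points=9)],
            "observations": [("pPILS_transcription", ScenarioSpec(genotype="bri1_6"), wt)],
            "truth": 0.55,
        },
        # bzr1-d: weakened BIN2-dependent BZR repression
        "bzr1_d": {
            "free": [FreeParameter("bzr1_d:delta_bzb", (0.1, 0.5), points=9)],
            "observations": [("pPILS_transcription", ScenarioSpec(genotype="bzr1_d"), wt)],
            "truth": 0.3,
        },
        # pils loss of function: residual ARF-dependent PILS transcription
        "pils_triple": {
            "free": [FreeParameter("pils_triple:alpha_pAF", (5.0, 45.0), points=9)],
            "observations": [("DR5", pils, wt), ("DII", wt, pils)],
            "truth": 10.0,
        },
    }


#: shipped fitting presets reproducing the model's calibrated parameters
FIT_PRESETS = _preset_panels()
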