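import numpy as np
import pytest

import pilsync as ps
from pilsync import FreeParameter, Observation, ScenarioSpec
from pilsync.fitting import FIT_PRESETS, grid_search, monte_carlo_refine, objective
from pilsync.scenarios import ScenarioError


def _identity_obs(mean):
    """Observation whose model prediction is exactly 1 (same scenario on
    both sides), so the objective reduces to (1 - mean)^2."""
    return Observation("DR5", ScenarioSpec(), ScenarioSpec(), (mean,))


def test_objective_simple_arithmetic(ref_params):
    assert objective([], [], ref_params, [_identity_obs(1.5)]) == pytest.approx(0.25, abs=1e-9)
    two = [_identity_obs(1.1), _identity_obs(1.3)]
    assert objective([], [], ref_params, two) == pytest.approx(0.05, abs=1e-9)


def test_objective_zero_at_truth(ref_params):
    spec = ps.GenerationSpec(true_parameters=ref_params, noise_sd=0.0, seed=0)
    obs = ps.generate_observations(spec)
    assert objective([], [], ref_params, obs) < 1e-8


def test_objective_nonnegative(ref_params):
    cfg = FIT_PRESETS["delta_PBR"]
    obs = [Observation(o, n, d, (2.0,)) for o, n, d in cfg["observations"]]
    for v in (0.2, 0.75, 1.3):
        assert objective([v], ["delta_PBR"], ref_params, obs) >= 0.0


def test_scoped_free_parameter_targets_one_genotype(ref_params):
    obs = [Observation("pPILS_transcription", ScenarioSpec(genotype="bri1_6"),
                       ScenarioSpec(), (1.0,))]
    # setting the mutant's value back to the wild-type rate makes the
    # scenarios identical, so the predicted ratio is 1 and the MSE vanishes
    mse = objective([0.7], ["bri1_6:delta_brb"], ref_params, obs)
    assert mse == pytest.approx(0.0, abs=1e-10)
    # at the calibrated mutant value the ratio differs from 1
    assert objective([0.55], ["bri1_6:delta_brb"], ref_params, obs) > 1e-4


def test_unknown_scope_rejected():
    with pytest.raises(ScenarioError):
        FreeParameter("imp1:delta_brb", (0.0, 1.0))


@pytest.fixture(scope="module")
def noiseless_pbr_obs(ref_params):
    cfg = FIT_PRESETS["delta_PBR"]
    return [
        Observation(o, n, d,
                    (ps.predict_ratio(o, n, d, ref_params).value,))
        for o, n, d in cfg["observations"]
    ]


def test_grid_search_recovers_delta_pbr(ref_params, noiseless_pbr_obs):
    free = [FreeParameter("delta_PBR", (0.0, 1.125), points=4)]  # {0, .375, .75, 1.125}
    result = grid_search(free, ref_params, noiseless_pbr_obs)
    assert result.best_values[0] == pytest.approx(0.75)
    assert result.best_mse < 1e-10


def test_grid_matches_independent_oracle(ref_params, noiseless_pbr_obs):
    free = [FreeParameter("delta_PBR", (0.0, 1.125), points=4)]
    result = grid_search(free, ref_params, noiseless_pbr_obs)
    # recompute every node by hand via compile -> steady -> ratio
    for (values, mse) in result.trace:
        p = ref_params.replace(delta_PBR=values[0])
        errs = [
            (ps.predict_ratio(o.observable, o.numerator, o.denominator, p).value
             - o.mean) ** 2
            for o in noiseless_pbr_obs
        ]
        assert mse == pytest.approx(float(np.mean(errs)), rel=1e-12)
    assert result.best_mse == min(m for _, m in result.trace)


def test_single_point_grid(ref_params, noiseless_pbr_obs):
    free = [FreeParameter("delta_PBR", (0.2, 0.4), points=1)]
    result = grid_search(free, ref_params, noiseless_pbr_obs)
    assert result.best_values == (pytest.approx(0.3),)
    assert len(result.trace) == 1


def test_empty_grid_rejected(ref_params):
    with pytest.raises(ValueError):
        grid_search([], ref_params, [])


def test_mc_refine_zero_width_returns_start(ref_params, noiseless_pbr_obs):
    free = [FreeParameter("delta_PBR", (0.0, 1.125), points=4)]
    start = grid_search(free, ref_params, noiseless_pbr_obs)
    out = monte_carlo_refine(start, ref_params, noiseless_pbr_obs,
                             n_samples=5, proposal_width=0.0, seed=1)
    assert out.best_values == start.best_values


def test_mc_refine_is_seed_deterministic(ref_params, noiseless_pbr_obs):
    free = [FreeParameter("delta_PBR", (0.3, 1.125), points=3)]
    start = grid_search(free, ref_params, noiseless_pbr_obs)
    a = monte_carlo_refine(start, ref_params, noiseless_pbr_obs,
                           n_samples=10, seed=123)
    b = monte_carlo_refine(start, ref_params, noiseless_pbr_obs,
                           n_samples=10, seed=123)
    assert a.trace == b.trace and a.best_values == b.best_values


def test_mc_requires_seed(ref_params, noiseless_pbr_obs):
    free = [FreeParameter("delta_PBR", (0.3, 1.125), points=3)]
    start = grid_search(free, ref_params, noiseless_pbr_obs)
    with pytest.raises(ValueError):
        monte_carlo_refine(start, ref_params, noiseless_pbr_obs, n_samples=1, seed=None)


def test_sensitivity_zero_fraction_reproduces_reference(ref_params):
    report = ps.sensitivity_scan(ref_params, fraction=0.0, n_draws=2, seed=9)
    for draw in report.draws:
        assert draw["status"] == "ok"
        assert draw["dispersion"] == pytest.approx(report.reference_dispersion)
    assert report.fraction_oscillating == 1.0


def test_sensitivity_seed_determinism(ref_params):
    a = ps.sensitivity_scan(ref_params, fraction=0.25, n_draws=2, seed=5)
    b = ps.sensitivity_scan(ref_params, fraction=0.25, n_draws=2, seed=5)
    assert a.to_dict() == b.to_dict()


def test_sensitivity_requires_seed(ref_params):
    with pytest.raises(ValueError):
        ps.sensitivity_scan(ref_params, n_draws=1, seed=None)
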