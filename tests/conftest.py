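import numpy as np
import pytest

import pilsync as ps


@pytest.fixture(scope="session")
def ref_params():
    return ps.ParameterSet()


@pytest.fixture(scope="session")
def wt_trajectory(ref_params):
    """Wild type, zero history, 300 h — the standard simulation run."""
    return ps.integrate(ref_params, ps.ScenarioSpec(), t_end=300.0)


@pytest.fixture(scope="session")
def onset_trajectories(ref_params):
    """Coupled vs PILS-feedback-disabled runs under the onset protocol."""
    from pilsync.protocols import ONSET, run_scenario

    return {
        "coupled": run_scenario(ref_params, ps.ScenarioSpec(), ONSET),
        "uncoupled": run_scenario(
            ref_params, ps.ScenarioSpec(pils_feedback=False), ONSET
        ),
    }


def naive_rhs(state, lagged_bzrd, lagged_arfd, p, phi=None):
    """Independent term-by-term transcription of the model equations,
    deliberately written without reusing any package code."""
    BR, BIN2, BZR, BZRD, BZRARFD, A, AUXIAA, ARF, ARFD, PILS = state
    phi = p.phi if phi is None else phi
    d = np.zeros(10)
    d[0] = phi + p.alpha_BR / (1 + p.k_BR * lagged_bzrd) - p.delta_BR * BR
    d[1] = p.alpha_bin - BIN2 * (p.delta_bin + p.delta_brb * BR)
    d[2] = (p.alpha_BZR - BZR * (p.delta_bzr + p.delta_bzb * BIN2)
            + p.gamma_dB * BZRD - p.gamma_aB * BZR ** 2
            + p.gamma_dAB * BZRARFD - p.gamma_aAB * BZR * ARF)
    d[3] = p.gamma_aB * BZR ** 2 - p.gamma_dB * BZRD
    d[4] = p.gamma_aAB * BZR * ARF - p.gamma_dAB * BZRARFD
    d[5] = p.alpha_A - A * (p.delta_A + p.T * PILS)
    d[6] = (p.alpha_bx
            + p.alpha * p.k_ARF * lagged_arfd / (1 + p.k_ARF * lagged_arfd)
            - AUXIAA * (p.delta_bx + p.delta_aux * A))
    d[7] = (p.alpha_ARF - ARF * (p.delta_ARF + p.theta * AUXIAA)
            + p.gamma_dAF * ARFD - p.gamma_aAF * ARF ** 2
            + p.gamma_dAB * BZRARFD - p.gamma_aAB * BZR * ARF)
    d[8] = p.gamma_aAF * ARF ** 2 - p.gamma_dAF * ARFD
    d[9] = (p.alpha_bP
            + p.alpha_pAF * p.k_AF * lagged_arfd
            / (1 + p.k_AF * lagged_arfd + p.k_BZ * lagged_bzrd)
            - PILS * (p.delta_PIL + p.delta_PBR * BR))
    return d
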