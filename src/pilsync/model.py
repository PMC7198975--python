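"""Right-hand sides of the ten-species delay model.

State ordering (used by every serializer and trajectory column layout):

==  =============  =========================================================
 0  BR             brassinosteroid
 1  BIN2           BIN2 kinase (active, BZR-inhibiting form)
 2  BZR            BZR monomer
 3  BZR_dimer      BZR homodimer (BZR^D), the BR-signaling output
 4  BZRARF_dimer   BZR-ARF heterodimer integrating the two branches
 5  auxin          nuclear auxin (A)
 6  AUXIAA         Aux/IAA repressors
 7  ARF            ARF monomer
 8  ARF_dimer      ARF homodimer (ARF^D), the auxin-signaling output
 9  PILS           PILS auxin-transport facilitator
==  =============  =========================================================

Three feedbacks act with a shared delay ``tau``: BZR^D(t - tau) represses
BR synthesis and PILS transcription, and ARF^D(t - tau) drives Aux/IAA and
PILS transcription.  The derivative of ARF uses basal production minus
first-order losses (``alpha_ARF - ARF*(delta_ARF + theta*AUXIAA)``),
mirroring the structure of the BZR equation.

The optional *BIN-on-ARF* variant lets BIN2 promote ARF activity by
reducing Aux/IAA-dependent sequestering: ``theta_eff = theta * bin2_ref /
max(BIN2, bin2_eps)``, so that ``theta_eff = theta`` when BIN2 sits at its
reference operating level.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .parameters import ParameterSet

__all__ = [
    "STATE_NAMES",
    "N_STATES",
    "DelayedView",
    "rhs",
    "pack_pvec",
    "model_rhs_jit",
]

STATE_NAMES: tuple[str, ...] = (
    "BR",
    "BIN2",
    "BZR",
    "BZR_dimer",
    "BZRARF_dimer",
    "auxin",
    "AUXIAA",
    "ARF",
    "ARF_dimer",
    "PILS",
)
N_STATES = len(STATE_NAMES)

# indices of the delayed channels within the state vector
IDX_BZR_DIMER = 3
IDX_ARF_DIMER = 8

# layout of the packed parameter vector consumed by the jitted kernel
_PVEC_NAMES = (
    "alpha_BR", "k_BR", "delta_BR",
    "alpha_bin", "delta_bin", "delta_brb",
    "alpha_BZR", "delta_bzr", "delta_bzb",
    "gamma_dB", "gamma_dAB", "gamma_dAF",
    "gamma_aB", "gamma_aAB", "gamma_aAF",
    "alpha_A", "delta_A", "T",
    "alpha_bx", "delta_bx", "delta_aux", "k_ARF", "alpha",
    "alpha_ARF", "delta_ARF", "theta",
    "alpha_bP", "delta_PIL", "alpha_pAF", "delta_PBR", "k_AF", "k_BZ",
    "tau", "phi",
)
_I_BIN_ON_ARF = len(_PVEC_NAMES)      # 34: 0.0 / 1.0 flag
_I_BIN2_REF = _I_BIN_ON_ARF + 1       # 35
_I_BIN2_EPS = _I_BIN_ON_ARF + 2       # 36
PVEC_LEN = _I_BIN_ON_ARF + 3


@dataclass(frozen=True)
class DelayedView:
    """The two delayed feedback channels evaluated at t - tau."""

    bzr_dimer_lagged: float
    arf_dimer_lagged: float

    def __post_init__(self) -> None:
        if self.bzr_dimer_lagged < 0 or self.arf_dimer_lagged < 0:
            raise ValueError("lagged dimer concentrations must be non-negative")


def pack_pvec(params: ParameterSet, bin_on_arf: bool = False) -> np.ndarray:
    """Pack a :class:`ParameterSet` into the flat float vector the jitted
    kernel consumes."""
    v = np.empty(PVEC_LEN)
    for i, name in enumerate(_PVEC_NAMES):
        v[i] = getattr(params, name)
    v[_I_BIN_ON_ARF] = 1.0 if bin_on_arf else 0.0
    if bin_on_arf:
        if params.bin2_ref is None:
            raise ValueError(
                "bin_on_arf requires bin2_ref; compile the scenario first or "
                "set ParameterSet.bin2_ref explicitly"
            )
        v[_I_BIN2_REF] = params.bin2_ref
    else:
        v[_I_BIN2_REF] = 1.0
    v[_I_BIN2_EPS] = params.bin2_eps
    return v


@njit(cache=True)
def model_rhs_jit(t, y, ylag, p, rep):  # pragma: no cover - exercised via wrappers
    """Time derivatives of the core species plus any attached reporter states.

    ``y`` holds the 10 core species followed by one state per reporter row of
    ``rep``; ``ylag`` is the full state interpolated at t - tau.  Reporter
    rows are ``[template, p1..p6]``: template 0 follows the PILS equation
    (params ``a_bP, a_pAF, k_AF, k_BZ, d_PIL, d_PBR``), template 1 follows
    the Aux/IAA equation (params ``a_bx, alpha, k_ARF, d_bx, d_aux``).
    Reporters read the core state but never feed back into it.
    """
    n = y.shape[0]
    d = np.empty(n)
    BR = y[0]
    BIN2 = y[1]
    BZR = y[2]
    BZRD = y[3]
    BZRARFD = y[4]
    A = y[5]
    AUXIAA = y[6]
    ARF = y[7]
    ARFD = y[8]
    PILS = y[9]
    BZRD_l = ylag[3]
    ARFD_l = ylag[8]

    th = p[25]
    if p[34] != 0.0:
        b = BIN2 if BIN2 > p[36] else p[36]
        th = p[25] * p[35] / b

    het_on = p[13] * BZR * ARF       # heterodimer association flux
    het_off = p[10] * BZRARFD        # heterodimer dissociation flux

    d[0] = p[33] + p[0] / (1.0 + p[1] * BZRD_l) - p[2] * BR
    d[1] = p[3] - BIN2 * (p[4] + p[5] * BR)
    d[2] = (p[6] - BZR * (p[7] + p[8] * BIN2)
            + p[9] * BZRD - p[12] * BZR * BZR + het_off - het_on)
    d[3] = p[12] * BZR * BZR - p[9] * BZRD
    d[4] = het_on - het_off
    d[5] = p[15] - A * (p[16] + p[17] * PILS)
    d[6] = (p[18] + p[22] * p[21] * ARFD_l / (1.0 + p[21] * ARFD_l)
            - AUXIAA * (p[19] + p[20] * A))
    d[7] = (p[23] - ARF * (p[24] + th * AUXIAA)
            + p[11] * ARFD - p[14] * ARF * ARF + het_off - het_on)
    d[8] = p[14] * ARF * ARF - p[11] * ARFD
    d[9] = (p[26] + p[28] * p[30] * ARFD_l / (1.0 + p[30] * ARFD_l + p[31] * BZRD_l)
            - PILS * (p[27] + p[29] * BR))

    for r in range(rep.shape[0]):
        R = y[10 + r]
        if rep[r, 0] == 0.0:
            d[10 + r] = (rep[r, 1]
                         + rep[r, 2] * rep[r, 3] * ARFD_l
                         / (1.0 + rep[r, 3] * ARFD_l + rep[r, 4] * BZRD_l)
                         - R * (rep[r, 5] + rep[r, 6] * BR))
        else:
            d[10 + r] = (rep[r, 1]
                         + rep[r, 2] * rep[r, 3] * ARFD_l / (1.0 + rep[r, 3] * ARFD_l)
                         - R * (rep[r, 4] + rep[r, 5] * A))
    return d


_NEG_TOL = -1e-9
_EMPTY_REP = np.zeros((0, 7))


def rhs(
    t: float,
    state: np.ndarray,
    lagged: DelayedView,
    params: ParameterSet,
    bin_on_arf: bool = False,
) -> np.ndarray:
    """Evaluate the ten core derivatives (uM/h) at time ``t``.

    ``state`` follows :data:`STATE_NAMES`; ``lagged`` supplies BZR^D and
    ARF^D at t - tau.  Inputs more negative than the solver tolerance
    (-1e-9) or non-finite are rejected.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} components, got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite values")
    if np.any(y < _NEG_TOL):
        raise ValueError("state components must be non-negative (>= -1e-9)")
    if not (math.isfinite(lagged.bzr_dimer_lagged) and math.isfinite(lagged.arf_dimer_lagged)):
        raise ValueError("lagged values must be finite")
    ylag = np.zeros(N_STATES)
    ylag[IDX_BZR_DIMER] = lagged.bzr_dimer_lagged
    ylag[IDX_ARF_DIMER] = lagged.arf_dimer_lagged
    pvec = pack_pvec(params, bin_on_arf=bin_on_arf)
    return model_rhs_jit(float(t), y, ylag, pvec, _EMPTY_REP)
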