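"""Deterministic building blocks of the developmental model.

The developmental model tracks five species in a single axon terminal:
short-lived filopodia (``sF``), long-lived filopodia (``lF``), transient
bulbous tips (``sB``), stabilized synaptogenic bulbous tips (``synB``) and
synapses (``S``).  Eight first-order reactions connect them:

====  ==================  ===========================================
id    reaction            propensity
====  ==================  ===========================================
R1sF  0 -> sF             f_F(t) * c1_sF
R2sF  sF -> 0             sF * c2_sF
R1lF  0 -> lF             f_F(t) * c1_lF
R2lF  lF -> 0             lF * c2_lF
R3    F -> sB             c3 * (sF+lF) * f1(synB, B50) * f_FB(t, t_half)
R4    sB -> 0             c4 * sB
R5    sB -> synB          c5 * sB
R6    synB -> S           c6 * synB
====  ==================  ===========================================

``F`` in R3 means any filopodium; R4 removes a transient bulb without
returning it to the filopodium pool (a deliberate simplification — bulbs
are rare and r4 is small, so the back-flux is negligible).  Times are in
minutes after the P40 pupal stage (60 min per percent of pupal
development, so P60 is t = 1200 min) and all rates are per minute.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .params import DevParams, DevState

__all__ = [
    "eval_f_F",
    "eval_f_FB",
    "eval_f1",
    "propensities",
    "compute_c3",
    "REACTIONS",
]

#: Reaction labels in propensity-vector order.
REACTIONS = ("R1sF", "R2sF", "R1lF", "R2lF", "R3", "R4", "R5", "R6")

#: Stoichiometry of each reaction on the state vector (sF, lF, sB, synB, S).
STOICHIOMETRY = {
    "R1sF": (1, 0, 0, 0, 0),
    "R2sF": (-1, 0, 0, 0, 0),
    "R1lF": (0, 1, 0, 0, 0),
    "R2lF": (0, -1, 0, 0, 0),
    "R3": (0, 0, 1, 0, 0),  # F -> sB without decrementing the filopodium pool
    "R4": (0, 0, -1, 0, 0),
    "R5": (0, 0, -1, 1, 0),
    "R6": (0, 0, 0, -1, 1),
}


def eval_f_F(t: float, poly_coeffs: Sequence[float]) -> float:
    """Slow-timescale filopodial drive: a clamped fifth-order polynomial.

    ``f_F(t) = max(0, sum_i p_i t^i)`` with coefficients ordered p0..p5 and
    t in minutes after P40.  The function multiplies the zero-order
    filopodium generation rates and models the slow developmental decline
    of filopodial activity.

    Parameters
    ----------
    t : float
        Minutes after P40; must be >= 0.
    poly_coeffs : sequence of 6 floats
        Polynomial coefficients (p0, p1, ..., p5).

    Returns
    -------
    float
        Non-negative drive value.
    """
    if len(poly_coeffs) != 6:
        raise ValueError(
            f"poly_coeffs must have exactly 6 entries (p0..p5), got {len(poly_coeffs)}"
        )
    if t < 0:
        raise ValueError(f"t must be >= 0 (minutes after P40), got {t}")
    # Horner evaluation, highest degree first.
    value = 0.0
    for p in reversed(list(poly_coeffs)):
        value = value * t + p
    return max(0.0, value)


def eval_f_FB(t: float, t_half: float) -> float:
    """Sigmoidal ramp of bulb-formation propensity over development.

    ``f_FB(t) = (1 + tanh[(3/t_half)(t - t_half)]) / 2`` rises from ~0 to 1
    with half-point at ``t_half`` (default 1000 min in all presets).
    Strictly increasing in t and bounded in (0, 1).
    """
    if t_half <= 0:
        raise ValueError(f"t_half must be > 0, got {t_half}")
    return 0.5 * (1.0 + math.tanh((3.0 / t_half) * (t - t_half)))


def eval_f1(synB: float, B50: float, f1_mode: str = "inhibition") -> float:
    """Feedback of stabilized bulbs on new bulb formation.

    In the default ``"inhibition"`` mode this is the saturating
    auto-inhibition ``B50 / (synB + B50)``: each stabilized synaptogenic
    bulb sequesters seeding factors, lowering the propensity to nucleate
    further bulbs (value 1 at synB = 0, 1/2 at synB = B50, -> 0 as synB
    grows).  The ``"as_printed"`` mode evaluates ``(synB + B50) / B50``
    instead, which *increases* with synB; it is retained only for
    comparison with the literature formula as typeset.
    """
    if B50 <= 0:
        raise ValueError(f"B50 must be > 0, got {B50}")
    if synB < 0:
        raise ValueError(f"synB must be >= 0, got {synB}")
    if f1_mode == "inhibition":
        return B50 / (synB + B50)
    if f1_mode == "as_printed":
        return (synB + B50) / B50
    raise ValueError(f"unknown f1_mode {f1_mode!r}")


def propensities(state: DevState, params: DevParams) -> np.ndarray:
    """Propensity vector of the eight developmental reactions.

    Returns rates in the order of :data:`REACTIONS`.  The time-dependent
    factors f_F and f_FB enter R1 and R3; everything else is linear
    mass-action.  When the parameter set carries a ``drive`` override
    (see :class:`~filokin.params.DevParams`), it replaces f_F.
    """
    if min(state.sF, state.lF, state.sB, state.synB, state.S) < 0:
        raise ValueError(f"negative copy number in state {state}")
    fF = params.filopodial_drive(state.t)
    fFB = eval_f_FB(state.t, params.t_half)
    f1 = eval_f1(state.synB, params.B50, params.f1_mode)
    return np.array(
        [
            fF * params.c1_sF,
            state.sF * params.c2_sF,
            fF * params.c1_lF,
            state.lF * params.c2_lF,
            params.c3 * (state.sF + state.lF) * f1 * fFB,
            params.c4 * state.sB,
            params.c5 * state.sB,
            params.c6 * state.synB,
        ]
    )


def compute_c3(r3: float, sF: float, lF: float, f_FB: float) -> float:
    """Invert the R3 factorization to recover the bulb-formation constant.

    ``c3 = r3 / ((sF + lF) * f_FB)`` evaluated at a reference time (the
    estimation pipeline uses P60 census means and f_FB(P60)).
    """
    denom = (sF + lF) * f_FB
    if denom <= 0:
        raise ValueError(
            "cannot derive c3: (sF + lF) * f_FB must be positive, got "
            f"sF={sF}, lF={lF}, f_FB={f_FB}"
        )
    return r3 / denom
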