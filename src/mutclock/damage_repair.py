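"""Damage--repair kinetics of non-replicative mutations.

A base pair is either intact or carries a single-strand miscoding lesion
(think deamination of 5-methylcytosine at a CpG).  Damage arrives at a
constant instantaneous rate ``mu`` and repair removes a standing lesion at
rate ``r``, giving

    dp1/dt = mu (1 - p1) - r p1,    p1(0) = 0,

whose solution is ``p1(t) = mu/(mu+r) (1 - exp(-(mu+r) t))``.  A lesion
still standing at replication mispairs, fixing a mutation in one of the two
daughters, so the per-division mutation rate for a cell dividing every ``T``
units of time is ``M(T) = p1(T)/2`` and the per-time rate at division rate
``c = 1/T`` is ``m(c) = c M(1/c)``.

Two limiting regimes follow.  When repair is slow relative to division
(``rT << 1``) almost every lesion converts: ``M(T) ~ mu T / 2`` and
mutations track absolute time.  When repair is fast (``rT >> 1``) the lesion
fraction equilibrates at ``mu/(mu+r)`` well before division: ``M(T) ~
mu/(2(mu+r))`` and mutations track cell divisions — mimicking replication
errors even though none occurred.

The extended model adds incorrect repair: a fraction ``epsilon`` of repair
events alters the undamaged strand instead of the lesion, committing the
site to a mutation.  The state fractions (intact ``p0``, lesioned ``p1``,
mutated ``q``) then obey the linear system

    dp0/dt = -mu p0 + r (1 - eps) p1
    dp1/dt =  mu p0 - r p1
    dq/dt  =  r eps p1

and the per-division rate ``q(T) + p1(T)/2`` keeps growing without a finite
asymptote for ``eps > 0``, although an intermediate near-equilibrium phase
persists while ``r eps t`` stays small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .params import DamageRepairParams, ParameterError, validate

__all__ = [
    "StateFractions",
    "RegimeLabel",
    "lesion_fraction",
    "per_division_mutation_rate",
    "per_time_mutation_rate",
    "regime",
    "extended_state_fractions",
    "extended_per_division_mutation_rate",
    "TIME_LIKE_MAX_RT",
    "DIVISION_LIKE_MIN_RT",
]


@dataclass(frozen=True)
class StateFractions:
    """Fractions of base pairs intact (p0), lesioned (p1), and mutated (q) at time t."""

    p0: float
    p1: float
    q: float
    t: float


@dataclass(frozen=True)
class RegimeLabel:
    """Which limiting behaviour the per-division mutation rate is in.

    ``time_like``: repair negligible within a cell cycle (rT small), mutations
    accrue with absolute time; ``division_like``: lesions equilibrate before
    division (rT large), mutations accrue with divisions; otherwise
    ``intermediate``.
    """

    label: str
    rT: float


# Thresholds on the dimensionless product r*T.  The asymptotic conditions are
# rT << 1 and rT >> 1; two decades on either side is where the corresponding
# approximation is comfortably below 1% error.
TIME_LIKE_MAX_RT = 0.01
DIVISION_LIKE_MIN_RT = 100.0


def lesion_fraction(dp: DamageRepairParams, t):
    """Standing single-strand lesion fraction p1(t), t since the last division.

    Monotonically increasing with asymptote ``mu/(mu+r)``.  Accepts scalar or
    array ``t``.  Uses expm1 so small ``(mu+r) t`` does not cancel.
    """
    validate(dp)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be >= 0")
    k = dp.mu + dp.r
    out = -(dp.mu / k) * np.expm1(-k * t)
    return float(out) if out.ndim == 0 else out


def per_division_mutation_rate(dp: DamageRepairParams, T):
    """Per-bp mutation rate of one cell division with inter-division time T.

    Half the lesion fraction at division, ``p1(T)/2``: each unrepaired
    single-strand lesion mispairs and fixes a substitution in one of the two
    daughter cells.  Increasing and concave in ``T``.  Warns when
    ``mu * T > 0.01``, outside the regime where the lesion fraction stays
    far from saturation within one cell cycle.
    """
    validate(dp)
    T_arr = np.asarray(T, dtype=float)
    if np.any(T_arr <= 0):
        raise ParameterError("T must be > 0")
    if np.any(dp.mu * T_arr > 0.01):
        warnings.warn(
            "mu * T > 0.01: the model assumes damage is slow relative to the "
            "cell cycle (mu << 1/T)",
            stacklevel=2,
        )
    return 0.5 * lesion_fraction(dp, T)


def per_time_mutation_rate(dp: DamageRepairParams, c):
    """Per-bp per-time mutation rate of a lineage dividing at rate c.

    ``m(c) = c * M(1/c)``: the per-division rate times the division rate.
    Concave and increasing in ``c``, rising from ``c/(2(1+R))`` at slow
    division toward the ceiling ``mu/2`` as ``c -> inf``.
    """
    validate(dp)
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr <= 0):
        raise ParameterError("c must be > 0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = c_arr * np.asarray(per_division_mutation_rate(dp, 1.0 / c_arr))
    return float(out) if out.ndim == 0 else out


def regime(dp: DamageRepairParams, T: float) -> RegimeLabel:
    """Classify the limiting behaviour at inter-division time T by rT."""
    validate(dp)
    if T <= 0:
        raise ParameterError("T must be > 0")
    rT = dp.r * T
    if rT <= TIME_LIKE_MAX_RT:
        label = "time_like"
    elif rT >= DIVISION_LIKE_MIN_RT:
        label = "division_like"
    else:
        label = "intermediate"
    return RegimeLabel(label=label, rT=rT)


def _generator_matrix(dp: DamageRepairParams) -> np.ndarray:
    """Generator of the (intact, lesion, mutated) linear system; columns sum to 0."""
    mu, r, eps = dp.mu, dp.r, dp.epsilon
    return np.array(
        [
            [-mu, r * (1.0 - eps), 0.0],
            [mu, -r, 0.0],
            [0.0, r * eps, 0.0],
        ]
    )


def extended_state_fractions(
    dp: DamageRepairParams, t: float, p1_init: float = 0.0
) -> StateFractions:
    """State fractions of the repair-error model at time t since the last division.

    Solves the three-state linear system by matrix exponential, starting from
    ``p0 = 1 - p1_init, p1 = p1_init, q = 0`` (a fresh post-division cell has
    ``p1_init = 0``).  Conservation ``p0 + p1 + q = 1`` holds to machine
    precision; with ``epsilon = 0`` the ``p1`` trajectory coincides with
    :func:`lesion_fraction`.
    """
    validate(dp)
    if t < 0:
        raise ParameterError("t must be >= 0")
    if not 0.0 <= p1_init <= 1.0:
        raise ParameterError("p1_init must be in [0, 1]")
    init = np.array([1.0 - p1_init, p1_init, 0.0])
    state = expm(_generator_matrix(dp) * t) @ init
    return StateFractions(p0=float(state[0]), p1=float(state[1]), q=float(state[2]), t=float(t))


def extended_per_division_mutation_rate(
    dp: DamageRepairParams, T: float, p1_init: float = 0.0
) -> float:
    """Per-bp per-division mutation rate with incorrect repair included.

    ``q(T) + p1(T)/2``: sites already committed by incorrect repair plus the
    replication-resolved half of standing lesions.  Reduces to
    :func:`per_division_mutation_rate` when ``epsilon = 0``; for
    ``epsilon > 0`` it is strictly increasing in ``T`` with no finite
    asymptote, though a near-equilibrium plateau at ``mu/(2(mu+r))`` persists
    while incorrect repair has committed few sites (``r eps t`` small).
    """
    if T <= 0:
        raise ParameterError("T must be > 0")
    s = extended_state_fractions(dp, T, p1_init=p1_init)
    return s.q + 0.5 * s.p1
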