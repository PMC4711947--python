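"""Closed-form accounting of replication-driven germline mutations.

Germ-cell development from fertilization to reproduction is split into
stages (first post-zygotic division; to sexual differentiation; to birth;
to puberty; post-puberty), each with its own division count and per-division
error rate.  Expected genome-wide mutation counts are then stage sums:

* maternal:  ``M_f = (mu0 + mu1 d1 + mu2_f d2_f) H``  — all female germ-cell
  divisions are completed by birth, so the count is independent of the
  mother's age at reproduction ``G``.
* paternal:  ``M_m = [mu0 + mu1 d1 + mu2_m d2_m + mu3_m d3_m
  + mu4_m (c_m (G - P - t_sg) + d_sg)] H`` — spermatogonial stem cells keep
  dividing after puberty, so the count grows linearly in ``G`` with slope
  ``mu4_m c_m H``.

The male bias ``alpha = M_m / M_f`` therefore increases with ``G``, and the
sex-averaged yearly per-bp rate can be written
``m_y = mu4_m c_m / 2 + A* / (2 G)`` where the age-zero intercept
``A* = 2 mu0 + 2 mu1 d1 + mu2_f d2_f + mu2_m d2_m + mu3_m d3_m
- mu4_m (c_m P + c_m t_sg - d_sg)`` is independent of ``G``.  The sign of
A* alone decides whether a longer generation time lowers, raises, or leaves
unchanged the yearly rate — the generation-time effect on the molecular
clock.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import ParameterError, ReplicationParams, validate

__all__ = [
    "GTEffectClass",
    "maternal_mutation_count",
    "paternal_mutation_count",
    "total_mutation_count",
    "male_bias",
    "yearly_rate",
    "a_star",
    "classify_gt_effect",
    "age_trajectory",
]


@dataclass(frozen=True)
class GTEffectClass:
    """Direction of the generation-time effect on the yearly mutation rate.

    ``label`` is ``"decreasing"`` (A* > 0: longer generations lower the
    yearly rate, the classic generation-time effect), ``"increasing"``
    (A* < 0), or ``"independent"`` (|A*| within tolerance of zero).
    ``a_star_value`` is the genome-equivalent per-bp intercept A*.
    """

    label: str
    a_star_value: float


def _require_valid_age(p: ReplicationParams, G: float) -> None:
    if G < p.P + p.t_sg:
        raise ParameterError(
            f"G = {G} < P + t_sg = {p.P + p.t_sg}: reproduction before completion "
            "of first spermatogenesis is outside the model"
        )


def maternal_mutation_count(p: ReplicationParams, G: float | None = None) -> float:
    """Expected genome-wide replication-driven mutations inherited from the mother.

    Independent of the maternal age ``G`` (accepted and ignored for symmetry):
    all mitotic divisions of female germ cells are completed by birth.
    """
    validate(p)
    return (p.mu0 + p.mu1 * p.d1 + p.mu2_f * p.d2_f) * p.H


def paternal_mutation_count(p: ReplicationParams, G: float) -> float:
    """Expected genome-wide replication-driven mutations inherited from the father.

    Linear in the paternal age ``G`` with slope ``mu4_m * c_m * H``; requires
    ``G >= P + t_sg`` (at least one completed spermatogenesis).
    """
    validate(p)
    _require_valid_age(p, G)
    per_bp = (
        p.mu0
        + p.mu1 * p.d1
        + p.mu2_m * p.d2_m
        + p.mu3_m * p.d3_m
        + p.mu4_m * (p.c_m * (G - p.P - p.t_sg) + p.d_sg)
    )
    return per_bp * p.H


def total_mutation_count(p: ReplicationParams, G: float) -> float:
    """Expected diploid genome-wide count inherited from both parents."""
    return maternal_mutation_count(p) + paternal_mutation_count(p, G)


def male_bias(p: ReplicationParams, G: float) -> float:
    """Ratio alpha of paternal to maternal replication-driven mutations.

    A linear function of ``G - P - t_sg`` with positive slope whenever
    ``mu4_m * c_m > 0``; raises if the maternal count is zero.
    """
    m_f = maternal_mutation_count(p)
    if m_f == 0:
        raise ParameterError("male bias undefined: maternal mutation count is zero")
    return paternal_mutation_count(p, G) / m_f


def yearly_rate(p: ReplicationParams, G: float) -> float:
    """Sex-averaged yearly mutation rate per bp (substitution rate if neutral).

    The per-generation diploid count divided by ``2 G H``, i.e. averaged over
    the two inherited genome copies and the generation time.
    """
    return total_mutation_count(p, G) / (2.0 * G * p.H)


def a_star(p: ReplicationParams) -> float:
    """Age-zero intercept A* of the post-puberty mutation trajectory (per bp).

    ``yearly_rate(p, G) == mu4_m c_m / 2 + a_star(p) / (2 G)`` for every
    valid ``G``; the sign of A* determines the direction of the
    generation-time effect.
    """
    validate(p)
    return (
        2 * p.mu0
        + 2 * p.mu1 * p.d1
        + p.mu2_f * p.d2_f
        + p.mu2_m * p.d2_m
        + p.mu3_m * p.d3_m
        - p.mu4_m * (p.c_m * p.P + p.c_m * p.t_sg - p.d_sg)
    )


def _a_star_scale(p: ReplicationParams) -> float:
    """Largest additive term of A*, the natural scale for its cancellation error."""
    terms = (
        2 * p.mu0,
        2 * p.mu1 * p.d1,
        p.mu2_f * p.d2_f,
        p.mu2_m * p.d2_m,
        p.mu3_m * p.d3_m,
        abs(p.mu4_m * (p.c_m * p.P + p.c_m * p.t_sg - p.d_sg)),
    )
    return max(terms)


def classify_gt_effect(p: ReplicationParams, tolerance: float | None = None) -> GTEffectClass:
    """Classify the generation-time effect by the sign of A*.

    ``tolerance`` is an absolute threshold on A*; by default it is 1e-12
    relative to the largest additive term of A*, so that classification is
    robust to floating-point cancellation between terms.
    """
    value = a_star(p)
    if tolerance is None:
        tolerance = 1e-12 * _a_star_scale(p)
    if value > tolerance:
        label = "decreasing"
    elif value < -tolerance:
        label = "increasing"
    else:
        label = "independent"
    return GTEffectClass(label=label, a_star_value=value)


# Default embryonic timepoints (years since fertilization) used to place the
# pre-birth stage boundaries on an age axis.  The closed-form counts do not
# depend on them; only trajectory plotting and the damage simulator do.
T_FIRST_DIVISION = 0.003  # ~1 day
T_SEX_DIFFERENTIATION = 0.12  # ~6 weeks
T_BIRTH = 0.75  # ~9 months


def age_trajectory(
    p: ReplicationParams,
    sex: str,
    ages: Sequence[float],
    G_reference: float | None = None,
    *,
    t_sex_diff: float = T_SEX_DIFFERENTIATION,
    t_birth: float = T_BIRTH,
) -> np.ndarray:
    """Expected mutation count of a germline lineage sampled at each age.

    The curve is piecewise linear in age: both sexes accrue ``mu0 H`` at the
    first division and then climb linearly through the embryonic stages; the
    female curve is flat after birth, while the male curve climbs slowly to
    puberty, gains the first spermatogenesis (``mu4_m d_sg H``) over
    ``[P, P + t_sg]``, and afterwards is linear with slope ``mu4_m c_m H``.
    Evaluating at a reproduction age ``a >= P + t_sg`` reproduces
    :func:`paternal_mutation_count` (males) or
    :func:`maternal_mutation_count` (females) exactly.

    ``G_reference`` is accepted for API symmetry with per-sex generation
    times in reporting; the trajectory itself does not depend on it.
    """
    validate(p)
    if sex not in ("f", "m"):
        raise ParameterError(f"sex must be 'f' or 'm', got {sex!r}")
    ages_arr = np.asarray(ages, dtype=float)
    if np.any(ages_arr < 0):
        raise ParameterError("ages must be >= 0")
    if not (0 < t_sex_diff < t_birth):
        raise ParameterError("embryonic timepoints must satisfy 0 < t_sex_diff < t_birth")

    # Node ages and cumulative genome-wide counts of the piecewise-linear curve.
    nodes = [0.0, t_sex_diff, t_birth]
    counts = [
        p.mu0 * p.H,
        (p.mu0 + p.mu1 * p.d1) * p.H,
    ]
    if sex == "f":
        counts.append((p.mu0 + p.mu1 * p.d1 + p.mu2_f * p.d2_f) * p.H)
    else:
        if p.P <= t_birth:
            raise ParameterError("male trajectory requires puberty age P > the birth timepoint")
        pre_birth = (p.mu0 + p.mu1 * p.d1 + p.mu2_m * p.d2_m) * p.H
        counts.append(pre_birth)
        nodes.extend([p.P, p.P + p.t_sg])
        at_puberty = pre_birth + p.mu3_m * p.d3_m * p.H
        counts.extend([at_puberty, at_puberty + p.mu4_m * p.d_sg * p.H])
    nodes_arr = np.asarray(nodes)
    counts_arr = np.asarray(counts)

    out = np.interp(ages_arr, nodes_arr, counts_arr)
    # Beyond the last node: females stay flat (np.interp default); males
    # continue linearly at the stem-cell slope.
    if sex == "m":
        beyond = ages_arr > nodes_arr[-1]
        slope = p.mu4_m * p.c_m * p.H
        out = np.where(beyond, counts_arr[-1] + slope * (ages_arr - nodes_arr[-1]), out)
    return out
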