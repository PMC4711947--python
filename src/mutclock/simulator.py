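"""Seeded per-site stochastic simulation of damage, repair, and replication.

This module is the brute-force counterpart of the closed-form models: it
realizes one germ-cell (or somatic) lineage as an explicit division schedule
and simulates mutation accrual along it.

* Replication errors: each division contributes a Poisson-distributed count
  with mean (stage-specific per-division rate) x (genome size).
* Damage-induced mutations: each genomic site is an independent
  continuous-time Markov chain with exponential waiting times — damage at
  rate ``mu`` from the intact state, repair at rate ``r`` from the lesion
  state, with a fraction ``epsilon`` of repairs incorrect.  At each cell
  division a site still in the lesion state fixes a mutation in the tracked
  daughter with probability 1/2 (one daughter inherits the mispaired
  strand) and returns to intact otherwise.  Mutated sites never revert
  (infinite-sites accounting), so mutation totals over many divisions are
  sums of per-division contributions.

No time discretization is used anywhere; waiting times are exact
exponentials, so the simulator is an independent oracle for every closed
form in :mod:`mutclock.replication` and :mod:`mutclock.damage_repair`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from . import replication as _rep
from .damage_repair import regime
from .params import (
    DamageRepairParams,
    LineageSchedule,
    ParameterError,
    ReplicationParams,
    validate,
)

__all__ = [
    "SimulationResult",
    "MutationAccount",
    "build_schedule",
    "simulate_damage_sites",
    "simulate_replication_errors",
    "simulate_germline",
    "stage_rate_map",
]

# Per-site states inside one inter-division interval.
_INTACT, _LESION, _COMMITTED, _PREMUT = 0, 1, 2, 3


@dataclass(frozen=True)
class SimulationResult:
    """Point estimate with Monte-Carlo standard error from one simulation run.

    ``mean_mutations`` is a per-site per-division rate for site simulations
    and a genome-wide per-lineage expectation for lineage simulations; the
    per-division (or per-replicate-summed) tallies always sum to the raw
    total count behind the estimate.
    """

    n_sites: int
    n_replicates: int
    mean_mutations: float
    std_error: float
    per_division_tallies: tuple
    seed: int

    @property
    def total_tally(self) -> int:
        return int(sum(self.per_division_tallies))


@dataclass(frozen=True)
class MutationAccount:
    """Genome-wide mutation counts decomposed by origin and stage.

    ``replicative`` maps developmental stage ("stage0" .. "stage4") to the
    replication-error count; ``damage_induced`` maps the kinetic class of the
    inter-division interval ("time_like", "intermediate", "division_like",
    plus "arrest" for the post-mitotic oocyte interval) to the damage-origin
    count.  Counts are expectation estimates when averaged over replicates.
    """

    replicative: Dict[str, float]
    damage_induced: Dict[str, float]
    sex: str
    sampling_age: float

    @property
    def replicative_total(self) -> float:
        return float(sum(self.replicative.values()))

    @property
    def damage_total(self) -> float:
        return float(sum(self.damage_induced.values()))

    @property
    def total(self) -> float:
        return self.replicative_total + self.damage_total


def stage_rate_map(p: ReplicationParams) -> Dict[str, float]:
    """Per-division error rate for each schedule stage label."""
    return {
        "s0": p.mu0,
        "s1": p.mu1,
        "s2f": p.mu2_f,
        "s2m": p.mu2_m,
        "s3m": p.mu3_m,
        "s4m": p.mu4_m,
    }


_STAGE_NAME = {"s0": "stage0", "s1": "stage1", "s2f": "stage2", "s2m": "stage2", "s3m": "stage3", "s4m": "stage4"}


def _spaced(t0: float, t1: float, n: int) -> np.ndarray:
    """n division times evenly spaced in (t0, t1]."""
    if n == 0:
        return np.empty(0)
    return t0 + (t1 - t0) * np.arange(1, n + 1) / n


def build_schedule(
    p: ReplicationParams,
    sex: str,
    G: float,
    *,
    t_first: float = _rep.T_FIRST_DIVISION,
    t_sex_diff: float = _rep.T_SEX_DIFFERENTIATION,
    t_birth: float = _rep.T_BIRTH,
) -> LineageSchedule:
    """Division times of one germ-cell lineage sampled at reproduction age G.

    Embryonic stages are placed at configurable timepoints (years since
    fertilization): the first cleavage at ``t_first``, sexual
    differentiation at ``t_sex_diff``, birth at ``t_birth``.  Females
    complete all ``1 + d1 + d2_f`` divisions before birth.  Males add
    ``d3_m`` divisions to puberty, then ``floor(c_m (G - P - t_sg))``
    spermatogonial stem-cell divisions evenly spaced at interval ``1/c_m``
    (the discrete realization of the continuous post-puberty term), then the
    ``d_sg`` divisions of the final spermatogenesis within ``t_sg``.
    """
    validate(p)
    if sex not in ("f", "m"):
        raise ParameterError(f"sex must be 'f' or 'm', got {sex!r}")
    if not 0 < t_first < t_sex_diff < t_birth:
        raise ParameterError("need 0 < t_first < t_sex_diff < t_birth")

    times = [np.array([t_first])]
    labels = ["s0"]
    times.append(_spaced(t_first, t_sex_diff, p.d1))
    labels += ["s1"] * p.d1

    if sex == "f":
        if G < t_birth:
            raise ParameterError(f"female sampling age G = {G} precedes birth ({t_birth})")
        times.append(_spaced(t_sex_diff, t_birth, p.d2_f))
        labels += ["s2f"] * p.d2_f
    else:
        if G < p.P + p.t_sg:
            raise ParameterError(
                f"G = {G} < P + t_sg = {p.P + p.t_sg}: reproduction before completion "
                "of first spermatogenesis is outside the model"
            )
        if p.P <= t_birth:
            raise ParameterError("male schedule requires puberty age P > the birth timepoint")
        times.append(_spaced(t_sex_diff, t_birth, p.d2_m))
        labels += ["s2m"] * p.d2_m
        times.append(_spaced(t_birth, p.P, p.d3_m))
        labels += ["s3m"] * p.d3_m
        n_ss = math.floor(p.c_m * (G - p.P - p.t_sg) + 1e-9)
        if n_ss > 0:
            times.append(p.P + np.arange(1, n_ss + 1) / p.c_m)
            labels += ["s4m"] * n_ss
        # terminal spermatogenesis; give it a tiny window if t_sg == 0 so
        # division times stay strictly increasing
        sg_window = p.t_sg if p.t_sg > 0 else min(1e-6, G * 1e-6)
        times.append(_spaced(G - sg_window, G, p.d_sg))
        labels += ["s4m"] * p.d_sg

    division_times = np.concatenate(times)
    return LineageSchedule(
        division_times=tuple(division_times), sampling_age=float(G), stage_labels=tuple(labels)
    ).validate()


def _evolve_interval(n: int, T: float, dp: DamageRepairParams, rng, variant: str):
    """Evolve n initially intact sites for time T; exact exponential waiting times.

    Returns (n_lesion, n_committed, n_premutation) at time T.  Committed
    sites arose from incorrect repair under the default ``"mutation"``
    variant; under the ``"premutation"`` variant incorrect repair instead
    parks the site in a premutation state fixed at the next replication.
    """
    mu, r, eps = dp.mu, dp.r, dp.epsilon
    t = np.zeros(n)
    state = np.zeros(n, dtype=np.int8)
    bad_state = _COMMITTED if variant == "mutation" else _PREMUT
    while True:
        act = np.flatnonzero((t < T) & (state <= _LESION))
        if act.size == 0:
            break
        rates = np.where(state[act] == _INTACT, mu, r)
        dt = np.full(act.size, np.inf)
        pos = rates > 0
        dt[pos] = rng.exponential(1.0 / rates[pos])
        t[act] = t[act] + dt
        trans = act[t[act] <= T]
        pre = state[trans].copy()
        damaged = trans[pre == _INTACT]
        repaired = trans[pre == _LESION]
        state[damaged] = _LESION
        if repaired.size:
            bad = rng.random(repaired.size) < eps
            state[repaired[bad]] = bad_state
            state[repaired[~bad]] = _INTACT
    return (
        int(np.count_nonzero(state == _LESION)),
        int(np.count_nonzero(state == _COMMITTED)),
        int(np.count_nonzero(state == _PREMUT)),
    )


def _resolve_division(n_lesion: int, n_committed: int, n_premut: int, rng) -> int:
    """New fixed mutations in the tracked daughter at a division boundary.

    Each standing lesion resolves to a mutation with probability 1/2 (the
    daughter inheriting the mispaired strand) and to intact otherwise; a
    premutation carries a substituted base on one strand and a miscoding
    lesion on the other, so both daughters emerge mutated.
    """
    return n_committed + n_premut + int(rng.binomial(n_lesion, 0.5))


def simulate_damage_sites(
    dp: DamageRepairParams,
    T: float,
    n_divisions: int,
    n_sites: int,
    seed: int,
    variant: str = "mutation",
) -> SimulationResult:
    """Per-site simulation of damage-induced mutation over regular divisions.

    Simulates ``n_sites`` independent sites through ``n_divisions`` cell
    cycles of length ``T`` and returns the per-site per-division mutation
    rate estimate with its binomial standard error.  Mutated sites are
    removed from further accounting (infinite sites).
    """
    validate(dp)
    if T <= 0:
        raise ParameterError("T must be > 0")
    if n_divisions < 1 or n_sites < 1:
        raise ParameterError("n_divisions and n_sites must be >= 1")
    if variant not in ("mutation", "premutation"):
        raise ParameterError(f"variant must be 'mutation' or 'premutation', got {variant!r}")
    rng = np.random.default_rng(seed)
    pool = n_sites
    tallies = []
    for _ in range(n_divisions):
        lesions, committed, premut = _evolve_interval(pool, T, dp, rng, variant)
        new = _resolve_division(lesions, committed, premut, rng)
        tallies.append(new)
        pool -= new
    total = sum(tallies)
    frac = total / n_sites
    se_frac = math.sqrt(max(frac * (1.0 - frac), 0.0) / n_sites)
    return SimulationResult(
        n_sites=n_sites,
        n_replicates=1,
        mean_mutations=frac / n_divisions,
        std_error=se_frac / n_divisions,
        per_division_tallies=tuple(tallies),
        seed=seed,
    )


def simulate_replication_errors(
    p: ReplicationParams,
    schedule: LineageSchedule,
    seed: int,
    n_replicates: int = 1,
) -> SimulationResult:
    """Poisson simulation of replication errors along a division schedule.

    Each division contributes ``Poisson(mu_stage * H)`` genome-wide
    mutations; the expectation over replicates matches the closed-form count
    operations (up to the floor discretization of the stem-cell term).
    """
    validate(p)
    schedule.validate()
    if schedule.stage_labels is None:
        raise ParameterError("schedule must carry stage_labels to assign per-stage error rates")
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    rates = stage_rate_map(p)
    unknown = set(schedule.stage_labels) - set(rates)
    if unknown:
        raise ParameterError(f"schedule stage labels not recognized: {sorted(unknown)}")
    means = np.array([rates[lab] for lab in schedule.stage_labels]) * p.H
    rng = np.random.default_rng(seed)
    draws = rng.poisson(np.broadcast_to(means, (n_replicates, means.size)))
    totals = draws.sum(axis=1)
    mean = float(totals.mean())
    se = float(totals.std(ddof=1) / math.sqrt(n_replicates)) if n_replicates > 1 else 0.0
    return SimulationResult(
        n_sites=int(p.H),
        n_replicates=n_replicates,
        mean_mutations=mean,
        std_error=se,
        per_division_tallies=tuple(int(x) for x in draws.sum(axis=0)),
        seed=seed,
    )


def simulate_germline(
    p: ReplicationParams,
    dp: DamageRepairParams,
    sex: str,
    G: float,
    seed: int,
    *,
    n_sites: int = 100_000,
    n_replicates: int = 1,
    variant: str = "mutation",
    schedule: Optional[LineageSchedule] = None,
) -> MutationAccount:
    """Simulate combined replicative + damage-induced accrual of one germline.

    Both mutation sources run on the same division schedule.  Damage accrues
    through every inter-division interval; for the post-mitotic oocyte the
    undivided interval from the last pre-birth division to age ``G`` is
    simulated as well, and standing lesions at fertilization are transmitted
    as mutations with probability 1/2 (the same resolution rule as an
    ordinary division).  Damage counts are simulated on ``n_sites`` sites
    and scaled to genome size ``H``.  With ``n_replicates > 1`` the account
    holds expectation estimates averaged over replicate lineages.
    """
    validate(p)
    validate(dp)
    sched = schedule if schedule is not None else build_schedule(p, sex, G)
    if sched.stage_labels is None:
        raise ParameterError("schedule must carry stage_labels")
    intervals = sched.intervals()
    arrest = G - sched.division_times[-1] if sched.n_divisions else G

    ss = np.random.SeedSequence(seed)
    rep_seed, dam_seed = ss.spawn(2)
    rng_rep = np.random.default_rng(rep_seed)
    rates = stage_rate_map(p)
    means = np.array([rates[lab] for lab in sched.stage_labels]) * p.H
    draws = rng_rep.poisson(np.broadcast_to(means, (n_replicates, means.size)))
    replicative: Dict[str, float] = {}
    for lab in sorted(set(_STAGE_NAME.values())):
        cols = [i for i, l in enumerate(sched.stage_labels) if _STAGE_NAME[l] == lab]
        if cols:
            replicative[lab] = float(draws[:, cols].sum() / n_replicates)

    rng_dam = np.random.default_rng(dam_seed)
    scale = p.H / n_sites
    damage: Dict[str, float] = {}
    for _ in range(n_replicates):
        pool = n_sites
        for T in intervals:
            lesions, committed, premut = _evolve_interval(pool, float(T), dp, rng_dam, variant)
            new = _resolve_division(lesions, committed, premut, rng_dam)
            cls = regime(dp, float(T)).label
            damage[cls] = damage.get(cls, 0.0) + new
            pool -= new
        if arrest > 0:
            lesions, committed, premut = _evolve_interval(pool, float(arrest), dp, rng_dam, variant)
            transmitted = _resolve_division(lesions, committed, premut, rng_dam)
            damage["arrest"] = damage.get("arrest", 0.0) + transmitted
    damage = {k: v * scale / n_replicates for k, v in damage.items()}

    return MutationAccount(
        replicative=replicative,
        damage_induced=damage,
        sex=sex,
        sampling_age=float(G),
    )
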