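"""Parameter records, validation, fixtures, and random scenario generators.

Two parameter families drive everything else in the package:

* :class:`ReplicationParams` — the stage-structured description of germ-cell
  development used by the replication-error model: per-stage division counts
  and per-division error rates by sex, life-history ages (puberty ``P``,
  spermatogenesis duration ``t_sg``), the yearly spermatogonial stem-cell
  division rate ``c_m``, and the haploid autosomal genome size ``H``.
  The age of reproduction ``G`` is deliberately *not* a field: it varies per
  query and is passed to the operations that need it.

* :class:`DamageRepairParams` — the kinetic description of non-replicative
  mutagenesis: instantaneous per-site damage rate ``mu``, repair rate ``r``
  (both per unit time), and the fraction ``epsilon`` of repair events that
  are incorrect (0 for the basic two-state model).

Female germ cells complete all mitotic divisions by birth, so stage-3 and
stage-4 division counts exist only for males and are not representable for
females.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "ReplicationParams",
    "DamageRepairParams",
    "LineageSchedule",
    "validate",
    "human_like_fixture",
    "cpg_like_damage_fixture",
    "random_params",
    "random_damage_params",
]


class ParameterError(ValueError):
    """A parameter record violates one of its invariants."""


def _check(cond: bool, message: str) -> None:
    if not cond:
        raise ParameterError(message)


@dataclass(frozen=True)
class ReplicationParams:
    """Per-stage division counts and replication-error rates for one genome.

    Rates are per base pair per cell division; division counts are integers.
    Stage 0 is the first post-zygotic division (shared by both sexes and
    possibly hypermutable), stage 1 runs from the second division to sexual
    differentiation, stage 2 to birth, stage 3 (males only) from birth to
    puberty, and stage 4 (males only) covers post-puberty spermatogonial
    stem-cell divisions plus the ``d_sg`` divisions of spermatogenesis
    itself.  Meiosis counts as a single division because only one round of
    DNA replication takes place.
    """

    mu0: float
    mu1: float
    mu2_f: float
    mu2_m: float
    mu3_m: float
    mu4_m: float
    d1: int
    d2_f: int
    d2_m: int
    d3_m: int
    c_m: float
    P: float
    t_sg: float
    d_sg: int
    H: float

    _RATE_FIELDS = ("mu0", "mu1", "mu2_f", "mu2_m", "mu3_m", "mu4_m")
    _COUNT_FIELDS = ("d1", "d2_f", "d2_m", "d3_m", "d_sg")

    def validate(self) -> "ReplicationParams":
        for name in self._RATE_FIELDS:
            v = getattr(self, name)
            _check(np.isfinite(v), f"{name} must be finite, got {v!r}")
            _check(0.0 <= v <= 1.0, f"{name} must be in [0, 1], got {v!r}")
        for name in self._COUNT_FIELDS:
            v = getattr(self, name)
            _check(
                isinstance(v, (int, np.integer)) and not isinstance(v, bool),
                f"{name} must be an integer division count, got {v!r}",
            )
            _check(v >= 0, f"{name} must be >= 0, got {v!r}")
        _check(np.isfinite(self.H) and self.H >= 1, f"H must be >= 1, got {self.H!r}")
        _check(np.isfinite(self.P) and self.P > 0, f"P must be > 0, got {self.P!r}")
        _check(
            np.isfinite(self.t_sg) and self.t_sg >= 0,
            f"t_sg must be >= 0, got {self.t_sg!r}",
        )
        _check(
            np.isfinite(self.c_m) and self.c_m >= 0,
            f"c_m must be >= 0, got {self.c_m!r}",
        )
        return self

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ReplicationParams":
        return _from_dict(cls, data).validate()

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ReplicationParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ReplicationParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ReplicationParams":
        return cls.from_dict(_load_section(path, "replication"))


@dataclass(frozen=True)
class DamageRepairParams:
    """Kinetic rates of the damage--repair model of non-replicative mutations.

    ``mu`` is the instantaneous rate at which an intact base pair acquires a
    single-strand miscoding lesion (per bp per unit time); ``r`` is the
    instantaneous rate at which the repair machinery recognizes and removes a
    standing lesion.  ``epsilon`` is the fraction of repair events that are
    incorrect, altering the undamaged strand instead (0 in the basic model).
    The dimensionless ratio ``R = r / mu`` is exposed read-only.
    """

    mu: float
    r: float
    epsilon: float = 0.0

    def validate(self) -> "DamageRepairParams":
        _check(np.isfinite(self.mu) and self.mu > 0, f"mu must be > 0, got {self.mu!r}")
        _check(np.isfinite(self.r) and self.r >= 0, f"r must be >= 0, got {self.r!r}")
        _check(
            np.isfinite(self.epsilon) and 0.0 <= self.epsilon <= 1.0,
            f"epsilon must be in [0, 1], got {self.epsilon!r}",
        )
        return self

    @property
    def R(self) -> float:
        """Relative repair rate ``r / mu``."""
        return self.r / self.mu

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "DamageRepairParams":
        return _from_dict(cls, data).validate()

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "DamageRepairParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "DamageRepairParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "DamageRepairParams":
        return cls.from_dict(_load_section(path, "damage"))


@dataclass(frozen=True)
class LineageSchedule:
    """Ordered division times of a single cell lineage.

    Times are years since fertilization; ``sampling_age`` is the age at which
    the lineage is observed (for a germline lineage, the age of reproduction).
    ``stage_labels``, when present, aligns one developmental-stage label with
    each division so the simulator can apply stage-specific error rates.
    """

    division_times: tuple
    sampling_age: float
    stage_labels: Optional[tuple] = None

    def __post_init__(self):
        object.__setattr__(self, "division_times", tuple(float(t) for t in self.division_times))
        if self.stage_labels is not None:
            object.__setattr__(self, "stage_labels", tuple(self.stage_labels))

    def validate(self) -> "LineageSchedule":
        times = np.asarray(self.division_times, dtype=float)
        _check(np.all(times >= 0), "division_times must all be >= 0")
        if times.size > 1:
            _check(
                np.all(np.diff(times) > 0),
                "division_times must be strictly increasing",
            )
        if times.size:
            _check(
                times[-1] <= self.sampling_age,
                "last division time must be <= sampling_age",
            )
        _check(self.sampling_age >= 0, "sampling_age must be >= 0")
        if self.stage_labels is not None:
            _check(
                len(self.stage_labels) == times.size,
                "stage_labels must align one label per division",
            )
        return self

    @property
    def n_divisions(self) -> int:
        return len(self.division_times)

    def intervals(self) -> np.ndarray:
        """Inter-division intervals, from fertilization to the last division."""
        times = np.asarray(self.division_times, dtype=float)
        return np.diff(np.concatenate([[0.0], times]))


def _from_dict(cls, data: dict):
    if not isinstance(data, dict):
        raise ParameterError(f"expected a mapping of {cls.__name__} fields, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ParameterError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    required = {
        f.name
        for f in dataclasses.fields(cls)
        if f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING
    }
    missing = required - set(data)
    if missing:
        raise ParameterError(f"missing {cls.__name__} keys: {sorted(missing)}")
    return cls(**data)


def _load_section(path: Union[str, Path], section: str) -> dict:
    """Load a params file, accepting either a flat mapping or a sectioned one."""
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"params file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if isinstance(data, dict) and section in data and isinstance(data[section], dict):
        return data[section]
    return data


def validate(params):
    """Validate any parameter record, returning it unchanged if all invariants hold."""
    return params.validate()


def human_like_fixture() -> ReplicationParams:
    """An illustrative human-like replication-parameter set.

    The per-division rates and division counts are loosely informed by the
    human germline literature (roughly 30 divisions from fertilization to
    birth, spermatogonial stem cells cycling ~23 times per year, puberty at
    13, spermatogenesis taking ~74 days and 4 divisions) but are illustrative
    placeholders, not estimates: they reproduce the qualitative human picture
    — tens of de novo mutations per generation, a male bias near 3 at a
    paternal age of 30 that grows with age — and satisfy P < G and
    t_sg < G − P for ordinary reproductive ages.  Tests rely on analytic
    identities and stochastic oracles, never on these numbers being "true".
    """
    return ReplicationParams(
        mu0=6e-10,
        mu1=2e-10,
        mu2_f=2e-10,
        mu2_m=2e-10,
        mu3_m=5e-11,
        mu4_m=3e-11,
        d1=15,
        d2_f=15,
        d2_m=15,
        d3_m=4,
        c_m=23.0,
        P=13.0,
        t_sg=0.2,
        d_sg=4,
        H=2.9e9,
    ).validate()


def cpg_like_damage_fixture() -> DamageRepairParams:
    """Illustrative damage--repair rates for a CpG-transition-like lesion class.

    Spontaneous deamination of 5-methylcytosine is slow (here mu = 1e-8 per
    site per year) and, to reproduce the clock-like behaviour of CpG
    transitions, repair is taken to be inefficient on germline inter-division
    timescales (r = 1e-4 per year, so rT << 1 for any realistic T).
    Illustrative values, not estimates.
    """
    return DamageRepairParams(mu=1e-8, r=1e-4, epsilon=0.0).validate()


_RATE_BOUNDS = (1e-12, 1e-8)
_COUNT_RANGES = {
    "d1": (5, 30),
    "d2_f": (5, 40),
    "d2_m": (5, 40),
    "d3_m": (0, 30),
    "d_sg": (1, 6),
}


def random_params(
    seed: int,
    *,
    a_star_sign: Optional[str] = None,
    rate_bounds: tuple = _RATE_BOUNDS,
    H: float = 2.9e9,
) -> ReplicationParams:
    """Draw a random, valid :class:`ReplicationParams` record.

    Deterministic in ``seed``.  Rates are sampled log-uniformly in
    ``rate_bounds`` (per bp per division) and division counts uniformly in
    fixed integer ranges; puberty age, spermatogenesis duration and the
    stem-cell division rate are drawn from plausible mammalian ranges.

    ``a_star_sign`` optionally constrains the sign of the age-zero intercept
    A* of the post-puberty mutation trajectory by solving for ``mu4_m``:
    ``"zero"`` makes A* vanish exactly (up to rounding), ``"positive"`` /
    ``"negative"`` halve / double the solved rate.  The solved ``mu4_m`` must
    land inside ``[0, 1]``; an infeasible constraint raises
    :class:`ParameterError`.
    """
    if a_star_sign not in (None, "zero", "positive", "negative"):
        raise ParameterError(f"a_star_sign must be one of zero/positive/negative, got {a_star_sign!r}")
    rng = np.random.default_rng(seed)
    lo, hi = rate_bounds
    if not (0 < lo <= hi <= 1):
        raise ParameterError(f"infeasible rate_bounds {rate_bounds!r}")

    def rate() -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    counts = {k: int(rng.integers(a, b + 1)) for k, (a, b) in _COUNT_RANGES.items()}
    fields = dict(
        mu0=rate(),
        mu1=rate(),
        mu2_f=rate(),
        mu2_m=rate(),
        mu3_m=rate(),
        mu4_m=rate(),
        c_m=float(rng.uniform(5.0, 40.0)),
        P=float(rng.uniform(8.0, 15.0)),
        t_sg=float(rng.uniform(0.1, 0.3)),
        H=H,
        **counts,
    )
    if a_star_sign is not None:
        # A* = S - mu4_m * (c_m (P + t_sg) - d_sg); solve S = mu4_m * denom.
        s = (
            2 * fields["mu0"]
            + 2 * fields["mu1"] * fields["d1"]
            + fields["mu2_f"] * fields["d2_f"]
            + fields["mu2_m"] * fields["d2_m"]
            + fields["mu3_m"] * fields["d3_m"]
        )
        denom = fields["c_m"] * (fields["P"] + fields["t_sg"]) - fields["d_sg"]
        if denom <= 0:
            raise ParameterError("infeasible a_star constraint: c_m (P + t_sg) <= d_sg")
        factor = {"zero": 1.0, "positive": 0.5, "negative": 2.0}[a_star_sign]
        mu4 = factor * s / denom
        if not 0.0 <= mu4 <= 1.0:
            raise ParameterError(f"infeasible a_star constraint: solved mu4_m = {mu4!r} outside [0, 1]")
        fields["mu4_m"] = mu4
    return ReplicationParams(**fields).validate()


def random_damage_params(
    seed: int,
    *,
    mu_bounds: tuple = (1e-6, 1e-2),
    R_bounds: tuple = (1e-3, 1e3),
    epsilon: Optional[float] = 0.0,
) -> DamageRepairParams:
    """Draw a random, valid :class:`DamageRepairParams` record.

    ``mu`` is log-uniform in ``mu_bounds``, the relative repair rate
    ``R = r/mu`` log-uniform in ``R_bounds`` (so slow- and fast-repair
    regimes are equally represented).  Pass ``epsilon=None`` to draw the
    repair-error fraction log-uniformly in [1e-6, 1e-2].
    """
    rng = np.random.default_rng(seed)
    mu = float(np.exp(rng.uniform(np.log(mu_bounds[0]), np.log(mu_bounds[1]))))
    R = float(np.exp(rng.uniform(np.log(R_bounds[0]), np.log(R_bounds[1]))))
    if epsilon is None:
        epsilon = float(np.exp(rng.uniform(np.log(1e-6), np.log(1e-2))))
    return DamageRepairParams(mu=mu, r=mu * R, epsilon=epsilon).validate()
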