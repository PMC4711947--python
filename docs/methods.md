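# Methods

`mutclock` implements two complementary models of how point mutations
accumulate in a cell lineage — germline or somatic — together with exact
stochastic simulators that reproduce every closed form by brute force.

## 1. Replication-driven mutations (`mutclock.replication`)

### Model

Germ-cell development from fertilization to reproduction is divided into
stages with stage-specific division counts `d_i` and per-division,
per-base-pair error rates `mu_i`:

| stage | span | female | male |
|---|---|---|---|
| 0 | first post-zygotic division | 1 division, rate `mu0` | same |
| 1 | to sexual differentiation | `d1`, `mu1` | same |
| 2 | to birth | `d2_f`, `mu2_f` | `d2_m`, `mu2_m` |
| 3 | birth to puberty `P` | none | `d3_m`, `mu3_m` |
| 4 | puberty to reproduction `G` | none | `c_m (G − P − t_sg) + d_sg`, `mu4_m` |

Stage 0 is singled out because the first cleavage division may be
hypermutable.  Females finish oocytogenesis by birth, so the maternal
genome-wide count `M_f = (mu0 + mu1 d1 + mu2_f d2_f) H` is independent of
maternal age.  Males produce sperm continuously from puberty: spermatogonial
stem cells cycle `c_m` times per year and a final spermatogenesis takes
`t_sg` years and `d_sg` divisions (meiosis counted once — one round of DNA
replication).  The paternal count is therefore linear in `G` with slope
`mu4_m c_m H`.

Derived quantities: the male bias `alpha(G) = M_m / M_f`; the sex-averaged
yearly per-bp rate `m_y(G) = (M_f + M_m) / (2 G H)`, which algebraically
equals `mu4_m c_m / 2 + A* / (2G)` with the age-zero intercept

    A* = 2 mu0 + 2 mu1 d1 + mu2_f d2_f + mu2_m d2_m + mu3_m d3_m
         − mu4_m (c_m P + c_m t_sg − d_sg).

`sign(A*)` alone determines whether a longer generation time lowers
(`A* > 0`), raises (`A* < 0`), or does not change (`A* = 0`) the yearly
rate.  Geometrically, `A* H` is the age-zero intercept of the straight line
through the post-puberty portion of the total count-vs-age curve, which is
why `plotting.post_puberty_intercept` (a least-squares fit to exactly
collinear points) recovers it to rounding error.

Numerical choices: `classify_gt_effect` treats `|A*|` below `1e-12` times
the largest additive term of `A*` as zero — `A*` is a difference of
like-sized products and exact cancellation is only meaningful up to
floating-point error at that scale.  `yearly_rate` divides by `2 G H`
(per bp, averaged over the two inherited genome copies) so that the
per-generation and intercept forms are dimensionally consistent; the two
forms agree to better than `1e-12` relative over random parameter sets.
Ages `G < P + t_sg` are a hard error, not clamped: the stem-cell term would
go negative, which is biologically meaningless.

## 2. Non-replicative mutations (`mutclock.damage_repair`)

A base pair is intact or carries a single-strand miscoding lesion
(prototype: deamination of 5-methylcytosine).  With constant damage rate
`mu` and repair rate `r` per unit time,

    dp1/dt = mu (1 − p1) − r p1,  p1(0) = 0
    ⇒ p1(t) = mu/(mu+r) · (1 − e^{−(mu+r) t}).

A lesion standing at replication fixes a substitution in one of the two
daughters, giving the per-division rate `M(T) = p1(T)/2` for inter-division
time `T`, and the per-time rate `m(c) = c · M(1/c)` at division rate
`c = 1/T`.  Two regimes follow from `rT`:

* `rT << 1` (*time-like*): `M(T) ≈ mu T / 2`; mutations track absolute
  time regardless of division rate — clock-like behaviour.
* `rT >> 1` (*division-like*): `M(T) ≈ mu / (2(mu+r))`; the lesion
  fraction equilibrates each cycle and mutations track divisions,
  mimicking replication errors.

`m(c)` is concave increasing: faster-dividing lineages accumulate more
damage mutations per unit time, but sublinearly (`m(kc)/m(c)` strictly
between 1 and `k`).

The regime thresholds exposed by `regime()` (`rT ≤ 0.01` time-like,
`rT ≥ 100` division-like) are implementation choices: two decades beyond
the asymptotic conditions, where each approximation is comfortably under 1%
of its limiting value.  Exponentials are computed with `expm1` so small
`(mu+r)T` does not cancel.  The model assumes `mu << 1/T`;
`per_division_mutation_rate` warns when `mu T > 0.01`.

### Repair errors (extended model)

A fraction `epsilon` of repair events recognizes the mismatch but alters
the *undamaged* strand, committing the site to a mutation.  States
(intact `p0`, lesioned `p1`, mutated `q`) evolve by the linear system

    dp0/dt = −mu p0 + r (1−eps) p1
    dp1/dt =  mu p0 − r p1
    dq/dt  =  r eps p1

solved by the matrix exponential of the 3-state generator (columns sum to
zero, so `p0 + p1 + q = 1` holds to machine precision).  The per-division
rate becomes `q(T) + p1(T)/2`, which reduces exactly to the basic model at
`epsilon = 0` and, for `epsilon > 0`, keeps growing linearly at rate
`r·eps·mu/(mu+r)` after the equilibrium phase — the plateau is transient,
not permanent, when repair can err.

Design choice: incorrect repair could be booked immediately as a
double-strand mutation, or as a *premutation* (lesion on one strand,
substituted base on the other) fixed at the next replication.  Since a
miscoding lesion templates the same wrong base again, both daughters of a
premutation carry the substitution, so the two conventions give identical
per-division totals and differ only in when within the cell cycle the
mutation is booked.  The simulator implements both behind
`variant={"mutation","premutation"}` (default `"mutation"`); the closed
forms are shared.

## 3. Stochastic simulators (`mutclock.simulator`)

`build_schedule` realizes a lineage as explicit division times: embryonic
stages at configurable timepoints (first cleavage 0.003 yr, sexual
differentiation 0.12 yr, birth 0.75 yr — the closed-form counts do not
depend on these; only damage kinetics do), stem-cell divisions evenly
spaced at `1/c_m` with their number floored (the discrete realization of
the continuous `c_m (G − P − t_sg)` term), and spermatogenesis divisions
inside the final `t_sg` years.

*Replication errors* are Poisson draws per division with mean
`mu_stage · H` — exact for independent per-bp Bernoulli errors at these
rates.  *Damage* is simulated per site as a continuous-time Markov chain
with exact exponential waiting times (no time discretization): damage at
`mu` from intact, repair at `r` from lesioned, an `epsilon` branch to
incorrect repair.  At each division a lesioned site becomes a fixed
mutation in the tracked daughter with probability 1/2.  Mutated sites are
absorbing (infinite sites).  Sites are exchangeable, so only state counts
cross division boundaries; within an interval the event loop is vectorized
over the sites still active.

Oocyte arrest: after her last pre-birth division the female lineage sits
undivided until reproduction at `G`.  Damage accrues through this interval
and standing lesions are resolved at fertilization by the same 1/2 rule as
an ordinary division.  This transmission mechanic is a modelling choice —
nothing in the kinetics dictates how a zygote resolves inherited lesions —
and alternatives (e.g. all-or-none repair at fertilization) would scale the
arrest-interval contribution by a constant without changing its age
dependence.

Damage is simulated on `n_sites` representative sites (default `1e5`) and
scaled by `H / n_sites`; this preserves expectations and inflates
Monte-Carlo noise by `sqrt(H / n_sites)`, which the tests account for by
working in site units.  All randomness flows from a single
`numpy.random.SeedSequence`, so results are bit-for-bit reproducible given
(seed, parameters, version).

## 4. What the generators emulate — and what they do not

`human_like_fixture()` is an *illustrative* human-like parameter set
(~19 maternal and ~54 paternal mutations at age 30, male bias ~2.8 rising
with paternal age, `A* > 0` hence a generation-time effect of decreasing
yearly rate).  It is literature-informed but not an estimate fitted to
pedigree or phylogenetic data; no test treats its numbers as ground truth —
tests rely on analytic identities and simulation oracles.
`random_params` / `random_damage_params` draw rates log-uniformly
(`1e-12`–`1e-8` per bp per division; damage `1e-6`–`1e-2` per unit time
with `R = r/mu` spanning `1e-3`–`1e3`) so both kinetic regimes and both
intercept signs are exercised.

Passing tests therefore demonstrate internal correctness of the models and
their simulators under the stated assumptions — constant rates within
stages, independent sites, infinite-sites accounting, no selection, no
tissue architecture, no inter-individual variation.  They do not
demonstrate that real germline mutagenesis follows these rates; fitting to
real data is explicitly out of scope.

## 5. Problem sizes

The test suite uses `2e5`–`1e6` sites for per-site oracle checks (binomial
standard errors small enough for 3-sigma agreement tests), `1e4` replicate
lineages for the paternal-count oracle, 50 random parameter sets for
identity/concavity properties, and 16 simulated oocyte lineages per
maternal-age scenario; the full suite runs in well under a minute, and
`scripts/acceptance.py` in ~10 s.

## 6. Known limitations

* The stem-cell division count is floored, so simulated paternal
  expectations differ from the continuous closed form by up to
  `mu4_m · H` (sub-mutation for realistic rates); oracle tests use the
  schedule's own expectation.
* The extended model treats incorrect repair as absorbing; re-repair of a
  premutation (ambiguous without a correct template) is not modelled.
* Phase boundaries of the extended model's four-phase time course are
  rendered qualitatively by the plotting module, not derived in closed
  form.
* No transcription-associated strand bias, no parameter inference, no
  clonal dynamics.
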