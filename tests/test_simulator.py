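"""Stochastic lineage simulator: schedules, oracle agreement, reproducibility."""

import math

import numpy as np
import pytest

from mutclock import (
    DamageRepairParams,
    ParameterError,
    ReplicationParams,
    build_schedule,
    human_like_fixture,
    per_division_mutation_rate,
    simulate_damage_sites,
    simulate_germline,
    simulate_replication_errors,
)
from mutclock.replication import T_BIRTH
from mutclock.simulator import stage_rate_map


def schedule_expected_count(p, schedule):
    """Independent expectation oracle: sum stage rates over the actual divisions."""
    rates = stage_rate_map(p)
    return sum(rates[lab] for lab in schedule.stage_labels) * p.H


class TestBuildSchedule:
    def test_female_divisions_all_before_birth(self, fixture_params):
        s = build_schedule(fixture_params, "f", 35.0)
        assert s.n_divisions == 1 + fixture_params.d1 + fixture_params.d2_f
        assert max(s.division_times) <= T_BIRTH

    def test_male_length_tracks_stem_cell_rate(self, fixture_params):
        p = fixture_params
        n30 = build_schedule(p, "m", 30.0).n_divisions
        n31 = build_schedule(p, "m", 31.0).n_divisions
        expected_extra = math.floor(p.c_m * (31 - p.P - p.t_sg) + 1e-9) - math.floor(
            p.c_m * (30 - p.P - p.t_sg) + 1e-9
        )
        assert n31 - n30 == expected_extra

    def test_no_stem_cell_divisions_when_rate_is_zero(self, fixture_params):
        import dataclasses

        p = dataclasses.replace(fixture_params, c_m=0.0)
        for G in (15.0, 30.0, 50.0):
            s = build_schedule(p, "m", G)
            assert s.n_divisions == 1 + p.d1 + p.d2_m + p.d3_m + p.d_sg

    def test_stem_cell_divisions_evenly_spaced(self, fixture_params):
        p = fixture_params
        s = build_schedule(p, "m", 30.0)
        times = np.array(s.division_times)
        labels = np.array(s.stage_labels)
        stem = times[(labels == "s4m")][: -p.d_sg]
        assert np.allclose(np.diff(stem), 1.0 / p.c_m)

    def test_reproduction_too_early_rejected(self, fixture_params):
        with pytest.raises(ParameterError, match="spermatogenesis"):
            build_schedule(fixture_params, "m", 10.0)


class TestDamageSites:
    def test_reproducible_bit_for_bit(self, damage_params):
        a = simulate_damage_sites(damage_params, 1.0, 3, 20_000, seed=42)
        b = simulate_damage_sites(damage_params, 1.0, 3, 20_000, seed=42)
        assert a == b

    def test_tallies_sum_to_total(self, damage_params):
        res = simulate_damage_sites(damage_params, 1.0, 5, 20_000, seed=1)
        assert res.total_tally == sum(res.per_division_tallies)
        assert res.std_error >= 0

    def test_no_repair_single_division_estimates_half_mu_T(self):
        dp = DamageRepairParams(mu=1e-3, r=0.0)
        res = simulate_damage_sites(dp, 2.0, 1, 300_000, seed=7)
        expected = per_division_mutation_rate(dp, 2.0)
        assert abs(res.mean_mutations - expected) <= 3 * res.std_error

    def test_single_division_matches_closed_form(self):
        dp = DamageRepairParams(mu=0.01, r=1.0)
        res = simulate_damage_sites(dp, 1.0, 1, 200_000, seed=11)
        expected = per_division_mutation_rate(dp, 1.0)
        se = math.sqrt(expected * (1 - expected) / 200_000)
        assert abs(res.mean_mutations - expected) <= 3 * se

    def test_many_divisions_additive(self):
        """Infinite-sites accounting: totals are sums of per-division rates."""
        dp = DamageRepairParams(mu=0.01, r=1.0)
        n_div, n_sites = 10, 200_000
        res = simulate_damage_sites(dp, 1.0, n_div, n_sites, seed=13)
        per_div = per_division_mutation_rate(dp, 1.0)
        se_total = math.sqrt(n_div * per_div / n_sites)  # Poisson-scale error on the sum
        assert abs(res.mean_mutations * n_div - per_div * n_div) <= 3 * se_total

    def test_premutation_variant_same_expectation(self):
        """Both incorrect-repair variants fix the site by the next division."""
        dp = DamageRepairParams(mu=0.01, r=1.0, epsilon=0.05)
        a = simulate_damage_sites(dp, 1.0, 1, 200_000, seed=3, variant="mutation")
        b = simulate_damage_sites(dp, 1.0, 1, 200_000, seed=4, variant="premutation")
        se = math.sqrt(2) * max(a.std_error, b.std_error)
        assert abs(a.mean_mutations - b.mean_mutations) <= 3 * se

    def test_bad_inputs_rejected(self, damage_params):
        with pytest.raises(ParameterError):
            simulate_damage_sites(damage_params, 1.0, 0, 100, seed=1)
        with pytest.raises(ParameterError):
            simulate_damage_sites(damage_params, 1.0, 1, 0, seed=1)
        with pytest.raises(ParameterError, match="variant"):
            simulate_damage_sites(damage_params, 1.0, 1, 100, seed=1, variant="bogus")


class TestReplicationErrors:
    def test_zero_rates_give_zero_always(self):
        p = ReplicationParams(
            mu0=0.0, mu1=0.0, mu2_f=0.0, mu2_m=0.0, mu3_m=0.0, mu4_m=0.0,
            d1=5, d2_f=5, d2_m=5, d3_m=2, c_m=10.0, P=12.0, t_sg=0.2, d_sg=3, H=1e9,
        )
        s = build_schedule(p, "m", 30.0)
        res = simulate_replication_errors(p, s, seed=5, n_replicates=50)
        assert res.mean_mutations == 0.0 and res.total_tally == 0

    def test_mean_matches_schedule_expectation(self, fixture_params):
        p = fixture_params
        s = build_schedule(p, "m", 30.0)
        res = simulate_replication_errors(p, s, seed=21, n_replicates=3000)
        expected = schedule_expected_count(p, s)
        assert abs(res.mean_mutations - expected) <= 3 * res.std_error

    def test_poisson_variance_matches_mean(self):
        p = ReplicationParams(
            mu0=0.0, mu1=1e-9, mu2_f=0.0, mu2_m=0.0, mu3_m=0.0, mu4_m=0.0,
            d1=20, d2_f=0, d2_m=0, d3_m=0, c_m=0.0, P=12.0, t_sg=0.0, d_sg=0, H=1e9,
        )
        s = build_schedule(p, "f", 30.0)
        n = 4000
        res = simulate_replication_errors(p, s, seed=9, n_replicates=n)
        var = (res.std_error**2) * n
        assert var == pytest.approx(res.mean_mutations, rel=0.15)

    def test_schedule_without_labels_rejected(self, fixture_params):
        from mutclock import LineageSchedule

        bare = LineageSchedule(division_times=(0.1, 0.2), sampling_age=30.0)
        with pytest.raises(ParameterError, match="stage_labels"):
            simulate_replication_errors(fixture_params, bare, seed=1)

    def test_reproducible_bit_for_bit(self, fixture_params):
        s = build_schedule(fixture_params, "m", 25.0)
        a = simulate_replication_errors(fixture_params, s, seed=2, n_replicates=10)
        b = simulate_replication_errors(fixture_params, s, seed=2, n_replicates=10)
        assert a == b


class TestGermline:
    def test_account_totals_decompose(self, fixture_params):
        dp = DamageRepairParams(mu=1e-3, r=1.0)
        acc = simulate_germline(fixture_params, dp, "f", 30.0, seed=6, n_sites=20_000)
        assert acc.total == pytest.approx(acc.replicative_total + acc.damage_total)
        assert all(v >= 0 for v in acc.replicative.values())
        assert all(v >= 0 for v in acc.damage_induced.values())

    def test_replicative_part_matches_analytic_oracle(self, fixture_params):
        p = fixture_params
        dp = DamageRepairParams(mu=1e-6, r=1.0)
        s = build_schedule(p, "f", 30.0)
        expected = schedule_expected_count(p, s)
        reps = 400
        acc = simulate_germline(p, dp, "f", 30.0, seed=8, n_sites=1000, n_replicates=reps)
        se = math.sqrt(expected / reps)  # Poisson
        assert abs(acc.replicative_total - expected) <= 3.5 * se

    def test_unrepaired_lesions_accumulate_with_maternal_age(self, fixture_params):
        dp = DamageRepairParams(mu=1e-3, r=0.0)
        young = simulate_germline(fixture_params, dp, "f", 20.0, seed=10, n_sites=50_000)
        old = simulate_germline(fixture_params, dp, "f", 50.0, seed=10, n_sites=50_000)
        assert old.damage_total > 1.5 * young.damage_total

    def test_efficient_repair_plateaus_with_maternal_age(self, fixture_params):
        # rT >> 1 in every interval: standing lesions are at equilibrium at any age
        import dataclasses

        p = dataclasses.replace(fixture_params, d1=5, d2_f=5)
        dp = DamageRepairParams(mu=0.4, r=2000.0)
        n_sites = 200_000
        plateau = 0.5 * dp.mu / (dp.mu + dp.r) * p.H
        scale = p.H / n_sites
        se = math.sqrt(plateau / scale) * scale
        for G, seed in ((20.0, 12), (50.0, 13)):
            acc = simulate_germline(p, dp, "f", G, seed=seed, n_sites=n_sites)
            arrest = acc.damage_induced.get("arrest", 0.0)
            assert abs(arrest - plateau) <= 4 * se
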