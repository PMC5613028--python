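"""Telegraph-model simulator, moment oracle and rate inversion."""

import math

import numpy as np
import pytest

from agingnoise.model import (
    GAL1_RATES,
    InfeasibleNoiseError,
    KineticRates,
    ModelState,
    ParameterError,
    PromoterRates,
    constitutive_cv_floor,
    default_t_end,
    ensemble_stats,
    fit_promoter_rates,
    moment_oracle,
    simulate_ssa,
    telegraph_closed_forms,
)

KIN = KineticRates()


class TestMomentOracle:
    def test_matches_closed_forms_on_grid(self):
        """Linear-system moments equal the telegraph closed forms on a 5x5
        grid spanning [r/8, 8r] around the fitted GAL1 rates."""
        for r_on in np.geomspace(GAL1_RATES.r_on / 8, GAL1_RATES.r_on * 8, 5):
            for r_off in np.geomspace(GAL1_RATES.r_off / 8, GAL1_RATES.r_off * 8, 5):
                rates = PromoterRates(r_on, r_off)
                mom = moment_oracle(rates, KIN)
                cf = telegraph_closed_forms(rates, KIN)
                assert mom.p_on == pytest.approx(cf["p_on"], rel=1e-10)
                assert mom.mean_m == pytest.approx(cf["mean_m"], rel=1e-10)
                assert mom.fano_m == pytest.approx(cf["fano_m"], rel=1e-10)
                assert mom.mean_p == pytest.approx(cf["mean_p"], rel=1e-10)

    def test_symmetric_rates_give_half_occupancy(self):
        mom = moment_oracle(PromoterRates(0.7, 0.7), KIN)
        assert mom.p_on == pytest.approx(0.5, rel=1e-12)

    def test_constitutive_promoter_is_poissonian_in_mrna(self):
        mom = moment_oracle(PromoterRates(0.3, 0.0), KIN)
        assert mom.fano_m == pytest.approx(1.0, rel=1e-10)

    def test_gal1_point_values(self):
        """Occupancy ~0.3969, mean mRNA ~7.938, mRNA Fano ~6.600 at the
        fitted GAL1 rates with k_m = 1/min, gamma_m = 0.05/min."""
        mom = moment_oracle(GAL1_RATES, KineticRates(k_m=1.0, gamma_m=0.05))
        assert mom.p_on == pytest.approx(0.3969, abs=5e-5)
        assert mom.mean_m == pytest.approx(7.938, abs=5e-4)
        assert mom.fano_m == pytest.approx(6.600, abs=5e-4)

    def test_variances_nonnegative_and_cov_finite(self):
        mom = moment_oracle(GAL1_RATES, KIN)
        assert mom.var_m > 0 and mom.var_p > 0 and np.isfinite(mom.cov_mp)

    @pytest.mark.parametrize("kin", [
        KineticRates(gamma_m=0.0), KineticRates(gamma_p=0.0),
    ])
    def test_zero_degradation_raises(self, kin):
        with pytest.raises(ParameterError):
            moment_oracle(GAL1_RATES, kin)

    def test_pinned_promoter_raises(self):
        with pytest.raises(ParameterError):
            moment_oracle(PromoterRates(0.0, 0.0), KIN)


class TestScalingMechanism:
    """The mean-conserving noise-reduction mechanism, exactly at the oracle."""

    def test_common_scaling_preserves_mean_reduces_noise(self):
        base = moment_oracle(GAL1_RATES, KIN)
        prev_fano, prev_cv = base.fano_p, base.cv_p
        for c in (2.0, 4.0, 8.0, 16.0):
            mom = moment_oracle(GAL1_RATES.scaled(c), KIN)
            assert mom.mean_p == pytest.approx(base.mean_p, rel=1e-10)
            assert mom.fano_p < prev_fano
            assert mom.cv_p < prev_cv
            prev_fano, prev_cv = mom.fano_p, mom.cv_p

    def test_increasing_r_on_increases_mean(self):
        means = [
            moment_oracle(PromoterRates(r_on, GAL1_RATES.r_off), KIN).mean_p
            for r_on in np.geomspace(0.005, 0.2, 6)
        ]
        assert all(b > a for a, b in zip(means, means[1:]))


class TestSimulateSsa:
    def test_zero_propensity_freezes_state(self):
        traj = simulate_ssa(
            PromoterRates(0, 0), KineticRates(0, 0, 0, 0),
            t_end=100, sample_interval=10,
            init=ModelState(promoter=1, m=5, p=7), seed=1,
        )
        assert np.all(traj.promoter == 1)
        assert np.all(traj.m == 5)
        assert np.all(traj.p == 7)
        assert traj.t[-1] == 100.0

    def test_unreachable_species_stays_zero(self):
        traj = simulate_ssa(
            GAL1_RATES, KineticRates(k_p=0.0),
            t_end=500, sample_interval=10,
            init=ModelState(promoter=1, m=3, p=0), seed=2,
        )
        assert np.all(traj.p == 0)

    def test_identical_seeds_bit_identical(self):
        a = simulate_ssa(GAL1_RATES, KIN, 300, 10, seed=9)
        b = simulate_ssa(GAL1_RATES, KIN, 300, 10, seed=9)
        c = simulate_ssa(GAL1_RATES, KIN, 300, 10, seed=10)
        assert np.array_equal(a.p, b.p) and np.array_equal(a.m, b.m)
        assert not np.array_equal(a.p, c.p)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ParameterError):
            PromoterRates(-0.1, 0.2)
        with pytest.raises(ParameterError):
            simulate_ssa(GAL1_RATES, KIN, t_end=-5, sample_interval=1)


class TestEnsembleStats:
    def test_frozen_ensemble_is_deterministic(self):
        es = ensemble_stats(
            PromoterRates(0, 0), KineticRates(0, 0, 0, 0),
            n_reps=50, t_end=100, seed=3, init=ModelState(promoter=1, m=0, p=7),
        )
        assert es.mean_p == 7.0
        assert es.cv_p == 0.0
        assert es.fano_p == 0.0

    def test_zero_mean_flagged_not_silent(self):
        es = ensemble_stats(
            PromoterRates(0, 0), KineticRates(0, 0, 0, 0),
            n_reps=10, t_end=50, seed=4, init=ModelState(promoter=0, m=0, p=0),
        )
        assert es.degenerate
        assert math.isnan(es.cv_p) and math.isnan(es.fano_p)

    def test_mean_matches_oracle_within_monte_carlo_error(self):
        mom = moment_oracle(GAL1_RATES, KIN)
        es = ensemble_stats(GAL1_RATES, KIN, n_reps=500, seed=5)
        assert abs(es.mean_p - mom.mean_p) < 4 * es.sem_mean

    def test_different_master_seed_changes_draws_not_mean(self):
        a = ensemble_stats(GAL1_RATES, KIN, n_reps=500, seed=6)
        b = ensemble_stats(GAL1_RATES, KIN, n_reps=500, seed=12)
        assert a.mean_p != b.mean_p  # different streams
        assert abs(a.mean_p - b.mean_p) < 3 * (a.sem_mean + b.sem_mean)


class TestFitPromoterRates:
    def test_oracle_round_trip(self):
        mom = moment_oracle(GAL1_RATES, KIN)
        fitted = fit_promoter_rates(mom.mean_p, mom.cv_p, KIN)
        assert fitted.r_on == pytest.approx(GAL1_RATES.r_on, rel=1e-6)
        assert fitted.r_off == pytest.approx(GAL1_RATES.r_off, rel=1e-6)

    def test_constitutive_boundary_returns_zero_r_off(self):
        mean_on = KIN.k_m * KIN.k_p / (KIN.gamma_m * KIN.gamma_p)
        floor = constitutive_cv_floor(mean_on, KIN)
        fitted = fit_promoter_rates(mean_on, floor, KIN)
        assert fitted.r_off == 0.0

    def test_below_floor_infeasible_reports_floor(self):
        mom = moment_oracle(GAL1_RATES, KIN)
        floor = constitutive_cv_floor(mom.mean_p, KIN)
        with pytest.raises(InfeasibleNoiseError) as exc:
            fit_promoter_rates(mom.mean_p, 0.5 * floor, KIN)
        assert exc.value.floor == pytest.approx(floor)

    def test_default_t_end_covers_slowest_timescale(self):
        t_end = default_t_end(GAL1_RATES, KIN)
        assert t_end >= 10 / KIN.gamma_p
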