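"""Ensemble pipeline: growth curves, switch statistics, knockouts, fitting."""

import numpy as np
import pytest

from crowdfba.core import GLUCOSE_MOLAR_MASS, SolverConfig, solve_fbawmc
from crowdfba.crowding import CrowdingAssignment, degenerate_distribution, sample_crowding
from crowdfba.efm import best_mode, enumerate_elementary_modes
from crowdfba.experiments import (
    GrowthCurve,
    GrowthCurvePoint,
    ObservedGrowth,
    add_overexpression,
    classify_low_yield,
    count_metabolic_modes,
    excretion_profile,
    fit_vprot,
    flux_decrease_statistic,
    growth_curve,
    knockout_exchange,
    nox_reaction,
    run_ensemble,
)
from crowdfba.synthetic_data import generate_observed_growth

from conftest import uniform_assignment


class TestGrowthCurve:
    def test_no_carbon_no_growth(self, simplified, config):
        a = uniform_assignment(simplified, 0.1)
        curve = growth_curve(simplified, a, config, [0.0])
        assert curve.points[0].growth_rate == pytest.approx(0.0, abs=1e-9)
        assert curve.points[0].growth_yield == 0.0

    def test_growth_nondecreasing_in_glucose(self, simplified, config):
        a = uniform_assignment(simplified, 0.1)
        curve = growth_curve(simplified, a, config, np.linspace(0, 3, 10))
        mu = [p.growth_rate for p in curve.points]
        assert all(b >= a_ - 1e-9 for a_, b in zip(mu, mu[1:]))

    def test_saturation_level_matches_mode_ratio(self, simplified, simplified_modes, config):
        # once crowding binds, growth plateaus at V_prot times the best
        # ATP-per-cost mode ratio (independently enumerated)
        a = uniform_assignment(simplified, 0.1)
        _, ratio = best_mode(simplified_modes, "ATPM", a.coefficients)
        plateau = config.v_prot * ratio
        curve = growth_curve(simplified, a, config, [1e4])
        assert curve.points[0].growth_rate == pytest.approx(plateau, rel=1e-8)

    def test_saturation_point_location(self, simplified, simplified_modes, config):
        # below the saturating glucose bound the best-yield mode runs
        # glucose-limited; the curve must still be glucose-limited just
        # under the bound where the *max-yield* mode's cost reaches V_prot
        a = uniform_assignment(simplified, 0.1)
        top = max(
            simplified_modes,
            key=lambda m: m.normalized("EX_glc").objective_flux("ATPM"),
        ).normalized("EX_glc")
        g_sat = config.v_prot / top.crowding_cost(a.coefficients)
        curve = growth_curve(simplified, a, config, [0.99 * g_sat])
        expected = 0.99 * g_sat * top.objective_flux("ATPM")
        assert curve.points[0].growth_rate == pytest.approx(expected, rel=1e-6)


class TestFluxDecrease:
    @staticmethod
    def curve_from(reporter_fluxes, growth):
        points = [
            GrowthCurvePoint(
                glucose_bound=float(i),
                growth_rate=g,
                growth_yield=0.0,
                reporter_fluxes={"EX_o2": -f},
            )
            for i, (f, g) in enumerate(zip(reporter_fluxes, growth))
        ]
        return GrowthCurve(points)

    def test_hand_example(self):
        # reporter 5, 10, 8 with maximal growth last: (10 - 8) / 10 = 0.2
        stat = flux_decrease_statistic(self.curve_from([5, 10, 8], [1, 2, 3]), "EX_o2")
        assert stat.flux_decrease == pytest.approx(0.2)

    def test_monotone_reporter_gives_zero(self):
        stat = flux_decrease_statistic(self.curve_from([1, 2, 3], [1, 2, 3]), "EX_o2")
        assert stat.flux_decrease == 0.0

    def test_full_shutdown_gives_one(self):
        stat = flux_decrease_statistic(self.curve_from([4, 9, 0], [1, 2, 3]), "EX_o2")
        assert stat.flux_decrease == 1.0

    def test_inactive_reporter_flagged(self):
        stat = flux_decrease_statistic(self.curve_from([0, 0, 0], [1, 2, 3]), "EX_o2")
        assert stat.flux_decrease == 0.0
        assert not stat.reporter_active

    def test_growth_plateau_evaluates_last_point(self):
        # ties in maximal growth resolve to the terminal, crowding-limited point
        stat = flux_decrease_statistic(self.curve_from([5, 10, 6], [1, 3, 3]), "EX_o2")
        assert stat.flux_decrease == pytest.approx(0.4)


class TestClassification:
    @pytest.mark.parametrize("y,expected", [(0.29, True), (0.30, False), (0.5, False), (0.0, True)])
    def test_low_yield_threshold_strict(self, y, expected):
        assert classify_low_yield(y) is expected

    def test_excretion_profiles(self, simplified, config):
        def sol_with(ac, waste):
            model = simplified.copy()
            model.set_uptake_bound("EX_glc", config.big_bound)
            a = uniform_assignment(model, 1.0)
            s = solve_fbawmc(model, a, config)
            s.fluxes = dict(s.fluxes)
            s.fluxes["EX_ac"], s.fluxes["EX_waste"] = ac, waste
            return s

        profile = lambda s: excretion_profile(s, lactate_exchange="EX_waste", ethanol_exchange=None)
        assert profile(sol_with(2.0, 0.0)) == "acetate_only"
        assert profile(sol_with(0.0, 0.0)) == "none"
        assert profile(sol_with(1.0, 1.0)) == "mixed"
        assert profile(sol_with(0.0, 1.5)) == "lactate_or_ethanol"


class TestKnockout:
    def test_knockout_forces_zero_flux(self, simplified, moderate_dist, config):
        ko = knockout_exchange(simplified, "EX_ac")
        ko.set_uptake_bound("EX_glc", config.big_bound)
        for seed in range(3):
            a = sample_crowding(ko, moderate_dist, seed)
            sol = solve_fbawmc(ko, a, config)
            assert sol.optimal
            assert sol.fluxes["EX_ac"] == pytest.approx(0.0, abs=1e-9)

    def test_idempotent_and_nonmutating(self, simplified):
        before = simplified.copy()
        ko1 = knockout_exchange(simplified, "EX_ac")
        ko2 = knockout_exchange(ko1, "EX_ac")
        assert simplified == before
        assert ko1 == ko2

    def test_acetate_modes_never_win_after_knockout(self, simplified, moderate_dist, config):
        ko = knockout_exchange(simplified, "EX_ac")
        modes = enumerate_elementary_modes(ko)
        ko_run = ko.copy()
        ko_run.set_uptake_bound("EX_glc", config.big_bound)
        for seed in range(10):
            a = sample_crowding(ko, moderate_dist, seed)
            winner, _ = best_mode(modes, "ATPM", a.coefficients)
            assert "R_acetate" not in winner.support()
            sol = solve_fbawmc(ko_run, a, config)
            assert sol.fluxes["R_acetate"] == pytest.approx(0.0, abs=1e-9)


class TestOverexpression:
    def test_inactive_addition_changes_nothing(self, simplified, config):
        model = simplified.copy()
        model.set_uptake_bound("EX_glc", 1.0)
        plus = add_overexpression(model, nox_reaction(), min_flux=0.0)
        a0 = CrowdingAssignment({r.id: 0.0 for r in plus.reactions})
        mu_plus = solve_fbawmc(plus, a0, config).growth_rate
        a1 = CrowdingAssignment({r.id: 0.0 for r in model.reactions})
        assert mu_plus == pytest.approx(solve_fbawmc(model, a1, config).growth_rate)

    def test_min_flux_enforced(self, simplified, moderate_dist, config):
        plus = add_overexpression(simplified, nox_reaction(), min_flux=0.5)
        plus.set_uptake_bound("EX_glc", config.big_bound)
        a = sample_crowding(plus, moderate_dist, seed=4)
        sol = solve_fbawmc(plus, a, config)
        assert sol.optimal
        assert sol.fluxes["NOX"] >= 0.5 - 1e-9

    def test_input_never_mutated(self, simplified):
        before = simplified.copy()
        add_overexpression(simplified, nox_reaction(), min_flux=1.0)
        assert simplified == before

    def test_forced_nox_weakly_reduces_waste_fermentation(self, simplified, moderate_dist, config):
        # an NADH sink substitutes for fermentative reoxidation: with the
        # same coefficient draws, forced NOX flux can only divert flux away
        # from the NADH-consuming waste branch
        base = simplified.copy()
        base.set_uptake_bound("EX_glc", config.big_bound)
        for seed in range(8):
            a = sample_crowding(simplified, moderate_dist, seed)
            waste0 = solve_fbawmc(base, a, config).fluxes["R_waste"]
            plus = add_overexpression(simplified, nox_reaction(), min_flux=2.0)
            plus.set_uptake_bound("EX_glc", config.big_bound)
            a_plus = sample_crowding(plus, moderate_dist, seed)
            assert a_plus.coefficients["R_waste"] == a.coefficients["R_waste"]
            sol = solve_fbawmc(plus, a_plus, config)
            if sol.optimal:
                assert sol.fluxes["R_waste"] <= waste0 + 1e-6


class TestEnsemble:
    def test_reproducible_from_master_seed(self, simplified, moderate_dist, config):
        e1 = run_ensemble(simplified, moderate_dist, config, 5, master_seed=9)
        e2 = run_ensemble(simplified, moderate_dist, config, 5, master_seed=9)
        assert e1 == e2

    def test_degenerate_distribution_gives_identical_yields(self, simplified, config):
        ens = run_ensemble(simplified, degenerate_distribution(0.1), config, 6, 0)
        assert np.ptp(ens.yields) == pytest.approx(0.0, abs=1e-9)

    def test_yields_bounded_by_max_fba_yield(self, simplified, moderate_dist, config):
        # crowding reallocates flux between modes but cannot beat the
        # stoichiometric optimum: 24 ATP/glc = 24/0.18016 in yield units
        ens = run_ensemble(simplified, moderate_dist, config, 20, 3)
        assert ens.yields.max() <= 24.0 / GLUCOSE_MOLAR_MASS + 1e-6

    def test_distinct_yields_at_most_mode_count(self, simplified, simplified_modes, synthetic_dist, config):
        ens = run_ensemble(simplified, synthetic_dist, config, 50, 17)
        distinct = count_metabolic_modes(ens, rel_tol=1e-6, min_freq=0.0)
        assert distinct <= len(simplified_modes)

    def test_switch_statistics_recorded(self, simplified, moderate_dist, config):
        ens = run_ensemble(
            simplified, moderate_dist, config, 3, 1,
            glucose_grid=np.linspace(0.0, 50.0, 6), reporter="EX_o2",
        )
        for s in ens.samples:
            assert s.switch is not None
            assert 0.0 <= s.switch.flux_decrease <= 1.0


class TestModeCounting:
    def test_single_cluster(self):
        assert count_metabolic_modes(np.full(100, 0.4)) == 1

    def test_two_separated_clusters(self):
        values = np.concatenate([np.full(50, 0.1), np.full(50, 0.5)])
        assert count_metabolic_modes(values, rel_tol=0.01, min_freq=0.01) == 2

    def test_rare_cluster_discarded(self):
        values = np.concatenate([np.full(995, 0.1), np.full(5, 0.5)])
        assert count_metabolic_modes(values, min_freq=0.01) == 1

    def test_matches_winning_mode_count_on_toy(self, simplified, simplified_modes, synthetic_dist, config):
        # the cluster count must equal the number of distinct modes that
        # win the ATP-per-cost race over the same coefficient draws
        from crowdfba.experiments import derive_seeds

        ens = run_ensemble(simplified, synthetic_dist, config, 200, 23)
        winners = set()
        for seed in derive_seeds(23, 200):
            a = sample_crowding(simplified, synthetic_dist, seed)
            winner, _ = best_mode(simplified_modes, "ATPM", a.coefficients)
            winners.add(winner.support())
        assert count_metabolic_modes(ens, min_freq=0.0) == len(winners)


class TestFitVprot:
    def test_exact_recovery_with_degenerate_distribution(self, simplified, config):
        dist = degenerate_distribution(0.2)
        grid = [round(v, 2) for v in np.arange(0.10, 0.21, 0.01)]
        observed = generate_observed_growth(simplified, dist, config, 0.15, n=5, seed=99)
        fitted = fit_vprot(simplified, dist, observed, grid, n=5, master_seed=7)
        assert fitted == pytest.approx(0.15)

    def test_argmin_contract(self, simplified, moderate_dist):
        observed = ObservedGrowth(mu_max_obs=1.0, gup_max_obs=0.5)
        grid = [0.1, 0.15, 0.2]
        fitted, profile = fit_vprot(
            simplified, moderate_dist, observed, grid, n=10, master_seed=5,
            return_profile=True,
        )
        best = profile.loc[profile["criterion"].idxmin(), "v_prot"]
        assert fitted == best
        assert (profile["criterion"] >= profile["criterion"].min()).all()

    def test_observed_growth_increases_with_v_prot(self, simplified, config):
        dist = degenerate_distribution(0.2)
        obs = [
            generate_observed_growth(simplified, dist, config, v, n=3, seed=1).mu_max_obs
            for v in (0.1, 0.2, 0.4)
        ]
        assert obs[0] < obs[1] < obs[2]
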