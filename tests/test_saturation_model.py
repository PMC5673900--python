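"""Speciation, saturation index, and remineralization titration."""

import math

import numpy as np
import pytest

import pelagicbarite as pb
from pelagicbarite.profiles_io import ValidationError
from pelagicbarite.saturation_model import Ion, MajorIonSolution, ThermoPreset


def simple_solution(ions, T=4.3, pH=8.11):
    return MajorIonSolution(
        ions=[Ion(name, charge, conc) for name, charge, conc in ions],
        temperature_C=T,
        pH=pH,
    )


class TestIonicStrength:
    def test_pure_water(self):
        assert pb.ionic_strength(simple_solution([])) == 0.0

    def test_one_one_electrolyte(self):
        sol = simple_solution([("Na+", 1, 1e-3), ("Cl-", -1, 1e-3)])
        assert pb.ionic_strength(sol) == pytest.approx(1.0e-3)

    def test_two_two_electrolyte(self):
        sol = simple_solution([("Mg+2", 2, 1e-3), ("SO4-2", -2, 1e-3)])
        assert pb.ionic_strength(sol) == pytest.approx(4.0e-3)


class TestActivityCoefficient:
    def test_infinite_dilution(self):
        assert pb.activity_coefficient(2, 0.0, 25.0) == 1.0

    def test_divalent_at_dilute_lake_strength(self):
        # direct Davies evaluation: A = 0.51, z = 2, I = 1.5e-3
        thermo = ThermoPreset(davies_A_coeffs=(0.51, 0.0, 0.0))
        s = math.sqrt(1.5e-3)
        expected = 10 ** (-0.51 * 4 * (s / (1 + s) - 0.3 * 1.5e-3))
        got = pb.activity_coefficient(2, 1.5e-3, 25.0, thermo)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.84, abs=0.01)

    def test_strictly_decreasing_in_ionic_strength(self):
        grid = np.linspace(0.0, 0.1, 200)
        gammas = [pb.activity_coefficient(2, i, 4.3) for i in grid]
        assert np.all(np.diff(gammas) < 0)

    def test_warns_outside_validity(self, caplog):
        with caplog.at_level("WARNING", logger="pelagicbarite"):
            pb.activity_coefficient(1, 0.6, 25.0)
        assert "validity" in caplog.text


class TestOmegaBarite:
    def test_ambient_lake_superior_is_two_percent_saturated(self, ambient):
        solution, thermo = ambient
        assert round(pb.omega_barite(solution, thermo), 2) == 0.02

    def test_zero_barium_means_zero_omega(self, ambient):
        solution, thermo = ambient
        assert pb.omega_barite(solution.with_concentration("Ba+2", 0.0), thermo) == 0.0

    def test_bilinear_in_ion_product_at_fixed_ionic_strength(self, ambient):
        # double Ba and SO4 while trimming the inert background so I (and
        # hence gamma) is unchanged: Omega must exactly quadruple
        solution, thermo = ambient
        d_ba = solution.concentration("Ba+2")
        doubled = (
            solution.with_concentration("Ba+2", 2 * d_ba)
            .with_concentration("SO4-2", 2 * 4.0e-5)
            # remove 0.5 * 4 * (4e-5 + d_ba) of I via the divalent background
            .with_concentration("Mg+2", 1.15e-4 - (4.0e-5 + d_ba))
        )
        assert pb.ionic_strength(doubled) == pytest.approx(
            pb.ionic_strength(solution), rel=1e-12
        )
        ratio = pb.omega_barite(doubled, thermo) / pb.omega_barite(solution, thermo)
        assert ratio == pytest.approx(4.0, rel=1e-9)

    def test_preset_charge_balance_within_five_percent(self, ambient):
        solution, _ = ambient
        assert solution.charge_imbalance() < 0.05

    def test_ksp_monotone_over_lake_temperatures(self):
        thermo = ThermoPreset()
        temps = np.linspace(0, 30, 61)
        assert np.all(np.diff([thermo.ksp(t) for t in temps]) > 0)


def quadratic_oracle_x(solution, thermo, s_p, ba_p_mM_M=0.44, target=1.0):
    """Closed-form saturation point with gamma frozen at ambient:
    (Ba0 + r x)(S0 + q x) = target * Ksp / gamma^2."""
    ba0 = solution.concentration("Ba+2")
    s0 = solution.concentration("SO4-2")
    g = pb.activity_coefficient(2, pb.ionic_strength(solution),
                                solution.temperature_C, thermo)
    k = target * thermo.ksp(solution.temperature_C) / g**2
    r, q = ba_p_mM_M * 1e-3, s_p
    # r q x^2 + (ba0 q + s0 r) x + (ba0 s0 - k) = 0
    roots = np.roots([r * q, ba0 * q + s0 * r, ba0 * s0 - k])
    return float(max(roots))


class TestTitration:
    def test_already_saturated_needs_nothing(self, ambient):
        solution, thermo = ambient
        rich = solution.with_concentration("Ba+2", 1e-3).with_concentration(
            "SO4-2", 1e-3
        )
        res = pb.titrate_remineralization(rich, thermo=thermo)
        assert res.x_p == 0.0
        assert res.frac_sulfate_from_remin == 0.0
        assert res.frac_ba_from_remin == 0.0

    def test_frozen_gamma_matches_quadratic_oracle(self, ambient):
        solution, thermo = ambient
        for s_p in (1.0, 1.5, 2.5):
            res = pb.titrate_remineralization(
                solution, pb.TitrationScenario("both", 0.44, s_p), thermo,
                freeze_gamma=True,
            )
            oracle = quadratic_oracle_x(solution, thermo, s_p)
            assert res.x_p == pytest.approx(oracle, rel=1e-6)

    def test_saturation_reached_within_solver_tolerance(self, ambient):
        solution, thermo = ambient
        res = pb.titrate_remineralization(solution, thermo=thermo)
        assert res.omega_final == pytest.approx(1.0, rel=1e-6)

    def test_omega_strictly_increases_along_trajectory(self, ambient):
        solution, thermo = ambient
        for mode in ("both", "sulfate_only", "ba_only"):
            res = pb.titrate_remineralization(
                solution, pb.TitrationScenario(mode, 0.44, 1.5), thermo
            )
            assert np.all(np.diff(res.trajectory["omega"]) > 0)

    def test_both_ions_need_least_remineralization(self, ambient):
        solution, thermo = ambient
        for s_p in np.linspace(1.0, 2.5, 4):
            x = {
                mode: pb.titrate_remineralization(
                    solution, pb.TitrationScenario(mode, 0.44, s_p), thermo
                ).x_p
                for mode in ("both", "sulfate_only", "ba_only")
            }
            assert x["both"] <= min(x["sulfate_only"], x["ba_only"])

    def test_fraction_monotonicity_in_stoichiometry(self, ambient):
        solution, thermo = ambient
        grid = np.linspace(1.0, 2.5, 7)
        results = [
            pb.titrate_remineralization(
                solution, pb.TitrationScenario("both", 0.44, s_p), thermo
            )
            for s_p in grid
        ]
        sulfate = [r.frac_sulfate_from_remin for r in results]
        barium = [r.frac_ba_from_remin for r in results]
        assert np.all(np.diff(sulfate) > 0)
        assert np.all(np.diff(barium) < 0)

    def test_result_independent_of_solver_tolerance_refinement(self, ambient):
        solution, thermo = ambient
        loose = pb.titrate_remineralization(solution, thermo=thermo, rtol=1e-6)
        tight = pb.titrate_remineralization(solution, thermo=thermo, rtol=1e-12)
        assert loose.x_p == pytest.approx(tight.x_p, rel=1e-6)

    def test_unreachable_target_errors(self, ambient):
        solution, thermo = ambient
        no_sulfate = solution.with_concentration("SO4-2", 0.0)
        with pytest.raises(ValidationError):
            pb.titrate_remineralization(
                no_sulfate, pb.TitrationScenario("ba_only", 0.44, 1.0), thermo
            )

    def test_scale_invariance_of_fractions_at_unit_gamma(self):
        """With gamma = 1 throughout, the fractions at saturation depend
        only on the ambient saturation state and the stoichiometry-to-
        ambient ratios, not the absolute concentration scale."""
        thermo = ThermoPreset(davies_A_coeffs=(0.0, 0.0, 0.0))
        base = simple_solution([("Ba+2", 2, 69.7e-9), ("SO4-2", -2, 4.0e-5)])
        omega0 = pb.omega_barite(base, thermo)
        scaled = simple_solution([("Ba+2", 2, 10 * 69.7e-9), ("SO4-2", -2, 10 * 4.0e-5)])
        # scale Ksp x100 so Omega0 is unchanged; S:P and Ba:P scale x10
        thermo100 = ThermoPreset(
            log10_ksp_25C=thermo.log10_ksp_25C + 2, davies_A_coeffs=(0.0, 0.0, 0.0)
        )
        assert pb.omega_barite(scaled, thermo100) == pytest.approx(omega0)
        a = pb.titrate_remineralization(
            base, pb.TitrationScenario("both", 0.44, 1.0), thermo
        )
        b = pb.titrate_remineralization(
            scaled, pb.TitrationScenario("both", 4.4, 10.0), thermo100
        )
        assert a.frac_sulfate_from_remin == pytest.approx(
            b.frac_sulfate_from_remin, rel=1e-9
        )
        assert a.frac_ba_from_remin == pytest.approx(b.frac_ba_from_remin, rel=1e-9)


class TestScenarioMultiplier:
    def test_single_ion_always_needs_more(self, ambient):
        solution, thermo = ambient
        for mode in ("sulfate_only", "ba_only"):
            assert pb.scenario_multiplier(solution, 1.0, thermo, mode) > 1.0

    def test_same_scenario_gives_unity(self, ambient):
        solution, thermo = ambient
        assert pb.scenario_multiplier(solution, 1.0, thermo, "both") == pytest.approx(1.0)

    def test_fixed_gamma_multiplier_matches_quadratic_oracle(self, ambient):
        solution, thermo = ambient
        mult = pb.scenario_multiplier(solution, 1.0, thermo, "sulfate_only",
                                      freeze_gamma=True)
        x_both = quadratic_oracle_x(solution, thermo, 1.0)
        # sulfate-only: (S0 + x) reaches Ksp/(gamma^2 Ba0), linear in x
        g = pb.activity_coefficient(2, pb.ionic_strength(solution),
                                    solution.temperature_C, thermo)
        k = thermo.ksp(solution.temperature_C) / g**2
        x_single = k / solution.concentration("Ba+2") - solution.concentration("SO4-2")
        assert mult == pytest.approx(x_single / x_both, rel=1e-6)
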