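"""Templated competitive-inhibition activity model."""


import numpy as np
import pytest
from scipy.optimize import brentq

import btarecruit as br
from btarecruit.errors import ParameterError


class TestScaffoldInhibitedFraction:
    def test_half_saturation_at_ki(self, inhibition_model):
        ki = inhibition_model.ki_solution
        assert br.scaffold_inhibited_fraction(ki, inhibition_model) == 0.5

    def test_zero_ceff_gives_zero(self, inhibition_model):
        assert br.scaffold_inhibited_fraction(0.0, inhibition_model) == 0.0

    def test_hand_computed_occupancy(self, inhibition_model):
        # 19.5 / (1.5 + 19.5) = 0.9286
        assert br.scaffold_inhibited_fraction(19.5e-6, inhibition_model) == (
            pytest.approx(0.9286, abs=1e-4)
        )


class TestNormalizedActivity:
    def test_no_inhibitor_gives_unity(
        self, composition_25pct, fiber, enzyme, inhibition_model
    ):
        inh = br.RecruitedSpecies("inhibitor", 200e-9, protein_total=0.0)
        v = br.normalized_activity(
            composition_25pct, fiber, enzyme, inh, inhibition_model
        )
        assert v == pytest.approx(1.0, rel=1e-12)

    def test_saturating_inhibitor_plateaus_at_free_enzyme_fraction(
        self, composition_25pct, fiber, enzyme, inhibition_model
    ):
        """~75% maximal inhibition: the plateau equals the unbound fraction."""
        f_e, _ = br.duplex_fraction_bound(
            composition_25pct.conc_btadna, enzyme.recruiter_total, enzyme.duplex_kd
        )
        # enormous inhibitor, no inhibitor recruiter so the enzyme equilibrium
        # is untouched; plain bulk convention to reach the theta -> 1 limit
        inh = br.RecruitedSpecies("inhibitor", 0.0, protein_total=1e-2)
        v = br.normalized_activity(
            composition_25pct,
            fiber,
            enzyme,
            inh,
            inhibition_model,
            apply_occupancy_to_inhibitor=False,
        )
        assert v == pytest.approx(1.0 - f_e, abs=1e-4)
        assert 1.0 - v == pytest.approx(0.75, abs=5e-3)

    def test_composition_of_occupancy_and_geometry_oracles(
        self, composition_25pct, fiber, inhibition_model
    ):
        """Full model equals the hand-composed f_E, f_I, C_eff, theta chain."""
        enzyme = br.RecruitedSpecies("enzyme", 20e-9, 1e-9)
        inhibitor = br.RecruitedSpecies("inhibitor", 200e-9, 10e-9)

        def resid(x):
            return (
                x
                + 20e-9 * x / (enzyme.duplex_kd + x)
                + 200e-9 * x / (inhibitor.duplex_kd + x)
                - 0.5e-6
            )

        x = brentq(resid, 0, 0.5e-6, xtol=1e-30, rtol=4 * np.finfo(float).eps)
        f_e = x / (enzyme.duplex_kd + x)
        f_i = x / (inhibitor.duplex_kd + x)
        ceff = br.effective_concentration(10e-9 * f_i, composition_25pct, fiber)
        theta = ceff / (inhibition_model.ki_solution + ceff)
        expected = (1 - f_e) + f_e * (1 - theta)

        v = br.normalized_activity(
            composition_25pct, fiber, enzyme, inhibitor, inhibition_model
        )
        assert v == pytest.approx(expected, rel=1e-9)

    def test_manual_chain_with_three_quarter_occupancies(self, inhibition_model):
        """With f_E = f_I = 0.75 and C_eff 19.5 uM the activity is ~0.304."""
        f = 0.75
        theta = br.scaffold_inhibited_fraction(19.5e-6, inhibition_model)
        v = (1 - f) + f * (1 - theta)
        assert v == pytest.approx(0.304, abs=1e-3)

    def test_controls_restore_full_activity(
        self, fiber, inhibition_model, composition_25pct
    ):
        """Omitting a recruiter or the receptors abolishes inhibition."""
        inhibitor = br.RecruitedSpecies("inhibitor", 200e-9, 10e-9)
        no_recruiter = br.RecruitedSpecies("enzyme", 0.0, 0.0)
        v1 = br.normalized_activity(
            composition_25pct, fiber, no_recruiter, inhibitor, inhibition_model
        )
        assert v1 == pytest.approx(1.0, rel=1e-12)

        no_handles = br.AssemblyComposition(conc_btadna=0.0, conc_bta3oh=2e-6)
        enzyme = br.RecruitedSpecies("enzyme", 20e-9, 1e-9)
        v2 = br.normalized_activity(
            no_handles, fiber, enzyme, inhibitor, inhibition_model
        )
        assert v2 == pytest.approx(1.0, rel=1e-12)

    def test_monotone_in_total_bta_dilution(
        self, fiber, enzyme, inhibitor, inhibition_model
    ):
        """More inert monomer dilutes the inhibitor and raises activity."""
        activities = []
        for bta3oh in [1.5e-6, 9.5e-6, 66e-6, 199.5e-6]:
            comp = br.AssemblyComposition(0.5e-6, bta3oh)
            activities.append(
                br.normalized_activity(comp, fiber, enzyme, inhibitor, inhibition_model)
            )
        assert all(a <= b + 1e-12 for a, b in zip(activities, activities[1:]))


class TestTitrationCurve:
    def test_starts_at_unity_and_decreases(
        self, composition_25pct, fiber, enzyme, inhibitor, inhibition_model,
        titration_grid,
    ):
        data = br.titration_curve(
            titration_grid, composition_25pct, fiber, enzyme, inhibitor,
            inhibition_model,
        )
        assert data.activity[0] == pytest.approx(1.0, rel=1e-12)
        assert np.all(np.diff(data.activity) <= 1e-12)

    def test_bounded_by_free_enzyme_fraction(
        self, composition_25pct, fiber, enzyme, inhibitor, inhibition_model,
        titration_grid,
    ):
        data = br.titration_curve(
            titration_grid, composition_25pct, fiber, enzyme, inhibitor,
            inhibition_model,
        )
        state = br.solve_competition(
            composition_25pct.conc_btadna, [enzyme, inhibitor]
        )
        f_e = state.species["enzyme"].scaffold_fraction
        assert np.all(data.activity >= 1 - f_e - 1e-12)
        assert np.all(data.activity <= 1 + 1e-12)

    def test_noiseless_curve_is_exactly_hyperbolic(
        self, composition_25pct, fiber, enzyme, inhibitor, inhibition_model,
        titration_grid,
    ):
        """The forward model collapses to V_b + (1-V_b) Ki_app/(I+Ki_app)."""
        data = br.titration_curve(
            titration_grid, composition_25pct, fiber, enzyme, inhibitor,
            inhibition_model,
        )
        state = br.solve_competition(
            composition_25pct.conc_btadna, [enzyme, inhibitor]
        )
        f_e = state.species["enzyme"].scaffold_fraction
        f_i = state.species["inhibitor"].scaffold_fraction
        slope = f_i * br.fold_enhancement(1e-9, composition_25pct, fiber)
        ki_app = inhibition_model.ki_solution / slope
        expected = br.eq1_activity(titration_grid, 1 - f_e, ki_app)
        np.testing.assert_allclose(data.activity, expected, rtol=1e-9)


class TestDensityScan:
    def test_dilution_below_threshold_raises_activity(
        self, fiber, inhibition_model
    ):
        enzyme = br.RecruitedSpecies("enzyme", 20e-9, 1e-9)
        inhibitor = br.RecruitedSpecies("inhibitor", 20e-9, 10e-9)
        frame = br.density_scan(
            [0.0025, 0.05, 0.25], 0.5e-6, fiber, enzyme, inhibitor, inhibition_model
        )
        by_density = frame.set_index("density")["activity"]
        assert by_density[0.0025] > by_density[0.05]

    def test_plateau_deep_in_saturating_regime(self, fiber, inhibition_model):
        """Where C_eff >> K_i the predicted inhibition is nearly flat."""
        enzyme = br.RecruitedSpecies("enzyme", 20e-9, 1e-9)
        inhibitor = br.RecruitedSpecies("inhibitor", 20e-9, 10e-9)
        frame = br.density_scan(
            [0.1, 0.175, 0.25], 0.5e-6, fiber, enzyme, inhibitor, inhibition_model
        )
        acts = frame["activity"].to_numpy()
        assert np.all(frame["ceff_inhibitor_M"] > 5 * inhibition_model.ki_solution)
        assert np.ptp(acts) < 0.1

    def test_activities_within_model_bounds(self, fiber, inhibition_model):
        enzyme = br.RecruitedSpecies("enzyme", 20e-9, 1e-9)
        inhibitor = br.RecruitedSpecies("inhibitor", 20e-9, 10e-9)
        frame = br.density_scan(
            np.linspace(0.0025, 1.0, 9), 0.5e-6, fiber, enzyme, inhibitor,
            inhibition_model,
        )
        assert np.all(frame["activity"] <= 1 + 1e-12)
        assert np.all(frame["activity"] >= 1 - frame["f_E"] - 1e-12)

    def test_invalid_density_rejected(self, fiber, inhibition_model):
        enzyme = br.RecruitedSpecies("enzyme", 20e-9, 1e-9)
        inhibitor = br.RecruitedSpecies("inhibitor", 20e-9, 10e-9)
        with pytest.raises(ParameterError):
            br.density_scan(
                [0.0], 0.5e-6, fiber, enzyme, inhibitor, inhibition_model
            )


class TestDisplacementCycle:
    @pytest.fixture
    def toehold_enzyme(self):
        return br.RecruitedSpecies(
            "enzyme", recruiter_total=0.0, protein_total=1e-9, has_toehold=True
        )

    @pytest.fixture
    def cycle_inhibitor(self):
        return br.RecruitedSpecies("inhibitor", 20e-9, 10e-9)

    def test_recruit_then_displace_restores_unity(
        self, composition_25pct, fiber, toehold_enzyme, cycle_inhibitor,
        inhibition_model,
    ):
        frame = br.displacement_cycle(
            [("recruiter", 20e-9), ("displacer", 40e-9)],
            composition_25pct, fiber, toehold_enzyme, cycle_inhibitor,
            inhibition_model,
        )
        acts = frame["activity"].to_numpy()
        assert acts[0] == pytest.approx(1.0, rel=1e-12)  # baseline
        assert acts[1] < 0.6  # recruited: inhibited
        assert acts[2] == pytest.approx(1.0, rel=1e-12)  # fully displaced

    def test_three_cycles_alternate_identically(
        self, composition_25pct, fiber, toehold_enzyme, cycle_inhibitor,
        inhibition_model,
    ):
        """Doubling additions keep the stoichiometric excess constant."""
        steps, r, d = [], 20e-9, 40e-9
        for _ in range(3):
            steps += [("recruiter", r), ("displacer", d)]
            r, d = r * 2, d * 2
        frame = br.displacement_cycle(
            steps, composition_25pct, fiber, toehold_enzyme, cycle_inhibitor,
            inhibition_model,
        )
        acts = frame["activity"].to_numpy()
        lows, highs = acts[1::2], acts[2::2]
        np.testing.assert_allclose(highs, 1.0, rtol=1e-12)
        np.testing.assert_allclose(lows, lows[0], rtol=1e-9)
        assert np.all(lows < 0.6)

    def test_empty_steps_single_baseline(
        self, composition_25pct, fiber, toehold_enzyme, cycle_inhibitor,
        inhibition_model,
    ):
        frame = br.displacement_cycle(
            [], composition_25pct, fiber, toehold_enzyme, cycle_inhibitor,
            inhibition_model,
        )
        assert len(frame) == 1
        assert frame["activity"].iloc[0] == pytest.approx(1.0, rel=1e-12)

    def test_toehold_required_for_cycling(
        self, composition_25pct, fiber, cycle_inhibitor, inhibition_model
    ):
        plain = br.RecruitedSpecies("enzyme", 0.0, 1e-9, has_toehold=False)
        with pytest.raises(ParameterError, match="toehold"):
            br.displacement_cycle(
                [("displacer", 10e-9)], composition_25pct, fiber, plain,
                cycle_inhibitor, inhibition_model,
            )
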