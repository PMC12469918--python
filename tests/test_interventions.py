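"""Dose formalism, minimum-dose search, surfaces, contours, synergy."""

import numpy as np
import pytest

from abkinetics import (InterventionSpec, apply_dose, dose_surface,
                        equal_dose_combination, final_abeta,
                        min_effective_dose, run_intervention, simulate,
                        synergy_report, threshold_contour)


class TestApplyDose:
    def test_full_dose_zeroes_production_ceiling(self, fitted_params):
        p = apply_dose(fitted_params, InterventionSpec("V1", 1.0))
        assert p.V1 <= 1e-300

    def test_full_dose_doubles_removal_rate(self, fitted_params):
        p = apply_dose(fitted_params, InterventionSpec("k2", 1.0))
        assert p.k2 == pytest.approx(900.0)

    def test_zero_dose_is_identity(self, fitted_params):
        assert apply_dose(fitted_params,
                          InterventionSpec("V1p", 0.0)) == fitted_params

    def test_production_dose_capped_at_one(self):
        with pytest.raises(ValueError):
            InterventionSpec("V1", 1.2)

    def test_removal_dose_may_exceed_one(self, fitted_params):
        p = apply_dose(fitted_params, InterventionSpec("k2p", 4.0))
        assert p.k2p == pytest.approx(5 * fitted_params.k2p)

    def test_half_saturation_constants_not_dosable(self):
        with pytest.raises(ValueError):
            InterventionSpec("K1", 0.5)


class TestRunIntervention:
    def test_no_intervention_matches_untreated(self, fitted_params,
                                               fitted_trajectory):
        traj = run_intervention(fitted_params, [])
        np.testing.assert_array_equal(traj.A, fitted_trajectory.A)

    def test_half_V1_from_start_is_successful(self, fitted_params):
        a27 = final_abeta(fitted_params, [InterventionSpec("V1", 0.5)])
        assert a27 <= 100.0

    def test_k2p_intervention_is_futile(self, fitted_params,
                                        fitted_trajectory):
        a27 = final_abeta(fitted_params, [InterventionSpec("k2p", 0.63)])
        assert a27 > 100.0
        assert a27 > 0.9 * fitted_trajectory.A[-1]

    def test_conflicting_doses_rejected(self, fitted_params):
        with pytest.raises(ValueError):
            run_intervention(fitted_params,
                             [InterventionSpec("V1", 0.2),
                              InterventionSpec("V1", 0.3)])

    def test_staggered_combination(self, fitted_params):
        """A second, later intervention can only lower the final burden."""
        one = final_abeta(fitted_params, [InterventionSpec("V1", 0.3)])
        two = final_abeta(fitted_params,
                          [InterventionSpec("V1", 0.3),
                           InterventionSpec("k2", 0.5, t_start=5.0)])
        assert two < one


class TestMinEffectiveDose:
    def test_trivial_threshold_needs_no_dose(self, fitted_params,
                                             fitted_trajectory):
        res = min_effective_dose(fitted_params, "V1",
                                 threshold=fitted_trajectory.A[-1] + 1)
        assert res.feasible and res.min_dose == 0.0

    def test_k2p_infeasible_within_unit_cap(self, fitted_params):
        res = min_effective_dose(fitted_params, "k2p", d_max=1.0)
        assert not res.feasible
        assert res.achieved_A27 > 1000.0

    def test_bracket_width_within_tolerance(self, fitted_params):
        res = min_effective_dose(fitted_params, "V1")
        lo, hi = res.bracket
        assert hi - lo <= 1e-3
        assert res.achieved_A27 <= 100.0

    def test_dose_response_is_monotone(self, fitted_params):
        for name, hi in [("V1", 1.0), ("V1p", 1.0), ("k2", 1.5),
                         ("k2p", 10.0)]:
            doses = np.linspace(0, hi, 12)
            a27 = [final_abeta(fitted_params, [InterventionSpec(name, d)])
                   for d in doses]
            assert np.all(np.diff(a27) <= 1e-6), name

    def test_later_start_needs_larger_dose(self, fitted_params):
        doses = [min_effective_dose(fitted_params, "V1", t_start=t).min_dose
                 for t in (1.0, 5.0, 10.0, 15.0)]
        assert np.all(np.diff(doses) > 0)


class TestEqualDoseCombination:
    def test_same_parameter_rejected(self, fitted_params):
        with pytest.raises(ValueError):
            equal_dose_combination(fitted_params, "V1", "V1")

    def test_combination_beats_both_monotherapies(self, fitted_params):
        combo = equal_dose_combination(fitted_params, "k2", "V1")
        mono_k2 = min_effective_dose(fitted_params, "k2")
        mono_v1 = min_effective_dose(fitted_params, "V1")
        assert combo.min_dose < mono_k2.min_dose
        assert combo.min_dose < mono_v1.min_dose


@pytest.fixture(scope="module")
def small_surface(fitted_params):
    return dose_surface(fitted_params, ("V1", "V1p"), n_grid=9)


class TestDoseSurface:
    def test_untreated_corner(self, small_surface, fitted_trajectory):
        assert small_surface.A27[0, 0] == pytest.approx(
            fitted_trajectory.A[-1], rel=1e-6)

    def test_edges_match_monotherapy(self, small_surface, fitted_params):
        for axis, name in [(0, "V1"), (1, "V1p")]:
            grid = (small_surface.dose_grid_1 if axis == 0
                    else small_surface.dose_grid_2)
            mono = [final_abeta(fitted_params, [InterventionSpec(name, d)])
                    for d in grid]
            np.testing.assert_allclose(small_surface.edge_curve(axis), mono,
                                       rtol=1e-8)

    def test_surface_is_monotone(self, small_surface):
        assert small_surface.monotone

    def test_threshold_crossed_inside_grid(self, small_surface):
        assert np.any(small_surface.A27 > 100) and np.any(
            small_surface.A27 < 100)


class TestThresholdContour:
    def test_contour_points_resimulate_to_threshold(self, small_surface,
                                                    fitted_params):
        contour = threshold_contour(small_surface)
        assert contour.feasible and len(contour.points) >= 5
        rng = np.random.default_rng(5)
        pick = rng.choice(len(contour.points), size=5, replace=False)
        for d1, d2 in contour.points[pick]:
            a27 = final_abeta(fitted_params,
                              [InterventionSpec("V1", d1),
                               InterventionSpec("V1p", d2)])
            assert abs(a27 - 100.0) < 1.0

    def test_optimal_point_off_both_axes(self, small_surface):
        """Early-start V1+V1' admits a genuine two-drug optimum cheaper
        than either monotherapy (0.39 / 0.64)."""
        contour = threshold_contour(small_surface)
        d1, d2 = contour.optimal_point
        assert d1 > 0.02 and d2 > 0.02
        assert contour.R < 0.39

    def test_equal_dose_point_on_diagonal_is_successful(self, fitted_params):
        combo = equal_dose_combination(fitted_params, "V1", "V1p")
        a27 = final_abeta(fitted_params,
                          [InterventionSpec("V1", combo.min_dose),
                           InterventionSpec("V1p", combo.min_dose)])
        assert a27 <= 100.0 + 0.5
        # the free optimum is at most the diagonal distance
        contour = threshold_contour(
            dose_surface(fitted_params, ("V1", "V1p"), n_grid=9))
        assert contour.R <= combo.min_dose * np.sqrt(2) + 0.02

    def test_infeasible_surface_reported(self, fitted_params):
        surf = dose_surface(fitted_params, ("k2p", "V1"),
                            grids=(np.linspace(0, 0.5, 4),
                                   np.linspace(0, 0.1, 4)))
        contour = threshold_contour(surf)
        assert not contour.feasible and contour.optimal_point is None


class TestSynergyReport:
    def test_categories(self, fitted_params, small_surface):
        mono_a = min_effective_dose(fitted_params, "V1")
        mono_b = min_effective_dose(fitted_params, "V1p")
        contour = threshold_contour(small_surface)
        rep = synergy_report(contour, mono_a, mono_b)
        assert rep.category in ("combination", "synergistic")

        from abkinetics import ThresholdContour
        axis = ThresholdContour(points=np.array([[0.39, 0.0]]),
                                optimal_point=(0.39, 0.0), R=0.39,
                                threshold=100.0, feasible=True,
                                param_pair=("V1", "k2"))
        assert synergy_report(axis, mono_a, mono_b).category == \
            "second intervention hardly useful"

        infeasible = ThresholdContour(points=np.empty((0, 2)),
                                      optimal_point=None, R=np.inf,
                                      threshold=100.0, feasible=False)
        assert synergy_report(infeasible, mono_a, mono_b).category == \
            "infeasible"
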