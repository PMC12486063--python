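"""Plan metrics, plan comparison and the nine-scenario robustness protocol."""

import numpy as np
import pandas as pd
import pytest

from letopt.evaluation import (
    RobustnessScenario,
    canonical_scenarios,
    compare_plans,
    plan_metrics,
    relative_difference_image,
    robustness_suite,
)
from letopt.grid import StructureSet, VoxelGrid
from letopt.influence import ForwardResult
from letopt.phantom import BeamModelParams, StructureSpec, make_phantom, opposed_fields_spots


def _structures(n=5):
    grid = VoxelGrid((n, n, n))
    s = StructureSet(grid)
    mask = np.zeros(grid.dims, dtype=bool)
    mask[1:-1, 1:-1, 1:-1] = True
    s.add("PTV", mask, "target")
    return grid, s


def _result(grid, dose, letd=1.0):
    dose = np.broadcast_to(dose, (grid.n_voxels,)).astype(float)
    letd = np.broadcast_to(letd, (grid.n_voxels,)).astype(float)
    return ForwardResult(dose=dose, letd=letd, cdl=0.04 * dose * letd)


class TestPlanMetrics:
    def test_uniform_prescription_dose_gives_full_coverage(self):
        grid, s = _structures()
        m = plan_metrics(_result(grid, 60.0), s, 60.0)
        row = m.structure("PTV")
        assert row["V95_pct"] == 100.0
        assert row["D_mean_Gy"] == pytest.approx(60.0)
        assert row["cDL30_Gy"] == pytest.approx(0.04 * 60.0)

    def test_partial_coverage_counts_voxels(self):
        grid, s = _structures()
        n_ptv = s.voxel_count("PTV")
        dose = np.full(grid.n_voxels, 60.0)
        ptv_idx = np.flatnonzero(s.flat("PTV"))
        dose[ptv_idx[:3]] = 10.0  # 3 cold voxels
        m = plan_metrics(
            ForwardResult(dose=dose, letd=np.ones_like(dose), cdl=0.04 * dose), s, 60.0
        )
        assert m.structure("PTV")["V95_pct"] == pytest.approx(100.0 * (n_ptv - 3) / n_ptv)

    def test_empty_plan_gives_zero_metrics(self):
        grid, s = _structures()
        m = plan_metrics(_result(grid, 0.0), s, 60.0)
        assert m.structure("PTV")["V95_pct"] == 0.0
        assert m.structure("PTV")["D_max_Gy"] == 0.0

    def test_v95_agrees_with_histogram_lookup(self, default_case):
        from letopt.constraints import cumulative_vh
        from letopt.influence import forward
        from letopt.pipeline import baseline_fluence

        fwd = forward(default_case.influence, baseline_fluence(default_case))
        m = plan_metrics(fwd, default_case.structures, 74.0)
        vh = cumulative_vh(fwd.dose[default_case.ptv_flat()])
        assert m.structure("PTV")["V95_pct"] == pytest.approx(
            100.0 * vh.volume_at(0.95 * 74.0 * (1 - 1e-9))
        )

    def test_grid_mismatch_rejected(self):
        grid, s = _structures()
        with pytest.raises(ValueError, match="voxels"):
            plan_metrics(_result(VoxelGrid((3, 3, 3)), 1.0), s, 60.0)


class TestComparePlans:
    def test_identical_plans_have_zero_deltas(self):
        grid, s = _structures()
        m = plan_metrics(_result(grid, 60.0), s, 60.0)
        rep = compare_plans(m, m)
        assert (rep.absolute.to_numpy() == 0).all()

    def test_relative_delta_example(self):
        grid, s = _structures()
        before = plan_metrics(_result(grid, 50.0, letd=2.0), s, 60.0)
        after = plan_metrics(_result(grid, 40.0, letd=2.0), s, 60.0)
        rep = compare_plans(before, after)
        assert rep.relative.loc["PTV", "cDL_max_Gy"] == pytest.approx(-0.2)

    def test_zero_baseline_flagged_not_computed(self):
        grid, s = _structures()
        before = plan_metrics(_result(grid, 0.0), s, 60.0)
        after = plan_metrics(_result(grid, 10.0), s, 60.0)
        rep = compare_plans(before, after)
        assert np.isnan(rep.relative.loc["PTV", "D_mean_Gy"])

    def test_absolute_deltas_are_antisymmetric(self):
        grid, s = _structures()
        a = plan_metrics(_result(grid, 50.0), s, 60.0)
        b = plan_metrics(_result(grid, 57.0), s, 60.0)
        pd.testing.assert_frame_equal(
            compare_plans(a, b).absolute, -compare_plans(b, a).absolute
        )

    def test_structure_mismatch_rejected(self):
        grid, s = _structures()
        m = plan_metrics(_result(grid, 60.0), s, 60.0)
        s2 = StructureSet(grid)
        s2.add("CTV", s.mask("PTV"), "target")
        m2 = plan_metrics(_result(grid, 60.0), s2, 60.0)
        with pytest.raises(ValueError, match="structure sets differ"):
            compare_plans(m, m2)


class TestRelativeDifferenceImage:
    def test_identical_images_give_zero(self):
        a = np.linspace(0, 10, 20)
        np.testing.assert_array_equal(relative_difference_image(a, a.copy()), 0.0)

    def test_floor_guards_near_zero_baseline(self):
        before = np.array([1e-12, 10.0])
        after = np.array([1.0, 8.0])
        out = relative_difference_image(after, before, floor=1.0)
        assert out[0] == pytest.approx(1.0 - 1e-12)  # denominator clipped to 1
        assert out[1] == pytest.approx(-0.2)

    def test_zero_baseline_without_floor_reports_zero(self):
        out = relative_difference_image(np.array([1.0]), np.array([0.0]))
        assert out[0] == 0.0


class TestScenarios:
    def test_canonical_protocol_has_nine_scenarios(self):
        scenarios = canonical_scenarios()
        assert len(scenarios) == 9
        shifts = {s.shift_mm for s in scenarios}
        assert (2.0, 0.0, 0.0) in shifts and (-2.0, 0.0, 0.0) in shifts
        assert (0.0, 2.0, 0.0) in shifts and (0.0, 0.0, -2.0) in shifts
        densities = sorted(s.density for s in scenarios)
        assert densities[0] == pytest.approx(0.965)
        assert densities[-1] == pytest.approx(1.035)
        assert sum(s.shift_mm == (0, 0, 0) and s.density == 1.0 for s in scenarios) == 1

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            RobustnessScenario("bad", density=-1.0)


class TestRobustnessSuite:
    def test_single_nominal_scenario_equals_nominal_metrics(self, default_case):
        from letopt.influence import forward
        from letopt.pipeline import baseline_fluence

        x = baseline_fluence(default_case)
        res = robustness_suite(
            x,
            default_case.grid,
            default_case.structures,
            default_case.spots,
            BeamModelParams(),
            74.0,
            scenarios=[RobustnessScenario("nominal")],
        )
        nominal = plan_metrics(
            forward(default_case.influence, x), default_case.structures, 74.0
        )
        pd.testing.assert_frame_equal(res.envelope_min, nominal.table)
        pd.testing.assert_frame_equal(res.envelope_max, nominal.table)

    def test_nominal_lies_inside_nine_scenario_envelope(self, default_case):
        from letopt.pipeline import baseline_fluence

        x = baseline_fluence(default_case)
        res = robustness_suite(
            x,
            default_case.grid,
            default_case.structures,
            default_case.spots,
            BeamModelParams(),
            74.0,
        )
        assert res.n_scenarios == 9
        nominal = res.per_scenario["nominal"].table
        assert (res.envelope_min.le(nominal + 1e-12)).all().all()
        assert (res.envelope_max.ge(nominal - 1e-12)).all().all()

    def test_opposed_x_shifts_are_mirror_symmetric_for_ptv(self):
        """On a symmetric phantom (no OAR) with opposed fields, +/-2 mm
        shifts along the beam axis give identical PTV dose metrics."""
        layout = [StructureSpec("PTV", "target", "sphere", (0, 0, 0), 9.0)]
        grid, structures = make_phantom((20, 20, 20), layout=layout, seed=1)
        params = BeamModelParams()
        spots = opposed_fields_spots(grid, structures.mask("PTV"), params)
        x = np.ones(spots.n_spots)
        res = robustness_suite(
            x,
            grid,
            structures,
            spots,
            params,
            74.0,
            scenarios=[
                RobustnessScenario("plus", (2.0, 0.0, 0.0)),
                RobustnessScenario("minus", (-2.0, 0.0, 0.0)),
            ],
        )
        plus = res.per_scenario["plus"].table.loc["PTV"]
        minus = res.per_scenario["minus"].table.loc["PTV"]
        pd.testing.assert_series_equal(plus, minus, atol=1e-6, rtol=0)

    def test_offgrid_scenario_error_names_scenario(self, default_case):
        from letopt.pipeline import baseline_fluence

        x = baseline_fluence(default_case)
        with pytest.raises(ValueError, match="way_off"):
            robustness_suite(
                x,
                default_case.grid,
                default_case.structures,
                default_case.spots,
                BeamModelParams(),
                74.0,
                scenarios=[RobustnessScenario("way_off", (1000.0, 0.0, 0.0))],
            )
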