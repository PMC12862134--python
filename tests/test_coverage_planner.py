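import numpy as np
import pandas as pd
import pytest

from irecar import (
    CoverageResult,
    ThresholdEstimate,
    compute_coverage,
    run_plan,
    sample_scenarios,
    select_dose,
    spacing_rule,
)
from irecar.coverage_planner import DEFAULT_RATIOS_V_PER_CM
from irecar.geometry_field import FieldMap

CAL = ThresholdEstimate(525.0, 77.0, 442.0, 613.0, 5)


@pytest.mark.parametrize("diameter, expected", [(6.0, 5.0), (4.0, 3.0), (8.0, 7.0)])
def test_spacing_rule_one_mm_below_diameter(diameter, expected):
    assert spacing_rule(diameter) == pytest.approx(expected)


def test_spacing_rule_rejects_tiny_tumors():
    with pytest.raises(ValueError):
        spacing_rule(1.0)


def test_sample_scenarios_ranges_and_spacing():
    scenarios = sample_scenarios(30, CAL, seed=7)
    assert len(scenarios) == 30
    for s in scenarios:
        assert 4.0 <= s.tumor_diameter_mm <= 8.0
        assert 0.1 <= s.tumor_conductivity_s_per_m <= 0.5
        assert 0.02 <= s.background_conductivity_s_per_m <= 0.2
        assert CAL.min_v_per_cm <= s.threshold_v_per_cm <= CAL.max_v_per_cm
        assert s.spacing_mm == pytest.approx(s.tumor_diameter_mm - 1.0)


def test_sample_scenarios_deterministic_under_seed():
    assert sample_scenarios(10, CAL, seed=3) == sample_scenarios(10, CAL, seed=3)
    assert sample_scenarios(10, CAL, seed=3) != sample_scenarios(10, CAL, seed=4)


def test_zero_sd_threshold_collapses_to_mean():
    flat = ThresholdEstimate(500.0, 0.0, 500.0, 500.0, 5)
    assert all(s.threshold_v_per_cm == 500.0 for s in sample_scenarios(8, flat, seed=1))


def test_threshold_modes():
    fixed = sample_scenarios(5, CAL, seed=1, threshold_mode="fixed")
    worst = sample_scenarios(5, CAL, seed=1, threshold_mode="worst_case")
    assert all(s.threshold_v_per_cm == CAL.mean_v_per_cm for s in fixed)
    assert all(s.threshold_v_per_cm == CAL.max_v_per_cm for s in worst)
    with pytest.raises(ValueError):
        sample_scenarios(5, CAL, seed=1, threshold_mode="nope")


def test_degenerate_ranges_rejected():
    with pytest.raises(ValueError):
        sample_scenarios(5, CAL, seed=1, diameter_range_mm=(8.0, 4.0))


def test_compute_coverage_limits_and_constructed_half(small_tumor_solution):
    dom, ec, fm = small_tumor_solution
    assert compute_coverage(fm, dom, 0.0) == 1.0
    above = fm.magnitude_grid[dom.tumor_mask].max() + 1.0
    assert compute_coverage(fm, dom, above) == 0.0

    # constructed map: exactly half the tumor voxels above the threshold
    mask = dom.tumor_mask
    n = int(mask.sum())
    mag = np.zeros_like(fm.magnitude_grid)
    vals = np.zeros(n)
    vals[: n // 2] = 100.0
    mag[mask] = vals
    half_map = FieldMap(mag, fm.potential_grid, fm.voxel_size_mm, ec, 0.0, 0)
    assert compute_coverage(half_map, dom, 50.0) == pytest.approx((n // 2) / n)


def _coverage_result(rows):
    table = pd.DataFrame(rows, columns=["scenario_id", "ratio_v_per_cm", "coverage"])
    return CoverageResult(table=table, summary=pd.DataFrame())


def _brute_force_select(table):
    for r in sorted(table["ratio_v_per_cm"].unique()):
        if (table.loc[table["ratio_v_per_cm"] == r, "coverage"] >= 1.0).all():
            return r
    return None


@pytest.mark.parametrize(
    "rows, expected, complete",
    [
        # all fully covered everywhere -> smallest candidate
        ([("a", 1000, 1.0), ("a", 1500, 1.0), ("b", 1000, 1.0), ("b", 1500, 1.0)], 1000, True),
        # full coverage first reached at the middle ratio
        ([("a", 1000, 0.8), ("a", 1500, 1.0), ("a", 2000, 1.0)], 1500, True),
        # never fully covered -> max ratio, flagged incomplete
        ([("a", 1000, 0.8), ("a", 2000, 0.99)], 2000, False),
    ],
)
def test_select_dose_matches_brute_force(rows, expected, complete):
    res = _coverage_result(rows)
    plan = select_dose(res)
    assert plan.selected_ratio_v_per_cm == expected
    assert plan.complete is complete
    brute = _brute_force_select(res.table)
    if complete:
        assert plan.selected_ratio_v_per_cm == brute
    else:
        assert brute is None


def test_select_dose_rejects_empty():
    with pytest.raises(ValueError):
        select_dose(_coverage_result([]))


def test_run_plan_small_monotone_and_summarized():
    """Coarse two-scenario plan: coverage non-decreasing in ratio,
    non-increasing in threshold, full table shape."""
    scenarios = sample_scenarios(2, CAL, seed=11)
    res = run_plan(scenarios, DEFAULT_RATIOS_V_PER_CM, resolution_mm=0.5)
    assert res.failures == []
    assert set(res.summary["n"]) == {2}
    for _, grp in res.table.groupby("scenario_id"):
        cov = grp.sort_values("ratio_v_per_cm")["coverage"].to_numpy()
        assert np.all(np.diff(cov) >= 0)

    # same scenarios with a lower threshold cover at least as much
    lower = [
        type(s)(
            s.scenario_id, s.tumor_diameter_mm, s.tumor_conductivity_s_per_m,
            s.background_conductivity_s_per_m, s.threshold_v_per_cm / 2.0,
            s.spacing_mm, s.rng_seed,
        )
        for s in scenarios
    ]
    res_lo = run_plan(lower, DEFAULT_RATIOS_V_PER_CM, resolution_mm=0.5)
    merged = res.table.merge(res_lo.table, on=["scenario_id", "ratio_v_per_cm"])
    assert (merged["coverage_y"] >= merged["coverage_x"]).all()


def test_zero_threshold_scenario_fully_covered_everywhere():
    s = sample_scenarios(1, ThresholdEstimate(1e-12, 0.0, 1e-12, 1e-12, 1), seed=5)
    res = run_plan(s, (1000.0, 3000.0), resolution_mm=0.5)
    assert (res.table["coverage"] == 1.0).all()


def test_coverage_saturates_at_extreme_ratio():
    """Any finite-threshold scenario is fully covered at 10,000 V/cm."""
    scenarios = sample_scenarios(1, CAL, seed=2, threshold_mode="worst_case")
    res = run_plan(scenarios, (10_000.0,), resolution_mm=0.5)
    assert (res.table["coverage"] == 1.0).all()


def test_coverage_invariant_to_global_conductivity_rescale():
    base = sample_scenarios(1, CAL, seed=9)[0]
    scaled = type(base)(
        base.scenario_id, base.tumor_diameter_mm,
        5.0 * base.tumor_conductivity_s_per_m,
        5.0 * base.background_conductivity_s_per_m,
        base.threshold_v_per_cm, base.spacing_mm, base.rng_seed,
    )
    r1 = run_plan([base], (1500.0,), resolution_mm=0.5)
    r2 = run_plan([scaled], (1500.0,), resolution_mm=0.5)
    assert r1.table["coverage"].iloc[0] == pytest.approx(r2.table["coverage"].iloc[0], abs=1e-9)


def test_run_plan_rejects_bad_ratio_grids():
    scenarios = sample_scenarios(1, CAL, seed=1)
    with pytest.raises(ValueError):
        run_plan(scenarios, (3000.0, 1000.0), resolution_mm=0.5)
    with pytest.raises(ValueError):
        run_plan(scenarios, (), resolution_mm=0.5)
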