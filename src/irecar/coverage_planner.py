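"""Monte-Carlo dose planning for two-needle IRE.

Tumor size and tissue conductivity vary animal to animal, so the applied
voltage-to-distance ratio is chosen by simulation: sample randomized
scenarios (tumor diameter 4-8 mm, tumor/background conductivities from
physiological ranges, lethal threshold from the calibrated distribution),
solve each scenario's field, and find the smallest candidate ratio at
which *every* scenario's tumor is fully covered by field at or above its
lethal threshold.

Electrode spacing follows the surgical rule of thumb: 1 mm less than the
maximum tumor diameter, so both needles sit inside the tumor.  The applied
voltage for a candidate ratio is ratio x spacing.

Because the conduction problem is linear in the applied voltage, each
scenario is solved once at a reference voltage and the field is rescaled
exactly for every candidate ratio — coverage across the whole ratio grid
costs one solve per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry_field import (
    ElectrodeConfig,
    FieldMap,
    TissueDomain,
    build_domain,
    solve_field,
)
from .threshold_calibration import ThresholdEstimate

__all__ = [
    "PlanningScenario",
    "CoverageResult",
    "DosePlan",
    "DEFAULT_RATIOS_V_PER_CM",
    "DEFAULT_CONDUCTIVITY_RANGES",
    "spacing_rule",
    "sample_scenarios",
    "compute_coverage",
    "run_plan",
    "select_dose",
]

#: candidate voltage-to-distance ratios, V/cm (1,000-3,000 in 500 steps)
DEFAULT_RATIOS_V_PER_CM = (1000.0, 1500.0, 2000.0, 2500.0, 3000.0)

#: literature-typical soft-tissue ranges, S/m: tumor and subcutaneous background
DEFAULT_CONDUCTIVITY_RANGES = {
    "tumor": (0.1, 0.5),
    "background": (0.02, 0.2),
}

DEFAULT_DIAMETER_RANGE_MM = (4.0, 8.0)


def spacing_rule(max_tumor_diameter_mm: float) -> float:
    """Needle spacing: 1 mm less than the maximum tumor diameter."""
    if max_tumor_diameter_mm <= 1.0:
        raise ValueError("tumor diameter must exceed 1 mm for needle insertion")
    return max_tumor_diameter_mm - 1.0


@dataclass(frozen=True)
class PlanningScenario:
    scenario_id: str
    tumor_diameter_mm: float
    tumor_conductivity_s_per_m: float
    background_conductivity_s_per_m: float
    threshold_v_per_cm: float
    spacing_mm: float
    rng_seed: int


@dataclass
class CoverageResult:
    """Per-scenario coverage table and per-ratio summary.

    ``table`` columns: scenario_id, ratio_v_per_cm, coverage (fraction of
    tumor voxels at/above the scenario threshold);
    ``summary`` columns: ratio_v_per_cm, mean, sd, n;
    ``scenario_stats`` columns: scenario_id, threshold_v_per_cm,
    min_field_v_per_cm (minimum tumor field at the reference ratio),
    ref_ratio_v_per_cm — by linearity, the smallest fully-ablating ratio
    for a scenario is ref * threshold / min_field.
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    scenario_stats: pd.DataFrame | None = None
    failures: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class DosePlan:
    selected_ratio_v_per_cm: float
    candidate_ratios_v_per_cm: tuple[float, ...]
    complete: bool
    decision_rule: str = "smallest candidate ratio with coverage 1.0 in every scenario"

    def applied_voltage_v(self, spacing_mm: float) -> float:
        return self.selected_ratio_v_per_cm * spacing_mm / 10.0


def sample_scenarios(
    n: int,
    threshold: ThresholdEstimate,
    seed: int,
    diameter_range_mm: tuple[float, float] = DEFAULT_DIAMETER_RANGE_MM,
    conductivity_ranges: dict[str, tuple[float, float]] | None = None,
    threshold_mode: str = "distribution",
) -> list[PlanningScenario]:
    """Draw randomized planning scenarios, reproducible under ``seed``.

    diameter ~ U(range); conductivities ~ U(configured ranges);
    threshold ~ Normal(mean, sd) truncated to [min, max] of the calibrated
    estimate.  ``threshold_mode``: ``"distribution"`` (default),
    ``"fixed"`` (calibrated mean in every scenario) or ``"worst_case"``
    (calibrated maximum).
    """
    if n < 1:
        raise ValueError("need at least one scenario")
    ranges = dict(DEFAULT_CONDUCTIVITY_RANGES)
    if conductivity_ranges:
        ranges.update(conductivity_ranges)
    for name, (lo, hi) in [("diameter", diameter_range_mm), *ranges.items()]:
        if lo > hi:
            raise ValueError(f"degenerate {name} range ({lo} > {hi})")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]

    diameters = rng.uniform(*diameter_range_mm, size=n)
    sig_t = rng.uniform(*ranges["tumor"], size=n)
    sig_b = rng.uniform(*ranges["background"], size=n)

    if threshold_mode == "fixed":
        thr = np.full(n, threshold.mean_v_per_cm)
    elif threshold_mode == "worst_case":
        thr = np.full(n, threshold.max_v_per_cm)
    elif threshold_mode == "distribution":
        if threshold.sd_v_per_cm == 0:
            thr = np.full(n, threshold.mean_v_per_cm)
        else:
            a = (threshold.min_v_per_cm - threshold.mean_v_per_cm) / threshold.sd_v_per_cm
            b = (threshold.max_v_per_cm - threshold.mean_v_per_cm) / threshold.sd_v_per_cm
            thr = stats.truncnorm.rvs(
                a, b,
                loc=threshold.mean_v_per_cm,
                scale=threshold.sd_v_per_cm,
                size=n,
                random_state=rng,
            )
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    return [
        PlanningScenario(
            scenario_id=f"s{i:03d}",
            tumor_diameter_mm=float(diameters[i]),
            tumor_conductivity_s_per_m=float(sig_t[i]),
            background_conductivity_s_per_m=float(sig_b[i]),
            threshold_v_per_cm=float(thr[i]),
            spacing_mm=spacing_rule(float(diameters[i])),
            rng_seed=child_seeds[i],
        )
        for i in range(n)
    ]


def compute_coverage(field: FieldMap, domain: TissueDomain, threshold_v_per_cm: float) -> float:
    """Fraction of tumor voxels with |E| at or above the lethal threshold."""
    mask = domain.tumor_mask
    n_tumor = int(np.count_nonzero(mask))
    if n_tumor == 0:
        raise ValueError("domain has no tumor voxels")
    return float(np.count_nonzero(field.magnitude_grid[mask] >= threshold_v_per_cm) / n_tumor)


def _solve_scenario(
    scenario: PlanningScenario,
    resolution_mm: float,
    tolerance: float,
    reference_ratio_v_per_cm: float,
) -> tuple[TissueDomain, FieldMap]:
    electrodes = ElectrodeConfig(
        mode="needle_pair",
        spacing_mm=scenario.spacing_mm,
        applied_voltage_v=reference_ratio_v_per_cm * scenario.spacing_mm / 10.0,
    )
    domain = build_domain(
        tumor_diameter_mm=scenario.tumor_diameter_mm,
        conductivities_s_per_m=(
            scenario.tumor_conductivity_s_per_m,
            scenario.background_conductivity_s_per_m,
        ),
        electrodes=electrodes,
        resolution_mm=resolution_mm,
    )
    return domain, solve_field(domain, electrodes, tolerance=tolerance)


def run_plan(
    scenarios: list[PlanningScenario],
    candidate_ratios_v_per_cm: tuple[float, ...] = DEFAULT_RATIOS_V_PER_CM,
    resolution_mm: float = 0.25,
    tolerance: float = 1e-6,
) -> CoverageResult:
    """Solve every scenario and tabulate coverage at each candidate ratio.

    One field solve per scenario (at the smallest candidate ratio); coverage
    at the other ratios uses the exact linear voltage rescaling.  Aborts if
    more than 10% of scenarios fail to solve.
    """
    ratios = tuple(float(r) for r in candidate_ratios_v_per_cm)
    if not ratios or any(r <= 0 for r in ratios) or list(ratios) != sorted(ratios):
        raise ValueError("candidate ratios must be positive and ascending")
    rows = []
    stat_rows = []
    failures: list[str] = []
    ref = ratios[0]
    for sc in scenarios:
        try:
            domain, fmap = _solve_scenario(sc, resolution_mm, tolerance, ref)
        except (ValueError, RuntimeError) as err:
            failures.append(f"{sc.scenario_id}: {err}")
            if len(failures) > 0.10 * len(scenarios):
                raise RuntimeError(
                    "more than 10% of planning scenarios failed: " + "; ".join(failures)
                ) from err
            continue
        mag_ref = fmap.magnitude_grid[domain.tumor_mask]
        n_tumor = mag_ref.size
        stat_rows.append((sc.scenario_id, sc.threshold_v_per_cm, float(mag_ref.min()), ref))
        for r in ratios:
            cov = float(np.count_nonzero(mag_ref * (r / ref) >= sc.threshold_v_per_cm) / n_tumor)
            rows.append((sc.scenario_id, r, cov))
    table = pd.DataFrame(rows, columns=["scenario_id", "ratio_v_per_cm", "coverage"])
    # coverage must never decrease with ratio within a scenario
    for sid, grp in table.groupby("scenario_id"):
        cov = grp.sort_values("ratio_v_per_cm")["coverage"].to_numpy()
        if np.any(np.diff(cov) < 0):
            raise AssertionError(f"coverage not monotone in ratio for scenario {sid}")
    summary = (
        table.groupby("ratio_v_per_cm")["coverage"]
        .agg(["mean", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, "count"])
        .reset_index()
    )
    summary.columns = ["ratio_v_per_cm", "mean", "sd", "n"]
    stats_df = pd.DataFrame(
        stat_rows,
        columns=["scenario_id", "threshold_v_per_cm", "min_field_v_per_cm", "ref_ratio_v_per_cm"],
    )
    return CoverageResult(table=table, summary=summary, scenario_stats=stats_df, failures=failures)


def select_dose(result: CoverageResult) -> DosePlan:
    """Smallest candidate ratio at which every scenario reaches coverage 1.0.

    If no candidate fully ablates every scenario, returns the maximum ratio
    flagged ``complete=False``.
    """
    if result.table.empty:
        raise ValueError("empty coverage result")
    ratios = tuple(sorted(result.table["ratio_v_per_cm"].unique()))
    for r in ratios:
        cov = result.table.loc[result.table["ratio_v_per_cm"] == r, "coverage"]
        if (cov >= 1.0).all():
            return DosePlan(float(r), ratios, complete=True)
    return DosePlan(float(ratios[-1]), ratios, complete=False)
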