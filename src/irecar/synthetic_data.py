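"""Synthetic-data generators emulating every pipeline input.

No raw data are deposited for this kind of study — only summary
statistics — so each analysis stage is exercised on generated data whose
statistical structure matches what the analysis assumes:

* hydrogel lesions — axis extents of a ground-truth lethal isocontour on
  a solved needle-pair field, with multiplicative measurement noise;
* spheroid time-lapse — two-channel images whose viable fraction follows
  a log-logistic field dose-response anchored to the measured post-IRE
  viabilities (~95% / 34% / 3% at 0 / 1 / 2 kV/cm), with rebound below
  1.5 kV/cm, field-dependent swelling, and CAR-T outside-in erosion and
  infiltration;
* in-vivo cohorts — exponential caliper growth with eradication at the
  first post-treatment measurement, stochastic recurrence in the IRE-only
  arm and none in the combination arm.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry_field import ElectrodeConfig, FieldMap, build_domain, solve_field
from .invivo_metrics import (
    ENDPOINT_DIMENSION_MM,
    FOLLOWUP_END_DAY,
    ResponseClass,
    SubjectRecord,
    treatment_trigger,
)
from .spheroid_quant import FluorFrame
from .threshold_calibration import LesionMeasurement, extent_of_level

__all__ = [
    "DoseResponseModel",
    "SpheroidTreatment",
    "SpheroidImagingSpec",
    "CohortSpec",
    "fit_dose_response",
    "viability_at",
    "gen_hydrogel_lesions",
    "gen_spheroid_timelapse",
    "gen_invivo_cohort",
]

# measured viable fractions after uniform-field IRE (flow cytometry, 3 h)
VIABILITY_ANCHORS = {0.0: 0.9499, 1000.0: 0.3440, 2000.0: 0.0330}


@dataclass(frozen=True)
class DoseResponseModel:
    """Log-logistic (Hill-type) field -> viable-fraction model.

    viability(E) = baseline / (1 + (E / midpoint)^slope); equals the
    baseline at E = 0 and decreases strictly with field.
    """

    midpoint_v_per_cm: float
    slope: float
    baseline_viability: float

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.midpoint_v_per_cm <= 0:
            raise ValueError("slope and midpoint must be positive")
        if not 0 < self.baseline_viability <= 1:
            raise ValueError("baseline viability must be in (0, 1]")


def fit_dose_response(anchors: dict[float, float] | None = None) -> DoseResponseModel:
    """Closed-form fit through the 0 / 1,000 / 2,000 V/cm viability anchors.

    With v0 = v(0), the two treated anchors give
    slope = log[(v0/v2 - 1)/(v0/v1 - 1)] / log(E2/E1) and
    midpoint = E1 / (v0/v1 - 1)^(1/slope).
    """
    a = anchors or VIABILITY_ANCHORS
    (e0, v0), (e1, v1), (e2, v2) = sorted(a.items())
    if e0 != 0:
        raise ValueError("anchors must include the untreated (E=0) viability")
    q1 = v0 / v1 - 1.0
    q2 = v0 / v2 - 1.0
    slope = math.log(q2 / q1) / math.log(e2 / e1)
    midpoint = e1 / q1 ** (1.0 / slope)
    return DoseResponseModel(midpoint, slope, v0)


DEFAULT_DOSE_RESPONSE = fit_dose_response()


def viability_at(field_v_per_cm: float, model: DoseResponseModel = DEFAULT_DOSE_RESPONSE) -> float:
    """Viable fraction immediately after treatment at the given field."""
    if field_v_per_cm < 0:
        raise ValueError("field must be non-negative")
    return model.baseline_viability / (
        1.0 + (field_v_per_cm / model.midpoint_v_per_cm) ** model.slope
    )


# ---------------------------------------------------------------------------
# hydrogel lesion generator


def gen_hydrogel_lesions(
    truth_threshold_v_per_cm: float,
    noise_cv: float,
    n: int,
    seed: int,
    electrodes: ElectrodeConfig | None = None,
    conductivity_s_per_m: float = 0.2,
    resolution_mm: float = 0.2,
    thickness_mm: float = 2.0,
) -> tuple[list[LesionMeasurement], FieldMap]:
    """Simulated hydrogel replicates: noisy lesion extents of a truth isocontour.

    The hydrogel is a homogeneous phantom, so a single solved field map
    serves all replicates.  Each extent is the truth isocontour's axis
    extent times (1 + eps), eps ~ Normal(0, noise_cv).  Returns the
    measurements together with the shared field map.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if electrodes is None:
        electrodes = ElectrodeConfig(spacing_mm=5.0, applied_voltage_v=1250.0)
    # full-thickness exposure keeps the slab z-invariant (2-D problem)
    domain = build_domain(
        tumor_diameter_mm=0.0,
        conductivities_s_per_m=(conductivity_s_per_m, conductivity_s_per_m),
        electrodes=electrodes,
        resolution_mm=resolution_mm,
        domain_thickness_mm=thickness_mm,
    )
    fmap = solve_field(domain, electrodes)
    true_extent = extent_of_level(fmap, truth_threshold_v_per_cm)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_cv, size=n) if noise_cv > 0 else np.zeros(n)
    measurements = [
        LesionMeasurement(
            replicate_id=f"r{i + 1}",
            electrodes=electrodes,
            extent_mm=float(true_extent * (1.0 + eps[i])),
        )
        for i in range(n)
    ]
    return measurements, fmap


# ---------------------------------------------------------------------------
# spheroid time-lapse generator


@dataclass(frozen=True)
class SpheroidTreatment:
    """Uniform field magnitude applied (V/cm; 0 = untreated) and CAR-T flag."""

    field_v_per_cm: float = 0.0
    cart: bool = False


@dataclass(frozen=True)
class SpheroidImagingSpec:
    shape: tuple[int, int] = (160, 160)
    pixel_size_um: float = 10.0
    radius_px: float = 40.0
    timepoints_h: tuple[float, ...] = (0.0, 3.0, 24.0, 48.0, 72.0)
    green_amplitude: float = 150.0
    green_background: float = 20.0
    deepred_amplitude: float = 120.0
    deepred_background: float = 15.0
    #: residual green signal retained by dead cells (keeps the spheroid
    #: segmentable even after near-complete kill, as in bright-field-guided ROIs)
    dead_signal_fraction: float = 0.08
    gaussian_noise_sd: float = 2.0
    #: logistic regrowth rate of the viable fraction, per hour
    regrowth_rate_per_h: float = 0.04
    #: no regrowth at or above this field (complete treatment)
    regrowth_cutoff_v_per_cm: float = 1500.0


def _viable_fraction(t_h, treatment, model, spec) -> float:
    """Viable fraction (relative to baseline) at time t after treatment."""
    e = treatment.field_v_per_cm
    f0 = viability_at(e, model) / model.baseline_viability
    if t_h <= 0:
        return 1.0
    if treatment.cart:
        if e == 0:
            # CAR-T alone: outside-in kill, viability drops late (after 48 h)
            return 1.0 - 0.4 * max(0.0, (t_h - 48.0) / 24.0)
        # combination: IRE drop, residual cells cleared instead of regrowing
        return f0 * max(0.35, 1.0 - 0.01 * t_h)
    if 0 < e <= spec.regrowth_cutoff_v_per_cm:
        # logistic regrowth of survivors
        r = spec.regrowth_rate_per_h
        return 1.0 / (1.0 + (1.0 - f0) / f0 * math.exp(-r * t_h))
    return f0


def _radius_px(t_h, treatment, spec) -> float:
    e = treatment.field_v_per_cm
    r = spec.radius_px
    if e > 0 and t_h >= 3.0:
        # electroporation dysregulates the spheroid: swelling grows with field
        r *= 1.0 + 0.08 + 0.12 * max(0.0, e - 1000.0) / 1500.0
    if treatment.cart and t_h > 3.0:
        # outside-in CAR-T erosion
        r *= max(0.5, 1.0 - 0.3 * (t_h - 3.0) / 69.0)
    return r


def infiltration_fraction(t_h: float, treatment: SpheroidTreatment) -> float:
    """Programmed CAR-T penetration depth signal (0-1) inside the spheroid.

    Combination: high early (disrupted spheroid lets T cells in), flat.
    CAR-T alone: low early, rising by 72 h.
    """
    if not treatment.cart or t_h <= 0:
        return 0.0
    if treatment.field_v_per_cm > 0:
        return 0.5
    return 0.1 + 0.5 * t_h / 72.0


def gen_spheroid_timelapse(
    treatment: SpheroidTreatment,
    seed: int,
    model: DoseResponseModel = DEFAULT_DOSE_RESPONSE,
    spec: SpheroidImagingSpec = SpheroidImagingSpec(),
    well_id: str = "w1",
) -> list[FluorFrame]:
    """Two-channel image series for one well under one treatment.

    Green inside the (swollen/eroded) disk scales with the viable fraction
    plus a small dead-cell residual; deep-red adds a thin T-cell ring at the
    boundary and an interior signal proportional to the programmed
    infiltration fraction.  Poisson-Gaussian pixel noise throughout.
    """
    times = spec.timepoints_h
    if 0.0 not in times or max(times) < 72.0:
        raise ValueError("timepoints must include 0 and extend to at least 72 h")
    if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
        raise ValueError("timepoints must be strictly increasing")
    rng = np.random.default_rng(seed)
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = (yy - ny / 2.0) ** 2 + (xx - nx / 2.0) ** 2

    frames = []
    for t in times:
        f = _viable_fraction(t, treatment, model, spec)
        r = _radius_px(t, treatment, spec)
        disk = d2 <= r**2
        green = np.full(spec.shape, spec.green_background)
        signal = spec.dead_signal_fraction + (1.0 - spec.dead_signal_fraction) * f
        green[disk] += spec.green_amplitude * signal

        deepred = np.full(spec.shape, spec.deepred_background)
        if treatment.cart and t > 0:
            ring = (d2 > r**2) & (d2 <= (r + 8.0) ** 2)
            deepred[ring] += spec.deepred_amplitude
            deepred[disk] += spec.deepred_amplitude * infiltration_fraction(t, treatment)

        green = rng.poisson(green).astype(float) + rng.normal(0, spec.gaussian_noise_sd, spec.shape)
        deepred = rng.poisson(deepred).astype(float) + rng.normal(
            0, spec.gaussian_noise_sd, spec.shape
        )
        frames.append(
            FluorFrame(
                well_id=well_id,
                timepoint_h=t,
                green=np.clip(green, 0, None),
                deepred=np.clip(deepred, 0, None),
                pixel_size_um=spec.pixel_size_um,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# in-vivo cohort generator


@dataclass(frozen=True)
class CohortSpec:
    """Study-arm structure of the 60-day survival experiment."""

    n_per_group: int = 6
    groups: tuple[str, ...] = ("sham", "CAR-T", "IRE", "combination")
    initial_volume_mm3: float = 15.0
    growth_rate_per_day: float = 0.15
    growth_rate_cv: float = 0.2
    cart_growth_factor: float = 0.8
    eradication_probability: float = 1.0
    recurrence_probability: float = 4.0 / 6.0
    recurrence_delay_range_days: tuple[float, float] = (10.0, 25.0)
    recurrence_volume_mm3: float = 10.0
    measurement_noise_cv: float = 0.0
    aspect_ratio: float = 0.8
    master_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.eradication_probability, self.recurrence_probability):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_per_group < 1:
            raise ValueError("need at least one subject per group")


def _measurement_days(end: int) -> list[int]:
    """Thrice-weekly schedule: days 0, 2, 4 of each week."""
    days = []
    week = 0
    while True:
        for off in (0, 2, 4):
            d = 7 * week + off
            if d > end:
                return days
            days.append(d)
        week += 1


def _dims_from_volume(v: float, aspect: float) -> tuple[float, float]:
    # V = 0.5 * L * W^2 with W = aspect * L
    if v <= 0:
        return 0.0, 0.0
    length = (2.0 * v / aspect**2) ** (1.0 / 3.0)
    return length, aspect * length


def gen_invivo_cohort(
    spec: CohortSpec = CohortSpec(),
) -> tuple[pd.DataFrame, list[SubjectRecord], dict[str, str]]:
    """Caliper table, subject records, and ground-truth response labels.

    Per animal: exponential growth (lognormal rate heterogeneity) from
    inoculation, treatment at the first measurement with volume > 100 mm^3,
    then group-specific dynamics — sham grows on; CAR-T grows slower; IRE
    and combination are eradicated at the first post-treatment measurement;
    IRE recurs with the configured probability after a uniform delay;
    euthanasia when any dimension reaches 12 mm; censoring at day 60.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    days = _measurement_days(FOLLOWUP_END_DAY + 30)
    caliper_rows = []
    subjects: list[SubjectRecord] = []
    truth: dict[str, str] = {}

    for group, child in zip(spec.groups, ss.spawn(len(spec.groups))):
        for i, sub_ss in enumerate(child.spawn(spec.n_per_group)):
            rng = np.random.default_rng(sub_ss)
            animal_id = f"{group}-{i + 1}"
            rate = spec.growth_rate_per_day * rng.lognormal(0.0, spec.growth_rate_cv)
            post_rate = rate * (spec.cart_growth_factor if group == "CAR-T" else 1.0)
            recurs = group == "IRE" and rng.random() < spec.recurrence_probability
            delay = rng.uniform(*spec.recurrence_delay_range_days)

            treatment_day: int | None = None
            recurrence_day: int | None = None
            endpoint_day = FOLLOWUP_END_DAY
            event = "censored"
            series: list[tuple[int, float]] = []
            v_at_treat = None

            for d in days:
                if treatment_day is None:
                    v = spec.initial_volume_mm3 * math.exp(rate * d)
                    if treatment_trigger(v):
                        treatment_day = d
                        v_at_treat = v
                elif group in ("IRE", "combination"):
                    if recurs and d >= treatment_day + delay:
                        if recurrence_day is None:
                            recurrence_day = d
                        v = spec.recurrence_volume_mm3 * math.exp(
                            post_rate * (d - recurrence_day)
                        )
                    else:
                        v = 0.0
                else:
                    v = v_at_treat * math.exp(post_rate * (d - treatment_day))
                if spec.measurement_noise_cv > 0 and v > 0:
                    v *= 1.0 + rng.normal(0.0, spec.measurement_noise_cv)
                    v = max(v, 0.0)
                length, width = _dims_from_volume(v, spec.aspect_ratio)
                series.append((d, v))
                caliper_rows.append((animal_id, group, d, length, width))
                if max(length, width) >= ENDPOINT_DIMENSION_MM:
                    endpoint_day = d
                    event = "death"
                    break
                if d >= FOLLOWUP_END_DAY:
                    endpoint_day = FOLLOWUP_END_DAY
                    break

            if treatment_day is None:
                raise RuntimeError(f"{animal_id}: tumor never reached the treatment trigger")
            subjects.append(
                SubjectRecord(
                    animal_id=animal_id,
                    group=group,
                    volume_series=series,
                    treatment_day=treatment_day,
                    endpoint_day=endpoint_day,
                    event=event,
                )
            )
            if group in ("sham", "CAR-T"):
                truth[animal_id] = ResponseClass.STABLE_OR_PROGRESSIVE
            elif recurrence_day is not None:
                truth[animal_id] = ResponseClass.ERADICATED_RECURRENT
            else:
                truth[animal_id] = ResponseClass.ERADICATED_DURABLE

    calipers = pd.DataFrame(
        caliper_rows, columns=["animal_id", "group", "day", "length_mm", "width_mm"]
    )
    return calipers, subjects, truth
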