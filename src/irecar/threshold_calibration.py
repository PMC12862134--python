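"""Lethal-threshold calibration by lesion inversion.

Cell-laden collagen hydrogels are pulsed with a known needle-pair
configuration and the resulting dead-cell lesion is measured.  Because the
hydrogel is a uniform phantom, the simulated field map for that
configuration is exact up to discretization, and the lethal electric-field
threshold is simply the field magnitude at the observed live/dead
boundary:

* extent mode — the lesion is summarized by its total width along the
  inter-electrode axis; the threshold is |E| at ``extent/2`` from the
  midpoint (outside the electrode, where the field decays monotonically);
* area mode — the lesion is a planar area on the equatorial plane; the
  threshold is the isocontour level enclosing that area (bisection).

Replicate thresholds are aggregated into mean, sample SD, min, max
(reported in the field's customary ``mean ± SD [min to max] V/cm`` form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_field import ElectrodeConfig, FieldMap

__all__ = [
    "LesionMeasurement",
    "ThresholdEstimate",
    "axis_field_profile",
    "invert_lesion",
    "estimate_threshold",
]


@dataclass(frozen=True)
class LesionMeasurement:
    """One hydrogel replicate: lesion axis extent (mm) XOR planar area (mm^2)."""

    replicate_id: str
    electrodes: ElectrodeConfig
    extent_mm: float | None = None
    area_mm2: float | None = None

    def __post_init__(self) -> None:
        if (self.extent_mm is None) == (self.area_mm2 is None):
            raise ValueError("provide exactly one of extent_mm or area_mm2")
        v = self.extent_mm if self.extent_mm is not None else self.area_mm2
        if v <= 0:
            raise ValueError("lesion measurement must be positive")


@dataclass(frozen=True)
class ThresholdEstimate:
    mean_v_per_cm: float
    sd_v_per_cm: float
    min_v_per_cm: float
    max_v_per_cm: float
    n: int

    def __post_init__(self) -> None:
        if not (self.min_v_per_cm <= self.mean_v_per_cm <= self.max_v_per_cm):
            raise ValueError("threshold summary violates min <= mean <= max")
        if self.sd_v_per_cm < 0 or self.n < 1:
            raise ValueError("invalid threshold summary")

    def __str__(self) -> str:
        return (
            f"{self.mean_v_per_cm:.0f} ± {self.sd_v_per_cm:.0f} "
            f"[{self.min_v_per_cm:.0f} to {self.max_v_per_cm:.0f}] V/cm"
        )

    def to_dict(self) -> dict:
        return {
            "mean_v_per_cm": self.mean_v_per_cm,
            "sd_v_per_cm": self.sd_v_per_cm,
            "min_v_per_cm": self.min_v_per_cm,
            "max_v_per_cm": self.max_v_per_cm,
            "n": self.n,
        }


def axis_field_profile(field: FieldMap) -> tuple[np.ndarray, np.ndarray]:
    """Field magnitude along the outward inter-electrode axis.

    Returns (distance from midpoint in mm, |E| in V/cm) restricted to the
    decaying branch beyond the outer electrode edge, averaged over the two
    symmetric half-axes.
    """
    x, prof = field.axis_profile()
    center = (x[0] + x[-1]) / 2.0  # domain midpoint
    d = x - center
    edge = field.electrodes.spacing_mm / 2.0 + field.electrodes.electrode_radius_mm
    right = d >= edge
    left = d <= -edge
    # average the two symmetric branches to suppress rasterization asymmetry
    dr, pr = d[right], prof[right]
    dl, pl = -d[left][::-1], prof[left][::-1]
    n = min(len(dr), len(dl))
    return dr[:n], 0.5 * (pr[:n] + pl[:n])


def _field_at_axis_distance(field: FieldMap, dist_mm: float) -> float:
    d, p = axis_field_profile(field)
    if dist_mm < d[0] or dist_mm > d[-1]:
        raise ValueError(
            f"lesion half-extent {dist_mm:.2f} mm outside the attainable axis range "
            f"[{d[0]:.2f}, {d[-1]:.2f}] mm"
        )
    return float(np.interp(dist_mm, d, p))


def extent_of_level(field: FieldMap, level_v_per_cm: float) -> float:
    """Axis extent (mm) of the isocontour at ``level_v_per_cm``.

    Inverse of the extent-mode inversion; used by the synthetic hydrogel
    generator.  The level must be crossed on the decaying outer branch.
    """
    d, p = axis_field_profile(field)
    if level_v_per_cm > p[0] or level_v_per_cm < p[-1]:
        raise ValueError("isocontour level outside the attainable axis range")
    # p decreases along d; interpolate the crossing
    order = np.argsort(p)
    half = float(np.interp(level_v_per_cm, p[order], d[order]))
    return 2.0 * half


def _invert_area(field: FieldMap, area_mm2: float) -> float:
    mag = field.magnitude_grid
    nz = mag.shape[2]
    plane = 0.5 * (mag[:, :, nz // 2 - 1 + nz % 2] + mag[:, :, nz // 2])
    px = field.voxel_size_mm**2

    def area_of(level: float) -> float:
        return float(np.count_nonzero(plane >= level) * px)

    lo, hi = float(plane.min()), float(plane.max())
    if area_mm2 >= area_of(lo):
        return lo
    if area_mm2 <= 0:
        raise ValueError("lesion area must be positive")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if area_of(mid) >= area_mm2:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def invert_lesion(field: FieldMap, measurement: LesionMeasurement) -> float:
    """Field magnitude (V/cm) at the measured lesion boundary."""
    if (
        measurement.electrodes.spacing_mm != field.electrodes.spacing_mm
        or measurement.electrodes.applied_voltage_v != field.electrodes.applied_voltage_v
    ):
        raise ValueError(
            f"replicate {measurement.replicate_id}: electrode configuration does not "
            "match the supplied field map"
        )
    if measurement.extent_mm is not None:
        return _field_at_axis_distance(field, measurement.extent_mm / 2.0)
    return _invert_area(field, measurement.area_mm2)


def estimate_threshold(
    measurements: list[LesionMeasurement],
    fields: FieldMap | list[FieldMap],
) -> ThresholdEstimate:
    """Invert each replicate and summarize as mean, sample SD, min, max, n.

    ``fields`` may be a single shared map (all replicates pulsed with the
    same configuration) or one map per replicate.
    """
    if not measurements:
        raise ValueError("no lesion measurements supplied")
    if isinstance(fields, FieldMap):
        fields = [fields] * len(measurements)
    if len(fields) != len(measurements):
        raise ValueError("need one field map per measurement (or a single shared map)")
    thresholds = []
    for meas, fmap in zip(measurements, fields):
        try:
            thresholds.append(invert_lesion(fmap, meas))
        except ValueError as err:
            raise ValueError(f"replicate {meas.replicate_id}: {err}") from err
    t = np.asarray(thresholds)
    sd = float(t.std(ddof=1)) if len(t) > 1 else 0.0
    return ThresholdEstimate(float(t.mean()), sd, float(t.min()), float(t.max()), len(t))
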