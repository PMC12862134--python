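"""Voxelized tissue/electrode geometry and quasi-static electric-field solver.

Two-needle irreversible-electroporation (IRE) treatments establish a
spatially heterogeneous electric field in tissue.  In the quasi-static
limit the potential phi satisfies the conduction equation

    div( sigma * grad(phi) ) = 0

with Dirichlet potentials +V/2 and -V/2 on the two electrode voxel sets
and an insulating (zero normal current) outer boundary.  The field
magnitude |grad phi| decides which tissue is ablated: voxels at or above
the lethal threshold (in V/cm) die.

Discretization: regular Cartesian grid, 7-point finite-difference stencil
with harmonic averaging of the conductivity at voxel-face interfaces,
which is robust across the tumor/background conductivity jump.  The
resulting symmetric positive-definite system is solved with a
Jacobi-preconditioned conjugate-gradient iteration.

Units: lengths in mm, voltages in V, conductivities in S/m, field
magnitudes in V/cm (the unit every printed dose value uses).  A helper
converts transmembrane values to MV/m.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import LinearOperator, cg

__all__ = [
    "Label",
    "PulseScheme",
    "ElectrodeConfig",
    "TissueDomain",
    "FieldMap",
    "build_domain",
    "solve_field",
    "uniform_field",
    "membrane_field",
    "two_wire_midpoint_field",
    "electrode_currents",
    "load_config",
    "export_vtk",
    "field_summary",
]

MM_PER_CM = 10.0


class Label(enum.IntEnum):
    """Per-voxel role in the simulation domain."""

    BACKGROUND = 0
    TUMOR = 1
    ELECTRODE_PLUS = 2
    ELECTRODE_MINUS = 3


@dataclass(frozen=True)
class PulseScheme:
    """Pulse-train metadata (carried, not simulated): count, width (us), rate (Hz).

    The conventional scheme is 90 bursts of 90-us pulses delivered at 1 Hz.
    """

    pulse_count: int = 90
    pulse_width_us: float = 90.0
    repetition_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        if self.pulse_count <= 0:
            raise ValueError("pulse_count must be positive")
        if self.pulse_width_us <= 0:
            raise ValueError("pulse_width_us must be positive")
        if self.repetition_rate_hz <= 0:
            raise ValueError("repetition_rate_hz must be positive")


@dataclass(frozen=True)
class ElectrodeConfig:
    """Electrode geometry and drive.

    Parameters
    ----------
    mode
        ``"needle_pair"`` (two parallel cylindrical needles) or
        ``"parallel_plate"`` (ideal uniform-field cuvette/plate setup).
    spacing_mm
        Center-to-center needle spacing, or the plate gap.
    electrode_radius_mm
        Needle radius (needles only).
    exposed_length_mm
        Conductive (non-insulated) needle length.  ``None`` defaults to the
        tumor diameter at domain-build time.
    applied_voltage_v
        Potential difference between the electrodes.
    """

    mode: str = "needle_pair"
    spacing_mm: float = 5.0
    electrode_radius_mm: float = 0.5
    exposed_length_mm: float | None = None
    applied_voltage_v: float = 0.0
    pulse_scheme: PulseScheme = field(default_factory=PulseScheme)

    def __post_init__(self) -> None:
        if self.mode not in ("needle_pair", "parallel_plate"):
            raise ValueError(f"unknown electrode mode {self.mode!r}")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if self.applied_voltage_v < 0:
            raise ValueError("applied voltage must be non-negative")
        if self.mode == "needle_pair" and self.spacing_mm <= 2 * self.electrode_radius_mm:
            raise ValueError(
                "needle spacing must exceed the electrode diameter "
                f"(spacing {self.spacing_mm} mm, radius {self.electrode_radius_mm} mm)"
            )

    @property
    def voltage_to_distance_ratio(self) -> float:
        """Applied voltage over spacing, in V/cm — the clinical dose parameter."""
        return self.applied_voltage_v / (self.spacing_mm / MM_PER_CM)


@dataclass
class TissueDomain:
    """Voxelized tumor-in-tissue conductivity model.

    ``label_grid`` assigns each voxel a :class:`Label`; ``conductivity_grid``
    holds sigma in S/m.  The tumor is a sphere centered on the
    inter-electrode midpoint.
    """

    label_grid: np.ndarray
    conductivity_grid: np.ndarray
    voxel_size_mm: float
    tumor_center_mm: tuple[float, float, float]
    tumor_diameter_mm: float
    tumor_conductivity_s_per_m: float
    background_conductivity_s_per_m: float

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.label_grid.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size_mm for n in self.grid_shape)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        n = self.grid_shape[axis]
        return (np.arange(n) + 0.5) * self.voxel_size_mm

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.label_grid == Label.TUMOR


@dataclass
class FieldMap:
    """Solved field: |E| per voxel in V/cm, plus the potential it came from."""

    magnitude_grid: np.ndarray
    potential_grid: np.ndarray
    voxel_size_mm: float
    electrodes: ElectrodeConfig
    solver_residual: float
    iterations: int

    def axis_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(x-coords mm, |E| V/cm) sampled along the inter-electrode axis.

        The axis runs along the first grid dimension through the domain
        center; off-grid center planes are averaged from the two adjacent
        voxel rows.
        """
        nx, ny, nz = self.magnitude_grid.shape
        x = (np.arange(nx) + 0.5) * self.voxel_size_mm

        def center_slice(arr: np.ndarray, axis: int) -> np.ndarray:
            n = arr.shape[axis]
            lo = arr.take(n // 2 - 1 + n % 2, axis=axis)
            hi = arr.take(n // 2, axis=axis)
            return 0.5 * (lo + hi)

        prof = center_slice(center_slice(self.magnitude_grid, 2), 1)
        return x, prof


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def uniform_field(voltage_v: float, gap_mm: float) -> float:
    """Ideal parallel-plate / cuvette field magnitude in V/cm.

    800 V across a 4-mm cuvette gives 2,000 V/cm; 400 V gives 1,000 V/cm.
    """
    _require(gap_mm > 0, "electrode gap must be positive")
    _require(voltage_v >= 0, "voltage must be non-negative")
    return voltage_v / (gap_mm / MM_PER_CM)


def membrane_field(transmembrane_potential_v: float, membrane_thickness_nm: float) -> float:
    """Field inside a membrane in MV/m (1 V across 5 nm is 200 MV/m)."""
    _require(membrane_thickness_nm > 0, "membrane thickness must be positive")
    # V / nm = 1e9 V/m = 1e3 MV/m
    return transmembrane_potential_v / membrane_thickness_nm * 1e3


def two_wire_midpoint_field(voltage_v: float, spacing_mm: float, radius_mm: float) -> float:
    """Closed-form midpoint |E| (V/cm) between two parallel conducting cylinders.

    Exact bipolar-coordinates solution for infinite cylinders of radius a at
    center spacing d held at +/- V/2 in a homogeneous medium:

        E_mid = V / ( b * acosh(d / 2a) ),   b = sqrt((d/2)^2 - a^2)

    For thin wires (a << d) this reduces to the familiar
    2V / (d * ln((d - a)/a)).  Serves as the analytic oracle for the
    finite-difference solver.
    """
    _require(spacing_mm > 2 * radius_mm, "cylinders must not overlap")
    b = np.sqrt((spacing_mm / 2.0) ** 2 - radius_mm**2)
    e_v_per_mm = voltage_v / (b * np.arccosh(spacing_mm / (2.0 * radius_mm)))
    return e_v_per_mm * MM_PER_CM


def build_domain(
    tumor_diameter_mm: float,
    conductivities_s_per_m: tuple[float, float],
    electrodes: ElectrodeConfig,
    resolution_mm: float,
    extent_mm: float | None = None,
    domain_thickness_mm: float | None = None,
) -> TissueDomain:
    """Rasterize the spherical-tumor / two-needle geometry on a regular grid.

    Parameters
    ----------
    tumor_diameter_mm
        Diameter of the spherical tumor centered on the inter-electrode
        midpoint.  ``0`` builds a homogeneous phantom (hydrogel calibration).
    conductivities_s_per_m
        ``(tumor, background)`` conductivities.
    electrodes
        Needle-pair geometry; needles are solid cylinders whose axes are
        perpendicular to the tumor equatorial plane (the z direction),
        separated by ``spacing_mm`` along x.
    resolution_mm
        Isotropic voxel edge.  Must not be coarser than the needle radius.
    extent_mm
        Cubic domain edge; defaults to 4x the electrode spacing (insulating
        far boundary).
    domain_thickness_mm
        Optional reduced z extent.  With needles exposed through the full
        thickness the problem is z-invariant, so a thin slab reproduces the
        2-D two-wire solution at a fraction of the cost.
    """
    sigma_tumor, sigma_background = conductivities_s_per_m
    _require(sigma_tumor > 0 and sigma_background > 0, "conductivities must be positive")
    _require(resolution_mm > 0, "resolution must be positive")
    if electrodes.mode != "needle_pair":
        raise ValueError("build_domain rasterizes needle-pair configurations only")
    _require(
        resolution_mm <= electrodes.electrode_radius_mm,
        f"resolution {resolution_mm} mm is coarser than the electrode radius "
        f"{electrodes.electrode_radius_mm} mm",
    )

    if extent_mm is None:
        extent_mm = 4.0 * electrodes.spacing_mm
    _require(tumor_diameter_mm >= 0, "tumor diameter must be non-negative")
    _require(tumor_diameter_mm < extent_mm, "tumor larger than domain")

    # even voxel counts keep the voxel-center lattice mirror-symmetric
    # about the domain center (electrode midpoint)
    def n_of(ext: float) -> int:
        n = int(np.ceil(ext / resolution_mm))
        return n + (n % 2)

    nx = ny = n_of(extent_mm)
    nz = n_of(domain_thickness_mm) if domain_thickness_mm is not None else nx
    h = resolution_mm
    cx = nx * h / 2.0
    cy = ny * h / 2.0
    cz = nz * h / 2.0

    xs = (np.arange(nx) + 0.5) * h
    ys = (np.arange(ny) + 0.5) * h
    zs = (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    if tumor_diameter_mm > 0:
        r = tumor_diameter_mm / 2.0
        d2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
        tumor = d2 <= r**2
        if not tumor.any():
            # sub-voxel tumor: keep at least the voxel nearest the center
            tumor.flat[np.argmin(d2)] = True
        labels[tumor] = Label.TUMOR

    exposed = electrodes.exposed_length_mm
    if exposed is None:
        exposed = tumor_diameter_mm if tumor_diameter_mm > 0 else nz * h
    exposed = min(exposed, nz * h)
    half_sep = electrodes.spacing_mm / 2.0
    a = electrodes.electrode_radius_mm
    for x0, lab in ((cx - half_sep, Label.ELECTRODE_PLUS), (cx + half_sep, Label.ELECTRODE_MINUS)):
        _require(x0 - a >= 0 and x0 + a <= nx * h, "electrodes outside domain")
        cyl = ((X - x0) ** 2 + (Y - cy) ** 2 <= a**2) & (np.abs(Z - cz) <= exposed / 2.0)
        if not cyl.any():
            raise ValueError("electrode rasterized to zero voxels; refine the grid")
        labels[cyl] = lab

    sigma = np.where(labels == Label.TUMOR, sigma_tumor, sigma_background)
    # electrode voxels are perfect conductors; the value here only feeds the
    # face conductance linking electrode surface to tissue
    sigma[labels >= Label.ELECTRODE_PLUS] = max(sigma_tumor, sigma_background) * 100.0

    return TissueDomain(
        label_grid=labels,
        conductivity_grid=sigma.astype(np.float64),
        voxel_size_mm=h,
        tumor_center_mm=(cx, cy, cz),
        tumor_diameter_mm=tumor_diameter_mm,
        tumor_conductivity_s_per_m=sigma_tumor,
        background_conductivity_s_per_m=sigma_background,
    )


def _assemble(domain: TissueDomain, electrodes: ElectrodeConfig):
    """Build the SPD finite-volume system for the free (non-electrode) voxels."""
    labels = domain.label_grid
    sigma = domain.conductivity_grid
    if (sigma <= 0).any():
        raise ValueError("zero or negative conductivity voxel")
    free = labels < Label.ELECTRODE_PLUS
    nfree = int(free.sum())
    idx = -np.ones(labels.shape, dtype=np.int64)
    idx[free] = np.arange(nfree)

    vplus = electrodes.applied_voltage_v / 2.0
    dirichlet = np.zeros(labels.shape)
    dirichlet[labels == Label.ELECTRODE_PLUS] = vplus
    dirichlet[labels == Label.ELECTRODE_MINUS] = -vplus

    rows, cols, vals = [], [], []
    diag = np.zeros(nfree)
    rhs = np.zeros(nfree)

    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        s_lo, s_hi = tuple(sl_lo), tuple(sl_hi)

        # face conductance g = sigma_face * h (units S*mm/m; constant factors
        # cancel in the linear system)
        g = 2.0 * sigma[s_lo] * sigma[s_hi] / (sigma[s_lo] + sigma[s_hi]) * domain.voxel_size_mm
        lo_free = free[s_lo]
        hi_free = free[s_hi]
        i_lo = idx[s_lo]
        i_hi = idx[s_hi]

        both = lo_free & hi_free
        rows.append(i_lo[both])
        cols.append(i_hi[both])
        vals.append(-g[both])
        np.add.at(diag, i_lo[both], g[both])
        np.add.at(diag, i_hi[both], g[both])

        # free voxel facing a Dirichlet electrode voxel
        lo_only = lo_free & ~hi_free
        np.add.at(diag, i_lo[lo_only], g[lo_only])
        np.add.at(rhs, i_lo[lo_only], g[lo_only] * dirichlet[s_hi][lo_only])
        hi_only = hi_free & ~lo_free
        np.add.at(diag, i_hi[hi_only], g[hi_only])
        np.add.at(rhs, i_hi[hi_only], g[hi_only] * dirichlet[s_lo][hi_only])

    r = np.concatenate(rows + [np.arange(nfree)])
    c = np.concatenate(cols + [np.arange(nfree)])
    v = np.concatenate(vals + [diag])
    upper = csr_matrix((v, (r, c)), shape=(nfree, nfree))
    A = upper + csr_matrix((np.concatenate(vals), (np.concatenate(cols), np.concatenate(rows))), shape=(nfree, nfree))
    return A, rhs, idx, free, dirichlet, diag


def solve_field(
    domain: TissueDomain,
    electrodes: ElectrodeConfig,
    tolerance: float = 1e-6,
    max_iter: int = 50_000,
) -> FieldMap:
    """Solve div(sigma grad phi) = 0 and return the field-magnitude map.

    Dirichlet +V/2 / -V/2 on the electrode voxel sets, insulating outer
    boundary.  Conjugate gradients with Jacobi preconditioning; raises
    ``RuntimeError`` if the relative residual does not reach ``tolerance``
    within ``max_iter`` iterations.
    """
    _require(tolerance > 0, "tolerance must be positive")
    if not (domain.label_grid >= Label.ELECTRODE_PLUS).any() and electrodes.applied_voltage_v > 0:
        raise ValueError("no electrode voxels in domain but voltage applied")

    h = domain.voxel_size_mm
    if electrodes.applied_voltage_v == 0.0:
        zeros = np.zeros(domain.grid_shape)
        return FieldMap(zeros, zeros.copy(), h, electrodes, 0.0, 0)

    A, rhs, idx, free, dirichlet, diag = _assemble(domain, electrodes)
    M = LinearOperator(A.shape, matvec=lambda x: x / diag)
    iters = 0

    def count(_):
        nonlocal iters
        iters += 1

    phi_free, info = cg(A, rhs, rtol=tolerance, atol=0.0, maxiter=max_iter, M=M, callback=count)
    if info != 0:
        raise RuntimeError(f"field solver failed to converge (cg info={info})")
    residual = float(np.linalg.norm(rhs - A @ phi_free) / np.linalg.norm(rhs))

    phi = dirichlet.copy()
    phi[free] = phi_free
    gx, gy, gz = np.gradient(phi, h)
    mag = np.sqrt(gx**2 + gy**2 + gz**2) * MM_PER_CM  # V/mm -> V/cm
    # interior of the electrodes is an equipotential; zero the rasterized core
    mag[domain.label_grid >= Label.ELECTRODE_PLUS] = 0.0
    return FieldMap(mag, phi, h, electrodes, residual, iters)


def electrode_currents(domain: TissueDomain, fieldmap: FieldMap) -> tuple[float, float]:
    """Net current (arbitrary consistent units) into the + and out of the - electrode.

    Summed face-by-face as g * (phi_electrode - phi_neighbor); with a
    converged solve the two magnitudes agree to well under 1%.
    """
    labels = domain.label_grid
    sigma = domain.conductivity_grid
    phi = fieldmap.potential_grid
    free = labels < Label.ELECTRODE_PLUS
    totals = {Label.ELECTRODE_PLUS: 0.0, Label.ELECTRODE_MINUS: 0.0}
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        s_lo, s_hi = tuple(sl_lo), tuple(sl_hi)
        g = 2.0 * sigma[s_lo] * sigma[s_hi] / (sigma[s_lo] + sigma[s_hi]) * domain.voxel_size_mm
        dphi = phi[s_lo] - phi[s_hi]
        for lab in totals:
            m = (labels[s_lo] == lab) & free[s_hi]
            totals[lab] += float(np.sum(g[m] * dphi[m]))
            m = (labels[s_hi] == lab) & free[s_lo]
            totals[lab] -= float(np.sum(g[m] * dphi[m]))
    return totals[Label.ELECTRODE_PLUS], totals[Label.ELECTRODE_MINUS]


def load_config(path: str | Path) -> tuple[ElectrodeConfig, dict]:
    """Read an electrode/tissue/grid/solver YAML or JSON configuration.

    Keys: ``electrode{mode, spacing_mm, radius_mm, voltage_V}``,
    ``tissue{tumor_diameter_mm, sigma_tumor_S_per_m, sigma_background_S_per_m}``,
    ``grid{voxel_mm, extent_mm}``, ``solver{tol, max_iter}``.
    Returns the ElectrodeConfig and the remaining sections as a dict.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    e = cfg.get("electrode", {})
    electrodes = ElectrodeConfig(
        mode=e.get("mode", "needle_pair"),
        spacing_mm=float(e.get("spacing_mm", 5.0)),
        electrode_radius_mm=float(e.get("radius_mm", 0.5)),
        exposed_length_mm=e.get("exposed_length_mm"),
        applied_voltage_v=float(e.get("voltage_V", 0.0)),
    )
    return electrodes, cfg


def build_domain_from_config(cfg: dict, electrodes: ElectrodeConfig) -> TissueDomain:
    t = cfg.get("tissue", {})
    g = cfg.get("grid", {})
    return build_domain(
        tumor_diameter_mm=float(t.get("tumor_diameter_mm", 0.0)),
        conductivities_s_per_m=(
            float(t.get("sigma_tumor_S_per_m", 0.2)),
            float(t.get("sigma_background_S_per_m", 0.2)),
        ),
        electrodes=electrodes,
        resolution_mm=float(g.get("voxel_mm", 0.25)),
        extent_mm=g.get("extent_mm"),
    )


def export_vtk(fieldmap: FieldMap, path: str | Path) -> None:
    """Write |E| as a legacy-ASCII VTK structured-points file."""
    mag = fieldmap.magnitude_grid
    nx, ny, nz = mag.shape
    h = fieldmap.voxel_size_mm
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("electric field magnitude (V/cm)\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {h / 2} {h / 2} {h / 2}\n")
        fh.write(f"SPACING {h} {h} {h}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("SCALARS E_magnitude float 1\nLOOKUP_TABLE default\n")
        # VTK expects x fastest
        np.savetxt(fh, mag.transpose(2, 1, 0).reshape(-1, 1), fmt="%.6g")


def field_summary(fieldmap: FieldMap, domain: TissueDomain) -> dict[str, float]:
    """Min/max/percentile |E| within the tumor, in V/cm."""
    vals = fieldmap.magnitude_grid[domain.tumor_mask]
    if vals.size == 0:
        raise ValueError("domain has no tumor voxels")
    return {
        "min_v_per_cm": float(vals.min()),
        "p05_v_per_cm": float(np.percentile(vals, 5)),
        "median_v_per_cm": float(np.median(vals)),
        "p95_v_per_cm": float(np.percentile(vals, 95)),
        "max_v_per_cm": float(vals.max()),
    }
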