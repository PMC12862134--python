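# Methods

## Electric-field model

IRE pulses are microseconds long, so the tissue response is quasi-static:
the potential obeys the conduction equation ∇·(σ∇φ) = 0 with Dirichlet
potentials +V/2 and −V/2 on the two needle surfaces and an insulating
(zero normal current) outer boundary. Pulse-train parameters (90 bursts of
90 µs at 1 Hz) are carried as metadata only — the transient waveform,
Joule heating, and field-dependent (dynamic) conductivity are outside the
model's scope, so the solved map is the *static* field at the applied
voltage.

**Discretization.** Regular Cartesian voxels (default 0.25 mm for
planning), a 7-point finite-volume stencil with *harmonic* averaging of σ
at voxel faces — the correct flux-continuous average across the
tumor/background conductivity jump. Needles are rasterized as solid
cylinders (radius 0.5 mm; published two-needle probes give no diameter),
axes perpendicular to the tumor's equatorial plane, exposed length
defaulting to the tumor diameter. Electrode voxels are eliminated as
Dirichlet unknowns, keeping the system symmetric positive-definite; it is
solved with Jacobi-preconditioned conjugate gradients (relative residual
1e-6, cap 50,000 iterations). |E| is the central-difference gradient
magnitude, reported in V/cm.

**Boundary placement.** The outer boundary is insulating and placed at 4×
the electrode spacing. Halving or doubling that margin moves the midpoint
field by well under 1% (the dipole-like return field decays quadratically),
which is why the default is not exposed as a tuning knob.

**Verification.** For a homogeneous medium with needles exposed through
the full slab thickness the problem is z-invariant and equals the 2-D
two-cylinder (bipolar coordinates) problem, whose exact midpoint field is
V / (b·acosh(d/2a)), b = √((d/2)² − a²). The solver converges to this
value monotonically under grid refinement (≈3.8% error at 0.2 mm, ≈1.9% at
0.1 mm for d = 5 mm, a = 0.5 mm). Discrete current conservation between
the two electrodes holds to machine precision by construction of the
symmetric system, and is asserted to <1% in tests via independent
face-flux summation.

**Linearity.** The problem is linear in V and invariant to a global σ
rescale. The planner exploits this: each scenario is solved once at a
reference voltage and |E| is rescaled exactly per candidate
voltage-to-distance ratio, so a 5-ratio (or 21-ratio) sweep costs one
solve per scenario.

## Threshold calibration

The hydrogel is a uniform phantom, so its field map is known up to
discretization, and the lethal threshold is read off at the lesion
boundary. The default lesion summary is the **axis extent** (caliper-like
total width along the inter-electrode axis): the threshold is |E|
interpolated at extent/2 from the midpoint, restricted to the decaying
branch outside the needle (inside the gap the mapping is not monotone and
a lesion enclosing both needles cannot end there). The two symmetric
half-axes are averaged to cancel rasterization asymmetry. An **area mode**
(isocontour level whose enclosed equatorial-plane area matches, found by
bisection) serves image-derived lesions. Replicates are inverted
independently and summarized as mean, sample SD (ddof = 1), min, max —
no hierarchical model, matching how such calibrations are reported.

Round-trip accuracy is grid-limited: generating a lesion from any level
and inverting recovers it to within one interpolation increment (exact to
~1e-6 relative in tests because generation and inversion share the
profile).

## Monte-Carlo dose planning

Per scenario: tumor diameter ~ U(4, 8) mm; needle spacing = diameter − 1 mm
(the insertion rule); tumor conductivity ~ U(0.1, 0.5) S/m and background
~ U(0.02, 0.2) S/m — literature-typical soft-tissue/subcutaneous-fat
ranges, chosen here because the study conditions do not pin them down, and
exposed in the sensitivity table rather than tuned; lethal threshold ~
Normal(525, 77) V/cm truncated to the calibrated [442, 613] range
(a `fixed` mode plans with the mean only, `worst_case` with 613).
Candidate ratios are 1,000–3,000 V/cm in 500-V/cm steps (the published
range; the step is an implementation choice, and the sensitivity table
reports the selection at 250- and 100-V/cm steps, computed exactly from
the same solves via linearity).

Coverage is the fraction of tumor voxels with |E| ≥ threshold; "fully
ablates" means coverage exactly 1.0 at the planning resolution (0.25 mm).
The selected dose is the smallest candidate ratio with coverage 1.0 in
*every* scenario; if none qualifies the maximum ratio is returned flagged
incomplete. Coverage is asserted non-decreasing in ratio on every run.
With 30 scenarios the selection concentrates on 2,500 V/cm: the binding
scenarios are large (≈8 mm), high-contrast (conductive tumor in resistive
fat) tumors with thresholds near the calibrated maximum, whose weakest
point is the tumor equator farthest from both needles. Because the
scenario draw is random, an occasional seed yields no scenario requiring
more than 2,000 V/cm; the per-scenario required-ratio distribution in the
sensitivity output makes this visible. Seeds fan out from one master
`SeedSequence`; identical seeds give identical plans.

Master-seed planning at 0.25 mm (30 solves, largest grid 112³) runs in
about two minutes on one CPU; conductivity-range sensitivity variants
re-solve 10 scenarios at 0.5 mm, a deliberate scale-down that leaves the
selected dose unchanged in all runs we report.

## Spheroid quantification

Segmentation replaces the manual ROI workflow deterministically: Gaussian
smoothing (σ = 2 px), Otsu threshold, largest connected component, hole
filling; a constant image yields an explicit empty-mask result.
Segmentation is invariant to affine intensity rescaling (Otsu property).
Intensities are summarized as mean inside the mask minus mean background,
where background excludes a 10-px dilation of the mask to avoid halo
contamination; the deep-red (CAR-T) channel is measured under the
green-derived mask, making net deep-red an infiltration measure. Net
intensities are invariant to constant offsets by construction. Tracks
normalize net green and area to each spheroid's own pre-treatment frame
(first timepoint); a plate-level baseline would differ only by well-to-well
brightness variation, which the generator does not model. XTT absorbance
uses the conventional reference-wavelength subtraction A475 − A660 (a
ratio mode is provided), expressed as fold of the untreated-control mean.

## Synthetic-data generators

All generators are pure functions of (spec, seed) via `numpy`
`SeedSequence` hierarchies.

**Dose–response.** Field → viable fraction is log-logistic,
v(E) = v₀ / (1 + (E/E₅₀)^h), the standard sigmoid for electroporation
kill curves. v₀, E₅₀, h are fixed in closed form by the three measured
viability anchors (94.99% at 0, 34.40% at 1,000, 3.30% at 2,000 V/cm),
giving E₅₀ ≈ 867 V/cm and h ≈ 3.98; the anchors are reproduced exactly and
therefore sit inside their printed min–max brackets.

**Hydrogel lesions.** One field solve (homogeneous slab, full-thickness
needles, 0.2-mm grid, 2-mm slab — z-invariant so equivalent to the full
3-D phantom at its midplane); the truth threshold's axis extent is
perturbed multiplicatively by Normal(0, cv) per replicate. 5% cv matches
caliper-scale relative error.

**Spheroid series.** Disk spheroid (radius 40 px at 10 µm/px) imaged at
0/3/24/48/72 h. Green inside the disk scales with the viable fraction
plus an 8% dead-cell residual (keeps near-complete-kill spheroids
segmentable, standing in for the bright-field guidance of manual ROIs —
normalized green therefore bottoms out near 0.09 rather than 0).
Survivors regrow logistically (0.04 h⁻¹) only below 1,500 V/cm and
without CAR-T, producing the 72 h > 3 h rebound; at/above 1,500 V/cm with
CAR-T the residual is cleared instead. Treated spheroids swell (radius
factor increasing linearly with field, reflecting electro-dysregulation,
not growth); CAR-T erodes the radius outside-in. Deep-red adds a thin
T-cell ring at the boundary (within the background-exclusion halo, so it
does not bias the background) and an interior signal proportional to the
programmed infiltration fraction — high-early-flat for the combination,
low-early-rising for CAR-T alone. Pixel noise is Poisson plus Gaussian
(σ = 2). Only qualitative orderings of these image-derived quantities are
asserted, because the source study reports no spheroid-size or
infiltration magnitudes.

**In-vivo cohort.** Four arms (sham, CAR-T, IRE, combination), n = 6.
Exponential growth from 15 mm³ with per-animal lognormal rate
heterogeneity (median 0.15 d⁻¹, cv 0.2 — a ~5-day doubling typical of
aggressive subcutaneous xenografts); measurements on a Mon/Wed/Fri
schedule. Treatment at the first measurement exceeding 100 mm³. IRE and
combination volumes drop to 0 at the first measurement ≥ 48 h
post-treatment; IRE recurs with probability 4/6 after a U(10, 25)-day
delay, regrowing from 10 mm³; the combination never recurs; CAR-T alone
grows 20% slower. Caliper pairs derive from volume with a fixed 0.8
width/length aspect; euthanasia when either dimension reaches 12 mm,
censoring at day 60. What these generators do *not* emulate — measurement
noise correlations, partial responses, immune kinetics — means passing
closure tests demonstrates the pipeline's logic, not biological fidelity.

## Survival analysis

Kaplan–Meier curves and log-rank statistics are computed with `lifelines`
and exposed as a plain (time, at-risk, events, survival) table; tests
cross-check a hand-computed six-subject product-limit table and the direct
hypergeometric-variance log-rank formula. PFS is defined operationally
(the source never states it): time from treatment to the first
progression/recurrence day from `classify_response`, censored at the
earlier of euthanasia and day 60. Bonferroni k defaults to the number of
pairwise comparisons (6 for 4 arms); adjusted p = min(1, p·k). Tied event
times share the simultaneous risk set.

## Known limitations

- Static, voltage-independent conductivity; no thermal model — the planner
  is a pre-treatment geometry tool, not a pulse-physics simulator.
- The skin/fat layering of real subcutaneous anatomy is collapsed into one
  background compartment, since the study randomizes conductivities without
  printing layer values.
- Coverage "exactly 1.0" is resolution-dependent at the tumor surface;
  the 0.25-mm default resolves the binding near-equator voxels to within
  the candidate-ratio step.
- The hydrogel calibration's electrode geometry, voltages, and conductivity
  are configurable but exercised only on synthetic data.
- Animal-level outcome statistics (recurrence fractions, survival
  significance) are generator contracts, not reproductions of experimental
  numbers.
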