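# Methods

This note documents the models behind `interplay4d`, their assumptions,
the tunable parameters with defaults, and the numerical choices made
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate conventions

All volumes, masks and fields share one grid with axis order (LR, AP,
IS): axis 0 toward patient left, axis 1 toward anterior, axis 2 toward
superior; millimetres at voxel centers, origin at the grid center.
Default study grids are 96³ at 2.5 mm (fine) and 64³ at 3 mm or 48³ at
4 mm (desk scale); all results in the test suite state the grid used.

## Synthetic phantom

The phantom emulates an abdominal planning CT with a pancreatic target:
an elliptic soft-tissue body with a fat rim, a posterior vertebral
column (bone, HU 700) enclosing a 4 mm-radius spinal cord, lateral
kidneys, a right-sided liver, an anterior bowel compartment, and an
ellipsoidal CTV just anterior to the spine. The CTV ellipsoid's radial
scale is bisected against the discrete voxel count so the voxelized
volume matches the requested volume in cc (within far less than the 5%
guard the builder enforces). GTV is a 0.75-scaled copy of the CTV;
ITV and PTV are placeholders (CTV, CTV + 5 mm) until breathing motion
is known. Configurations whose CTV touches the vertebral column are
rejected. Grids coarser than ~4 mm cannot resolve the cord and are
rejected by the structure validator.

What the phantom does **not** emulate: realistic HU texture, gas
pockets, patient-to-patient anatomical topology changes, or CTV shapes
other than ellipsoids. Conclusions from tests on this phantom
demonstrate the mechanics and statistics of interplay, not absolute
patient dosimetry.

## Breathing motion model

One "measurement" is a 20-phase periodic displacement field set with
period T ∈ [2.8, 10] s (the range spanned by the studied cohort).
Fields are separable:

    u(x, j) = envelope(x) · sin²(π j / 20) · a ,

* `envelope` — product of per-axis C¹ raised-cosine windows, equal to 1
  at a focus point (the CTV centroid), zero for all AP positions at or
  behind the spine (so bone and cord stay static) and zero at the grid
  boundary. An optional seed shrinks the window support by up to 25%
  per side, emulating day-to-day variation of the motion *shape*
  without changing the focus amplitude.
* `sin²` — the regular-breathing temporal factor; phase 0 is
  end-exhalation (EEX, zero field), phase 10 end-inhalation (EIN,
  maximal displacement). Phases are uniform in time; amplitude binning
  is not modelled. Only regular breathing is represented — no drift,
  no irregular cycles.
* `a` — signed peak displacement (default signs: left, anterior,
  inferior at inhalation). Requested amplitudes are met exactly at the
  focus; the generator rejects amplitudes that would fold space
  (min det(I + ∇u) ≤ 0.05 of the EIN field).

`rescale_period` produces a variant sharing the displacement fields
with only T replaced — amplitudes are deliberately **not** rescaled
with the cycle length. Variants are flagged as non-measured and share
all geometric caches with their source.

### Warping conventions

Two mutually incompatible conventions circulate for applying a
displacement field that "maps EEX to phase j", and a single field
cannot serve pull-back image warping and pull-back dose mapping
simultaneously without a sign inconsistency. This package resolves the
ambiguity by fixing the *material* interpretation: material at
reference position x sits at x + u(x) during phase j. Consequently:

* `warp_image` is the generic pull-back resampler (output(x) =
  input(x + u(x)), trilinear, air fill −1000 HU) — useful as a building
  block and tested as such;
* everything that must move *with* the anatomy — the synthetic phase CT
  (`phase_image`), warped delineations (`warp_mask_forward`, trilinear
  with a 0.5 threshold), the ITV union, the per-phase density the dose
  engine sees, and the QA mass ratio's EIN volume — uses the
  first-order inverse, sampling at x − u(x);
* dose accumulation pulls each phase dose back by sampling at
  x + u(x), i.e. material at x reads the dose at its displaced
  position. ITV coverage and dose accumulation are therefore on the
  same side of the motion by construction.

The first-order inverse is accurate to O(|u|·|∇u|), which for ≤15 mm
amplitudes and ≥40 mm envelope length scales is well below a voxel.

Trilinear-threshold (not nearest-neighbour) mask warping is used
because nearest-neighbour resampling of near-identity fields exhibits a
lattice-commensurability bias of a few percent in warped-mask volumes.

## Deformation-field QA

* **Jacobian determinants**: det(I + ∇u) with central finite
  differences in mm (one-sided at the boundary), evaluated inside the
  OAR delineations (liver, kidneys, bowel) for the EEX→EIN field.
  Values ≤ 0 are counted as folding.
* **Mass conservation**: m_EEX = Σ voxel·ρ(HU) over the delineation;
  m_EIN likewise over the delineation and image pushed to EIN; the
  ratio m_EEX/m_EIN estimates how far intensity warping is from mass
  conserving. The HU→density table is generic piecewise-linear with
  nodes (−1000, 0.001), (−100, 0.93), (0, 1.0), (100, 1.09),
  (1000, 1.6) g/cm³, clamped outside.

## PBS dose engine

A deliberately simplified, self-contained engine: the study's claims
concern interplay *statistics*, which depend on delivery time structure
and geometry, not on absolute dosimetric fidelity.

* **Range–energy**: R[cm] = α·E^p with α = 0.0022, p = 1.77 (protons in
  water); energy table 30–250 MeV.
* **Depth dose**: a straggling-broadened Gaussian peak at R(E) riding
  on a gently rising entrance plateau (entrance ≈ 25% of peak) that is
  faded out logistically across the peak; normalized to 1 at the actual
  curve maximum; identically zero beyond R + 4σ_R. The peak width is
  σ_R = hypot(0.012·R^0.935 cm, 2.5 mm); the 2.5 mm floor represents
  beam energy spread and keeps adjacent 5 mm energy layers overlapping
  into a smooth spread-out peak — with pure range straggling (~1 mm at
  10 cm) the layer ripple would force unrealistically spiky weights.
* **Lateral model**: single Gaussian, σ(wepl) = 3 mm + 0.02·wepl,
  normalized to unit lateral integral (so integral depth dose is
  independent of σ). No nuclear halo, no aperture.
* **WEPL**: density (standing in for relative stopping power) is
  resampled onto a beam-aligned (u, v, s) grid and cumulatively
  integrated along s with half-cell trapezoid correction — exact in
  homogeneous media. The patient array is padded by one air voxel so
  the boundary blends over half a voxel, and the depth axis extends two
  steps beyond the grid so no entry skirt is clipped. Gantry rotates in
  the axial plane: direction d = (−sin θ, −cos θ, 0), lateral axes
  u = (cos θ, −sin θ, 0), v = IS (right-handed).
* **Dose computation**: per energy layer, the per-voxel Bragg depth
  factor multiplies a lateral sum of spot Gaussians synthesized in the
  Fourier domain (exact spot positions as phase factors; σ taken at
  each slice's mean radiological depth; batched inverse FFT). A direct
  per-spot superposition (`deposit_spots`, σ per voxel) is retained as
  the reference path and cross-checked against the Fourier path in the
  tests; in water the two agree to a few percent of the maximum, the
  difference being the slice-averaged σ and the grid's band limit.

### SFUD planning

Each of the two fields is optimized independently to a uniform
half-prescription dose on the PTV: spots on a 5 mm lateral grid
covering the PTV projection (one spot ring of margin) and energy layers
every 5 mm WEPL with 2 mm proximal/distal margins. Non-negative weights
come from multiplicative (MLEM-style) updates w ← w·(Aᵀd)/(AᵀAw) on up
to 3000 sampled PTV voxels, stopped when the relative residual improves
by less than 1e-4 or after 60 iterations. The iteration cap is a
deliberate regularizer: fully converged multiplicative updates produce
spiky weight maps (single spots carrying large dose), which are neither
clinically realistic nor representative of SFUD delivery; early
stopping keeps weights smooth. The init is near-uniform with a small
gradient (Aᵀd) tilt — scale-invariant in shape, hence optimized weights
are exactly linear in the prescription. After optimization the plan is
normalized so the static CTV median dose is 100%; all 4D doses are then
in % of the per-fraction prescription.

### Delivery dynamics

Spots are delivered layer by layer (most distal first), serpentine
within a layer. Timing: weight-proportional dwell (calibrated per field
so the median dwell is 5 ms unless `seconds_per_mu` is set), 3 ms
lateral moves, 1 s energy-layer switches — the same order of magnitude
as scanned-proton gantries, so a field takes some tens of seconds and
spans several 2.8–10 s breathing cycles. These constants are declared
substitutes for proprietary machine parameters, not reconstructions.

## 4D dose accumulation

Each spot's start timestamp, the period T and the field's starting
phase give its breathing phase (uniform time bins). Spots of one phase
deposit on that phase's geometry — the per-phase density is the CT
sampled at x − u_j(x), i.e. WEPL is re-traced per phase, which is the
density-change mechanism — and the phase dose is pulled back to the
reference frame at x + u_j(x). The fraction dose sums both fields with
independent starting phases (i, k); whether the second field's start
should instead continue from the first field's end is not modelled —
independent randomization is used.

The engine exploits two structural facts for speed: (1) grouping spots
by (energy layer, time-bin mod 20) makes the groups independent of the
starting phase, so each group's lateral dose field is computed once per
(field, period) and reused for all 20 starts and all motion inputs
sharing the period; (2) with 20 phases there are only 20 distinct
per-field doses per motion input, so arbitrarily many simulated
fractions are combinations of ≤ 40 cached dose grids per motion input.
CTV-restricted dose vectors are cached separately from full grids.
Within-spot motion is neglected (dwell ≪ phase bin width). The lateral
σ of the Fourier path uses the static slice-mean WEPL for all phases;
breathing perturbs the slice-mean WEPL by a few mm at most, i.e. σ by
hundredths of a mm, while the per-phase Bragg depth factor carries the
full density change.

The single-fraction (4Dx1) ensemble enumerates starting phases either
as the 20 diagonal pairs (i = k) or the full 20×20 grid (configurable;
the study default is diagonal, the acceptance checks state which they
use).

## Fractionation simulation

Per fraction, a motion input m and starting phases (i, k) are drawn
independently and uniformly; the cumulative dose after n fractions is
the mean of the first n fraction doses (all in % of per-fraction
prescription, so metrics are comparable across n). Randomness comes
from the counter-based Philox generator with one named seed per
realization (ensemble seeds spawned from a master seed), making
realizations reproducible and order-independent. The longitudinal
comparison runs 30 simulated treatments using only the first
measurement versus 30 sampling all measurements per fraction, and
reports per-n ensemble means of d5/d95 and their absolute difference.

## Dose metrics and statistics

Percentile metrics (d2, d5, d95) use the linear-interpolation quantile
of the sorted voxel-dose list — bit-reproducible given a dose grid;
volume metrics (v95, v107, v30) are exact voxel counts. The exported
DVH curve uses 0.1% bins, but queries interpolate on raw voxel doses,
so bins affect exports only. Scenario comparisons use the one-sided
Wilcoxon rank-sum test (exact null for combined n ≤ 20 without ties,
normal approximation with tie correction otherwise, α = 0.05); fully
tied samples return p = 0.5 with a flag.

## Correlation analysis

Weighted Pearson correlation with frequency-weight semantics (equal to
replicating each patient by its number of repeated motion
measurements). Significance uses t = ρ_w·√((N−2)/(1−ρ_w²)) against the
one-sided 95% Student-t critical value, strict inequality. For N = 9
the conventional tabulated value 1.833 corresponds to df = 9, while the
statistic's N − 2 = 7 degrees of freedom would give 1.895; both are
supported and df = 9 is the default, matching common tabulated usage.
|ρ| = 1 yields a flagged signed infinity. The four-row suite correlates
amplitude↔d5/d95, period↔amplitude and period↔d5/d95 with measurement
weights, and CTV volume↔d5/d95 unweighted (volumes are constant across
fractions, so repeated measurements add no information). Intra-patient
dependencies are reported descriptively only; no coefficients are fit
to samples of fewer than about five points.

## Default study population

Nine pseudo-patients span IS amplitudes 2–15 mm (AP/LR a few mm),
periods 2.8–10 s, CTV volumes 33–195 cc, and 1–3 repeated measurements
each plus period-rescaled variants — the regime of the motivating
clinical cohort, with a built-in positive period–amplitude association.
Posterior-oblique (160/210°) and anterior (20/340°) beam arrangements
both occur. Desk-scale defaults: 48³ grid at 4 mm, diagonal starting
phases, 5 fractionation realizations and 10 longitudinal realizations
per patient (the full study runs in about two minutes on one CPU);
the acceptance-grade checks use 64³ at 3 mm with ≥ 20–30 realizations,
and the static-limit check uses the full 96³ grid.

## Known limitations

* Separable single-mode motion: no hysteresis (inhale and exhale
  trajectories coincide), no irregular breathing, no baseline drift.
* The phase CT is a resampling of one reference CT: no sliding
  interfaces, no density changes from lung inflation.
* Analytic beam model: no Monte-Carlo transport, no nuclear halo, no
  heterogeneity-induced lateral scattering; density stands in for
  stopping power; constant RBE 1.1 is implicit in the prescription and
  never varied.
* Deformable dose mapping by trilinear pull-back, not mass- or
  energy-conserving remapping; the QA module quantifies the associated
  mass error instead.
* Machine timing constants are order-of-magnitude substitutes; absolute
  interplay magnitudes therefore carry a model uncertainty that the
  relative comparisons (3DDC vs 4Dx1 vs 4Dx28, amplitude sweeps) are
  designed to cancel.
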