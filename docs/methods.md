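# Methods

This note records the models behind `spectdose`, the parameters that matter
and their defaults, what the synthetic data does and does not emulate, and
the numerical choices a maintainer would want explained.

## Scope and design stance

The package qualifies a quantitative ¹⁷⁷Lu SPECT/CT chain end to end at
desk scale.  Physical measurements that depend on a particular scanner —
the absolute volume sensitivity of a camera, the mechanical misalignment of
an NM/CT gantry pair — cannot be derived from first principles, so the
package treats them two ways: measured commissioning values are carried as
*inputs* (`spectdose.datasets`) on which the QA arithmetic is exercised
exactly, and the measurement *procedures* are validated as parameter-recovery
simulations against a synthetic truth (impose a known sensitivity or shift,
run the full estimation chain, compare).

## Decay bookkeeping (`units`)

Activity follows A(t) = A₀·2^(−Δt/T½).  T½ is fixed at 6.6500 d — the value
used on the bundled chamber commissioning ledger — rather than the common
literature 6.647 d; the difference is 0.05% over a week and using the ledger
value lets the ledger's own calculated column reproduce to ≤0.04% on four of
five rows.  The fifth row (10/31) disagrees by 0.10% however the decay is
computed, consistent with a timestamp rounded on the original worksheet; it
is not forced.  Timestamps are naive local times in `MM/DD/YY HH:MM` at
minute resolution — the dialect of calibrator worksheets — with no timezone
or DST handling.  mCi↔MBq uses the exact definitional factor 37.

`energy_per_decay_J` defaults to 147.9 keV (2.369×10⁻¹⁴ J): the mean β
energy plus conversion/Auger electrons of ¹⁷⁷Lu from standard decay data,
i.e. the locally absorbed energy per decay.  It is a configurable constant
of the dose model, not a measured system value, and the 208-keV photon
emission deliberately does not contribute (photons mostly escape the voxel;
local deposition applies to the electron component).

## Calibrator QA (`calibrator`)

Constancy rows carry the decay-calculated activity and the signed percent
difference 100·(measured − calculated)/calculated per chamber; rounding to
two decimals is display-only.  Linearity fits measured vs expected activity
directly (the response is plotted against activity, not log-activity) with
ordinary least squares; the correlation is reported at full precision and
rounded to one decimal for the QA sheet.  Tolerance flags (default warn at
±5%) are configurable — no universal numeric action level exists for
constancy checks.

## Digital phantoms (`phantoms`)

The NEMA-style body is a water-filled elliptical cylinder; the full IEC
outline (lung insert, shaped contour) adds attenuation detail that does not
change the quantification logic under test.  Default semi-axes in the
end-to-end configuration are 140×95 mm so the body fits inside the circle
inscribed in the default 64-pixel, 283-mm field of view (the projector
drops content rotated outside the grid).  The three spheres (22/28/37 mm;
0.13/0.27/0.63 mCi) sit on the conventional 114.4-mm-diameter ring, 120°
apart — sphere centres are a configuration choice since only the sphere
sizes and fills are fixed by convention.  The background is cold (spheres
hot in a non-radioactive body), matching the commissioning scenario.

Voxelization weights boundary voxels by a 3×3×3 midpoint sub-lattice
(configurable), which holds per-sphere activity totals to ≲0.2% on the
4.42-mm NM grid and improves under grid refinement.  Attenuation is single
energy: water μ = 0.0136 mm⁻¹ at 208 keV (from standard photon
cross-sections), uniform inside the body, zero outside; no bone or air
inserts.  Point sources are deposited with trilinear weights over eight
voxels, so each deposit's centroid equals the requested position to
machine precision — this sub-voxel fidelity is what lets registration QA
resolve hundredths of a millimetre on a 4.42-mm grid.

## Acquisition model (`simulate`, `projector`)

Parallel-beam geometry with one detector pixel per in-plane voxel column;
60 views over 360°, 64×64 pixels at 4.42 mm by default.  The collimator
response is a distance-independent 2-D Gaussian on the projection
(σ = 4.5 mm ≈ 10.6 mm FWHM, medium-energy general-purpose class);
distance-dependent response and septal penetration are out of scope — the
vendor reconstruction being emulated is itself a black box, and the
package's claims are about the correction/calibration chain, not collimator
physics.  Attenuation uses Beer–Lambert line integrals from each voxel to
the detector with a half-voxel self-attenuation term.

The in-plane rotation underlying the projector is a precomputed sparse
bilinear-interpolation matrix per angle with **columns normalized to unit
sum**, so rotation conserves activity exactly (plain bilinear gather leaks
a few percent for voxel-sharp sources).  The adjoint used everywhere is the
exact matrix transpose; with the self-adjoint zero-padded Gaussian blur and
diagonal attenuation weights, forward and adjoint are exact transposes of
each other, which keeps the MLEM likelihood monotone.

Scatter is modelled as the primary projection convolved with a wide
Gaussian (σ = 20 mm) scaled by a scatter-to-primary fraction (0.3, typical
of ¹⁷⁷Lu photopeak imaging in water), then distributed to the three energy
windows by fixed split fractions.  The default split is proportional to the
window widths (17.8/41.6/24.0 keV), i.e. a locally flat scatter spectrum —
exactly the regime the TEW trapezoid estimates without bias, so the
correction is exercised against a truth it can in principle recover.  Real
spectra are not flat; a deliberately skewed split will bias TEW and can be
configured to study that.  Window bounds are carried verbatim
(187.6–229.2, 228–252, 168.9–186.7 keV); no spectral transport is
simulated.  System sensitivity defaults to 5.1 cps/MBq per view, anchoring
count levels to a camera whose volume sensitivity is of order 5 cps/MBq;
view duration (30 s) and matrix size are modelling choices.  Poisson noise
is sampled per window with a single seed; noise-free simulation is exactly
linear in activity.

Rigid NM↔CT misalignment is applied to the emission map before projection.
`apply_offset` is trilinear by default (positivity-preserving, exact for
integer-voxel shifts); a spectral (`fourier`) variant is exact for
band-limited content and serves the shift-inverse property.

## Reconstruction and calibration (`recon`)

TEW: scatter per pixel = (C_low/W_low + C_up/W_up)·W_main/2, corrected
counts clamped at zero (negative counts would break the Poisson model
downstream).  MLEM with optional ordered subsets; default 8 iterations × 5
subsets = 40 MLEM-equivalent updates — a typical clinical operating point
that trades residual convergence bias for noise control.  The
reconstruction is returned in cps/voxel (counts over view duration) with
attenuation modelled in the projector, so images are attenuation- and
scatter-corrected but **not** resolution-recovered: no partial-volume or
recovery-coefficient correction is applied anywhere, matching the
calibration philosophy under test (the 10-mm VOI margin absorbs spill-out
instead).

Volume sensitivity: CF = (VOI count rate)/(true activity in MBq) on a
uniform-cylinder scan, with the VOI dilated by the same 10-mm margin so the
blur spill-out captured for spheres is captured for the calibration phantom
too; in the closed loop the measured CF recovers the simulated per-view
sensitivity to well under 5%.  Sphere recovery dilates each CT contour
**metrically** (Euclidean distance transform threshold, not voxel counts)
because the CT and NM grids differ; dilated VOIs must not overlap, and the
percent difference is signed with the injected activity as reference.

Mask resampling between grids interpolates the fractional indicator and
re-thresholds at 0.5, which preserves enclosed volume to about one NM voxel
(voxel-centre nearest sampling errs by many voxels for 22–37-mm spheres at
4.42 mm); fractional coverage itself is the volume-faithful representation,
and binary masks are used only where VOI membership is needed.

## Registration QA (`registration`)

Offsets are intensity-weighted-centroid differences (NM − CT) per source —
centroids rather than Gaussian fits for robustness at 4.42-mm voxels —
summarized as mean ± SD over the sources of one acquisition (five by
default; configurable).  Means are signed; the gate compares |mean| per
axis against 2.2 mm (the vendor limit spec; the one-pixel criterion is
reported informationally, not gated).  Images whose over-half-maximum
voxels form more than one substantial component are rejected as multi-modal
rather than silently averaged.

`correct_and_verify` applies the negated mean shift to the same NM volumes
and re-estimates; because a trilinear shift moves a centroid exactly, this
residual is ~0 by construction and mainly proves the plumbing.  The
end-to-end pipeline therefore also runs a *confirmatory acquisition*: the
correction is treated as stored in the acquisition system, a fresh noisy
point-source set is simulated under the corrected geometry, and the
re-estimated offset is the reported residual (~0.01–0.05 mm with default
counts) — the quantity that honestly reflects estimation error.

COR analysis reduces each projection of an off-axis point source to its
lateral centroid and fits x(θ) = a·cosθ + b·sinθ + c by linear least
squares; c is the centre-of-rotation offset, recovered to <0.1 mm
noise-free, with a coarse grid search over (r, φ, c) as the test oracle.

## Dosimetry (`dosimetry`)

Single-time-point cumulated activity Ã = A/λ assumes physical decay only —
correct for sealed phantoms, an approximation for patients (no biological
clearance; an effective half-life can be passed via the nuclide spec).
Local deposition converts Ã to dose per voxel as Ã·10⁶·E_decay/m_voxel with
m_voxel = water density × voxel volume; energy is conserved to 1e−9 by
construction.  Voxel-S-value kernel convolution is exposed as a plug-in
registry (`DOSE_KERNELS`) but no kernel is bundled — publishing one would
require a validated kernel table, which is out of scope.

## What the synthetic data does not show

The simulator and reconstruction share the same projector (an inverse
crime), so end-to-end recovery errors (a few percent, seed-dependent, and
largest for the 22-mm sphere — with nonnegativity constraints, rectified
background noise after scatter subtraction competes with the smallest
sphere's counts) quantify the correctness of the correction/calibration
chain, not the accuracy a physical camera would achieve (±12% was the observed clinical band for this kind of chain;
model mismatch, septal penetration, dead time, CT-to-μ conversion and
respiratory motion all live outside this model).  Likewise the registration
study validates the estimator and correction bookkeeping, not gantry
mechanics.  Recovery-coefficient curves, spatial-resolution
characterization and Monte-Carlo dose-kernel validation are deliberately
absent.

## Problem sizes and determinism

Default end-to-end scale: 64×64×64 NM grid, 60 views, native CT grids
(0.98×0.98×3.75 mm), ~7 s on one CPU; unit tests run on 16–32-voxel grids
with 12–24 views.  Every stochastic stage draws its seed from one
`numpy` generator seeded by the run seed, so a report is byte-identical
across reruns with the same configuration and seed.
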