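# Methods

This note documents the models, numerical choices and limitations behind
`flow4d`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Velocity field and grid conventions

A 4D flow acquisition is represented as a velocity vector per voxel per
cardiac phase, in cm/s (the phase-contrast convention; kinetic-energy code
converts to SI at the single point of use). The grid is voxel-centered:
voxel index (i, j, k) sits at physical (i·dx, j·dy, k·dz) mm, and the
interpolation domain is the voxel-center hull. The cardiac cycle is
periodic — frame T wraps to frame 0 — which retrospectively gated CMR
justifies and backward tracing through the preceding diastole requires.
Segmentation labels (0 background, 1 LV, 2 RV) are categorical and are
matched to the nearest frame in time; temporally interpolating labels would
create fractional membership that the component definitions do not define.

## Pathline engine

Velocity is interpolated trilinearly in space and linearly in time between
the two bracketing frames, with periodic wrap. Interpolation is exact at
voxel centers on frame times and for fields affine in space and time
(property-tested). Particles are advected with classic fixed-step RK4;
the default step is one fifth of the frame interval (`advection.dt_fraction
= 0.2`), a deterministic choice adequate for ~30-frame cycles — the
measured error order on a rigid-rotation field is 4 (acceptance suite).
Steps larger than one frame interval are clamped with a warning, since the
time interpolation cannot be meaningfully sub-sampled beyond that.
Positions are recorded at every frame time crossed. A particle whose
sub-step leaves the bounding box keeps its last position and is flagged
`left_grid`; classification treats it as having left the chamber, which in
both the phantoms and clinical fields is what leaving the imaged volume
implies. Velocity outside the mask but inside the grid is used as stored —
particles must traverse atria and outflow tracts to register entry/exit.

## Flow-component classification

Seeds are placed at every labelled voxel center of the seeding ventricle at
end diastole (ED), optionally strided (`advection.seed_spacing`). ED and ES
are the argmax/argmin of the ventricular volume curve (earliest frame on
ties); analytic phantoms with static masks declare them explicitly instead.
Each seed is traced forward over [ED, ES] and backward over [previous ES,
ED]. *Entered* means the backward trace is outside the time-varying mask at
≥ 1 recorded frame; *ejected* likewise on the forward trace. A single
outside frame suffices by default — the simplest rule consistent with the
component definitions — with `min_outside_frames` exposed for sensitivity
analysis. Entry/exit is detected purely by mask membership; no valve planes
are modelled, because the segmented blood pool is the only geometry the
pipeline receives. The four labels partition the seeds; percentages sum to
100 by construction. The fractional flow ratio direct/residual is defined
whenever residual volume is positive (0/100 = 0) and reported as missing
when residual volume is zero.

## Kinetic energy

KE(t) = Σ_voxels ½ ρ V_voxel |v|² over the labelled pool, reported in µJ;
KEI_EDV = KE/EDV in µJ/ml. Blood density defaults to ρ = 1060 kg/m³, the
standard haemorheology value, and is configurable. The unit identity
1 J/m³ = 1 µJ/ml means a uniform-speed pool whose volume equals EDV has
KEI_EDV = ½ρ|v|² exactly; the acceptance suite verifies this to machine
precision. Phasic summaries: peak and mean over the closed systolic frame
interval [ED, ES] (closed so short cycles remain well-defined), and the
E-wave peak as the maximum over the first half of diastole
(`ke.e_wave_fraction = 0.5`). Restricting the E-wave search to early
diastole excludes the late-diastolic A-wave by construction; the exact
window used by clinical core-lab software is not standardized, hence the
configurable fraction.

## Cine and CPET metrics

The adverse-remodelling cutoff is the control mean + 3 sample SD (n−1
denominator, matching cohort-summary convention), reported to 2 decimals.
The synchrony index is the absolute time difference between maximal
tricuspid-lateral and mitral-lateral displacement (earliest frame on ties);
the signed RV−LV value is also available since the sign convention differs
between reports. Polygon areas use the shoelace formula after a
simple-polygon validity check. GLS keeps the sign convention of its input.

Peak VO₂ is the maximum 10-s averaged exercise sample (raw breaths are
binned first if supplied). The VE/VCO₂ slope interval runs from exercise
start to the first sample attaining peak VO₂ — first occurrence for
determinism. Incomplete tests receive the conventional defaults
(14 ml/kg/min, 46 %, slope 45). Stratification thresholds are inclusive at
the boundary (≤ 15 ml/kg/min abnormal; ≤ 65 % or ≥ 36 at risk). The
composite risk grade is the mean of available per-variable 1–3 grades
rounded to the nearest integer; half-points round *up*, the conservative
clinical choice (toward higher risk), configurable in principle by wrapping
`overall_risk`. When some graded variables are missing, the mean is over
the available grades.

## Statistics

* **Group comparisons** gate on Shapiro–Wilk per group at α = 0.05: both
  normal → pooled-variance two-sample t test, otherwise Mann–Whitney U.
  The gate itself is a design choice; the source dichotomy (t vs
  Mann–Whitney by normality) does not specify one.
* **Bonferroni families** are reported as literal 0.05/m. Note that the
  conventional printed levels for 7- and 9-test families (0.0065, 0.0045)
  are slightly below plain division (0.0071, 0.0056); the package computes
  the literal quotient and leaves stricter published levels to the caller.
* **Stepwise regression**: univariate screen at P < 0.05, then forward
  selection (entry P < 0.05) with backward elimination (removal P > 0.10) —
  conventional SPSS-style defaults, configurable. Outcomes may be
  ln-transformed to normalize residuals. Near-duplicate survivors
  (|r| > 0.999) drop the later-entering one with a warning.
* **ROC/Youden**: empirical ROC over observed cut-points; the threshold
  maximizes sensitivity + specificity − 1, preferring higher specificity
  and then the higher threshold on ties. Predictors inversely related to
  the outcome are sign-flipped (`direction='auto'`) so AUC ≥ 0.5.
* **DeLong** uses the structural-components covariance estimator with
  midrank handling of ties; coincident predictors reduce exactly to the
  single-AUC variance, and identical predictors short-circuit to P = 1.
* **Nested logistic**: model χ² = 2(ℓ − ℓ_null); the increment for one
  added predictor is referred to χ²(1). A rank-deficient full design
  (added variable collinear with the base) contributes Δχ² = 0 by
  construction; non-convergent ML fits are flagged as possible separation.
* **Bland–Altman**: bias ± 1.96 SD limits; CoV % = 100 × SD(diff)/grand
  mean of all measurements (the most common convention; alternatives exist
  and are documented here rather than multiplied into options).

## Synthetic data

**Phantoms.** The plug-transit phantom is a box chamber of length L voxels:
uniform inflow during diastole (transit distance a), faster uniform outflow
during systole (transit distance b), giving the closed-form partition
direct = max(0, a+b−L), retained = a−direct, delayed = b−direct, residual =
L−a−b+direct, as % of L. Two numerical details make the ground truth exact
rather than approximate: (i) the plug speeds are solved so the *exact time
integral of the linearly interpolated frame waveform* equals a and b — the
half-frame blending at phase transitions is thereby absorbed into the
ground truth instead of biasing it; (ii) a and b are integers of voxels, so
classification boundaries fall between voxel centers and no seed is
ambiguous. The two-channel variant adds an equal-volume static channel
(all-residual), guaranteeing all four components are non-zero. The default
phantom (L = 40, a = 24, b = 28, 30 frames, 16 000 seeds) has partition
(15, 15, 20, 50) %. The rotation phantom is steady rigid rotation with
period equal to the cycle; because nearest-node mask membership is not
rotationally invariant at a label rim, the membership disk is dilated by
0.75 voxel on non-seeding frames so closed orbits provably stay inside the
label — without this, rim orbits intermittently round to unlabeled nodes.
Phantom masks are otherwise static and declare their ED/ES frames; the
volume-curve inference path is tested separately with a deforming mask
whose per-frame volumes are programmed.

**Cohorts.** Variables reported as mean ± SD are sampled from (truncated)
normals; variables reported as median (IQR) from log-normals with
σ = asinh(IQR/2m)/z₀.₇₅ — reproducing skewness without inventing data.
Cross-variable dependence is a Gaussian copula; the single default planted
correlation is remodelling index vs RV direct flow (−0.624), the
association the study highlights. Sampling is bit-reproducible per seed.
Component percentages are sampled marginally and deliberately *not*
renormalized to sum to 100 within a subject — the cohort table mimics
per-subject measured summaries, not a coupled decomposition.

**Planted regression design.** The support-recovery benchmark uses two true
predictors (coefficients 0.6 and 0.2, correlated at r = 0.5) plus five
independent decoys at n = 96, noise SD 0.4. The signal correlation is load-
bearing, not cosmetic: with independent unit-variance signals, the strong
signal's variance inflates the weak signal's univariate residual, capping
its screen power near 0.9 even with zero noise, so no noise level makes
exact-support recovery comfortably achievable. Correlated signals — the
realistic case for physiological covariates — let the weak signal borrow
marginal association and restore screen detectability.

**What the generators do not emulate.** No phase-contrast noise model
beyond optional white Gaussian, no eddy-current or background-phase
artifacts, no wall motion in the phantoms (hence no flow–wall interaction),
no CFD-realistic intraventricular flow structure, and no within-subject
coupling between the flow, cine and CPET blocks beyond the declared copula
correlations. Passing tests therefore demonstrate correctness of the
numerics and statistics on known ground truth — not clinical accuracy on
real acquisitions.

## Problem sizes and determinism

The verification suite uses the full-size two-channel phantom (16 000
seeds, 30 frames), 2000 null simulations at n = 96 for each calibration
check, 500 seeds for stepwise recovery, and 200 simulated cohorts at the
study sizes (51 controls / 45 patients) for the contrast power check —
sizes at which Monte-Carlo error is small relative to the asserted bounds.
All simulations are seeded; `scripts/acceptance.py` derives every stream
from its single `--seed` argument.

## Known limitations

Fixed-step RK4 with no divergence-free interpolation means long
integrations in strongly sheared clinical fields accumulate volume error;
component fractions are robust to this at the tested step sizes, but
absolute pathline positions late in diastole are less certain. Entry/exit
by mask membership cannot distinguish valves from segmentation error at the
base. The Kruskal–Wallis >2-group machinery, Cox outcome models, ICC, and
REVEAL 2.0 scoring are out of scope; REVEAL scores are consumed as a column
when provided.
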