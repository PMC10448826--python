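# Methods

This note documents the models, conventions and numerical choices behind
`boldmod`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic-study model

The generator (`boldmod.simulate`) emulates a two-group, two-session
resting-state design: each subject is scanned at rest (rs1), then either
performs a blocked finger-tapping task or rests, then is scanned at rest
again (rs2).

**Phantom parcellation.** Grey matter is a set of mirrored left/right
cubic blocks (default 8 bilateral pairs of 5³ voxels at 1.5 mm isotropic),
embedded in a white-matter compartment with a central ventricle block and
a background shell. The block side equals the 7.5 mm seed-sphere kernel
(5 voxels) so that a seed sphere is contained in its host region — in real
data seed spheres are small relative to anatomical regions, and a phantom
whose spheres leak into neighbouring tissue would systematically
contaminate every seed time course.

**Signal model.** Region mean courses are drawn from a multivariate normal
whose correlation targets encode the planted structure: homotopic partners
r = 0.6, same functional community r = 0.3 (two communities of four pairs),
otherwise r = 0.05; white matter and ventricle courses are independent.
Each voxel receives its region course (SD 10 intensity units on a
GM baseline of 1000, i.e. ~1% fluctuation), independent thermal noise
(SD 10, giving tSNR ≈ 70), a common sinusoidal scanner drift (amplitude
10, period 120 s — just below the 0.009 Hz band edge, so the band-pass is
exercised) and its tissue baseline (GM 1000 / WM 800 / CSF 500,
background ≈ 0). Hand-specified or perturbed correlation targets are
repaired to the nearest positive semi-definite matrix by eigenvalue
clipping at 1e-8 with the unit diagonal restored.

There is **no spatial autocorrelation within a region** beyond the shared
region course; spatial smoothing in preprocessing reintroduces local
correlation. A consequence worth knowing: the sampling error of a
seed–target correlation is *one shared draw per region pair and session*,
so region-level statistics at n = 9 subjects are intrinsically
heterogeneous across regions — real data, with spatially varying neural
signal, behaves more smoothly.

**Planted modulation.** The ft-group's rs2 correlation targets receive
+Δr (default 0.3) on five edges from one seed region (the right member of
the first bilateral pair — the analogue of the contralateral motor cortex)
to five members of its own community. Within-community targets are the
deliberate choice: a Δr = 0.3 on a 0.05-baseline edge yields voxelwise
correlations near 0.33, below the BY-FDR detection floor of the
seed-correlation maps at the effective temporal dof of band-passed data,
so a modulation planted on unconnected regions is invisible to a
thresholded-map pipeline by construction; modulation within the
task-positive network is also the phenomenon the pipeline exists to
detect. Because the planted Δ is applied to the *target* correlation (not
post hoc to samples), ground truth is interpretable directly as Δr.
Per-subject covariance jitter (symmetric off-diagonal noise, SD 0.03,
PSD-repaired, recorded in the ground truth) provides between-subject
variability. Sessions are deterministic functions of the study seed.

**What the generator does not emulate.** Physiological noise spectra
(cardiac/respiratory), subject motion, field inhomogeneity, multi-echo
acquisition, spatial normalisation error, and spatially varying
haemodynamics. Passing tests therefore demonstrate the *statistical
machinery* — calibration of the permutation procedures, correctness of the
estimators, end-to-end recoverability of a known effect — not robustness
to artifacts of real acquisitions.

## Preprocessing conventions

* Band-pass: zero-phase FFT filter with flat gain 1 in [f_lo, f_hi] and
  raised-cosine edges entirely outside the band (transition width 5% of
  the edge frequency); DC always removed. Contract, asserted by test: gain
  ≥ 0.9 in band, ≤ 0.1 one octave outside.
* Smoothing: σ_vox = FWHM/(2.3548·voxel size) per axis, `nearest`
  boundary; FWHM 0 is the identity.
* Nuisance regression: voxelwise OLS on [intercept, WM mean, CSF mean];
  residuals returned; rank deficiency falls back to the pseudo-inverse
  with a logged warning.
* Task runs use a "GLM-Fourier" high-pass defined here as the removal of
  the intercept and the two lowest-frequency sine/cosine pairs of the run
  as confounds.
* Fixed resting-state order: discard → band-pass → smooth → nuisance
  regression.

**Effective temporal dof.** A band-limited series of duration T carries
≈ 2·bandwidth·T independent samples (~85 for 298 volumes at TR 2 s in
0.009–0.08 Hz). All voxelwise correlation p-values computed after
band-passing use this effective count; using the raw volume count was
verified (on synthetic data) to be badly anticonservative, flooding
near-null seed-map edges with tail-selected "significant" voxels. The df
convention is configurable everywhere (`n_timepoints`/`n_nuisance`
arguments), never hard-coded.

## Quality metrics

Spatial metrics (SNR, CNR, FBER, EFC) are computed on the temporal mean
volume (the definition leaves raw-first-volume vs mean open; the mean is
the lower-variance choice and is recorded here). EFC uses the
equal-energy-uniform normalisation to [0, 1]. The background mask takes
the largest 6-connected component of voxels outside the brain below the
5% in-brain intensity quantile, which excludes bright skull/muscle.
zDVARS standardises the spatial SD of the temporal difference image by
its expected value from per-voxel robust SDs (IQR/1.349) and lag-1
autocorrelations (Var[diff] = 2σ²(1−ρ₁)). Gcorr uses the norm identity
(mean pairwise correlation of z-scored voxel courses = ‖mean course‖²),
exact to 1e-10 against the brute force. Fingerprints score the better
acquisition 1.0 and the other min/max respecting directionality (Gcorr by
magnitude).

## Statistics

* **FDR.** BH/BY step-up implemented directly (threshold = largest p
  passing; ties share fate; BY divides q by Σ1/i), equal to brute-force
  threshold search and to the statsmodels reference in tests.
* **Critical correlation.** r_c = t_c/√(t_c²+df) with the two-tailed t
  quantile, Fisher-transformed; at α = 0.05, df = 744 this gives
  z = 0.072.
* **TFCE.** Right-endpoint sum of extent^E·h^H·dh over thresholds,
  default dh = max|stat|/100 (refinement-stability guarded by test, <2%
  against dh/10), 6-connectivity, positive and negative lobes enhanced
  separately. The permutation null records, per sign-flip permutation,
  the 99.9th percentile of enhanced voxel values (the outlier-robust
  stand-in for the maximum); the rejection threshold is the 95% quantile
  of those summaries, **on the raw enhanced scale** as in standard TFCE
  permutation practice. The enhanced map rescaled to the original t range
  (and the threshold on that scale) is returned for reporting. A variant
  that self-normalises every permuted map before thresholding was
  implemented first and rejected: with H = 2 it reduces each permutation
  to a scale-free ratio and cubically suppresses every cluster but the
  single strongest, which collapses multi-region recovery at toy scale.
  Using the sub-maximum percentile summary deliberately trades
  specificity for sensitivity; the null-calibration tests document the
  any-voxel rejection rate of both the exact-max (≈ 5%) and percentile
  variants.
* **NBS.** Edge-wise t (paired or homoscedastic) at p < α, components by
  shared nodes, size = edge count ("interconnected extent"), null = max
  component size under group-label exchange or sign flips, identity
  permutation always included. Measured property: with a concentrated
  planted star the observed size is capped at the planted extent while
  unbalanced permutation splits retain a diluted effect, so power
  saturates near 0.8 at Δz = 0.5, n = 9+9 — and *decreases* when edge
  noise shrinks (the permuted edge statistics become fully correlated).
* **pNBS.** α = the quantile of control-cohort paired-t p-values leaving
  1% of edges below it (the operative reading of the control-derived
  threshold: almost no control edge suprathreshold, α values of order
  0.01–0.03); experimental components no larger than the biggest control
  component are eliminated; FWE by permuting subject-pairs between
  cohorts, recomputing α per permutation. The pair-exchange null re-seats
  effect pairs into the permuted control, so attainable p_FWE saturates
  with strong effects — a structural property, documented in the tests.
* **Asymmetric matrices** are symmetrized by averaging the two directed
  cells before any graph operation; cells with no significant target
  voxels are 0 with an explicit count of 0.
* **Louvain communities** are run with 8 restart shufflings, keeping the
  best modularity; on graphs of ≤ 8 nodes this attains the exhaustive
  optimum in ≥ 90% of random instances (test and acceptance script).

## Modulation pipeline conventions

Paired rs2-vs-rs1 contrasts operate on sign-lobe-split, *unthresholded*
Fisher-z seed-correlation maps: the BY-FDR mask defines which voxels
enter the connectivity matrix, while the voxelwise contrast uses the full
map (thresholded maps produce zero-inflated, heteroscedastic differences).
Positive and negative correlation lobes are parallel analyses; the other
sign is zeroed. Dominant regions are all regions attaining maximal degree
within the significant NBS components (k configurable). Region Δz means
require mask coverage > 1% of the region's voxels. The final
homoscedastic t-tests are BH-FDR corrected jointly across seeds × signs ×
regions. rs1 seed maps are computed lazily, only for the selected seeds.

## Problem sizes in tests and acceptance

The synthetic studies run at the design's sample sizes (9 + 9 subjects,
300 volumes at TR 2 s, 105-volume task runs) on a 16×27×15 grid with 16
grey-matter regions; permutation counts are reduced (NBS 500/200, TFCE
200/150) relative to the 10,000/1,000 defaults, chosen so the full
calibration suite completes comfortably on one CPU. The NBS calibration
uses 200 direct-matrix null studies of 20 nodes; the end-to-end null
calibration uses 50 no-effect studies; planted recovery uses 3 replicate
studies (the data-driven NBS first stage operates near its power limit at
these conditions, so acceptance requires success on 2 of 3).

## Known limitations

* The shared-region-course noise model makes per-region statistics
  heterogeneous at small n (see above); TFCE-based masks consequently
  favour the luckiest regions more than they would on real data.
* pNBS significance saturates under strong planted effects (contaminated
  pair-exchange null).
* The 99.9th-percentile TFCE null is liberal by design for any-voxel
  error.
* Registration, motion and distortion handling are out of scope; real
  data must arrive pre-registered on a common grid.
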