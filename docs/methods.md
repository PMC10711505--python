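# Methods

`lungt2star` implements a quantitative-MRI analysis chain for the developing
fetal lung: multi-echo gradient-echo signal simulation on a digital thorax
phantom, voxelwise mono-exponential T2* mapping, per-lung summary statistics,
gliding-box lacunarity as a tissue-heterogeneity score, a gestational-age (GA)
normative model with z-scores and centiles, and two-way absolute-agreement
intraclass correlation for observer reliability. This note records the models,
the defaults and why, and the choices made where the design was genuinely open.

## Signal model and acquisition defaults

Magnitude gradient-echo signal decays mono-exponentially with echo time,

    S(TE) = S0 * exp(-TE / T2*),

with S0 the extrapolated zero-echo signal (receive gain, proton density and
flip-angle effects folded in) and T2* the effective transverse relaxation time
(ms), sensitive to deoxyhemoglobin content, field inhomogeneity and tissue
composition. The default acquisition mirrors a 3 T fetal-thorax protocol:
five echoes at 13.8 / 70.4 / 127.0 / 183.6 / 240.2 ms, TR 3 s, flip angle 90°
(metadata only), 3 mm isotropic voxels.

Noise on magnitude images is Rician: with per-channel Gaussian noise sigma and
true magnitude S, the observed magnitude is |S + n1 + i n2|, which positively
biases low-SNR samples (first-order excess ≈ sigma²/(2S) at high SNR). SNR is
defined as S0(lung)/sigma. A clipped-Gaussian option and a noiseless mode
exist for testing; Rician is the physically appropriate default.

## Digital thorax phantom

No anatomically realistic geometry is attempted; the phantom exists to give
every downstream stage an analytic oracle. Two lung ellipsoids (semi-axis
proportions 0.55 : 0.65 : 1.0) sit laterally inside a body cylinder with a
spherical heart; lungs are rasterised last so their digitised voxel volume
tracks the analytic ellipsoid volume (within ~2% at 3 mm). Total analytic
lung volume grows linearly with GA, 4 mL/week from a 16-week intercept —
within the range reported for fetal lungs in the late second and third
trimesters and large enough to keep ≥ 500 lung voxels at 21 weeks and 3 mm
resolution. The left lung is fixed at 0.85× the right analytically, matching
the smaller left lung seen in vivo. Default lung T2* is the normative mean
at the phantom's GA, so noiseless end-to-end runs close the loop at z ≈ 0;
body (40 ms) and heart (150 ms) values are fixed, documented constants.
Optional tissue texture is a multiplicative lognormal field with unit mean and
a chosen fractional SD; it is spatially white, which is a simplification —
real parenchymal heterogeneity is spatially correlated, so lacunarity results
on phantoms demonstrate sensitivity to variance, not to realistic spatial
structure.

All randomness flows from one explicit seed per call; no global state.

## Cohort generator

A cohort table has one scan per row. First-scan GA is drawn from a truncated
normal on [20.6, 38.3] weeks; 11.5% of subjects (per the study's 10 repeat
scans among 87 datasets) receive a second scan at GA + Δ, Δ ~ U(2, 8) weeks,
clipped to the range. Because truncation shrinks the SD (to ≈ 3.8 for a
latent SD of 4.3) and clipped repeats shift the mean up (≈ +0.4 weeks), the
latent (mu, sigma) are calibrated so that the *scan-level* GA distribution has
the target sample moments, 29.9 ± 4.3 weeks. The calibration is
deterministic: scan-level mixture moments are computed by quadrature (801-point
GA grid × 161-point Δ grid) and solved by least squares; residuals are below
1e-6 weeks. `CohortSpec(calibrate_ga=False)` gives the literal
truncated-Normal(29.9, 4.3) behaviour instead. The per-scan metric is drawn
from Normal(mean(GA), SD(GA)) using the packaged normative coefficients by
default; the SD function must be positive over the GA range or the spec is
rejected at construction.

## T2* fitting

Two fitters, same contract: estimates clamped to [t2_min, t2_max]
(default 1–500 ms; wider values are non-physiological at 3 T), with the clamp
recorded in a per-voxel status flag, and voxels with fewer than three positive
samples marked failed without raising so whole-map fits always complete.

* **Log-linear**: OLS of ln S on TE after dropping nonpositive samples;
  T2* = −1/slope, S0 = exp(intercept), R² in the log domain. Closed-form and
  vectorised; biased under Rician noise because the floor lifts late echoes.
* **NLLS** (default): bounded trust-region least squares of S0·exp(−TE/T2*)
  in the linear domain with analytic Jacobian, initialised from the log-linear
  solution (so its residual sum of squares never exceeds the initialiser's);
  R² in the linear domain. Non-convergence falls back to the initialiser with
  a warning.

Flat or rising signals clamp high (status `clamped_high`); constant signals
report R² = 1 (zero residual on zero variance). No Rician-bias correction
term is applied — a known limitation; at SNR 30 with the default echo times
the lung median error stays under 5%, measured on the phantom. Units follow
the echo-time units: fitting TEs in seconds returns T2* in seconds, provided
the clamp bounds are expressed in the same units.

## ROI statistics

The lung mask convention is 0 background / 1 right / 2 left; readers validate
it. "Both lungs" means the pooled union of voxels — the combined mean is the
voxel-count-weighted mean of the per-lung means exactly, matching the voxel
histogram view. Volumes are voxel count × voxel volume, reported in mL
(1 mL = 1000 mm³). ROI SD is descriptive (ddof = 0). Empty ROIs yield a
flagged summary rather than an exception so batch runs never abort. The
right-vs-left comparison is a paired two-sided t-test on scan-matched values;
zero-variance differences are handled deterministically (statistic 0/±inf,
p 1/0) and flagged degenerate.

## Lacunarity

Continuous-mass gliding-box lacunarity on intensities (not occupancy):
a cubic box of edge r slides at unit step over the mask bounding box; boxes
with ≥ 90% of their voxels in-mask are retained; box mass M is the sum of
in-mask intensities; Λ(r) = E[M²]/E[M]². Λ = 1 for homogeneous fields, ≥ 1
always (Cauchy–Schwarz), and invariant to intensity rescaling and to joint
translation of map and mask. One consequence of retaining partially covered
boxes: a constant field on an irregular mask gives Λ slightly above 1
(≈ 1.0003 on lung-shaped masks; bounded by (1/0.9)² ≈ 1.23), exactly 1 only
when all retained boxes are fully inside. The implementation uses summed-area
tables and is verified against exhaustive enumeration on small volumes.

Default box sizes {2, 3, 4, 6, 8} voxels span sub-lobe scales at 3 mm
resolution; the default scalar score is the mean of ln Λ over unflagged sizes
(log-mean stabilises scale mixing), with Λ-at-a-fixed-box as the alternative.
Whether the original analysis used intensities or a derived/binarised field,
and its box sizes, is not stated anywhere we could follow; these defaults are
documented package choices.

## Normative model, z-scores, centiles

The packaged published reference for mean lung T2* (ms) is

    mean(GA) = 1.488884 * GA + 21.997645
    SD(GA)   = 1.488884 * GA − 18.451005

on the GA domain [20.6, 38.3] weeks (the study range; the printed SD function
turns negative below ≈ 12.4 weeks, so the domain is restricted and enforced).
The SD slope being digit-identical to the mean slope may be a transcription
artefact in the source; it is packaged exactly as printed and never
"corrected". z = (observed − mean(GA))/SD(GA); centile = 100·Φ(z) with the
exact normal CDF. Reference bands are mean(GA) + Φ⁻¹(c/100)·SD(GA). Note the
published OLS trend of the real cohort (slope 1.61, intercept 19.61, R² 0.13
for both lungs) is a distinct artifact from these z-score coefficients; the
package documents both and reconciles neither, and the real-cohort numbers are
not reproducible here because the imaging data are not public.

Trend fitting is OLS of metric on GA (statsmodels). Serial scans are handled
by cluster-robust standard errors over subject id (CR1 small-sample
correction — adequate for ~77 clusters); point estimates are unchanged by
clustering. The SD-vs-GA function is estimated either from absolute mean-fit
residuals scaled by sqrt(pi/2) (since E|N(0, s)| = s·sqrt(2/pi); the default —
simple and unbiased under normality) or from GA-binned sample SDs (for
designed cohorts with many scans per GA). GAMLSS-style or quantile centile
modelling is out of scope.

## Reliability

ICC from the two-way model without replication: single-measures
absolute-agreement ICC(A,1) by default,

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n),

with average-measures ICC(A,k) as an option, and 95% CIs from the McGraw–Wong
F-based construction (Satterthwaite degrees of freedom). Single measures is
the default because one observer's measurement is the unit of clinical use.
Complete-case rows only; degenerate (zero between-target variance) matrices
are flagged, and edge cases (identical columns, zero error MS) return exact
unit ICC with a collapsed interval.

## Pipeline and problem sizes

`run_pipeline` composes simulate → fit → ROI metrics → lacunarity → normative
z-scores, writing per-scan CSVs, the model JSON, the resolved configuration
and a run log; identical configuration and seed reproduce byte-identical CSV
outputs. Defaults in tests use 40–48-voxel cubic grids and cohorts of 2–20
scans, and the calibration studies use 200 draws per integer GA and
5000-subject cohorts — sizes chosen so each check isolates one property at
comfortably sub-minute cost while keeping Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

* Phantom geometry is schematic; no motion simulation or motion-corrected
  reconstruction (inputs are assumed already reconstructed), no B0/shimming
  effects, no partial-volume modelling beyond voxelisation.
* No Rician-bias correction in the fitters.
* Texture is spatially white; lacunarity-vs-GA findings on synthetic cohorts
  demonstrate statistical machinery, not biological effect sizes.
* The normative model is linear in GA with a linear SD, as published;
  no nonlinearity checks are possible without the original data.
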