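# Methods

## Scope and data model

`mrsdyn` analyses cohorts of MEGA-PRESS edited MRS acquisitions. A cohort
is a set of subjects, each contributing an alternating series of OFF/ON
transients (complex frequency-domain spectra on a decreasing ppm axis).
Two acquisition profiles are built in:

| profile | transients | TR (s) | points | duration | residual water |
|---------|-----------:|-------:|-------:|---------:|----------------|
| `vc`    | 256        | 3.0    | 2048   | 768 s    | no             |
| `pcc`   | 320        | 2.0    | 2048   | 640 s    | yes            |

The spectral width is 2000 Hz at 127.7 MHz proton frequency (so 1 ppm =
127.7 Hz) with the carrier at 4.7 ppm. Editing physics is not simulated:
the analyses only consume the ON−OFF difference spectrum, so the generator
injects the edited signature directly into ON transients — a positive
GABA+ Gaussian at 3.0 ppm, a positive double-Gaussian Glx multiplet at
3.71/3.79 ppm (the field reports the composite near 3.75–3.8 ppm; the
sub-peak split is a modelling choice, unresolved at 3 T), and a negative
co-edited tNAA Lorentzian at 2.0 ppm.

## Synthetic cohort generator

Per subject, baseline peak areas (in tCr units) are drawn from normal
distributions (defaults: GABA+ 0.12 ± 0.012, Glx 1.00 ± 0.08, tNAA
1.40 ± 0.10, tCr 1.00 ± 0.08, edited-tNAA control 0.40). Line widths are
Lorentzian half-widths of 4.25 Hz (tCr, fitted FWHM 8.5 Hz) and 4.2 Hz
(tNAA), and Gaussian sigmas giving fitted FWHMs of ~25 Hz (GABA+) and
~14 Hz per Glx sub-peak, with a ±5% per-subject width scale. Gaussian
components carry a Dawson-function dispersive channel so phase rotations
behave like real spectra.

Time structure of the metabolite amplitude for subject s, metabolite m:

    a_sm(t) = base_sm * max(0, 1 + drift_m * t/(T-1) + latent_m[bin(t)])

* **Deterministic drift** (`drift_total`): fractional endpoint-to-endpoint
  change. Visual-cortex defaults are −0.100 for GABA+ and +0.054 for Glx
  (zero for tNAA/tCr), chosen so a 128-transient sliding window recovers
  maximum group changes of about −5% and +2.7% via the ramp identity: the
  mean of a linear ramp over a width-w window moves by
  `drift * (T−w)/(T−1)` between the first and last windows
  (−0.10 · 128/255 ≈ −5.0%).
* **Cohort-shared latent fluctuation**: the GABA+ latent g is a stationary
  AR(1) per 12 s bin (SD `latent_sd` = 0.02, coefficient `latent_ar` =
  0.5) shared by every subject; the Glx latent is a delayed anti-coupled
  copy, `glx[t] = −kappa · g[t − d] + e[t]` with `kappa` = 1.5, delay d =
  10 bins (120 s) and innovation SD 0.006. The AR(1) is extended d bins
  into the past so the coupling is defined at every bin, which gives the
  exact stationary relation `corr(g[t], glx[t+d]) =
  −kappa·sigma_g / sqrt(kappa²·sigma_g² + sigma_e²)` used as a test
  oracle. The posterior-cingulate profile sets drifts, latent and coupling
  to zero (a stable control region).
* **Instrument effects**: per-transient frequency jitter (SD 0.0088 ppm,
  matching the reported across-OFF-transient Cr position SD), optional
  linear scanner frequency drift (default 0), per-transient zero-order
  phase jitter (SD 2°), per-subject linear baseline, and complex white
  noise per spectral point (`noise_sd` = 0.05 in tCr-area units).

Tissue fractions are Dirichlet draws (mean GM/WM/CSF = 0.45/0.35/0.20,
concentration 120), so fractions sum to one by construction.

### Calibration of the latent process

The generator's defaults were calibrated against the recoverable effect
sizes: the drift values reproduce the target sliding-window extrema; the
latent/coupling parameters were set so that the cluster-corrected
cross-correlation recovers the injected −120 s delay as the peak
significant negative lag in the large majority of cohorts, while leaving
the sliding-window extrema within ±1.5 percentage points of their targets.
These two requirements are in tension — any cohort-shared fluctuation
strong enough to dominate the lag map also perturbs the windowed group
trace — and the chosen point favours reliable lag recovery. One
consequence: with opposing deterministic drifts present, the GABA+ and Glx
traces are anti-correlated at *every* lag (baseline r ≈ −0.4), and the
coupling appears as a localized dip (r ≈ −0.7) at −120 s rather than an
isolated significant lag on a null background; real cohorts, with much
larger uncoupled physiological variability, show a weaker and more
localized correlation (values near −0.36 are reported for resting
visual cortex). The synthetic
world is also cleaner than real data in other ways that matter for
interpretation: there is no macromolecule background, no lipid
contamination, no subject motion, and fit errors are noise-dominated
rather than model-mismatch-dominated, so passing recovery tests here
demonstrates correctness of the estimators and inference machinery, not
field robustness.

## Preprocessing

Each transient's creatine peak is fitted over 2.4–3.6 ppm with a complex
Lorentzian (absorption + dispersion), zero-order phase and a complex
linear baseline — eight parameters, real/imaginary channels fitted
simultaneously. Within each subject (ON and OFF pooled), transients with
any of frequency/phase/area/FWHM more than k = 3 SD from the subject mean
are discarded (parameters with zero spread are skipped). Retained
transients are shifted so Cr sits at exactly 3.0 ppm and rotated to zero
phase; the shift is applied as a phase ramp in the Fourier-conjugate
domain (exact, sub-sample). Frequency drift is summarised per subject as
the SD of the Cr position across retained OFF transients before alignment.

The per-transient Cr fit on ON transients sees the GABA+ signal underneath
the creatine line and therefore carries a small constant frequency/phase
bias relative to OFF fits. After alignment this leaves an odd-shaped
creatine subtraction artifact at 3.0 ppm in the difference spectrum
(Lorentzian absorption-derivative and dispersion shapes) that, if ignored,
biases the GABA+ area by ~10% and — because it is additive — distorts
percent-change traces. The GABA+ quantification model therefore includes
these two shapes (widths taken from the tCr fit of the same selection) as
free linear nuisance components; they are odd around the Cr centre and
leave the even Gaussian essentially unbiased. This is the same concern
addressed by subtraction-artifact modelling in established edited-MRS
fitting tools.

## Quantification

All peaks are fitted by nonlinear least squares (model + linear baseline)
over fixed windows: tCr 2.6–3.4 and tNAA 1.8–2.2 ppm on the mean OFF
spectrum (Lorentzians); GABA+ 2.8–3.3 ppm (single Gaussian + nuisance) and
Glx 3.45–4.10 ppm (double Gaussian, shared width) on the difference
spectrum; the edited negative tNAA lobe 1.8–2.2 ppm (inverse Lorentzian,
reported as a positive magnitude). Windows are package conventions (the
literature typically names only the peak centres). Areas are analytic —
πAγ for Lorentzians, Aσ√(2π) per Gaussian component — and FWHMs are 2γ or
2σ√(2 ln 2) converted to Hz. The fit error is the residual SD over the
window divided by the fitted peak amplitude (×100); the residual-SD
numerator is a package definition. Ratios use tCr by default (tNAA via
config). CSF correction divides a ratio by (1 − f_csf); participants whose
FWHM on any metabolite exceeds 3 cohort SDs are excluded (computed from
all-transient average spectra). Note that with n participants the maximum
attainable |z| is (n−1)/√n, so this exclusion cannot trigger in very small
cohorts.

The solver is a batched Levenberg–Marquardt iteration with analytic
Jacobians, vectorised over problems sharing a ppm grid (tens of thousands
of window fits per cohort), with exact linear least-squares initialisation
of the amplitude/baseline/nuisance parameters at the initial centre and
width, convergence at relative step < 1e−8, and an active set so converged
problems drop out. Widths are reflected positive; Glx sub-peaks are kept
ordered. Tests cross-check it against `scipy.optimize.curve_fit`.

## Low-resolution analysis

Windows are half-open intervals `[i·step, i·step + width)`; the count is
`floor((T − width)/step) + 1` and window-centre times are
`(start + (width−1)/2)·TR`. Width defaults to 128 transients (VC) and 192
(PCC) — the same ~6.4 min duration — at step 2. Each (subject, window)
selection is quantified from its retained transients (condition means via
prefix sums); traces are 100·(v − v₀)/v₀ with v₀ the first window
(percent-of-mean normalisation available). Fit-error control traces use
differences from the first window (they are already percentages); the
edited-tNAA control uses percent change.

Cluster inference: per window, a two-sided one-sample t test across
subjects (windows with zero variance — the reference window — get t = 0;
missing windows are excluded pairwise). Clusters are maximal runs of
same-sign threshold exceedances (point-wise two-sided p < α), scored by
the sum of member t values. The null records, per permutation, the maximal
positive and |negative| cluster masses. Two exchangeability schemes are
implemented:

* `sign_flip` (default): each subject's whole trace is multiplied by a
  random ±1. For a change-versus-zero test this is the standard
  exchangeability assumption; it preserves the strong autocorrelation that
  98%-overlapping windows induce, and empirically controls the family-wise
  error at nominal level on null cohorts.
* `shuffle_windows`: each subject's window labels are permuted
  independently. This destroys the overlap-induced autocorrelation in the
  null while the observed traces retain it, and measurably inflates the
  family-wise error (~2–4× nominal on null cohorts); it is kept as an
  option for comparison only.

Because the positive and negative tails are tested separately, each tail
is compared against the 1 − α/2 quantile of its null so the two-sided
family-wise rate is α. Measured on 200 null cohorts the family-wise rate
is ~3–5% per metabolite at α = 0.05.

## High-resolution analysis

All retained transients with index in `[b·bs, (b+1)·bs)` are pooled across
subjects per bin (bs = 4 or 6 transients → 12 s; leftover transients past
the last full bin are discarded; even sizes give balanced ON/OFF counts).
Condition means → difference → quantification gives one `GroupTrace` per
metabolite (64 bins for VC, 53 for PCC). Traces are normalised as percent
of mean for reporting; correlations are affine-invariant so the choice
does not affect inference. A centred moving average with shrinking edges
(`smooth_trace`) is provided for plots only.

Cross-correlation: for lag index k ≥ 0 with n = n_bins − k ≥ 25, Pearson r
between A[0:n] and B[k:k+n] is reported at signed lag −k·Δt (A = GABA+
precedes B = Glx) and the mirrored pairing at +k·Δt, giving
n_bins − 24 lags per direction (40 for VC, 29 for PCC; lag 0 belongs to
both). Per-lag 95% CIs use the Fisher z transform with that lag's n. For
cluster correction each lag's t = r·√((n−2)/(1−r²)) is thresholded at the
two-sided point-wise α (|r| = 1 is clipped with a warning); clusters are
contiguous same-sign lags within a predictive direction; the null reorders
the time labels of one trace (full random permutations, not circular
shifts), recomputes the entire lag map, and records maximal cluster masses
within each predictive direction, matching the per-direction framing of
the lag analysis; observed clusters are compared against their own
direction's null with per-tail 1 − α/2 quantiles as above, controlling the
family-wise error per direction at α (measured ~5–6% per direction on
white-noise traces).

Cross-validation of the two analyses: the high-resolution trace is
averaged with a full-window moving average whose span in transients equals
the sliding-window width (32 bins × 4 = 128), and compared with the
low-resolution group-mean trace at the window starts representable on both
grids (33 points for the VC geometry); agreement is summarised by Pearson
r (≥ 0.999 on default synthetic cohorts).

## Pipeline, formats, determinism

Cohorts are stored as HDF5 (`/subjects/<id>/{real,imag,condition}` plus
acquisition attributes and per-subject tissue fractions); synthetic
cohorts carry a JSON sidecar with the generating ground truth and realised
latent series for recovery tests. All result tables are CSV with a
`# columns:` schema comment; `run_pipeline` writes a YAML manifest
(config, versions, per-stage counts, summary). Every random element —
generator, permutation tests — is seeded, and a rerun with the same
configuration is byte-identical. Cohort spectra are stored complex64
(single precision is far below the noise floor); fitting runs in float64.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use: 8–10 default VC cohorts of
57 subjects for drift/coupling/validation recovery (20 cohorts for the
modal peak lag), 200 null cohorts of 12 subjects for type-I studies (error
control is a size-free property of the permutation test; 12 subjects keeps
a 200-cohort study tractable), 10 PCC cohorts of 20 subjects for the
stable-region control, and 1000 permutations (500 in the null studies)
against a production default of 5000. Most unit tests run on a reduced
32-transient, 1024-point profile.

## Known limitations

* No macromolecule baseline, lipids, eddy currents, motion or
  frequency-dependent editing efficiency; control analyses (fit-error
  traces, edited-tNAA amplitude, drift correlations) are therefore
  expected to be null on synthetic data unless such effects are injected.
* Absolute (water-referenced) quantification and relaxation corrections
  are out of scope; only the CSF fraction correction is applied.
* The high-resolution group trace is a single realisation; no
  within-trace significance is attached to it beyond the
  cross-correlation cluster test.
* With both drift and coupling at their defaults the lag map's negative
  baseline (see calibration note) means the *extent* of the significant
  negative cluster is wider than in real data; the peak location is the
  calibrated, tested quantity.
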