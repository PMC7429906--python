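# mrsdyn

Temporal dynamics of GABA+ and Glx from MEGA-PRESS edited magnetic
resonance spectroscopy (MRS).

Conventional MRS studies average hundreds of transients into a single
"static" concentration estimate, discarding everything that happens during
the ~13 minute acquisition. `mrsdyn` implements two complementary dynamic
analyses for cohorts of MEGA-PRESS acquisitions, together with a fully
synthetic cohort generator with known ground truth so every stage can be
verified without scanner data:

1. **Low-resolution (within-subject) analysis.** A sliding window (width
   128 transients, step 2 → 65 windows over a 256-transient series)
   produces a percent-change trace of GABA+:tCr, Glx:tCr and tNAA:tCr per
   subject. At each window a one-sample t test against zero is computed
   across subjects, and contiguous supra-threshold windows are scored by
   the sum of their t values and tested against a permutation null of
   maximal cluster masses (cluster-based permutation correction).
2. **High-resolution (across-subject) analysis.** Short blocks of
   transients (4 transients = 12 s for TR 3 s) are pooled across all
   subjects, giving one group-level trace per metabolite with no temporal
   smoothing. Predictive coupling between GABA+ and Glx is probed by a
   lag-constrained Pearson cross-correlation: at signed lag −k·12 s the
   GABA+ sample precedes the Glx sample it is paired with. Only lags with
   ≥ 25 overlapping bins are evaluated (40 per direction on a 64-bin
   trace), with per-lag Fisher-z confidence intervals and the same
   cluster-mass permutation correction over lags.

Quantification follows edited-MRS conventions: a complex Lorentzian fit of
the creatine reference at 3.0 ppm per transient drives 3 SD outlier
rejection and frequency/phase alignment; tCr and tNAA are Lorentzian fits
of the mean OFF spectrum; GABA+ (3.0 ppm) is a single Gaussian and Glx
(3.71/3.79 ppm) a double Gaussian on the ON−OFF difference spectrum; the
edited negative tNAA lobe is an inverse Lorentzian control for editing
efficiency. Concentrations are analytic peak areas referenced to tCr (or
tNAA), with CSF partial-volume correction `C_tisscorr = C_meas / (1 −
f_csf)`.

## Worked example

Simulate a default visual-cortex style cohort (57 subjects, 256 transients
of 2048 points at TR 3 s, opposing GABA+/Glx drifts and a 120 s delayed
GABA+→Glx anti-coupling) and run the full pipeline:

```bash
mrsdyn report --profile vc --subjects 57 --seed 7 --out results/vc --n-perm 1000
```

which prints

```
bundle written to results/vc
gaba: max change -4.53%
glx: max change +1.83%
```

The bundle contains, among others, `lowres_traces.csv` (65-row group
change trace per metabolite with cluster significance), `crosscorr.csv`
(79 signed lags with r, per-lag n, Fisher-z CI and cluster flags),
`validation_low_high.csv` and a YAML run manifest. For this seed the
manifest summary reads

```yaml
summary:
  max_change_pct: {gaba: -4.53, glx: 1.83, tnaa: -0.02}
  peak_significant_negative_lag_s: -120.0
  validation_r: {gaba: 0.99968, glx: 0.99998}
```

i.e. the sliding-window analysis recovers the injected −10% GABA+ drift as
a maximum group change near −5% (a 128-transient window averages roughly
half the ramp; the cohort-shared fluctuation moves single-seed extrema by
a point or so around it, here −4.53%) and the +5.4% Glx drift as a
maximum increase near +2.7% (here +1.83%), the cross-correlation
identifies the injected 120 s GABA+→Glx delay as the peak significant
negative lag, and the smoothed high-resolution trace reproduces the
low-resolution trace at r > 0.999 (n = 33 matched windows). tNAA:tCr, the
stability control, stays flat (−0.02%).

The same stages are available individually (`mrsdyn simulate`,
`preprocess`, `quantify`, `dynlow`, `dynhigh`, `xcorr`) on a cohort HDF5
file, and as library functions (`simulate_cohort`, `preprocess_cohort`,
`lowres_analysis`, `highres_analysis`, ...).

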