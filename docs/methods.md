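# Methods

`milkcal` implements the chemometric calibration workflow customary in milk
spectroscopy: spectra are pretreated, regressed on reference chemistry with
modified partial least squares (MPLS), model complexity is chosen by
cross-validation, outlying samples are eliminated in at most two passes, and
the surviving model is judged on an external validation set whose errors can
be compared across spectroscopy techniques. This note records the exact
conventions used, the choices that were genuinely open, and what the
synthetic test bed does and does not demonstrate.

## Pretreatment grammar

A treatment is written as `<scatter> d,g,s` (e.g. `SNV and Detrend 1,4,4`):
a scatter-correction method followed by derivative order *d*, gap *g* and
smoothing segment *s*, all in grid points.

* **SNV** centres one spectrum and scales it to unit sample standard
  deviation (n−1 denominator).
* **Detrend** removes a least-squares polynomial (degree 2 by default) in
  the axis *index*; index rather than physical wavelength keeps the
  operator scale-free on evenly gridded data. `SNV and Detrend` applies SNV
  first, then detrend (the Barnes convention).
* **MSC** regresses the spectrum *x* on the calibration-set mean *m*:
  standard MSC fits x = a + b·m and returns (x−a)/b; inverse MSC fits
  m = a′ + b′·x and returns a′ + b′·x; weighted MSC is the standard fit by
  weighted least squares with weights 1/var_j, the reciprocal between-sample
  variance at each wavelength (floored at 1e−12). The exact weighted and
  inverse formulas used by commercial packages are not public; these
  definitions are documented substitutes with the right invariances.
  Slopes below 1e−12 raise a degenerate-spectrum error.
* **Gap-segment derivative** smooths with a centred moving average of *s*
  points (even windows sit one point right of centre), then applies the gap
  difference ȳ(i+h) − ȳ(i−h), h = ⌈g/2⌉, *d* times. Edges where the stencil
  is unsupported are truncated — no padding is invented — and the shortened
  axis is recorded in the fitted pretreatment. The printed triples carry no
  fourth "second smooth" number, so none is implemented.

Order of operations: axis window → scatter correction → derivative. All
operators are row-local except the MSC family, which sees the calibration
set only through the stored reference mean and weights; applying a fitted
pretreatment to new samples never reads their neighbours.

## MPLS regression

The core is NIPALS PLS1 on column-centred spectra and centred
concentrations; `y` is never autoscaled and `X` columns are not
standardised before the first factor. The single MPLS modification is
controlled by one flag: after each factor is extracted and both `X` and `y`
deflated, every spectral residual column is divided by its standard
deviation (floored at 1e−10 so dead regions, e.g. derivative edges, cannot
explode). The scaling vectors are stored and replayed at prediction, so the
fitted map is exactly linear and reproducible; with the flag off the model
is standard PLS1 (verified against scikit-learn and a hand-rolled NIPALS to
1e−8, and against OLS when the factor count equals the rank). Whether the
original MPLS also standardises the *y* residuals is not documented in the
sources followed here; only X-scaling is performed, and the flag
architecture isolates that choice.

The standardized Mahalanobis distance of a spectrum is computed in latent
score space: GH = D²/T, where D² uses the calibration score mean and
covariance (n−1 denominator). This standardisation makes the calibration
mean GH equal (n−1)/n ≈ 1 exactly, so the customary outlier threshold of 3
is meaningful.

## Model building loop

* **Split.** `round(fraction·n)` samples go to calibration (default
  fraction 0.77, reproducing a 186/56 split at n = 242); one split is
  shared by all modalities.
* **Cross-validation.** The calibration set is permuted under a named
  sub-seed and cut into 4 contiguous blocks as equal as possible. Held-out
  residuals are pooled into one SECV per term count T (denominator n, no
  df correction); the chosen T minimises SECV, taking the smallest T on
  numerical ties (relative tolerance 1e−6, so exact-fit data does not
  inflate T on floating-point noise). T_max defaults to 10.
* **Outlier elimination.** At most two passes. Each pass re-chooses T by
  cross-validation, fits the full calibration model, computes
  SEC = √(Σe²/(n−T−1)), and flags concentration outliers
  (|e| > 2.5·SEC, reason `T_residual`) and spectral outliers (GH > 3,
  reason `H_distance`) from the same fit. Flagged samples are removed and
  the model refit. Note these thresholds intrinsically flag roughly 1–3% of
  perfectly clean Gaussian data; a "clean" run therefore typically loses a
  few samples, which matches practice.
* **Grid search.** Every treatment in the grid (default: the 36 distinct
  codes used in this workflow's tradition) runs the full loop; the winner
  has the highest R²CV, ties broken by lower SECV then input order.
  R² is always 1 − SSE/SST, never a squared correlation.

## Validation statistics

With validation errors e = ŷ − y: bias = mean(e), SEP = √(Σe²/n),
SEPc = √(Σ(e−bias)²/(n−1)), giving the identity
SEP² = bias² + SEPc²·(n−1)/n. These denominators are the only convention
under which the identity holds exactly and SEPc ≤ SEP; they are asserted in
the tests. The bias is tested with a one-sample t (t = bias/(SEPc/√n),
n−1 df, two-sided). Two techniques validated on the same samples are
compared on SEPc by the Pitman–Morgan paired variance test on bias-centred
errors: with s = e₁+e₂ and d = e₁−e₂, corr(s, d) = 0 iff the variances are
equal, and t = r√(n−2)/√(1−r²) with n−2 df. Degenerate inputs (identical
vectors, zero-variance sums) give p = 1 by convention. No multiplicity
correction is applied across analytes; tests are reported per analyte. The
compact letter display is computed exactly from the maximal cliques of the
"not significantly different" graph, letters assigned in ascending SEPc
order with technique order NIR, MIR-ATR, fluorescence breaking exact ties.

## Synthetic test bed

No raw milk spectra are distributed with the emulated study, so the test
bed is a forward model with known truth:

* **Concentrations.** 242 samples of 10 analytes (five carotenoids, two
  vitamins, three fatty acids) drawn from a multivariate normal with the
  emulated study's means/SDs and a correlation matrix embedding its
  strongest reported pair (r = 0.95 between zeaxanthin and
  cis9-β-carotene), truncated at zero by whole-sample resampling (≤ 100
  redraws, then clamping). For analytes whose mean is under ~2 SD from
  zero this truncation biases means upward by 2–5% and attenuates strong
  correlations by ~0.02; the tests therefore check the sample mean against
  the analytic truncated-normal value, and correlation recovery in the
  far-from-zero regime.
* **Spectra.** Each analyte owns one Gaussian band per modality with
  intensity 1/mean (so every analyte contributes comparably and is
  resolvable); a broad two-band constant background dominates each modality
  the way water/fat absorption dominates real milk spectra. Per sample the
  signal is slope·(mixture + polynomial baseline) + offset + iid noise,
  with slope ~ N(1, 0.15), offset ~ N(0, 0.05), baseline coefficients
  ~ N(0, 0.1) up to degree 2, and noise SD 0.01 (recovery experiments pin
  noise to 1% of the clean signal's dynamic range). The strong multiplicative
  scatter is deliberate — it is the phenomenon scatter corrections exist
  for, and typical of dried-film reflectance measurements. Axes are
  decimated to desk scale (NIR every 8 nm, MIR-ATR every 16 cm⁻¹,
  synchronous fluorescence every 2 nm; < 1,200 points total).
* **Planted outliers.** Reference shifts of magnitude·SD exercise the
  2.5·SEC rule; spectra scaled ×magnitude exercise the GH rule.

Because the bands are dominated by a smooth background and the scatter is
exactly affine, passing tests show the machinery is correct and
well-calibrated; they do not show that milk carotenoids are predictable at
any particular accuracy from real instruments — the synthetic R² values are
far higher than any real milk study achieves, precisely because the forward
model contains no unmodelled chemistry.

## Numerical choices and limitations

* All randomness flows through `numpy.random.default_rng`; a single global
  seed fans out to named sub-seeds (simulation, split, cross-validation)
  via `SeedSequence`, so stages are independently reproducible and reports
  are byte-identical under a fixed seed.
* Model JSON stores float64 exactly (repr round-trip); reports are written
  both at 2 decimals (human layout) and full precision.
* MSC cannot recover the truly unscattered spectrum: the calibration mean
  absorbs the set's mean scatter, and with chemical variation MSC removes
  the component of each sample's deviation collinear with the mean
  spectrum. Tests assert the recoverable statement (collapse onto the
  reference up to noise; truth up to one global affine map).
* PLS2, kernel/sparse PLS, wavelength-selection searches, EMSC/OSC
  filters, sample-selection algorithms and slope/bias post-correction are
  out of scope. Vendor binary formats are not read; all I/O is CSV.
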