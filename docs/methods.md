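# Methods

This note documents the models and procedures implemented in `phenothz`,
the defaults they use, and the design decisions taken where more than one
reasonable convention exists.

## Data model and units

Spectra live on a shared, uniformly spaced wavenumber grid; the native
instrument axis is 674 points over 29.98–678.92 cm⁻¹. Frequencies convert
to THz with ν[THz] = ν̃[cm⁻¹] · c, c = 0.0299792458 cm·THz (exact SI
definition), so the axis spans 0.8988–20.3535 THz. Absorbance is
dimensionless; for these pressed-powder ATR measurements physically valid
values lie in [0, 1].

Range selection keeps exactly the axis points whose THz value lies in a
**closed** interval [fmin, fmax]. The named ranges are R0 = (0.9, 20.3),
R1 = (1.5, 20.3) and R2 = (5, 17) THz. Note that R0's nominal bounds are
rounded display values: the instrument's first point (0.8988 THz) and last
point (20.3535 THz) fall just outside the closed interval and are dropped.
This is deliberate — a deterministic closed-interval rule beats a fuzzy
"approximately equal" match, and classification is insensitive to one grid
point at either end.

Replicate averaging produces one spectrum per (compound, supplier) standard;
supplier averaging then yields one representative spectrum per compound.
Both are plain pointwise means, so they are idempotent and commute with
range selection. Session labels are opaque strings used only for grouping,
never parsed as dates.

The CSV exchange format is one row per spectrum: leading metadata columns
(`compound, family, compound_class, supplier, replicate, session`) followed
by one `wn_<wavenumber>` column per grid point. Absorbances are written
with 12 significant digits, so a round trip is lossless to ~1e-12 relative.

## Cleaning

Values strictly below 0 or strictly above 1 are flagged (the bounds
themselves are valid) and replaced by **modified Akima** (makima)
piecewise-cubic Hermite interpolation over the spectrum's in-range points.
The node derivative at point *i* is the weighted mean of the neighbouring
secant slopes d:

    w1 = |d[i+1] − d[i]|   + |d[i+1] + d[i]| / 2
    w2 = |d[i−1] − d[i−2]| + |d[i−1] + d[i−2]| / 2
    t[i] = (w1 · d[i−1] + w2 · d[i]) / (w1 + w2)

with slopes extended past the ends by d[−1] = 2d[0] − d[1] (and again), and
t[i] = 0 when both weights vanish (locally flat data). The modified weights
differ from Akima's original by the |d₊ + d₋|/2 term, which removes the
flat-spot artifacts around equal slopes. Flagged points at the very edge of
the support are extrapolated with the end cubic and then clipped to [0, 1].
With two support points the scheme degenerates to linear interpolation;
with three it remains a well-defined Hermite cubic through the extended
slopes. Fewer than two in-range points is an error — there is nothing to
interpolate from.

The interpolant is implemented in `phenothz.makima` from the formula above;
`scipy.interpolate.Akima1DInterpolator(method="makima")` serves as an
independent reference in the tests only (node slopes agree to ~1e-15;
evaluation to well below 1e-8 at realistic extrapolation distances).

Cleaning precedes replicate averaging in the canonical pipeline: averaging
spike-contaminated replicates would smear out-of-range values into the mean
where they can no longer be detected.

## Savitzky–Golay derivative

The derivative filter fits a local second-order polynomial over a
seven-point window and evaluates its first derivative; on a uniform grid
the interior of the filter is a convolution with the closed-form kernel
j/28 (j = −3…3) divided by the grid spacing. Two conventions are fixed
here:

- **Units.** The derivative is taken with respect to frequency in THz
  (`delta = spacing · c`), so loadings are comparable across ranges.
  Any consistent choice works for classification; per-THz is the natural
  one for axes quoted in THz.
- **Edges.** The first/last three samples are obtained by fitting the
  polynomial to the first/last full window and evaluating its derivative
  there (scipy's `mode="interp"`), not by padding or truncation. This
  preserves exactness on polynomials up to the fit order at the edges too.
  The price is a higher noise gain at the outermost samples — the edge fit
  extrapolates — which is visible as an RSD bump at the axis extremes (see
  below).

Because differentiation annihilates constants, additive baseline shifts
between replicates (optical-path/compaction variation in pressed powders)
are removed exactly; multiplicative gain differences are not, by design.
Pre-processing is applied only after range selection so window edge effects
never cross range boundaries; the public pipeline enforces this order.

## Repeatability / reproducibility RSD

For a class *k* of n_k spectra that should agree,

    RSD_k(ν) = σ_k^inter(ν) / ( Σᵢ σᵢ^intra / n_k )

σ_k^inter(ν) is the sample SD (n−1 denominator) across the class's spectra
at frequency ν; σᵢ^intra is the sample SD of spectrum *i* over all
frequencies. The same n−1 convention is used for both (the within-spectrum
denominator is a free choice; consistency was preferred). RSD = 1 means
between-measurement variability equals the average within-spectrum
variability; ≪ 1 indicates consistent measurements.

Class definitions: for **repeatability**, a class is the set of successive
measurements of one standard within a session; for **reproducibility**, a
class is one standard across sessions, with duplicate measurements within a
session averaged first. Classes with a single measurement (the roster
contains one such standard) are skipped with a warning rather than
failing the analysis. The mean RSD curve is the unweighted mean over
classes.

On the default synthetic data, the pre-processed repeatability mean RSD is
~0.13 above 5 THz and rises steeply below 4 THz where the generator
inflates noise — except at the outermost half-window of the axis, where
the SG edge refit inflates the derivative variance and the curve peaks
near 0.5. Property tests therefore assert the low-RSD claim away from the
edge samples; trimming the range extremes (R1, R2) is exactly how the
analysis avoids them.

## PLS-DA

Classes are encoded as an indicator matrix (one column per class, sorted
vocabulary order). PLS is NIPALS PLS2 on mean-centered X and Y — no
unit-variance scaling, the usual choice for derivative spectra where
amplitude is informative. The inner power iteration runs to a 1e-12
relative tolerance on the score vector (cap 500 iterations; with a 2-column
indicator Y it converges in a handful of steps). X is deflated by t·pᵀ per
component; the rotation R = W(PᵀW)⁻¹ is computed with a pseudo-inverse,
which is stabler at near-full rank and matches common reference
implementations. If the X residual vanishes before the requested number of
latent variables (exact fit), extraction stops and the model carries the
achievable count; predictions requested at a higher LV count clamp to it.

Prediction is ŷ = (X − x̄)B + ȳ; the label is the argmax over class
columns (equivalent to a 0.5 threshold for two classes), ties resolved to
the first class in vocabulary order. Explained class variance per LV is
the cumulative share of the centered-Y sum of squares captured by the
rank-one fits, with non-negative increments. Models serialize to JSON
(centering vectors, W/P/Q, scores, vocabulary) for reproducible reload.

## Double cross-validation

- **Folds** are stratified: within each class the samples are shuffled and
  dealt round-robin, so per-fold class counts differ by at most one. With
  only 13 samples in the smallest case study, unstratified splits would
  frequently produce single-class folds. (The stratification is a design
  choice; only "random fold splits" is inherent to the protocol.)
- **Outer loop:** each of the 5 folds is withheld once; the remaining four
  form the tuning set.
- **Inner loop:** the tuning set's own four folds are reused (no fresh
  inner randomization); each in turn is held out, models with 1–20 LVs are
  fit on the rest, and the LV count maximizing the pooled inner OA is
  selected, ties to the smallest. Candidates are capped at what the
  smallest inner training set supports, min(n_train − 1, n_variables).
- **Refit and test:** the model is refit on the full tuning set at the
  selected LV count and predicts the withheld fold; OA per repetition is
  computed on the pooled outer predictions (with 7–8-sample folds, pooling
  is the stable convention for a single OA per repetition).
- **Repetitions:** 30 by default; repetition r draws folds from seed
  base_seed + r. A draw that leaves any fold without one of the classes is
  re-drawn (logged, up to 100 attempts, deterministic offset schedule).
  All seeds used are recorded in the result.
- **Final model:** the modal LV count over all (repetition × outer fold)
  selections, ties to the smallest, fit on all samples; its scores and
  loadings are the exported per-case-study summaries. Per-sample
  correct-classification rates across repetitions are also reported.

Centering statistics are computed inside each PLS fit on its training rows
only, so no information from a withheld fold reaches the model that
predicts it; a test asserts this by corrupting a withheld fold and checking
the tuning outcome is unchanged.

## Synthetic data generator

The generator reproduces the *statistical structure* the analysis assumes,
not the spectroscopy of any real compound:

- **Roster:** 39 distinct compounds (13 phenolic acids in 2 classes, 26
  flavonoids in 7 classes) from up to three suppliers, 55 standards total;
  2–4 replicates per standard drawn uniformly, with one compound measured
  only once (mirroring a standard of limited availability). Replicate
  counts are configuration, not an assertion — the measured total
  (~140–170 spectra) varies with seed.
- **Bands:** Lorentzian by default (common for condensed-phase far-IR;
  Gaussian by config). Each *class* owns 3 motif bands and each *family* 2
  motif bands; motif centers are placed on a randomly permuted uniform grid
  over 1.0–19.5 THz, which guarantees motifs of different groups never
  coincide (rejection sampling is infeasible at this motif density). A
  motif's width (0.2–0.4 THz FWHM) and amplitude (0.15 AU) are properties
  of the motif shared by all compounds in the group; only its center is
  jittered per compound (SD 0.05 THz). Each compound adds 3–8 bands of its
  own (0.2–1.0 THz wide, 0.05–0.25 AU). Family-level motifs exist because
  the analysis discriminates at both taxonomy levels: without a shared
  family feature, family membership would not be a spectral property at
  all and family classification would be unlearnable in principle.
- **Measurement model:** A(ν) = baseline + b + g·Σbands(ν) + ε(ν), with
  per-replicate offset b ~ N(0, 0.02) and gain g ~ N(1, 0.05) (additive and
  multiplicative effects of optical-path variation), and heteroscedastic
  noise ε: SD 0.005, inflated ×5 below 4 THz where the instrument loses
  signal-to-noise. A reproducibility fixture adds a per-session offset
  (SD 0.03) for four selected standards measured in duplicate over five
  weekly sessions.
- **Spikes:** out-of-[0,1] values injected only inside the zones where
  such artifacts occur (0.9–1.1 and 4.5–5.0 THz), per-spectrum probability
  0.3, 1–7 spikes each, drawn from [−0.4, −0.02] ∪ [1.02, 1.4]; a
  calibrated mode injects an exact total for contamination experiments.
  The ground-truth spike map is returned so cleaning recall is measurable.
- **Seeding:** one master seed feeds named substreams (band library,
  replicate effects, noise, spikes), so each stage is independently
  reproducible.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: real band positions or intensities of phenolic
compounds; inter-supplier polymorphism (supplier spectra differ only by
measurement effects); correlated (non-white) noise; ATR penetration-depth
wavelength dependence; detector nonlinearity. In particular, classification
accuracy on the synthetic roster reflects the generator's built-in,
well-separated group motifs and is expected to be near-perfect; it says
nothing about the attainable accuracy on measured spectra, where group
signatures are weaker and distributed.

## Numerical choices and degenerate inputs

- Axis uniformity is validated to 1e-9 relative; wavenumber↔THz round
  trips are exact to the same tolerance.
- Cleaning is idempotent, conserves in-range values bit-exactly, and its
  output is always inside [0, 1].
- RSD on an all-constant class (zero denominator) is an explicit error,
  not a NaN; multiplying a class by a positive constant or adding a common
  offset leaves its RSD curve unchanged.
- A zero-variance spectral variable gets zero PLS weight and never
  produces NaNs; classification ties break deterministically.
- Fold drawing, the double-CV loop and the pipeline are deterministic
  functions of their seeds; re-running a pipeline config reproduces its
  reports byte for byte.
- Problem sizes in the shipped tests and the acceptance script are the
  study's own: the full 674-point axis, the 55-standard roster, 5 folds,
  LV range 1–20, and the 30-repetition protocol (unit tests use fewer
  repetitions where only the contract, not the estimate, is under test).

## Known limitations

- PLS-DA with argmax classification is used as an exploratory
  discriminator; no probabilistic calibration, class-imbalance correction
  or alternative classifiers are provided.
- The RSD statistic has no attached inference (no confidence bands or
  tests); curves are meant for qualitative comparison.
- CSV is the only I/O format; proprietary instrument formats are out of
  scope.
- Permuted-label accuracy for the imbalanced family split concentrates
  near the majority fraction (2/3) rather than 1/2 — expected for argmax
  classifiers under imbalance, and worth remembering when reading
  chance-level baselines.
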