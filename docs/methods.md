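# Methods

This note documents the models, parameter choices and known limitations of
the package.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Synthetic measurement campaign

The generator emulates a colloidal-SERS quantification campaign for
ternary caffeine / theobromine / paraxanthine mixtures.

**Design.** A full simplex-lattice: all compositions of three non-negative
fractions on a 10 % step summing to one — C(12, 2) = 66 mixtures — at a
fixed total analyte concentration of 10⁻⁵ mol/dm³, in triplicate
(198 samples).  Per-analyte concentrations therefore span 0–10⁻⁵ mol/dm³;
nonzero design points start at 10⁻⁶ mol/dm³.  A finer `step` (e.g. 0.01)
extends the lower end to 10⁻⁷ mol/dm³.

**Spectra.** 1024 equally spaced channels from 200 to 3400 cm⁻¹.  Pure
components are sums of Lorentzian bands with FWHM 8 cm⁻¹ (the nominal
spectral resolution of the emulated portable probe), normalised to unit
maximum.  Band positions follow published SERS band assignments: caffeine
and paraxanthine share one position list (509, 650, 693, 1006, 1247, 1450,
1672, 2953 cm⁻¹ — including the unassigned 1672 cm⁻¹ band listed for the
pair), theobromine has its own (637, 1228, 1303, 1353, 1413, 1603,
2953 cm⁻¹).  The *relative intensities* are declared modelling
assumptions, not literature values: caffeine emphasises 693/1450 cm⁻¹ and
paraxanthine 650/1247/1672 cm⁻¹, which keeps the two same-position spectra
linearly independent so that a full-spectrum model can separate them.

**Response.** Component amplitude is `sensitivity · c` (default
sensitivity 10⁵ per mol/dm³, i.e. unit amplitude at the total
concentration) or, when `saturation_conc` is set, the saturating form
`sensitivity · c / (1 + c/c_sat)`.  Caffeine defaults to
`c_sat = 10⁻⁵ mol/dm³`, mirroring its narrower linear range and slower
surface association.

**Noise model.**  Per sample:

* additive white noise, SD = 0.001 of the reference amplitude (the largest
  pure-component response at the total concentration);
* a smooth baseline: three Gaussians with random centres, widths ~600 cm⁻¹
  and amplitudes up to 0.1 of the reference amplitude — the low-frequency
  background ALS is designed to remove;
* component-wise multiplicative noise, SD = 1 % of each component's
  contribution, scaled by the component's `noise_scale_multiplier`
  (caffeine 2.5, others 1);
* a shared *aggregation-state* enhancement factor (SD 15 %) applied to all
  fast-associating components.  Theobromine and paraxanthine associate with
  the silver surface almost instantly and are surface-bound when the
  aggregating salt is added, so they feel the same hot-spot enhancement
  fluctuation; caffeine associates slowly and sees an effectively
  independent enhancement.  This factor varies at the *mixture level* (one
  draw per prepared composition, shared by its replicate measurements,
  i.e. a per-session aggregation state), so it does not inflate replicate
  peak-area RSDs.

The additive/multiplicative/baseline defaults were calibrated once so that
the replicate %RSD of the 693 cm⁻¹ peak area of a mid-design mixture falls
inside the 0.8–2.7 % band reported for well-optimised colloidal SERS; the
acceptance suite recomputes this number.

Why the aggregation term exists: with a fixed total concentration, SNV
normalisation and a discrete 10 %-step design, any *independent*
per-sample amplitude noise small enough to respect the %RSD band is almost
entirely corrected by a trained network — the composition can be read from
the two well-measured analytes plus the sum constraint, and predictions
snap back to the design lattice.  Under such noise the slow associator
actually comes out *easiest* to predict, contradicting the experimental
observation that caffeine is the worst-predicted analyte.  A common-mode
metabolite-vs-caffeine enhancement fluctuation is the structural noise
that cannot be routed around (it corrupts the sum constraint itself, making
the two metabolite errors positively correlated), and with it the
simulation reproduces the observed accuracy ordering.  The per-component
multiplier and saturation knobs are kept as configurable secondary
imperfections.

**Reproducibility.** A master seed spawns one independent substream per
sample (plus one per mixture for the session factor), so datasets are
bit-reproducible and independent of generation order.

**What the generator does not emulate:** electromagnetic/chemical
enhancement physics, colloid aggregation kinetics, pH-dependent spectral
changes, day-to-day instrument drift, wavenumber miscalibration and cosmic
rays.  Passing tests on synthetic data show that the *analysis chain*
recovers known compositions under the stated noise structure — not that
the noise structure captures every failure mode of real SERS campaigns.

## Preprocessing

**ALS baseline.** Minimises `Σ wᵢ(yᵢ−zᵢ)² + λ Σ (Δ²zᵢ)²` with asymmetric
weights (`p` above the baseline, `1−p` below), iterated to weight
convergence.  Defaults λ = 10⁵, p = 0.001, max 10 sweeps, standard for
~1000-channel Raman spectra.  The discrete second difference assumes unit
channel spacing; the grid spacing is absorbed into λ, which is valid
because the grid is equally spaced.  Non-convergence of the weight pattern
(common: a few channels keep flipping at the crossing points) returns the
last iterate with a logged warning rather than an error.  The solver uses
a banded symmetric-positive-definite factorisation
(`scipy.linalg.solveh_banded`), making one sweep O(n).

**SNV.** Per spectrum, subtract the mean and divide by the *sample*
(n−1 denominator) standard deviation; the choice of denominator is fixed
and documented since both conventions exist.  SNV runs strictly after ALS.
A constant spectrum raises a degenerate-input error naming the sample.

**Peak areas.** Trapezoidal integration over all channels within
± half-width of the band centre; default half-width 20 cm⁻¹ (≈2.5 × FWHM;
the integration window is not otherwise constrained).  Characteristic
bands: 693 cm⁻¹ (C=O deformation, caffeine/paraxanthine) and 1303 cm⁻¹
(ν(C–N)+ρ(CH₃), theobromine).  Input spectra are expected to be
baseline-corrected but *not* SNV-normalised — SNV rescales each spectrum
individually and would distort between-replicate area comparisons.

## Neural calibration

Single-hidden-layer feed-forward networks, 1024-20-1 (one per analyte) or
1024-20-3.  The hidden activation is tanh with a linear output — the
standard regression MLP of the relevant era; activations are not dictated
by the emulated study and are config-exposed.  Inputs are mean-centred per
channel on the inner training set (SNV already standardises each spectrum;
channel centring is a cheap additional stabiliser, switchable off).
Targets are min-max scaled to [0.1, 0.9] on the inner training set only;
scalers never see tuning or test data.  Weights start uniform in
±1/√fan-in, deterministically from the seed.

**Training** is full-batch scaled conjugate gradient (SCG): conjugate
directions with the curvature along the search direction estimated by a
one-sided finite difference of the gradient (σ = 10⁻⁴) and regularised by
a Levenberg–Marquardt-style scaling λ (initial 10⁻⁶) that grows when the
local quadratic model fails and shrinks when it is accurate; no line
search.  One epoch = one attempted update.  Early stopping: training runs
to 300 epochs at most and stops after 20 epochs without tuning-set
improvement; the returned weights are always the snapshot with the lowest
tuning error.  Those defaults bracket the 20–100 epochs the emulated
study reports for convergence.  A non-finite loss aborts with a
diagnostic; constant targets raise a degenerate-input error.

**PCA** diagnostics (scores, loadings, explained-variance fractions) are
mean-centred SVD via scikit-learn, used for batch-reproducibility checks.

## Bootstrap validation

Per iteration: draw n samples with replacement (sample-level by default;
`group_by_mixture=True` draws whole triplicates instead, avoiding
replicate leakage between training and test — the default mirrors the
emulated study's sample-level procedure); an empty out-of-bag set triggers
a logged redraw.  The drawn multiset is permuted and split 70/30 into
inner-training and tuning sets; scaling is fitted on inner-training only;
the trained network predicts the out-of-bag samples.  Q² uses the
test-set mean ȳ recomputed per bootstrap test set (the natural reading of
the statistic's definition).  Per-analyte Q²/RMSEP are averaged over
iterations for the primary report; pooled-residual statistics over all
out-of-bag predictions are computed alongside.  Inner-training R² is also
reported and labelled as a fit statistic.  Per-iteration seeds derive from
the master seed, so any single iteration is reproducible in isolation.
Iterations that fail (degenerate split, diverged training) are logged and
skipped; more than 5 % failures aborts the run.  Per-sample accumulators
record how often each sample was out-of-bag with the mean and SD of its
predictions; an SD from fewer than two draws is reported as missing, and
the default 100-iteration desk scale leaves every sample out-of-bag many
times with overwhelming probability.

The shipped pipeline config runs 200 iterations; the full-scale procedure
is 1000.  The acceptance script and suite use 100, which stabilises the
mean statistics to well within the margins of the checks while keeping a
complete four-network study around one to two minutes on one CPU.

## Numerical and degenerate-input policy

* ALS: exact identity `corrected = spectrum − baseline` by construction;
  non-finite inputs rejected.
* SNV: zero-variance spectrum → degenerate-input error.
* Q²: constant actual values (zero denominator) → degenerate-input error.
* SCG: λ clamped to [10⁻²⁰, 10²⁵]; a vanishing search direction or
  gradient ends training.
* Mixture design: compositions are enumerated exactly over integer parts
  and sorted lexicographically; counts obey C(m+k−1, k−1).

## Known limitations

* The relative band intensities of the three analytes are assumptions;
  real pure-component SERS spectra would replace `default_components()`.
* The aggregation-state noise is a deliberately coarse stand-in for the
  many correlated instabilities of real campaigns (day effects, colloid
  batch variation); its size (15 %) was chosen to reproduce the observed
  accuracy ordering, not measured.
* Accuracy statistics at the default noise levels are higher than those
  typically reported for laboratory SERS data; the synthetic campaign is
  cleaner than five days of bench work, so the reported bounds should be
  read as "the chain recovers what the data contain", not as a claim about
  instrument performance.
* JCAMP-DX support covers the plain AFFN `(X++(Y..Y))` form only (no
  SQZ/DIF/DUP compression).
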