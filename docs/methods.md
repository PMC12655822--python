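# Methods

## Spectral model and grid

All spectra live on a uniform wavenumber grid, by default 250–3000 cm⁻¹ at
7 cm⁻¹ steps (394 points), the acquisition grid of a portable Raman
spectrometer. Axis values are treated as bin centers; resampling onto a
target grid is linear interpolation, with points outside the source range
set to zero and flagged in metadata. Spectrum tables are delimited text
(comma, tab, or whitespace; autodetected), column 1 wavenumber, columns
2..k one spectrum each; reading uses pandas' round-trip float parser and
writing prints 17 significant digits, so a write→read cycle is
value-identical.

## Preprocessing

**Baseline subtraction.** The broad SERS continuum is estimated by
multi-segment iterative polynomial fitting: the axis is split into
`n_segments` equal-width segments (default 4), each fit by a polynomial of
degree 3 (default) to all points, after which points lying more than
3·σ above the fit (σ = the standard deviation of the residuals of the
currently kept points) are excluded and the fit repeated. Exclusions are
never revoked, so the kept set shrinks monotonically and the iteration
terminates without limit cycles — a property plain clip-to-fit ModPoly-style
iterations lack on noiseless inputs, where we observed them oscillating
between two fits. Neighbouring segment fits are blended with linearly
tapering weights over a 3-point overlap to avoid steps. A constant spectrum
is recognised as pure baseline exactly; on a synthetic ramp-plus-Lorentzian
fixture the residual baseline away from the peak is under 1% of the peak
amplitude, and a second application changes the corrected peak height by
well under 5%. Corrected intensities are floored at 0 by default because the
downstream weight factors are interpreted as non-negative signal fractions;
the flag `floor_at_zero=False` disables this. Defaults: `n_segments=4`,
`degree=3`, `n_iterations=50`, convergence tolerance 1e-6 (relative norm
change of the fitted baseline).

**Smoothing.** A centered boxcar (moving average), default 5 points
(35 cm⁻¹), with the window shrinking symmetrically at the edges. Window 1
is the identity. The acquisition software's segment count, polynomial
degrees and boxcar width are not public; these defaults are this package's
own choices and every knob is exposed in the config.

## Synthetic reference spectra

Only the strongest band of each reporter is an instrument fact (DTDC 510,
SiNC 684, BHQ3 1094, QXL680 1140, QSY21 1496 cm⁻¹). Each default reporter
model is a Lorentzian main peak (amplitude 1, FWHM 18 cm⁻¹) plus two minor
Lorentzians at fixed positions that are *invented fixtures*, chosen to be
non-overlapping across reporters so the reference matrix stays well
conditioned; they are configurable and never presented as measured spectra.
The reference library refuses spectra whose global maximum strays more than
one bin from the reporter's characteristic shift.

## Forward model and unmixing

A mixture is `S_total = Σ CᵢSᵢ + noise + baseline`: additive Gaussian noise
with SD expressed as a fraction of the library's global peak (default 1.5%),
plus an optional smooth random baseline (cubic spline through uniform random
knots) whose amplitude uses the same convention (default 0 for mixtures, 2%
for simulated cell spectra in the pipeline). At zero noise the model is
exactly linear in the weights.

CLS unmixing solves the linear model by `numpy.linalg.lstsq` (`ols`) or
`scipy.optimize.nnls` (`nnls`, default). The spectrum and library must share
one axis; a library condition number above 1e8 raises an error naming the
most collinear reporter pair rather than silently pseudo-inverting. No
intercept column is fitted by default since the baseline is removed in
preprocessing. Weights are relative to the references as given — references
are never re-normalised; only for ratio-recovery comparisons are recovered
weights renormalised to fractions summing to 1. Pearson correlations are
reported with the two-sided t-test p-value of the ordinary-least-squares
slope (n−2 degrees of freedom), via `scipy.stats.linregress`.

In the full pipeline the references used for unmixing are run through the
identical preprocessing chain as the cell spectra, keeping the weight
semantics consistent; the raw library is what gets written to disk.

## Synthetic cell populations

Each cell line is a truncated-normal distribution per marker (rejection
sampling), truncated to [0, 0.79] — the observed single-cell weight-factor
range. Default per-line means (α3, β1, β3, β4, β5):

| line  | α3   | β1   | β3   | β4   | β5   |
|-------|------|------|------|------|------|
| MM231 | 0.45 | 0.55 | 0.02 | 0.05 | 0.25 |
| MCF7  | 0.20 | 0.50 | 0.15 | 0.02 | 0.40 |
| SKBR3 | 0.30 | 0.60 | 0.02 | 0.02 | 0.03 |

with a common SD of 0.06. These are synthetic calibrations reproducing the
qualitative pattern of the three lines (β1 highest everywhere, β4 near zero
everywhere, β5 elevated in MCF7, β3 low outside MCF7); they are not
measured values and are overridable in the config. Note that truncation at
0 shifts the realised mean of near-zero markers upward (e.g. a configured
mean of 0.02 with SD 0.06 realises ≈ 0.056); tests compare sample moments
against the closed-form truncated-normal expectation.

**What the generator does not emulate:** correlated marker expression
within a cell, heavy-tailed single-cell heterogeneity, instrument drift,
cosmic rays, or cell-to-cell focus/coupling variation in SERS intensity.
Passing tests therefore demonstrate the correctness of the computational
chain under the stated statistical model, not instrument-grade performance
on real cells.

## Classification protocol

Features are the five weight factors only — no spectral features reach the
classifier. Stratified 70/30 split (per-class proportions preserved within
rounding), scikit-learn random forest with 100 trees and unlimited depth
(the library defaults), and the split/fit/evaluate cycle repeated — 200
iterations by default — with per-iteration seeds derived from one top-level
seed; the protocol reports the mean macro F1 and mean held-out accuracy
across iterations, with per-iteration reports retained. Repeated
*resplitting* (rather than refitting one fixed split) is the interpretation
under which averaging an F1 over iterations is meaningful. "Average F1" is
the unweighted macro mean over the three classes, appropriate because the
classes are balanced by construction. For mixed-population prediction the
forest is retrained on the full labelled table and applied to an unlabelled
population; the summary reports per-class counts (conserving the population
size) and per-class mean predicted profiles. The default mixed population
is 450 cells drawn 150 per line — a balanced choice, since the true mixture
composition is not part of the statistical model.

**Separability ceiling.** Under the default population the nearest class
pair (MM231 vs SKBR3) has mean separation ‖Δμ‖ ≈ 0.273 against an isotropic
SD of 0.06, i.e. a pairwise Bayes error of Φ(−‖Δμ‖/2σ) ≈ 1.2%. The
Bayes-optimal three-class accuracy is therefore ≈ 99.2–99.5%, and the
random-forest protocol measures ≈ 98.2–98.3% (mean macro F1 ≈ 0.982). These
are the honest ceilings of this generator configuration; raising them would
require wider class separation or smaller single-cell variability than the
defaults posit.

## Embedding selection

t-SNE (scikit-learn, all hyperparameters except perplexity at library
defaults) is fit `n_replicates` times (default 5) per candidate perplexity
(default grid 5, 10, 20, 30, 45, 60, 90, 120, 150, 200, 250, 300 — twelve
values spanning 5–300, hence 60 fits), each replicate with a derived seed
and its final KL divergence recorded. Per perplexity the lowest-KL
replicate is kept (ties broken by lowest replicate index); across
perplexities the kept embedding with the lowest Davies–Bouldin index wins.
DBI uses Euclidean centroids, mean member-to-centroid distances as scatter,
and errors on coincident centroids; it is computed in the 2-D embedding
with the known training labels. DBI is translation/rotation invariant and
scales as 1/s when between-cluster distances scale by s at fixed scatter.

## Reproducibility and numerics

Every stochastic operation takes an explicit seed; composite protocols
derive per-stage/per-iteration seeds (all below 2³¹) from a single
top-level seed via `numpy.random.default_rng`, so the full pipeline is
byte-reproducible: identical config + seed ⇒ identical output tables.
Degenerate inputs fail loudly: non-monotonic axes, ragged tables, even
boxcar windows, all-zero mixing ratios, rank-deficient libraries,
zero-variance correlation inputs, single-class training sets, perplexities
at or above the cell count, and coincident DBI centroids all raise errors
naming the offence.

## Problem sizes

The shipped protocol runs 300 cells per line (900 cells), 200 classifier
iterations, an 8-design mixture panel, and a fresh 450-cell mixed
population; `scripts/acceptance.py` executes exactly that in roughly half a
minute on one CPU. The examples and the pipeline smoke tests use reduced
sizes (tens of cells, a few iterations, two-point perplexity grids) chosen
to demonstrate each capability quickly; the statistics they print are the
same quantities at smaller n.

## Known limitations

* Baseline estimation on peak-dense spectra absorbs part of the Lorentzian
  wing intensity into the continuum, attenuating recovered weights by a few
  percent (systematic, shared across cells, so classification is barely
  affected). This is inherent to continuum fitting, not a defect of the
  peeling scheme.
* The boxcar (35 cm⁻¹ over 18 cm⁻¹ FWHM bands) visibly flattens peaks; the
  pipeline compensates by smoothing the references identically before
  unmixing.
* No vendor binary formats (SPC/WDF), cosmic-ray removal, or wavelength
  calibration; inputs are delimited text on a shared or resampleable grid.
* The synthetic generator's independence of markers within a cell is a
  simplification; real integrin co-expression is correlated.
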