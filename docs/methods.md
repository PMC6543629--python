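# Methods

## Model and assumptions

All estimators assume the classical constant-efficiency kinetics of qPCR: a
reaction with efficiency E and initial template (in fluorescence-equivalent
units) F0 produces readings

    F_i = (F0 / b^D) (1 + E)^i

at cycle i for a sample diluted D steps at base b, as long as the signal is
above the baseline noise and below saturation. Four standing assumptions are
inherited from the calibration-curve framework: kinetics are independent of
template concentration; E is constant and maximal before saturation;
fluorescence is linear in product concentration; and the intended dilutions are
accurate (a systematic pipetting error biases any dilution-based estimator).

Under this model, any two readings (i, F_i, D1) and (j, F_j, D2) of one
dilution set determine E exactly:

    E_ij = b ** ((log_b F_j − log_b F_i + (D2 − D1)) / (j − i)) − 1.

The pairwise estimator enumerates all unordered pairs of admitted readings,
including same-curve pairs (D1 = D2), excluding only pairs that share a cycle
number (j = i leaves E undefined). The set-level estimate is the arithmetic
mean of the per-pair values after outlier exclusion.

## The analysis window

Pairs are formed only from readings inside a closed RFU interval
[lower, upper]. The default 20–180 RFU was chosen for two-fold Actb-like
series on a CFX-class instrument: high enough that readings clear the
baseline-noise band (roughly ±10 RFU), low enough to stay in the portion of
the curve where per-cycle efficiency has not yet begun its decline toward the
plateau, and wide enough to admit about 4 readings per curve. The window
should be re-derived for other chemistries/instruments; the module provides:

* **noise profile** — pooled early-cycle readings (min/max/mean/sd +
  histogram). When the band reaches ±10 RFU, `FluorWindow.clamped` raises a
  lower bound below 10 RFU to 10 RFU, with a warning.
* **takeoff detection** (lower bound): for each candidate cycle c a linear
  background is fitted to cycles 1..c−1 and the studentized prediction
  residual of F(c) is tested one-sided at alpha (default 0.01). Because the
  scan tests ~25 cycles per series, a raw single-cycle rule would accumulate a
  family-wise false-flag rate of ~20%; the detector therefore requires the
  *next* reading to exceed its own threshold against the same background fit
  (confirmation, default on), which brings the per-series false-flag rate
  under alpha while leaving the flagged takeoff cycle unchanged on genuine
  exponential takeoffs.
* **First Derivative Maximum** (upper bound): the cycle maximising the
  centered difference (F(c+1) − F(c−1))/2 on raw readings (no smoothing; ties
  break to the earliest cycle). Offset-invariant by construction.
* **stable-E scan**: per-cycle E(i) = (F_i/f0)^(1/i) − 1 under a candidate f0;
  the stable span is the longest initial run of detected-signal cycles
  (readings ≥ 10 RFU by default) with E standard deviation ≤ 0.01.
* **boundary grid search**: candidate windows ranked by the Monte-Carlo SD of
  the pairwise estimate over resampled set triplets; the same seed is used for
  every window so comparisons are paired. Windows admitting fewer than two
  readings in some set are reported infeasible rather than raising.

## Distribution diagnostics and outlier exclusion

Pairwise-E arrays are markedly non-normal (skewed, leptokurtic), so parametric
outlier rules (sigma ranges, quartiles) are inappropriate. The diagnostics
histogram the values into half-open bins of width 0.05 anchored at 0 and
report bias-corrected skewness and excess kurtosis (the spreadsheet-compatible
definitions) plus a chi-square goodness-of-fit against a normal with the
sample mean and sd. Tail bins with expected count < 5 are pooled into single
left/right cells before the statistic is formed (otherwise near-empty tail
bins dominate the statistic and genuinely normal samples are rejected), and
df = cells − 3. The test requires n ≥ 50; the standard validity annotation
(≤ 20% of cells with expected < 5) is reported, not enforced.

Outlier exclusion applies the frequency criterion of the chi-square framework
directly: scanning outward from the modal bin, the first bin below the mode
with fewer than 5 values sets the low cutoff at that bin's upper edge, the
first such bin above the mode sets the high cutoff at its lower edge, and
values outside [low, high] are discarded. If every bin is sparse the array is
left untouched (warning). Exclusion requires n ≥ 50 pairs; smaller arrays fall
back to the raw mean with a warning.

## Calibration baseline

Cq values are regressed on log10(concentration) by ordinary least squares and
E = 10^(−1/slope) − 1. Concentrations default to b^(−D) in arbitrary units
(only the intercept depends on the unit). One code path serves every dilution
base: regressing on log_b with E = b^(−1/slope_b) − 1 is algebraically
identical.

## Monte-Carlo precision

Precision is the SD of "sampling" means: each sampling draws a fixed number of
replicate sets (default 3, the common wet-lab triplicate) without replacement
from the available pool (default 16), averages their per-set efficiencies, and
the SD/max/min/range are taken over the (default 100) sampling means, with an
n−1 denominator. Draws are without replacement within a sampling — a
triplicate consists of three *different* replicas — and independent across
samplings. For the pairwise arm, E is computed per six-well set and the drawn
estimates averaged, structurally parallel to the calibration arm; pooling all
wells of a sampling into one pair enumeration is possible via the library but
is not the default.

## Relative quantification

* F0 per well is the arithmetic mean of F_i/(1+E)^i over in-window readings
  (scale-equivariant; exact on noiseless exponentials).
* Pfaffl-style ratio: (1+E)^(Cq_control − Cq_sample); the base is the
  amplification factor 1+E since E is fractional efficiency.
* Worst-case replicate error: among replicate undiluted wells (true ratio 1),
  the Cq route takes the ratio of the extreme Cqs at the maximal per-set
  calibration E (the error grows with E), the F0 route takes max(F0)/min(F0)
  at the maximal per-set pairwise E. Ratios are oriented > 1.
* Accuracy table: per concentration group, the observed fold is
  mean F0(reference)/mean F0(group) for the pairwise route (per-well F0 under
  the owning set's efficiency, not rescaled by b^D — with identical set
  structures the scaling cancels in the ratio), and the Pfaffl ratio of
  group-mean Cqs at the group's mean calibration E for the classical route.
  Errors use error_pct = 100·(observed − expected)/observed, the share of the
  observed fold that is spurious; the summary is the mean absolute error over
  non-reference groups.

## Synthetic plates

The generator emulates the structure the estimator assumes: per-well curves
F_i following the recurrence F_i = F_{i−1}(1 + E(1 − F_{i−1}/plateau)) —
exactly exponential for plateau = ∞, smoothly damped (logistic) otherwise —
plus i.i.d. Gaussian baseline noise on every reading. Defaults define the
study conditions used throughout the tests and the acceptance script: E = 0.8,
F0(undiluted) = 0.008 RFU-equivalents (signal emerges from the noise band
around cycle 13 and F0 back-calculations land near 0.008, matching reported
magnitudes for 100 ng of template), base 2, steps 0–5, 16 replicate sets,
33 cycles, plateau 2000 RFU, noise sd 3 RFU (band ≈ ±10 RFU, instrument-like),
noise mean 0. Optional per-well lognormal F0 jitter and per-set F0 scale
factors emulate pipetting variability and concentration-grouped plate designs.
Cq calls interpolate log-linearly between the flanking cycles of the first
threshold crossing (exact for exponentials; linear fallback when the lower
flank is non-positive). The threshold is always explicit (31.07 RFU in the
examples) — threshold placement is instrument-specific and is not derived from
the plateau.

What the simulator does **not** model: mechanistic chemistry (primer/dNTP
depletion, product inhibition), cycle-dependent efficiency before saturation,
spatial plate effects, correlated or heteroscedastic noise, and vendor
baseline-subtraction artefacts. Tests passing on synthetic plates therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every failure mode of real instruments; the dataset-bound checks
in `tests/test_acceptance.py` cover a real 96-well run when its measurement
files are present under `data/`.

## Numerical choices and degenerate inputs

* Window membership is the closed interval; readings ≤ 0 are never admitted
  (log undefined).
* Pair enumeration is an exact double loop; the count obeys
  C(n,2) − Σ_c C(n_c,2) with n_c readings at cycle c.
* The per-pair formula is evaluated so that swapping the two readings flips
  the sign of both numerator and denominator, making orientation invariance
  exact in floating point.
* Modal-bin ties in the outlier scan resolve to the lowest bin; degenerate
  (zero-variance) arrays skip the chi-square test with a warning.
* Monte-Carlo set ids are sorted before drawing, so results are reproducible
  across dict orderings; sd uses ddof = 1 throughout.
* `first_outlier_cycle` needs ≥ 8 cycles and ≥ 5 background cycles; a
  numerically perfect background fit (rss ≈ 0) flags any positive departure.

## Problem sizes

The test suite and acceptance script run entirely on synthetic plates at the
study's native scale (96 wells × 33 cycles; 100 Monte-Carlo samplings), with
200 seeded single-set plates for bias recovery and 50 seeded full plates for
the precision comparison — a few seconds end to end.

## Known limitations

* The pairwise values of one set are heavily cross-correlated (each reading
  enters ~n−1 pairs); the array size overstates the effective sample size, so
  no analytic standard error is attached to the set-level mean — precision is
  assessed by resampling instead.
* With very tight windows (< 2 admitted readings per set) the estimator is
  undefined; the grid search reports such windows infeasible.
* Efficiency estimates above the window's saturation onset are biased low;
  choosing the upper bound below the FDM fluorescence is the intended guard.
* The takeoff detector assumes a linear (or flat) background; strongly curved
  baselines can advance or delay the flagged cycle.
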