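# Methods

## Assay model

The pipeline models a droplet-microfluidics experiment in which single B
cells are encapsulated in water-in-oil droplets (default 50 pL) with
fluorogenic reporter chemistry and imaged on a fixed grid of six frames at
600 s intervals (t = 0 at the first frame; only intervals enter any
formula, so the origin is arbitrary and rate estimates are invariant to
shifting it). Encapsulation is Poisson: the number of cells per droplet is
Poisson(λ) with λ typically 0.25–0.50, so most droplets are empty and
multi-cell droplets (flagged, never quantified) are rare.

Two calibrated channels carry the secretion read-outs:

* **Lactate.** Secreted lactate accumulates in the droplet; an enzymatic
  assay converts it to a fluorescent product, so the whole-droplet signal
  is a saturating function of concentration. We model it as an increasing
  four-parameter logistic, y = bottom + (top − bottom)/(1 + (EC50/x)^h)
  with h > 0. The in-droplet concentration of a cell secreting at rate r
  (amol/s) is C(t) = r·t/V (amol/nL, numerically µM, with V in nL).
* **Antibody relocation.** Secreted IgG/IgM is captured on paramagnetic
  nanoparticles; the ratio of nanoparticle to whole-droplet fluorescence
  rises with concentration as y = y_plateau − (y_plateau − y_blank)e^(−Kx)
  (x in nM), with the exact inverse
  x = −ln((y_plateau − y)/(y_plateau − y_blank))/K. Concentrations convert
  to molecule counts via n = x·10⁻⁹·V·N_A (1 nM in 50 pL ≈ 30,111
  molecules).

## Detection limits and cutoffs

* Lactate LoD (signal space): median of the lowest nonzero standard
  (2 amol/nL) plus 1.646·(SD_low + SD_low+1) over the two lowest standards.
  The coefficient is 1.646 as used operationally by this assay family (a
  variant of the classical 1.645).
* Lactate cutoff: plateau − 2·SD with SD = √N·(upper − lower plateau 95%
  CI)/3.92, N the number of distinct standard concentrations. The plateau
  CI comes from the asymptotic covariance of the nonlinear least-squares
  fit (t-quantile at the residual degrees of freedom).
* Relocation LoD: median_empty + 1.645·2·σ̂ with σ̂ = 1.4826·MAD over all
  time points of all empty droplets of the same experiment (LoDs are
  per-experiment quantities).
* Relocation cutoff: fitted plateau minus the half-width of a 90%
  prediction interval, computed as t(0.95, dof)·residual_sd·√(1 + h) with
  h the leverage of the highest-concentration design point (the point
  closest to the plateau). This is a standard prediction-interval
  construction; no exact recipe is prescribed by the threshold definition
  itself.

## Detection criteria and rate estimation

A droplet is a secretor candidate when its relocation series (I) reaches
the LoD at least once, (II) increases over time, and (III) has
max − min > 1.645·2·σ̂. Criterion II is operationalized as a positive
least-squares slope of signal vs time (computed in covariance form so a
constant series has exactly zero slope), which is robust to single-frame
dips. All "above threshold" comparisons in the package are ≥, matching the
"equal or above" convention of the rate thresholds.

Rates are interval averages. Lactate: per interval,
(C(t+1) − C(t))·V/Δt in amol/s; the concentration-change-only form would
carry the wrong units, so the droplet volume multiplies in. Antibodies:
molecule differences per interval. Negative intervals are retained (the
mean stays unbiased); for the noiseless forward model the interval mean
telescopes to the exact rate. Lactate signals below the fitted bottom clamp
to concentration 0, signals at/above the plateau clamp just inside it and
flag the estimate `above_range`; saturated relocation points are excluded
from averaging rather than clamped (clamping would bias the rate), and a
fully saturated trace reports the cutoff-equivalent rate with
`above_range=True` so the "≥ cutoff" share of a cohort remains reportable.

The quantitative ranges (0.10–0.80 amol/s lactate; 3–375 IgG/s; 7–150
IgM/s) and the secretor thresholds (≥ 3 IgG/s, ≥ 7 IgM/s) are assay
working constants and therefore configuration values, not derived
quantities: the effective lactate range reflects instrument limitations
beyond the raw LoD/cutoff arithmetic.

## Affinity and cell-state classifiers

The affinity slope regresses antigen relocation on antibody relocation
(intercept fitted) over the time points with antibody relocation inside
[LoD, cutoff]; a higher slope means more antigen captured per unit
antibody, i.e. higher affinity. The axis convention (antigen on y) is the
one under which the slope increases with affinity and is recorded in the
estimate metadata via the field semantics. Antigen specificity requires
the antigen channel to reach its own empty-droplet LoD at least once.

ROS: the per-cell increase is max − first frame (decay after the maximum is
ignored); the threshold is mean + 2·SD (sample SD, ddof 1) of a
reference-day distribution of increases, pooled over animals. pH: the
first-frame dye signal is normalized to the cohort median (assumed near
physiological pH); the threshold is the average of per-replicate
calibration means at pH 5.5 plus their SEM (SD/√n over replicates). The
dye response is modeled as increasing with acidity (pHrodo-type), so
normalized signals at or above the threshold are "acidic". Caspase-3/7:
a droplet is active when the SD of its whole-droplet signal (SD_WDF)
reaches median + 3·SD of the empty-droplet SD_WDF values at the first
frame, at any time point; "3 SD" is read as three times the dispersion of
that empty-droplet reference set, the only reading that yields a
noise-scaled threshold.

## Cohort statistics

λ is estimated by the Poisson MLE (sample mean of occupancy counts, SE
√(λ̂/n)); the empty-fraction estimator −ln P̂(0) is kept as a cross-check.
Grubbs screening is single-pass and two-sided with the t-based critical
value at α = 0.05. Distribution comparisons delegate to SciPy
(Kolmogorov–Smirnov, Wilcoxon signed-rank with p = 1 for all-zero paired
differences, Kruskal–Wallis); Dunn's post-hoc z-tests on pooled mean ranks
(with tie correction) are implemented in-package and Bonferroni-adjusted.
Significance tiers are the step function <0.05 *, <0.01 **, <0.001 ***,
<0.0001 ****.

## Pathway activity

DEG tables (gene, cluster, log2FC, p) are filtered at p < alpha (strict
inequality, default 0.05). Expresser subsets split at log2FC = 1 with the
boundary in "low" (low: log2FC ≤ 1); an alternative data-driven threshold
(mean log2FC of the immunoglobulin genes) can be passed explicitly but has
no default. Pathway activity is the unweighted mean log2FC of a pathway's
significant genes; empty intersections are reported with n = 0 rather than
raised. The bundled gene sets are documented placeholders covering
canonical pathway members and are meant to be replaced by user-curated
lists.

## Synthetic-data generator

The generator is the package's stand-in for raw microscopy data and
defines the conditions every test runs under: 2,000 droplets at λ = 0.3 by
default, 6 frames × 600 s, 50 pL. Channel noise is additive Gaussian with
SD = 1.4826 × the configured blank MAD (lactate MAD 10 AU on a 200 AU
blank; relocation MAD 0.002 on a blank ratio of 1.0), consistent with the
normality assumption behind σ̂ = 1.4826·MAD. Ground-truth secretion rates
are log-uniform across (and slightly beyond) each assay's quantitative
range so that in-range recovery and out-of-range flagging are both
exercised. The antigen channel applies the cell's true slope to the
noise-free antibody relocation and adds its own noise, so regression
attenuation from a noisy regressor is a property of the estimator rather
than of the data generator. The truth calibration curves place the
informative flank of each assay over the concentrations that in-range
secretion actually produces (lactate EC50 10,000 amol/nL; relocation
K = 0.02 /nM).

What the generator does **not** emulate: image formation and segmentation,
photobleaching/photoactivation drift (an optional linear blank drift
parameter exists, default 0), bead-capture depletion of the analyte,
secretion bursts (rates are constant per cell), and biological correlation
structure between channels beyond the programmed states. Passing tests
therefore demonstrate correctness of the quantification machinery under
the stated statistical assumptions, not performance on raw microscopy
data.

## Numerical choices and degenerate inputs

4PL and exponential fits use `scipy.optimize.curve_fit` with data-driven
initial values (extremes for asymptotes, half-saturation point for
EC50/K) and bounded positivity for EC50, hill and K; non-convergent or
transition-free tables raise a fit error with diagnostics. Inverse curves
are exact algebra; saturated signals raise rather than return a number,
blank-subceeding relocation signals clamp to 0 nM with a warning. The
empty-droplet statistic requires a configurable floor (default 30) of
empty droplets. Classifier thresholds on degenerate references (zero
dispersion) collapse to the location statistic, and ties still call the
activated side.

## Problem sizes

The bundled demonstrations and checks use 2,000-droplet cohorts for
recovery, 10,000 droplets for the null false-positive control, 50,000
draws for Poisson consistency, 2,000 replicates for the Grubbs type-I
simulation and 200 replicate fits for plateau-CI coverage — sizes at which
the Monte-Carlo error of each summary is comfortably below the margin it
is compared against, while a full run stays in the seconds-to-minutes
range on a single CPU.

## Known limitations

Overall accuracy of the ROS classifier is bounded by its own threshold
definition: placing the cut at mean + 2 SD of the low-state reference
fixes the low-state false-positive rate near 2.3% under Gaussian noise
regardless of class separation, so accuracy claims are about detection of
the elevated class. The caspase classifier's any-time-point rule trades a
small specificity loss (~0.8% with six frames) for near-perfect
sensitivity. The relocation cutoff depends on the design of the standard
ladder through the leverage term; sparse ladders widen the prediction
interval and lower the cutoff. Affinity slopes for slow secretors rest on
a narrow regressor range and are accordingly noisy — rank order is
recoverable, absolute slopes less so.
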