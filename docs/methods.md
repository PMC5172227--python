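# Methods

This note documents the models, parameter choices and numerical
conventions of `mitoprofiler`, and what the synthetic-screen validation
does and does not establish about real screen data.

## Synthetic screen model

The generator emulates a fixed-cell RNAi screen in a U-2-OS-like cell
line: 47 targets × 2 siRNAs × 3 replicates, cell counts Poisson around
700 per siRNA condition, five readouts per cell, plus live-cell
trajectories recorded every 30 min for 72 h.

**Baseline feature distributions.** Intensity features are log-normal
(positivity, multiplicative shot-to-shot variation), shape features
Normal, focus counts Poisson (53BP1 rate 2.0, γ-H2AX rate 1.5 per cell).
Derived features respect their identities by construction: integrated
intensity = average × area, elliptical form factor = length/breadth ≥ 1.
EdU is a two-component mixture (replicating fraction 0.45 at high
incorporation) rather than a single mode, because the S-phase fraction is
what perturbations actually move.

**Effect encoding.** A perturbation is a standardized mean shift per
readout (units of the baseline s.d., applied to continuous features) plus
a multiplicative factor on the focus-count rates; for EdU the shift acts
on the replicating fraction (0.15 per shift unit), which keeps
intensities positive and is the biologically meaningful dial. Default
strengths follow four archetypes mirroring the phenotype classes the
analysis should resolve — (1) mild mitotic, (2) strong mitotic with weak
DNA damage, (3) strong mitotic with strong DNA damage, (4)
cytokinesis-failure-like (binucleation, delayed replication-stress DDR,
S-phase extension) — times a deterministic per-target factor in
[0.75, 1.25] so the 47 targets form a graded series rather than four
exact replicas. The scalar "planted strength" used by recovery tests is
|shift| (+ log focus-rate for the focus readouts).

**Proliferation coupling.** Cell counts are multiplied by
exp(−0.3 × morphology shift), normalized to mean 1 across targets: the
screen-wide mean stays at the configured 700 cells per siRNA while
relative proliferation differences (the "dot size" covariate) are
preserved.

**Trajectories.** Each cell cycles G1 → S → G2 → M on the frame grid.
S duration and mitotic duration are *cell-intrinsic*: drawn once per cell
(S ~ Normal(16 h, 1 h) for controls; the 1-h s.d. is a free choice, no
empirical dispersion being available) and reused every cycle. This makes
the longest-run duration estimators unbiased for the planted mean;
per-cycle redraws would bias them upward by the expected maximum of
several draws. Condition parameters set mitotic duration, per-mitosis
death probability (death is absorbing), the probability that a mitosis
is aberrant, the probability that an aberrant mitosis is a cytokinesis
failure (binucleated state thereafter), S-phase extensions after the
first and second aberrant mitosis (+2 h / +6 h for the
cytokinesis-failure archetype, on a 16-h control base), and an absolute
DDR onset time after which the 53BP1 focus-count rate jumps by the
condition's focus-rate factor. The aberrant-morphology flag marks the
generation born of an aberrant mitosis (until the next division) and is
permanent once a cell is binucleated. Per-frame misclassification noise
(default 5%) independently corrupts the state label, the replication
pattern and the aberrant flag; dead frames are never corrupted. The 5%
default exists to exercise the median smoothing in the duration
estimators.

**Images.** Nuclei are non-overlapping ellipses with an ellipsoidal
(√(1−d²)) intensity profile; foci are Gaussian blobs (σ = 1.0 px ≈
320 nm at the 0.32 µm/px pixel size, amplitude 8000 on a 3000-count
nucleus) placed within 0.7 of the nuclear radius with ≥ 5 px separation
so planted counts are resolvable; Gaussian read noise is added and the
result clipped to the 16-bit range. Placement is rejection sampling with
bounded retries; saturation raises a generation error rather than
silently dropping objects.

## Feature extraction

Segmentation thresholds the DAPI channel (Otsu or a fixed value), splits
touching nuclei by a watershed on the distance transform (markers =
distance maxima ≥ 7 px apart), removes border-touching objects (their
features would be truncated) and filters by area. Vendor-software
area/intensity gates from production screens are not canonical here; all
gates are exposed as parameters.

Focus detection is a white top-hat with a disk of radius 5 px (≈ 1.6 µm,
sized to pass typical 53BP1 foci at 0.32 µm/px) followed by per-nucleus
thresholding at median + 3 × robust s.d. (1.4826 × MAD) of the response
inside the nucleus. Two guards matter in practice: the threshold is
floored at 10% of the nucleus' peak response (on near-noiseless images
the MAD collapses to 0 and the adaptive threshold with it), and the
outermost 2 px of each nucleus are excluded because the top-hat cannot
follow the steep intensity fall-off at the nuclear rim and leaves a
spurious annular response there. Components ≥ 2 px become foci.

Feature conventions: 0-based (row, column) pixel coordinates, areas in
pixels, intensities in camera units; perimeter is the boundary contour
length; cell length/breadth are the major/minor axes of the
intensity-weighted second-moment ellipse. The γ-H2AX "minimum/maximum
average intensities" are implemented as the per-nucleus extrema of the
3 × 3 mean-filtered channel — a documented reading of an ambiguous
definition (a per-population reading would also be defensible).

The mitotic γ-H2AX score identifies mitotic cells as DAPI objects whose
mean intensity exceeds a condensed-chromatin threshold, sums each cell's
focus integrated intensities, and averages over all mitotic cells
(0 with a warning when none are found).

## Probability scoring

`fit_lr` maximizes the Bernoulli log-likelihood by IRLS on features
standardized with training mean/s.d. (weights become comparable across
features; standardization parameters are part of the model so held-out
cells are transformed with training statistics only). An L2 penalty of
1e-6 on the weights — not the intercept — bounds the weights under
complete separation while leaving ordinary fits at the MLE to well
below reporting precision. Convergence: max coefficient change < 1e-8 or
100 iterations (non-convergence warns and returns the last iterate —
this occurs for strongly separated conditions where the penalized
optimum has very large weights; predicted probabilities are saturated
and stable there). Constant training features get s.d. 1 with a warning.

Choices the population scoring makes explicit:

* **Ensemble = mean of member probabilities; population score = mean of
  cell scores.** Both aggregations are the simplest symmetric choices.
* **"Strongest phenotypes" = highest training AUC**, ties broken by
  larger training n then siRNA id; the ensemble keeps the top 10 (all,
  if fewer candidates). Selection is per readout; each member model
  standardizes with its own training cells.
* **AUC** is the rank statistic P(s⁺ > s⁻) + ½P(tie), identical to the
  trapezoidal ROC area, computed via midranks.
* **Mann–Whitney U**: exact null distribution when both groups have
  ≤ 20 observations and no ties, otherwise the normal approximation with
  continuity and tie correction (scipy).
* **KS normality** is applied to standardized scores (s − mean)/s.d.
  against the standard normal; raw scores live in [0, 1], so a
  standard-normal reference is only meaningful after standardization.
  H = 1 iff p < 0.05; zero-variance scores leave H undefined with a
  warning.
* **Hedges' g** uses the sample-size-weighted pooled s.d. without the
  small-sample correction factor (equivalently Cohen's d); with ~700
  cells per group the correction would be ≪ 1%.
* **CI** for the mean uses Student-t quantiles.
* Mann–Whitney p-values are reported raw per siRNA with an optional
  Bonferroni column.
* **DeLong**: placement values via midranks, paired covariance, two-sided
  z-test on the AUC difference; identical score vectors return p = 1.

Cross-validation is leave-one-replicate-out: each fold's ensemble is
selected, fitted and standardized on the remaining replicates only, and
scores are reported for held-out cells. With three equal replicates each
fold trains on 2/3 ≈ 66% of cells.

## Clustering and concordance

k-means uses k-means++ initialization, Euclidean distance on the 5-D
probability profile, best of 50 restarts by within-cluster sum of
squares (scikit-learn). No feature scaling is applied — the five
variables are already probabilities on [0, 1]. Cluster labels are
renumbered by ascending centroid norm, so the highest label is the
strongest combined phenotype; this is a presentation convention. The
"mitotic phenotypes" clustering variable is the single morphology-readout
score (nuclear morphology and mitotic figures are features of the same
readout here). k is fixed at 4 by default; `choose_k` offers
silhouette-based selection for data where the group count is unknown.
Pearson concordance between siRNA #1 and #2 uses the product-moment
formula with a Fisher-z 95% CI and a t-test for the null of no
correlation.

## Temporal profiling

The composite morphology value is the unweighted sum of the aberrant,
mitotic and dead cell fractions per frame (sums of event fractions are
additive); folds divide by the control composite floored at 1e-3 to
avoid early-time division blow-ups. The DDR trace is mean 53BP1 foci per
interphase cell (binucleated cells count as interphase for this
purpose), control-normalized per frame; frames without interphase cells
carry the previous value forward with a warning.

Onset classification: t_mito = first frame with morphology fold ≥ 3.0,
t_ddr = first frame with DDR fold ≥ 1.5; neither crossing → "mild",
t_mito ≤ t_ddr (ties included) or t_ddr absent → "mitosis-first",
otherwise "ddr-first". The heat-map sort key is the 1.5× crossing frame
(the same criterion as the grouping threshold); rows are ordered mild →
mitosis-first → ddr-first, ascending sort key within groups, a
deterministic function of the classifications. Row colours anchor white
at each series' own mean, blue below (control = 1 included), red above;
the anchor value itself maps to white exactly.

Durations are the longest contiguous run of the relevant state times the
frame interval, after a median filter (window 3 frames) of the binary
indicator; the longest run is robust to spurious isolated flips that
survive smoothing, and on noiseless trajectories the estimators are
exact (integer frame counts × interval). The same smoothing is applied
to the mitotic-state indicator: without it, a single mid-run
misclassification would split an 8-h mitotic arrest and bias the
estimate by hours at a 5% frame noise rate. `mitotic_duration` warns
when fewer than 25 cells contribute. Replication asymmetry of
binucleated cells is the absolute difference of the two nuclei's first
S-pattern frames; cells with a never-replicating nucleus are excluded
and counted.

## Validation scale and scope

The test suite and the acceptance script run the real pipeline at desk
scale: the full default screen (47 × 2 × 3, ~200k cells) for
effect-recovery and concordance checks, 10-target screens at 700
cells/siRNA for null calibration, 50–200 cells per condition for
trajectory recovery, and 2 × 2000 cells for the AUC calibration —
sizes chosen so every check reruns in seconds to a few minutes while
keeping sampling error far below the asserted tolerances.

What passing these checks shows: the estimators recover what the
generator planted, the statistics match independent oracles (exhaustive
enumeration, grid search, bootstrap), and the null calibration is sound.
What it does not show: robustness to everything real screens add —
segmentation errors that correlate with phenotype, optical crosstalk
between channels, plate and edge effects, batch drift between
replicates, mixed or partial knockdown populations, and focus patterns
(pan-nuclear γ-H2AX, nuclear bodies vs. foci) richer than Gaussian
blobs. The synthetic images are single-channel 2-D fields; multi-channel
acquisition is represented as co-registered per-channel files.

## Known limitations

* The ensemble-combination and score-aggregation rules (both "mean") are
  one reasonable reading of an under-specified procedure; medians or
  ranked-vote combinations would be alternatives.
* Per-nucleus adaptive focus thresholds assume enough non-focus pixels
  per nucleus for a stable median/MAD; pan-nuclear signals push the
  threshold up and suppress focus calls (the nuclear-intensity features
  carry that signal instead).
* The trajectory model has no lineage structure: daughters are not
  tracked separately after division, and re-replication is represented
  only through extended/shifted S phases.
* `choose_k` uses the mean silhouette; for strongly unbalanced cluster
  sizes a gap statistic may behave better.
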