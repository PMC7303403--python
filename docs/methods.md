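# Methods

## Signal model and what the simulator emulates

The synthetic generator treats resting EEG as a semi-Markov sequence of
discrete topographic states. Each state k has a gamma dwell-time
distribution (mean `dwell_mean_ms[k]`, shape `dwell_shape`, default shape 2 —
right-skewed, as empirical microstate durations are); the next state is drawn
from a row-normalized nonnegative weight matrix with zero diagonal. The
explicit-dwell (semi-Markov) formulation was chosen over a first-order
Markov chain so that per-map duration and occurrence can be planted
independently, mirroring the way those two statistics are analyzed as
separate effects downstream.

The emitted frame at sample t is the active template map scaled by
`|sin(2π·f·t)|` with carrier f = 10 Hz, so the GFP trace shows discrete peaks
at ≈ 2f per second — the peak density the GFP-peak extraction step expects
from alpha-dominant resting EEG. White Gaussian sensor noise is added at a
configurable clean-signal-RMS / noise-RMS ratio (`snr`, default 8), then the
sum is average-referenced. Amplitudes are in arbitrary units: every
downstream statistic (labels, durations, GEV) is scale-invariant by
construction, so no µV calibration is needed or attempted.

Template maps are synthetic archetypes built from 2-D electrode coordinates:
A and B are mirror-image diagonal gradients (right-anterior/left-posterior
and its reflection), C an anterior–posterior gradient, D a fronto-central
focal pattern. They satisfy the structural constraints that matter for the
method (zero-mean unit-norm rows, exact A/B mirror symmetry, pairwise
|correlation| < 0.9); no published numeric map values exist to copy. One
geometric consequence: A + B is proportional to C (the lateral components
cancel), so hybrid-label behavior is exercised with A + C instead.

Cohorts add per-group dwell offsets (default: +15 ms on map A in the MCI and
AD groups, matching the direction of the published patient effect) and draw
covariates — age, sex, education, five medication flags, MMSE and CERAD
scores — from group-specific marginals emulating the published three-group
memory-clinic cohort (e.g. AD age 75.49 ± 7.65 years). Covariates are
independent of the EEG given group membership; this is the simplest design
that exercises covariate adjustment, and it deliberately does not model
age–EEG coupling. What passing tests show is therefore parameter recovery
under the stated generative model — clean, artifact-free, spatially white
noise — not robustness to real-world artifacts, volume-conduction noise
structure, or covariate confounding of the signal itself.

## Preprocessing

Filters are linear-phase Kaiser-window FIRs applied by centered convolution
(forward filtering with the group delay compensated), so segment timing — the
measurand — is not shifted. The order and beta follow from the standard
Kaiser design formulas given a maximum passband ripple of 0.001 and a
transition width of 25% of the lower band edge (the referenced design
heuristic); the realized order is logged per filter. A nominal "order two"
is not meaningful for a windowed FIR and is not used. Resampling to 200 Hz
is polyphase with built-in anti-aliasing. Epochs are half-open one-second
windows; a trailing partial epoch is dropped. Epochs are treated as
temporally discontinuous everywhere downstream (in source data they survive
artifact rejection, so adjacency is not guaranteed): GFP peaks, segment
runs, and transitions never span epoch boundaries.

The delta band is realized as a pure lowpass below 4 Hz (no 1 Hz high edge)
although conventionally named 1–4 Hz — the procedure, not the label, is
followed. Broadband analysis lowpasses at 40 Hz.

## Microstate segmentation

GFP is the spatial standard deviation of the average-referenced frame. Peak
extraction takes within-epoch local maxima with ≥ 10 ms spacing (the higher
peak wins conflicts), excludes outlier peaks, and keeps the first 1,000 in
temporal order. The exclusion rule is configurable because the natural
reading of "exceeds two standard deviations" is ambiguous: the default drops
peaks above mean + 2·SD of the detected peak GFPs; a literal `2sd` variant
(above 2·SD) is provided. With all-equal peak GFPs the SD is zero and
nothing is excluded.

Modified K-means: assignment maximizes the squared projection onto unit-norm
maps (equivalent to squared spatial correlation for average-referenced
frames — the standard polarity-invariant criterion); the update is the
dominant eigenvector of the cluster scatter. 50 restarts (initial maps drawn
uniformly without replacement from the topographies, child-seeded from one
master seed), up to 1,000 iterations, convergence when the relative change
in residual variance falls below 1e-6. Empty clusters are re-seeded from the
worst-fit topography so K stays fixed. Restart count is a free accuracy
parameter: on tiny instances (n ≤ 10, K = 2) where exhaustive enumeration is
feasible, ~100 restarts reliably attain the global optimum.

Cross-subject maps are obtained by pooling up to `peaks_per_subject`
topographies per subject (equalizing contributions of long and short
recordings) and clustering once. Cluster maps are matched to the canonical
templates by Hungarian assignment on absolute spatial correlation; a map
whose top-two template correlations differ by < 0.05 is reported with a
hybrid display label ("A/C"). For feature tables the maps are reordered into
template order and keyed by template letter, with hybrid names kept as
metadata, so feature columns stay stable across cohorts and bands.

Back-fitting labels every sample (not only peaks) with the map of maximal
squared correlation; ties break to the lowest map index. Smoothing
iteratively takes the shortest sub-30 ms run (leftmost on ties) and
reassigns its samples, sample by sample, to whichever flanking run's map
fits better, until no run is below threshold or an iteration cap (1,000 per
epoch) is hit; the exact reassignment rule of the original toolbox is not
published, so this rule is documented, deterministic and tested for
idempotence on already-smooth segmentations. A threshold of one sample or
less is a no-op.

Statistics pool runs over epochs. Edge runs (first/last of an epoch) are
included in duration averaging by default (configurable), since one-second
epochs truncate many runs and excluding them would discard most of the data.
GEV is computed over all samples of the back-fitted recording, including
samples whose peaks were excluded by the SD rule — the definition is about
explained variance of the whole signal, not of the clustering input. A map
that never occurs reports duration NaN, occurrence 0, coverage 0.

## Syntax

Observed transition percentages count run-to-run transitions within epochs.
Expected percentages use the product rule over ordered distinct pairs,
E(i→j) = 100·p_i·p_j / Σ_{k≠m} p_k·p_m, with p the relative segment
occurrence per map; the row-conditional alternative p_j/(1−p_i) is
deliberately not the default (the product rule is the convention in the
syntax literature this analysis follows). The chi-square distance skips
zero-expected entries. The permutation test statistic is the chi-square
distance between across-subject mean observed and mean expected vectors
(group-mean convention); the null swaps each subject's pair independently
with probability ½ (equivalent to random relabeling), 5,000 repetitions by
default, and the add-one convention avoids p = 0.

## Group statistics

Features are natural-log transformed; exact zeros (possible for transition
percentages in short recordings) are offset by half the smallest positive
observed value of that feature and flagged in the log. The ANCOVA is an OLS
fit of feature ~ group + covariates with a Type II F-test for the group
factor — appropriate for near-balanced designs with covariates entered
alongside. Zero-variance covariates are dropped by name; genuinely collinear
designs raise. Complete-case handling throughout. The FDR battery is exactly
12 map features + 12 transitions per band (asserted at runtime; the BH
implementation accepts a declared battery size m ≥ the number of supplied
p-values). GEV is compared with the same ANCOVA but outside the 24-feature
family, mirroring its separate reporting. Post hoc pairwise GLM contrasts
run only for features surviving FDR. Partial correlation residualizes both
variables on the covariates and tests the residual Pearson r against a
t-distribution with n − 2 − k degrees of freedom.

## Classification

Feature blocks are 24 columns per band (120 for broadband + four narrow
bands, counting broadband as one of five). By default z-scoring and PCA
(retaining 99% variance) are refit inside every LOO training fold — the
statistically correct protocol; `paper_mode` fits them once on the full
matrix for comparison with descriptions that do not state fold-internal
fitting. PCA is skipped for LDA and SVM. Multinomial/logistic regression is
near-unpenalized maximum likelihood (L2 with C = 1e6) so perfectly separable
folds remain finite; the SVM uses an RBF kernel with a small inner 3-fold
grid over C ∈ {0.1, 1, 10, 100} and gamma ∈ {scale, 0.01, 0.1}. Specificity
is the correct-classification rate of the HC class. A fold that fails to
fit is counted as a misclassification and flagged.

## Pipeline and problem sizes

`run_pipeline` derives one child seed per stochastic stage from the master
seed in a fixed order, so runs are bit-reproducible; the manifest records
the config, child seeds and a hash of the feature table. The
parameter-recovery test battery uses deliberately modest problem sizes
chosen as the smallest at which the planted effects are statistically
unambiguous: 50 cohorts of 3 × 30 subjects with 20 s recordings and 10
clustering restarts for dwell recovery (the +15 ms planted effect is a ~6 SE
group difference there), 12 subjects × 60 s for map recovery, and 200
replicates for permutation-test calibration. The acceptance script runs the
full five-band pipeline on 3 × 20 subjects × 60 s.

## Known limitations

- No biophysical forward model: noise is spatially white after average
  referencing, whereas real EEG noise is volume-conducted and correlated.
- No artifact simulation (blinks, ECG, line noise transients) and no
  artifact rejection; the corresponding manual preprocessing steps of
  clinical practice (visual epoch rejection, ICA, channel interpolation)
  are out of scope.
- Covariates influence nothing but themselves; the ANCOVA's covariate
  adjustment is exercised, but confounding of the EEG by age is not modeled.
- Individual-subject map segmentation, source localization and higher-order
  syntax are out of scope.
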