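# Methods

This note documents the models, conventions and numerical choices behind
`patchseq`, and what the synthetic-data tests do and do not establish about
real recordings.

## Electrophysiological feature extraction

**Stimulus model.** Cells are probed with 600-ms square current pulses
(default −200 … +1380 pA in 20-pA steps, onset at 0.1 s, 1.3-s inter-sweep
interval). All features are computed from the raw voltage traces; time is in
seconds, voltage in mV, current in pA, R_input in MΩ, τ and AP width in ms.

**Spike detection.** The detection criterion follows the Allen-SDK
convention: an AP is a voltage peak above −20 mV (prominence ≥ 10 mV) whose
preceding depolarization exceeds 20 V/s; the threshold point is where dV/dt
first crosses that rate before the peak, the trough is the minimum between
the peak and the next threshold (or within 100 ms), and the ADP is the
height of the first local maximum (prominence ≥ 0.5 mV) after the trough.
These thresholds are declared defaults, configurable through
`SpikeDetectionParams`; on a flat or rectangular trough the trough index is
taken at the centre of the minimal plateau so the 5-ms averaging window is
unbiased.

**Passive features.** V_rest is the mean voltage over the 100 ms before
onset, the steady state the mean over the last 100 ms of the pulse, R_input
their difference divided by the injected current, and τ comes from a
nonlinear least-squares fit of A·exp(−t/τ) + C between onset and the first
local minimum of a 5-ms-smoothed trace; all three are medians over every
hyperpolarizing sweep, with repeats included as separate observations.

**Rheobase.** RANSAC regression (fixed random_state, so deterministic) of
spike count on current over the five lowest spiking currents; the
x-intercept is accepted if it lies between the highest silent and the
lowest spiking current, otherwise the lowest spiking current is used.

**Derived statistics.** Adaptation indices are medians over the five lowest
qualifying currents (≥ 3 spikes for ISI indices, ≥ 2 for amplitude
indices). The highest firing trace is the first (lowest-current,
lowest-repeat) depolarizing sweep attaining the maximum in-window count
after excluding any sweep firing in the 100 ms before or 200 ms after the
window; SFA needs ≥ 5 APs. The sag/rebound zeroing rules (sag < 4 mV; no
return to rest within 300 ms; no out-of-window firing) return exact
floating-point zeros. Burst detection classifies each ISI as detour
(non-zero ADP, or a ≥ 0.5 mV drawdown between trough and next threshold),
pauselike (longer than a configurable 3× the trace median ISI) or direct; a
burst starts at a detour→direct transition and runs through the consecutive
direct ISIs. Undefined features propagate as NaN, never 0, except where a
zeroing rule applies.

**Analysis vector.** Of the 29 features, 17 enter statistical analyses
(dropping mostly-zero, redundant, heavily skewed or sometimes-undefined
features); AP CV, ISI CV, ISI adaptation and latency are natural-log
transformed. Cells with any missing retained feature are flagged incomplete.

## Transcriptomic mapping

Expression of read-based data is log₂(exon/len_e + intron/(len_i + 10⁻⁶) + 1)
with lengths in kb; UMI reference counts pass through as log₂(x + 1) without
length normalization. Variable genes are those with a high near-zero
fraction τ at a given mean non-zero log₂ expression µ: genes with counts
≥ c_min (32 read-based, 0 UMI) in fewer than 10 cells are excluded, then a
binary search over the offset b selects exactly the target number of genes
with τ > exp(−1.5 µ + b) + 0.002. Genes whose counts never exceed c_min
have undefined µ and are treated as ineligible. Ties at identical (µ, τ)
move together; when the exact target is unattainable the nearest achievable
count is returned with a warning.

Mapping round 1 assigns each query cell to the combined reference atlas by
Pearson correlation with per-t-type centroids over the 3,000 most variable
genes, and applies three exclusion rules (best correlation < 0.4;
would-be non-neural assignment; margin < 0.02 over the best correlation in
either other transcriptomic group — computed on the same gene set). Round 2
maps each passing cell, restricted to its group's t-types, to every
reference atlas over that atlas/group's 500 most variable genes; genes
absent from the query data are dropped and counted. Confidence is the
fraction of 100 gene bootstraps (resampled with replacement at full set
size) in which the cell maps to each type; per-cell random streams are
spawned independently from the master seed so the procedure parallelizes
safely. Consensus is the unweighted mean across atlases; argmax ties break
to the first type in atlas order. Manually curated exclusions enter as a
user-supplied cell list, not as code.

## Morphology

SWC reconstructions are validated (single root, connected, acyclic),
soma-centred in x (slice width) and y (slice depth) and pia-aligned in z so
z = 0 at the pia and z = cortical thickness at the white matter; nodes below
the white matter are kept with a warning. Branch paths are resampled to
≤ 1 µm spacing; the y coordinate is smoothed per branch with a
Savitzky–Golay filter (order 3, window 21), with branches shorter than the
window mirror-padded. The z-profile bins the resampled point cloud's
normalized depths into 20 equal bins on [0, 1] (half-open bins, last
closed; depths clipped to the range) and normalizes to unit mass; mass is
point-count weighted, which after 1-µm resampling is equivalent to
arc-length weighting up to discretization. Morphometrics are computed per
compartment from a pluggable catalogue (total length, branch/tip counts,
branch order, path and Euclidean reach, x/z extents and their log-ratio,
branch-length moments, tortuosity, bifurcation angles, somatic features;
the apical dendrite — the dendritic stem with the longest total path — for
excitatory cells; an axon–dendrite z-profile overlap for inhibitory cells).
Excitatory cells get no axonal features, no cell gets y-direction features,
and positive-valued features with CV < 0.25 are filtered per class. Layers
are assigned from normalized soma depth with boundaries 0.07 / 0.29 / 0.73;
a depth exactly on a boundary goes to the deeper layer. Tissue shrinkage is
not corrected.

## Sparse reduced-rank regression

The model is Y ≈ X W Vᵀ (Y: n × 17 standardized ephys features; X: n × 1000
standardized log₂-CPM of the most variable genes) with orthonormal V and an
elastic-net penalty on the rows of W, normalized per observation, so that
"selected genes" are the nonzero rows (α = 1 is pure lasso). Fitting
alternates a multi-task elastic-net regression of YV on X with the
orthogonal Procrustes update V ← UΣVᵀ-polar factor of Yᵀ(XW), stopping at a
relative loss change < 10⁻⁶ or 100 iterations; V is initialized from the
top-r right singular vectors of the ridge prediction of Y, with seeded
jitter only when the spectrum is degenerate. At λ = 0 the W-step is ordinary
least squares and the algorithm converges to the closed-form reduced-rank
solution (verified to 10⁻⁶ against an SVD oracle). Cross-validation uses
10 shuffled folds over a (rank, α, λ) grid and reports test R² computed
against ‖Y_test‖² (columns standardized on the full set), the mean selected
gene count, and per-component test correlations corr(XW_k, YV_k). Biplot
tables give the correlation of every gene and feature with each latent
score; the display mask keeps variables whose correlation-line length over
the two plotted dimensions exceeds 0.4. An unpenalized refit on the
selected support is available but off by default.

## Representations, embeddings, classification

The ephys representation standardizes the 17 features, takes all PCs and
divides by sd(PC1); the retained-PC count is a parameter because the
combined representation uses a 16-dimensional ephys block (default 17 for
ephys-only analyses, 16 in the combined stack). The morphological
representation is built per class (excitatory: dendritic z-profiles;
inhibitory: axonal): 20 morphometric PCs scaled by sd(PC1) plus z-profile
PCs 2–5 scaled by sd(PC2) (PC1 tracks soma depth and is discarded),
assembled block-diagonally into 48 dimensions with +0.25 added to the
excitatory block; the combined representation appends the ephys block
multiplied by √2 (one scaled PC set vs. two on the morphology side),
giving 64 columns. PCA signs are fixed (largest-magnitude loading made
positive) for reproducibility. t-SNE is consumed from scikit-learn under a
pinned contract — perplexity 30 (100 recommended for large excitatory
subsets), early exaggeration 4, learning rate n/12 (floored at sklearn's
minimum of 10), scaled-PCA initialization (PC coordinates rescaled to
sd 10⁻⁴) — and is deterministic given the seed and initialization.
New cells are positioned on a reference embedding at the coordinate-wise
median of their ten nearest reference neighbours under Pearson correlation
distance in the high-dimensional space (no optimizer run). Family
classification is leave-one-out kNN (k = 10, Euclidean); majority ties go
to the single nearest neighbour's family, and confusion matrices are
row-normalized to percent. An 80%-coverage Gaussian ellipse utility
(mean + χ²₂-quantile contour) supports the positioning checks.

## Variability statistics

The normalized total variance of a t-type is the population-normalized
(1/|T|, 1/n) within-type variance summed over dimensions, divided by the
same sum for the whole data set: exactly 0 for identical member cells,
exactly 1 when the type is the full data set. The k-means baseline clusters
the cells of the K qualifying t-types into K clusters (scikit-learn
defaults, seeded) and reports the min–max band of per-cluster normalized
variances. The Leiden analysis builds a k = 10 kNN graph, tunes the
RBConfiguration resolution by geometric binary search to a target cluster
count ± 1, subsamples each qualifying t-type (≥ 10 cells) to 10 cells, and
records the Shannon entropy (bits) of its cluster-ID distribution over 100
seeded repetitions. Pairwise within-family t-type distances use
1 − Pearson r between centroid log expressions as the transcriptomic
distance (the conversion from "correlation as distance" is made explicit;
only relative structure matters for the correlation analyses), Euclidean
distance between mean feature vectors for electrophysiology, and absolute
mean-depth differences for soma depth; types need ≥ 5 assigned cells.
Pooled distance correlations are computed on raw distances across families
(per-family values are also available; no within-family standardization is
applied before pooling).

## Synthetic data: what it emulates, and what it does not

The trace generator composes a passive response (exponential charging, an
alpha-function sag scaled linearly with current, an exponential post-offset
decay plus an alpha-function rebound) with an analytic AP template — linear
upstroke at the stated dV/dt, a flat cap sized to make the half-width
exact, an exponential downstroke whose initial slope is the stated
downstroke rate, AHP trough, optional ADP bump — inserted at planted spike
times, plus Gaussian noise. On sweeps that fire, the sub-threshold baseline
is stylized to a fast-charging plateau placed between the AHP trough and
the ADP peak so every planted shape parameter remains the local extremum
the extractor measures. Sag-trough and rebound ground truths are evaluated
on the analytic noiseless trace because the alpha-function excursions
interact with charging. This is not a conductance-based simulation: spike
timing does not emerge from the stimulus, AP shapes do not vary within a
train, and τ estimates on sag cells inherit the single-exponential fit's
bias. Passing tests therefore establish that the extraction rules are
implemented correctly and are robust at realistic noise (≈ 0.2 mV), not
that they are robust to biological waveform diversity.

The expression generator draws negative-binomial counts (gamma–Poisson,
dispersion 0.3 by default, log-normal library sizes, sd 0.25) around
planted per-type centroids (log₂ scale, ~30 marker genes elevated by 4 log₂
units per type) and splits query counts into exon/intron parts binomially
with per-gene exon fractions; at query noise 0 the counts are the rounded
centroid means exactly. It does not model batch effects, contamination,
dropout beyond the NB law, or realistic gene-length/expression
correlations. The morphology generator realizes planted 20-bin depth
profiles with a vertical trunk plus horizontal branchlets (per-bin lengths
proportional to the planted mass; trunk contamination is kept small by
making branchlet length dominate), or grows random branching trees for
morphometric tests; it makes no claim to realistic arbor statistics.

## Problem sizes and numerical choices in the test suite

The suite runs entirely on synthetic data at desk scale: sweep sets of
10–31 currents at 20 kHz, atlases of 4–10 types × 30–50 cells × 300–2,000
genes, 100-draw bootstraps, RRR at n = 500 × p = 1,000 (20 seeds for
support recovery at snr 2, exact-support rate ≥ 90%), 100 random
morphologies for the binning oracle, and a 36-cell end-to-end pipeline run.
Tolerances follow the quantity: planted ratios and counts are checked
near-exactly (10⁻³–10⁻⁶), waveform-derived quantities to the sample period
(AP width) or a few percent (τ 5%, UDR 8% — discrete sampling of the
exponential downstroke biases the measured rate by ≈ dt/τ_down), zeroing
rules and variance anchors exactly (0.0, or 10⁻¹²). Determinism is asserted
bit-for-bit for generators, bootstraps, Leiden repetitions and whole
pipeline reruns.

## Known limitations

* The morphometric catalogue is a representative, pluggable set, not an
  authoritative 75-feature list; apical and overlap features are minimal.
* Round-2 consensus assumes the reference atlases share a t-type namespace
  per group (true for the synthetic atlases; real atlases need a mapping).
* The burst detector implements the declared detour/direct/pauselike rules,
  a simplification of the full Allen-SDK burst logic.
* The t-SNE optimizer is scikit-learn's; embeddings are reproducible given
  a seed but not identical to other implementations.
* CPM normalization uses a fixed 10⁶ scale rather than the median
  sequencing depth; both are linear rescalings absorbed by standardization.
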