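# Methods

This note documents the models, numerical choices and known limits of
the `escnn` package: an ensemble sleep stager that couples unsupervised
subject clustering with per-subgroup sequential convolutional networks.

## Problem setting

Overnight single-channel EEG is scored in 30 s epochs into the five
AASM stages (Wake, N1, N2, N3, REM). A single classifier trained on a
whole population tends to fail on individuals whose spectral makeup is
atypical; the ensemble addresses this by (1) grouping subjects with
similar spectral fingerprints, (2) training one network per subgroup,
and (3) staging a new subject with a distance-weighted mixture of the
subgroup models.

## Preprocessing

Signals pass an optional mains notch (50 or 60 Hz, second-order IIR,
Q = 30), then a 4th-order Butterworth band-pass 0.3–35 Hz. Both are
applied forward–backward (zero phase) so filtering cannot displace
stage boundaries. The whole night is then z-normalized (mean 0, SD 1);
normalization is per recording, not per epoch, so relative amplitude
differences between stages survive. When the notch frequency sits at
or above Nyquist (e.g. 50 Hz on a 100 Hz recording) the notch is
skipped with a warning — the 35 Hz low-pass already removes mains
energy there. Hypnograms in R&K notation are remapped to AASM (S3 and
S4 merge into N3); movement/unknown epochs are dropped before any
downstream step, so the epoch count P everywhere refers to scored
epochs.

## Subject fingerprints and clustering

Per epoch we estimate a Welch spectral density (4 s Hann windows, 50 %
overlap, density scaling) and reduce it to 13 features: absolute power
and mean density in delta (0.5–4 Hz), theta (4–8), alpha (8–13), beta
(13–30) and gamma (30–35 Hz), plus three fast/slow ratios
(alpha/delta, beta/theta, (alpha+beta)/(delta+theta), denominator
floor 1e−12). Band powers integrate the density with trapezoids, with
band edges interpolated onto the frequency grid.

**Subject aggregation.** The subject fingerprint is *not* the plain
mean of per-epoch features. A night's mean feature vector is dominated
by how much of the night each stage occupied (the stage mix), which
varies strongly between subjects and swamps genuine spectral traits —
empirically, clustering plain means recovers planted subgroups
erratically (adjusted Rand index anywhere from 0 to 1 across seeds).
Instead, epochs are z-scored, k-means-clustered into at most five
unsupervised *spectral states*, and the fingerprint is the equal-weight
average of the per-state mean feature vectors. This removes the stage
mix without using stage labels, so it applies identically to an
unscored test subject; with it, subgroup recovery on synthetic cohorts
is exact (ARI 1.0, 10/10 seeds). The plain mean remains available via
`aggregate="mean"`.

Cohort fingerprints are z-scored column-wise (scale floored at 1e−12
for constant columns) and reduced by PCA (eigendecomposition of the
covariance matrix; default 3 components). The retention of information
of U components is the fraction of total eigenvalue mass they carry.
Subjects are then partitioned by Euclidean k-means (10 seeded
restarts); the subgroup count is chosen by the mean silhouette
coefficient over k ∈ {2, 3, 4, 5}, ties to the smaller k. A partition
into all singletons scores silhouette 0 by the convention that a
singleton contributes 0. For a query subject, the distance to subgroup
C is the mean Euclidean distance to C's member points (a
distance-to-centroid mode exists behind a flag).

## Sequence codec

A night of P epochs is encoded into P − L + 1 overlapping windows of
L = 10 consecutive epochs (stride one epoch); window i, position j
holds absolute epoch i + j (0-based). After classification, each
(window, position) probability row is L1-normalized (a zero row becomes
uniform, with a warning), rows referring to the same absolute epoch are
summed, and the stage is the per-epoch argmax, ties toward the lower
stage index (Wake first). Boundary epochs are covered by fewer windows
(coverage min(m+1, L, P−L+1, P−m)) and are kept, not discarded. With a
softmax classifier the L1 normalization is a no-op; it keeps the
decoder correct for any nonnegative scorer.

## Sequential CNN

The classifier is a dual-scale 2-D CNN over the (epoch, sample) plane
of a window, implemented in NumPy with hand-written backpropagation:

* **Small-scale branch** — kernel width fs/2 samples (0.5 s), stride
  fs/16, tuned to fast activity (spindles, beta).
* **Large-scale branch** — kernel width 4·fs (4 s), stride fs/2, tuned
  to slow waves.
* Both first-layer kernels have **height 2** on the epoch axis (the
  window is padded with one zero epoch at the end), so position j mixes
  epochs j and j+1; a height-1 ablation is available and is verified to
  see epoch j only.
* Each branch continues with ReLU, max-pool 8, a width-8 convolution to
  2·n_filters channels, max-pool 4, a second width-8 convolution, a
  squeeze-and-excitation gate (global average pool over width → FC to
  C/r → ReLU → FC to C → sigmoid → channel-wise multiply; r = 16), and
  global average pooling. Pool and kernel widths clamp to the available
  width so the same recipe holds at any sampling rate.
* Branch features are concatenated (large scale first) and a linear
  head shared across the L positions emits 5 logits per position. The
  head is initialized with small weights (SD 0.01) so an untrained
  network starts near the uniform distribution.

Training minimizes softmax cross-entropy averaged over all L positions
of each window (Adam, lr 2e−3, batch 32, max 30 epochs — 25 in the
compact configs used by the test protocol). Optional inverse-frequency
class weights exist but default off.

**Augmentation.** Each training batch receives a random circular time
shift within the epoch and a random sign flip. Both operations leave
band powers unchanged, so they do not alter the class-relevant content,
but they prevent the network from memorizing individual noise
realizations; on 2-subject training sets this is the difference between
~0.85 and ~0.99 held-out accuracy.

**Early stopping.** One window in ten — taken *interleaved* across the
night, not as a contiguous tail — is held out, and the monitored score
is the macro recall over stages present in that slice. Both choices are
deliberate: a contiguous tail can contain no N1 at all, letting
training stop while N1 is still collapsed into N2 (observed), and plain
accuracy hides the collapse of a rare stage. Training stops after 5
non-improving epochs (not before epoch 8 in the compact config, since
slow phases early in training are common) or immediately when the
balanced score reaches 0.998.

## Ensemble fusion

Subgroup model i receives weight w_i = (1/D_i²)/Σ_j(1/D_j²), where D_i
is the query subject's mean distance to subgroup i's members in PCA
space. Weights sum to one, never increase with distance, and are
invariant to rescaling all distances. A distance below 1e−9 takes all
the weight (split uniformly among exact ties). Each model's decoded
per-epoch scores are mixed with these weights before the final argmax,
so the fusion is a convex combination of consolidated score profiles.

In leave-one-subject-out evaluation, PCA, clustering and all models are
refitted for every fold with the test subject excluded, so no test
information leaks into the subgroup structure. A fold whose clustering
degenerates falls back to a pooled model with a warning.

## Synthetic cohorts

The generator produces what the pipeline needs to be testable without
clinical data: per-stage band-power signatures (Wake alpha/beta-
dominant, N1 theta, N2 theta plus two 1 s amplitude-modulated 13 Hz
spindle bursts per epoch, N3 delta, REM mixed theta/beta, each with a
broadband noise floor; budgets sum to 1 and epochs have unit variance
within 10 %), a diagonal-heavy Markov stage chain started in Wake
(bouts of a few epochs), and ≥2 spectral subgroups created by
multiplying the alpha/beta weights of one group by 1.5 and
renormalizing — shifting the fast/slow-wave axis the clusterer uses.
Band noise is filtered once per night and rescaled per epoch, keeping
the signal continuous across epoch boundaries. Everything derives from
one cohort seed via spawned generators.

What the generator does *not* emulate: within-subgroup inter-subject
variability, artifacts, K-complexes, age effects, non-stationarity
within a stage, and — importantly — spectral patterns whose stage label
differs between subgroups. Passing tests therefore show the pipeline's
mechanics are correct under clean, separable conditions; they do not
certify clinical performance.

## Protocol sizes

The test protocol uses 6-subject cohorts (3 per subgroup), 200 epochs
per subject at 100 Hz, and a compact network (8 first-layer filters per
branch), chosen so each subgroup specialist trains on at least two
subjects and converges; smaller cohorts leave single-subject
specialists that miss rare stages entirely. The ensemble-vs-pooled
comparison holds out one rotating subject per cohort across five
seeded cohorts.

## Known limitations

* The ensemble's advantage over a single pooled model depends on
  population heterogeneity that actively harms a shared model. The
  synthetic subgroups differ by a uniform band-power shift that never
  makes one subgroup's stage resemble a *different* stage of the other
  subgroup, so a pooled model fits both subgroups without interference
  and benefits from twice the training data; at this scale the pooled
  ablation is a near-tie or slightly ahead. See the package README for
  how this is reported.
* The NumPy network is CPU-bound and sized for desk-scale experiments,
  not for full clinical datasets.
* EDF writing is a minimal fixture writer (16-bit, one data channel,
  optional annotation track), not a general exporter.
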