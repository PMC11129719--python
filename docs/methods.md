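# Methods

`woodsim` reimplements, as a tested pipeline on synthetic data, a
two-experiment workflow for characterizing perceived material appearance:
(1) a 2AFC match-to-sample triplet task whose choices are explained by a
sparse non-negative perceptual embedding, and (2) a direct attribute-rating
task on a 0–100 visual-analog scale. The two resulting representations are
compared through similarity matrices, cross-modal regressions, classical
MDS with Procrustes alignment, hierarchical clustering, and linear
prediction from simple texture image statistics.

## Triplet design

A trial shows a target item and two match items; the observer picks the
more similar match. The design covers a fraction (default 10%) of all
`n · C(n−1, 2)` unique (target, match-pair) combinations under two balance
constraints: per-item target counts differ by at most one, and within each
target's trials every other item appears as a match partner as evenly as
possible. The sampler assigns per-target quotas, builds the partner
multiset (counts differing by at most one), and pairs partners by random
matching with seeded edge-swap repair until all pairs are distinct; targets
whose quota equals the full pair count are enumerated exhaustively. At the
canonical scale (30 items, 10% coverage) this yields 1218 triplets with
target quotas 40/41 and partner counts 2–3.

Participant sets replicate the design four times (two repetitions with
match sides swapped). Unswapped repetitions are dealt into sets of 87
trials (no set contains the same triplet twice); each set gets exactly one
swapped mirror copy, giving 28 + 28 sets and 4872 trials. This mirroring
scheme requires `reps = 2 · swapped_reps` (or no swapping); other
combinations are rejected as inconsistent. Three catch trials (the target
duplicated as one match) sit at fixed positions — 40, 65 and 84 of the 90
presented trials at the canonical set size, scaled proportionally for
smaller sets — and three flagged practice trials precede the sequence.
Catch and practice rows are excluded from every analysis.

## Decision model and synthetic ground truth

Simulated observers choose by a softmax on embedding dot products:
`p(choose a) = exp(s_ta/τ)/(exp(s_ta/τ) + exp(s_tb/τ))` with
`s_ij = x_i · x_j` and temperature τ. This memoryless noise model is an
assumption for testing; the behavioural studies it emulates do not specify
an internal noise process. One consequence is that swapped repetitions
disagree with their originals far more often than human observers do
(humans are strongly self-consistent within a session), so the
swap-consistency statistic is reported but not calibrated.

The planted embedding has a per-column zero fraction equal to the requested
sparsity; non-zero entries are Exponential(1) draws. Rows that would be
entirely zero receive one planted entry (a featureless item is not a
meaningful stimulus), and rows are then normalized to unit length. The
normalization is deliberate: attribute ratings induce a *difference-based*
similarity (below), while the embedding induces a *dot-product* similarity;
with wildly varying item norms these two geometries decouple and no
analysis could relate the two tasks, contrary to the phenomenon being
modelled. On the unit sphere the Gram matrix is a monotone transform of
distance and the two tasks probe one shared configuration, which is the
premise of the cross-method analyses.

The default study conditions are frozen as: 30 items, 1218 triplets × 4
repetitions, 5 planted dimensions, sparsity 0.5, 45 raters, rating noise
SD 10 (0–100 scale units). Sparsity 0.5 (rather than the 0.8 that the
fitted-embedding sparsity of real data might suggest) keeps the fraction of
exactly-tied triplets negligible; at sparsity 0.8 with 5 dimensions most
items load on a single dimension, ~70% of triplets are exact ties, and no
temperature reaches the 0.82 repetition agreement of the emulated study.

τ is calibrated by bisection against the closed-form expected repetition
agreement: for reps = 4, a triplet with choice probability p contributes
`p⁴+q⁴ + 0.75·4(p³q+pq³) + 0.5·6p²q²`. The default target is 0.82. At the
calibrated temperature the expected unanimous-triplet fraction is ≈ 0.46,
bracketing the behavioural ~47%. The same closed form supplies the
generator's Bayes accuracy `E[max(p, q)]`, the benchmark for held-out
model accuracy.

Ratings are noisy linear read-outs: item i's true score on attribute a is
`x_i · w_a` (signed standard-normal attribute loadings), affinely rescaled
per attribute so items span [0, 100]; each rater adds independent
`N(0, σ²)` noise and the result is clipped to [0, 100] (a slider cannot
leave its scale; clipping, not resampling).

Texture movies are Gaussian noise shaped in the Fourier domain by a radial
band envelope (amplitude `√(w_b/n_b)` per band, so band energy fractions
equal the requested weights) times a von-Mises envelope on the doubled
orientation angle whose concentration grows monotonically with the
directionality-strength knob. Frames share one complex spectrum and evolve
by per-frequency random phase drift (smooth change, emulating slow sample
rotation); each frame is renormalized to the requested mean and SD exactly.

## Variational embedding (fit)

Each weight of the n × d loading matrix gets a mean-field Gaussian
posterior `q(w) = N(μ, σ²)` (σ through a softplus); non-negativity enters
by rectifying sampled weights inside the likelihood. The prior is a
zero-mean spike-and-slab mixture (Gaussian or Laplace components). The
objective per step is the single-sample Monte-Carlo estimate of

    mean NLL(batch) + (1/N_trials) · Σ_w [log q(w) − log p(w)],

with hand-derived reparameterization gradients and Adam (β = 0.9/0.999).
The KL against the mixture has no closed form, so the complexity term
shares the likelihood's weight sample. Divergent (non-finite) losses raise
an error naming the offending hyperparameters.

Extraction takes the point estimate max(0, μ) and keeps a dimension iff at
least `min_items` = 2 items satisfy `P(w > 0) = Φ(μ/σ) ≥ 1 − α` (α = 0.05);
retained columns are sorted by decreasing loading sum. Accuracy counts the
higher-probability side, crediting exact ties 0.5. Train/test splits are
stratified by target item.

Defaults: the shipped prior is Laplace spike-and-slab with scales
0.125/1.0 and spike weight 0.6; the training schedule for the recovery
analyses is 400 epochs at learning rate 0.002, batch 128, `d_max` = n.
All prior values and the learning rate come from the standard grid (the
`default_grid()` of 162 configurations); the longer schedule was chosen
once from a multi-seed recovery study on synthetic data because the KL
term keeps merging redundant split dimensions well after the loss has
flattened — at 200 epochs the retained dimensionality occasionally
overshoots by 3–7 columns that longer training folds back into their
parents. With these settings, study-scale recovery gives retained
dimensionality within ±1 of the planted 5, truth–fit similarity
correlations ≈ 0.97, and seed-to-seed stability ≈ 0.99.

The grid includes spike/slab combinations where the "spike" is wider than
the "slab" (e.g. 0.75/0.2); these are permitted with a warning rather than
rejected, since the standard grid enumerates them.

## Cross-validated dimensionality

A plain maximum-likelihood non-negative embedding (no prior, point
weights, rectified likelihood) is fit at each candidate d with k-fold CV
over trials; the estimate is the smallest d whose mean test accuracy is
within one standard error of the maximum. The rectified factorization has
poor local optima at small d, so each fit runs once from a spectral
initialization — rectified top-d eigenvectors of the symmetrized empirical
win-rate matrix (how often each match was chosen when shown for each
target) — plus random restarts, keeping the best training likelihood.
Without the spectral start, low-d fits stall far below the Bayes rate and
the procedure systematically overestimates d.

## Similarity matrices and comparisons

- Embedding → similarity: default is the Gram form `S_ij = x_i · x_j`
  (diagonal = squared norms). A `choice_prob` mode averages the
  target-matching probability of preferring the pair (i, j) over every
  third item, over both target roles. Similarities are used unnormalized.
- Ratings → similarity: per attribute `S_ij = 100 − |r_i − r_j|` on
  rater-averaged ratings (diagonal exactly 100); the joint matrix is the
  entrywise root mean square across attributes.
- Matrices are compared by Pearson correlation over the upper triangle,
  excluding the diagonal unless explicitly included.
- Matrix-on-matrices regression vectorizes upper triangles (diagonal kept
  by default, anchoring the scale), fits OLS with intercept, and reports
  r/r² plus per-predictor leave-one-out drops in r. All regressions are
  descriptive; no multiple-testing correction is applied, and an intercept
  is always included (a no-intercept toggle exists as a sensitivity
  option).

## Geometry

Similarity matrices are bridged to distances by
`d_ij = √(S_ii + S_jj − 2S_ij)` (Gram sources) or `d_ij = 100 − S_ij`
(rating sources). MDS is classical (Torgerson): double-centering, top-m
eigenpairs, coordinates scaled by √eigenvalue; negative eigenvalues are
truncated but reported. Deterministic spectral output motivates this over
stress-based variants. Procrustes alignment optimizes translation,
rotation/reflection, and isotropic scale; disparity is the normalized
residual in [0, 1]. Clustering is agglomerative with weighted-average
(WPGMA) linkage — the reading of "weighted average L2-norm" adopted here —
cut at k = 3 by default (the three main visual modes the analyses group
samples into).

## Image statistics

Ten named per-movie statistics, each averaged over frames: min, max, mean,
population variance, skewness `m₃/m₂^{3/2}`, non-excess kurtosis `m₄/m₂²`
(3 for a Gaussian; constant frames return 0 for both shape statistics by
convention); directionality as the magnitude-weighted resultant of gradient
orientations on the doubled angle (`|Σ m e^{2iθ}|/Σ m`, 0 isotropic, 1
perfectly oriented); and the fractions of non-DC spectral power in three
equal-width radial annuli over (0, Nyquist] (supra-Nyquist grid corners are
excluded from the normalization so fractions sum to 1). Color frames are
collapsed by Rec. 709 luminance weights at ingestion. The source analyses
advertise eleven statistics but enumerate these ten; the unenumerated
eleventh cannot be reconstructed and is not invented here. The
directionality formula and band edges are isolated configuration points
(log-spaced bands can be substituted), since the originals are not fully
specified.

## Reliability and consistency

The repetition-agreement distribution classifies each triplet's four
responses (recoded to chosen items, so swapped repetitions group with
their originals) as unanimous / 3-of-4 / even; the noise ceiling is the
mean agreement (unanimous 1, majority 0.75, split 0.5) — a pure function
of the counts. Swap consistency pairs each unswapped trial with its
mirrored copy by position and counts differing chosen items. Rating
reliability is ICC(C,k): two-way items × raters ANOVA, consistency
definition, average-of-k-raters form `(MS_items − MS_error)/MS_items`; the
single-measures form is exposed but not default. Summary SDs are
population-form for consistency with the image-statistic moments.

## Problem sizes and what the tests show

The default test suite and the acceptance script run the full canonical
scale (1218 × 4 trials, two variational fits, a 7-candidate CV
dimensionality estimate); smaller worlds (6–15 items) back the unit tests.
Passing tests show the pipeline recovers structure *its generator planted
under its own decision model*; they cannot show that human similarity
judgments obey a softmax on dot products, that real rating noise is
Gaussian and independent, or that real wood appearance is five-dimensional.
Known limitations: the synthetic movies are grayscale filtered noise (no
photorealistic wood structure, color, or specularity), the swap statistic
is uncalibrated (above), and the CV dimensionality estimate inherits the
non-convexity of the rectified factorization despite the spectral start.
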