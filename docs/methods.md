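# Methods

## The personalization model

`harlearn` treats personalization as incremental ensemble growth.  An
ensemble `E = {m_1, …, m_M}` of weak base classifiers is built in phases:

1. **User-independent phase.** Three base models are trained on pooled data
   from every subject except the target wearer.  Each is trained on a
   bootstrap sample (with replacement) of the pooled windows at the pooled
   size S, with its own feature subset chosen by sequential forward
   selection (SFS).  The ensemble after this phase is the *static
   user-independent baseline*.
2. **Personalization rounds.** The wearer's stream arrives in chunks.  Each
   chunk is labeled by the configured policy (below), then three personal
   base models are trained from it and appended.  With two chunks the final
   ensemble holds 3 user-independent + 6 personal members and has been
   evaluated after every addition — nine evaluation points.

Members are combined by equal-weight majority voting realised at the
posterior level: the ensemble posterior is the arithmetic mean of member
posteriors, each embedded into the sorted union of member class lists
(unknown classes contribute 0) and renormalised.  Equal weights are used
because under non- and semi-supervised labeling no trustworthy accuracy
estimate exists for a new member, so accuracy-proportional weighting is not
available; the same weighting is kept in the supervised case for
comparability.  The hard label is the argmax (ties to the lexicographically
smallest class, for determinism) and the prediction confidence is the
maximum of the mean posterior.  Posterior-level combination is essential:
the labeling policies threshold a *graded* confidence, which hard votes
would not provide.

## Labeling policies

For an incoming chunk of n windows, in stream order:

* **non-supervised**: assigned labels are the ensemble predictions; no user
  involvement (risk: self-training on wrong labels causes concept drift).
* **supervised**: every window is labeled by the user (simulated by a
  ground-truth oracle keyed on (subject, window index)).
* **semi-supervised**: windows whose confidence is strictly below a
  threshold *th* are queried from the user.  *th* = 0.95 while the ensemble
  contains only user-independent members and 0.75 once any personal member
  exists — user-independent ensembles produce overconfident posteriors, so a
  single threshold would unbalance the query load between rounds.  Each
  queried window's true label is then propagated to in-chunk neighbours
  within ±2 windows (activities are long-bout, so neighbours almost surely
  share the class).  Propagation never overwrites a queried window and never
  crosses the chunk boundary; when a window lies within range of several
  queries, the nearest wins, with distance ties going to the earlier query.
  Propagated windows count as "replaced" labels but not as user inputs.

Two exact limits tie the policies together and are enforced by tests: with
thresholds 0/0 the semi-supervised policy reproduces the non-supervised
labeling bit-for-bit, and with thresholds 1.01/1.01 (confidence ≤ 1, strict
comparison) the supervised labeling.

## Base classifiers

All three kinds expose `predict_posterior` (rows sum to 1):

* **LDA** — Gaussian discriminant with pooled within-class covariance,
  empirical class priors, and a relative diagonal ridge of 1e−6 (bootstrap
  resamples can make a selected feature nearly constant).  Implemented
  directly (and cross-checked against scikit-learn's LDA in the tests)
  because the SFS wrapper needs its closed form: candidate evaluation reuses
  per-fold class means and lazily built scatter columns, so scoring all
  one-feature extensions costs O(n·p) rather than O(n·p²) per step.
* **QDA** — per-class covariances shrunk toward their own diagonal,
  Σ_c ← (1−λ)Σ_c + λ·diag(Σ_c) with λ = 0.1, plus the same ridge.  This
  target preserves per-feature scales, unlike shrinking toward a scaled
  identity, and keeps small personal chunks from producing singular
  covariances.
* **CART** — a depth-6 decision tree with minimum leaf size 3; leaf
  posteriors are Laplace-smoothed class counts (n_c + 1)/(n_leaf + K), so
  probabilities are never exactly 0/1 — raw leaf proportions would make the
  confidence thresholds degenerate.

## Chunk-to-model training

Personal chunks are small, so each base model is built as: noise injection →
bootstrap → SFS → fit.

* **Noise injection**: R = 2 noisy copies of every window are appended; copy
  features are the original plus N(0, α·sd_f) with α = 0.1 and sd_f the
  feature's SD within the chunk.  Injection operates in feature space —
  the training flow labels and augments *extracted* windows, and raw-signal
  injection would force re-featurization.
* **Bootstrap**: personal models draw |chunk| rows (the chunk's original
  size, before augmentation) from the augmented pool; the alternative
  (augmented-pool size) is available as `bootstrap_size_rule="pool_size"`.
  User-independent models draw pool-size samples from the raw pool, with no
  injection.
* **SFS**: greedy forward selection maximising mean stratified 3-fold CV
  balanced accuracy of the classifier kind being trained; stop at
  `sfs_max_features` (default 10) or when the gain is ≤ 0; score ties go to
  the smallest feature index.  Balanced accuracy is used as the criterion to
  match the evaluation metric.
* Every model gets an independent RNG stream keyed by (seed, subject,
  round, replicate), so the three models per chunk differ (bootstap and
  fold draws) yet the whole experiment is bit-reproducible, and the
  user-independent phase is identical across policies by construction.

## Windowing and features

Recordings are segmented into 4.2 s windows sliding by 1.4 s (sample counts
round-half-up, so a 1/3 s slide at 50 Hz is 17 samples); a window's label is
the per-sample mode (ties to first occurrence), and windows below a purity
floor (default 1.0) are dropped.  Intervals are 0-based half-open
throughout.

Channels are expanded per (x, y, z) triad with the Euclidean magnitude and
the three pairwise magnitudes — 7 signals per triad — and each signal yields
30 features: std, min, max, median; percentiles 10/25/75/90 (linear
interpolation); tail sums and square sums (below the low percentiles, above
the high ones — one tail per percentile, giving symmetric summaries);
percentile level-crossing counts (sign changes of x − P_q, zeros carrying
the previous sign); and 10 equal contiguous band sums of the
non-negative-frequency FFT magnitudes excluding the DC term.  A 3-channel
recording gives 210 features per window.  No standardisation is applied at
this stage, keeping feature semantics stable for SFS.

## Evaluation protocol

Leave-one-subject-out: each subject in turn is the personalization/test
wearer; everyone else forms the user-independent pool.  The wearer's each
contiguous activity block is cut into three equal-length raw-signal thirds
*before* windowing (trailing remainder dropped), assigned in temporal order
to chunk 1, chunk 2 and the test part; windows never straddle a cut, so the
parts share no raw samples and the test part cannot leak into training.
Metrics: balanced accuracy (mean per-class recall over classes present in
the truth), error rate = 1 − balanced accuracy, macro false-negative rate =
mean per-class (1 − recall) — identically the error rate, an identity the
tests enforce.

A control experiment replaces the personal models of rounds 1–2 with fresh
user-independent models; its error trace should stay flat, showing that the
improvement comes from personalization and not from ensemble size.

## The synthetic cohort

The generator emulates multi-subject, multi-class inertial streams: per
class, a three-axis sinusoid amplitude·sin(2π f t + φ_axis) + offset with
axis phases (0, 2π/3, 4π/3); per (subject, class), a gain ~ N(1, 0.15), a
per-axis offset ~ N(0, 0.3) and a frequency factor ~ N(1, 0.05) drawn once;
plus iid N(0, 0.2) noise per sample.  Defaults: 8 subjects, 5 classes,
50 Hz, 120 s per class — one contiguous block per class per subject, equal
data per activity.  Each subject's randomness is keyed by (seed, subject
index), so cohorts are reproducible regardless of iteration order.

The five default class signatures span three base frequencies (1, 1, 2, 2,
3 Hz) with paired classes sharing a frequency and differing in amplitude
and offsets.  The pairing is deliberate: frequency-band features alone
cannot separate all classes, so the subject-level gain/offset perturbations
(comparable in size to the between-class offset gaps) make classes
confusable *across* subjects while remaining cleanly separable *within* one
subject.  That is the premise personalization exploits, and a generator
invariant verified by test: over ten seeds, a classifier trained on the
other subjects scores strictly lower mean balanced accuracy on a new
subject than one trained on that subject's own data.

What the generator does **not** model: realistic biomechanics, gravity
orientation, sensor drift, transitional movements between activities, or
label noise in the "user" responses.  Passing tests therefore demonstrate
the mechanics and the qualitative behaviour of the method (personalization
helps, the semi-supervised policy approaches supervised accuracy at a
fraction of the labeling cost, dual thresholds balance query load), not the
absolute accuracy figures achievable on real recordings.

## Numerical and design choices

* Sample counts from seconds use round-half-up; the three-way split uses
  floor(L/3) with the remainder dropped.
* Confidence querying is strict (<), so th = 0 queries nothing.
* Argmax ties everywhere resolve to the first (lexicographically smallest)
  class; SFS ties to the smallest feature index; propagation ties to the
  earlier query — all for determinism.
* A degenerate labeled chunk (a single class after labeling) skips its
  round with a warning rather than aborting the subject.
* Window purity default is 1.0 because synthetic blocks are contiguous;
  real data with transitions should lower it.
* Experiment-scale runs (the acceptance script and the heavy tests) cap SFS
  at 5 features per base model and evaluate 10 cohort seeds × 8 held-out
  subjects; unit tests use 2–4 subject cohorts with 30 s blocks.

## Known limitations

* Ensemble size grows without bound (no pruning); with many rounds,
  prediction cost grows linearly.
* Equal weighting cannot down-weight a base model trained on badly labeled
  data; the non-supervised policy's drift is therefore permanent.
* The oracle is error-free; real user labels are not.
* Propagation radius is fixed (±2) rather than adaptive to bout length.
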