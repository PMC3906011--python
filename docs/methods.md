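# Methods

This note records the models, estimators and design decisions behind
`scpoim`, including the places where the design was genuinely open and the
package had to commit to a convention.

## Signal model and SCP extraction

A dialog is a pair of synchronized binary sample streams at a common rate
(default 100 Hz; the rate is a free parameter of the data, not of the
method).  Chain identity is fixed throughout: chain 1 is the moderator,
chain 2 the participant.  Segments use 0-based, half-open `[start, end)`
sample coordinates; durations are reported in seconds.

SCP extraction cuts both streams at the union of their change points plus
the two ends.  The operation is deterministic, idempotent, and exact: the
segment durations sum to the total signal duration in samples, and the
internal boundary count equals the size of the change-point union (tested
against a brute-force oracle).  A constant dyad yields a single segment.

Audio binarization (frame RMS energy against a fixed threshold, with runs
shorter than a minimum duration merged shortest-first into their
neighbors) is deliberately plain plumbing: any voice-activity detector can
be substituted upstream, and everything downstream consumes only the
binary streams.

## Duration quantization

Speech and silence durations (pooled over both chains — whether to pool
was an open choice; pooling is the default because the segment duration is
shared by construction, and a per-chain option would double the parameter
count of the quantizer without changing its role) are clustered with 1-D
Gaussian mixtures, k = 3 components per type, fitted by EM through
scikit-learn's `GaussianMixture`: k-means initialization, variance floor
1e-6 s², tolerance 1e-6 on the per-sample log-likelihood, at most 500
iterations.  The fit is stepped one EM iteration at a time so the
monotone log-likelihood trace is available as a diagnostic.  Components
are sorted by mean; decision boundaries between adjacent components are
the points of equal weighted density (root-finding between the means, with
the midpoint as a logged fallback when one component dominates the whole
interval).  Assignment is by maximum responsibility; an exact tie resolves
to the shorter-duration component, making labeling deterministic.

Clustering operates on raw durations in seconds by default; a log-space
option exists behind a flag.  Raw-scale clustering has a real failure
mode: when the long-duration scale is heavy relative to the separations,
k-means initialization merges the short and medium clumps and splits the
long tail.  The synthetic generator's duration scales were chosen so that
the raw-scale EM resolves them reliably (see below); on real data with
overlapping duration scales the log-space option is the safer choice.

The state alphabet is 2k: speech labels 1..k, silence labels k+1..2k, so
label type always matches the chain's binary state.  k is configurable
(k = 2 gives the 4-state alphabet, k = 1 the bare speech/silence chain);
the 6-state default follows the classification-accuracy argument for
three scales per type.

## The observed influence model

For C first-order chains with N states the joint transition probability
factorizes as a convex combination of pairwise transition probabilities,
with influence weights θ_{·c} on the simplex for each target chain.  The
package implements the observed-state simplification throughout: states
are directly observed labels, never hidden.

**Estimation.**  Transition matrices and initial distributions come from
state counting; rows never observed become the uniform distribution (and
are counted in the fit report) — no pseudo-counts are added anywhere else,
so observed probabilities stay exact.  π is the chain's marginal state
frequency over all R segments: a single dialog offers only one first
state, and the marginal is the only stable counting estimator.  The
influence weights are fitted per target chain by projected gradient ascent
on the log-likelihood: the per-column objective Σ_r log(θ·m_r) is concave
on the simplex, so ascent with Euclidean simplex projection, a fixed
initial step of 0.1 halved on non-improvement, tolerance 1e-8 on the
log-likelihood gain and at most 1000 accepted steps converges to the
maximizer.  Only improving steps are accepted, so the likelihood trace is
non-decreasing by construction.  A likelihood of exactly zero is reported
as −∞, a value rather than an error, so comparisons over chain orderings
stay total.

**What counting estimates.**  Pairwise counting converges to the pairwise
conditionals of the joint process, P(S_t^c | S_{t-1}^{c'}).  These
coincide with the model's own matrices only for *self-consistent*
parameter settings; under generic off-diagonal influence the counted
intra-chain matrix converges to a θ-mixture of the intra matrix and the
induced cross-conditional, so the count/ascent procedure is a
quasi-likelihood method, not a consistent estimator of an arbitrary
generating OIM.  Parameter-recovery checks therefore use a
self-consistent construction (`recovery_influence_model`): identity
influence, inter-chain matrices equal to the stationary one-step marginals
they induce, stationary initial distributions.  Under that model, R =
10000 simulated segments recover every transition cell within 0.05 and
the influence weights within 0.1 (measured ≈ 0.03 and ≈ 0.005).  This is
a statement about the estimator, not a defect: on real data the fitted
parameters are descriptive statistics of the dialog, and identical
processing across groups keeps them comparable.

**Orderings.**  A dyad can be presented to a fitted model in two chain
orders; `best_ordering_score` evaluates both and returns the higher
likelihood, ties keeping the original order.

## Generative score space

Each dialog is embedded as the concatenation of its fitted OIM parameters
— the parameter-extractor map with the identity operator and Euclidean
metric; Fisher-score and TOP-kernel variants are out of scope, as is any
score-space normalization.  The canonical layout (1-based positions, N =
6, C = 2): transition matrices in the order A^(11), A^(12), A^(21),
A^(22), each flattened column-major (within a matrix the linear index is
`(to_state − 1)·N + from_state`), then the influence matrix column-major,
then π¹ and π².  No flattening convention is uniquely "right"; this one
was adopted because it is the simple convention under which the two
independently meaningful anchor positions decode correctly — position 17
is the moderator's intra-chain medium-silence → long-speech probability
and position 80 the participant-medium-speech → moderator-medium-speech
inter-chain probability — and it is frozen by unit tests on every position
via the decoder.

## Feature selection and stability

Three policies, each deterministic with ties resolved to the lowest
feature index:

* **Forward selection** greedily adds the feature that most improves the
  wrapper criterion — the inner leave-one-out mean recall of the 3-NN
  classifier on the provided samples — stopping at T features or when no
  addition strictly improves.
* **Branch and bound** maximizes a monotone separability criterion,
  trace((S_W + λI)⁻¹ S_B) with ridge λ = 1e-6 applied to the full
  within-class scatter so every principal submatrix inherits positive
  definiteness and the criterion is exactly monotone under feature
  addition (the property the bound requires; a wrapper criterion is not
  monotone and cannot drive this search).  The backward search with
  pruning returns the same subset as exhaustive enumeration, verified
  against full enumeration on 10-feature instances.  Exact search is
  exponential in the worst case, so above 12 features the candidate pool
  is first reduced to the 12 individually best features under the same
  criterion and the exact search runs inside the pool — the classical
  remedy for this algorithm's scaling, stated here as part of the design.
* **mRMR** discretizes each feature into three equal-frequency bins and
  greedily maximizes relevance (mutual information with the class label)
  minus mean redundancy (mutual information with the already-selected
  features).  A constant feature has zero information with everything and
  can never precede an informative one.

T defaults to 10.  The **stability ranking** runs every policy once per
leave-one-out fold (the held-out sample is never seen by the policy),
pools all instances — n folds × 3 policies, so 54 instances for an
18-dialog cohort — and scores each feature by its appearance frequency;
ordering is by descending frequency with index ties ascending.

## Classification and evaluation

* **3-NN**, Euclidean, with fully specified tie handling: distance ties
  resolve to the lower training-sample index, vote ties to the class of
  the nearest neighbor.  Implemented directly (a stable argsort makes both
  rules exact) and tested against a brute-force scan.
* **Linear SVM** via scikit-learn's SVC.  The regularization constant is
  fixed but configurable; the default is C = 100 because the score-space
  features are unnormalized probabilities whose between-class gaps are of
  order 0.1–0.3: with C = 1 the margin penalty dominates the hinge loss at
  that scale, the fitted weight vector stays near zero and leave-one-out
  collapses to anti-majority voting (mean recall ≈ 0.11 observed on the
  demo cohort).  C = 100 makes the hinge term dominant without affecting
  hard-margin solutions on separable data.
* The scalar accuracy everywhere is the **unweighted mean of the two class
  recalls**; per-class precision and recall are reported alongside, and
  every report stores its per-fold predictions so the metrics can be
  re-derived (a self-audit the tests perform).
* **Leave-one-out** never trains on the held-out sample.  The default
  evaluation is *fold-nested*: each fold re-runs the entire stability
  ranking on its n−1 training samples and classifies the held-out sample
  on that fold's top-k features.  Ranking once on all samples and then
  cross-validating — the protocol a small-sample study would typically
  report next to its feature table — is available as the `pooled` mode,
  but it inherits selection bias: with 160 candidate features and 18
  samples, features selected on the full sample classify pure-noise
  cohorts well above chance, so only the nested protocol is calibrated
  (null cohorts score 0.44 ± 0.12 per replicate here).  The same
  leakage reasoning puts the duration quantizer behind a per-fold refit in
  the strict pipeline mode; the simulation experiments fit it once on the
  pooled durations because both synthetic classes share their duration
  models by construction, so the quantizer carries no class information.
* **Separation** (resubstitution) trains and evaluates on the same
  samples and is reported strictly separately from LOO; for K-NN the query
  is excluded from its own neighbor search, otherwise the score would be
  trivially perfect.  Decision-boundary grids classify every node of an
  r × r grid spanning the 2-D data range ± 10%.

## The synthetic cohort generator

The generator is the package's stand-in for unavailable clinical
recordings and defines the study conditions: two classes of 9 dialogs
each, 150 SCPs per dialog (≈ 7–8 minutes at 100 Hz), sampled from
ground-truth OIMs and rendered to binary streams.

* **Dynamics.**  The base model prefers type alternation (speech →
  silence and back), which is conversationally realistic and keeps rare
  the draws in which neither chain changes type.  Influence is
  asymmetric: the moderator is mostly self-driven (θ₁₁ = 0.7) while the
  participant is driven by the moderator (θ₁₂ = 0.6).
* **Global-transition constraint.**  An SCP boundary requires a
  speech/silence change in at least one chain, so a drawn joint state in
  which both chains keep their *type* is resampled (up to 100 times), then
  merged with its predecessor and logged; after 50 consecutive merges
  generation stops early with a truncation flag (degenerate absorbing
  dynamics).  Label-identical draws are a special case of type-identical
  ones.  This is what makes the render → extract round trip exact on
  boundaries and states.
* **Durations.**  One duration per SCP, shared by both chains (boundaries
  are global by definition), drawn from the log-normal model of chain 1's
  label: speech medians 0.4 / 2.5 / 8.0 s, silence 0.3 / 2.0 / 7.0 s,
  log-sd 0.2.  Scales a factor 5–6 apart with this spread are reliably
  resolved by the raw-scale EM quantizer (label agreement ≈ 0.99);
  a consequence of the shared duration is that only chain 1's
  short/medium/long dynamics survive rendering exactly — the participant
  chain keeps its speech/silence states but inherits the moderator's
  duration scales, which is an intrinsic limit of binary rendering under
  globally shared boundaries.
* **Planted effect.**  The case class moves 0.3 of mass within the
  moderator's medium-silence row from the short-speech to the long-speech
  target, so exactly two ground-truth transition cells (score positions 5
  and 17) differ.  In the *estimated* score space the difference is not
  confined to those two cells: the occupancy shift propagates into π and
  into conditional cells of every matrix, which is faithful
  quasi-likelihood behavior, not leakage.  The planted cells still
  dominate the stability ranking in most replicates.
* **Seeds.**  One cohort seed; per-dialog generators are spawned from a
  `numpy.random.SeedSequence` in class-then-dialog order, so cohorts are
  byte-reproducible from the seed alone.
* **Not emulated:** overlapping speech, acoustic or prosodic realism,
  voice-activity-detection errors, duration scales that genuinely overlap,
  and any within-class heterogeneity beyond OIM sampling noise.  Passing
  tests therefore demonstrate that the pipeline recovers structure that is
  present in the generating law under clean segmentation; they do not
  certify performance on real recordings.

## Problem sizes and runtime

The shipped experiments use the sizes the analyses report: 9 + 9 dialogs
of 150 segments, 20 replicates per condition in the power study, R =
10000 for parameter recovery, R = 20000 for frequency-convergence checks,
1000 random dyads for the boundary oracle.  The full test suite runs in
about 4 minutes and the acceptance script in about 3 minutes on one CPU.

## Known limitations

* The influence-weight estimator is quasi-likelihood (see above); fitted
  inter-chain matrices describe pairwise conditionals, not causal
  couplings.
* Branch and bound above 12 features is exact only within the
  criterion-prefiltered pool.
* The pipeline targets dyads; the types and the OIM code are generic in C,
  but orderings, the CLI-level drivers and the score-space decoding assume
  C = 2.
* With 18 samples every accuracy estimate has wide sampling bands; the
  replicate study, not any single cohort, is the meaningful summary.
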