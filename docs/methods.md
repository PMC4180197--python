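# Methods

## Problem setting and model

The pipeline asks whether a small subset of clinical variables suffices to
recover known disease subtypes by unsupervised clustering. Its object is a
mixed-type table: `n` cases × `p` features, each feature declared
`numeric`, `categorical`, or `asymmetric_binary` in a schema sidecar, plus
a class column holding the subtype labels. Labels are stored outside the
feature table; by construction no distance or clustering step can touch
them. Filters are supervised and do see the labels, as does the purity
evaluation — the clustering itself is the only unsupervised stage, which
is exactly the design being stress-tested.

## Supervised discretization

The entropy-based filters need discrete features. Numeric columns are cut
by recursive binary splitting on class entropy with the MDL acceptance
rule (Fayyad–Irani): a cut at threshold T on a segment of n values is
accepted iff

    Gain(T) > [log2(n−1) + log2(3^k − 2) − k·H(S) + k1·H(S1) + k2·H(S2)] / n

with k, k1, k2 the number of classes present in the segment and its two
halves. Candidate thresholds are midpoints between adjacent distinct
values; the minimizer of the weighted child entropy is tested (ties take
the lowest threshold). Features with no accepted cut collapse to a single
interval and score 0 on every ranker — this is the main mechanism by which
noise numerics drop to the bottom of rankings. Discretization is applied
once per dataset, before any filter. Entropy-based scores are invariant to
monotone rescaling after discretization, so no normalization is applied.

Missing cells: a row missing the feature under evaluation is dropped
pairwise for that feature's probability tables. Inside the consistency
criterion a missing cell is instead a pattern symbol of its own, because
patterns must match exactly. All logarithms are base 2.

## The five filters

* **Information gain** and **symmetrical uncertainty** are computed from
  the feature-value × class joint table; zero-probability cells contribute
  0. SU divides 2·MI by the two marginal entropies and returns 0 by
  convention when both vanish (constant feature and constant class).
* **Chi-squared** is the contingency statistic Σ(O−E)²/E over the same
  table. The textbook two-valued form generalizes to multi-valued features
  and four classes by summing over all cells; for a binary feature and
  binary class the two coincide (a property the tests check numerically).
* **CFS** scores a subset S of size k by `M_S = k·r̄_cf / √(k + k(k−1)·r̄_ff)`
  where both correlation kinds are SU values (the standard choice for this
  criterion). Search is best-first forward from the empty set, terminating
  after 5 consecutive expansions that fail to improve the best merit.
  Identical duplicate features give the pair exactly the singleton's merit
  (2r/√4 = r), so strict-improvement search keeps one copy — redundancy is
  never rewarded, though it is only actively penalized when r̄_ff > r̄_cf
  structure allows.
* **Consistency** seeks the smallest subset whose inconsistency rate —
  Σ_patterns (count − majority-class count), divided by the number of
  instances — does not exceed the full feature set's. The denominator
  ("instances" vs "distinct patterns") is switchable; instances is the
  default. Search is exhaustive in order of increasing size for p ≤ 15
  (ties: lower rate, then lexicographic feature order) and best-first
  forward beyond that.

Rankings sort scores descending with ties kept in original column order,
so all runs are deterministic.

## Gower distances

Similarity of two rows averages per-feature terms over the comparable
features: numeric terms `1 − |x_i − x_j|/G_h` (G_h = observed range over
the whole dataset, ignoring missing), categorical match/mismatch, and
asymmetric-binary features contributing 1 for joint presence while joint
absences leave the denominator entirely. A feature missing in either row
is skipped for that pair (Gower's original weighting). A pair with no
comparable feature is an error rather than a silent guess.

Two transforms are offered: the default `d = √(1−S)` (the form the
similarity-to-distance relation is usually printed in, and the one that
makes d metric when S is a Gower similarity) and `1−S` (what most software
implementations return, including R's `cluster::daisy`, against which the
implementation is cross-checked to 1e-10). Since PAM sums raw distances,
the two can select different medoids; every report records which was used.
Constant numeric features (zero range) contribute similarity 1 to every
pair and trigger a warning suggesting they be dropped. Feature weights are
uniform.

For the ranked-subset sweep the per-feature numerator and denominator
stacks are precomputed once (p × n × n arrays) and accumulated
incrementally in rank order, so a full sweep over sizes 2..p costs one
Gower pass plus one PAM run per size.

## PAM

Classical Kaufman–Rousseeuw BUILD + SWAP on the precomputed distance
matrix. BUILD seeds the medoid minimizing total distance, then repeatedly
the object with the largest cost decrease; SWAP applies the best
(medoid, non-medoid) exchange until none decreases the cost
`E = Σ_clusters Σ_members dist(o, m)`. Every tie breaks toward the lowest
object index and medoids are kept sorted, so runs are bit-reproducible; a
seeded random initialization is available for robustness checks. The
iteration cap is 10·n (warned, never silently truncated in practice).
PAM is a local search: on tiny instances it reaches the exhaustive-
enumeration optimum in the high 90s of percent (and provably always for
k = 1), matching the behavior of the R reference implementation.

## Purity

`purity = (1/N) Σ_clusters max_class |cluster ∩ class|`, accumulated in
exact integer arithmetic (a `Fraction`) and converted to float only for
display. It is invariant to relabeling on either side, bounded below by
the largest class share, and reaches 1 trivially at k = N — the reason
the k-sweep is reported but conclusions are anchored at the known k.
Majority-class *names* in reports break ties alphabetically; the value
itself is tie-free.

## Synthetic cohort generator

Defaults emulate the motivating cohort: 129 cases in four subtypes sized
20/37/59/13 (the real-world imbalance, with the smallest group n = 13, is
kept deliberately), 156 features = 128 numeric + 28 categorical, grouped
121 nerve-conduction / 4 CSF / 31 clinical. Planted structure:

* 7 informative numerics: class-conditional Gaussians with unit
  within-class SD and means at `Δ · perm(0..3)` (a fresh random class
  order per feature), default Δ = 2.0 — adjacent classes two SDs apart,
  strong but not trivially separable through 149 masking features;
* 9 redundant features: an informative source plus Gaussian noise scaled
  for correlation ≈ 0.9;
* 112 noise numerics from one shared normal per feature (random location
  and scale, no class information);
* 28 categoricals, 3 informative: four symbols, the class-specific symbol
  drawn with probability 0.6, others uniform; noise categoricals have 2–5
  uniform symbols;
* optional missing-completely-at-random masking (default rate 0).

One `numpy` Generator seeded from the config drives every draw. The
generator reproduces the statistical *shape* the analysis assumes —
informative/redundant/noise partition, mixed types, class imbalance — not
real nerve-conduction physiology: features are independent given class,
noise is Gaussian, and categorical informativeness is a symmetric tilt.
Passing recovery tests therefore shows the pipeline recovers planted
low-dimensional structure under realistic dimensions and imbalance; it
does not certify performance on correlated clinical measurements.

## Experimental protocols

* **Baseline**: Gower → PAM(k) → purity on all features.
* **Ranker sweep**: for each size s = 2..p (distances need ≥ 2 features),
  cluster the top-s features; the best subset is the *smallest* s
  attaining the maximum purity (parsimony tie-break).
* **Method comparison**: rankers report their sweep optimum; CFS and
  consistency report their selected subset's purity. A single-feature
  selection is flagged `NC` rather than erroring.
* **Pairwise**: rows restricted to each unordered subtype pair, features
  re-selected per pair, k = 2.
* **k-sweep** (default k ∈ {2,3,4,5,6,10,20}): ranker subsets re-selected
  per k (their objective depends on k); CFS/consistency subsets depend
  only on the labels and are selected once.
* **Parameter recovery** (`recovery_replicate`): one full study per fresh
  generator draw, scoring informative-feature retrieval (all 7 in the
  ranker's top 12), selected-vs-baseline purity at k = 4, per-pair wins at
  k = 2, and the ascending purity trend from k = 2 to k = 20. The
  acceptance script aggregates 20 replicates; at the default effect size
  the study's qualitative conclusions reproduce in essentially every
  replicate, and with Δ = 0 the planted features are indistinguishable
  from noise (the null check lives in the test suite).

## Numerical choices and limitations

* Tolerances: 1e-12 for strict-improvement decisions in searches, 1e-9
  for cost comparisons in PAM tests; purity is exact.
* Problem sizes are the cohort's own (n = 129, p = 156); the whole
  20-replicate recovery study runs in about two minutes on one CPU thanks
  to the incremental Gower sweep.
* The Gower per-feature stacks hold two p × n × n arrays (~40 MB at
  default size) — fine for cohorts of hundreds, not for thousands.
* No imputation: missing values are handled by pairwise deletion inside
  each stage. No internal validity indices (silhouette, Dunn, etc.) —
  evaluation is purity-only, by design, since the subtype labels exist.
* CFS best-first is a heuristic; it provably matches exhaustive search on
  the small-p oracle tests, but has no global guarantee at p = 156.
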