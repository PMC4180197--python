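# gbscluster

Filter feature selection and k-medoids clustering for identifying subtypes
of Guillain-Barré syndrome (GBS) in mixed-type clinical data.

GBS is an acute autoimmune neuropathy with four main subtypes — AIDP, AMAN,
AMSAN, and Miller-Fisher (MF) — that differ in severity, treatment, and
prognosis. A typical cohort is described by a mix of numeric measurements
(nerve conduction amplitudes/latencies, cerebrospinal-fluid values) and
categorical clinical findings, most of which are irrelevant or redundant
for telling the subtypes apart. This package implements a complete,
deterministic pipeline for asking: *how few variables suffice to recover
the subtypes by unsupervised clustering?*

The pipeline, stage by stage:

1. **Supervised discretization.** Numeric features are cut by recursive
   entropy minimization with the MDL stopping rule (Fayyad–Irani), so the
   information-theoretic filters apply uniformly to all features.
2. **Filter feature selection** (five classical criteria):
   - *information gain* `IG(f,c) = Σ_f Σ_c P(f,c) log₂ P(f,c)/(P(f)P(c))`
   - *symmetrical uncertainty* `U(A,B) = 2·MI(A,B)/(H(A)+H(B))`
   - *chi-squared* `X² = Σ_cells (O−E)²/E` over the feature × class table
   - *CFS merit* `M_S = k·r̄_cf / √(k + k(k−1)·r̄_ff)` with best-first search
   - *consistency*: the smallest subset whose inconsistency rate (fraction
     of instances outside their pattern's majority class) does not exceed
     the full feature set's.
3. **Gower distances** for mixed rows:
   `S_ij = [Σ_h (1−|x_ih−x_jh|/G_h) + a + α] / [p₁ + (p₂−d) + p₃]`, with
   joint absences on asymmetric binary features dropped from the
   denominator and `d_ij = √(1−S_ij)` by default.
4. **PAM (partitioning around medoids)** — deterministic BUILD + SWAP —
   minimizing the configuration cost `E = Σ_i Σ_{o∈C_i} dist(o, m_i)`.
5. **Purity** against the true subtypes:
   `purity(C,W) = (1/N) Σ_k max_j |c_k ∩ w_j|`, computed in exact integer
   arithmetic.

Rankers (IG, SU, chi²) are evaluated by clustering the top-*s* features for
every *s* from 2 to *p* and keeping the smallest *s* with maximal purity;
subset selectors (CFS, consistency) are evaluated on the subset they
return. Class labels are visible to the filters (they are supervised) and
to the purity computation, never to the clustering.

Because real GBS cohorts of this kind are not publicly available, the
package ships a planted-cluster generator (`gbscluster.synthetic`) that
emulates one: 129 cases split 20/37/59/13 across the four subtypes, 156
features (128 numeric, 28 categorical) of which 7 numeric features carry
the subtype signal, 9 are noisy copies of informative ones, and the rest
are noise. Ground truth is returned alongside, so recovery can be scored.

## Worked example

```
python analysis/01_simulate.py --seed 1      # write the synthetic cohort
python analysis/02_baseline.py               # all-features baseline
python analysis/03_feature_selection.py      # the five filters at k=4
python analysis/04_pairwise.py               # subtype pairs at k=2
python analysis/05_ksweep.py                 # purity across k
python analysis/06_recovery.py               # 20-replicate recovery study
```

On the seed-1 cohort the baseline clustering of all 156 features reaches
purity 0.6977 — a third of cases land in the wrong cluster because noise
features dominate the distances. The filter comparison prints:

```
ig             4 features  purity 1.0000
su             5 features  purity 1.0000
cfs           14 features  purity 1.0000
consistency    3 features  purity 1.0000
chi2           3 features  purity 1.0000
all_features 156 features  purity 0.6977
```

Every method finds a handful of (planted) informative features whose
4-cluster solution matches the subtypes exactly, while the all-features
baseline does not — the motivating point of filtering before clustering.
The pairwise experiment shows each of the six subtype pairs separating
perfectly at k = 2 with two to six selected features (cells marked `NC (1)`
are single-feature selections, for which a distance matrix — hence a
purity — cannot be computed), and the k-sweep shows purity inflating
mechanically with k (0.74 at k = 2 up to 1.0 by k = 4–20 for every method),
which is why comparisons are anchored at the known k = 4.

The same pipeline is exposed as a CLI (`gbscluster simulate | filter |
distance | cluster | purity | sweep | compare | pairwise | ksweep`) over
CSV files with a plain-text schema sidecar declaring each column numeric,
categorical, or asymmetric-binary.

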