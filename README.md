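# nomas

**NoMAS** (Network of Mutations Associated with Survival) finds connected
subnetworks of a gene–gene interaction network whose somatic mutations are
associated with patient survival, directly — rather than testing genes one
at a time and intersecting the hits afterwards.

Cancer cohorts measure somatic mutations for thousands of genes together
with (censored) survival times. Driver mutations act through pathways, so
different patients carry mutations in different members of the same gene
module; no single gene need reach significance even when the module as a
whole separates short- from long-surviving patients. NoMAS searches a
genome-scale interaction network for the connected k-gene set S whose
"mutated in at least one gene of S" patient split maximizes the log-rank
statistic.

## The score and the algorithm

Order the m samples by increasing survival time. With censoring indicators
c (c_j = 1 for an observed event) and population indicator x (x_j = 1 if
sample j carries a mutation in S), the log-rank numerator is

    V(x, c) = Σ_j c_j · ( x_j − (m₁ − Σ_{i<j} x_i) / (m − j + 1) ),

where m₁ = Σ x_j. Because c is fixed for a cohort, σ(x,c) factorizes as
√(m₁(m−m₁)) · f(c), and NoMAS optimizes

    w(S) = V(x^S) / √(m₁ (m − m₁)),

reporting also the normalized statistic w(S)/f(c), which is asymptotically
N(0,1) under the null. Maximizing w finds sets associated with *reduced*
survival; maximizing −w finds association with *increased* survival.
Finding the best connected k-set is NP-hard, and w is not set additive
(two genes mutated in the same patient count once), so classical
color-coding guarantees do not transfer. NoMAS still uses color-coding:
each of L iterations colors every vertex uniformly at random with one of k
colors and fills a (2^k−1) × |V| table whose entry (T, u) holds one
connected *colorful* subnetwork with colorset T anchored at u, built by
merging smaller entries across edges. Under a planted-subnetwork model of
cancer mutations the search recovers the optimum with the classical
color-coding probability, and it does so in practice on simulated data.

The package also provides:

- exhaustive enumeration of connected k-sets (the oracle), three greedy
  seed-and-extend baselines (G1/G2/G3), and an additive-score comparator
  (color-coding on a(S) = Σ −log₁₀ p(gene));
- significance procedures: a rank-matched permutation test (gene rows
  reassigned at random) and a survival-stratified train/holdout scheme
  with Monte-Carlo log-rank p-values;
- a planted-subnetwork simulator so the whole pipeline is testable without
  external downloads.

## Worked example

Simulate a cohort (100 genes, 120 samples, a planted 4-gene module mutated
with probability 0.9 in the shortest-surviving quartile) and search it:

```
nomas simulate --n 100 --avg-degree 6 --k 4 --p 0.9 --m 120 --seed 7 \
      --out-prefix demo/
nomas run --network demo/network.tsv --mutations demo/mutations.tsv \
      --clinical demo/clinical.tsv --k 4 --iterations 64 \
      --direction reduced --top 3 --seed 42 --out demo/results.json
```

`demo/truth.json` records the planted module: `g0066 g0069 g0089 g0094`.
The top three subnetworks found (from `demo/results.json`):

| rank | genes                       | w      | normalized | iteration |
|------|-----------------------------|--------|------------|-----------|
| 1    | g0049 g0062 g0069 g0094     | 0.2782 | 3.6961     | 14        |
| 2    | g0066 g0069 g0089 g0094     | 0.2775 | 3.6862     | 9         |
| 3    | g0062 g0066 g0069 g0094     | 0.2753 | 3.6573     | 9         |

The planted module is recovered at rank 2; at this modest sample size a
neighboring set that swaps two planted genes for background genes with
luckily placed mutations edges it out by 0.003 in normalized score — the
reason the top-N list, not only rank 1, is worth inspecting, and the reason
the permutation test (`nomas permtest`) and the holdout scheme
(`nomas holdout`) exist. A normalized score of 3.69 sits far in the upper
tail of N(0,1): patients with a mutation in this module die markedly
earlier. `nomas validate` prints the harmonization report (here: 120
samples, 84 events, 28 of 100 network genes carry no mutations after the
min-3-samples filter and act only as connectors).

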