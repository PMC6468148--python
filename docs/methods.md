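# Methods

This note documents the statistical model, the algorithmic and numerical
choices, and what the simulation-based validation does and does not show.

## The log-rank score

Samples are sorted by increasing survival time; ties violate the model's
assumptions and are broken deterministically (time, then event before
censored, then original index) with a warning. For a gene set S, the
population indicator x^S marks samples with a mutation in at least one
gene of S. The log-rank numerator V(x,c) is the sum over event times of
observed-minus-expected membership of the event in population 1, and its
permutation standard deviation factorizes as σ(x,c) = √(m₁(m−m₁))·f(c)
with

    f(c) = sqrt( (Σ_j c_j − Σ_j c_j/(m−j+1)) / (m(m−1)) ).

The search optimizes w(S) = V/√(m₁(m−m₁)); f(c) is a positive cohort
constant, so it cannot change any argmax and is applied only when
reporting the normalized statistic w/f(c).

Two conventions worth making explicit:

- **Degenerate splits.** When m₁ ∈ {0, m}, V ≡ 0 and σ(x) = 0; w is
  defined as 0. A set mutating all samples or none carries no signal, and
  this avoids 0/0 in the DP.
- **Variance convention.** The normalization uses the exact permutation
  variance of V given c (a closed form in c alone), not the sum of
  per-event-time hypergeometric variances used by some survival packages.
  The two agree asymptotically; cross-checks against lifelines therefore
  assert close agreement rather than identity.

**Linearity.** V is linear in x: V(x) = Σ_i x_i·b_i with
b_i = c_i − Σ_{j≤i} c_j/(m−j+1). The implementation precomputes b once
per cohort. Linearity gives V(x∨y) = V(x) + V(y) − V(x∧y), which is what
makes the dynamic program fast (below).

**Monte-Carlo p-values.** The null conditions on the observed m₁: B
uniformly random labelings with exactly m₁ ones are drawn and the add-one
estimator (#{at least as extreme}+1)/(B+1) is returned, so estimates are
never exactly zero. What exactly is resampled was an open design point;
conditioning on m₁ matches the two-fixed-populations framing of the
statistic. Because the null is discrete, "at least as extreme" tolerates
last-ulp float differences between scoring paths. With m=200, m₁=60 and
10⁵ draws the normalized statistic is indistinguishable from N(0,1) by a
KS test (skewness ≈ 10⁻³); the asymptotic normal tail is therefore used
for per-gene p-values (with a Monte-Carlo option for small cohorts).

## The color-coding search

Each iteration draws an i.i.d. uniform k-coloring and fills a
(2^k−1)×|V| table; entry (T,u) stores one connected colorful subnetwork
with colorset exactly T containing u, built by combining W(Q,u) with
W(R,v) for neighbors v, over all submasks Q ∋ color(u), R = T∖Q. Since
the score is not set additive, keeping one maximizer per entry is a
heuristic: the discarded candidates may have been the right building
blocks for a larger set. Under the planted-subnetwork generative model
this loss provably does not bite, and empirically the search matches
exhaustive enumeration in ≥95% of random desk-scale instances; the table
entry is still always a valid connected colorful set, so reported scores
are never optimistic.

Implementation choices:

- **Bitset entries.** Each entry caches its sample indicator packed 63
  bits per signed 64-bit word (the sign bit is never used, keeping all
  bit arithmetic in signed integer space for the JIT), plus V and m₁.
  Scoring a candidate union costs O(words + |overlap|) via the linearity
  identity, instead of O(m).
- **Tie-breaking.** Among equal-score candidates the lexicographically
  smallest sorted vertex tuple wins. Graph nodes are indexed in sorted
  symbol order, so positional and symbol order coincide and runs are
  bit-reproducible.
- **Directions.** Reduced- and increased-survival searches are two
  independent optimizations (of +w and −w) sharing colorings; |w| is not
  optimized directly.
- **RNG.** Coloring i is drawn from substream (seed, i), so extending L
  leaves earlier colorings unchanged and the best score is monotone in L.
- **Parallel fill.** Columns are partitioned across workers; rows of
  colorset-group i read only groups < i, so a barrier per group makes the
  result identical to the serial fill regardless of worker count.
- **Merge rule plug-in.** `fill_table(kernel=...)` accepts an alternative
  candidate-merging kernel with the same signature, as an extension point
  for variants that store more than one candidate per entry; only the
  max-w rule ships.
- **Iteration budget.** L = ⌈ln(1/δ)·e^k⌉ iterations bound by δ the
  probability that a fixed k-set is never colorful (k!/k^k ≥ e^−k per
  coloring). Defaults: k=5, L=256. Candidate evaluations per iteration
  are bounded by |E|·3^k ∈ O(|E|·4^k); tests assert the count, not
  wall-clock. Memory is Θ(2^k·|V|·(m/63 + k)); k beyond ~12 is out of
  scope.

## Baselines

- **Exhaustive**: recursive extension with an exclusion rule enumerates
  every connected k-set exactly once (anchor-ordered growth, neighbors of
  the current set excluded from re-entry), then scores each.
- **Greedy G1/G2/G3**: all grow a solution from every start node and keep
  the best final set. G1 adds the neighbor maximizing the new score; G2
  additionally considers nodes at distance 2 together with their best
  connector (only while ≥2 slots remain, so solutions end at exactly k);
  G3 is G1 with one-step lookahead (the added node is judged by the best
  pair it enables). These are reconstructions faithful to the
  seed-and-extend family they represent — the original variants'
  definitions were not available in detail — and are flagged as such.
- **Additive comparator**: per-gene one-sided log-rank p-values partition
  genes by direction of association; a(S) = Σ −log₁₀ p(g) is optimized by
  the same color-coding DP restricted to one partition. Additivity makes
  each colorful optimum exact per coloring, which is precisely why the
  comparison with the non-additive w is informative: the additive optimum
  re-scored in w consistently trails the direct optimization of w.

## Significance procedures

- **Permutation test**: gene rows are reassigned to gene labels uniformly
  at random, destroying network placement while preserving each mutation
  profile; the rank-i observed score is compared with rank-i scores over
  permuted datasets (100 permutations and 32 iterations on permuted data
  by default). The p-value is reported as the plain ratio, annotated
  "< 1/n_perm" when the count is zero. Using a weaker search on the
  permuted data (e.g. greedy) understates the permuted scores and hence
  the p-values; the validation suite reproduces this effect.
- **Holdout**: the observed time range is cut into g equal-width
  intervals (right-closed last); within each interval ⌊n_i·v⌋ samples go
  to training, and any shortfall against the global target ⌊mv⌋ is
  distributed one sample at a time to the largest intervals. Censoring
  status is not explicitly balanced — only the time distribution is
  stratified. Solutions found on training are re-scored on the holdout
  samples with Monte-Carlo log-rank p-values, with the tail matching the
  training direction.

## The simulator

The planted model draws a connected k-set D by a simple random walk, then:
for each of the ⌊m/4⌋ shortest-surviving samples, with probability p one
uniformly chosen gene of D is mutated; every gene of D carries passenger
mutations at rate 0.01 in every sample (independent of, and OR-ed with,
the planted mutations); every other gene mutates i.i.d. at its own
background frequency, independent of survival; censoring marks exactly
round(censor_ratio·m) samples chosen uniformly. Survival times are the
ranks 1..m themselves — the statistic depends only on ranks — and emitted
sample order is randomly permuted. Defaults: k=5, p=0.85, m=268,
censor_ratio=0.3 (chosen once as realistic for an aggressive-cancer
cohort where most patients reach the event during follow-up), background
frequencies drawn from a heavy-tailed distribution clipped to
[3/m, 0.15] emulating the long-tailed frequency spectrum of exome
studies; a user-supplied frequency vector reproduces a real cohort's
spectrum when available. `check_model_conditions` reports diagnostics for
the planted-model assumptions (unnormalized signal strength V(D) ≥ c√m,
per-gene marginal contributions, per-gene signal signs) with default
constants c = c′ = 0.5.

What the simulator does **not** emulate: mutational signatures, gene
length and expression covariates of mutation rate, copy-number and
methylation events, co-occurrence/exclusivity structure beyond the
planted set, and non-uniform censoring mechanisms. Passing validation on
this model shows the search and its statistics behave as designed under
the model's independence assumptions, not that real cohorts satisfy them.

## Validation scales

The desk-scale experiments (in `nomas.validation`, run by both the test
suite and `scripts/acceptance.py`) use: 100 oracle-comparison instances
(n=25, degree 4, m=40, k=3, L=100); 25 planted-recovery replicates
(n=500, degree 8, k=5, p=0.85, m=1000, L=64); 50 signal-free permutation
datasets (n=150, degree 8, m=60, k=4, L=L_perm=64, 30 permutations); and
5 hierarchy instances (n=60, degree 6, k=4, m=200). Sizes were chosen so
the complete set runs in a few minutes on a single core while each
experiment retains enough replicates for its qualitative assertion.
Full-scale analyses (10⁴-node networks, k up to 8, 256 iterations, 100
permutations, 10⁸ Monte-Carlo draws) use the identical code paths via the
CLI; see the README for the recipe.

## Known limitations

- Per-coloring optimality is heuristic for the non-additive score
  (adversarial instances exist where the optimum is colorful yet
  missed); L iterations mitigate but do not eliminate this.
- The permutation test preserves row marginals only; gene-gene
  correlation structure within samples is destroyed by design.
- Tied survival times are handled by a deterministic ordering rather
  than the standard tied-risk-set corrections; heavily tied data should
  be jittered or pre-processed upstream.
- p-value floors: asymptotic per-gene p-values are floored at 10⁻³⁰⁰;
  Monte-Carlo p-values at 1/(B+1).
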