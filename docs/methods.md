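# Methods

## Model

A ranked list L of length l over a universe of p features is the top-l
prefix of an unknown complete ranking. Its *completions* are the (p − l)!
permutations of S_p agreeing with L on the first l positions. The
dissimilarity between two lists is defined as the mean Canberra distance
between their completion pairs, the Canberra distance on rank vectors
being Σ |x_i − y_i| / (x_i + y_i). The aggregation function over
completion pairs is fixed to the mean: the Canberra distance on S_p is
asymptotically normal (it satisfies Hoeffding's combinatorial CLT
condition), so the mean is the natural one-number summary and no other
aggregator is implemented.

Writing z for the number of shared features and u = p − (l1 + l2 − z) for
the features in neither list, linearity of expectation over the two
independent uniform completions splits the mean into

- T1 = Σ_{g in both} |τ1(g) − τ2(g)| / (τ1(g) + τ2(g)),
- T2 = Σ_{g in one list, rank r} (1/(p − l_other)) Σ_{j=l_other+1..p} |r − j| / (r + j),
- T3 = u · (1/((p − l1)(p − l2))) Σ_{i=l1+1..p} Σ_{j=l2+1..p} |i − j| / (i + j).

Complete = T1 + T2 + T3; Core = T1 + T2. T3 depends only on
(p, l1, l2, u) — permuting ranks inside fixed supports leaves it
bit-identical (asserted in tests).

Properties worth keeping in mind:

- The Complete measure is a *dissimilarity*, not a metric: for a partial
  list with at least two unselected features, Complete(L, L) > 0, because
  the two completions disagree on the bottom block. When l ≥ p − 1 the
  completion is unique and the self-measure vanishes. Core(L, L) = 0
  always.
- On complete lists (l = p) T2 = T3 = 0 and the measure reduces to the
  ordinary Canberra distance between the two permutations.
- Both measures are symmetric under argument swap in every strategy.

## Normalisation

Raw values are divided by the exact group mean
E(p) = (1/p) Σ_{i,j ≤ p} |i − j| / (i + j) (each pairing i → j occurs in
(p − 1)! permutations, hence the 1/p). E(p) is a mean, not a maximum, so
normalized values above 1 occur and are deliberately not clamped. The
asymptotic form E(p) ≈ (2 ln 2 − 1)(p + 1) − 1, obtained by substituting
Euler's approximation H_s ≈ ln s + γ into the harmonic expression, is
provided for magnitude estimates only; the normaliser is always exact.
Normalisation requires p ≥ 2 (E(1) = 0); breakdowns over a singleton
universe report NaN normalized fields.

## Evaluation strategies and numerical choices

Three interchangeable routes are implemented and cross-checked to 1e−9
relative, componentwise, on hundreds of random instances:

1. **Enumeration** (`measure_bruteforce`): the defining mean over all
   (p − l1)!(p − l2)! completion pairs, refused above a cap (10^6 pairs
   by default) with an explicit size report. Oracle only.
2. **Expectation form** (`measure_marginal`): the T1/T2/T3 sums written
   out directly, O(p) per exclusive feature and O(p²) for T3. Readable
   reference.
3. **Harmonic closed form** (`measure_closed`): every T2 term collapses
   to a two-piece expression in harmonic numbers (split the range at
   j = r), and T3 to an inclusion-exclusion of four rectangle sums
   F(m, n) = Σ_{i≤m, j≤n} |i − j| / (i + j), each O(min(m, n)) from the
   same table. Cost: O(p) table build once, then O(l1 + l2) per pair.
   Production path, used by the stability matrix.

Numerical notes:

- Harmonic numbers are cumulative float sums up to 2p; the absolute error
  grows like p·ε, negligible against the 1e−9 cross-strategy tolerance
  for p up to 10^6.
- E(p) has two independent O(p) implementations (grouping the double sum
  by rank-sum s = i + j, whose numerators are arithmetic series, and a
  row-wise harmonic reduction); they agree to 1e−9 and the grouped form
  is the default.
- The T3 inclusion-exclusion can cancel to a tiny negative float when its
  exact value is ~0 (e.g. u ≤ 1); it is floored at 0, which is exact.
- Empty lists are legal: Core = 0 and Complete = T3 with u = p, which
  equals E(p) exactly for a pair of empty lists.
- Ties are not representable: lists are orderings, and duplicate tokens
  are a hard error.

## Stability indicator

For B ≥ 2 lists the indicator is the mean of the B(B−1)/2 distinct
pairwise measures. Self-pairs are excluded from the mean — including the
positive complete-mode self-dissimilarity would bias sets of identical
partial lists away from zero-spread intuition — but the diagonal is still
computed and reported, since it is informative for partial lists. Because
E(p) is exactly the expected pairwise distance of random complete
rankings, the normalized complete-mode indicator of such sets is unbiased
at 1 for every (B, p); observed 10-replicate means scatter around 1 with
a standard error of ~0.02 at (B=5, p=10) and shrink rapidly with p and B.

## Borda aggregation

Each feature gets its extraction count (number of lists containing it)
and its mean 1-based position *over the lists that contain it* — absent
features are not imputed a bottom rank. Ordering: decreasing extractions,
then increasing mean position, then universe order. The last tie-break is
our choice for determinism (any total order would do); on complete lists
the rule provably coincides with the classical ascending-total-rank Borda
count, which the suite checks by brute force. Features extracted by no
list are omitted by default and appended in universe order when
requested, since an aggregate of selections should not silently contain
never-selected features.

## Maximally distant ordering

The ordering of 1..l farthest from the identity is found by exhaustive,
vectorised search over all l! orderings, capped at l = 10 (≈3.6·10^6
candidates, a few seconds); beyond the cap the function refuses rather
than approximate. Ties go to the lexicographically first maximiser. By
right-invariance of the Canberra distance the single ordering realises
the maximally distant pair for any shared support of size l inside any
universe. The test suite independently verifies the optimum against the
equivalent linear-assignment formulation (maximising Σ_i c[i, σ(i)] over
permutations) solved exactly by the Hungarian algorithm.

## Synthetic generators and what they show

All generators are pure functions of an integer seed (one documented
NumPy PCG64 generator; derived per-replicate seeds come from
`SeedSequence.spawn`). They emulate the two benchmark regimes the
measures are calibrated on:

- sets of uniform random complete rankings (stability-indicator grid:
  defaults of 10 replicates per cell, n ∈ {5, 10}, p ∈ {10, 1000} in the
  reference runs);
- length-l partial lists with independent or shared supports (reference
  pair grid at l = 10, p = 10^c, c = 2..5, with identical / one random
  draw / maximally distant rows; the random row is a single draw by
  construction, so it is checked against a simulated 3σ band, not for
  equality).

They produce exchangeable, uniformly random rankings only: no correlation
between lists, no signal features, no length heterogeneity within a set
unless requested. Passing benchmarks therefore demonstrates correctness
of the combinatorics and calibration of the normaliser, not that any
particular biological selector is stable.

A qualitative regime check is also asserted: for shared-support random
pairs the Core/Complete ratio grows with l/p, and for l/p ≲ 0.15 the two
measures are nearly proportional — the regime where Core is the
informative choice.

## Problem sizes in the shipped runs

The default test suite and the reproduction script keep exhaustive
enumerations under 10^5 completion pairs per instance, the maximal-pair
search at l = 10, and closed-form evaluations up to p = 10^5; everything
completes in well under a minute per component on one CPU.

## Known limitations

- Choosing the truncation length l is out of scope; lists arrive already
  truncated.
- No tie handling and no weighted or L_q Canberra variants.
- The exhaustive maximal-distance search refuses l > 10; the closed-form
  constructions from the rank-metric literature are not reproduced.
- Core/Complete values for wildly different list lengths share one
  normaliser E(p); cross-study comparisons should hold p fixed.
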