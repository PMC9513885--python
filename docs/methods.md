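# Methods

## Model and assumptions

`circannot` treats a circRNA's functional context as a directed tripartite
graph: circRNA → miRNA edges (sponging) and miRNA → mRNA edges
(targeting). Paths cannot connect molecules of the same layer. For a fixed
circRNA the relevant structure collapses to two weight vectors: the binary
miRNA incidence **a** and the length-2 path counts **Aa** per mRNA. The
overlap statistic s(c,g) = aᵀg^μ + (Aa)ᵀg^m counts paths ending in term
members; it is a sufficient summary because the graph is fixed and only
the term varies under the null.

The null model draws k_μ miRNAs uniformly without replacement from the
*full* miRNA universe and, independently, k_m mRNAs from the full mRNA
universe. Two modelling points deserve emphasis:

- **Full universe, not the neighborhood.** RNAs with weight zero (not
  reached by the circRNA) remain in the selection pool. This is what makes
  the expectation formula (k_μ/|μ|)·‖a‖₁ + (k_m/|m|)·‖Aa‖₁ and the
  combination total C(|μ|,k_μ)·C(|m|,k_m) consistent with each other; the
  package treats a description of the null as sampling only interacting
  RNAs as a misreading and tests the full-universe form against exhaustive
  enumeration.
- **Independence of the two draws.** The miRNA and mRNA parts of a real
  annotation term are of course correlated; the product-form null ignores
  that, which is exactly what makes it tractable (the two restricted
  polynomials multiply).

The p-value is the inclusive upper tail P(S ≥ s_obs): the observed
configuration counts toward its own tail, so p ≥ 1/total always, and
s_obs = 0 gives exactly 1 — an unconnected circRNA can never be annotated.

## The generating-polynomial engine

`restricted_genpoly(w, k)` computes the coefficients of
∏ᵢ(1 + x^{wᵢ}y) restricted to y^k. Implementation choices:

- **Grouping + binomial expansion.** Weights repeat heavily in real
  graphs (most mRNAs are reached by few paths), so equal weights are
  grouped and each group (1 + x^w y)^n is expanded as
  Σ_t C(n,t) x^{wt} y^t; the dynamic program convolves one table per
  *distinct* weight instead of one per RNA.
- **Trimming.** The y-dimension is truncated at k, and any x-power above
  the sum of the k largest weights is dropped during the convolution —
  all remaining weight additions are non-negative, so such states can
  never re-enter the feasible range.
- **Zero-weight group.** RNAs outside the neighborhood form the group
  (1 + y)^{n₀}, folded in analytically at the end: selecting k−j of them
  multiplies the j-column of the table by C(n₀, k−j) at x-power 0.
- **Exactness.** Coefficients are Python arbitrary-precision integers and
  the p-value a `fractions.Fraction`. Counts like C(19375, k) overflow
  any fixed-width type; exact arithmetic is the point of the method, and
  it also makes the closed-form expectation and the polynomial-route null
  mean comparable bit for bit in tests.

A naive term-by-term polynomial product (`naive_restricted_genpoly`) is
kept solely as an independent oracle; the test suite asserts equality of
the two routes on randomized batteries, and equality of the resulting
null distribution, p-values and means with exhaustive enumeration over
all subset pairs on instances small enough to enumerate (|μ| ≤ 6,
|m| ≤ 8, several hundred seeded instances).

The per-RNA influence report uses the closed forms
Δ^μ = diag(a)(g^μ + Aᵀg^m) and Δ^m = diag(Aa)g^m; a miRNA's delta counts
both its own membership and the annotated paths it mediates, which is
verified in tests against literal node deletion and recomputation. The
identity ΣΔ^μ = s holds for every instance.

## Monte-Carlo reference sampler

`sample_pvalue` draws term subsets with a per-call
`numpy.random.Generator` (no global state) and reports the positively
biased estimator (r+1)/(n+1), which cannot produce an impossible zero.
Subsets are sampled by ranking i.i.d. uniforms per trial (argpartition),
which vectorizes the whole battery. The sampler exists to cross-validate
the exact engine, and the acceptance suite checks that the exact p lies
in the Clopper–Pearson 99% interval of (r, n). Because the CP interval
itself misses at just under 1% per instance even for a perfectly
calibrated sampler, that check uses a 1000-instance battery at 10⁴ trials
each: large enough that the observed miss rate concentrates near its
analytic value (~0.9%) and the ≥98% pass band reflects the sampler, not
binomial luck.

## Pipeline conventions

- **Term filtering** keeps terms with 10–1000 in-graph members by default
  (inclusive); narrower terms are statistically fragile, broader ones
  uninformative. Term size counts miRNA + mRNA members *present in the
  graph universes* — GMT members that do not match any graph identifier
  are dropped (logged), since the null's denominators are the graph's
  universes.
- **Multiple testing.** Three adjustments are exposed: Bonferroni and
  Holm (both FWER) and Benjamini–Hochberg (FDR). The report's `fdr`
  column is BH; Holm is sometimes mislabelled FDR in the field, so the
  package keeps it separate under `p_holm`. All three are computed in
  exact rational arithmetic over the filtered family only; tests
  cross-check them against statsmodels in floating point.
- **Identifier matching** is exact-string and case-sensitive. No
  miRBase/HGNC aliasing: symbol normalization belongs upstream and hidden
  mapping tables would make results irreproducible.
- **Output formatting**: p-values print in scientific notation with 3
  significant digits; the normalized ratio with 12, so a written table
  read back reproduces it to that precision. Per-term wall time is
  recorded as information only and never asserted on.

## Synthetic data

`SyntheticSpec` generates graphs with independent Bernoulli edges per
layer and uniformly drawn term memberships. Defaults (40 miRNAs, 150
mRNAs, circRNA-to-miRNA edge probability 0.25, miRNA-to-mRNA density
0.08, 20 terms of 10–40 members) are a desk-scale analogue of a
genome-wide ceRNA graph, where a circRNA reaches a few tens of miRNAs and
each mRNA is targeted by a handful — small enough that the exhaustive and
Monte-Carlo oracles stay cheap, while exercising repeated weights, zero
weights and size filtering. What the generator does *not* emulate:
scale-free degree distributions, correlation between a term's miRNA and
mRNA memberships, or the sheer size of real universes. Passing tests
therefore demonstrate the correctness of the combinatorics on arbitrary
binary graphs (which is distribution-free), not calibration against any
particular biological network topology. A `plant_first_term` mode wires
the circRNA to the first term's miRNAs so that genuinely small p-values
occur in demonstrations.

## Degenerate inputs and tie-breaks

- Unconnected circRNA: all weights zero, null mass concentrated at 0,
  every p = 1 (asserted in the acceptance suite).
- E[s] = 0 (empty term after restriction, or empty neighborhood): the
  normalized ratio is undefined and reported as missing, never infinity.
- Result rows sort by ascending p, ties by term id; influence rows by
  descending delta, ties by identifier. Duplicate input edges collapse to
  one with a warning; duplicate term names are an error.

## Known limitations

- The whole restricted polynomial is held in memory: the table size is
  O(total path count × term size), which is the binding constraint for
  very highly connected hubs.
- No early-stopping/bounded evaluation of the tail, and no log-space
  approximate mode; the engine is exact or nothing.
- The annotation loop over multiple circRNAs is naive (no checkpointing
  or parallelism).
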