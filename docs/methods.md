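# Methods

`pollinet` implements the standard quantitative analysis of a community
plant–pollinator visitation network: a bipartite matrix of visit counts is
summarized by connectance, nestedness, complementary specialization and
modularity; the metrics are tested against a fixed-marginal null model;
species are ranked by centrality to flag keystones; and dated sub-networks
are compared with a size-corrected nestedness index. This note records the
models, the conventions chosen where the literature is ambiguous, and the
limits of what the synthetic tests demonstrate.

## Data model

A network holds an R×A integer matrix `A` (plants × pollinators) in which
every row and column has at least one positive cell. Species observed in
the community with zero interactions are kept on an *isolated-species
register*, outside the matrix. This convention matters: connectance is
`C = L/(R·A)` over *interacting* species, while links-per-species `L/S`
counts every observed species by default. Symbols used throughout:
row totals `k_i`, column totals `d_j`, grand total `F`, links `L`
(positive cells).

## Nestedness (NODF and weighted NODF)

For every unordered pair of rows (and of columns), the paired nestedness is
zero when the two binary fills are equal, and otherwise the overlap count
divided by the smaller fill. NODF is the mean over all
`R(R−1)/2 + A(A−1)/2` pairs, on a 0–1 scale (×100 for the conventional
percent presentation). The classical algorithm sorts the matrix by fill
first; because the decreasing-fill condition is evaluated per pair, sorting
is unnecessary and the index is invariant to row/column permutation.

The weighted variant keys the decreasing-fill condition on *binary fill*
(pairs with equal fills contribute zero) and scores the fraction of the
smaller-fill line's positive cells that are strictly exceeded in the
larger-fill line. This matches the reference implementation in
`vegan::nestednodf(weighted = TRUE)` (which the R `bipartite` package
wraps), and is cross-checked against it in the test suite. A consequence
worth knowing: any matrix with constant positive weights has weighted
NODF 0.

## Complementary specialization H2′

The observed interaction entropy is `H2 = −Σ p_ij ln p_ij` with
`p_ij = a_ij/F` (natural log). H2′ rescales it between the extremes
attainable by *integer* tables sharing the observed marginals:
`H2′ = (H2max − H2)/(H2max − H2min)`, clamped to [0, 1], so 0 means the
most even (generalized) table the marginals allow and 1 the most
concentrated (specialized). For tables with ≤ 12 cells the extremes are
found by exhaustive enumeration of all tables with those marginals (with
an internal cap of 2·10⁵ tables); larger tables use deterministic
heuristics:

* **H2max** — units are placed one at a time into the cell whose
  independence expectation `k_i d_j / F` is least satisfied (ties: lowest
  row, then column). This honors both marginals exactly and is near-
  optimal; measured deficits on enumerable tables are < 0.04 nats.
* **H2min** — repeatedly pour `min(remaining row, remaining column)` into
  the cell pairing the two largest remaining marginals. This greedy
  concentration can sit up to ≈ 0.2 nats above the true minimum on small
  adversarial tables; the clamp absorbs the slack.

Degenerate marginals (`H2max = H2min`, e.g. a single cell) define
H2′ = 0 with a warning.

## Fixed-marginal null model

Significance of any network-level metric is judged against tables drawn
uniformly from the multiple-hypergeometric (Fisher) distribution with the
observed row and column totals — the Patefield null. The sampler pairs the
F row tokens with a uniformly shuffled sequence of F column tokens and
tabulates; this is distributionally identical to Patefield's sequential
conditional algorithm and is verified in the tests against the exact
hypergeometric law on enumerable 2×2 cases (total-variation < 0.02 at
5·10⁴ draws) and against SciPy's independent Patefield implementation.
The default ensemble is 1000 randomizations; the 95% band is the 2.5% and
97.5% linear-interpolation quantiles of the sampled metric, and a metric
is "significant" when the observed value falls outside the band (two-
sided; no p-value is reported). Every stochastic entry point takes an
explicit seed.

## Quantitative modularity

The objective is Barber-type weighted bipartite modularity
`Q = (1/F) Σ_ij [A_ij − k_i d_j/F] δ(m_i, m_j)`, with plants and
pollinators assigned to a shared module-id space and the module count
emergent. Q is maximized by simulated annealing: moves are single-species
reassignment (85%, including to a fresh module), module merge (10%) and
random module split (5%); worsening moves are accepted with probability
`exp(ΔQ/T)` under geometric cooling (defaults: T₀ = 0.02, α = 0.995,
10⁴ moves). Each repetition ends with a steepest single-move refinement
pass, and the best of `n_repetitions` (default 100) independent
repetitions is returned — the usual best-of-restarts treatment for a
stochastic modularity search; "maximum likelihood" selection across runs
is equivalent to maximum Q here. On every enumerable instance (≤ 3×3) the
search matches exhaustive maximization over all set partitions, and on
planted-partition matrices with 95% within-module weight it recovers the
planted modules with adjusted Rand index ≥ 0.9.

Inside null-model ensembles the annealing is run with reduced settings
(default 2 repetitions × 1500 moves per randomization): a full
100-repetition search inside each of 1000 randomizations would multiply
the cost a thousandfold for no change in the verdict logic. The reduced
search is a slightly conservative estimate of each null table's maximal Q.

## Centrality and keystones

Centralities are computed on the binary structure, by default on the
single two-mode graph over all interacting species (one-mode projections
per level are available, since both conventions circulate and published
tables rarely say which was used). Betweenness is shortest-path
betweenness normalized by `(n−1)(n−2)/2`. Closeness uses the un-rescaled
convention `CC(v) = 1/Σ_u d(v,u)` over vertices reachable from `v` —
chosen because it reproduces the magnitude range (~0.03–0.11) of published
field-network tables; unreachable pairs contribute nothing and the
reachable-pair fraction is reported alongside. Isolated species carry
degree 0 and undefined centralities.

The keystone of a trophic level is a composite: species are ranked
separately on degree, BC and CC (average ranks on ties), ordered by mean
rank with ties broken by degree then label. This formalizes the informal
"high degree and centrality" criterion; when two species dominate
different scores the composite can be a near-tie, and the full ordering is
returned so such cases are visible.

## Maximum NODF and combined NODF

Raw NODF is not comparable across networks of different shape and fill, so
daily networks are compared with

    NODF_c = (NODF / max NODF) / (C · log10(√(R·A))),

where `max NODF` is the largest NODF attainable by *any* R×A binary matrix
with the same link count and `C` uses the original (pre-augmentation)
links. The analysis requires `R + A ≤ L`; sparser networks are handled by
raising the link count (`L_eff = max(L, R+A)` by default, with per-day
overrides to reproduce published augmentations). Because the optimum
depends only on (R, A, L), augmentation is a pure link-count adjustment.
A network whose augmented count reaches `R·A` is a full matrix (max
NODF 0) and is excluded from the comparison as undefined.

`max_nodf` enumerates all placements with no empty line when
`C(R·A, L) ≤ 10⁶` and otherwise uses a greedy start (staircase skeleton
plus one-at-a-time link addition at the NODF-argmax cell) followed by
steepest-ascent 1-swap hill climbing with seeded random restarts
(default 50). The returned witness matrix always satisfies
`nodf(witness) = max_nodf`, so every reported optimum is constructively
attained. The heuristic equals the exhaustive optimum on every shape
≤ 4×4 at every feasible link count.

A caution for cross-study comparison: published per-day "max NODF" values
are themselves heuristic outputs and can be loose in either direction.
For a 4×8 matrix with 13 links this optimizer attains 0.662 (witness
verified independently), above the 0.647 circulating for that
configuration, and for 10×9 with 20 links it attains 0.549 versus a
published 0.469; NODF_c values computed from different optimizers are
therefore not interchangeable.

## Synthetic data and the packaged fixture

* `generate_nested` fills the L best cells of a superellipse score
  `((i+½)/R)^p + ((j+½)/A)^p` (plus a seeded jitter of the boundary) over
  a validity skeleton. Small `p` orders cells hyperbolically (steep,
  mutually distinct row fills — strongly nested); `p = 1` gives a
  triangular staircase; large `p` an even block with many tied fills.
  Mean NODF is non-increasing in `p`.
* `generate_modular` splits species evenly into k planted modules and
  assigns F visits multinomially with a `within_share` fraction of mass on
  within-module cells (each species seeded with one within-module visit so
  no line is empty). `within_share = 0.5` reproduces the unstructured
  case.
* `realize_degree_sequence` checks the Gale–Ryser condition and constructs
  one realization maximal-first with seeded random tie-breaking;
  infeasibility is a returned verdict, not an exception.
* `attach_weights` puts overdispersed `1 + NegBin` counts on links
  (dispersion 1, mean 4 by default) — the typical variance behaviour of
  visitation counts.

The packaged fixture carries the printed summaries of a one-season survey
of the food-deceptive orchid *Cypripedium guttatum* and its co-flowering
community (12 plants, 19 flower visitors, 42 links, four dated
sub-networks, timed visitation bouts of the effective pollinator
*Lasioglossum virideglaucum*). The quantitative visit matrix of that
survey was never published; the shipped interaction CSV is a *binary
reconstruction* of the printed degree sequences (flagged `synthetic` in
its filename), one of many consistent matrices. Quantities that depend
only on the degree structure (connectance 0.201, links per species 1.4,
degree tables, total links 42) are exact; anything weight- or
adjacency-dependent computed from the reconstruction (weighted NODF, H2′,
module membership, centrality values) is illustrative only, and the tests
assert nothing matrix-dependent about it. In particular, a binary
realization has constant weights, so its weighted NODF is 0 and its H2′
is near the generalized extreme by construction.

## Numerical conventions and degenerate inputs

Ties everywhere break deterministically (lowest row, then column; lowest
module id; earliest window/day; labels alphabetically). Quantiles are
linear-interpolation order statistics. Entropies are in nats. Networks
with a single row or column have no pairs of that orientation and simply
contribute none. The flowering-span convention is a day difference
(end − start), not an inclusive count. Visit-duration SD uses the N−1
denominator and is undefined (None) for a single bout.

## Problem sizes in the shipped tests

The suite runs single-CPU in well under a minute: null-model
distributional checks use 2·10⁴–5·10⁴ draws on tables with F ≤ 12;
oracle comparisons sweep hundreds of random matrices up to 6×6 (metrics)
and 8×8 (centralities); modularity recovery uses 9×9 networks with 400
visits over 20 seeds; the max-NODF sweep enumerates every shape ≤ 4×4.
These sizes are chosen to make the checks exact or statistically decisive,
not to emulate field-scale surveys; real survey matrices are comfortably
within the same code paths.

## Known limitations

* H2max/H2min heuristics are near-optimal, not exact, beyond 12 cells.
* The annealing optimizer is stochastic; Q values are lower bounds on the
  true maximum (self-consistent with their returned partitions).
* The heuristic max-NODF is exact on all enumerable instances tested but
  carries no global guarantee for large shapes.
* The null model conditions on both marginals; it does not address
  sampling-effort biases, which require comparison across networks rather
  than within one (the motivation for NODF_c here).
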