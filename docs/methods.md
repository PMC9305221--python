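# Methods

This note documents the models and algorithms implemented in `batplant`,
the numerical choices behind them, what the synthetic generator does and
does not emulate, and known limitations.

## Network representation

A network is a labeled *R* × *C* matrix of nonnegative integer counts
(consumers = bats on rows, resources = plants on columns). A cell counts
detection events — individual bats in whose faeces a plant taxon was
detected — so weights are counts, never rates; integral decimals such as
`3.0` are accepted on read (R's `write.csv` output), anything else is a
parse error naming the offending row and column. Files in the transposed
orientation are handled by an explicit `transpose` flag rather than
auto-detection, which is unsafe for square-ish matrices. Hygiene
(`drop_empty`) removes species with no detections and is a precondition for
every metric; it is idempotent and logs what it removed. Edge lists carry
no guild ordering, so `from_edge_list` orders labels lexicographically; the
matrix ↔ edge-list round trip is exact for sorted-label networks.

## Structure descriptors

**Connectance** is *L*/(*R·C*). **Compartments** are connected components
of the bipartite graph on the nonzero cells, computed with
`scipy.sparse.csgraph`; component ids are ordered by decreasing size, ties
by smallest row index, so labels are reproducible.

**WNODF.** For an ordered row pair (*i*, *j*) with marginal totals
MT<sub>i</sub> > MT<sub>j</sub>, the pair score is
100 · #{c : 0 < w<sub>jc</sub> < w<sub>ic</sub>} / #{c : w<sub>jc</sub> > 0};
pairs with MT<sub>i</sub> ≤ MT<sub>j</sub> score 0, and ties in individual
cells contribute nothing (strict inequalities throughout). Column pairs are
scored the same way on the transpose. The index is the sum of pair scores
divided by *R*(*R*−1)/2 + *C*(*C*−1)/2. Because comparisons use marginal
totals directly, no pre-sorting of the matrix is needed and the index is
invariant under row/column permutation. Reported on 0–1 (the raw 0–100
value is exposed as `wnodf_raw`). A 1 × 1 matrix has no pairs and raises an
undefined-metric error.

**Barber modularity.**
*Q* = (1/*F*) Σ<sub>ij</sub> [*A<sub>ij</sub>* − *k<sub>i</sub>d<sub>j</sub>*/*F*] δ(*g<sub>i</sub>*, *h<sub>j</sub>*).
Reports use this raw (unnormalized) value; a normalized variant
(*Q*/*Q*<sub>max</sub> with *Q*<sub>max</sub> = 1 − Σ<sub>m</sub>(*F<sub>m</sub>*/*F*)²
the all-weight-within-modules bound) is exposed for cross-network
comparison but never enters reports.

**DIRTLPAwb+ search.** Stage 1 is label propagation: given fixed column
labels, *F·Q* separates over rows, so assigning every row the label that
maximizes its own term is the exact row-optimal move; sweeps alternate
guilds until the *Q* improvement falls below 10⁻¹⁰. Ties pick the lowest
canonical label id (determinism); a node whose best attainable term is
negative retreats to a fresh singleton label. Stage 2 greedily merges the
module pair with the largest positive ΔQ (computed from module-aggregated
weight and marginal matrices) and re-runs propagation after every merge.
The DIRT wrapper restarts this from random seedings at initial module
counts {1, 2, 4, …, min(*R*, *C*)}, 10 restarts each by default, and keeps
the best *Q*. The winning partition is canonicalized: module ids 0..m−1 by
decreasing module marginal weight, ties by smallest member node index. On
every random network with *R*+*C* ≤ 8 we have fuzzed, this search attains
the exhaustive-partition optimum.

**WNODF_SM** applies the WNODF pair scoring only to row pairs in the same
module and column pairs in the same module (both sum and denominator); with
no same-module pair it returns an undefined marker (NaN). It is evaluated on
the single best partition found above, with the same seed as the report.

## Null models

**vaznull.** Cell probabilities are *p<sub>ij</sub>* ∝ *r<sub>i</sub>c<sub>j</sub>*
(products of observed marginal totals). Stage 1 places the *L* links one at
a time by sampling *p* over still-empty cells, rejecting a draw that would
strand coverage; since one future cell can cover one empty row *and* one
empty column at once, the exact feasibility bound is
remaining ≥ max(#uncovered rows, #uncovered columns) — with this bound no
dead end can occur, but a bounded retry budget (10⁵ rejected draws) is kept
as a hard stop. Stage 2 distributes the remaining *T* − *L* events over the
filled cells by repeated categorical draws proportional to *p* renormalized
over those cells; sequential draws (rather than one multinomial jump) keep
seed replay exact. Hard invariants of every replicate: dimensions, *L*,
*T*, and full row/column coverage.

**Module-conserving null.** The matrix is partitioned into regions by
module pair (*g*, *h*); the vaznull procedure runs independently inside
every region with observed links, preserving each region's fill and weight
(hence global *L* and *T*). Within diagonal regions, rows/columns with an
observed within-module link must keep at least one; between-module regions
carry no coverage requirement — whole-matrix coverage follows from the
diagonal regions, and the rare replicate in which a species whose links are
all between-module loses them entirely is discarded and redrawn. A stricter
or laxer between-module treatment is a plausible alternative; this one is
the package's choice and is what the region-conservation tests pin down.

**z-scores** use the sample (n−1) standard deviation. When the null spread
is zero — conserved quantities such as *T* or connectance — the z-score is
an undefined marker, with a guard at 10⁻¹² relative spread so float residue
in an all-identical ensemble does not masquerade as variance. Ensembles are
bitwise reproducible from their seed. Null ensembles for modularity
re-optimize every replicate (2 restarts per initial count by default —
cheaper than the observed search, since nulls only need an honest
comparison value, not a certified optimum).

Marginal sums are conserved *probabilistically*, not exactly: the coverage
constraint and without-replacement link placement give the null mean row
sum a small systematic offset from the observed value (a fraction of one
event in study-scale matrices). The tests therefore check that each row's
null mean lies well within the null spread of the observed value and that
null means track observed marginals almost perfectly (r > 0.99), rather
than asserting exact unbiasedness, which this construction — including its
original R formulation — does not possess.

## β-diversity

Links are identity pairs (bat, plant); weights are ignored. All
dissimilarities are Sørensen-family, (b+c)/(2a+b+c), matching the betalink
default (Jaccard is available behind a flag). β<sub>S</sub> pools both
guilds into one species set; per-guild values are reported for diagnostics.
β<sub>OS</sub> is computed on the subnetworks induced on species present in
both networks (guild-respecting); β<sub>ST</sub> = β<sub>WN</sub> − β<sub>OS</sub>
exactly, by construction. When the shared-species subnetworks contain no
links at all, β<sub>OS</sub> is undefined and β<sub>ST</sub> is reported
equal to β<sub>WN</sub> with a flag.

## Sampling completeness

The accumulation frame treats faecal detections as individuals. For network
completeness the classes are links and a link's abundance is its cell
count: Chao1 = *S*<sub>obs</sub> + *f*₁²/(2*f*₂) (classic) or
*S*<sub>obs</sub> + *f*₁(*f*₁−1)/(2(*f*₂+1)) (bias-corrected), with
completeness = 100·*L*/Chao1. Classic falls back to bias-corrected when
*f*₂ = 0 and *f*₁ > 0 (flagged); with *f*₁ = *f*₂ = 0 both give
*S*<sub>obs</sub>. Both variants are always computed side by side.
Rarefaction is the exact hypergeometric expectation
E[S<sub>n</sub>] = Σ<sub>k</sub> [1 − C(N−N<sub>k</sub>, n)/C(N, n)],
evaluated with exact integer binomial coefficients (no log-space
approximation is needed at diet-sample sizes), and is validated against
Monte-Carlo subsampling.

## Synthetic generator

`generate_network` plants modules (round-robin assignment), lognormal(0,
σ) abundance weights per species, and cell probabilities ∝
*a<sub>i</sub>b<sub>j</sub>* · ratio^[same module]; *T* detection events
are drawn multinomially and never-detected species are dropped. The product
form generates nestedness through abundance skew — the mechanism the
vaznull comparison is designed to absorb — which makes the null analysis on
synthetic data meaningful. Defaults are study-scale: 12 bats × 22 plant
taxa before hygiene, 4 modules, affinity ratio 8, abundance σ = 1, and 130
detection events (on the order of one season's guano sampling at one site).

`generate_season_pair` derives network B from A by replacing a fraction τ
of each guild with fresh species (keeping sizes comparable, as in real
season pairs where richness changes modestly), rewiring a fraction ρ of the
surviving links to a different shared plant (avoiding duplicates), and
resampling counts over B's link set with every link keeping at least one
event. Across a ρ × τ grid, β<sub>OS</sub> is monotone in ρ and
β<sub>ST</sub> in τ, which is what the recovery tests assert.

What the generator does **not** emulate: DNA-detection false negatives
beyond multinomial sampling, phenology or climate forcing, taxonomic
mis-assignment, and the heavy dominance of a few link counts seen in real
diet data — generated matrices spread events more evenly over links, so
their Chao1 completeness (∼50–75%) runs below the 79–96% of well-sampled
field networks. Passing tests on synthetic data therefore certify the
algorithms and their planted-structure behavior, not any empirical claim
about real bat–plant systems.

## Problem sizes and runtime choices

The test suite fuzzes the metric oracles on 1,000 tiny networks
(*R*+*C* ≤ 10, exhaustive partition checks on *R*+*C* ≤ 8), draws 1,000
null replicates for the contract checks, and uses 10–20 replicate pairs per
grid point for recovery sweeps. The acceptance script uses the generator
defaults and full 1,000-replicate null ensembles. Null modularity
re-optimization uses 2 restarts per initial count; observed values use 10.

## Limitations

- The DIRT search is a heuristic: optimality is certified only on the tiny
  fuzzed instances; on larger networks the reported *Q* is a best-found
  value, stabilized by the restart schedule and seed.
- vaznull z-scores inherit the model's conservatism: structure explainable
  by size, fill and marginal skew is absorbed into the null, so abundance-
  driven nestedness yields z ≈ 0 by design.
- The β decomposition is binary in link identity; weight rearrangements
  that do not create or destroy links are invisible to it.
- Chao1 completeness depends on the accumulation frame (links vs taxa);
  both the variant and the frame are explicit arguments so alternative
  conventions can be compared on the same data.
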