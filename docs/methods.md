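# Methods

## The system and the data model

The package analyses quantitative bipartite flower-visitation webs: one
matrix per habitat with plant species on the rows (the lower trophic
level), flower-visiting butterfly species on the columns (the higher
level), and non-negative integer visit counts `a_ij` in the cells.
Validation enforces unique labels, integral counts and that every species
has at least one recorded interaction; an all-zero row or column is an
error on read, never a silent drop (null-model draws are the one place
where empty lines are legitimate, and those never pass through
validation). Merging webs — e.g. pooling two under-sampled forest
transects before computing metrics, since very small webs give unstable
network statistics — sums counts cell-wise over the union of the label
sets, so the merged grand total is the sum of the parts.

## Assemblage diversity and similarity

Per-habitat diversity is Shannon `H' = -Σ p_k ln p_k` in nats. The
acceptance surface uses presence data, where all weights are equal and
`H' = ln S` with `S` the habitat's richness; an abundance-weighted variant
is available through the same function but is not what the habitat
comparison reports. Similarity between habitat assemblages is the classic
qualitative Jaccard index `J = |A∩B| / |A∪B|`; habitats are clustered on
`1 - J` with UPGMA (average linkage, merge height = half the
between-cluster distance). Ties on the minimal distance are broken by the
lexicographically smallest merged label set, which makes trees
deterministic. Node support comes from bootstrapping species: each of
`n_rep` replicates (default 9,999) resamples columns of the
habitat-by-species incidence table with replacement, recomputes Jaccard
distances and the UPGMA tree, and a reference node counts as supported
when its exact leaf set reappears as a cluster. Replicates that strip a
habitat of all its species are redrawn (at most 100 attempts, then the
replicate counts as unsupported); support is reported only for the
reference tree's nodes, and the root is supported by construction.

## Dependencies and species roles

The dependence of species *x* on partner *y* is the fraction of *x*'s
interactions that involve *y*: row-normalising the web gives each plant's
dependences on its visitors, column-normalising gives each visitor's
dependences on its plants. From these:

- **DEG** — number of realised links of a species.
- **ST** (species strength) — the sum over a species' partners of the
  partners' dependences on it. Strengths are exactly conserved: visitor
  strengths sum to the number of plants and vice versa, which the tests
  use as an invariant.
- **IPP** (interaction push/pull) — for every realised link the dependence
  asymmetry (partner's dependence on the focal species minus the focal
  species' dependence on the partner) is normalised by the larger of the
  two; IPP is the mean over the focal species' links and lies in [-1, 1].
  Positive means the species affects its partners more than it is affected
  ("pusher"). The per-link normalisation is this package's choice; it
  fixes the sign contract and boundedness, but decimals need not agree
  with other implementations that weight links differently, so IPP is
  treated as a sign/ranking quantity, not a decimals quantity.
- **d′** — specialization as the Kullback–Leibler divergence of a species'
  partner-use distribution from partner availability (partner marginal
  totals over the grand total), standardised by the continuous upper bound
  `d_max = ln(m / A_s)` where `A_s` is the focal species' marginal total,
  and clamped to [0, 1]. `d_min = 0` (proportional use). A degenerate
  denominator (a species holding all visits, or a 1x1 web) yields d′ = 0
  by convention.
- **Gc** — within-guild standardised degree `(k - k̄)/σ_k` with the sample
  (n-1) standard deviation; species with Gc strictly greater than 1 are
  core, everything else peripheral. A guild with no degree variation has
  Gc = 0 everywhere and no core species.

## Network-level metrics

- **WBAS** = (C - R)/(C + R): positive when visitors outnumber plants.
- **ISA**: the mean over realised links of the normalised dependence
  asymmetry (visitor's dependence minus plant's dependence over the larger
  of the two). Links enter unweighted — the simplest estimator satisfying
  the sign contract (positive = higher level depends more); decimals from
  frequency-weighted variants will differ, so ISA is also held to sign.
- **SA** = mean d′ of visitors minus mean d′ of plants; negative means
  plants are the more specialized guild.
- **H′ of interactions** = `-Σ p_ij ln p_ij` over realised links with
  `p_ij = a_ij/m`.

Report tables round to 3 decimals.

## Nestedness

NODF on the binarized web: for every pair of rows with strictly decreasing
marginal totals (`MT_u > MT_v > 0`) the pair scores
`100 · |shared partners| / MT_v`; ties or an empty poorer line score 0.
Column pairs analogously. The row/column components are means over all
pairs of that axis, and NODF_total pools both sums over the combined pair
count. The implementation is cross-checked in the tests against
`vegan::nestednodf(order = TRUE)` as an independent oracle and agrees to
4 decimals on random fixtures.

Significance uses the Ce null model (the probabilistic "null model II"
family): each cell is an independent Bernoulli draw with probability equal
to the mean of its row's and its column's fill proportions,
`p_ij = (d_i/C + d_j/R)/2`. Degenerate draws (empty rows or columns) are
kept — resampling them would bias the null distribution — and simply score
zero on their pairs. The upper-tail p-value uses the add-one convention
`p = (1 + #{null ≥ observed})/(n_null + 1)`, so p is never exactly zero
and is bit-reproducible given a seed; the default is 1,000 draws, and a
web is called nested at α = 0.01 (α = 0.05 is selectable but stricter is
the default because the per-habitat verdicts treat p = 0.06 as
non-nested).

## Synthetic data generator

The generator emulates the statistical shape of a year-long visitation
census rather than any particular data set: visitor richness twice plant
richness (R = 20, C = 40 per habitat by default), lognormal species
abundances (σ = 1) so a few core species dominate visits, cell
probabilities proportional to abundance products, and a multinomial draw
of a fixed census effort (n = 2,000 visits per habitat) — a fixed-effort
design, not Poisson cells. Abundance-product sampling is exactly the
mechanism that produces nested webs, and the tests verify that neutral
webs are on average more nested than uniform webs at matched size and
effort (20 seeds). A `uniform` mode gives flat cell probabilities and a
`modular` mode multiplies within-block probabilities by a large factor.
Multi-habitat simulation composes each habitat's species pool from a
community-wide core, a group core (so a planted clade of habitats shares a
configured fraction of species) and unique species, then generates one web
per habitat; UPGMA recovers a planted three-habitat clade in ≥ 90% of
seeds under the defaults. What the generator does not emulate: phenology
and temporal turnover, observation error beyond multinomial sampling,
trait matching, or spatial structure — so passing tests demonstrate
correctness of the estimators and the pipeline on data with the assumed
structure, not robustness of the field inferences to those processes.

Problem sizes used in the simulation-based tests (20 seeds for the
nestedness contrast, 50 seeds for clade recovery, 10,000 draws for the
null-model calibration, a few hundred bootstrap replicates) are the
package's choice of a desk-scale design that keeps the whole suite in a
few seconds while leaving the Monte-Carlo error far below the asserted
margins; the shipped analysis scripts use the full 9,999-replicate
bootstrap and 1,000 null draws.

## Numerical and design notes

- All randomness flows through explicit `numpy.random.Generator` seeds; no
  global state. Null draws consume randomness row-major, so results are
  bit-reproducible for a given seed and draw count.
- Dependencies are computed in double precision from integer counts, no
  pseudo-counts.
- Delimiters are auto-detected among tab/comma/semicolon; counts must be
  integral (fractional cells are a format error), labels are trimmed but
  never fuzzily matched.
- Gc exactly equal to 1 is peripheral (the core rule is strict).
- The long-format census records treat repeated (habitat, plant, visitor)
  rows as additive.

## Known limitations

- IPP and ISA decimals are implementation-specific (link weighting); only
  sign and ranking are contractual.
- The binary NODF is the only nestedness estimator (no weighted NODF,
  temperature or spectral variants) and Ce the only null model; fixed-fill
  swap models are out of scope.
- Modularity detection is out of scope.
- The distinct-link count of a web is reported alongside, but it is not
  asserted to equal any particular census record count: a "record" may be
  a census event rather than a distinct link, and the two only coincide
  when every pair is seen once.
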