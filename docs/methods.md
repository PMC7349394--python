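# Methods

This note records the statistical conventions, defaults and design choices
behind `pondpop`, in the order the pipeline runs them.

## Diversity statistics

Haplotype diversity uses Nei's unbiased estimator
`Hd = n(1 − Σ p_i²)/(n − 1)`. The correction matters here: with it, every
per-pond value in the bundled survey table (including the n = 3, 8, 9, 10
ponds) reproduces the published three-decimal figures; without it none of
the small-n ponds do. `Hd` is undefined for n < 2 and raises rather than
returning a placeholder.

Nucleotide diversity is `π = [n/(n−1)] Σ_{i<j} 2 p_i p_j d_ij / L` with
`d_ij` the mutational steps between haplotypes i and j. The denominator is
the full alignment length; positions unresolved in one sequence (N or gap)
are instead skipped pairwise inside the step count. This is the simplest
defensible convention for near-complete Sanger alignments; with
heavy missingness a pairwise-denominator π would differ.

Chao1 is the bias-corrected form `h + f₁(f₁−1)/(2(f₂+1))`, defined (and
equal to `h`) when no doubletons exist. The abundance-based Chao–Jaccard
dissimilarity uses the published U/V estimators: `U` is the probability
mass of assemblage x belonging to shared haplotypes, plus the
`((m−1)/m)·f₊₁/(2f₊₂)` correction term for shared haplotypes unseen in y
(`f₊₂ = 0` falls back to 1, the standard convention); `U` and `V` are
clamped to 1 and the dissimilarity is `1 − UV/(U+V−UV)`, clamped to [0, 1].
Two assemblages with no shared haplotype are at dissimilarity 1; two empty
assemblages are an error, not a value.

## Haplotype network

The network is a minimum spanning network: pairs are visited in increasing
Hamming distance, and within one distance class every pair that connected
two previously separate components is retained before components merge, so
tied alternative connections survive (a network, not a tree). Ties are
visited in lexicographic haplotype-id order, making construction
deterministic. `total_length` is defined as the weight of the minimal
spanning backbone; the retained tied edges are extra connections and do
not inflate it (with ties, summing all retained edges would exceed the
minimum and would no longer be a spanning-structure length).
`expand_intermediates()` splits an s-step edge into s unit steps through
s − 1 inferred (frequency-0) nodes, matching the usual rendering of
unobserved haplotypes as hollow circles.

## Clustering, ordination, isolation by distance

Ward clustering follows the ward.D2 convention: the Lance–Williams update
runs on squared input dissimilarities and merge heights are reported on the
original scale. Ties at the minimum merge cost are broken by the
lexicographically smallest merged label set, so the dendrogram is
reproducible for any input. Heights are non-decreasing (verified by fuzz);
the implementation is cross-checked against both a membership-level
centroid oracle and `scipy`'s linkage. Flat clusters come from cutting the
merge sequence, labelled by order of each cluster's first leaf.

NMDS minimises Kruskal stress-1,
`sqrt(Σ(δ̂_ij − d_ij)² / Σ d_ij²)`, where the disparities δ̂ are the
isotonic (pool-adjacent-violators) regression of configuration distances on
the input dissimilarities using Kruskal's *primary* tie treatment (tied
dissimilarities impose no order constraint; within a tie block the
configuration distances are taken ascending). One restart starts from
classical-scaling (Torgerson) coordinates and the remaining restarts from
seeded Gaussian configurations, each refined by nonmetric SMACOF until the
relative stress change falls below 1e-6 or 500 iterations; the best
configuration over restarts is returned. Defaults: k = 2 dimensions, 20
restarts. A degenerate consequence of primary tie handling: a fully
equidistant input has stress 0 for essentially any configuration; the test
suite pins this against a direct numerical minimiser of the same objective.

Geographic distances are great-circle (haversine) with Earth radius
6371.0088 km; coordinates stay in decimal degrees WGS84 and are never
projected. The between-pond genetic distance for the isolation-by-distance
test is the plain population p-distance
`Σ_ij p_i^A p_j^B d_ij / L` — no within-pond term and no net-divergence
correction (this is not Φ_ST), which keeps it faithful to a "p-distance
matrix" input. The Mantel statistic is the Pearson correlation over
upper-triangle pairs; the null permutes rows and columns of the second
matrix simultaneously; the default test is one-tailed for positive
association (the IBD hypothesis), p = (#{r* ≥ r} + 1)/(B + 1) with
B = 1000 permutations by default, all driven by one seed. Small inputs
(n ≤ 8) can be tested exactly by full enumeration. Population-level (not
individual-level) matrices are used throughout.

## Overwintering, grading, source–sink rules

The overwintering success rate is spring/autumn captures; it is undefined
(not zero) when nothing was caught in autumn, and values above 1 are
reported with a flag, never clamped. Ponds enter rate-based analyses only
when the autumn count *strictly* exceeds the inclusion threshold — the
basin median, 10 in the bundled survey — so a pond with exactly 10 autumn
captures stays out. Fractional medians are floored to an integer.

Factor grading is rank-based: ranks (ties averaged) are binned at the
20/40/60/80 percentiles of the rank scale, which places the cohort median
in grade 3 by construction and makes grades invariant under monotone
transformations — important because surface areas and densities are heavily
skewed. "Lower is better" factors (concrete revetment, shore gradient,
inflow count) have grades reversed so 5 is always favourable. The radar
cohort is all occupied ponds.

Source–sink labels are rule-based and total: unoccupied (autumn count 0);
source (density grade ≥ 4 and Hd grade ≥ 4, and overwintering not observed
to fail: rate ≥ 0.25, or no usable rate because the pond fell under the
inclusion rule); sink (included pond with rate < 0.10, or density grade ≤ 2
with a spring collapse below a quarter of the autumn count); otherwise
intermediate. These four thresholds are configuration defaults chosen so
the labels reproduce the bundled survey's exemplar source and sink ponds;
they are not field-measured constants and are exposed in the
`sourcesink` config block.

The GLM engine is iteratively reweighted least squares with canonical links
(logit for binomial — grouped successes/trials or Bernoulli — log for
Poisson), convergence on relative deviance change < 1e-9 within 100
iterations, and Wald z / two-sided p per coefficient. Perfect separation is
detected from numerically saturated fitted probabilities and flagged as
non-convergence with the last coefficients still reported. The fixed-effects
binomial GLM also stands in for mixed-model fits of overwintering success:
with one observation per pond a pond-level random intercept is
unidentifiable, so no random-effect structure is estimated.

## Synthetic basin generator

The generator emulates the survey's statistical shape: a 658-bp COI
alignment (the Folmer-primer fragment length — a convention, the survey
does not print it); one central haplotype at 79% of the basin pool (the
observed dominant-haplotype share); 26 haplotypes at 1–6 substitutions from
the centre with geometrically decaying frequencies (decay 0.6), mutations
at globally distinct positions (infinite-sites approximation, so Hamming
distance equals true steps); 25 ponds with 20 genotyped specimens each,
drawn multinomially.

Planted structure uses three frequency reallocations, always taken from the
central haplotype: (i) four geographic clusters of ponds, each cluster
marked by two private haplotypes carrying 0.30 of local mass; (ii) a
west–east cline moving `ibd_slope` (default 0.012) of mass per km between
the two most divergent non-private derived haplotypes, over a 25-km basin;
(iii) overwintering: autumn counts Poisson(25), spring counts binomial with
logit(survival) = −0.756 − 0.0307 × concrete revetment %, the GLM estimates
obtained from the survey's eight printed autumn/spring pairs, with concrete
rates uniform on [0, 100]. Private haplotypes attach directly to the centre
(single-step), matching the observed star-like network and keeping
between-cluster sequence divergence uniform so the cline carries the
distance gradient.

The planted masses are deliberately strong enough for the planted partition
and cline to be identifiable from 20-specimen multinomial samples —
per-pond dominance of the central haplotype is correspondingly weaker
(~0.19–0.49) than in the real basin (0.6–0.95). Passing recovery tests
therefore demonstrates that the pipeline finds structure of this planted
magnitude at survey-scale sampling; they do not certify power against the
weaker, unbalanced structure of the real basin. Other simplifications: no
back-mutation, no selection, no within-season drift, environment factors
drawn independently of each other and of the genetic structure.

All randomness derives from one top-level seed; stage k draws from
`numpy.random.default_rng([seed, k])`, so any stage replays in isolation.

## Problem sizes in the test suite

Stochastic recovery checks run at the generator's default scale
(25 ponds × 20 specimens): cluster recovery over 20 seeds (mean adjusted
Rand), GLM slope coverage over 100 basins, Mantel power over 100 basins
with 999 permutations each, GLM and Mantel type-I behaviour over 200
replicates, and Mantel p-value uniformity over 500 independent random-matrix
pairs with 199 permutations. Oracle-equivalence checks use exhaustive or
brute-force references at small n (Ward ≤ 6 leaves, network ≤ 7 haplotypes,
exact Mantel at n = 5).

## Known limitations

- Per-pond π values cannot be certified against the published table without
  the deposited sequences: the haplotype step matrix is only depicted, not
  tabulated, in the source survey; π is exercised against brute-force
  oracles and on synthetic alignments instead.
- The Chao–Jaccard/Ward chain treats the corrected dissimilarity as the
  clustering metric directly; the source survey does not state its
  intermediate data object.
- One published overwintering percentage (1/44 shown as 2.2%) is
  floor-rounded in the source text; the package reports 2.27% and the test
  holds it to one unit in the last printed digit.
- Right-censored transparency readings (">100 cm") keep the bound and a
  flag; downstream grading would treat the bound as the value, and
  transparency is not among the default radar axes.
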