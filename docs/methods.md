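# Methods

This note documents the statistical definitions, numerical conventions and
design choices behind `fishdiv`, in the spirit of a package methods
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A survey year is a `CommunityMatrix`: sites in rows, species in columns,
entries either individual counts (integers) or biomass in grams (reals).
Counts and biomass are separate instances, never mixed in one matrix.  A
species is "present" in a year only if its total abundance that year is
positive; zero columns are treated as absences everywhere (species lists
are observation-based).  Site labels are free strings and each year's site
set is taken as given — no reconciliation of site names across years is
attempted, since repeated surveys commonly add or drop a station.

## Alpha diversity and dominance

All indices use natural logarithms and are computed at full precision;
rounding (2 dp for indices, 3 dp for MPD/NRI) happens only in display.

- Shannon–Wiener `H = −Σ pᵢ ln pᵢ` with `pᵢ = Nᵢ/ΣNⱼ`; zero abundances are
  skipped.
- Margalef `D = (S−1)/ln N`; undefined (error) for `N < 2`.
- Gini–Simpson `F = 1 − Σ pᵢ²`.  Survey reports sometimes label this a
  "dominance" index even though it *increases* with evenness; the formula
  is implemented exactly as written and the naming tension is left to the
  caller's interpretation.
- Pielou `J = H/ln S`; reported as missing with a warning for `S < 2`.
- Pooled (reserve-level) indices are computed on counts summed across
  sites, not on averaged per-site indices — consistent with reporting one
  total N per year.
- IRI per species is `(%N + %W) × f` with `%N`, `%W` shares of total
  individuals and total biomass on the 0–100 scale and `f` the fraction of
  sites occupied on 0–1, so the maximum is 200.  The default dominance
  cutoff is IRI ≥ 10; field studies rarely print their cutoff, so it is a
  configurable parameter, and the *ranking* is what the analysis relies
  on (it is invariant to rescaling all weights).
- Chao1 uses the classical estimator `S_obs + f₁²/(2f₂)` with the
  bias-corrected fallback `S_obs + f₁(f₁−1)/2` when there are no
  doubletons; "sampling completeness" is `S_obs/chao1`.  Rarefaction is
  the exact hypergeometric expectation
  `E[S_m] = Σᵢ (1 − C(N−Nᵢ, m)/C(N, m))`, evaluated on a log-gamma scale;
  extrapolation beyond N (coverage-based estimation, bootstrap CIs) is
  deliberately out of scope.

## Beta diversity

For one site pair with `a` shared species and `b`, `c` uniques:
`βsor = (b+c)/(2a+b+c)`, `βsim = min(b,c)/(a+min(b,c))`,
`βsne = βsor − βsim`.  The additive identity holds to 1e−12 by
construction and is fuzz-tested.  Two aggregate modes are provided: the
arithmetic mean over all site pairs (the default, matching analyses that
describe "each pair of sampling sites") and the Baselga multiple-site
form built from `Σ min(b_ij, b_ji)` and `Σ max(b_ij, b_ji)` with the
shared core `ΣSᵢ − S_T`.  Species unseen in a year are dropped before
partitioning (they change nothing but would clutter incidence tables).
Homogenization is the exact difference
`Δβsor = βsor(earlier) − βsor(later)`; no rounding is applied by the
operation itself, so a report that prints rounded annual values can show
a delta that differs from the difference of its printed inputs.

## Assemblage structure

Counts are fourth-root transformed (`x^(1/4)`) before Bray–Curtis.  The
intent of that transform is to *damp* the influence of very abundant
species; the phrase "converted to the fourth power" in some survey
write-ups refers to this root transform — raising counts to the fourth
power would do the opposite.

- Bray–Curtis `d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)`; a pair of empty sites gets
  d = 0 by convention with a warning.
- UPGMA via group-average agglomerative linkage; merge heights are
  non-decreasing and reproduce ultrametric inputs exactly.  The exported
  newick places nodes at height/2 so tip-to-tip path lengths equal merge
  heights.
- NMDS minimizes Kruskal stress-1
  `sqrt(Σ(d̂ᵢⱼ − δ̂ᵢⱼ)²/Σ d̂ᵢⱼ²)` with weak (primary) monotone regression,
  SMACOF iterations, 50 random restarts by default, and a mandatory seed;
  the best configuration is returned centered at the origin.  Two
  dimensions are the default (the dimensionality used by typical survey
  ordinations).
- ANOSIM ranks all pairwise dissimilarities (average ranks on ties) and
  computes `R = (r̄_between − r̄_within)/(M/2)`, `M = n(n−1)/2`; the
  one-sided p-value uses random label permutations with the
  `(count ≥ observed + 1)/(n_perm + 1)` estimator, 999 permutations by
  default.  The statistic is R (in [−1, 1]); reports that print "R²" for
  this test are mislabeling the same statistic.
- SIMPER averages the species-wise terms `|xᵢ−yᵢ|/Σⱼ(xⱼ+yⱼ)` over all
  between-group site pairs, on the *same* fourth-root-transformed matrix
  used for Bray–Curtis; the contributions sum exactly to the average
  between-group dissimilarity (tested to 1e−9).
- Group labels for ANOSIM/SIMPER should come from an a-priori assignment
  so that clustering and testing stay independent; as a convenience, the
  workflow cuts the UPGMA dendrogram into three flat groups when no
  labels are supplied (mirroring the common three-group structure of
  small stream surveys).

## Phylogenetic community structure

Distances from an aligned single-marker FASTA use pairwise deletion
(sites with a gap/ambiguity in either sequence are excluded for that
pair).  The default model is Kimura two-parameter,
`d = ½ ln(1/(1−2P−Q)) + ¼ ln(1/(1−2Q))` with P, Q the transition and
transversion proportions — the conventional default of desktop
phylogenetics tools when no model is stated; p-distance is available.
Saturated pairs (non-positive log argument) are an error rather than a
silent NaN.

Neighbor joining follows Saitou–Nei exactly (Q-criterion, canonical split
branch lengths, negative estimates clamped to 0 with a warning) and is
exact on additive matrices — property-tested by round-tripping random
pure-birth trees through their cophenetic matrices, and cross-checked
against an independent NJ implementation.

MPD is the unweighted mean cophenetic distance over unordered pairs of
present species.  The null model is richness-preserving uniform sampling
without replacement from the species pool (identical in distribution to
shuffling tip labels), 999 draws by default.  The pool is the set of all
species recorded in that survey year; per-site NRI is computed against
this common year pool.  A consequence is that the pooled "Total"
community, which equals its own pool, has a degenerate null (SD = 0) and
an undefined NRI — pass the union of both years as the pool if an
informative Total row is wanted.  The null SD uses the population
(divide-by-n) form; at 999 draws it differs from the sample form by
< 0.1%.

The sign convention is `NRI = (mean(MPD_null) − MPD_obs)/SD(MPD_null)`,
i.e. −1 × SES(MPD): positive NRI means observed co-occurring species are
*closer* than the null expects (clustering → environmental filtering),
negative means overdispersion (→ competition).  Published tables
sometimes display the formula with the opposite difference while
tabulating values consistent only with this convention; the convention
that reproduces tabulated values is the one implemented.  Communities
with fewer than 2 species have undefined MPD and get an NA row.

## Synthetic surveys

The generator emulates the study design the pipeline targets, not any
particular dataset's numbers:

- 13 sites on a one-dimensional habitat gradient; a 17-species year-A
  pool plus 4 later newcomers, all tips of one pure-birth (Yule) tree
  scaled to height 0.3 expected substitutions/site (crown start; the
  expected lineage count at time t is 2e^(λt)).
- Species mean abundances are lognormal with σ = 1.5 (a handful of
  strongly dominant species, as in small stream-fish surveys); per-site
  counts are 1 + Poisson draws with a lognormal site effect.
- Occupancy follows Gaussian niches (breadth 0.22 on the unit gradient,
  peak occupancy 0.85), which makes among-site beta diversity
  turnover-dominated.
- Assembly modes share one successive-sampling code path: *neutral*
  weights species by niche match only; *filtering* multiplies weights by
  `exp(−strength · 3d(i, focal)/d̄)` toward a site-specific focal species,
  clustering co-occurring species on the tree; *competition* multiplies a
  candidate's weight after each pick by `(d/d_max)^(4·strength)`,
  repelling close relatives.  At strength 0 all three modes coincide
  exactly.
- Year B removes the 5 lowest-occupancy species (surveys lose rare
  specialists first; uniform-random loss is available), adds the 4
  newcomers, widens niches by ×1.35 (driving homogenization) and raises
  the dominance exponent to 1.6 (driving the evenness decline).
- Sequences evolve down the tree under the same K2P process the distance
  estimator assumes (closed-form branch transition probabilities,
  transition/transversion ratio κ = 3 by default, L = 1071 bp), so NJ on
  simulated alignments recovers most true splits at that length.
- Biomass = counts × per-species lognormal mean weight (median 20 g,
  right-skewed), used only by IRI.

What the generator does *not* emulate: spatially explicit river networks,
detection error, gear selectivity, temporal autocorrelation within a
year, or any fitting to a real survey's tables.  Passing tests therefore
demonstrate correctness of the statistics and recoverability of the
built-in assembly signals under these idealized conditions — not
agreement with any particular field dataset.

## Reproducibility and problem sizes

Every stochastic operation takes a seed; the workflow derives per-stage
seeds from one master seed via named `SeedSequence` substreams and
records them in a run manifest, so reruns are bit-identical.  The test
suite's statistical checks use the design-scale replicate counts (500
null ANOSIM simulations, 200 assembly-recovery replicates per scenario,
100 NJ oracle trees, 10³ SIMPER fuzz cases) with 99–199 permutations or
null draws inside each replicate — the package's standard small-replicate
settings for distribution-level assertions; the 999-draw defaults apply
to real analyses.

## Known limitations

- No Hill-number framework, coverage-based extrapolation, or bootstrap
  confidence intervals for alpha diversity.
- No abundance-weighted beta partition (Bray–Curtis family partitioning),
  PERMANOVA, NTI/MNTD, abundance-weighted MPD, or bootstrap support on
  trees.
- NMDS uses SMACOF with monotone regression; like all NMDS it can land in
  local minima — raise `n_restarts` for hard matrices.
- The K2P simulator and estimator share the substitution model; model
  misspecification effects on NRI are not explored.
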