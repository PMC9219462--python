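# fishdiv

Multi-faceted analysis of repeated freshwater-fish surveys: species
diversity, assemblage structure, and phylogenetic community structure, in
one reproducible Python pipeline.

The motivating setting is a small mountain-stream reserve surveyed in two
years (~13 streams, 16–17 species, a few strongly dominant species),
where the questions are: did diversity decline, did the fauna homogenize
across sites, do site groups differ in composition, and is community
assembly driven by environmental filtering or by competition?  `fishdiv`
implements every statistic of that workflow over a common site × species
data model, plus a synthetic survey generator with ground truth so the
whole pipeline is testable end to end without field data.

## What it computes

**Alpha diversity and dominance** (per site and pooled, natural logs):
Shannon–Wiener *H* = −Σ pᵢ ln pᵢ, Margalef *D* = (S−1)/ln N, Gini–Simpson
*F* = 1 − Σ pᵢ², Pielou *J* = H/ln S; dominant species by the index of
relative importance IRI = (%N + %W) × f (percentages 0–100, occurrence
frequency f 0–1, maximum 200); sampling completeness via Chao1
(S_obs + f₁²/2f₂) and exact abundance-based rarefaction.

**Beta diversity and homogenization**: Sørensen dissimilarity partitioned
additively into spatial turnover and nestedness, βsor = βsim + βsne, both
as the mean over site pairs and in the Baselga multiple-site form;
Δβsor = βsor(earlier) − βsor(later) > 0 indicates biotic homogenization.

**Assemblage structure** (the PRIMER-style workflow): fourth-root
transform, Bray–Curtis dissimilarity Σ|x−y|/Σ(x+y), UPGMA clustering,
non-metric MDS minimizing Kruskal stress-1, ANOSIM
R = (r̄_between − r̄_within)/(M/2) with permutation p-values, and SIMPER
per-species decomposition of between-group dissimilarity.

**Phylogenetic structure**: Kimura two-parameter (or p-) distances from an
aligned single-marker FASTA (e.g. 1071-bp cytochrome b), Saitou–Nei
neighbor joining, cophenetic distances, observed mean pairwise distance
MPD per community, a richness-preserving taxa-shuffle null model (999
draws), and the net relatedness index

    NRI = (mean(MPD_null) − MPD_obs) / SD(MPD_null)

with NRI > 0 read as phylogenetic clustering (environmental filtering)
and NRI < 0 as overdispersion (competition).

## Worked example

`examples/full_report.py` simulates a default two-year survey and runs the
complete analysis:

```
Pooled alpha indices (year A -> year B):
  H 1.78 -> 1.56   D 1.96 -> 1.85   J 0.63 -> 0.56
Turnover: lost 5, gained 4; beta_sor 0.68 -> 0.61 (delta +0.072, homogenization)
ANOSIM: year A R=0.603 (p=0.005), year B R=0.655 (p=0.001)
NMDS stress: 0.120 / 0.144
NRI calls year A: {'environmental_filtering': 10, 'competition': 3, 'indeterminate': 1}
NRI calls year B: {'environmental_filtering': 7, 'competition': 6, 'indeterminate': 1}
```

Read: diversity and evenness fell between the two years while five
species disappeared and four appeared; among-site dissimilarity dropped
(positive Δβsor — the fauna homogenized); site groups differ significantly
in composition (ANOSIM R with p < 0.05 at interpretable NMDS stress); and
most sites show positive NRI, i.e. co-occurring species are closer
relatives than random draws from the year's species pool — the signature
of environmental filtering, which is exactly the assembly rule this
bundle was generated under.

The other scripts in `examples/` exercise each capability on its own
(alpha/IRI/Chao1, beta partition + homogenization, ordination + ANOSIM +
SIMPER, sequences → NJ → NRI, and writing a full synthetic bundle to
disk).

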