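"""Phylogenetic community structure: sequences -> K2P -> NJ -> MPD -> NRI.

Simulates a cytochrome-b-like alignment on a known tree, rebuilds the tree
by neighbor joining, and scores each site's net relatedness index against a
taxa-shuffle null model.
"""

from fishdiv import (
    ScenarioConfig,
    assemble_communities,
    cophenetic,
    k2p_distance,
    nj_tree,
    nri_table,
)

bundle = assemble_communities(ScenarioConfig(seed=42, assembly="filtering"))
print(f"Alignment: {bundle.sequences.n} species x {bundle.sequences.length} bp")

dist = k2p_distance(bundle.sequences)
tree = nj_tree(dist)
print("NJ tree (newick, truncated):", str(tree)[:90], "...")

table = nri_table(bundle.counts_a, cophenetic(tree), n_rand=999, seed=0)
print("\nPer-site NRI (null mean, observed MPD, null SD, NRI, call):")
print(table.round(3))
# NRI > 0: co-occurring species are closer relatives than random draws from
# the year's pool predict -> phylogenetic clustering, read as environmental
# filtering.  NRI < 0 -> overdispersion, read as competition.  This bundle
# was generated under filtering, so most sites should come out positive.
calls = table["assembly_call"].value_counts()
print("\nAssembly calls:", dict(calls))
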