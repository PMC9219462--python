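"""End-to-end two-year survey analysis.

``run_full_analysis`` chains every stage on a pair of survey years: alpha
indices per river and pooled, dominance (IRI), sampling completeness, the
Sørensen turnover/nestedness partition and the temporal homogenization
contrast, fourth-root Bray–Curtis with UPGMA/NMDS/ANOSIM/SIMPER, and the
NJ-tree MPD/NRI table per year.  All stochastic stages draw from named
substreams of one master seed, so a rerun with the same inputs and seed is
bit-identical; the :class:`RunManifest` records enough to prove it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alpha as alpha_mod
from . import assemblage as asm
from . import beta as beta_mod
from . import phylo
from .community import CommunityMatrix, compare_species_lists

__all__ = ["RunManifest", "AnalysisReport", "run_full_analysis"]

_STAGES = ("nmds_a", "nmds_b", "anosim_a", "anosim_b", "nri_a", "nri_b")


@dataclass
class RunManifest:
    """Reproducibility record: seeds per stochastic stage plus input digests."""

    master_seed: int
    stage_seeds: dict
    input_digests: dict
    config: dict
    version: str = "0.1.0"

    def to_json(self) -> str:
        return json.dumps(
            {
                "master_seed": self.master_seed,
                "stage_seeds": self.stage_seeds,
                "input_digests": self.input_digests,
                "config": self.config,
                "version": self.version,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class AnalysisReport:
    """All stage outputs of one two-year analysis, untouched by rounding."""

    alpha_a: pd.DataFrame
    alpha_b: pd.DataFrame
    dominance_a: pd.DataFrame
    dominance_b: pd.DataFrame
    completeness_a: alpha_mod.CompletenessReport
    completeness_b: alpha_mod.CompletenessReport
    turnover: object
    beta_a: beta_mod.BetaPartition
    beta_b: beta_mod.BetaPartition
    beta_multisite_a: beta_mod.BetaPartition
    beta_multisite_b: beta_mod.BetaPartition
    homogenization: beta_mod.HomogenizationReport
    bray_a: asm.DissimilarityMatrix
    bray_b: asm.DissimilarityMatrix
    dendrogram_a: asm.Dendrogram
    dendrogram_b: asm.Dendrogram
    nmds_a: asm.NMDSResult
    nmds_b: asm.NMDSResult
    anosim_a: asm.AnosimResult
    anosim_b: asm.AnosimResult
    simper_a: dict
    simper_b: dict
    nri_a: pd.DataFrame
    nri_b: pd.DataFrame
    groups_a: dict
    groups_b: dict
    manifest: RunManifest = field(default=None)


def _digest(cm: CommunityMatrix) -> str:
    payload = cm.data.to_csv().encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _stage_seeds(master_seed: int) -> dict:
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {name: int(child.generate_state(1)[0] % (2**31)) for name, child in zip(_STAGES, children)}


def run_full_analysis(
    counts_a: CommunityMatrix,
    counts_b: CommunityMatrix,
    *,
    biomass_a: CommunityMatrix | None = None,
    biomass_b: CommunityMatrix | None = None,
    species_distances: phylo.DissimilarityMatrix | None = None,
    sequences: phylo.SequenceSet | None = None,
    tree=None,
    groups_a: dict | None = None,
    groups_b: dict | None = None,
    n_groups: int = 3,
    n_rand: int = 999,
    n_permutations: int = 999,
    nmds_restarts: int = 50,
    seed: int = 0,
) -> AnalysisReport:
    """Run the complete two-year analysis and return every stage's output.

    Phylogenetic input is, in order of precedence, ``species_distances``
    (a cophenetic matrix), ``tree`` (newick-style TreeNode), or
    ``sequences`` (aligned FASTA -> K2P -> NJ).  ANOSIM/SIMPER groups per
    year default to cutting the UPGMA dendrogram into ``n_groups`` flat
    clusters when no explicit labels are given (a convenience; supply
    labels to keep clustering and testing independent).
    """
    # --- phylogeny -> species distance matrix ---------------------------------
    if species_distances is None:
        if tree is None:
            if sequences is None:
                raise ValueError("need species_distances, tree, or sequences")
            tree = phylo.nj_tree(phylo.k2p_distance(sequences))
        species_distances = phylo.cophenetic(tree)
    covered = set(species_distances.labels)
    for cm in (counts_a, counts_b):
        missing = [s for s in cm.species_present() if s not in covered]
        if missing:
            raise ValueError(
                f"species in year {cm.year} matrix missing from the phylogeny: {sorted(missing)}"
            )

    seeds = _stage_seeds(seed)

    # --- alpha / dominance / completeness -------------------------------------
    alpha_a = alpha_mod.alpha_table(counts_a)
    alpha_b = alpha_mod.alpha_table(counts_b)
    dominance_a = (
        alpha_mod.iri(counts_a, biomass_a) if biomass_a is not None else None
    )
    dominance_b = (
        alpha_mod.iri(counts_b, biomass_b) if biomass_b is not None else None
    )
    completeness_a = alpha_mod.completeness_report(counts_a.pooled_counts().to_numpy())
    completeness_b = alpha_mod.completeness_report(counts_b.pooled_counts().to_numpy())
    turnover = compare_species_lists(counts_a, counts_b)

    # --- beta diversity / homogenization --------------------------------------
    beta_a = beta_mod.mean_pairwise_partition(counts_a)
    beta_b = beta_mod.mean_pairwise_partition(counts_b)
    beta_ms_a = beta_mod.multisite_partition(counts_a)
    beta_ms_b = beta_mod.multisite_partition(counts_b)
    homog = beta_mod.homogenization(beta_a, beta_b)

    # --- assemblage structure ---------------------------------------------------
    def structure(cm: CommunityMatrix, groups: dict | None, which: str):
        transformed = asm.fourth_root_transform(cm)
        bray = asm.bray_curtis(transformed)
        dendro = asm.upgma(bray)
        ordination = asm.nmds(
            bray, n_restarts=nmds_restarts, seed=seeds[f"nmds_{which}"]
        )
        if groups is None:
            groups = dendro.cut(n_groups)
        result_anosim = asm.anosim(
            bray, groups, n_permutations=n_permutations, seed=seeds[f"anosim_{which}"]
        )
        simper_tables = {}
        group_ids = sorted(set(groups.values()), key=str)
        for i, g1 in enumerate(group_ids):
            for g2 in group_ids[i + 1 :]:
                simper_tables[(g1, g2)] = asm.simper(transformed, groups, (g1, g2))
        return bray, dendro, ordination, result_anosim, simper_tables, groups

    bray_a, dendro_a, nmds_a, anosim_a, simper_a, groups_a = structure(
        counts_a, groups_a, "a"
    )
    bray_b, dendro_b, nmds_b, anosim_b, simper_b, groups_b = structure(
        counts_b, groups_b, "b"
    )

    # --- phylogenetic community structure --------------------------------------
    nri_a = phylo.nri_table(
        counts_a, species_distances, n_rand=n_rand, seed=seeds["nri_a"]
    )
    nri_b = phylo.nri_table(
        counts_b, species_distances, n_rand=n_rand, seed=seeds["nri_b"]
    )

    manifest = RunManifest(
        master_seed=seed,
        stage_seeds=seeds,
        input_digests={
            "counts_a": _digest(counts_a),
            "counts_b": _digest(counts_b),
        },
        config={
            "n_rand": n_rand,
            "n_permutations": n_permutations,
            "nmds_restarts": nmds_restarts,
            "n_groups": n_groups,
        },
    )
    return AnalysisReport(
        alpha_a=alpha_a,
        alpha_b=alpha_b,
        dominance_a=dominance_a,
        dominance_b=dominance_b,
        completeness_a=completeness_a,
        completeness_b=completeness_b,
        turnover=turnover,
        beta_a=beta_a,
        beta_b=beta_b,
        beta_multisite_a=beta_ms_a,
        beta_multisite_b=beta_ms_b,
        homogenization=homog,
        bray_a=bray_a,
        bray_b=bray_b,
        dendrogram_a=dendro_a,
        dendrogram_b=dendro_b,
        nmds_a=nmds_a,
        nmds_b=nmds_b,
        anosim_a=anosim_a,
        anosim_b=anosim_b,
        simper_a=simper_a,
        simper_b=simper_b,
        nri_a=nri_a,
        nri_b=nri_b,
        groups_a=groups_a,
        groups_b=groups_b,
        manifest=manifest,
    )
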