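"""Abundance-based assemblage structure.

The workflow mirrors the standard PRIMER-style analysis of survey count
matrices: a fourth-root transform to damp the influence of highly abundant
species, Bray–Curtis dissimilarity between sites, group-average (UPGMA)
clustering, non-metric multidimensional scaling (NMDS, Kruskal stress-1),
an ANOSIM permutation test for differences between a-priori site groups,
and SIMPER decomposition of the average between-group dissimilarity into
per-species contributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.manifold import MDS

from .community import CommunityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DissimilarityMatrix",
    "Dendrogram",
    "NMDSResult",
    "AnosimResult",
    "fourth_root_transform",
    "bray_curtis",
    "upgma",
    "nmds",
    "anosim",
    "simper",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal, values in [0, 1]."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        if not np.isfinite(v).all():
            raise ValueError("non-finite dissimilarities")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    """Group-average dendrogram: scipy linkage matrix plus leaf labels."""

    labels: list
    linkage_matrix: np.ndarray

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, n_groups: int) -> dict:
        """Cut into ``n_groups`` flat clusters; returns {label: group_id}."""
        assignments = fcluster(self.linkage_matrix, t=n_groups, criterion="maxclust")
        return dict(zip(self.labels, (int(g) for g in assignments)))

    def to_newick(self) -> str:
        """Ultrametric newick; tip-to-tip path length equals the merge height."""
        root = to_tree(self.linkage_matrix)

        def render(node, parent_height):
            height = node.dist / 2.0
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height - 0.0:.10g}"
            left = render(node.left, height)
            right = render(node.right, height)
            return f"({left},{right}):{parent_height - height:.10g}"

        h = root.dist / 2.0
        left = render(root.left, h)
        right = render(root.right, h)
        return f"({left},{right});"


@dataclass
class NMDSResult:
    configuration: pd.DataFrame  # n_sites x k
    stress: float
    n_restarts: int
    converged: bool
    seed: int


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int


def fourth_root_transform(cm: CommunityMatrix) -> CommunityMatrix:
    """Fourth-root transform x -> x^(1/4), damping dominant-species influence."""
    if (cm.data.to_numpy() < 0).any():
        raise ValueError("negative abundances")
    return CommunityMatrix(
        cm.data.astype(float) ** 0.25, year=cm.year, kind="biomass"
    )


def bray_curtis(cm: CommunityMatrix) -> DissimilarityMatrix:
    """Bray–Curtis dissimilarity d(x, y) = Σ|x_i − y_i| / Σ(x_i + y_i).

    A pair of empty sites gets d = 0 by convention, with a warning.
    """
    x = cm.data.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    n = x.shape[0]
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        denom = (x[i] + x[j]).sum()
        if denom == 0:
            logger.warning(
                "sites %r and %r are both empty; Bray-Curtis set to 0",
                cm.site_ids[i],
                cm.site_ids[j],
            )
            d = 0.0
        else:
            d = float(np.abs(x[i] - x[j]).sum() / denom)
        out[i, j] = out[j, i] = d
    return DissimilarityMatrix(labels=list(cm.site_ids), values=out)


def upgma(dm: DissimilarityMatrix) -> Dendrogram:
    """Group-average agglomerative clustering; merge heights are non-decreasing."""
    if dm.n < 2:
        raise ValueError("need at least 2 sites to cluster")
    return Dendrogram(labels=list(dm.labels), linkage_matrix=linkage(dm.condensed(), method="average"))


def nmds(
    dm: DissimilarityMatrix,
    *,
    k: int = 2,
    n_restarts: int = 50,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int = 0,
) -> NMDSResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    SMACOF iterations with weak (primary) monotone regression of the
    disparities; the best of ``n_restarts`` random starts is returned,
    centered at the origin.  Stress-1 = sqrt(Σ(d̂ − δ̂)² / Σ d̂²).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    model = MDS(
        n_components=k,
        metric="precomputed",
        metric_mds=False,
        n_init=n_restarts,
        max_iter=max_iter,
        eps=tol,
        init="random",
        normalized_stress=True,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords = model.fit_transform(dm.values)
    coords = coords - coords.mean(axis=0)
    config = pd.DataFrame(
        coords, index=dm.labels, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return NMDSResult(
        configuration=config,
        stress=float(model.stress_),
        n_restarts=n_restarts,
        converged=bool(model.n_iter_ < max_iter),
        seed=seed,
    )


def _anosim_r(ranks: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    m = n * (n - 1) / 2
    r_within = ranks[within_mask].mean()
    r_between = ranks[~within_mask].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(
    dm: DissimilarityMatrix,
    groups,
    *,
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """ANOSIM: rank-based test of between- vs within-group dissimilarity.

    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2 pairwise dissimilarities (average ranks on ties).  The
    one-sided p-value uses random label permutations with the
    (count ≥ observed + 1)/(n_permutations + 1) estimator.
    """
    if isinstance(groups, dict):
        labels = np.asarray([groups[s] for s in dm.labels])
    else:
        labels = np.asarray(list(groups))
    n = dm.n
    if labels.size != n:
        raise ValueError("one group label per site required")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    ranks = rankdata(dm.condensed())
    ii, jj = np.triu_indices(n, k=1)
    within = labels[ii] == labels[jj]
    if within.all():
        raise ValueError("a single group contains all sites")
    r_obs = _anosim_r(ranks, within, n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        w = perm[ii] == perm[jj]
        if _anosim_r(ranks, w, n) >= r_obs:
            count += 1
    return AnosimResult(
        R=r_obs,
        p_value=(count + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
    )


def simper(
    cm: CommunityMatrix,
    groups,
    pair: tuple,
) -> pd.DataFrame:
    """SIMPER: per-species contributions to between-group Bray–Curtis.

    For every between-group site pair the species-i term
    |x_i − y_i| / Σ_j (x_j + y_j) is computed and averaged over pairs; the
    contributions sum to the average between-group dissimilarity.  Columns:
    ``average_dissimilarity`` (species contribution), ``contribution_pct``,
    ``cumulative_pct``; rows sorted by contribution descending.

    ``cm`` should be the same (typically fourth-root-transformed) matrix
    used for the Bray–Curtis analysis.
    """
    if isinstance(groups, dict):
        labels = np.asarray([groups[s] for s in cm.site_ids])
    else:
        labels = np.asarray(list(groups))
    g1, g2 = pair
    idx1 = np.flatnonzero(labels == g1)
    idx2 = np.flatnonzero(labels == g2)
    if idx1.size == 0 or idx2.size == 0:
        raise ValueError(f"empty group in pair {pair!r}")
    if set(idx1) & set(idx2):
        raise ValueError("groups overlap")
    x = cm.data.to_numpy(dtype=float)
    contrib = np.zeros(x.shape[1])
    n_pairs = 0
    for i, j in product(idx1, idx2):
        denom = (x[i] + x[j]).sum()
        if denom == 0:
            continue
        contrib += np.abs(x[i] - x[j]) / denom
        n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no comparable between-group pairs")
    contrib /= n_pairs
    avg_diss = contrib.sum()
    out = pd.DataFrame(
        {
            "average_dissimilarity": contrib,
            "contribution_pct": 100.0 * contrib / avg_diss if avg_diss > 0 else 0.0,
        },
        index=cm.species_ids,
    ).sort_values("average_dissimilarity", ascending=False)
    out["cumulative_pct"] = out["contribution_pct"].cumsum()
    out.attrs["average_dissimilarity"] = float(avg_diss)
    out.attrs["groups"] = (g1, g2)
    return out
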