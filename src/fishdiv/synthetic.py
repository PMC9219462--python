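"""Synthetic two-year river-survey datasets with known structure.

The generator emulates the statistical shape of a small mountain-stream
fish survey repeated in two years: ~13 sites, a pool of 16–17 species with
a few strongly dominant ones, turnover-dominated beta diversity along a
habitat gradient, a handful of species lost and gained between years, and
co-occurrence that is phylogenetically clustered (environmental filtering),
overdispersed (competition) or neutral.  Every stage of the analysis
pipeline can therefore be exercised, with ground truth, without any real
survey or sequence data.

All randomness flows from ``ScenarioConfig.seed`` through named
substreams, so the same config yields a bit-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community import CommunityMatrix
from .phylo import SequenceSet, cophenetic, DissimilarityMatrix

__all__ = ["ScenarioConfig", "SyntheticBundle", "yule_tree", "evolve_sequences", "assemble_communities"]


@dataclass
class ScenarioConfig:
    """Parameters of one simulated two-year survey.

    Defaults mirror the motivating study design: 13 sites, a 17-species
    year-A pool, 4-ish strongly dominant species (lognormal rank-abundance,
    sigma ``dominance_shape``), 5 species lost and 4 gained by year B, and
    a niche gradient strong enough that among-site beta diversity is
    dominated by spatial turnover.
    """

    n_sites: int = 13
    pool_size: int = 17
    species_lost: int = 5
    species_gained: int = 4
    dominance_shape: float = 1.5  # lognormal sigma of species mean abundances
    mean_abundance: float = 7.0  # lognormal scale (median individuals/site)
    niche_breadth: float = 0.22  # Gaussian niche width on the [0,1] gradient
    max_occupancy: float = 0.85  # inclusion probability at the niche optimum
    assembly: str = "filtering"  # neutral | filtering | competition
    filtering_strength: float = 0.8  # 0 = neutral, 1 = strong
    evenness_decay: float = 1.6  # year-B exponent on species abundances
    breadth_widening: float = 1.35  # year-B niche-breadth factor (homogenization)
    abundance_growth: float = 1.3  # year-B multiplier on total catch
    loss_mode: str = "lowest-occupancy"  # or "random"
    tree_height: float = 0.3  # expected substitutions/site, root to tip
    birth_rate: float = 1.0
    seq_length: int = 1071
    kappa: float = 3.0  # transition/transversion ratio of the simulator
    mean_weight_g: float = 20.0  # median per-individual weight
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < self.species_lost + 2:
            raise ValueError("pool_size must be at least species_lost + 2")
        if self.assembly not in ("neutral", "filtering", "competition"):
            raise ValueError(f"unknown assembly mode {self.assembly!r}")
        if not 0.0 <= self.filtering_strength <= 1.0:
            raise ValueError("filtering_strength must lie in [0, 1]")
        for name in ("max_occupancy",):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class SyntheticBundle:
    """One simulated survey: matrices, phylogeny, sequences and ground truth."""

    config: ScenarioConfig
    counts_a: CommunityMatrix
    counts_b: CommunityMatrix
    biomass_a: CommunityMatrix
    biomass_b: CommunityMatrix
    tree: TreeNode
    distances: DissimilarityMatrix  # cophenetic, full two-year pool
    sequences: SequenceSet | None
    truth: dict = field(default_factory=dict)


def yule_tree(
    n_leaves: int,
    *,
    birth_rate: float = 1.0,
    seed=None,
    target_height: float | None = 0.3,
) -> TreeNode:
    """Pure-birth (Yule) tree on ``n_leaves`` tips, crown start.

    Two lineages exist at the root (time 0) and each splits at rate
    ``birth_rate``; the process stops the moment the ``n_leaves``-th
    lineage appears, so all tips are contemporaneous.  If ``target_height``
    is given, branch lengths are rescaled so the root-to-tip height equals
    it (units: expected substitutions/site); ``None`` keeps the raw
    time scale, under which the expected lineage count at time t is
    2 e^(birth_rate * t).
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    active = [TreeNode(), TreeNode()]
    root.extend(active)
    birth = {id(node): 0.0 for node in active}
    t = 0.0
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        node.length = t - birth[id(node)]
        kids = [TreeNode(), TreeNode()]
        for kid in kids:
            birth[id(kid)] = t
        node.extend(kids)
        active.extend(kids)
    for node in active:
        node.length = t - birth[id(node)]
    if target_height is not None and t > 0:
        scale = target_height / t
        for node in root.traverse(include_self=False):
            node.length *= scale
    for i, tip in enumerate(root.tips()):
        tip.name = f"sp{i + 1:02d}"
    return root


def evolve_sequences(
    tree: TreeNode, *, L: int = 1071, kappa: float = 3.0, seed=None
) -> SequenceSet:
    """Simulate a Kimura two-parameter substitution process down the tree.

    The root sequence is uniform over {A, C, G, T}; on a branch of length d
    (expected substitutions/site) each site changes according to the K2P
    transition probabilities with transition/transversion ratio ``kappa``
    (kappa = 0.5 makes all changes equally likely).
    """
    rng = np.random.default_rng(seed)
    beta = 1.0 / (2.0 * kappa + 2.0)
    alpha = kappa / (kappa + 1.0)  # alpha + 2*beta = 1: branch length in subs/site

    transition_partner = np.array([2, 3, 0, 1], dtype=np.uint8)  # A<->G, C<->T
    # the two transversion targets for each base (other chemical class)
    tv1 = np.array([1, 0, 1, 0], dtype=np.uint8)
    tv2 = np.array([3, 2, 3, 2], dtype=np.uint8)

    def step(parent_seq: np.ndarray, d: float) -> np.ndarray:
        if d <= 0:
            return parent_seq.copy()
        e_ts = np.exp(-4.0 * beta * d)
        e_mix = np.exp(-2.0 * (alpha + beta) * d)
        p_ts = 0.25 + 0.25 * e_ts - 0.5 * e_mix
        p_tv_each = 0.25 - 0.25 * e_ts
        u = rng.random(parent_seq.size)
        child = parent_seq.copy()
        ts_mask = u < p_ts
        tv1_mask = (u >= p_ts) & (u < p_ts + p_tv_each)
        tv2_mask = (u >= p_ts + p_tv_each) & (u < p_ts + 2 * p_tv_each)
        child[ts_mask] = transition_partner[parent_seq[ts_mask]]
        child[tv1_mask] = tv1[parent_seq[tv1_mask]]
        child[tv2_mask] = tv2[parent_seq[tv2_mask]]
        return child

    seqs: dict[str, np.ndarray] = {}
    state = {id(tree): rng.integers(0, 4, size=L).astype(np.uint8)}
    for node in tree.preorder(include_self=False):
        parent_seq = state[id(node.parent)]
        child_seq = step(parent_seq, node.length or 0.0)
        state[id(node)] = child_seq
        if node.is_tip():
            seqs[node.name] = child_seq
    ids = [tip.name for tip in tree.tips()]
    return SequenceSet(ids=ids, matrix=np.vstack([seqs[i] for i in ids]))


def _sample_membership(
    rng, weights: np.ndarray, k: int, *, dist: np.ndarray | None, mode: str, strength: float
) -> np.ndarray:
    """Draw ``k`` species without replacement by successive weighted picks.

    Under ``competition`` the weight of a candidate is multiplied after each
    pick by a repulsion factor that penalizes proximity to already-present
    species; with ``strength`` 0 every mode reduces to plain successive
    sampling, so the neutral and zero-strength scenarios coincide exactly.
    """
    n = weights.size
    w = weights.astype(float).copy()
    chosen: list[int] = []
    d_max = dist.max() if dist is not None and dist.max() > 0 else 1.0
    for _ in range(k):
        if w.sum() <= 0:
            w = np.where(w > 0, w, 0.0)
            remaining = [i for i in range(n) if i not in chosen]
            w[remaining] = 1.0
        probs = w / w.sum()
        pick = rng.choice(n, p=probs)
        chosen.append(pick)
        w[pick] = 0.0
        if mode == "competition" and strength > 0:
            # down-weight close relatives of the newly added species
            rel = dist[pick] / d_max
            w *= np.clip(rel, 1e-6, None) ** (4.0 * strength)
    return np.array(sorted(chosen))


def _assemble_year(
    rng,
    species: list,
    optima: np.ndarray,
    breadth: float,
    lam: np.ndarray,
    dist_df: pd.DataFrame,
    cfg: ScenarioConfig,
    site_ids: list,
) -> tuple[pd.DataFrame, dict]:
    n_sites = len(site_ids)
    x = np.linspace(0.0, 1.0, n_sites)
    D = dist_df.loc[species, species].to_numpy()
    d_scale = D[np.triu_indices(len(species), k=1)].mean() if len(species) > 1 else 1.0
    counts = np.zeros((n_sites, len(species)), dtype=np.int64)
    focal: dict = {}
    for s in range(n_sites):
        q = cfg.max_occupancy * np.exp(-((x[s] - optima) ** 2) / (2.0 * breadth**2))
        k = int(np.clip(rng.binomial(len(species), q.mean()), 2, len(species)))
        if cfg.assembly == "filtering" and cfg.filtering_strength > 0:
            f = rng.integers(len(species))
            focal[site_ids[s]] = species[f]
            w = q * np.exp(-cfg.filtering_strength * 3.0 * D[f] / d_scale)
        else:
            w = q
        members = _sample_membership(
            rng, w, k, dist=D, mode=cfg.assembly, strength=cfg.filtering_strength
        )
        site_factor = rng.lognormal(0.0, 0.3)
        counts[s, members] = 1 + rng.poisson(lam[members] * site_factor)
    # every pool species must be observed somewhere this year
    for i in np.flatnonzero(counts.sum(axis=0) == 0):
        best = int(np.argmin(np.abs(x - optima[i])))
        counts[best, i] = 1
    frame = pd.DataFrame(counts, index=site_ids, columns=species)
    return frame, focal


def assemble_communities(
    config: ScenarioConfig, tree: TreeNode | None = None, *, with_sequences: bool = True
) -> SyntheticBundle:
    """Generate a full two-year synthetic survey bundle.

    The phylogeny covers the union pool (``pool_size`` year-A species plus
    ``species_gained`` newcomers).  Year A assembles all pool species over a
    niche gradient; year B drops the ``species_lost`` lowest-occupancy
    species, adds the newcomers, widens niches (homogenization), raises
    total catch, and sharpens dominance (evenness decline).
    """
    cfg = config
    total_pool = cfg.pool_size + cfg.species_gained
    master = np.random.SeedSequence(cfg.seed)
    s_tree, s_seq, s_niche, s_year_a, s_year_b, s_biomass = master.spawn(6)

    if tree is None:
        tree = yule_tree(
            total_pool,
            birth_rate=cfg.birth_rate,
            seed=s_tree,
            target_height=cfg.tree_height,
        )
    tips = [t.name for t in tree.tips()]
    if len(tips) != total_pool:
        raise ValueError(
            f"tree has {len(tips)} leaves; config needs pool_size + species_gained = {total_pool}"
        )
    dist = cophenetic(tree)
    dist_df = dist.to_frame()

    rng_niche = np.random.default_rng(s_niche)
    order = rng_niche.permutation(total_pool)
    pool_a = [tips[i] for i in sorted(order[: cfg.pool_size])]
    gained = [tips[i] for i in sorted(order[cfg.pool_size :])]
    optima_all = {t: u for t, u in zip(tips, rng_niche.random(total_pool))}
    lam_all = {
        t: v
        for t, v in zip(
            tips,
            rng_niche.lognormal(np.log(cfg.mean_abundance), cfg.dominance_shape, total_pool),
        )
    }

    site_ids = [f"site{i + 1:02d}" for i in range(cfg.n_sites)]
    rng_a = np.random.default_rng(s_year_a)
    frame_a, focal_a = _assemble_year(
        rng_a,
        pool_a,
        np.array([optima_all[t] for t in pool_a]),
        cfg.niche_breadth,
        np.array([lam_all[t] for t in pool_a]),
        dist_df,
        cfg,
        site_ids,
    )

    occupancy = (frame_a > 0).sum(axis=0)
    if cfg.species_lost > len(pool_a) - 2:
        raise ValueError("species_lost leaves fewer than 2 year-B survivors")
    if cfg.loss_mode == "lowest-occupancy":
        lost = list(occupancy.sort_values(kind="stable").index[: cfg.species_lost])
    elif cfg.loss_mode == "random":
        lost = list(rng_a.choice(pool_a, size=cfg.species_lost, replace=False))
    else:
        raise ValueError(f"unknown loss_mode {cfg.loss_mode!r}")
    pool_b = [t for t in pool_a if t not in set(lost)] + gained

    rng_b = np.random.default_rng(s_year_b)
    lam_b = np.array([lam_all[t] for t in pool_b])
    # sharper dominance + larger catch in year B
    lam_b = lam_b ** cfg.evenness_decay
    lam_b *= cfg.abundance_growth * np.array([lam_all[t] for t in pool_b]).sum() / lam_b.sum()
    frame_b, focal_b = _assemble_year(
        rng_b,
        pool_b,
        np.array([optima_all[t] for t in pool_b]),
        cfg.niche_breadth * cfg.breadth_widening,
        lam_b,
        dist_df,
        cfg,
        site_ids,
    )

    rng_w = np.random.default_rng(s_biomass)
    mean_w = {t: rng_w.lognormal(np.log(cfg.mean_weight_g), 0.8) for t in tips}

    def biomass(frame: pd.DataFrame) -> pd.DataFrame:
        noise = rng_w.lognormal(0.0, 0.2, size=frame.shape)
        w = np.array([mean_w[t] for t in frame.columns])
        return frame.to_numpy() * w[None, :] * noise

    biomass_a = pd.DataFrame(biomass(frame_a), index=site_ids, columns=frame_a.columns)
    biomass_b = pd.DataFrame(biomass(frame_b), index=site_ids, columns=frame_b.columns)

    sequences = (
        evolve_sequences(tree, L=cfg.seq_length, kappa=cfg.kappa, seed=s_seq)
        if with_sequences
        else None
    )

    truth = {
        "assembly": cfg.assembly,
        "filtering_strength": cfg.filtering_strength,
        "lost": sorted(lost),
        "gained": sorted(gained),
        "pool_a": list(pool_a),
        "pool_b": list(pool_b),
        "focal_a": focal_a,
        "focal_b": focal_b,
        "mean_weight_g": mean_w,
    }
    return SyntheticBundle(
        config=cfg,
        counts_a=CommunityMatrix(frame_a, year=2008, kind="count"),
        counts_b=CommunityMatrix(frame_b, year=2021, kind="count"),
        biomass_a=CommunityMatrix(biomass_a, year=2008, kind="biomass"),
        biomass_b=CommunityMatrix(biomass_b, year=2021, kind="biomass"),
        tree=tree,
        distances=dist,
        sequences=sequences,
        truth=truth,
    )
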