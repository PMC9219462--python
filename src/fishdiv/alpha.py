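"""Alpha diversity, dominance (IRI) and sampling completeness.

Indices follow the classical survey-ecology definitions, all on natural
logarithms: Shannon–Wiener H = −Σ p_i ln p_i, Margalef D = (S−1)/ln N,
Gini–Simpson F = 1 − Σ p_i² (reported in some survey literature as a
"dominance" index), and Pielou evenness J = H/ln S.  Dominant species are
ranked by the index of relative importance IRI = (%N + %W) × f, with the
percentages on the 0–100 scale and the occurrence frequency f on 0–1
(maximum 200).  Sampling completeness uses the Chao1 estimator and exact
hypergeometric rarefaction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .community import CommunityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AlphaIndices",
    "CompletenessReport",
    "relative_abundance",
    "shannon",
    "margalef",
    "gini_simpson",
    "pielou",
    "alpha_indices",
    "alpha_table",
    "iri",
    "chao1",
    "rarefaction_curve",
    "completeness_report",
]

#: Default IRI cutoff for calling a species dominant, on the 0–200 scale.
DEFAULT_DOMINANCE_THRESHOLD = 10.0


@dataclass
class AlphaIndices:
    """Diversity indices for one community (a site, or the pooled reserve)."""

    S: int
    N: float
    H: float
    D: float | None
    F: float
    J: float | None


@dataclass
class CompletenessReport:
    """Chao1 richness estimate and sampling completeness."""

    S_obs: int
    f1: int
    f2: int
    chao1: float
    completeness: float
    rarefaction: pd.DataFrame  # columns: m, expected_richness


def relative_abundance(counts) -> np.ndarray:
    """Normalize non-negative counts to a probability vector p_i = N_i / ΣN_j."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    return x / total


def shannon(p) -> float:
    """Shannon–Wiener index H = −Σ p_i ln p_i (natural log; zeros skipped)."""
    p = np.asarray(p, dtype=float)
    pos = p[p > 0]
    return float(-(pos * np.log(pos)).sum())


def margalef(S: int, N: float) -> float:
    """Margalef richness index D = (S − 1)/ln N.  Requires N ≥ 2."""
    if N < 2:
        raise ValueError(f"Margalef index undefined for N = {N} (< 2)")
    return (S - 1) / math.log(N)


def gini_simpson(p) -> float:
    """Gini–Simpson index F = 1 − Σ p_i²."""
    p = np.asarray(p, dtype=float)
    return float(1.0 - (p**2).sum())


def pielou(H: float, S: int) -> float | None:
    """Pielou evenness J = H/ln S; undefined (None, with warning) for S < 2."""
    if S < 2:
        logger.warning("Pielou evenness undefined for S = %d; reporting missing", S)
        return None
    return H / math.log(S)


def alpha_indices(counts) -> AlphaIndices:
    """All alpha indices for one abundance vector."""
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("empty community")
    S = int(x.size)
    N = float(x.sum())
    p = relative_abundance(x)
    H = shannon(p)
    D = margalef(S, N) if N >= 2 else None
    return AlphaIndices(S=S, N=N, H=H, D=D, F=gini_simpson(p), J=pielou(H, S))


def alpha_table(cm: CommunityMatrix, *, pooled: bool = True) -> pd.DataFrame:
    """Per-site alpha indices, optionally with a pooled (all-sites) row.

    The pooled row is computed on counts summed across sites, not on
    averaged per-site indices.
    """
    rows = {}
    for site in cm.site_ids:
        counts = cm.data.loc[site].to_numpy()
        if counts.sum() == 0:
            logger.warning("site %r has no individuals; skipped", site)
            continue
        rows[site] = alpha_indices(counts).__dict__
    if pooled:
        rows["Total"] = alpha_indices(cm.pooled_counts().to_numpy()).__dict__
    return pd.DataFrame.from_dict(rows, orient="index")


def iri(
    counts: CommunityMatrix,
    biomass: CommunityMatrix,
    *,
    dominance_threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
) -> pd.DataFrame:
    """Index of relative importance per species, ranked descending.

    IRI = (%N + %W) × f with %N the species' share of total individuals, %W
    its share of total biomass (both 0–100) and f the fraction of sites where
    it occurs (0–1).  Species with IRI at or above ``dominance_threshold``
    are flagged dominant.
    """
    if counts.kind != "count" or biomass.kind != "biomass":
        raise ValueError("iri needs a count matrix and a biomass matrix, in that order")
    if list(counts.species_ids) != list(biomass.species_ids) or list(
        counts.site_ids
    ) != list(biomass.site_ids):
        missing = set(counts.species_ids) - set(biomass.species_ids)
        if missing:
            raise ValueError(f"species missing from biomass matrix: {sorted(missing)}")
        raise ValueError("count and biomass matrices must share sites and species")
    n = counts.pooled_counts().to_numpy(dtype=float)
    w = biomass.pooled_counts().to_numpy(dtype=float)
    if n.sum() <= 0 or w.sum() <= 0:
        raise ValueError("empty survey")
    pct_n = 100.0 * n / n.sum()
    pct_w = 100.0 * w / w.sum()
    f = (counts.data.to_numpy() > 0).mean(axis=0)
    out = pd.DataFrame(
        {
            "pct_number": pct_n,
            "pct_weight": pct_w,
            "occurrence_frequency": f,
            "IRI": (pct_n + pct_w) * f,
        },
        index=counts.species_ids,
    )
    out["dominant"] = out["IRI"] >= dominance_threshold
    return out.sort_values("IRI", ascending=False)


def chao1(counts) -> tuple[int, float]:
    """Chao1 richness estimate from singleton/doubleton counts.

    Returns ``(S_obs, chao1)``.  Classical estimator
    S_obs + f1²/(2 f2); when there are no doubletons, the bias-corrected
    fallback S_obs + f1(f1−1)/2 is used.
    """
    x = np.asarray(counts)
    if not np.allclose(x, np.round(x)):
        raise ValueError("Chao1 needs integer counts")
    x = np.round(x).astype(np.int64)
    x = x[x > 0]
    S_obs = int(x.size)
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        est = S_obs + f1**2 / (2 * f2)
    else:
        est = S_obs + f1 * (f1 - 1) / 2
    return S_obs, float(est)


def rarefaction_curve(counts, m_grid=None) -> pd.DataFrame:
    """Expected richness under exact abundance-based rarefaction.

    E[S_m] = Σ_i [1 − C(N−N_i, m)/C(N, m)], evaluated on a log-binomial
    scale for stability.  ``m_grid`` defaults to ~20 points from 1 to N.
    Subsample sizes above N are an error (no extrapolation).
    """
    x = np.asarray(counts)
    if not np.allclose(x, np.round(x)):
        raise ValueError("rarefaction needs integer counts")
    x = np.round(x).astype(np.int64)
    x = x[x > 0]
    N = int(x.sum())
    if m_grid is None:
        m_grid = np.unique(np.linspace(1, N, min(20, N)).round().astype(int))
    m_grid = np.asarray(m_grid, dtype=np.int64)
    if (m_grid < 1).any() or (m_grid > N).any():
        raise ValueError(f"subsample sizes must lie in [1, N={N}]")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    expected = np.empty(m_grid.size)
    for idx, m in enumerate(m_grid):
        # species i is missed with prob C(N−N_i, m)/C(N, m); impossible if N−N_i < m
        keep = (N - x) >= m
        miss = np.zeros(x.size)
        if keep.any():
            miss[keep] = np.exp(log_choose(N - x[keep], m) - log_choose(N, m))
        expected[idx] = (1.0 - miss).sum()
    return pd.DataFrame({"m": m_grid, "expected_richness": expected})


def completeness_report(counts, m_grid=None) -> CompletenessReport:
    """Chao1, completeness = S_obs/chao1 and the rarefaction curve together."""
    S_obs, est = chao1(counts)
    x = np.asarray(counts)
    x = np.round(x).astype(np.int64)
    x = x[x > 0]
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return CompletenessReport(
        S_obs=S_obs,
        f1=f1,
        f2=f2,
        chao1=est,
        completeness=S_obs / est,
        rarefaction=rarefaction_curve(counts, m_grid),
    )
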