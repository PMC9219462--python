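"""Incidence-based beta diversity and its turnover/nestedness partition.

Sørensen dissimilarity βsor decomposes additively into a spatial-turnover
component (βsim, the Simpson dissimilarity) and a nestedness-resultant
component (βsne = βsor − βsim).  Both the mean over all site pairs and the
Baselga multiple-site forms are provided; comparing a year's βsor against a
later year's quantifies biotic homogenization (Δβsor > 0 means sites became
compositionally more similar over time).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .community import CommunityMatrix, presence_absence

__all__ = [
    "BetaPartition",
    "HomogenizationReport",
    "pairwise_partition",
    "pairwise_sorensen_matrix",
    "mean_pairwise_partition",
    "multisite_partition",
    "homogenization",
]


@dataclass
class BetaPartition:
    beta_sor: float
    beta_sim: float
    beta_sne: float
    mode: str  # "pairwise-mean" | "multisite" | "pairwise"


@dataclass
class HomogenizationReport:
    """Temporal contrast of beta diversity: Δβsor = βsor(earlier) − βsor(later)."""

    delta_beta_sor: float
    direction: str  # "homogenization" | "differentiation" | "none"


def _abc(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int]:
    x = np.asarray(x) > 0
    y = np.asarray(y) > 0
    a = int((x & y).sum())
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    return a, b, c


def pairwise_partition(x, y) -> BetaPartition:
    """Sørensen partition for one site pair.

    With a = shared species, b and c the species unique to each site:
    βsor = (b+c)/(2a+b+c), βsim = min(b,c)/(a+min(b,c)), βsne = βsor − βsim.
    """
    a, b, c = _abc(x, y)
    if a + b + c == 0:
        raise ValueError("both sites are empty")
    beta_sor = (b + c) / (2 * a + b + c)
    m = min(b, c)
    beta_sim = m / (a + m) if (a + m) > 0 else 0.0
    return BetaPartition(beta_sor, beta_sim, beta_sor - beta_sim, mode="pairwise")


def pairwise_sorensen_matrix(cm: CommunityMatrix) -> np.ndarray:
    """Symmetric matrix of pairwise βsor values (site order as in ``cm``)."""
    pa = presence_absence(cm).data.to_numpy()
    n = pa.shape[0]
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        out[i, j] = out[j, i] = pairwise_partition(pa[i], pa[j]).beta_sor
    return out


def _nonempty_incidence(cm: CommunityMatrix) -> np.ndarray:
    pa = presence_absence(cm).data.to_numpy()
    pa = pa[pa.sum(axis=1) > 0]
    # drop species never seen this year; harmless for the formulas, clearer
    pa = pa[:, pa.sum(axis=0) > 0]
    if pa.shape[0] < 2:
        raise ValueError("need at least 2 non-empty sites")
    return pa


def mean_pairwise_partition(cm: CommunityMatrix) -> BetaPartition:
    """Arithmetic mean of each partition component over all site pairs."""
    pa = _nonempty_incidence(cm)
    parts = [
        pairwise_partition(pa[i], pa[j])
        for i, j in combinations(range(pa.shape[0]), 2)
    ]
    return BetaPartition(
        beta_sor=float(np.mean([p.beta_sor for p in parts])),
        beta_sim=float(np.mean([p.beta_sim for p in parts])),
        beta_sne=float(np.mean([p.beta_sne for p in parts])),
        mode="pairwise-mean",
    )


def multisite_partition(cm: CommunityMatrix) -> BetaPartition:
    """Baselga multiple-site partition βSOR = βSIM + βSNE.

    Uses the Σmin/Σmax constructions over directed unique-species counts
    b_ij: with S_T the pooled richness and ΣS_i the summed site richnesses,

        βSIM = Σmin / (ΣS_i − S_T + Σmin)
        βSOR = (Σmin + Σmax) / (2(ΣS_i − S_T) + Σmin + Σmax)
    """
    pa = _nonempty_incidence(cm)
    sum_si = int(pa.sum())
    s_t = int((pa.sum(axis=0) > 0).sum())
    sum_min = 0
    sum_max = 0
    for i, j in combinations(range(pa.shape[0]), 2):
        _, b_ij, b_ji = _abc(pa[i], pa[j])
        sum_min += min(b_ij, b_ji)
        sum_max += max(b_ij, b_ji)
    shared_core = sum_si - s_t  # equals Σ_pairs a only through inclusion–exclusion core
    beta_sim = sum_min / (shared_core + sum_min) if (shared_core + sum_min) > 0 else 0.0
    denom = 2 * shared_core + sum_min + sum_max
    beta_sor = (sum_min + sum_max) / denom if denom > 0 else 0.0
    return BetaPartition(beta_sor, beta_sim, beta_sor - beta_sim, mode="multisite")


def homogenization(beta_a: BetaPartition, beta_b: BetaPartition) -> HomogenizationReport:
    """Δβsor between an earlier (``beta_a``) and later (``beta_b``) survey.

    Positive Δβsor means among-site dissimilarity declined over time —
    biotic homogenization; negative means differentiation.  The exact
    difference of the inputs is returned, with no extra rounding.
    """
    if beta_a.mode != beta_b.mode:
        raise ValueError(f"mode mismatch: {beta_a.mode!r} vs {beta_b.mode!r}")
    delta = beta_a.beta_sor - beta_b.beta_sor
    if delta > 0:
        direction = "homogenization"
    elif delta < 0:
        direction = "differentiation"
    else:
        direction = "none"
    return HomogenizationReport(delta_beta_sor=delta, direction=direction)
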