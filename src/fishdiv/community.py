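"""Survey data model and IO.

The central container is :class:`CommunityMatrix`, a labelled site x species
table of counts (individuals) or biomass (grams) for one survey year.  Every
downstream statistic — alpha indices, beta partitions, Bray–Curtis ordination,
MPD/NRI — consumes this object.  Specimen-level records (body length, weight)
are aggregated into a :class:`SpecimenTable`, which feeds the index of
relative importance (IRI) and survey summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityMatrix",
    "SpecimenTable",
    "SpeciesTurnoverReport",
    "read_community_matrix",
    "write_community_matrix",
    "read_specimen_records",
    "specimen_table",
    "presence_absence",
    "compare_species_lists",
]


@dataclass
class CommunityMatrix:
    """Site x species abundance table for one survey year.

    Parameters
    ----------
    data : pandas.DataFrame
        Sites in rows, species in columns.  Counts (``kind="count"``) must be
        non-negative integers; biomass (``kind="biomass"``) non-negative reals
        in grams.
    year : int, optional
        Survey-year label.
    kind : {"count", "biomass"}
    """

    data: pd.DataFrame
    year: int | None = None
    kind: str = "count"

    def __post_init__(self) -> None:
        if self.kind not in ("count", "biomass"):
            raise ValueError(f"kind must be 'count' or 'biomass', got {self.kind!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate site label(s): {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species label(s): {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("community matrix contains non-finite entries")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at site {self.data.index[i]!r}, "
                f"species {self.data.columns[j]!r}"
            )
        if self.kind == "count" and not np.allclose(values, np.round(values)):
            i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ValueError(
                f"count matrix has non-integer entry at site {self.data.index[i]!r}, "
                f"species {self.data.columns[j]!r}"
            )
        if self.kind == "count":
            self.data = self.data.astype(np.int64)

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def species_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def richness(self) -> int:
        """Number of species with positive total abundance."""
        return int((self.data.sum(axis=0) > 0).sum())

    @property
    def total(self) -> float:
        return float(self.data.to_numpy().sum())

    def species_present(self) -> list:
        """Species with positive total abundance, in column order."""
        totals = self.data.sum(axis=0)
        return list(totals.index[totals > 0])

    def drop_absent_species(self) -> "CommunityMatrix":
        """Return a copy without zero-total species columns."""
        return CommunityMatrix(
            self.data.loc[:, self.data.sum(axis=0) > 0].copy(),
            year=self.year,
            kind=self.kind,
        )

    def pooled_counts(self) -> pd.Series:
        """Per-species totals summed across sites."""
        return self.data.sum(axis=0)


@dataclass
class SpecimenTable:
    """Per-species aggregate of specimen records.

    ``data`` has one row per species with columns ``total_count``,
    ``total_weight_g``, ``mean_length_cm``, ``occurrence_frequency`` (fraction
    of surveyed sites where the species was recorded, in [0, 1]) and
    ``pct_number`` / ``pct_weight`` on the 0–100 scale.
    """

    data: pd.DataFrame
    n_sites: int = 0

    def __post_init__(self) -> None:
        f = self.data["occurrence_frequency"]
        if ((f < 0) | (f > 1)).any():
            raise ValueError("occurrence_frequency outside [0, 1]")
        if (self.data["total_count"] < 0).any() or (self.data["total_weight_g"] < 0).any():
            raise ValueError("negative count or weight")
        for col in ("pct_number", "pct_weight"):
            s = self.data[col].sum()
            if abs(s - 100.0) > 1e-6:
                raise ValueError(f"{col} sums to {s}, expected 100")


@dataclass
class SpeciesTurnoverReport:
    """Temporal species-list comparison between two survey years."""

    lost: set = field(default_factory=set)
    gained: set = field(default_factory=set)
    shared: set = field(default_factory=set)

    @property
    def n_lost(self) -> int:
        return len(self.lost)

    @property
    def n_gained(self) -> int:
        return len(self.gained)

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def read_community_matrix(
    path, *, year: int | None = None, kind: str = "count", sep: str | None = None
) -> CommunityMatrix:
    """Read a delimited site x species table.

    First row holds species labels, first column site labels.  The delimiter
    is sniffed (comma or tab) unless ``sep`` is given.  Empty cells are read
    as 0 with a logged warning; negative or non-numeric cells and duplicate
    labels are hard errors.
    """
    with open(path) as fh:
        header = fh.readline()
    if sep is None:
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    species = [c.strip() for c in header.rstrip("\n").split(sep)[1:]]
    dups = {s for s in species if species.count(s) > 1}
    if dups:
        # pandas would silently mangle repeated columns, so check the raw header
        raise ValueError(f"duplicate species label(s): {sorted(dups)}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        n_blank = int(df.isna().sum().sum())
        logger.warning("%s: %d empty cell(s) read as 0", path, n_blank)
        df = df.fillna(0)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"non-numeric cell at site {row!r}, species {col!r}")
    return CommunityMatrix(df.apply(pd.to_numeric), year=year, kind=kind)


def write_community_matrix(cm: CommunityMatrix, path, *, sep: str = ",") -> None:
    """Write the table in the same layout ``read_community_matrix`` expects."""
    cm.data.to_csv(path, sep=sep)


def read_specimen_records(path) -> pd.DataFrame:
    """Read per-specimen records: columns species, count, weight_g, length_cm, site."""
    df = pd.read_csv(path)
    required = {"species", "count", "weight_g", "length_cm", "site"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"specimen file missing column(s): {sorted(missing)}")
    return df


def specimen_table(records: pd.DataFrame) -> SpecimenTable:
    """Aggregate specimen records into per-species totals and percentages.

    ``mean_length_cm`` is the count-weighted mean body length; occurrence
    frequency is the fraction of distinct sites where the species appears.
    """
    n_sites = records["site"].nunique()
    grouped = records.groupby("species")
    out = pd.DataFrame(
        {
            "total_count": grouped["count"].sum(),
            "total_weight_g": grouped["weight_g"].sum(),
            "mean_length_cm": grouped.apply(
                lambda g: np.average(g["length_cm"], weights=g["count"]),
                include_groups=False,
            ),
            "occurrence_frequency": grouped["site"].nunique() / n_sites,
        }
    )
    out["pct_number"] = 100.0 * out["total_count"] / out["total_count"].sum()
    out["pct_weight"] = 100.0 * out["total_weight_g"] / out["total_weight_g"].sum()
    return SpecimenTable(out, n_sites=n_sites)


def presence_absence(cm: CommunityMatrix) -> CommunityMatrix:
    """Map abundances to incidence: 1 where positive, else 0.

    Idempotent; required by the Sørensen family of beta-diversity measures,
    which is incidence-based.
    """
    pa = (cm.data > 0).astype(np.int64)
    return CommunityMatrix(pa, year=cm.year, kind="count")


def compare_species_lists(cm_a: CommunityMatrix, cm_b: CommunityMatrix) -> SpeciesTurnoverReport:
    """Species lost, gained and shared between two survey years.

    A species counts as present in a year only if its total abundance that
    year is positive (observation-based lists; zero columns are absences).
    """
    a = set(cm_a.species_present())
    b = set(cm_b.species_present())
    return SpeciesTurnoverReport(lost=a - b, gained=b - a, shared=a & b)
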