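"""Prepare raw presence-only records for occupancy modelling.

A *record* is a unique (species, 1 km site, date) triple; a *visit* is a
unique (site, date) combination. Non-detections are inferred: a visit on
which other species of the taxonomic group were recorded, but not the
focal species, counts as a non-detection of the focal species. The
number of species recorded on a visit (its list length) proxies recorder
effort, categorized as 1 (single-species list), 2 (2-3 species) or 3
(>3 species, a comprehensive day list). Run the pipeline once per
taxonomic group so list lengths are computed only within the group.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "DetectionHistory",
    "load_records",
    "filter_records",
    "build_visits",
    "build_detection_history",
]


@dataclass
class FilterReport:
    """Bookkeeping of every row removed during filtering; counts reconcile."""

    n_records_in: int = 0
    n_records_out: int = 0
    n_duplicates_collapsed: int = 0
    n_removed_year_window: int = 0
    n_removed_site_filter: int = 0
    n_removed_species_filter: int = 0
    n_removed_exclusions: int = 0
    year_range: tuple[int | None, int | None] = (None, None)
    species_dropped: dict[str, int] = field(default_factory=dict)
    sites_dropped: dict[str, int] = field(default_factory=dict)

    def reconciles(self) -> bool:
        removed = (
            self.n_removed_year_window
            + self.n_removed_site_filter
            + self.n_removed_species_filter
            + self.n_removed_exclusions
        )
        return self.n_records_in - self.n_duplicates_collapsed - removed == self.n_records_out

    def to_json(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        data["year_range"] = list(self.year_range)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)


@dataclass
class DetectionHistory:
    """Visit-level detection history for one focal species.

    Arrays are aligned to the visit table: ``y[v]`` is 1 iff the focal
    species was recorded on visit v, ``dt2``/``dt3`` indicate list-length
    categories 2 and 3, and ``site_index``/``year_index`` map each visit
    into the full site list and the contiguous year range of the prepared
    dataset. Occupancy denominators use *all* sites in ``site_ids``, not
    only those visited in a given year.
    """

    species: str
    y: np.ndarray
    site_index: np.ndarray
    year_index: np.ndarray
    dt2: np.ndarray
    dt3: np.ndarray
    site_ids: list[str]
    years: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_visits(self) -> int:
        return len(self.y)


def load_records(path: str | Path) -> pd.DataFrame:
    """Read a species,site,date CSV; dates must parse as ISO calendar days."""
    df = pd.read_csv(path, dtype={"species": str, "site": str})
    missing = {"species", "site", "date"} - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    if parsed.isna().any():
        bad = df.index[parsed.isna()][0]
        raise ValueError(f"malformed date at row {bad}: {df.loc[bad, 'date']!r}")
    df["date"] = parsed.dt.date
    return df[["species", "site", "date"]]


def _normalize(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse duplicate (species, site, date) rows; return count collapsed."""
    n_in = len(records)
    out = records.drop_duplicates(subset=["species", "site", "date"]).reset_index(drop=True)
    return out, n_in - len(out)


def filter_records(
    records: pd.DataFrame,
    year_min: int | None = None,
    year_max: int | None = None,
    min_records_per_species: int = 50,
    min_years_per_site: int = 2,
    exclude_species: list[str] | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the study-window and data-quality filters, in a fixed order.

    Order: (1) clip to the year window, (2) drop sites with fewer than
    ``min_years_per_site`` distinct years of remaining data, (3) drop
    species with fewer than ``min_records_per_species`` remaining records
    (strictly fewer: a species with exactly the threshold is retained).
    An optional exclusion list (e.g. taxonomically problematic or
    non-pollinator species) is applied before the record-count filter.
    The report reconciles all removals exactly.
    """
    report = FilterReport(n_records_in=len(records), year_range=(year_min, year_max))
    df, report.n_duplicates_collapsed = _normalize(records)

    years = pd.to_datetime(df["date"]).dt.year if len(df) else pd.Series([], dtype=int)
    keep = pd.Series(True, index=df.index)
    if year_min is not None:
        keep &= years >= year_min
    if year_max is not None:
        keep &= years <= year_max
    report.n_removed_year_window = int((~keep).sum())
    df = df[keep]
    years = years[keep]

    site_years = years.groupby(df["site"]).nunique()
    bad_sites = site_years[site_years < min_years_per_site]
    report.sites_dropped = {s: int(n) for s, n in bad_sites.items()}
    keep = ~df["site"].isin(bad_sites.index)
    report.n_removed_site_filter = int((~keep).sum())
    df = df[keep]

    if exclude_species:
        excl = set(exclude_species)
        keep = ~df["species"].isin(excl)
        report.n_removed_exclusions = int((~keep).sum())
        df = df[keep]

    counts = df["species"].value_counts()
    bad_species = counts[counts < min_records_per_species]
    report.species_dropped = {s: int(n) for s, n in bad_species.items()}
    keep = ~df["species"].isin(bad_species.index)
    report.n_removed_species_filter = int((~keep).sum())
    df = df[keep].reset_index(drop=True)

    report.n_records_out = len(df)
    if report.n_records_out == 0:
        warnings.warn("filter_records produced an empty records table", stacklevel=2)
    assert report.reconciles()
    return df, report


def build_visits(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate records into visits: one row per unique (site, date).

    ``n_species_recorded`` counts distinct species on the visit;
    ``category`` is 1 for single-species lists, 2 for 2-3 species,
    3 for more than 3.
    """
    df, _ = _normalize(records)
    if df.empty:
        return pd.DataFrame(
            columns=["site", "date", "year", "n_species_recorded", "category"]
        ).astype({"year": int, "n_species_recorded": int, "category": int})
    visits = (
        df.groupby(["site", "date"], sort=True)["species"]
        .nunique()
        .rename("n_species_recorded")
        .reset_index()
    )
    visits["year"] = pd.to_datetime(visits["date"]).dt.year
    n = visits["n_species_recorded"]
    visits["category"] = np.select([n == 1, n <= 3], [1, 2], default=3)
    return visits[["site", "date", "year", "n_species_recorded", "category"]]


def build_detection_history(
    records: pd.DataFrame, visits: pd.DataFrame, focal: str
) -> DetectionHistory:
    """Build the focal species' per-visit detection/non-detection history.

    ``y`` has one entry per visit row; its sum equals the focal species'
    record count. Site and year indices span the whole prepared dataset
    (all sites; the contiguous year range), so that annual occupancy is
    always a proportion of all modelled sites.
    """
    if focal not in set(records["species"]):
        raise ValueError(f"focal species {focal!r} has no records")
    df, _ = _normalize(records)

    site_ids = sorted(visits["site"].unique())
    year_lo, year_hi = int(visits["year"].min()), int(visits["year"].max())
    years = np.arange(year_lo, year_hi + 1)
    site_pos = {s: k for k, s in enumerate(site_ids)}

    focal_visits = set(
        map(tuple, df.loc[df["species"] == focal, ["site", "date"]].itertuples(index=False))
    )
    keys = list(map(tuple, visits[["site", "date"]].itertuples(index=False)))
    y = np.fromiter((k in focal_visits for k in keys), dtype=np.int8, count=len(keys))

    return DetectionHistory(
        species=focal,
        y=y,
        site_index=visits["site"].map(site_pos).to_numpy(),
        year_index=(visits["year"].to_numpy() - year_lo),
        dt2=(visits["category"].to_numpy() == 2).astype(np.int8),
        dt3=(visits["category"].to_numpy() == 3).astype(np.int8),
        site_ids=site_ids,
        years=years,
    )
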