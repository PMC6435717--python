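"""Downstream statistics on posterior occupancy draws.

All summaries propagate uncertainty by operating draw-wise on a
subsampled set of posterior occupancy values (default 1000 per
species-year), reporting equal-tailed posterior medians and credible
intervals. Provided statistics: clipped species growth rates with a
CI-based trend classification, multispecies composite (geometric-mean)
occupancy via a sum-contrast log-linear model, Simpson's evenness
(-ln D) of the occupancy shares, first derivatives with notable-year
flags, and net range change extrapolated to a national grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from occutrend.model import OccupancySamples

__all__ = [
    "TrendSummary",
    "CompositeSeries",
    "DerivativeSeries",
    "subsample_posterior",
    "clip_series",
    "species_growth_rate",
    "composite_trend",
    "simpson_evenness",
    "evenness_series",
    "first_derivative",
    "net_change",
]


@dataclass
class TrendSummary:
    """Species growth rate (% per year) with CI and trend classification."""

    species: str
    first_year: int
    last_year: int
    rate_median: float
    rate_lower: float
    rate_upper: float
    classification: str  # decreasing / increasing / no clear trend
    rate_samples: np.ndarray = field(repr=False, default=None)


@dataclass
class CompositeSeries:
    """Composite (geometric-mean) occupancy of a species group by year."""

    group: str
    years: np.ndarray
    samples: np.ndarray  # draws x years
    n_species: int

    @property
    def median(self) -> np.ndarray:
        return np.median(self.samples, axis=0)

    def ci(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        alpha = (1 - level) / 2
        return (
            np.quantile(self.samples, alpha, axis=0),
            np.quantile(self.samples, 1 - alpha, axis=0),
        )


@dataclass
class DerivativeSeries:
    """Year-on-year differences of a composite series with notable flags.

    A year is flagged "decrease" when the upper 95% credible bound of
    the difference from the previous year is below zero, "increase" when
    the lower bound is above zero, else "none".
    """

    group: str
    years: np.ndarray  # year t of each (t-1, t) pair
    samples: np.ndarray  # draws x (n_years - 1)
    median: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    lower80: np.ndarray
    upper80: np.ndarray
    flags: np.ndarray  # "decrease" / "increase" / "none"


def subsample_posterior(samples: OccupancySamples, k: int = 1000, seed: int = 0) -> OccupancySamples:
    """Select k posterior draws without replacement, reproducibly.

    All downstream statistics are computed from this reduced working
    set. If fewer than k draws are available all are used (warning).
    """
    n = samples.n_draws
    if n < k:
        warnings.warn(
            f"{samples.species}: only {n} draws available (< {k}); using all", stacklevel=2
        )
        return samples
    if n == k:
        return samples
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return OccupancySamples(
        species=samples.species,
        years=samples.years.copy(),
        samples=samples.samples[idx],
        n_sites=samples.n_sites,
    )


def clip_series(
    samples: OccupancySamples, first_record_year: int, last_record_year: int
) -> OccupancySamples:
    """Drop years before the species' first record and after its last.

    Occupancy estimates outside the recorded span are extrapolations of
    the smoothing prior and are excluded from trend statistics. Raises
    if fewer than two years remain (no trend can be estimated).
    """
    keep = (samples.years >= first_record_year) & (samples.years <= last_record_year)
    if keep.sum() < 2:
        raise ValueError(
            f"{samples.species}: clipped series has < 2 years "
            f"({first_record_year}-{last_record_year}); no trend"
        )
    return OccupancySamples(
        species=samples.species,
        years=samples.years[keep],
        samples=samples.samples[:, keep],
        n_sites=samples.n_sites,
    )


def _floor(values: np.ndarray, n_sites: int) -> np.ndarray:
    """Epsilon floor below the site-grid resolution, so logs/ratios are finite."""
    return np.maximum(values, 1.0 / (2.0 * max(n_sites, 1)))


def species_growth_rate(clipped: OccupancySamples, compound: bool = True) -> TrendSummary:
    """Annual growth rate (% change per year) between first and last year.

    Per posterior draw the compound rate is
    ``100 * ((occ_last / occ_first)**(1 / (y_last - y_first)) - 1)``;
    the arithmetic alternative ``100 * (occ_last - occ_first) /
    (occ_first * (y_last - y_first))`` is available via
    ``compound=False``. Draw-level zeros are floored at half a site's
    worth of occupancy. Classification: "decreasing" iff the 95% CI lies
    entirely below 0, "increasing" iff entirely above, else "no clear
    trend".
    """
    years = clipped.years
    span = int(years[-1] - years[0])
    if span < 1:
        raise ValueError("growth rate needs a span of at least one year")
    first = _floor(clipped.samples[:, 0], clipped.n_sites)
    last = _floor(clipped.samples[:, -1], clipped.n_sites)
    if compound:
        rates = 100.0 * ((last / first) ** (1.0 / span) - 1.0)
    else:
        rates = 100.0 * (last - first) / (first * span)
    lo, med, hi = np.quantile(rates, [0.025, 0.5, 0.975])
    if hi < 0:
        cls = "decreasing"
    elif lo > 0:
        cls = "increasing"
    else:
        cls = "no clear trend"
    return TrendSummary(
        species=clipped.species,
        first_year=int(years[0]),
        last_year=int(years[-1]),
        rate_median=float(med),
        rate_lower=float(lo),
        rate_upper=float(hi),
        classification=cls,
        rate_samples=rates,
    )


def composite_trend(group_samples: list[OccupancySamples], group: str = "all") -> CompositeSeries:
    """Multispecies composite trend via a sum-contrast log-linear model.

    Per posterior draw, log occupancy is modelled with year and species
    as categorical effects under sum-to-zero contrasts; the year effects
    (intercept + year coefficient) are exponentiated back to the
    occupancy scale. On a complete species x year table this equals the
    per-year geometric mean across species exactly; with clipped
    (missing) species-years the least-squares fit adjusts for the
    unbalanced design, which is the reason a model is used rather than a
    raw geometric mean.
    """
    if not group_samples:
        raise ValueError("composite_trend needs at least one species")
    n_draws = group_samples[0].n_draws
    if any(s.n_draws != n_draws for s in group_samples):
        raise ValueError("all species must carry the same number of draws")

    years = np.unique(np.concatenate([s.years for s in group_samples]))
    T, S = len(years), len(group_samples)
    year_pos = {y: j for j, y in enumerate(years)}

    rows_y, rows_s, logocc = [], [], []
    for si, s in enumerate(group_samples):
        for j, year in enumerate(s.years):
            rows_y.append(year_pos[year])
            rows_s.append(si)
            logocc.append(np.log(_floor(s.samples[:, j], s.n_sites)))
    rows_y = np.asarray(rows_y)
    rows_s = np.asarray(rows_s)
    Y = np.asarray(logocc)  # cells x draws

    n_cells = len(rows_y)
    X = np.ones((n_cells, 1 + (T - 1) + (S - 1)))
    # sum-to-zero contrasts: last level is minus the sum of the others
    for j in range(T - 1):
        X[:, 1 + j] = (rows_y == j).astype(float) - (rows_y == T - 1).astype(float)
    for i in range(S - 1):
        X[:, T + i] = (rows_s == i).astype(float) - (rows_s == S - 1).astype(float)

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    year_eff = np.empty((T, n_draws))
    year_eff[: T - 1] = beta[1:T]
    year_eff[T - 1] = -beta[1:T].sum(axis=0)
    comp = np.exp(beta[0][None, :] + year_eff)  # years x draws

    return CompositeSeries(group=group, years=years, samples=comp.T, n_species=S)


def simpson_evenness(occupancies: np.ndarray) -> np.ndarray:
    """Simpson's evenness, the -ln D formulation, of occupancy shares.

    ``occupancies`` is (n_species,) or (n_species, n_draws); shares are
    p_i = occ_i / sum_j occ_j and D = sum_i p_i**2. Returns -ln D per
    draw: ln(S) for S equally occupied species, approaching 0 as one
    species dominates. All-zero communities yield NaN with a warning.
    """
    occ = np.atleast_2d(np.asarray(occupancies, dtype=float).T).T  # species x draws
    if occ.shape[0] < 2:
        raise ValueError("evenness needs at least 2 species")
    if np.any(occ < 0):
        raise ValueError("occupancies must be non-negative")
    total = occ.sum(axis=0)
    zero = total == 0
    if zero.any():
        warnings.warn("all-zero occupancy in some draws; evenness undefined", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = occ / total
        d = (shares**2).sum(axis=0)
        out = -np.log(d)
    out[zero] = np.nan
    result = out if np.asarray(occupancies).ndim > 1 else float(out[0])
    return result


def evenness_series(
    group_samples: list[OccupancySamples], group: str = "all"
) -> CompositeSeries:
    """Annual Simpson's evenness of the group's occupancy shares, per draw.

    Requires all species to share the same year axis (evenness compares
    the community composition within a year, so clipped series should be
    computed on the full modelled span or a common window).
    """
    years = group_samples[0].years
    if any(not np.array_equal(s.years, years) for s in group_samples):
        raise ValueError("evenness requires species aligned on the same years")
    occ = np.stack([s.samples for s in group_samples])  # species x draws x years
    n_draws = occ.shape[1]
    ev = np.empty((n_draws, len(years)))
    for t in range(len(years)):
        ev[:, t] = simpson_evenness(occ[:, :, t])
    return CompositeSeries(group=group, years=years.copy(), samples=ev, n_species=len(group_samples))


def first_derivative(series: CompositeSeries) -> DerivativeSeries:
    """Differences between adjacent years with notable-year flags.

    Per draw, ``delta_t = value_t - value_{t-1}``; a year is notable
    when its 95% credible interval for the difference excludes zero
    (80% intervals are also reported for plotting).
    """
    if series.samples.shape[1] < 2:
        raise ValueError("first derivative needs >= 2 years")
    diffs = np.diff(series.samples, axis=1)
    lo95, lo80, med, hi80, hi95 = np.quantile(diffs, [0.025, 0.10, 0.5, 0.90, 0.975], axis=0)
    flags = np.full(diffs.shape[1], "none", dtype=object)
    # tie-break: bounds within floating roundoff of zero do not flag
    tol = 1e-12
    flags[hi95 < -tol] = "decrease"
    flags[lo95 > tol] = "increase"
    return DerivativeSeries(
        group=series.group,
        years=series.years[1:].copy(),
        samples=diffs,
        median=med,
        lower95=lo95,
        upper95=hi95,
        lower80=lo80,
        upper80=hi80,
        flags=flags,
    )


def net_change(
    clipped_by_species: dict[str, OccupancySamples], n_cells_total: int = 240_000
) -> pd.DataFrame:
    """Net change in species per cell and its national extrapolation.

    Per posterior draw the per-cell net change is the sum over species
    of (occupancy in the last clipped year minus occupancy in the
    first); multiplying by the total number of grid cells gives the net
    change in occupied cells nationally. Returns a one-row summary frame
    with medians and 95% CIs of both quantities.
    """
    if not clipped_by_species:
        raise ValueError("net_change needs at least one species")
    deltas = np.stack(
        [s.samples[:, -1] - s.samples[:, 0] for s in clipped_by_species.values()]
    )  # species x draws
    per_cell = deltas.sum(axis=0)
    extrapolated = per_cell * n_cells_total
    lo_c, med_c, hi_c = np.quantile(per_cell, [0.025, 0.5, 0.975])
    lo_e, med_e, hi_e = np.quantile(extrapolated, [0.025, 0.5, 0.975])
    return pd.DataFrame(
        {
            "n_species": [len(clipped_by_species)],
            "n_cells_total": [n_cells_total],
            "per_cell_median": [med_c],
            "per_cell_lower": [lo_c],
            "per_cell_upper": [hi_c],
            "extrapolated_median": [med_e],
            "extrapolated_lower": [lo_e],
            "extrapolated_upper": [hi_e],
        }
    )
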