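"""Synthetic biological-records generator with known ground truth.

Emulates a volunteer recording scheme: multiple species with
heterogeneous occupancy, site random effects, year-to-year occupancy
change with random-walk structure, year-varying detectability, visit
list lengths that feed back into detection probability, and more visits
in later years (temporal recording bias). Because the true presence
matrix and all parameters are retained, every downstream stage of the
pipeline can be tested against ground truth without any real download.

The list-length category of a visit is *derived from the detections the
generator actually emits*, exactly as the category is derived from data
during preparation: detection probabilities and realized categories are
iterated to a self-consistent fixed point (which exists whenever the
category offsets are non-negative, the realistic case).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from occutrend.config import SimulationConfig

__all__ = ["TrueParams", "SimulatedRecords", "simulate_truth", "simulate_records"]


@dataclass
class TrueParams:
    """Ground-truth parameters and presences behind a simulated dataset.

    Arrays cover all simulated species, focal ("SP...") first and then
    background ("BG..."). ``b`` (species x years) are logit-occupancy
    year effects following a first-order random walk per species; ``u`` (n_sites) site effects;
    ``a`` (n_years) logit-detection year effects; ``delta1``/``delta2``
    the detection offsets of list-length categories 2 and 3; ``z_true``
    (n_species x n_sites x n_years) binary presence.
    """

    b: np.ndarray
    u: np.ndarray
    a: np.ndarray
    delta1: float
    delta2: float
    z_true: np.ndarray
    species_ids: list[str]
    site_ids: list[str]
    years: np.ndarray

    @property
    def psi(self) -> np.ndarray:
        """Occupancy probability, species x sites x years."""
        return expit(self.b[:, None, :] + self.u[None, :, None])

    @property
    def occupancy(self) -> np.ndarray:
        """True annual proportion of occupied sites, species x years."""
        return self.z_true.mean(axis=1)

    def to_csvs(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.b, index=self.species_ids, columns=self.years).rename_axis(
            "species"
        ).to_csv(out / "b.csv")
        pd.DataFrame({"site": self.site_ids, "u": self.u}).to_csv(out / "u.csv", index=False)
        pd.DataFrame({"year": self.years, "a": self.a}).to_csv(out / "a.csv", index=False)
        pd.DataFrame({"delta1": [self.delta1], "delta2": [self.delta2]}).to_csv(
            out / "delta.csv", index=False
        )
        occ = pd.DataFrame(self.occupancy, index=self.species_ids, columns=self.years)
        occ.rename_axis("species").to_csv(out / "true_occupancy.csv")


@dataclass
class SimulatedRecords:
    """Presence-only records plus the generator's internal bookkeeping.

    ``records`` is the pipeline input (unique species/site/date rows).
    ``visits`` and ``detections`` retain what the generator knows — the
    realized visit schedule with list-length categories, and the full
    per-visit detection matrix — so round-trip tests can check the
    preparation stage reconstructs them exactly.
    """

    records: pd.DataFrame
    visits: pd.DataFrame
    detections: np.ndarray  # n_visits x n_species, 0/1, incl. empty visits
    visit_site: np.ndarray
    visit_year: np.ndarray


def simulate_truth(config: SimulationConfig) -> TrueParams:
    """Draw ground-truth parameters and the true presence array.

    Occupancy follows logit(psi_it) = b_t + u_i per species, with b a
    random walk started at a species-specific baseline and u zero-mean
    normal site effects; z_true is Bernoulli(psi).
    """
    rng = np.random.default_rng(config.seed)
    S = config.n_species + config.n_background_species
    I, T = config.n_sites, config.n_years

    b0 = logit(config.baseline_occupancy) + config.species_sd * rng.standard_normal(S)
    innov = config.year_walk_sd * rng.standard_normal((S, T - 1)) if T > 1 else np.empty((S, 0))
    b = np.concatenate([b0[:, None], b0[:, None] + np.cumsum(innov, axis=1)], axis=1)

    u = config.site_effect_sd * rng.standard_normal(I)
    a = logit(config.baseline_detection) + config.detection_year_sd * rng.standard_normal(T)

    psi = expit(b[:, None, :] + u[None, :, None])
    z_true = (rng.random((S, I, T)) < psi).astype(np.int8)

    species_ids = [f"SP{k + 1:03d}" for k in range(config.n_species)] + [
        f"BG{k + 1:03d}" for k in range(config.n_background_species)
    ]
    site_ids = [f"S{k + 1:04d}" for k in range(I)]
    years = np.arange(config.first_year, config.first_year + T)
    return TrueParams(
        b=b,
        u=u,
        a=a,
        delta1=config.delta_dt2,
        delta2=config.delta_dt3,
        z_true=z_true,
        species_ids=species_ids,
        site_ids=site_ids,
        years=years,
    )


def _visit_category(n_detected: np.ndarray) -> np.ndarray:
    """List-length category from the number of species recorded: 1; 2-3; >3."""
    cat = np.ones_like(n_detected)
    cat[(n_detected >= 2) & (n_detected <= 3)] = 2
    cat[n_detected > 3] = 3
    return cat


def simulate_records(truth: TrueParams, config: SimulationConfig) -> SimulatedRecords:
    """Generate presence-only records from the truth via the detection model.

    Visits are scheduled per site and year with a Poisson rate growing
    linearly from ``visits_per_site_year`` to ``visits_per_site_year *
    visit_growth`` across years. On each visit every present species is
    detected with probability expit(a_t + delta1*DT2 + delta2*DT3) where
    the category indicators come from the visit's realized list length.
    A single uniform draw per (visit, species) is reused while iterating
    the category to its fixed point, so detections are monotone in the
    category and the emitted records are self-consistent with the
    categories the preparation stage will derive from them. Visits on
    which no species is detected produce no records (presence-only data).
    """
    S = config.n_species + config.n_background_species
    I, T = config.n_sites, config.n_years
    if truth.z_true.shape != (S, I, T):
        raise ValueError(
            f"truth/config dimension mismatch: z_true {truth.z_true.shape} vs ({S}, {I}, {T})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    if T > 1:
        rates = config.visits_per_site_year * (
            1 + (config.visit_growth - 1) * np.arange(T) / (T - 1)
        )
    else:
        rates = np.array([config.visits_per_site_year])

    n_visits_sy = rng.poisson(rates[None, :], size=(I, T))  # sites x years
    visit_site = np.repeat(np.arange(I), n_visits_sy.sum(axis=1))
    visit_year = np.concatenate(
        [np.repeat(np.arange(T), n_visits_sy[i]) for i in range(I)]
    ) if I else np.empty(0, dtype=int)
    n_visits = visit_site.size

    # unique date within (site, year): sample distinct day-of-year per visit
    day_of_year = np.empty(n_visits, dtype=int)
    pos = 0
    for i in range(I):
        for t in range(T):
            k = n_visits_sy[i, t]
            if k:
                day_of_year[pos : pos + k] = rng.choice(365, size=min(k, 365), replace=False)[:k]
                pos += k

    # presence of each species on each visit
    present = truth.z_true[:, visit_site, visit_year].T.astype(bool)  # visits x species
    unif = rng.random((n_visits, S))

    # iterate list-length category to a self-consistent fixed point
    a_v = truth.a[visit_year]
    cat = np.ones(n_visits, dtype=int)
    for _ in range(4):
        offset = np.where(cat == 2, truth.delta1, np.where(cat == 3, truth.delta2, 0.0))
        p = expit(a_v[:, None] + offset[:, None])
        detected = present & (unif < p)
        new_cat = _visit_category(detected.sum(axis=1))
        new_cat[detected.sum(axis=1) == 0] = 1
        if np.array_equal(new_cat, cat):
            break
        cat = new_cat

    n_det = detected.sum(axis=1)
    cat = _visit_category(n_det)

    years_cal = truth.years[visit_year]
    dates = pd.to_datetime(
        {"year": years_cal, "month": np.ones(n_visits, int), "day": np.ones(n_visits, int)}
    ) + pd.to_timedelta(day_of_year, unit="D")

    v_idx, s_idx = np.nonzero(detected)
    records = pd.DataFrame(
        {
            "species": np.asarray(truth.species_ids)[s_idx],
            "site": np.asarray(truth.site_ids)[visit_site[v_idx]],
            "date": dates.values[v_idx],
        }
    )
    records["date"] = pd.to_datetime(records["date"]).dt.date
    records = records.sort_values(["site", "date", "species"], kind="stable").reset_index(
        drop=True
    )

    # rows stay in generation order so they align with detections[n_det > 0]
    kept = n_det > 0
    visits = pd.DataFrame(
        {
            "site": np.asarray(truth.site_ids)[visit_site[kept]],
            "date": pd.to_datetime(dates.values[kept]).date,
            "year": years_cal[kept],
            "n_species_recorded": n_det[kept],
            "category": cat[kept],
        }
    )

    return SimulatedRecords(
        records=records,
        visits=visits,
        detections=detected.astype(np.int8),
        visit_site=visit_site,
        visit_year=visit_year,
    )


def write_records(sim: SimulatedRecords, path: str | Path) -> None:
    """Write the records table as a species,site,date CSV (ISO dates)."""
    sim.records.to_csv(path, index=False)
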