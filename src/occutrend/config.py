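"""Configuration dataclasses for the simulation, model and pipeline stages.

All configs validate on construction and round-trip losslessly through
plain dicts (and hence YAML), so a run is fully described by its config
file plus the seeds recorded in output sidecars.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised when a config field fails validation; names the field."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{name}: {msg}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic biological-records generator.

    The generator draws from the same generative model the occupancy
    model assumes: per-species annual occupancy follows a random walk on
    the logit scale with site random effects, and detection on a visit
    depends on a year effect plus offsets for list-length categories 2
    (2-3 species) and 3 (>3 species).

    Parameters
    ----------
    n_species, n_sites, n_years
        Dimensions of the simulated community of focal species.
    n_background_species
        Additional species emulating the unmodelled remainder of the
        taxonomic group. In real recording schemes visits and list
        lengths arise from records of the *whole* group (hundreds of
        species), so virtually every recording event yields at least one
        record. A presence-only generator over a small community alone
        would silently drop empty outings, making the very existence of
        a visit informative about the focal species — a selection effect
        absent from real scheme data. Background species (identical
        generative model, ids "BG...") keep the visit process realistic;
        set to 0 to study the small-community artifact itself.
    visits_per_site_year
        Mean number of visits per site in the first year (Poisson rate).
    visit_growth
        Ratio of the last year's visit rate to the first year's; the rate
        grows linearly in between, emulating the temporal recording bias
        of volunteer datasets (more visits in recent years).
    baseline_occupancy
        Mean probability a site is occupied in year 1, across species.
    species_sd
        Logit-scale spread of species' initial occupancy around the
        baseline (heterogeneous true occupancy between species).
    site_effect_sd
        Logit-scale sd of the site random effect u_i.
    year_walk_sd
        Logit-scale sd of the annual random-walk innovations in the
        species year effect b_t.
    detection_year_sd
        Logit-scale sd of the annual detection effect a_t around the
        baseline detection logit.
    delta_dt2, delta_dt3
        Logit-scale detection offsets for list-length categories 2 and 3
        relative to single-species lists.
    baseline_detection
        Detection probability on a category-1 visit in an average year.
    seed
        Seed for all random draws; identical config + seed gives
        byte-identical output.
    """

    n_species: int = 20
    n_background_species: int = 40
    n_sites: int = 200
    n_years: int = 10
    visits_per_site_year: float = 2.0
    visit_growth: float = 2.0
    baseline_occupancy: float = 0.3
    species_sd: float = 0.7
    site_effect_sd: float = 1.0
    year_walk_sd: float = 0.15
    detection_year_sd: float = 0.3
    delta_dt2: float = 0.8
    delta_dt3: float = 1.6
    baseline_detection: float = 0.35
    seed: int = 0
    first_year: int = 2000

    def __post_init__(self) -> None:
        for name in ("n_species", "n_sites", "n_years"):
            _check(int(getattr(self, name)) >= 1, name, "must be >= 1")
            setattr(self, name, int(getattr(self, name)))
        _check(int(self.n_background_species) >= 0, "n_background_species", "must be >= 0")
        self.n_background_species = int(self.n_background_species)
        for name in ("site_effect_sd", "year_walk_sd", "detection_year_sd", "species_sd"):
            _check(getattr(self, name) >= 0, name, "must be >= 0")
        for name in ("baseline_occupancy", "baseline_detection"):
            _check(0 < getattr(self, name) < 1, name, "must be in (0, 1)")
        _check(self.visits_per_site_year > 0, "visits_per_site_year", "must be > 0")
        _check(self.visit_growth > 0, "visit_growth", "must be > 0")
        self.seed = int(self.seed)


@dataclass
class ModelConfig:
    """MCMC settings and priors for the occupancy-detection model.

    Defaults mirror common practice for this model family: 3 chains of
    20,000 iterations with a 10,000 burn-in and thinning of 3, retaining
    draws flagged (not dropped) when the Gelman-Rubin Rhat exceeds 1.1.

    ``rw_scale`` is the half-Cauchy scale of the random-walk innovation
    sd that smooths the annual state-model year effects b_t; ``re_scale``
    the half-Cauchy scale for the site and detection-year random-effect
    sds. ``b1_sd``, ``mu_a_sd`` and ``delta_sd`` are the sds of the vague
    normal priors on the initial year effect, the detection intercept and
    the list-length offsets.
    """

    n_chains: int = 3
    n_iterations: int = 20000
    burn_in: int = 10000
    thin: int = 3
    rhat_threshold: float = 1.1
    rw_scale: float = 1.0
    re_scale: float = 1.0
    b1_sd: float = 10.0
    mu_a_sd: float = 10.0
    delta_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_chains >= 1, "n_chains", "must be >= 1")
        _check(self.burn_in < self.n_iterations, "burn_in", "must be < n_iterations")
        _check(self.thin >= 1, "thin", "must be >= 1")
        _check(self.rhat_threshold > 1, "rhat_threshold", "must be > 1")
        for name in ("rw_scale", "re_scale", "b1_sd", "mu_a_sd", "delta_sd"):
            _check(getattr(self, name) > 0, name, "must be > 0")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (paths, windows, thresholds, seeds)."""

    records_path: str = "records.csv"
    prep_dir: str = "prep"
    posteriors_dir: str = "posteriors"
    results_dir: str = "results"
    year_min: int | None = None
    year_max: int | None = None
    min_records_per_species: int = 50
    min_years_per_site: int = 2
    exclusions_path: str | None = None
    groups_path: str | None = None
    n_cells_total: int = 240_000
    subsample_size: int = 1000
    subsample_seed: int = 42
    simulation: SimulationConfig | None = None
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        _check(self.min_records_per_species >= 0, "min_records_per_species", "must be >= 0")
        _check(self.min_years_per_site >= 1, "min_years_per_site", "must be >= 1")
        _check(self.subsample_size >= 1, "subsample_size", "must be >= 1")
        _check(self.n_cells_total >= 1, "n_cells_total", "must be >= 1")
        if isinstance(self.model, dict):
            self.model = ModelConfig(**self.model)
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
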