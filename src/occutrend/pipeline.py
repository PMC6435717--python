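"""File-based pipeline tying the stages into a reproducible dataflow.

Stages (simulate -> prepare -> fit -> trends) communicate only through
files; no stage mutates another stage's inputs. Every stage writes a
JSON provenance sidecar recording the configuration and seeds, so any
artifact can be regenerated exactly. Reruns with identical configs are
deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from occutrend.config import ConfigurationError, ModelConfig, PipelineConfig, SimulationConfig
from occutrend.model import compute_occupancy_series, fit_occupancy
from occutrend.prep import build_detection_history, build_visits, filter_records, load_records
from occutrend.simulate import simulate_records, simulate_truth
from occutrend.trends import (
    OccupancySamples,
    clip_series,
    composite_trend,
    evenness_series,
    first_derivative,
    net_change,
    species_growth_rate,
    subsample_posterior,
)

log = logging.getLogger("occutrend")

__all__ = [
    "stage_simulate",
    "stage_prepare",
    "stage_fit",
    "stage_trends",
    "run_pipeline",
]


def _write_sidecar(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def stage_simulate(config: SimulationConfig, records_path: str | Path, truth_dir: str | Path) -> None:
    """Generate a synthetic records CSV plus ground-truth parameter CSVs."""
    truth = simulate_truth(config)
    sim = simulate_records(truth, config)
    records_path = Path(records_path)
    records_path.parent.mkdir(parents=True, exist_ok=True)
    sim.records.to_csv(records_path, index=False)
    truth.to_csvs(truth_dir)
    _write_sidecar(records_path.with_suffix(".provenance.json"), {"stage": "simulate", "config": asdict(config)})
    log.info("simulate: %d records, %d visits", len(sim.records), len(sim.visits))


def stage_prepare(
    records_path: str | Path,
    prep_dir: str | Path,
    year_min: int | None = None,
    year_max: int | None = None,
    min_records_per_species: int = 50,
    min_years_per_site: int = 2,
    exclusions_path: str | Path | None = None,
) -> None:
    """Filter records, build the visit table and per-species metadata."""
    prep = Path(prep_dir)
    prep.mkdir(parents=True, exist_ok=True)
    records = load_records(records_path)
    exclusions = None
    if exclusions_path is not None:
        if not Path(exclusions_path).exists():
            raise ConfigurationError(f"exclusions_path: file not found: {exclusions_path}")
        exclusions = [
            line.strip() for line in Path(exclusions_path).read_text().splitlines() if line.strip()
        ]
    filtered, report = filter_records(
        records,
        year_min=year_min,
        year_max=year_max,
        min_records_per_species=min_records_per_species,
        min_years_per_site=min_years_per_site,
        exclude_species=exclusions,
    )
    visits = build_visits(filtered)
    filtered.to_csv(prep / "records_filtered.csv", index=False)
    visits.to_csv(prep / "visits.csv", index=False)
    report.to_json(prep / "filter_report.json")

    yrs = pd.to_datetime(filtered["date"]).dt.year if len(filtered) else pd.Series([], dtype=int)
    meta = (
        pd.DataFrame({"species": filtered["species"], "year": yrs})
        .groupby("species")["year"]
        .agg(n_records="size", first_record_year="min", last_record_year="max")
        .reset_index()
    )
    meta.to_csv(prep / "species_meta.csv", index=False)
    _write_sidecar(
        prep / "provenance.json",
        {
            "stage": "prepare",
            "records_path": str(records_path),
            "year_min": year_min,
            "year_max": year_max,
            "min_records_per_species": min_records_per_species,
            "min_years_per_site": min_years_per_site,
            "n_records_out": report.n_records_out,
            "n_visits": len(visits),
            "n_sites": int(visits["site"].nunique()) if len(visits) else 0,
            "n_species": int(filtered["species"].nunique()) if len(filtered) else 0,
        },
    )
    log.info(
        "prepare: %d -> %d records, %d visits, %d species",
        report.n_records_in,
        report.n_records_out,
        len(visits),
        meta.shape[0],
    )


def stage_fit(
    prep_dir: str | Path,
    posteriors_dir: str | Path,
    config: ModelConfig,
    species: list[str] | None = None,
) -> list[str]:
    """Fit the occupancy model per species; write occupancy draws and Rhat.

    Species whose detection history is degenerate (e.g. detected on
    every visit) are skipped with a log message. Per-species fits are
    independent, so results do not depend on execution order. Returns
    the list of species fitted.
    """
    prep = Path(prep_dir)
    out = Path(posteriors_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = load_records(prep / "records_filtered.csv")
    visits = pd.read_csv(prep / "visits.csv")
    visits["date"] = pd.to_datetime(visits["date"]).dt.date
    meta = pd.read_csv(prep / "species_meta.csv").set_index("species")

    todo = species if species is not None else sorted(records["species"].unique())
    fitted = []
    for k, sp in enumerate(todo):
        history = build_detection_history(records, visits, sp)
        # decorrelate per-species seeds while keeping them reproducible
        sp_config = ModelConfig(**{**asdict(config), "seed": (config.seed + 1000003 * k) & 0x7FFFFFFF})
        try:
            posterior = fit_occupancy(history, sp_config)
        except ValueError as exc:
            log.warning("fit: skipping %s (%s)", sp, exc)
            continue
        occ = compute_occupancy_series(posterior)
        df = pd.DataFrame(occ.samples, columns=occ.years)
        df.to_csv(out / f"occ_{sp}.csv", index=False)
        posterior.rhat.to_csv(out / f"rhat_{sp}.csv", index=False)
        _write_sidecar(
            out / f"occ_{sp}.json",
            {
                "stage": "fit",
                "species": sp,
                "n_sites": occ.n_sites,
                "years": [int(y) for y in occ.years],
                "first_record_year": int(meta.loc[sp, "first_record_year"]),
                "last_record_year": int(meta.loc[sp, "last_record_year"]),
                "n_draws": occ.n_draws,
                "n_rhat_flagged": int(posterior.rhat["flagged"].sum()),
                "config": asdict(sp_config),
            },
        )
        fitted.append(sp)
        log.info("fit: %s (%d/%d), %d draws", sp, k + 1, len(todo), occ.n_draws)
    return fitted


def _load_posteriors(posteriors_dir: str | Path) -> tuple[dict[str, OccupancySamples], dict[str, dict]]:
    out = Path(posteriors_dir)
    samples, meta = {}, {}
    for path in sorted(out.glob("occ_*.csv")):
        sp = path.stem[len("occ_") :]
        sidecar = json.loads(path.with_suffix(".json").read_text())
        df = pd.read_csv(path)
        samples[sp] = OccupancySamples(
            species=sp,
            years=np.array([int(c) for c in df.columns]),
            samples=df.to_numpy(),
            n_sites=sidecar["n_sites"],
        )
        meta[sp] = sidecar
    return samples, meta


def stage_trends(
    posteriors_dir: str | Path,
    results_dir: str | Path,
    groups_path: str | Path | None = None,
    n_cells_total: int = 240_000,
    subsample_size: int = 1000,
    subsample_seed: int = 42,
) -> None:
    """Compute species trends, composites, evenness, derivatives, net change.

    Species trends use each species' clipped series (between its first
    and last record years). Composite trends per group are fitted on the
    clipped, possibly unbalanced, species x year table; evenness and the
    derivative series use the full modelled span so that species share a
    common year axis.
    """
    res = Path(results_dir)
    res.mkdir(parents=True, exist_ok=True)
    samples, meta = _load_posteriors(posteriors_dir)
    if not samples:
        raise ConfigurationError(f"posteriors_dir: no posterior files in {posteriors_dir}")

    groups: dict[str, list[str]] = {"all": sorted(samples)}
    if groups_path is not None:
        if not Path(groups_path).exists():
            raise ConfigurationError(f"groups_path: file not found: {groups_path}")
        gdf = pd.read_csv(groups_path, dtype=str)
        if "species" not in gdf.columns:
            raise ConfigurationError("groups_path: file must have a 'species' column")
        for col in [c for c in gdf.columns if c != "species"]:
            for label, members in gdf.groupby(col)["species"]:
                key = f"{col}:{label}"
                groups[key] = sorted(set(members) & set(samples))

    sub = {
        sp: subsample_posterior(s, k=subsample_size, seed=(subsample_seed + i) & 0x7FFFFFFF)
        for i, (sp, s) in enumerate(sorted(samples.items()))
    }

    clipped: dict[str, OccupancySamples] = {}
    trend_rows = []
    for sp, s in sorted(sub.items()):
        try:
            c = clip_series(s, meta[sp]["first_record_year"], meta[sp]["last_record_year"])
        except ValueError as exc:
            log.warning("trends: %s excluded from trend (%s)", sp, exc)
            continue
        clipped[sp] = c
        t = species_growth_rate(c)
        trend_rows.append(
            {
                "species": sp,
                "first_year": t.first_year,
                "last_year": t.last_year,
                "rate_median": t.rate_median,
                "rate_lower": t.rate_lower,
                "rate_upper": t.rate_upper,
                "classification": t.classification,
            }
        )
    trends_df = pd.DataFrame(trend_rows)
    trends_df.to_csv(res / "trends.csv", index=False)

    comp_rows, deriv_rows, even_rows = [], [], []
    for label, members in sorted(groups.items()):
        member_clipped = [clipped[sp] for sp in members if sp in clipped]
        member_full = [sub[sp] for sp in members if sp in sub]
        if not member_clipped:
            continue
        comp = composite_trend(member_clipped, group=label)
        lo95, hi95 = comp.ci(0.95)
        lo80, hi80 = comp.ci(0.80)
        for j, year in enumerate(comp.years):
            comp_rows.append(
                {
                    "group": label,
                    "year": int(year),
                    "median": comp.median[j],
                    "lower95": lo95[j],
                    "upper95": hi95[j],
                    "lower80": lo80[j],
                    "upper80": hi80[j],
                    "n_species": comp.n_species,
                }
            )
        full_comp = composite_trend(member_full, group=label)
        deriv = first_derivative(full_comp)
        for j, year in enumerate(deriv.years):
            deriv_rows.append(
                {
                    "group": label,
                    "year": int(year),
                    "metric": "composite",
                    "median": deriv.median[j],
                    "lower95": deriv.lower95[j],
                    "upper95": deriv.upper95[j],
                    "lower80": deriv.lower80[j],
                    "upper80": deriv.upper80[j],
                    "flag": deriv.flags[j],
                }
            )
        if len(member_full) >= 2:
            even = evenness_series(member_full, group=label)
            elo95, ehi95 = even.ci(0.95)
            elo80, ehi80 = even.ci(0.80)
            for j, year in enumerate(even.years):
                even_rows.append(
                    {
                        "group": label,
                        "year": int(year),
                        "median": even.median[j],
                        "lower95": elo95[j],
                        "upper95": ehi95[j],
                        "lower80": elo80[j],
                        "upper80": ehi80[j],
                    }
                )
            ederiv = first_derivative(even)
            for j, year in enumerate(ederiv.years):
                deriv_rows.append(
                    {
                        "group": label,
                        "year": int(year),
                        "metric": "evenness",
                        "median": ederiv.median[j],
                        "lower95": ederiv.lower95[j],
                        "upper95": ederiv.upper95[j],
                        "lower80": ederiv.lower80[j],
                        "upper80": ederiv.upper80[j],
                        "flag": ederiv.flags[j],
                    }
                )

    pd.DataFrame(comp_rows).to_csv(res / "composite.csv", index=False)
    pd.DataFrame(even_rows).to_csv(res / "evenness.csv", index=False)
    pd.DataFrame(deriv_rows).to_csv(res / "derivatives.csv", index=False)
    if clipped:
        net_change(clipped, n_cells_total=n_cells_total).to_csv(res / "net_change.csv", index=False)
    _write_sidecar(
        res / "provenance.json",
        {
            "stage": "trends",
            "posteriors_dir": str(posteriors_dir),
            "groups_path": str(groups_path) if groups_path else None,
            "n_cells_total": n_cells_total,
            "subsample_size": subsample_size,
            "subsample_seed": subsample_seed,
            "n_species_trended": len(clipped),
        },
    )
    log.info("trends: %d species, %d groups", len(clipped), len(groups))


def run_pipeline(config: PipelineConfig) -> None:
    """Run (optional) simulate -> prepare -> fit -> trends end to end.

    A stage failure raises with the stage named; artifacts written by
    completed stages are valid on their own. Reruns with an identical
    config produce identical output tables.
    """
    stages: list[tuple[str, callable]] = []
    if config.simulation is not None:
        stages.append(
            (
                "simulate",
                lambda: stage_simulate(
                    config.simulation, config.records_path, Path(config.prep_dir) / "truth"
                ),
            )
        )
    stages += [
        (
            "prepare",
            lambda: stage_prepare(
                config.records_path,
                config.prep_dir,
                year_min=config.year_min,
                year_max=config.year_max,
                min_records_per_species=config.min_records_per_species,
                min_years_per_site=config.min_years_per_site,
                exclusions_path=config.exclusions_path,
            ),
        ),
        ("fit", lambda: stage_fit(config.prep_dir, config.posteriors_dir, config.model)),
        (
            "trends",
            lambda: stage_trends(
                config.posteriors_dir,
                config.results_dir,
                groups_path=config.groups_path,
                n_cells_total=config.n_cells_total,
                subsample_size=config.subsample_size,
                subsample_seed=config.subsample_seed,
            ),
        ),
    ]
    for name, fn in stages:
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
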