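import numpy as np
import pandas as pd
import pytest

from occutrend.config import ModelConfig, SimulationConfig
from occutrend.simulate import simulate_records, simulate_truth


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated community reused across read-only tests."""
    cfg = SimulationConfig(
        n_species=25, n_sites=60, n_years=8, visits_per_site_year=2.5, seed=101
    )
    truth = simulate_truth(cfg)
    sim = simulate_records(truth, cfg)
    return cfg, truth, sim


@pytest.fixture
def fast_model_config():
    return ModelConfig(n_chains=2, n_iterations=600, burn_in=300, thin=3, seed=5)


@pytest.fixture
def toy_records():
    """Hand-constructed records table with known visit structure."""
    rows = [
        # site A, day 1: 2 species -> category 2
        ("spA", "A", "2001-05-01"),
        ("spB", "A", "2001-05-01"),
        # site A, day 2: 1 species -> category 1
        ("spA", "A", "2001-06-01"),
        # site B, day 1: 5 species -> category 3
        *[(f"sp{c}", "B", "2002-05-01") for c in "ABCDE"],
        # site B, day 2: 3 species -> category 2
        ("spA", "B", "2002-06-01"),
        ("spB", "B", "2002-06-01"),
        ("spC", "B", "2002-06-01"),
    ]
    df = pd.DataFrame(rows, columns=["species", "site", "date"])
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def make_records(n_per_species: dict[str, int], site="S1", start_year=2000) -> pd.DataFrame:
    """Records with a given per-species count, one record per day."""
    rows = []
    for sp, n in n_per_species.items():
        dates = pd.date_range(f"{start_year}-01-01", periods=n, freq="D")
        rows += [(sp, site, d.date()) for d in dates]
    return pd.DataFrame(rows, columns=["species", "site", "date"])
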