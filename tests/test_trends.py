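"""Tests of trend, composite, evenness, derivative and net-change statistics."""

import numpy as np
import pytest

from occutrend.model import OccupancySamples
from occutrend.trends import (
    clip_series,
    composite_trend,
    evenness_series,
    first_derivative,
    net_change,
    simpson_evenness,
    species_growth_rate,
    subsample_posterior,
)


def make_samples(
    values, species="sp", years=None, n_draws=200, noise=0.0, seed=0, n_sites=100, lo=0.01
):
    """Occupancy draws around a deterministic series.

    The default lower clip stays above the epsilon floor of a
    100-site grid (1/200), so log-scale statistics are exact.
    """
    values = np.asarray(values, dtype=float)
    years = np.arange(2000, 2000 + len(values)) if years is None else np.asarray(years)
    rng = np.random.default_rng(seed)
    draws = np.clip(values[None, :] + noise * rng.standard_normal((n_draws, len(values))), lo, 1)
    return OccupancySamples(species=species, years=years, samples=draws, n_sites=n_sites)


class TestSubsample:
    def test_reduces_to_k(self):
        s = make_samples([0.5] * 5, n_draws=3000)
        out = subsample_posterior(s, k=1000, seed=1)
        assert out.samples.shape == (1000, 5)

    def test_identity_when_k_exceeds_draws(self):
        s = make_samples([0.5] * 5, n_draws=100)
        with pytest.warns(UserWarning, match="only 100 draws"):
            out = subsample_posterior(s, k=1000, seed=1)
        assert out.samples.shape == (100, 5)

    def test_seed_reproducible_and_without_replacement(self):
        s = make_samples([0.5] * 3, n_draws=500, noise=0.1)
        a = subsample_posterior(s, k=200, seed=7)
        b = subsample_posterior(s, k=200, seed=7)
        assert np.array_equal(a.samples, b.samples)
        # without replacement: all selected rows distinct
        assert len(np.unique(a.samples[:, 0])) > 190


class TestClip:
    def test_clipping_rule(self):
        s = make_samples([0.5] * 34, years=np.arange(1980, 2014))
        c = clip_series(s, 1985, 2010)
        assert c.years[0] == 1985 and c.years[-1] == 2010
        assert c.samples.shape[1] == 26

    def test_full_span_identity(self):
        s = make_samples([0.5] * 10)
        c = clip_series(s, 1990, 2020)
        assert np.array_equal(c.samples, s.samples)

    def test_single_year_raises(self):
        s = make_samples([0.5] * 10)
        with pytest.raises(ValueError, match="< 2 years"):
            clip_series(s, 2003, 2003)


class TestGrowthRate:
    def test_flat_series_zero_rate(self):
        s = make_samples([0.4] * 8)
        t = species_growth_rate(s)
        assert t.rate_median == pytest.approx(0.0, abs=1e-12)
        assert t.classification == "no clear trend"

    def test_doubling_over_ten_years(self):
        # 0.1 -> 0.2 over a 10-year gap: 100*(2**0.1 - 1) = 7.177 %/yr
        s = make_samples([0.1] + [0.15] * 9 + [0.2], years=np.arange(2000, 2011))
        t = species_growth_rate(s)
        assert t.rate_median == pytest.approx(7.177, abs=0.01)

    def test_arithmetic_variant(self):
        s = make_samples([0.1] + [0.15] * 9 + [0.2], years=np.arange(2000, 2011))
        t = species_growth_rate(s, compound=False)
        # 100 * (0.2 - 0.1) / (0.1 * 10) = 10 %/yr
        assert t.rate_median == pytest.approx(10.0, abs=1e-9)

    def test_declining_series_classified_decreasing(self):
        s = make_samples([0.5, 0.4, 0.3, 0.2], noise=0.005, seed=3)
        t = species_growth_rate(s)
        assert t.classification == "decreasing"
        assert t.rate_upper < 0

    def test_increasing_series_classified_increasing(self):
        s = make_samples([0.2, 0.3, 0.4, 0.5], noise=0.005, seed=3)
        assert species_growth_rate(s).classification == "increasing"

    def test_zero_occupancy_floored_not_infinite(self):
        s = make_samples([1e-9, 0.2], n_sites=50, lo=1e-12)
        t = species_growth_rate(s)
        assert np.isfinite(t.rate_median)


class TestComposite:
    def test_two_species_geometric_mean(self):
        a = make_samples([0.1] * 4)
        b = make_samples([0.4] * 4, species="b")
        comp = composite_trend([a, b])
        assert np.allclose(comp.samples, 0.2)

    def test_single_species_identity(self):
        a = make_samples([0.3, 0.25, 0.2], noise=0.01, seed=5)
        comp = composite_trend([a])
        assert np.allclose(comp.samples, a.samples)

    def test_identical_species_equal_common_series(self):
        vals = [0.3, 0.2, 0.4, 0.35]
        group = [make_samples(vals, species=f"s{i}") for i in range(3)]
        comp = composite_trend(group)
        assert np.allclose(comp.samples, np.asarray(vals)[None, :])

    def test_complete_table_equals_geometric_mean_exactly(self):
        rng = np.random.default_rng(8)
        group = [
            make_samples(rng.uniform(0.05, 0.9, 6), species=f"s{i}", noise=0.02, seed=i)
            for i in range(5)
        ]
        comp = composite_trend(group)
        gm = np.exp(np.mean([np.log(s.samples) for s in group], axis=0))
        assert np.allclose(comp.samples, gm, rtol=1e-10, atol=1e-12)

    def test_unbalanced_matches_normal_equations_oracle(self):
        # one species missing early years: compare against an independent
        # least-squares solve of the same sum-contrast design
        full = make_samples([0.3, 0.25, 0.28, 0.26], noise=0.02, seed=1)
        late = make_samples([0.1, 0.12], years=np.arange(2002, 2004),
                            species="late", noise=0.02, seed=2)
        comp = composite_trend([full, late])

        # oracle: explicit normal equations per draw on a small instance
        years = np.arange(2000, 2004)
        cells = [(0, t) for t in range(4)] + [(1, 2), (1, 3)]
        X = []
        for sp, t in cells:
            row = [1.0]
            row += [(1.0 if t == j else 0.0) - (1.0 if t == 3 else 0.0) for j in range(3)]
            row += [(1.0 if sp == 0 else 0.0) - (1.0 if sp == 1 else 0.0)]
            X.append(row)
        X = np.asarray(X)
        draws = full.n_draws
        expected = np.empty((draws, 4))
        for d in range(draws):
            yvec = np.concatenate([np.log(full.samples[d]), np.log(late.samples[d])])
            beta = np.linalg.solve(X.T @ X, X.T @ yvec)
            year_eff = np.append(beta[1:4], -beta[1:4].sum())
            expected[d] = np.exp(beta[0] + year_eff)
        assert np.allclose(comp.samples, expected, rtol=1e-8)

    def test_order_invariance(self):
        group = [make_samples([0.2, 0.3], species=f"s{i}", noise=0.01, seed=i) for i in range(4)]
        a = composite_trend(group)
        b = composite_trend(group[::-1])
        assert np.allclose(a.samples, b.samples)


class TestEvenness:
    def test_equal_shares_log_s(self):
        assert simpson_evenness(np.full(4, 0.2)) == pytest.approx(np.log(4))
        assert simpson_evenness(np.full(7, 0.61)) == pytest.approx(np.log(7))

    def test_dominance_approaches_zero(self):
        vals = np.array([0.9, 1e-9, 1e-9])
        assert simpson_evenness(vals) == pytest.approx(0.0, abs=1e-6)

    def test_half_quarter_quarter(self):
        # D = 0.25 + 0.0625 + 0.0625 = 0.375
        assert simpson_evenness(np.array([0.5, 0.25, 0.25])) == pytest.approx(-np.log(0.375))

    def test_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            occ = rng.uniform(0.01, 1, size=rng.integers(2, 10))
            ev = simpson_evenness(occ)
            assert 0 < ev <= np.log(len(occ)) + 1e-12

    def test_scale_invariance(self):
        occ = np.array([0.1, 0.3, 0.6])
        assert simpson_evenness(occ) == pytest.approx(simpson_evenness(occ * 0.25))

    def test_all_zero_draw_is_nan(self):
        occ = np.zeros((3, 2))
        occ[:, 1] = [0.2, 0.3, 0.5]
        with pytest.warns(UserWarning, match="all-zero"):
            out = simpson_evenness(occ)
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_series_per_draw(self):
        group = [make_samples([0.2, 0.2], species=f"s{i}") for i in range(4)]
        series = evenness_series(group)
        assert np.allclose(series.samples, np.log(4))


class TestDerivative:
    def test_constant_series_no_flags(self):
        comp = composite_trend([make_samples([0.3] * 5, noise=0.0)])
        deriv = first_derivative(comp)
        assert np.allclose(deriv.samples, 0.0)
        assert (deriv.flags == "none").all()

    def test_monotone_increase_all_flagged(self):
        comp = composite_trend([make_samples([0.2, 0.3, 0.4, 0.5], noise=0.001, seed=2)])
        deriv = first_derivative(comp)
        assert (deriv.flags == "increase").all()

    def test_engineered_drop_year_uniquely_flagged(self):
        # a single large drop in 2003 against small posterior spread
        vals = [0.50, 0.50, 0.50, 0.30, 0.30, 0.30]
        comp = composite_trend([make_samples(vals, noise=0.01, seed=4)])
        deriv = first_derivative(comp)
        assert deriv.flags[list(deriv.years).index(2003)] == "decrease"
        assert (deriv.flags == "decrease").sum() == 1

    def test_ci_nesting(self):
        comp = composite_trend([make_samples([0.3, 0.4, 0.2], noise=0.05, seed=6)])
        d = first_derivative(comp)
        assert (d.lower95 <= d.lower80).all() and (d.upper80 <= d.upper95).all()


class TestNetChange:
    def test_hand_computed_sum(self):
        # delta occupancies +0.1, -0.2, -0.1 -> per-cell -0.2; x240000 = -48000
        species = {
            "up": make_samples([0.2, 0.3]),
            "down": make_samples([0.5, 0.3]),
            "down2": make_samples([0.3, 0.2]),
        }
        out = net_change(species, n_cells_total=240_000)
        assert out.loc[0, "per_cell_median"] == pytest.approx(-0.2)
        assert out.loc[0, "extrapolated_median"] == pytest.approx(-48_000)

    def test_no_change_zero(self):
        out = net_change({"a": make_samples([0.4, 0.4])}, n_cells_total=1000)
        assert out.loc[0, "per_cell_median"] == pytest.approx(0.0)

    def test_random_cohort_matches_direct_summation(self):
        rng = np.random.default_rng(12)
        species = {
            f"s{i}": make_samples(rng.uniform(0.05, 0.8, 3), noise=0.02, seed=i)
            for i in range(6)
        }
        out = net_change(species, n_cells_total=10_000)
        direct = sum(s.samples[:, -1] - s.samples[:, 0] for s in species.values())
        assert out.loc[0, "per_cell_median"] == pytest.approx(np.median(direct))
        assert out.loc[0, "extrapolated_median"] == pytest.approx(np.median(direct) * 10_000)
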