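"""Hierarchical Bayesian occupancy-detection model, fitted per species.

The model couples a state process and an observation process::

    z_it ~ Bernoulli(psi_it),        logit(psi_it) = b_t + u_i
    y_itv | z_it ~ Bernoulli(z_it * p_itv),
    logit(p_itv) = a_t + delta1 * DT2_itv + delta2 * DT3_itv

where z_it is the latent presence of the species at site i in year t,
b_t a year effect smoothed by a first-order random walk whose innovation
sd carries a half-Cauchy prior, u_i a zero-mean normal site effect, a_t
a normal random year effect on detection, and delta1/delta2 the effects
of list-length categories 2 (2-3 species) and 3 (>3 species) relative to
single-species lists.

Inference is by Markov chain Monte Carlo written for this model: the
latent z_it are updated by Gibbs steps using the closed-form conditional
(see :func:`conditional_z_probability`), the logistic-scale parameters
by adaptive Metropolis-within-Gibbs (proposal scales tuned during
burn-in only, frozen afterwards so the retained chain is a valid MCMC
sample), and the variance hyperparameters by conjugate Gibbs steps via
the inverse-gamma scale-mixture representation of the half-Cauchy.
Convergence is monitored with the Gelman-Rubin Rhat across chains;
parameters exceeding the threshold are flagged but retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from occutrend.config import ModelConfig
from occutrend.prep import DetectionHistory

__all__ = [
    "FixedParams",
    "OccupancyPosterior",
    "OccupancySamples",
    "fit_occupancy",
    "conditional_z_probability",
    "compute_occupancy_series",
    "compute_rhat",
]

_ADAPT_TARGET = 0.44  # optimal acceptance for scalar random-walk Metropolis


@dataclass
class FixedParams:
    """Fix all non-latent parameters (validation/debugging use).

    When passed to :func:`fit_occupancy` only the latent presences z are
    sampled, allowing the Gibbs z-update to be checked against exact
    enumeration on instances small enough to enumerate.
    """

    b: np.ndarray
    u: np.ndarray
    a: np.ndarray
    delta1: float
    delta2: float


@dataclass
class OccupancyPosterior:
    """Retained MCMC draws for one species.

    Sample arrays are stacked over chains (``chain_id`` gives
    provenance). ``z`` is draws x sites x years; ``b``/``a`` draws x
    years; ``u`` draws x sites. ``rhat`` is a per-parameter table with a
    ``flagged`` column for values above the configured threshold.
    """

    species: str
    years: np.ndarray
    site_ids: list[str]
    z: np.ndarray
    b: np.ndarray
    u: np.ndarray
    a: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    mu_a: np.ndarray
    sigma_rw: np.ndarray
    sigma_u: np.ndarray
    sigma_a: np.ndarray
    chain_id: np.ndarray
    rhat: pd.DataFrame
    config: ModelConfig

    @property
    def psi(self) -> np.ndarray:
        """Occupancy probability per draw: draws x sites x years."""
        return expit(self.b[:, None, :] + self.u[:, :, None])

    def occupancy(self) -> np.ndarray:
        """Annual proportion of occupied sites per draw: draws x years."""
        return self.z.mean(axis=1)

    @property
    def n_draws(self) -> int:
        return self.z.shape[0]


@dataclass
class OccupancySamples:
    """Posterior draws of annual occupancy for one species (draws x years)."""

    species: str
    years: np.ndarray
    samples: np.ndarray
    n_sites: int

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape[1] != len(self.years):
            raise ValueError("samples/years length mismatch")

    @property
    def n_draws(self) -> int:
        return self.samples.shape[0]


def conditional_z_probability(
    psi: float, p: Sequence[float] | np.ndarray, y: Sequence[int] | np.ndarray
) -> float:
    """Posterior probability a site-year is occupied given its visit history.

    If the species was detected on any visit, occupancy is certain
    (the model allows no false presences). Otherwise

        P(z=1 | no detections) = psi * q / (psi * q + 1 - psi),
        q = prod_v (1 - p_v),

    i.e. Bayes' rule with the probability q of missing the species on
    every visit. With no visits at all the prior psi is returned.
    """
    if not 0 < psi < 1:
        raise ValueError("psi must be in (0, 1)")
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    if p.size and (np.any(p <= 0) or np.any(p >= 1)):
        raise ValueError("detection probabilities must be in (0, 1)")
    if y.size and y.any():
        return 1.0
    if p.size == 0:
        return float(psi)
    q = float(np.prod(1.0 - p))
    return psi * q / (psi * q + 1.0 - psi)


def compute_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    ``chains`` is an (n_chains, n_draws) array. Requires at least two
    chains of equal length. Values near 1 indicate the chains are
    sampling the same distribution.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("compute_rhat requires >= 2 chains of equal length")
    m, n = chains.shape
    if n < 2:
        raise ValueError("chains too short for Rhat")
    within = chains.var(axis=1, ddof=1).mean()
    between = n * chains.mean(axis=1).var(ddof=0) * m / (m - 1)
    if within == 0:
        return 1.0 if between == 0 else np.inf
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _inv_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return 1.0 / rng.gamma(shape, 1.0 / scale)


def _sample_halfcauchy_sd(
    rng: np.random.Generator, resid_ss: float, n: int, aux: float, hc_scale: float
) -> tuple[float, float]:
    """Gibbs step for sigma^2 with sigma ~ half-Cauchy(hc_scale).

    Uses the inverse-gamma mixture: sigma^2 | aux ~ IG(1/2, 1/aux) and
    aux ~ IG(1/2, 1/hc_scale^2), which marginally gives the half-Cauchy.
    """
    var = _inv_gamma(rng, (n + 1) / 2.0, 1.0 / aux + resid_ss / 2.0)
    aux = _inv_gamma(rng, 1.0, 1.0 / hc_scale**2 + 1.0 / var)
    return float(np.sqrt(var)), aux


class _ChainState:
    """Mutable state and adaptive proposal scales for one MCMC chain."""

    def __init__(self, hist: DetectionHistory, config: ModelConfig, rng: np.random.Generator):
        I, T = hist.n_sites, hist.n_years
        self.rng = rng
        det_rate = hist.y.mean()
        jitter = rng.normal(0, 0.5)
        self.b = np.full(T, logit(np.clip(hist.y.mean() * 2, 0.05, 0.95))) + rng.normal(
            0, 0.3, T
        )
        self.u = rng.normal(0, 0.1, I)
        self.mu_a = float(logit(np.clip(det_rate, 0.05, 0.95)) + jitter)
        self.a = self.mu_a + rng.normal(0, 0.1, T)
        self.d1 = rng.normal(0, 0.2)
        self.d2 = rng.normal(0, 0.2)
        self.sigma_rw = 0.2
        self.sigma_u = 1.0
        self.sigma_a = 0.5
        self.aux_rw = self.aux_u = self.aux_a = 1.0
        # z starts at 1 wherever the species was ever detected at the site
        ever = np.zeros(I, dtype=bool)
        ever[np.unique(hist.site_index[hist.y == 1])] = True
        self.z = (rng.random((I, T)) < 0.5).astype(np.int8)
        self.z[ever, :] = 1
        # adaptive log proposal scales
        self.ls_b = np.full(T, np.log(0.5))
        self.ls_u = np.full(I, np.log(0.5))
        self.ls_a = np.full(T, np.log(0.5))
        self.ls_d = np.full(2, np.log(0.2))


def _state_loglik_cols(b_vals: np.ndarray, u: np.ndarray, z_cols: np.ndarray) -> np.ndarray:
    """Bernoulli-logit loglik of z columns given candidate b values.

    ``b_vals`` (k,), ``z_cols`` (I, k); returns per-column sums.
    """
    eta = u[:, None] + b_vals[None, :]
    return (z_cols * eta - _softplus(eta)).sum(axis=0)


def _run_chain(
    hist: DetectionHistory,
    config: ModelConfig,
    rng: np.random.Generator,
    fixed: FixedParams | None,
) -> dict[str, np.ndarray]:
    I, T = hist.n_sites, hist.n_years
    y = hist.y.astype(float)
    vsite, vyear = hist.site_index, hist.year_index
    off_cov = np.stack([hist.dt2.astype(float), hist.dt3.astype(float)])
    sy = vsite * T + vyear
    det_any = np.zeros((I, T), dtype=bool)
    det_any[vsite[hist.y == 1], vyear[hist.y == 1]] = True

    st = _ChainState(hist, config, rng)
    if fixed is not None:
        st.b = np.asarray(fixed.b, dtype=float).copy()
        st.u = np.asarray(fixed.u, dtype=float).copy()
        st.a = np.asarray(fixed.a, dtype=float).copy()
        st.d1, st.d2 = float(fixed.delta1), float(fixed.delta2)

    n_ret = config.n_retained_per_chain
    out = {
        "z": np.empty((n_ret, I, T), dtype=np.int8),
        "b": np.empty((n_ret, T)),
        "u": np.empty((n_ret, I)),
        "a": np.empty((n_ret, T)),
        "delta1": np.empty(n_ret),
        "delta2": np.empty(n_ret),
        "mu_a": np.empty(n_ret),
        "sigma_rw": np.empty(n_ret),
        "sigma_u": np.empty(n_ret),
        "sigma_a": np.empty(n_ret),
    }

    even = np.arange(0, T, 2)
    odd = np.arange(1, T, 2)
    kept = 0

    for it in range(config.n_iterations):
        adapting = it < config.burn_in
        gain = 2.0 / np.sqrt(it + 10.0)

        # --- latent z | everything: exact Gibbs using the closed form ---
        eta_p = st.a[vyear] + st.d1 * off_cov[0] + st.d2 * off_cov[1]
        log_q = np.bincount(sy, weights=-_softplus(eta_p), minlength=I * T).reshape(I, T)
        eta_psi = st.u[:, None] + st.b[None, :]
        # P(z=1 | no det) = psi*q / (psi*q + 1-psi) computed stably via logits
        logit_cond = eta_psi + log_q
        prob = expit(logit_cond)
        st.z = (rng.random((I, T)) < prob).astype(np.int8)
        st.z[det_any] = 1

        if fixed is None:
            zf = st.z.astype(float)

            # --- b_t | z, u, sigma_rw: even/odd adaptive MH ---
            for idx in (even, odd):
                if idx.size == 0:
                    continue
                step = np.exp(st.ls_b[idx]) * rng.standard_normal(idx.size)
                prop = st.b.copy()
                prop[idx] += step
                ll_cur = _state_loglik_cols(st.b[idx], st.u, zf[:, idx])
                ll_prop = _state_loglik_cols(prop[idx], st.u, zf[:, idx])
                lp_cur = _rw_logprior(st.b, idx, config, st.sigma_rw)
                lp_prop = _rw_logprior(prop, idx, config, st.sigma_rw)
                acc = np.log(rng.random(idx.size)) < (ll_prop + lp_prop - ll_cur - lp_cur)
                st.b[idx[acc]] = prop[idx[acc]]
                if adapting:
                    st.ls_b[idx] += gain * (acc - _ADAPT_TARGET)

            # --- u_i | z, b, sigma_u: parallel adaptive MH ---
            step = np.exp(st.ls_u) * rng.standard_normal(I)
            prop_u = st.u + step
            eta_c = st.u[:, None] + st.b[None, :]
            eta_pr = prop_u[:, None] + st.b[None, :]
            ll_cur = (zf * eta_c - _softplus(eta_c)).sum(axis=1)
            ll_prop = (zf * eta_pr - _softplus(eta_pr)).sum(axis=1)
            lp = -0.5 * (prop_u**2 - st.u**2) / st.sigma_u**2
            acc = np.log(rng.random(I)) < (ll_prop - ll_cur + lp)
            st.u[acc] = prop_u[acc]
            if adapting:
                st.ls_u += gain * (acc - _ADAPT_TARGET)

            # --- detection parameters on visits at occupied site-years ---
            m = st.z.reshape(-1)[sy].astype(float)
            off = st.d1 * off_cov[0] + st.d2 * off_cov[1]

            # a_t: parallel MH (likelihood factorizes over years given z)
            step = np.exp(st.ls_a) * rng.standard_normal(T)
            eta_c = st.a[vyear] + off
            eta_pr = eta_c + step[vyear]
            contrib_c = m * (y * eta_c - _softplus(eta_c))
            contrib_p = m * (y * eta_pr - _softplus(eta_pr))
            ll_cur = np.bincount(vyear, weights=contrib_c, minlength=T)
            ll_prop = np.bincount(vyear, weights=contrib_p, minlength=T)
            prop_a = st.a + step
            lp = -0.5 * ((prop_a - st.mu_a) ** 2 - (st.a - st.mu_a) ** 2) / st.sigma_a**2
            acc = np.log(rng.random(T)) < (ll_prop - ll_cur + lp)
            st.a[acc] = prop_a[acc]
            if adapting:
                st.ls_a += gain * (acc - _ADAPT_TARGET)

            # delta1, delta2: scalar MH
            for j, name in ((0, "d1"), (1, "d2")):
                cur = getattr(st, name)
                prop = cur + np.exp(st.ls_d[j]) * rng.standard_normal()
                base = st.a[vyear] + st.d1 * off_cov[0] + st.d2 * off_cov[1]
                eta_pr = base + (prop - cur) * off_cov[j]
                ll_cur = np.sum(m * (y * base - _softplus(base)))
                ll_prop = np.sum(m * (y * eta_pr - _softplus(eta_pr)))
                lp = -0.5 * (prop**2 - cur**2) / config.delta_sd**2
                acc = np.log(rng.random()) < (ll_prop - ll_cur + lp)
                if acc:
                    setattr(st, name, prop)
                if adapting:
                    st.ls_d[j] += gain * (float(acc) - _ADAPT_TARGET)

            # mu_a: conjugate normal
            prec = T / st.sigma_a**2 + 1.0 / config.mu_a_sd**2
            mean = (st.a.sum() / st.sigma_a**2) / prec
            st.mu_a = float(mean + rng.standard_normal() / np.sqrt(prec))

            # variance hyperparameters: conjugate via half-Cauchy mixture
            if T > 1:
                innov = np.diff(st.b)
                st.sigma_rw, st.aux_rw = _sample_halfcauchy_sd(
                    rng, float(innov @ innov), T - 1, st.aux_rw, config.rw_scale
                )
            st.sigma_u, st.aux_u = _sample_halfcauchy_sd(
                rng, float(st.u @ st.u), I, st.aux_u, config.re_scale
            )
            resid = st.a - st.mu_a
            st.sigma_a, st.aux_a = _sample_halfcauchy_sd(
                rng, float(resid @ resid), T, st.aux_a, config.re_scale
            )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and kept < n_ret:
            out["z"][kept] = st.z
            out["b"][kept] = st.b
            out["u"][kept] = st.u
            out["a"][kept] = st.a
            out["delta1"][kept] = st.d1
            out["delta2"][kept] = st.d2
            out["mu_a"][kept] = st.mu_a
            out["sigma_rw"][kept] = st.sigma_rw
            out["sigma_u"][kept] = st.sigma_u
            out["sigma_a"][kept] = st.sigma_a
            kept += 1

    return out


def _rw_logprior(
    b: np.ndarray, idx: np.ndarray, config: ModelConfig, sigma_rw: float
) -> np.ndarray:
    """Random-walk prior terms touching each index (neighbours only)."""
    T = b.size
    lp = np.zeros(idx.size)
    first = idx == 0
    lp[first] = -0.5 * (b[0] / config.b1_sd) ** 2
    prev = idx > 0
    lp[prev] += -0.5 * ((b[idx[prev]] - b[idx[prev] - 1]) / sigma_rw) ** 2
    nxt = idx < T - 1
    lp[nxt] += -0.5 * ((b[idx[nxt] + 1] - b[idx[nxt]]) / sigma_rw) ** 2
    return lp


def fit_occupancy(
    history: DetectionHistory,
    config: ModelConfig,
    fixed_params: FixedParams | None = None,
) -> OccupancyPosterior:
    """Fit the occupancy-detection model to one species' detection history.

    Runs ``config.n_chains`` independent chains, discards ``burn_in``
    iterations and thins by ``config.thin``; the retained draws from all
    chains are stacked. Convergence is summarized by per-parameter Rhat
    values (annual occupancy, year effects, detection parameters);
    parameters with Rhat above the threshold are flagged — with a
    warning — but their draws are retained.

    Raises ``ValueError`` for degenerate histories: no detections at
    all, detections on every visit, or a single modelled year.
    """
    if history.n_visits == 0:
        raise ValueError("detection history has no visits")
    n_det = int(history.y.sum())
    if n_det == 0:
        raise ValueError(f"species {history.species!r}: no detections; cannot fit")
    if n_det == history.n_visits:
        raise ValueError(
            f"species {history.species!r}: detected on every visit; model degenerate"
        )
    if history.n_years < 2 and fixed_params is None:
        raise ValueError("need >= 2 modelled years")

    seeds = np.random.SeedSequence([config.seed & 0x7FFFFFFF]).spawn(config.n_chains)
    chains = [
        _run_chain(history, config, np.random.default_rng(s), fixed_params) for s in seeds
    ]

    def stack(key: str) -> np.ndarray:
        return np.concatenate([c[key] for c in chains], axis=0)

    n_ret = config.n_retained_per_chain
    chain_id = np.repeat(np.arange(config.n_chains), n_ret)

    rhat_rows = []
    occ = [c["z"].mean(axis=1) for c in chains]  # per chain: draws x years
    if config.n_chains >= 2 and n_ret >= 2:
        for t, year in enumerate(history.years):
            rhat_rows.append((f"occ[{year}]", compute_rhat(np.stack([o[:, t] for o in occ]))))
            rhat_rows.append(
                (f"b[{year}]", compute_rhat(np.stack([c["b"][:, t] for c in chains])))
            )
            rhat_rows.append(
                (f"a[{year}]", compute_rhat(np.stack([c["a"][:, t] for c in chains])))
            )
        for key in ("delta1", "delta2", "mu_a", "sigma_rw", "sigma_u", "sigma_a"):
            rhat_rows.append((key, compute_rhat(np.stack([c[key] for c in chains]))))
    rhat = pd.DataFrame(rhat_rows, columns=["parameter", "rhat"])
    rhat["flagged"] = rhat["rhat"] > config.rhat_threshold
    if fixed_params is None and rhat["flagged"].any():
        flagged = rhat.loc[rhat["flagged"], "parameter"].tolist()
        warnings.warn(
            f"species {history.species!r}: Rhat > {config.rhat_threshold} for "
            f"{len(flagged)} parameter(s) (e.g. {flagged[:5]}); draws retained",
            stacklevel=2,
        )

    return OccupancyPosterior(
        species=history.species,
        years=history.years.copy(),
        site_ids=list(history.site_ids),
        z=stack("z"),
        b=stack("b"),
        u=stack("u"),
        a=stack("a"),
        delta1=stack("delta1"),
        delta2=stack("delta2"),
        mu_a=stack("mu_a"),
        sigma_rw=stack("sigma_rw"),
        sigma_u=stack("sigma_u"),
        sigma_a=stack("sigma_a"),
        chain_id=chain_id,
        rhat=rhat,
        config=config,
    )


def compute_occupancy_series(posterior: OccupancyPosterior) -> OccupancySamples:
    """Annual occupancy draws: per sample, the mean of z over all sites.

    The denominator is every site in the prepared dataset, so an
    occupancy of 1 means the species occupies every modelled 1 km cell
    that year, including sites not visited that year (whose z is imputed
    from psi).
    """
    return OccupancySamples(
        species=posterior.species,
        years=posterior.years.copy(),
        samples=posterior.occupancy(),
        n_sites=len(posterior.site_ids),
    )
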