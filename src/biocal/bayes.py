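"""Hierarchical Bayesian estimation of growth-model parameters.

The growth experiment is modeled hierarchically: wells share the global
parameters (maximum growth rate mu_max, biomass yield Y_XS, initial
substrate S0) while each well's initial biomass is X0_well = X0_mu *
F_offset_well, with the per-well offsets F concentrating around 1.  Priors:

    X0_mu    ~ Lognormal(log 0.25, 0.1)   [g/L]
    F_offset ~ Lognormal(0, 0.2)          per well
    S0       ~ Lognormal(log 20, 0.1)     [g/L]
    Y_XS     ~ Beta(mean 0.6, sd 0.05)    [gCDW/gglucose]
    mu_max   ~ Beta(mean 0.4, sd 0.1)     [1/h]
    K_S fixed at 0.02 g/L (practically non-identifiable at this resolution)

Posteriors are explored with a self-contained DE-MCMC-Z sampler: proposals
are scaled differences of two states drawn from the chain's own history plus
a small Gaussian jitter, Metropolis-accepted; at the end of the tuning phase
the first ``tune_drop_fraction`` of the accumulated history is discarded,
cutting away unconverged burn-in.  Convergence is checked with the
rank-normalized split-R-hat diagnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numba
import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _fastmonod
from .calibration import CalibrationModel
from .multirep import (
    Dataset,
    ODEModelTemplate,
    ParameterMapping,
    make_monod_template,
    objective_for_dataset,
    solve_replicate,
)

__all__ = [
    "beta_from_mean_sd",
    "beta_hdi",
    "sample_hdi",
    "Lognormal",
    "BetaPrior",
    "HierarchicalGrowthSpec",
    "make_growth_mapping",
    "log_posterior",
    "find_map",
    "SamplerConfig",
    "Trace",
    "sample_demcmc_z",
    "rhat",
    "posterior_predictive",
    "HierarchicalGrowthModel",
]


# -- priors ------------------------------------------------------------------------


def beta_from_mean_sd(mean: float, sd: float) -> tuple:
    """Moment-match Beta shape parameters (alpha, beta) from mean and sd."""
    if not 0 < mean < 1:
        raise ValueError("mean must be in (0, 1)")
    if not sd > 0 or sd * sd >= mean * (1 - mean):
        raise ValueError(f"infeasible sd {sd} for mean {mean}: need sd^2 < mean(1-mean)")
    nu = mean * (1 - mean) / sd**2 - 1
    return mean * nu, (1 - mean) * nu


def beta_hdi(alpha: float, beta: float, ci_prob: float = 0.95) -> tuple:
    """Highest-density interval of a Beta distribution (width minimization)."""
    d = stats.beta(alpha, beta)

    def width(p_lo):
        return d.ppf(p_lo + ci_prob) - d.ppf(p_lo)

    res = optimize.minimize_scalar(
        width, bounds=(1e-12, 1 - ci_prob - 1e-12), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(d.ppf(res.x)), float(d.ppf(res.x + ci_prob))


def sample_hdi(samples, ci_prob: float = 0.9) -> tuple:
    """Narrowest interval containing ci_prob of the sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    k = max(int(math.ceil(ci_prob * n)), 2)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


@dataclass(frozen=True)
class Lognormal:
    """Lognormal prior parametrized by log-mean and log-sd."""

    mu: float
    sd: float

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        z = (math.log(x) - self.mu) / self.sd
        return -math.log(x) - math.log(self.sd) - 0.5 * math.log(2 * math.pi) - 0.5 * z * z

    @property
    def mode(self) -> float:
        return math.exp(self.mu - self.sd**2)


@dataclass(frozen=True)
class BetaPrior:
    """Beta prior parametrized by its first two moments."""

    mean: float
    sd: float

    @property
    def shape(self) -> tuple:
        return beta_from_mean_sd(self.mean, self.sd)

    def logpdf(self, x: float) -> float:
        if not 0 < x < 1:
            return -np.inf
        a, b = self.shape
        return float(stats.beta.logpdf(x, a, b))

    @property
    def mode(self) -> float:
        a, b = self.shape
        return (a - 1) / (a + b - 2)

    def hdi(self, ci_prob: float = 0.95) -> tuple:
        return beta_hdi(*self.shape, ci_prob=ci_prob)


@dataclass(frozen=True)
class HierarchicalGrowthSpec:
    """Priors and fixed constants of the hierarchical Monod growth model."""

    x0_mu_prior: Lognormal = Lognormal(math.log(0.25), 0.1)
    f_offset_prior: Lognormal = Lognormal(0.0, 0.2)
    s0_prior: Lognormal = Lognormal(math.log(20.0), 0.1)
    y_xs_prior: BetaPrior = BetaPrior(0.6, 0.05)
    mu_max_prior: BetaPrior = BetaPrior(0.4, 0.1)
    K_S: float = 0.02

    def prior_mode_theta(self, n_wells: int) -> np.ndarray:
        """(mu_max, Y_XS, S0, X0_mu, F_1..n) at the prior modes."""
        return np.concatenate(
            [
                [
                    self.mu_max_prior.mode,
                    self.y_xs_prior.mode,
                    self.s0_prior.mode,
                    self.x0_mu_prior.mode,
                ],
                np.full(n_wells, self.f_offset_prior.mode),
            ]
        )

    def log_prior(self, theta) -> float:
        mu_max, y_xs, s0, x0_mu = theta[:4]
        lp = (
            self.mu_max_prior.logpdf(mu_max)
            + self.y_xs_prior.logpdf(y_xs)
            + self.s0_prior.logpdf(s0)
            + self.x0_mu_prior.logpdf(x0_mu)
        )
        for f in theta[4:]:
            lp += self.f_offset_prior.logpdf(f)
        return lp


def make_growth_mapping(
    rids: Sequence[str],
    K_S: float = 0.02,
    x0_bounds=(0.01, 1.0),
    x0_guess: float = 0.25,
) -> ParameterMapping:
    """Monod mapping with shared S0/mu_max/Y_XS, per-well X0 and fixed K_S."""
    table = pd.DataFrame(
        {
            "S0": ["S0"] * len(rids),
            "X0": [f"X0_{rid}" for rid in rids],
            "mu_max": ["mu_max"] * len(rids),
            "K_S": [K_S] * len(rids),
            "Y_XS": ["Y_XS"] * len(rids),
        },
        index=list(rids),
    )
    bounds = {"S0": (5.0, 40.0), "mu_max": (0.05, 1.0), "Y_XS": (0.2, 0.95)}
    guesses = {"S0": 20.0, "mu_max": 0.4, "Y_XS": 0.6}
    for rid in rids:
        bounds[f"X0_{rid}"] = x0_bounds
        guesses[f"X0_{rid}"] = x0_guess
    return ParameterMapping(table, bounds, guesses)


def log_posterior(spec: HierarchicalGrowthSpec, objective, rids: Sequence[str]):
    """Hierarchical log-posterior over theta = (mu_max, Y_XS, S0, X0_mu, F...).

    ``objective`` is a dataset objective accepting a name->value dict with
    entries mu_max, Y_XS, S0 and X0_{rid}; well-wise initial biomass enters
    as X0_well = X0_mu * F_offset_well.
    """
    rids = list(rids)

    def logpost(theta) -> float:
        theta = np.asarray(theta, dtype=float)
        lp = spec.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        mu_max, y_xs, s0, x0_mu = theta[:4]
        full = {"mu_max": mu_max, "Y_XS": y_xs, "S0": s0}
        for rid, f in zip(rids, theta[4:]):
            full[f"X0_{rid}"] = x0_mu * f
        return lp + objective(full)

    return logpost


def find_map(logpost: Callable, guess, bounds=None, maxiter: int = 20000):
    """MAP estimate by bound-constrained gradient-free maximization.

    Returns (theta_map, info); non-convergence returns the best point found
    with ``info["converged"] = False``.
    """
    guess = np.asarray(guess, dtype=float)
    if not np.isfinite(logpost(guess)):
        raise ValueError("log-posterior is not finite at the guess")
    res = optimize.minimize(
        lambda t: -logpost(t),
        guess,
        method="Powell",
        bounds=bounds,
        options={"maxiter": maxiter, "xtol": 1e-8, "ftol": 1e-10},
    )
    info = {"converged": bool(res.success), "log_posterior": float(-res.fun)}
    if not res.success:
        warnings.warn(f"MAP optimization did not converge: {res.message}")
    return np.asarray(res.x, dtype=float), info


# -- DE-MCMC-Z sampler -------------------------------------------------------------


@dataclass(frozen=True)
class SamplerConfig:
    """Settings of the DE-MCMC-Z sampler."""

    n_tune: int = 2000
    n_draws: int = 10000
    n_chains: int = 4
    tune_drop_fraction: float = 0.9
    lam: Optional[float] = None  # default 2.38/sqrt(2 d)
    epsilon: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tune <= 0 or self.n_draws <= 0:
            raise ValueError("n_tune and n_draws must be positive")
        if not 0 <= self.tune_drop_fraction <= 1:
            raise ValueError("tune_drop_fraction must be in [0, 1]")


@dataclass
class Trace:
    """Posterior draws of all chains plus sampler metadata."""

    chains: List[np.ndarray]  # each (n_draws, d)
    names: List[str]
    tuning: dict = field(default_factory=dict)
    acceptance_rates: List[float] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def stacked(self) -> np.ndarray:
        return np.vstack(self.chains)

    def array(self) -> np.ndarray:
        """(chain, draw, dim) array."""
        return np.stack(self.chains)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stacked(), columns=self.names)

    def summary(self, ci_prob: float = 0.9) -> pd.DataFrame:
        """Mean, sd, HDI bounds and split-R-hat per parameter."""
        flat = self.stacked()
        rh = rhat(self)
        rows = []
        for j, name in enumerate(self.names):
            lo, hi = sample_hdi(flat[:, j], ci_prob)
            rows.append(
                {
                    "mean": flat[:, j].mean(),
                    "sd": flat[:, j].std(ddof=1),
                    f"hdi_{ci_prob:g}_lower": lo,
                    f"hdi_{ci_prob:g}_upper": hi,
                    "r_hat": rh[name],
                }
            )
        return pd.DataFrame(rows, index=self.names)


def _run_chain_python(logpost, x0, n_tune, n_draws, drop_frac, lam, eps, seed):
    rng = np.random.default_rng(seed)
    d = x0.size
    total = n_tune + n_draws
    hist = np.empty((total + 1, d))
    hist[0] = x0
    n_hist = 1
    x = x0.copy()
    lx = logpost(x)
    draws = np.empty((n_draws, d))
    acc = 0
    for it in range(total):
        if n_hist >= 2:
            i1, i2 = rng.choice(n_hist, size=2, replace=False)
            diff = hist[i1] - hist[i2]
        else:
            diff = np.zeros(d)
        prop = x + lam * diff + eps * rng.standard_normal(d)
        lprop = logpost(prop)
        if math.log(rng.random()) < lprop - lx:
            x, lx = prop, lprop
            if it >= n_tune:
                acc += 1
        hist[n_hist] = x
        n_hist += 1
        if it == n_tune - 1:
            n_drop = int(drop_frac * n_hist)
            keep = n_hist - n_drop
            hist[:keep] = hist[n_drop:n_hist]
            n_hist = keep
        if it >= n_tune:
            draws[it - n_tune] = x
    return draws, acc / n_draws


def _make_njit_driver(logpost):
    @numba.njit(cache=False)
    def run(x0, n_tune, n_draws, drop_frac, lam, eps, seed):
        np.random.seed(seed)
        d = x0.size
        total = n_tune + n_draws
        hist = np.empty((total + 1, d))
        hist[0] = x0
        n_hist = 1
        x = x0.copy()
        lx = logpost(x)
        draws = np.empty((n_draws, d))
        acc = 0
        for it in range(total):
            prop = np.empty(d)
            if n_hist >= 2:
                i1 = np.random.randint(0, n_hist)
                i2 = np.random.randint(0, n_hist)
                while i2 == i1:
                    i2 = np.random.randint(0, n_hist)
                for k in range(d):
                    prop[k] = x[k] + lam * (hist[i1, k] - hist[i2, k]) + eps * np.random.normal()
            else:
                for k in range(d):
                    prop[k] = x[k] + eps * np.random.normal()
            lprop = logpost(prop)
            if math.log(np.random.random()) < lprop - lx:
                x = prop.copy()
                lx = lprop
                if it >= n_tune:
                    acc += 1
            hist[n_hist] = x
            n_hist += 1
            if it == n_tune - 1:
                n_drop = int(drop_frac * n_hist)
                keep = n_hist - n_drop
                for r in range(keep):
                    for k in range(d):
                        hist[r, k] = hist[r + n_drop, k]
                n_hist = keep
            if it >= n_tune:
                for k in range(d):
                    draws[it - n_tune, k] = x[k]
        return draws, acc

    return run


def sample_demcmc_z(
    logpost: Callable,
    config: SamplerConfig,
    start,
    names: Optional[List[str]] = None,
) -> Trace:
    """Run independent DE-MCMC-Z chains targeting ``logpost``.

    Each proposal is x + lambda*(z1 - z2) + epsilon*eta with z1, z2 two
    distinct states from the chain's retained history and eta standard
    normal.  ``start`` may be a single vector (all chains start there) or a
    (n_chains, d) array.  Compiled log-posteriors (numba dispatchers) are
    driven by a compiled chain loop.
    """
    start = np.atleast_2d(np.asarray(start, dtype=float))
    if start.shape[0] == 1 and config.n_chains > 1:
        start = np.repeat(start, config.n_chains, axis=0)
    if start.shape[0] != config.n_chains:
        raise ValueError("start must be a vector or have n_chains rows")
    d = start.shape[1]
    lam = config.lam if config.lam is not None else 2.38 / math.sqrt(2 * d)
    names = names if names is not None else [f"theta_{j}" for j in range(d)]

    compiled = isinstance(logpost, numba.core.dispatcher.Dispatcher)
    driver = _make_njit_driver(logpost) if compiled else None

    chains, rates = [], []
    for c in range(config.n_chains):
        seed_c = (config.seed + 99991 * (c + 1)) % (2**31)
        if compiled:
            draws, acc = driver(
                start[c].copy(),
                config.n_tune,
                config.n_draws,
                config.tune_drop_fraction,
                lam,
                config.epsilon,
                seed_c,
            )
            rate = acc / config.n_draws
        else:
            draws, rate = _run_chain_python(
                logpost,
                start[c].copy(),
                config.n_tune,
                config.n_draws,
                config.tune_drop_fraction,
                lam,
                config.epsilon,
                seed_c,
            )
        if rate == 0.0:
            warnings.warn(f"chain {c}: no proposals accepted after tuning")
        chains.append(draws)
        rates.append(rate)
    return Trace(
        chains=chains,
        names=list(names),
        tuning={
            "lambda": lam,
            "epsilon": config.epsilon,
            "n_tune": config.n_tune,
            "tune_drop_fraction": config.tune_drop_fraction,
            "seed": config.seed,
        },
        acceptance_rates=rates,
    )


def rhat(trace: Trace) -> Dict[str, float]:
    """Rank-normalized split-R-hat per parameter (1 for constant chains)."""
    import arviz as az

    arr = trace.array()  # (chain, draw, dim)
    if arr.shape[1] < 8:
        raise ValueError("need at least 8 draws per chain for split-R-hat")
    out = {}
    for j, name in enumerate(trace.names):
        x = arr[:, :, j]
        if np.ptp(x) == 0.0:
            out[name] = 1.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val = float(az.rhat(az.convert_to_dataset(x), method="rank")["x"].values)
        out[name] = 1.0 if np.isnan(val) else val
    return out


def posterior_predictive(
    trace: Trace,
    template: ODEModelTemplate,
    mapping: ParameterMapping,
    cal_models: Dict[str, CalibrationModel],
    t_grid,
    n_samples: int = 1000,
    seed: int = 0,
    assemble: Optional[Callable] = None,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Sample predicted measurement responses from posterior draws.

    For each drawn parameter vector, the states are solved on ``t_grid`` and
    one response per time point is drawn from each calibration model's
    predicted distribution.  Returns {rid: {dependent_key: (n_samples, T)}}.
    ``assemble`` maps a name->value row of the trace to the mapping's full
    vector (identity by default).
    """
    rng = np.random.default_rng(seed)
    flat = trace.stacked()
    replace = flat.shape[0] < n_samples
    idx = rng.choice(flat.shape[0], size=n_samples, replace=replace)
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    rids = [str(r) for r in mapping.table.index]
    out = {
        rid: {dk: np.empty((n_samples, t_grid.size)) for dk in cal_models} for rid in rids
    }
    state_idx = {
        dk: list(template.state_names).index(cal.independent_key)
        for dk, cal in cal_models.items()
    }
    for s, i in enumerate(idx):
        row = dict(zip(trace.names, flat[i]))
        full = assemble(row) if assemble is not None else row
        per_rep = mapping.repmap(full)
        for rid in rids:
            pred = solve_replicate(
                template, t_grid, per_rep[rid], rid=rid, rtol=1e-6, atol=1e-8
            )
            states = np.vstack([pred[k].y for k in template.state_names])
            for dk, cal in cal_models.items():
                d = cal.predict_dependent(np.maximum(states[state_idx[dk]], 1e-12))
                if d.nu is not None:
                    y = stats.t.rvs(df=d.nu, loc=d.mu, scale=d.scale, random_state=rng)
                else:
                    y = stats.norm.rvs(loc=d.mu, scale=d.scale, random_state=rng)
                out[rid][dk][s] = y
    return out


# -- high-level hierarchical growth model ------------------------------------------


class HierarchicalGrowthModel:
    """Hierarchical Monod growth model bound to a dataset and calibrations.

    Builds the compiled log-posterior (unconstrained parametrization with
    Jacobian corrections), exposes MAP estimation and DE-MCMC-Z sampling,
    and returns traces on the natural parameter scale with names
    mu_max, Y_XS, S0, X0_mu, F_offset_{rid}...

    Requires the standard experiment layout: one backscatter-like series per
    well plus one endpoint observation of the substrate located on the
    backscatter time grid.
    """

    def __init__(
        self,
        dataset: Dataset,
        cal_biomass: CalibrationModel,
        cal_glucose: CalibrationModel,
        spec: HierarchicalGrowthSpec = HierarchicalGrowthSpec(),
    ):
        self.spec = spec
        self.cal_biomass = cal_biomass
        self.cal_glucose = cal_glucose
        self.rids = sorted(dataset.replicates)
        self.names = ["mu_max", "Y_XS", "S0", "X0_mu"] + [
            f"F_offset_{rid}" for rid in self.rids
        ]
        self.template = make_monod_template()
        self.mapping = make_growth_mapping(self.rids, K_S=spec.K_S)
        self._dataset = dataset

        t_parts, y_parts, glc_loc, yglc = [], [], [], []
        offsets = [0]
        for rid in self.rids:
            rep = dataset[rid]
            ts_bs = rep[cal_biomass.dependent_key]
            ts_glc = rep[cal_glucose.dependent_key]
            if ts_glc.t.size != 1:
                raise ValueError(f"{rid}: expected a length-1 substrate series")
            j = int(np.argmin(np.abs(ts_bs.t - ts_glc.t[0])))
            if abs(ts_bs.t[j] - ts_glc.t[0]) > 1e-9:
                raise ValueError(
                    f"{rid}: substrate observation time is not on the series grid; "
                    "use the generic objective instead"
                )
            t_parts.append(ts_bs.t)
            y_parts.append(ts_bs.y)
            glc_loc.append(j)
            yglc.append(ts_glc.y[0])
            offsets.append(offsets[-1] + ts_bs.t.size)

        def _cal_arrays(cal):
            trend, scale, nu = cal._split_theta()
            scale = np.concatenate([scale, np.zeros(2 - scale.size)])
            return np.asarray(trend, dtype=float), scale.astype(float), float(nu)

        self._compile_args = (
            np.concatenate(t_parts),
            np.asarray(offsets, dtype=np.int64),
            np.concatenate(y_parts),
            np.asarray(glc_loc, dtype=np.int64),
            np.asarray(yglc, dtype=float),
            *_cal_arrays(cal_biomass),
            *_cal_arrays(cal_glucose),
            spec.K_S,
            spec.mu_max_prior.shape,
            spec.y_xs_prior.shape,
            (spec.s0_prior.mu, spec.s0_prior.sd),
            (spec.x0_mu_prior.mu, spec.x0_mu_prior.sd),
            (spec.f_offset_prior.mu, spec.f_offset_prior.sd),
        )
        self.logpost_z = _fastmonod.compile_growth_logpost(*self._compile_args)
        self._loglik_z = None

    @property
    def loglik_z(self):
        """Compiled pure log-likelihood (no prior/Jacobian) of z."""
        if self._loglik_z is None:
            self._loglik_z = _fastmonod.compile_growth_logpost(
                *self._compile_args, include_prior=False
            )
        return self._loglik_z

    # -- parameter transforms ------------------------------------------------------
    def z_from_theta(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        z = np.empty_like(theta)
        z[0] = math.log(theta[0] / (1 - theta[0]))
        z[1] = math.log(theta[1] / (1 - theta[1]))
        z[2:] = np.log(theta[2:])
        return z

    def theta_from_z(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        theta = np.empty_like(z)
        theta[0] = 1 / (1 + math.exp(-z[0]))
        theta[1] = 1 / (1 + math.exp(-z[1]))
        theta[2:] = np.exp(z[2:])
        return theta

    # -- generic (uncompiled) posterior for cross-checking -------------------------
    def log_posterior_natural(self, theta) -> float:
        """Slow reference path via the adaptive-solver dataset objective."""
        objective = objective_for_dataset(
            self._dataset,
            self.template,
            self.mapping,
            {
                self.cal_biomass.dependent_key: self.cal_biomass,
                self.cal_glucose.dependent_key: self.cal_glucose,
            },
        )
        return log_posterior(self.spec, objective, self.rids)(theta)

    # -- estimation ----------------------------------------------------------------
    def find_map(self, guess=None):
        """MAP estimate on the natural scale (optimized unconstrained)."""
        if guess is None:
            guess = self.spec.prior_mode_theta(len(self.rids))
        z0 = self.z_from_theta(guess)
        z_map, info = find_map(self.logpost_z, z0)
        return self.theta_from_z(z_map), info

    def find_mle(self, guess=None):
        """Maximum-likelihood estimate (no priors) on the natural scale."""
        if guess is None:
            guess = self.spec.prior_mode_theta(len(self.rids))
        z0 = self.z_from_theta(guess)
        z_mle, info = find_map(self.loglik_z, z0)
        return self.theta_from_z(z_mle), info

    def sample(
        self,
        config: SamplerConfig,
        start_theta=None,
        jitter: float = 0.01,
    ) -> Trace:
        """DE-MCMC-Z sampling, chains initialized at the (jittered) MAP."""
        if start_theta is None:
            start_theta, _ = self.find_map()
        rng = np.random.default_rng(config.seed)
        starts = np.empty((config.n_chains, len(start_theta)))
        for c in range(config.n_chains):
            jittered = np.asarray(start_theta) * (
                1 + jitter * rng.standard_normal(len(start_theta))
            )
            jittered[:2] = np.clip(jittered[:2], 1e-4, 1 - 1e-4)
            starts[c] = self.z_from_theta(jittered)
        trace_z = sample_demcmc_z(self.logpost_z, config, starts, names=self.names)
        chains = [
            np.apply_along_axis(self.theta_from_z, 1, ch) for ch in trace_z.chains
        ]
        return Trace(
            chains=chains,
            names=self.names,
            tuning=trace_z.tuning,
            acceptance_rates=trace_z.acceptance_rates,
        )

    def assemble_full_vector(self, row: Dict[str, float]) -> Dict[str, float]:
        """Map a trace row to the parameter-mapping's full vector."""
        full = {"mu_max": row["mu_max"], "Y_XS": row["Y_XS"], "S0": row["S0"]}
        for rid in self.rids:
            full[f"X0_{rid}"] = row["X0_mu"] * row[f"F_offset_{rid}"]
        return full
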