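"""Fitting the joint hierarchical model by MCMC, with standard diagnostics.

The full model couples three sub-models through shared parameters:

* detection: half-normal perpendicular distances, strip width log-linear in
  Beaufort and group size with per-sighting and per-cell residuals;
* group size: Poisson (whale-like) or log-normal (dolphin-like), fitted from
  the sightings alone;
* counts: per-cell Poisson group counts whose mean combines the effectively
  sampled area, the trackline detection probability g(0) (informative Beta
  prior) and a log-polynomial habitat response to rescaled dynamic topography.

Priors are non-informative except for g(0): Normal(0, 100) on all regression
coefficients, Uniform(0, 10) on residual SDs, Uniform(0, 100) on the Poisson
group-size mean, Uniform(0, 1) on the model-averaging weight.

Diagnostics follow common practice for Gibbs-type output: the Gelman-Rubin
potential scale reduction factor across chains, batch-means Monte Carlo
standard errors, DIC for model choice, and a posterior predictive Bayesian
p-value on the count likelihood using a sums-of-squares-type (Freeman-Tukey
by default) discrepancy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from ._sampler import _Chain
from .detection import WHALE_LIKE, _check_form
from .density import G0Prior, g0_prior
from .habitat import HABITAT_FORMS

__all__ = [
    "McmcConfig",
    "PosteriorResult",
    "CetaceanDensityModel",
    "fit_model",
    "gelman_rubin",
    "mc_error",
    "bayesian_pvalue",
    "dic",
]

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.1


@dataclass
class McmcConfig:
    """Chain length protocol; defaults retain (10000 - 2000)/10 = 800 draws per chain."""

    n_iterations: int = 10_000
    n_burnin: int = 2_000
    thin: int = 10
    n_chains: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


def gelman_rubin(draws) -> float:
    """Potential scale reduction factor R-hat from >= 2 chains.

    ``draws`` has shape (n_chains, n_draws).  Compares the between-chain
    variance of the chain means with the mean within-chain variance.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("gelman_rubin needs >= 2 chains of draws")
    m, n = draws.shape
    if n < 10:
        raise ValueError("gelman_rubin needs >= 10 draws per chain")
    within = float(np.mean(np.var(draws, axis=1, ddof=1)))
    b_over_n = float(np.var(np.mean(draws, axis=1), ddof=1))
    if within == 0.0:
        return 1.0 if b_over_n == 0.0 else np.inf
    var_hat = (n - 1) / n * within + b_over_n
    return float(np.sqrt(var_hat / within))


def mc_error(draws, n_batches: int = 50) -> float:
    """Batch-means Monte Carlo standard error of the posterior mean."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < n_batches:
        raise ValueError(f"mc_error needs at least {n_batches} draws")
    size = draws.size // n_batches
    batches = draws[: size * n_batches].reshape(n_batches, size).mean(axis=1)
    return float(np.std(batches, ddof=1) / np.sqrt(n_batches))


@dataclass
class PosteriorResult:
    """Posterior draws and per-draw derived quantities of one fitted model."""

    draws: dict                     # name -> (n_chains, n_draws)
    lambda_draws: np.ndarray        # (n_chains, n_draws, n_cells)
    deviance_draws: np.ndarray      # (n_chains, n_draws)
    deviance_at_means: float
    discrepancy_obs: np.ndarray     # (n_chains, n_draws)
    discrepancy_rep: np.ndarray
    random_effect_means: dict       # name -> posterior-mean vector
    species_form: str
    habitat_form: str
    adt_reference_mean: float
    adt_fitted_range: tuple
    config: McmcConfig
    g0_prior: G0Prior
    n_counts: np.ndarray            # observed per-cell group counts
    converged: bool = True

    @property
    def parameters(self) -> list:
        return list(self.draws)

    def pooled(self, name: str) -> np.ndarray:
        return np.asarray(self.draws[name]).ravel()

    def rhat(self) -> pd.Series:
        return pd.Series({k: gelman_rubin(v) for k, v in self.draws.items()},
                         name="rhat")

    def summary(self) -> pd.DataFrame:
        """Posterior summaries: mean, SD, 2.5% / median / 97.5%, MC error, R-hat."""
        rows = {}
        for name, v in self.draws.items():
            pooled = np.asarray(v).ravel()
            q = np.quantile(pooled, [0.025, 0.5, 0.975])
            rows[name] = {
                "mean": pooled.mean(), "sd": pooled.std(ddof=1),
                "q2.5": q[0], "median": q[1], "q97.5": q[2],
                "mc_error": mc_error(pooled),
                "rhat": gelman_rubin(v) if np.asarray(v).shape[0] > 1 else np.nan,
            }
        return pd.DataFrame(rows).T


def bayesian_pvalue(result: PosteriorResult, cells: pd.DataFrame | None = None,
                    discrepancy: str = "freeman_tukey",
                    seed: int | None = None) -> float:
    """Posterior predictive p-value of the Poisson count likelihood.

    Fraction of retained draws in which the discrepancy of a replicated
    dataset (counts drawn from the draw's per-cell means) meets or exceeds
    that of the observed counts; ties count half.  By default reuses the
    discrepancies accumulated during sampling; passing ``cells`` (or a
    different ``discrepancy``) recomputes them from the stored per-cell
    mean-count draws.
    """
    if cells is None and discrepancy == "freeman_tukey" and seed is None:
        t_obs, t_rep = result.discrepancy_obs, result.discrepancy_rep
    else:
        n = (cells["n_groups"].to_numpy(dtype=float)
             if cells is not None else result.n_counts.astype(float))
        lam = result.lambda_draws.reshape(-1, result.lambda_draws.shape[-1])
        rng = np.random.default_rng(
            seed if seed is not None else (result.config.seed or 0) + 777)
        n_rep = rng.poisson(np.clip(lam, 0.0, 1e12))
        if discrepancy == "freeman_tukey":
            t_obs = np.sum((np.sqrt(n) - np.sqrt(lam)) ** 2, axis=1)
            t_rep = np.sum((np.sqrt(n_rep) - np.sqrt(lam)) ** 2, axis=1)
        elif discrepancy == "sums_of_squares":
            t_obs = np.sum((n - lam) ** 2, axis=1)
            t_rep = np.sum((n_rep - lam) ** 2, axis=1)
        else:
            raise ValueError(f"unknown discrepancy {discrepancy!r}")
    t_obs = np.asarray(t_obs).ravel()
    t_rep = np.asarray(t_rep).ravel()
    return float(np.mean(t_rep > t_obs) + 0.5 * np.mean(t_rep == t_obs))


def dic(result: PosteriorResult) -> tuple:
    """Deviance Information Criterion: (DIC, pD, mean deviance).

    ``pD = Dbar - D(theta_bar)`` with the plug-in deviance evaluated at the
    posterior means of all stochastic quantities (random effects included);
    ``DIC = Dbar + pD``.
    """
    dbar = float(np.mean(result.deviance_draws))
    p_d = dbar - result.deviance_at_means
    return dbar + p_d, p_d, dbar


# ---------------------------------------------------------------------------


def _prepare_data(cells: pd.DataFrame, sightings: pd.DataFrame,
                  species_form: str, reference_mean: float | None):
    cells = cells.loc[cells["effort_km"] > 0].reset_index(drop=True)
    if cells.empty:
        raise ValueError("no cells with positive effort")
    if sightings.empty:
        raise ValueError("sightings table is empty")
    required = {"effort_km", "beaufort", "n_groups", "adt_cm"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells table lacks columns: {sorted(missing)}")
    x = sightings["distance_km"].to_numpy(dtype=float)
    s = sightings["group_size"].to_numpy(dtype=float)
    b = sightings["beaufort"].to_numpy(dtype=float)
    if np.any(x < 0) or np.any(s < 1):
        raise ValueError("sightings must have distance >= 0 and group size >= 1")
    if species_form == WHALE_LIKE and not np.allclose(s, np.round(s)):
        raise ValueError("whale-like group sizes must be integers")
    adt = cells["adt_cm"].to_numpy(dtype=float)
    effort = cells["effort_km"].to_numpy(dtype=float)
    if reference_mean is None:
        reference_mean = float(np.average(adt, weights=effort))
    data = {
        "x": x, "s": s, "b": b,
        "scov": s if species_form == WHALE_LIKE else np.log(s),
        "L": effort,
        "B": cells["beaufort"].to_numpy(dtype=float),
        "n": cells["n_groups"].to_numpy(dtype=float),
        "z": (adt - reference_mean) / 100.0,
    }
    return cells, data, reference_mean


class CetaceanDensityModel:
    """Hierarchical Bayesian distance-sampling model of density vs. ADT.

    An sklearn-style estimator: construct with hyperparameters, ``fit`` on a
    model-ready cell table and a sightings table (see
    :mod:`hbdsm.gridding` for the schemas), then inspect ``summary_`` /
    ``result_`` or call ``predict`` on an ADT raster.

    Parameters
    ----------
    species_form : "whale_like" | "dolphin_like"
        Group-size likelihood and detection covariate scale.
    habitat_form : "poly2" | "poly3" | "average"
        Habitat response: 2nd-order, 3rd-order, or their mixture.
    g0_mean, g0_cv
        Mean and CV defining the informative Beta prior on g(0).
    n_iterations, n_burnin, thin, n_chains, seed
        MCMC protocol (defaults: 10000 / 2000 / 10 / 3).
    adt_reference_mean
        Centering constant (cm) of the rescaled ADT covariate; by default the
        effort-weighted mean ADT of the fitted cells.
    discrepancy : "freeman_tukey" | "sums_of_squares"
        Goodness-of-fit statistic for the posterior predictive check.
    sigma_e2_fixed
        If set, fixes the habitat residual SD (0 disables the per-cell
        ecological residual); by default it is estimated.

    Attributes (after fit)
    ----------------------
    result_ : PosteriorResult
    summary_ : pandas.DataFrame (Table-style posterior summaries)
    dic_, pd_, mean_deviance_ : float
    bayesian_pvalue_ : float
    rhat_ : pandas.Series
    converged_ : bool
    adt_reference_mean_ : float
    """

    def __init__(self, species_form: str = WHALE_LIKE,
                 habitat_form: str = "poly2",
                 g0_mean: float = 0.921, g0_cv: float = 0.023,
                 n_iterations: int = 10_000, n_burnin: int = 2_000,
                 thin: int = 10, n_chains: int = 3, seed: int | None = None,
                 adt_reference_mean: float | None = None,
                 coef_prior_sd: float = 100.0, sigma_prior_upper: float = 10.0,
                 lambda_s_prior_upper: float = 100.0,
                 discrepancy: str = "freeman_tukey",
                 sigma_e1_fixed: float | None = None,
                 sigma_e2_fixed: float | None = None,
                 zero_truncated_groupsize: bool = True):
        self.species_form = species_form
        self.habitat_form = habitat_form
        self.g0_mean = g0_mean
        self.g0_cv = g0_cv
        self.n_iterations = n_iterations
        self.n_burnin = n_burnin
        self.thin = thin
        self.n_chains = n_chains
        self.seed = seed
        self.adt_reference_mean = adt_reference_mean
        self.coef_prior_sd = coef_prior_sd
        self.sigma_prior_upper = sigma_prior_upper
        self.lambda_s_prior_upper = lambda_s_prior_upper
        self.discrepancy = discrepancy
        self.sigma_e1_fixed = sigma_e1_fixed
        self.sigma_e2_fixed = sigma_e2_fixed
        self.zero_truncated_groupsize = zero_truncated_groupsize

    # minimal sklearn estimator API
    def get_params(self, deep: bool = True) -> dict:
        import inspect
        names = inspect.signature(type(self).__init__).parameters
        return {k: getattr(self, k) for k in names if k != "self"}

    def set_params(self, **params) -> "CetaceanDensityModel":
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r} for {type(self).__name__}")
            setattr(self, k, v)
        return self

    def __repr__(self) -> str:
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({args})"

    # ------------------------------------------------------------------

    def fit(self, cells: pd.DataFrame, sightings: pd.DataFrame
            ) -> "CetaceanDensityModel":
        """Sample the joint posterior given gridded cells and sightings."""
        _check_form(self.species_form)
        if self.habitat_form not in HABITAT_FORMS:
            raise ValueError(f"habitat_form must be one of {HABITAT_FORMS}")
        config = McmcConfig(self.n_iterations, self.n_burnin, self.thin,
                            self.n_chains, self.seed)
        cells, data, ref_mean = _prepare_data(
            cells, sightings, self.species_form, self.adt_reference_mean)
        prior = g0_prior(self.g0_mean, self.g0_cv)
        spec = {
            "species_form": self.species_form,
            "habitat_form": self.habitat_form,
            "priors": {
                "g0": prior,
                "coef_sd": self.coef_prior_sd,
                "sigma_upper": self.sigma_prior_upper,
                "lambda_s_upper": self.lambda_s_prior_upper,
            },
            "sigma_e1_fixed": self.sigma_e1_fixed,
            "sigma_e2_fixed": self.sigma_e2_fixed,
            "zero_truncated": self.zero_truncated_groupsize,
        }
        root = np.random.SeedSequence(config.seed if config.seed is not None else 0)
        chain_seeds = root.spawn(config.n_chains)

        n_ret = config.retained_per_chain
        nc = len(data["L"])
        all_scalars: list = []
        lam_draws = np.empty((config.n_chains, n_ret, nc))
        dev_draws = np.empty((config.n_chains, n_ret))
        t_obs = np.empty((config.n_chains, n_ret))
        t_rep = np.empty((config.n_chains, n_ret))
        eps_sums = {"eps0": np.zeros(len(data["x"])),
                    "eps1": np.zeros(nc), "eps2": np.zeros(nc)}

        for c in range(config.n_chains):
            chain = _Chain(data, spec, chain_seeds[c])
            scalars: dict = {}
            k = 0
            for it in range(config.n_iterations):
                chain.step()
                if it < config.n_burnin:
                    if (it + 1) % 50 == 0:
                        chain.refresh_blocks()
                    if it + 1 == config.n_burnin:
                        chain.freeze()
                    continue
                if (it - config.n_burnin) % config.thin == config.thin - 1:
                    if k >= n_ret:
                        continue
                    for name, val in chain.scalars().items():
                        scalars.setdefault(name, np.empty(n_ret))[k] = val
                    lam_draws[c, k] = chain.lam()
                    dev_draws[c, k] = chain.deviance()
                    t_obs[c, k], t_rep[c, k] = chain.discrepancies(self.discrepancy)
                    eps_sums["eps0"] += chain.eps0
                    eps_sums["eps1"] += chain.eps1
                    eps_sums["eps2"] += chain.eps2
                    k += 1
            all_scalars.append(scalars)

        draws = {name: np.stack([s[name] for s in all_scalars])
                 for name in all_scalars[0]}
        total = config.n_chains * n_ret
        eps_means = {k: v / total for k, v in eps_sums.items()}
        dev_at_means = _deviance_at_means(data, spec, draws, eps_means)

        result = PosteriorResult(
            draws=draws, lambda_draws=lam_draws, deviance_draws=dev_draws,
            deviance_at_means=dev_at_means,
            discrepancy_obs=t_obs, discrepancy_rep=t_rep,
            random_effect_means=eps_means,
            species_form=self.species_form, habitat_form=self.habitat_form,
            adt_reference_mean=ref_mean,
            adt_fitted_range=(float(cells["adt_cm"].min()),
                              float(cells["adt_cm"].max())),
            config=config, g0_prior=prior,
            n_counts=data["n"].astype(int),
        )
        rhat = result.rhat()
        result.converged = bool((rhat <= RHAT_THRESHOLD).all())
        if not result.converged:
            bad = rhat[rhat > RHAT_THRESHOLD]
            warnings.warn(
                "chains may not have converged; R-hat > "
                f"{RHAT_THRESHOLD} for: {dict(bad.round(3))}", RuntimeWarning,
            )
        self.result_ = result
        self.summary_ = result.summary()
        self.rhat_ = rhat
        self.converged_ = result.converged
        self.dic_, self.pd_, self.mean_deviance_ = dic(result)
        self.bayesian_pvalue_ = bayesian_pvalue(result)
        self.adt_reference_mean_ = ref_mean
        self.cells_ = cells
        return self

    def predict(self, adt, include_residuals: bool = False):
        """Density surface (q2.5 / median / q97.5) for an ADT raster in cm."""
        from .prediction import predict_surface
        if not hasattr(self, "result_"):
            raise RuntimeError("model is not fitted")
        return predict_surface(self.result_, adt,
                               include_residuals=include_residuals)


def _deviance_at_means(data, spec, draws, eps_means) -> float:
    """Plug-in deviance at the posterior means of all stochastic quantities."""
    chain = _Chain(data, spec, np.random.SeedSequence(0))
    mean = {k: float(np.mean(v)) for k, v in draws.items()}
    chain.alpha = np.array([mean["alpha0"], mean["alpha1"], mean["alpha2"]])
    chain.g0 = mean["g0"]
    chain.sig_e0 = mean["sigma_eps0"]
    chain.sig_e1 = mean["sigma_eps1"]
    if "sigma_eps2" in mean:
        chain.sig_e2 = mean["sigma_eps2"]
    if spec["species_form"] == WHALE_LIKE:
        chain.lam_s = mean["lambda_s"]
    else:
        chain.mu_s = mean["mu_s"]
        chain.sig_s = mean["sigma_s"]
    if "omega0" in mean:
        chain.omega = np.array([mean["omega0"], mean["omega1"], mean["omega2"]])
    if "theta0" in mean:
        chain.theta = np.array([mean[f"theta{i}"] for i in range(4)])
    if "vartheta" in mean:
        chain.vartheta = mean["vartheta"]
    chain.eps0 = eps_means["eps0"].copy()
    chain.eps1 = eps_means["eps1"].copy()
    chain.eps2 = eps_means["eps2"].copy()
    chain._refresh_all()
    return chain.deviance()


def fit_model(cells: pd.DataFrame, sightings: pd.DataFrame,
              priors: dict | None = None, config: McmcConfig | None = None,
              habitat_form: str = "poly2", species_form: str = WHALE_LIKE,
              **kwargs) -> PosteriorResult:
    """Functional wrapper over :class:`CetaceanDensityModel`.

    ``priors`` may override ``g0_mean`` / ``g0_cv`` / ``coef_prior_sd`` /
    ``sigma_prior_upper`` / ``lambda_s_prior_upper``.
    """
    params = dict(species_form=species_form, habitat_form=habitat_form)
    if priors:
        params.update(priors)
    if config is not None:
        params.update(n_iterations=config.n_iterations, n_burnin=config.n_burnin,
                      thin=config.thin, n_chains=config.n_chains, seed=config.seed)
    params.update(kwargs)
    return CetaceanDensityModel(**params).fit(cells, sightings).result_
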