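"""Bayesian accelerated failure time model for annual adult-female survival.

Survival is modeled on discrete female-year rows with time-varying covariates
(one social-integration measure at a time, age, dominance rank, mean group
size) and crossed random intercepts for female and group. The baseline is
piecewise-exponential per female-year on a log-days timescale: with linear
predictor

    eta_it = mu + beta_social * s*_it + beta_age * age_it
           + beta_rank * rank_it + beta_gs * gs_it + u_female(i) + v_group(g)

the hazard over the year is exp(-eta), so the probability of dying in the
year is

    p_it = 1 - exp(-Delta * exp(-eta_it)),   Delta = 365.25 days.

Positive coefficients therefore lengthen expected lifetime (the accelerated
failure time sign convention), and the intercept is interpretable as a log
expected lifespan in days for the average standardized female. Measurement
uncertainty in the first-stage social-integration estimate is propagated by
treating the true score as latent, s*_it ~ Normal(mean_it, sd_it), with the
stage-one posterior mean and SD as the per-row measurement model.

Death rows contribute log p_it, survived and censored rows log(1 - p_it);
deaths are assigned the full year of exposure. All covariates are
standardized before fitting; the integration SD is divided by the same scale
as the integration mean so the measurement model is consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactions import ADULT_AGE_YEARS, age_years
from .mcmc import SamplerConfig, convergence_summary, sample

logger = logging.getLogger(__name__)

DELTA_DAYS = 365.25
CI_LO, CI_HI = 0.055, 0.945  # central 89% interval

FEMALE_YEAR_COLUMNS = [
    "id", "year", "age", "rank", "group_size", "group", "status",
    "integration_mean", "integration_sd", "lag",
]
COEF_NAMES = ["intercept", "beta_social", "beta_age", "beta_rank", "beta_groupsize"]


@dataclass
class AFTConfig:
    mcmc: SamplerConfig = field(default_factory=SamplerConfig)
    delta_days: float = DELTA_DAYS
    random_effects: bool = True
    measurement_error: bool = True
    prior_mu_mean: float = 9.5
    prior_mu_scale: float = 2.0
    prior_beta_scale: float = 1.0
    prior_sd_scale: float = 1.0
    rhat_threshold: float = 1.05


@dataclass
class AFTResult:
    draws: dict[str, np.ndarray]     # each (chains, samples)
    summary: pd.DataFrame
    diagnostics: dict
    scaling: dict | None
    n_rows: int
    n_deaths: int
    converged: bool
    config: AFTConfig


def assemble_female_years(
    individuals: pd.DataFrame,
    demography: pd.DataFrame,
    covariates: pd.DataFrame,
    estimates: pd.DataFrame,
    lag: int = 0,
) -> pd.DataFrame:
    """Join demography, annual covariates and one integration measure into
    the female-year analysis table.

    The observation window per female is the span of her covariate rows; her
    final row is ``died`` if her death date falls in that year and
    ``censored`` if observation ends without death. With ``lag=1`` the
    integration estimate of year t-1 predicts survival in year t, which drops
    each female's first observed year. Rows lacking an estimate are dropped
    with a logged count.
    """
    if lag not in (0, 1):
        raise ValueError("lag must be 0 or 1")
    dirs = set(estimates["direction"]) if not estimates.empty else set()
    if len(set(estimates["behavior"])) > 1 or len(dirs) > 1:
        raise ValueError("estimates must be a single behavior/direction measure")

    birth = dict(zip(individuals["id"], individuals["birth_date"]))
    sex = dict(zip(individuals["id"], individuals["sex"]))
    death = dict(zip(demography["id"], demography["death_date"]))

    if covariates.duplicated(subset=["id", "year"]).any():
        raise ValueError("overlapping female-years in covariate table")

    est = estimates.set_index(["id", "year"])[["post_mean", "post_sd"]]

    rows = []
    n_dropped = 0
    for iid, g in covariates.groupby("id", sort=True):
        if sex.get(iid) != "F":
            continue
        g = g.sort_values("year")
        last_year = int(g["year"].max())
        for rec in g.itertuples(index=False):
            year = int(rec.year)
            mid = pd.Timestamp(year=year, month=7, day=1)
            age = age_years(birth[iid], mid)
            if age < ADULT_AGE_YEARS:
                continue
            d = death.get(iid)
            if pd.notna(d) and d.year < year:
                continue
            if pd.notna(d) and d.year == year:
                status = "died"
            elif year == last_year:
                status = "censored"
            else:
                status = "survived"
            key = (iid, year - lag)
            if key not in est.index:
                n_dropped += 1
                continue
            m, s = est.loc[key]
            rows.append(
                dict(id=iid, year=year, age=age, rank=rec.rank,
                     group_size=rec.group_size, group=rec.group, status=status,
                     integration_mean=m, integration_sd=s, lag=lag)
            )
        # stop emitting rows after a death year
    if n_dropped:
        logger.info("dropped %d female-years without an integration estimate", n_dropped)
    df = pd.DataFrame(rows, columns=FEMALE_YEAR_COLUMNS)
    return df.sort_values(["id", "year"]).reset_index(drop=True)


def standardize_covariates(rows: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Z-score age, rank, group size and the integration mean over the
    analysis rows; the integration SD is divided by the integration mean's
    scale. Returns the transformed table and the scaling record needed to
    back-transform predictions."""
    out = rows.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for col in ["age", "rank", "group_size", "integration_mean"]:
        m = float(out[col].mean())
        s = float(out[col].std(ddof=0))
        if s == 0.0:
            raise ValueError(f"zero variance in covariate {col!r}")
        out[col] = (out[col] - m) / s
        scaling[col] = (m, s)
    out["integration_sd"] = out["integration_sd"] / scaling["integration_mean"][1]
    return out, scaling


def unstandardize(value: np.ndarray, col: str, scaling: dict) -> np.ndarray:
    m, s = scaling[col]
    return value * s + m


def fit_aft(rows: pd.DataFrame, config: AFTConfig | None = None) -> AFTResult:
    """Fit the annual piecewise-exponential AFT model on standardized rows."""
    config = config or AFTConfig()
    delta = config.delta_days

    died = (rows["status"] == "died").to_numpy()
    x = rows[["integration_mean", "age", "rank", "group_size"]].to_numpy(float)
    sd = rows["integration_sd"].to_numpy(float)
    if (sd <= 0).any() and config.measurement_error:
        raise ValueError("integration_sd must be positive under measurement error")

    females = sorted(rows["id"].unique())
    groups = sorted(rows["group"].unique())
    fidx = rows["id"].map({f: i for i, f in enumerate(females)}).to_numpy()
    gidx = rows["group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    F, G, N = len(females), len(groups), len(rows)

    use_re = config.random_effects
    use_me = config.measurement_error
    # layout: mu, b_social, b_age, b_rank, b_gs | log_su, log_sv | zu | zv | zs
    dim = 5 + (2 + F + G if use_re else 0) + (N if use_me else 0)
    s2mu = config.prior_mu_scale ** 2
    s2b = config.prior_beta_scale ** 2

    def logp_grad(q: np.ndarray):
        mu = q[0]
        betas = q[1:5]
        pos = 5
        if use_re:
            lsu, lsv = q[pos], q[pos + 1]
            su, sv = np.exp(lsu), np.exp(lsv)
            zu = q[pos + 2 : pos + 2 + F]
            zv = q[pos + 2 + F : pos + 2 + F + G]
            pos += 2 + F + G
        if use_me:
            zs = q[pos:]

        s_star = x[:, 0] + sd * zs if use_me else x[:, 0]
        eta = (
            mu
            + betas[0] * s_star
            + x[:, 1:] @ betas[1:]
        )
        if use_re:
            eta = eta + su * zu[fidx] + sv * zv[gidx]

        log_h = np.log(delta) - eta
        log_h = np.minimum(log_h, 30.0)  # guard against overflow at absurd eta
        h = np.exp(log_h)
        ll = np.where(died, np.log(-np.expm1(-np.minimum(h, 700.0))), -h)
        # d ll / d eta
        d = np.where(died, -h / np.expm1(np.minimum(h, 700.0)), h)

        logp = ll.sum()
        logp += -0.5 * (mu - config.prior_mu_mean) ** 2 / s2mu
        logp += -0.5 * (betas @ betas) / s2b

        grad = np.zeros_like(q)
        grad[0] = d.sum() - (mu - config.prior_mu_mean) / s2mu
        grad[1] = (s_star * d).sum() - betas[0] / s2b
        grad[2:5] = x[:, 1:].T @ d - betas[1:] / s2b
        pos2 = 5
        if use_re:
            logp += -0.5 * (zu @ zu) - 0.5 * (zv @ zv)
            logp += -0.5 * (su / config.prior_sd_scale) ** 2 + lsu
            logp += -0.5 * (sv / config.prior_sd_scale) ** 2 + lsv
            grad[pos2] = su * (zu[fidx] * d).sum() + 1.0 - (su / config.prior_sd_scale) ** 2
            grad[pos2 + 1] = sv * (zv[gidx] * d).sum() + 1.0 - (sv / config.prior_sd_scale) ** 2
            grad[pos2 + 2 : pos2 + 2 + F] = su * np.bincount(fidx, weights=d, minlength=F) - zu
            grad[pos2 + 2 + F : pos2 + 2 + F + G] = (
                sv * np.bincount(gidx, weights=d, minlength=G) - zv
            )
            pos2 += 2 + F + G
        if use_me:
            logp += -0.5 * (zs @ zs)
            grad[pos2:] = betas[0] * sd * d - zs
        return float(logp), grad

    init = np.zeros(dim)
    init[0] = config.prior_mu_mean
    groups = []
    if use_re:
        # non-centered families: rescale z against sigma (sigma*z invariant)
        groups = [
            (5, np.arange(7, 7 + F), -1),
            (6, np.arange(7 + F, 7 + F + G), -1),
        ]
    bounds: list = [(None, None)] * dim
    if use_re:
        bounds[5] = bounds[6] = (-4.0, 3.0)
    res = sample(
        logp_grad, dim, config.mcmc, init=init, map_bounds=bounds, scale_groups=groups
    )

    flat = res.draws
    draws = {
        "intercept": flat[:, :, 0],
        "beta_social": flat[:, :, 1],
        "beta_age": flat[:, :, 2],
        "beta_rank": flat[:, :, 3],
        "beta_groupsize": flat[:, :, 4],
    }
    if use_re:
        draws["sigma_female"] = np.exp(flat[:, :, 5])
        draws["sigma_group"] = np.exp(flat[:, :, 6])

    summary = summarize_fit_draws(draws)
    diag = convergence_summary({k: v for k, v in draws.items()})
    diag["divergences"] = res.divergences
    diag["accept_rate"] = res.accept_rate.tolist()
    converged = diag["max_rhat"] <= config.rhat_threshold
    diag["converged"] = converged
    if not converged:
        logger.warning("AFT fit flagged: max R-hat %.3f", diag["max_rhat"])

    return AFTResult(
        draws=draws,
        summary=summary,
        diagnostics=diag,
        scaling=None,
        n_rows=N,
        n_deaths=int(died.sum()),
        converged=converged,
        config=config,
    )


def summarize_fit_draws(draws: dict[str, np.ndarray]) -> pd.DataFrame:
    """Posterior mean and central 89% interval per parameter, with the
    conventional ``mean (lo; hi)`` formatting."""
    rows = []
    for name, d in draws.items():
        v = np.asarray(d).ravel()
        mean = float(v.mean())
        lo, hi = (float(np.quantile(v, q)) for q in (CI_LO, CI_HI))
        rows.append(
            dict(term=name, mean=mean, ci_lo=lo, ci_hi=hi,
                 formatted=f"{mean:.2f} ({lo:.2f}; {hi:.2f})")
        )
    return pd.DataFrame(rows)


def summarize_fit(result: AFTResult) -> pd.DataFrame:
    return summarize_fit_draws(result.draws)


def predict_death_probability(
    result: AFTResult,
    integration_grid: np.ndarray,
    scaling: dict,
) -> pd.DataFrame:
    """Predicted annual death probability over an integration grid.

    The grid is on the original (offset logit) scale; all other covariates
    sit at the sample mean (0 after standardization) and random intercepts at
    0. Returns the posterior-mean curve with an 89% credible band.
    """
    m, s = scaling["integration_mean"]
    grid_std = (np.asarray(integration_grid, float) - m) / s
    mu = result.draws["intercept"].ravel()[:, None]
    b = result.draws["beta_social"].ravel()[:, None]
    eta = mu + b * grid_std[None, :]
    p = 1.0 - np.exp(-result.config.delta_days * np.exp(-eta))
    return pd.DataFrame(
        {
            "integration": integration_grid,
            "p_mean": p.mean(axis=0),
            "p_lo": np.quantile(p, CI_LO, axis=0),
            "p_hi": np.quantile(p, CI_HI, axis=0),
        }
    )


MEASURES = [
    ("grooming", "giving"),
    ("grooming", "receiving"),
    ("support", "giving"),
    ("support", "receiving"),
    ("foraging", "undirected"),
]
PARTNER_TYPES = ["all", "adult_females", "adult_males"]


def run_model_battery(
    individuals: pd.DataFrame,
    demography: pd.DataFrame,
    covariates: pd.DataFrame,
    estimates_by_dataset: dict[str, pd.DataFrame],
    lag: int = 0,
    config: AFTConfig | None = None,
) -> tuple[pd.DataFrame, dict, dict]:
    """Fit the 5 measures x 3 partner datasets battery with one shared config.

    ``estimates_by_dataset`` maps partner type -> integration estimate table
    (all behaviors/directions concatenated). Returns the stacked coefficient
    table, a manifest with per-model row counts and convergence flags, and
    the fitted :class:`AFTResult` objects keyed by model name. Foraging
    contributes a single undirected measure, hence 15 models.
    """
    config = config or AFTConfig()
    blocks = []
    manifest: dict[str, dict] = {}
    results: dict[str, AFTResult] = {}
    for partner_type in PARTNER_TYPES:
        est_all = estimates_by_dataset.get(partner_type)
        if est_all is None or est_all.empty:
            continue
        for behavior, direction in MEASURES:
            est = est_all[
                (est_all["behavior"] == behavior) & (est_all["direction"] == direction)
            ]
            name = f"{behavior}_{direction}__{partner_type}"
            if est.empty:
                manifest[name] = {"status": "no-estimates"}
                continue
            fy = assemble_female_years(individuals, demography, covariates, est, lag=lag)
            if fy.empty or (fy["status"] == "died").sum() == 0:
                manifest[name] = {"status": "insufficient-data", "rows": len(fy)}
                continue
            std, scaling = standardize_covariates(fy)
            result = fit_aft(std, config)
            result.scaling = scaling
            results[name] = result
            block = result.summary.copy()
            block.insert(0, "model", name)
            block.insert(1, "behavior", behavior)
            block.insert(2, "direction", direction)
            block.insert(3, "partner_type", partner_type)
            blocks.append(block)
            manifest[name] = {
                "status": "ok" if result.converged else "flagged",
                "rows": result.n_rows,
                "deaths": result.n_deaths,
                "max_rhat": result.diagnostics["max_rhat"],
            }
    table = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame()
    return table, manifest, results
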