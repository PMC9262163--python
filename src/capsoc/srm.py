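"""Annualized multilevel Social Relations Model (SRM) for dyadic count data.

The observational unit is the dyad-year: for a directed behavior, the count
of interactions from actor *i* to partner *j* in year *t* out of the dyad's
opportunities is modeled as

    count_ijt ~ Binomial(opportunities_ijt, p_ijt)
    logit p_ijt = alpha + y_t + g_it + r_jt        (directed)
    logit p_ijt = alpha + y_t + s_it + s_jt        (undirected foraging)

where g (giving), r (receiving) and s (undirected sociability) are
zero-centered individual-year random effects with estimated scales, and y_t
are zero-centered year offsets (omitted when the table spans a single year).
The individual-year offsets are the social-integration measures: an offset of
zero is the population-average individual, and the posterior SD of an offset
grows for sparsely observed individuals, which is exactly the measurement
uncertainty the survival stage propagates.

Priors: Normal(0, 2.5) on the intercept and half-Normal(1) on the
random-effect scales — weakly informative on the logit scale and
config-overridable. Offsets are sampled in centered form (each family
centered on its mean inside the likelihood) with a dedicated rescaling move
handling the scale-offset coupling; see :mod:`capsoc.mcmc`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .mcmc import SamplerConfig, SampleResult, convergence_summary, sample

ESTIMATE_COLUMNS = ["id", "year", "behavior", "direction", "post_mean", "post_sd"]


@dataclass
class SRMSpec:
    directed: bool = True
    prior_scale_intercept: float = 2.5
    prior_scale_sd: float = 1.0
    mcmc: SamplerConfig = field(default_factory=SamplerConfig)
    rhat_threshold: float = 1.05


@dataclass
class SRMFit:
    estimates: pd.DataFrame
    diagnostics: dict
    draws: dict[str, np.ndarray]
    converged: bool


def _index(keys: list) -> dict:
    return {k: i for i, k in enumerate(keys)}


def fit_srm(dyads: pd.DataFrame, spec: SRMSpec) -> SRMFit:
    """Fit the SRM to one behavior x partner-type dyad-year table.

    Returns per individual-year the posterior mean and SD of each offset
    (giving/receiving for directed behaviors, a single undirected offset for
    foraging) plus convergence diagnostics computed on the reported offsets.
    """
    if dyads.empty:
        raise ValueError("empty dyad table")
    if (dyads["count"] > dyads["opportunities"]).any():
        raise ValueError("count exceeds opportunities")
    behaviors = set(dyads["behavior"])
    if len(behaviors) != 1:
        raise ValueError(f"table mixes behaviors: {behaviors}")
    behavior = behaviors.pop()

    k = dyads["count"].to_numpy(float)
    n = dyads["opportunities"].to_numpy(float)
    years = sorted(dyads["year"].unique())
    use_year = len(years) > 1
    iy = dyads["year"].map(_index(years)).to_numpy()

    if spec.directed:
        actor_keys = sorted(set(zip(dyads["actor"], dyads["year"])))
        partner_keys = sorted(set(zip(dyads["partner"], dyads["year"])))
        ia = pd.Series(zip(dyads["actor"], dyads["year"])).map(_index(actor_keys)).to_numpy()
        ip = pd.Series(zip(dyads["partner"], dyads["year"])).map(_index(partner_keys)).to_numpy()
        A, B = len(actor_keys), len(partner_keys)
    else:
        node_keys = sorted(
            set(zip(dyads["actor"], dyads["year"])) | set(zip(dyads["partner"], dyads["year"]))
        )
        node_index = _index(node_keys)
        ia = pd.Series(zip(dyads["actor"], dyads["year"])).map(node_index).to_numpy()
        ip = pd.Series(zip(dyads["partner"], dyads["year"])).map(node_index).to_numpy()
        A = B = len(node_keys)

    T = len(years)
    s2a = spec.prior_scale_intercept ** 2

    # layout: alpha | log-scales | z_g | z_r | z_y
    if spec.directed:
        n_scales = 2 + int(use_year)
        dim = 1 + n_scales + A + B + (T if use_year else 0)
    else:
        n_scales = 1 + int(use_year)
        dim = 1 + n_scales + A + (T if use_year else 0)

    def unpack(q: np.ndarray):
        alpha = q[0]
        lam = q[1 : 1 + n_scales]
        rest = q[1 + n_scales :]
        if spec.directed:
            zg = rest[:A]
            zr = rest[A : A + B]
            zy = rest[A + B :] if use_year else None
        else:
            zg = rest[:A]
            zr = None
            zy = rest[A:] if use_year else None
        return alpha, lam, zg, zr, zy

    def logp_grad(q: np.ndarray):
        # Centered parameterization (offsets g carry their own scale, with
        # the family SD only in the prior): the dyadic data inform each
        # offset strongly, which is the regime where centering mixes well.
        # Each offset family enters the likelihood centered on its mean
        # (g - g_bar), matching the offsets' definition as zero-centered
        # deviations from the population average and decoupling them from
        # the intercept.
        alpha, lam, zg, zr, zy = unpack(q)
        sig = np.exp(lam)
        s2 = sig ** 2
        cg = zg - zg.mean()
        eta = np.full(k.shape, alpha)
        if spec.directed:
            cr = zr - zr.mean()
            eta = eta + cg[ia] + cr[ip]
        else:
            eta = eta + cg[ia] + cg[ip]
        if use_year:
            cy = zy - zy.mean()
            eta = eta + cy[iy]

        # binomial log-likelihood up to a constant
        ll = k * eta - n * np.logaddexp(0.0, eta)
        d = k - n * expit(eta)
        dsum = d.sum()

        grad = np.empty_like(q)
        logp = ll.sum()
        logp += -0.5 * alpha ** 2 / s2a
        logp += (-0.5 * (sig / spec.prior_scale_sd) ** 2 + lam).sum()
        grad[0] = dsum - alpha / s2a

        glam = np.empty(n_scales)
        # half-normal prior on sigma plus the log-scale jacobian
        glam[:] = 1.0 - s2 / spec.prior_scale_sd ** 2
        logp += -0.5 * (zg @ zg) / s2[0] - A * lam[0]
        glam[0] += (zg @ zg) / s2[0] - A
        if spec.directed:
            logp += -0.5 * (zr @ zr) / s2[1] - B * lam[1]
            glam[1] += (zr @ zr) / s2[1] - B
            gzg = np.bincount(ia, weights=d, minlength=A) - dsum / A - zg / s2[0]
            gzr = np.bincount(ip, weights=d, minlength=B) - dsum / B - zr / s2[1]
            parts = [gzg, gzr]
        else:
            gzg = (
                np.bincount(ia, weights=d, minlength=A)
                + np.bincount(ip, weights=d, minlength=A)
                - 2 * dsum / A
                - zg / s2[0]
            )
            parts = [gzg]
        if use_year:
            logp += -0.5 * (zy @ zy) / s2[-1] - T * lam[-1]
            glam[-1] += (zy @ zy) / s2[-1] - T
            gzy = np.bincount(iy, weights=d, minlength=T) - dsum / T - zy / s2[-1]
            parts.append(gzy)
        grad[1 : 1 + n_scales] = glam
        grad[1 + n_scales :] = np.concatenate(parts)
        return float(logp), grad

    init = np.zeros(dim)
    init[0] = np.log((k.sum() + 0.5) / (n.sum() - k.sum() + 0.5))  # empirical logit
    init[1 : 1 + n_scales] = np.log(0.5)
    bounds: list = [(None, None)] * dim
    for i in range(1, 1 + n_scales):
        bounds[i] = (-4.0, 3.0)  # keep the MAP off the sigma -> 0 ridge
    base = 1 + n_scales
    if spec.directed:
        groups = [
            (1, np.arange(base, base + A), 1),
            (2, np.arange(base + A, base + A + B), 1),
        ]
        if use_year:
            groups.append((3, np.arange(base + A + B, dim), 1))
    else:
        groups = [(1, np.arange(base, base + A), 1)]
        if use_year:
            groups.append((2, np.arange(base + A, dim), 1))
    res: SampleResult = sample(
        logp_grad, dim, spec.mcmc, init=init, map_bounds=bounds, scale_groups=groups
    )
    flat = res.draws  # (chains, samples, dim)
    alpha_d = flat[:, :, 0]
    sig_d = np.exp(flat[:, :, 1 : 1 + n_scales])

    if spec.directed:
        zg_d = flat[:, :, 1 + n_scales : 1 + n_scales + A]
        zr_d = flat[:, :, 1 + n_scales + A : 1 + n_scales + A + B]
        g_d = zg_d - zg_d.mean(axis=2, keepdims=True)
        r_d = zr_d - zr_d.mean(axis=2, keepdims=True)
        offset_draws = {"giving": (actor_keys, g_d), "receiving": (partner_keys, r_d)}
    else:
        zg_d = flat[:, :, 1 + n_scales : 1 + n_scales + A]
        s_d = zg_d - zg_d.mean(axis=2, keepdims=True)
        offset_draws = {"undirected": (node_keys, s_d)}

    records = []
    for direction, (keys, d3) in offset_draws.items():
        means = d3.mean(axis=(0, 1))
        sds = d3.std(axis=(0, 1), ddof=1)
        for (iid, year), m, s in zip(keys, means, sds):
            records.append(
                dict(id=iid, year=year, behavior=behavior, direction=direction,
                     post_mean=m, post_sd=s)
            )
    estimates = pd.DataFrame(records, columns=ESTIMATE_COLUMNS)
    estimates = estimates.sort_values(["direction", "id", "year"]).reset_index(drop=True)

    named = {"alpha": alpha_d, "sigma": np.exp(flat[:, :, 1 : 1 + n_scales])}
    for direction, (keys, d3) in offset_draws.items():
        named[f"offset_{direction}"] = d3
    diag = convergence_summary(named)
    diag["divergences"] = res.divergences
    diag["accept_rate"] = res.accept_rate.tolist()
    offset_rhat = max(
        diag[f"offset_{d}"]["rhat_max"] for d in offset_draws
    )
    converged = offset_rhat <= spec.rhat_threshold
    diag["converged"] = converged

    draws = {"alpha": alpha_d}
    for i, nm in enumerate(
        (["sigma_giving", "sigma_receiving"] if spec.directed else ["sigma_undirected"])
        + (["sigma_year"] if use_year else [])
    ):
        draws[nm] = sig_d[:, :, i]
    return SRMFit(estimates=estimates, diagnostics=diag, draws=draws, converged=converged)


def summarize_integration_ranges(estimates: pd.DataFrame) -> pd.DataFrame:
    """Min and max posterior-mean offset per (behavior, direction) measure —
    the per-dataset column of the integration-range table."""
    if estimates.empty:
        raise ValueError("no estimates to summarize")
    out = (
        estimates.groupby(["behavior", "direction"], sort=True)["post_mean"]
        .agg(["min", "max"])
        .reset_index()
        .rename(columns={"min": "post_mean_min", "max": "post_mean_max"})
    )
    return out
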