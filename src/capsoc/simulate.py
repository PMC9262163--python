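"""Synthetic capuchin-like study populations with known ground truth.

The generator emulates the structure of a long-term field study of several
social groups: philopatric females (adults from age 5) with stable group
residence, migrating males with exponentially distributed tenures, immatures
who mature during the study (natal males emigrate at 5), annual dominance
ranks in [0, 1], and five dyadic interaction channels observed through
realistic sampling protocols (10-min focal follows for grooming, an
aggression event stream for coalitionary support, group scans with neighbor
distances for foraging proximity).

Every individual-year carries a latent sociality core on the logit scale;
channel-specific actor/partner propensities load on that core with
channel-specific noise, and adult-female survival depends on the core through
the same annual piecewise-exponential hazard the survival stage fits. Ground
truth (latent propensities, realized deaths, all parameters) is returned so
parameter-recovery tests can close the loop.

Default observation densities are roughly one fifth of the source study's
(about 7 focal follows per individual-year, 64 aggressive intervals and 420
group scans per group-year) so that full pipeline runs stay fast; the
``paper_scale`` preset restores full densities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import EventBundle
from .interactions import MembershipIndex, age_years

DAY = pd.Timedelta(days=1)


@dataclass
class SimConfig:
    # population structure
    n_groups: int = 10
    females_per_group: int = 8
    males_per_group: int = 4
    immatures_per_group: int = 6
    years: int = 15
    start_year: int = 2005
    male_mean_tenure_years: float = 4.0
    births_per_group_year: float = 1.2
    # observation densities (~1/5 of the source study's averages)
    follows_per_ind_year: int = 7
    intervals_per_group_year: int = 64
    scans_per_group_year: int = 420
    foraging_scan_frac: float = 0.6
    far_neighbor_prob: float = 0.15
    # SRM truth: baseline logit rates and propensity scales per channel
    base_logit_grooming: float = -3.5
    base_logit_support: float = -3.5
    base_logit_foraging: float = -2.0
    sd_giving: float = 1.0
    sd_receiving: float = 0.5
    sd_foraging: float = 0.7
    # survival acts on the sociality core; grooming giving tracks it exactly
    # (the flagship measure), the other channels carry channel-specific noise
    loading_giving: float = 1.0
    loading_support: float = 0.8
    loading_receiving: float = 0.5
    loading_foraging: float = 0.7
    sociality_jitter: float = 0.15
    # survival truth (AFT scale, log-days)
    mu_days: float = 9.46
    beta_social: float = 0.5
    beta_age: float = -0.08
    beta_rank: float = -0.10
    beta_groupsize: float = 0.10
    sigma_female: float = 0.3
    sigma_group: float = 0.2
    delta_days: float = 365.25
    # nominal standardization used inside the generator's hazard
    age_ref_mean: float = 12.0
    age_ref_sd: float = 6.0
    rank_ref_mean: float = 0.5
    rank_ref_sd: float = 0.2887
    gs_ref_mean: float = 20.0
    gs_ref_sd: float = 4.0
    rank_noise: float = 0.05
    seed: int = 1

    @classmethod
    def test_scale(cls, **overrides) -> "SimConfig":
        """A small preset for unit tests and quick runs."""
        base = cls(
            n_groups=2, females_per_group=4, males_per_group=2,
            immatures_per_group=2, years=5, follows_per_ind_year=5,
            intervals_per_group_year=24, scans_per_group_year=120,
        )
        return replace(base, **overrides)

    @classmethod
    def paper_scale(cls, **overrides) -> "SimConfig":
        """Observation densities and population size of the source study."""
        base = cls(
            n_groups=11, females_per_group=12, males_per_group=5,
            immatures_per_group=8, years=18, follows_per_ind_year=35,
            intervals_per_group_year=322, scans_per_group_year=2086,
        )
        return replace(base, **overrides)


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    config: SimConfig
    latents: pd.DataFrame        # id, year, sociality + channel propensities
    female_effects: dict[str, float]
    group_effects: dict[str, float]
    death_year: dict[str, int]   # realized death year per female
    rank_quantile: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "latents": self.latents.to_dict(orient="list"),
            "female_effects": self.female_effects,
            "group_effects": self.group_effects,
            "death_year": self.death_year,
            "rank_quantile": self.rank_quantile,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class Population:
    individuals: pd.DataFrame
    membership: pd.DataFrame
    covariates: pd.DataFrame
    demography: pd.DataFrame
    truth: SimTruth


def _ts(year: int, day_frac: float) -> pd.Timestamp:
    return pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(
        days=float(day_frac)
    )


def simulate_population(config: SimConfig, rng: np.random.Generator | None = None):
    """Individuals, group histories and latent propensities (no deaths yet).

    Deterministic given ``config.seed``; pass an explicit generator to chain
    with other stages.
    """
    rng = rng or np.random.default_rng(config.seed)
    start = pd.Timestamp(year=config.start_year, month=1, day=1)
    end = pd.Timestamp(year=config.start_year + config.years - 1, month=12, day=31)

    individuals = []
    membership = []

    def add(iid, sex, birth, group, entry, exit_):
        individuals.append(dict(id=iid, sex=sex, birth_date=birth))
        membership.append(dict(id=iid, group=group, entry=entry, exit=exit_))

    for g in range(config.n_groups):
        group = f"G{g + 1:02d}"
        for f in range(config.females_per_group):
            iid = f"{group}-F{f + 1:02d}"
            age0 = rng.uniform(5.0, 20.0)
            add(iid, "F", start - pd.Timedelta(days=age0 * 365.25), group, start, end)
        # male slots: a sequence of migrants per slot
        for m in range(config.males_per_group):
            t = start
            k = 0
            while t < end:
                k += 1
                iid = f"{group}-M{m + 1:02d}{chr(96 + min(k, 26))}"
                age0 = rng.uniform(7.0, 18.0)
                tenure = pd.Timedelta(
                    days=float(rng.exponential(config.male_mean_tenure_years) * 365.25 + 30)
                )
                exit_ = min(t + tenure, end)
                add(iid, "M", t - pd.Timedelta(days=age0 * 365.25), group, t, exit_)
                t = exit_ + DAY
        for i in range(config.immatures_per_group):
            sex = "F" if rng.random() < 0.5 else "M"
            iid = f"{group}-I{i + 1:02d}"
            age0 = rng.uniform(0.5, 5.0)
            birth = start - pd.Timedelta(days=age0 * 365.25)
            if sex == "M":
                emigrate = birth + pd.Timedelta(days=5 * 365.25)
                exit_ = min(max(emigrate, start), end)
            else:
                exit_ = end
            add(iid, sex, birth, group, start, exit_)
        # births during the study
        n_births = rng.poisson(config.births_per_group_year * config.years)
        for b in range(n_births):
            sex = "F" if rng.random() < 0.5 else "M"
            iid = f"{group}-B{b + 1:02d}"
            birth = start + pd.Timedelta(days=float(rng.uniform(0, (end - start).days - 30)))
            if sex == "M":
                exit_ = min(birth + pd.Timedelta(days=5 * 365.25), end)
            else:
                exit_ = end
            add(iid, sex, birth, group, birth, exit_)

    individuals = pd.DataFrame(individuals)
    membership = pd.DataFrame(membership)

    # latent sociality core per individual-year, unit marginal variance
    years = list(range(config.start_year, config.start_year + config.years))
    core = {iid: rng.standard_normal() for iid in individuals["id"]}
    jit = config.sociality_jitter
    lat_rows = []
    for iid in individuals["id"]:
        for year in years:
            c = np.sqrt(1 - jit ** 2) * core[iid] + jit * rng.standard_normal()
            row = dict(id=iid, year=year, sociality=c)
            for channel, sd, w in [
                ("groom_give", config.sd_giving, config.loading_giving),
                ("groom_recv", config.sd_receiving, config.loading_receiving),
                ("support_give", config.sd_giving, config.loading_support),
                ("support_recv", config.sd_receiving, config.loading_receiving),
                ("forage", config.sd_foraging, config.loading_foraging),
            ]:
                row[channel] = sd * (w * c + np.sqrt(1 - w ** 2) * rng.standard_normal())
            lat_rows.append(row)
    latents = pd.DataFrame(lat_rows)

    female_ids = individuals.loc[individuals["sex"] == "F", "id"]
    truth = SimTruth(
        config=config,
        latents=latents,
        female_effects={
            iid: float(config.sigma_female * rng.standard_normal()) for iid in female_ids
        },
        group_effects={
            f"G{g + 1:02d}": float(config.sigma_group * rng.standard_normal())
            for g in range(config.n_groups)
        },
        death_year={},
        rank_quantile={iid: float(rng.uniform()) for iid in female_ids},
    )
    return individuals, membership, truth


def annual_death_probability(eta: float | np.ndarray, delta_days: float = 365.25):
    """p(die within the year) = 1 - exp(-Delta * exp(-eta))."""
    return 1.0 - np.exp(-delta_days * np.exp(-np.asarray(eta, float)))


def simulate_survival(
    individuals: pd.DataFrame,
    membership: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> Population:
    """Draw adult-female deaths year by year from the true hazard.

    Uses the TRUE latent sociality core (not any estimate), covariates
    standardized by the generator's nominal reference moments, and the true
    female/group intercepts. Deaths truncate group membership; survivors are
    censored at study end. Also emits the annual covariate table (rank, mean
    group size) for every adult female-year under observation.
    """
    mem = membership.copy()
    end = pd.Timestamp(year=config.start_year + config.years - 1, month=12, day=31)
    birth = dict(zip(individuals["id"], individuals["birth_date"]))
    sex = dict(zip(individuals["id"], individuals["sex"]))
    lat = truth.latents.set_index(["id", "year"])["sociality"]

    cov_rows = []
    dead: dict[str, pd.Timestamp] = {}
    years = range(config.start_year, config.start_year + config.years)
    for year in years:
        index = MembershipIndex(mem)
        mid = pd.Timestamp(year=year, month=7, day=1)
        quarters = [pd.Timestamp(year=year, month=m, day=15) for m in (2, 5, 8, 11)]
        gsize = {}
        for g in range(config.n_groups):
            group = f"G{g + 1:02d}"
            gsize[group] = float(
                np.mean([len(index.members_at(group, q)) for q in quarters])
            )
        for iid in sorted(sex):
            if sex[iid] != "F" or iid in dead:
                continue
            age = age_years(birth[iid], mid)
            if age < 5.0:
                continue
            group = index.group_at(iid, mid)
            if group is None:
                continue
            rank = float(
                np.clip(truth.rank_quantile[iid] + config.rank_noise * rng.standard_normal(), 0, 1)
            )
            gs = gsize[group]
            eta = (
                config.mu_days
                + config.beta_social * lat[(iid, year)]
                + config.beta_age * (age - config.age_ref_mean) / config.age_ref_sd
                + config.beta_rank * (rank - config.rank_ref_mean) / config.rank_ref_sd
                + config.beta_groupsize * (gs - config.gs_ref_mean) / config.gs_ref_sd
                + truth.female_effects[iid]
                + truth.group_effects[group]
            )
            p = float(annual_death_probability(eta, config.delta_days))
            cov_rows.append(
                dict(id=iid, year=year, rank=round(rank, 4),
                     group_size=round(gs, 2), group=group)
            )
            if rng.random() < p:
                death = _ts(year, rng.uniform(0, 364.2))
                dead[iid] = death
                truth.death_year[iid] = year
                mem.loc[mem["id"] == iid, "exit"] = death

    demo_rows = []
    for iid in sorted(sex):
        if sex[iid] != "F":
            continue
        if iid in dead:
            demo_rows.append(dict(id=iid, death_date=dead[iid], censor_date=pd.NaT))
        else:
            demo_rows.append(dict(id=iid, death_date=pd.NaT, censor_date=end))
    covariates = pd.DataFrame(cov_rows, columns=["id", "year", "rank", "group_size", "group"])
    demography = pd.DataFrame(demo_rows, columns=["id", "death_date", "censor_date"])
    return Population(individuals, mem, covariates, demography, truth)


def simulate_interactions(
    pop: Population, config: SimConfig, rng: np.random.Generator
) -> EventBundle:
    """Generate the raw behavioral event streams from the latent propensities.

    Grooming is drawn per focal follow and ordered co-resident dyad with
    logit p = base + give_i + recv_j (so the builder's count/opportunity
    table is exactly binomial in the SRM's generative model); support events
    are seeded by one aggressor-target pair per 5-min burst with co-residents
    joining either side; foraging proximity is drawn per scan and neighbor.
    """
    index = MembershipIndex(pop.membership)
    lat = pop.truth.latents.set_index(["id", "year"])
    give = {ch: lat[ch].to_dict() for ch in ["groom_give", "support_give"]}
    recv = {ch: lat[ch].to_dict() for ch in ["groom_recv", "support_recv"]}
    forage = lat["forage"].to_dict()

    years = list(range(config.start_year, config.start_year + config.years))
    follows, groom_events, aggression, scans, neighbors = [], [], [], [], []
    fid = sid = 0

    for year in years:
        ystart = pd.Timestamp(year=year, month=1, day=1)
        mid = pd.Timestamp(year=year, month=7, day=1)
        for g in range(config.n_groups):
            group = f"G{g + 1:02d}"
            residents = sorted(index.members_at(group, mid))
            if len(residents) < 2:
                continue

            # --- focal follows and grooming
            for focal in residents:
                n_f = config.follows_per_ind_year
                for day in rng.uniform(0, 364, size=n_f):
                    t = ystart + pd.Timedelta(days=float(day))
                    if index.group_at(focal, t) != group:
                        continue
                    fid += 1
                    follow_id = f"FL{fid:07d}"
                    follows.append(
                        dict(follow_id=follow_id, focal=focal, group=group,
                             start=t, duration_min=10)
                    )
                    partners = [p for p in index.members_at(group, t) if p != focal]
                    if not partners:
                        continue
                    p_fwd = expit(
                        config.base_logit_grooming
                        + give["groom_give"].get((focal, year), 0.0)
                        + np.array([recv["groom_recv"].get((p, year), 0.0) for p in partners])
                    )
                    p_bwd = expit(
                        config.base_logit_grooming
                        + np.array([give["groom_give"].get((p, year), 0.0) for p in partners])
                        + recv["groom_recv"].get((focal, year), 0.0)
                    )
                    fwd = rng.random(len(partners)) < p_fwd
                    bwd = rng.random(len(partners)) < p_bwd
                    for j, p in enumerate(partners):
                        if fwd[j]:
                            groom_events.append(
                                dict(follow_id=follow_id, groomer=focal, groomee=p,
                                     time=t + pd.Timedelta(minutes=float(rng.uniform(0, 9))))
                            )
                            if rng.random() < 0.25:  # repeat within follow collapses to 1
                                groom_events.append(
                                    dict(follow_id=follow_id, groomer=focal, groomee=p,
                                         time=t + pd.Timedelta(minutes=float(rng.uniform(0, 9))))
                                )
                        if bwd[j]:
                            groom_events.append(
                                dict(follow_id=follow_id, groomer=p, groomee=focal,
                                     time=t + pd.Timedelta(minutes=float(rng.uniform(0, 9))))
                            )

            # --- aggression bursts and joining
            n_iv = config.intervals_per_group_year
            gap = 364 * 24 * 60 / max(n_iv, 1)  # minutes between burst anchors
            for b in range(n_iv):
                t = ystart + pd.Timedelta(minutes=b * gap + float(rng.uniform(0, gap / 3)))
                res_t = sorted(index.members_at(group, t))
                if len(res_t) < 2:
                    continue
                a, v = rng.choice(res_t, size=2, replace=False)
                aggression.append(dict(time=t, group=group, aggressor=a, target=v))
                for i in res_t:
                    if i in (a, v):
                        continue
                    for joinee, opponent in ((a, v), (v, a)):
                        pj = expit(
                            config.base_logit_support
                            + give["support_give"].get((i, year), 0.0)
                            + recv["support_recv"].get((joinee, year), 0.0)
                        )
                        if rng.random() < pj:
                            aggression.append(
                                dict(time=t + pd.Timedelta(minutes=float(rng.uniform(0.5, 4.5))),
                                     group=group, aggressor=i, target=opponent)
                            )

            # --- group scans and foraging proximity
            n_sc = config.scans_per_group_year
            sgap = 364 * 24 * 60 / max(n_sc, 1)
            for s in range(n_sc):
                t = ystart + pd.Timedelta(minutes=s * sgap + float(rng.uniform(0, sgap / 3)))
                res_t = sorted(index.members_at(group, t))
                if len(res_t) < 2:
                    continue
                subject = str(rng.choice(res_t))
                activity = "foraging" if rng.random() < config.foraging_scan_frac else "other"
                sid += 1
                scan_id = f"SC{sid:07d}"
                scans.append(
                    dict(scan_id=scan_id, time=t, group=group, subject=subject,
                         activity=activity)
                )
                others = [o for o in res_t if o != subject]
                s_i = forage.get((subject, year), 0.0)
                p_close = expit(
                    config.base_logit_foraging
                    + s_i
                    + np.array([forage.get((o, year), 0.0) for o in others])
                )
                u = rng.random(len(others))
                for j, o in enumerate(others):
                    if u[j] < p_close[j]:
                        neighbors.append(
                            dict(scan_id=scan_id, neighbor=o,
                                 distance_bl=round(float(rng.uniform(0.3, 5.0)), 2))
                        )
                    elif rng.random() < config.far_neighbor_prob:
                        neighbors.append(
                            dict(scan_id=scan_id, neighbor=o,
                                 distance_bl=round(float(rng.uniform(5.01, 10.0)), 2))
                        )

    bundle = EventBundle(
        individuals=pop.individuals,
        membership=pop.membership,
        follows=pd.DataFrame(follows, columns=["follow_id", "focal", "group", "start", "duration_min"]),
        grooming=pd.DataFrame(groom_events, columns=["follow_id", "groomer", "groomee", "time"]),
        aggression=pd.DataFrame(aggression, columns=["time", "group", "aggressor", "target"]),
        scans=pd.DataFrame(scans, columns=["scan_id", "time", "group", "subject", "activity"]),
        scan_neighbors=pd.DataFrame(neighbors, columns=["scan_id", "neighbor", "distance_bl"]),
        covariates=pop.covariates,
        demography=pop.demography,
    )
    return bundle


def simulate_study(config: SimConfig) -> tuple[EventBundle, SimTruth]:
    """Full generator: population, survival, then interaction streams."""
    rng = np.random.default_rng(config.seed)
    individuals, membership, truth = simulate_population(config, rng)
    pop = simulate_survival(individuals, membership, truth, config, rng)
    bundle = simulate_interactions(pop, config, rng)
    return bundle, truth


def simulate_integration_estimates(
    pop: Population,
    config: SimConfig,
    rng: np.random.Generator,
    noise_var: float = 0.15,
    behavior: str = "truth",
    direction: str = "sociality",
) -> pd.DataFrame:
    """Stage-one-like estimates generated directly from the truth.

    Emulates a posterior for the latent sociality core: with measurement
    y = c + Normal(0, tau) and prior c ~ Normal(0, 1), the posterior is
    Normal(y / (1 + tau^2), tau^2 / (1 + tau^2)) — so conditioning on the
    emitted (mean, sd), the true core is exactly Normal(mean, sd), which is
    the assumption the survival stage's measurement-error model makes.
    """
    lat = pop.truth.latents.set_index(["id", "year"])["sociality"]
    tau2 = noise_var
    post_var = tau2 / (1 + tau2)
    rows = []
    for rec in pop.covariates.itertuples(index=False):
        c = lat[(rec.id, rec.year)]
        y = c + np.sqrt(tau2) * rng.standard_normal()
        rows.append(
            dict(id=rec.id, year=rec.year, behavior=behavior, direction=direction,
                 post_mean=y / (1 + tau2), post_sd=np.sqrt(post_var))
        )
    return pd.DataFrame(rows)
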