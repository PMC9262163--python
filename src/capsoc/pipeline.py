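"""End-to-end orchestration: simulate/load -> dyad tables -> SRM -> survival.

A single configuration drives all stages. Per-stage seeds are derived from
one master seed with a documented splitting rule (``stage_seed``), so a rerun
with the same configuration and master seed reproduces byte-identical
summary tables. A run manifest records the configuration hash, derived
seeds, SHA-256 checksums of every output file, and per-stage status.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .interactions import build_partner_dataset
from .io import read_bundle, write_bundle, write_table
from .mcmc import SamplerConfig
from .simulate import SimConfig, simulate_study
from .srm import SRMSpec, fit_srm, summarize_integration_ranges
from .survival import (
    AFTConfig,
    MEASURES,
    PARTNER_TYPES,
    predict_death_probability,
    run_model_battery,
)

logger = logging.getLogger(__name__)

BEHAVIORS = ["grooming", "support", "foraging"]

_STAGE_IDS = {"simulate": 1, "srm": 2, "survival": 3}


def stage_seed(master: int, stage: str, k: int = 0) -> int:
    """Deterministic per-stage seed: fold (master, stage index, substage)
    through SeedSequence and keep it below 2^31."""
    ss = np.random.SeedSequence([int(master), _STAGE_IDS[stage], int(k)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    out_dir: str = "capsoc_run"
    seed: int = 1
    simulate: bool = True
    events_dir: str | None = None
    sim_preset: str = "default"          # default | test | paper
    sim_overrides: dict = field(default_factory=dict)
    partner_types: list = field(default_factory=lambda: list(PARTNER_TYPES))
    lags: list = field(default_factory=lambda: [0])
    srm_mcmc: dict = field(
        default_factory=lambda: dict(
            chains=2, warmup=500, samples=400, max_leapfrog=48, target_accept=0.8
        )
    )
    aft_mcmc: dict = field(
        default_factory=lambda: dict(chains=2, warmup=400, samples=400, max_leapfrog=32)
    )
    strict: bool = False
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    overrides = dict(cfg.sim_overrides)
    overrides["seed"] = stage_seed(cfg.seed, "simulate")
    if cfg.sim_preset == "test":
        return SimConfig.test_scale(**overrides)
    if cfg.sim_preset == "paper":
        return SimConfig.paper_scale(**overrides)
    return SimConfig(**overrides)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "master_seed": cfg.seed,
        "config_hash": hashlib.sha256(
            yaml.safe_dump(asdict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "outputs": {},
    }

    # ---- stage 1: data
    if cfg.simulate:
        sim_cfg = _sim_config(cfg)
        bundle, truth = simulate_study(sim_cfg)
        data_dir = out / "data"
        write_bundle(bundle, data_dir)
        truth.to_json(data_dir / "truth.json")
        manifest["stages"]["simulate"] = {
            "seed": sim_cfg.seed,
            "n_individuals": len(bundle.individuals),
            "n_follows": len(bundle.follows),
        }
    else:
        if not cfg.events_dir:
            raise FileNotFoundError("events_dir required when simulate=False")
        bundle = read_bundle(cfg.events_dir)
        manifest["stages"]["load"] = {"events_dir": str(cfg.events_dir)}
    bundle.validate()

    # ---- stage 2: dyad tables and SRM fits per behavior x partner dataset
    est_by_dataset: dict[str, pd.DataFrame] = {}
    range_blocks = []
    flagged = []
    k = 0
    for partner_type in cfg.partner_types:
        est_parts = []
        for behavior in BEHAVIORS:
            k += 1
            dyads = build_partner_dataset(bundle, behavior, partner_type)
            write_table(dyads, out / "dyads" / f"dyads_{behavior}_{partner_type}.csv")
            if dyads.empty:
                manifest["stages"][f"srm_{behavior}_{partner_type}"] = {"status": "empty"}
                continue
            spec = SRMSpec(
                directed=(behavior != "foraging"),
                mcmc=SamplerConfig(seed=stage_seed(cfg.seed, "srm", k), **cfg.srm_mcmc),
            )
            fit = fit_srm(dyads, spec)
            est_parts.append(fit.estimates)
            write_table(
                fit.estimates,
                out / "integration" / f"integration_{behavior}_{partner_type}.csv",
            )
            (out / "integration" / f"diagnostics_{behavior}_{partner_type}.json").write_text(
                json.dumps(fit.diagnostics, indent=1, default=float)
            )
            manifest["stages"][f"srm_{behavior}_{partner_type}"] = {
                "status": "ok" if fit.converged else "flagged",
                "max_rhat": fit.diagnostics["max_rhat"],
                "n_estimates": len(fit.estimates),
            }
            if not fit.converged:
                flagged.append(f"srm_{behavior}_{partner_type}")
        if est_parts:
            est = pd.concat(est_parts, ignore_index=True)
            est_by_dataset[partner_type] = est
            # integration-range table restricted to adult-female subjects
            females = set(bundle.individuals.loc[bundle.individuals["sex"] == "F", "id"])
            ranges = summarize_integration_ranges(est[est["id"].isin(females)])
            ranges.insert(0, "partner_type", partner_type)
            range_blocks.append(ranges)

    if range_blocks:
        ranges = pd.concat(range_blocks, ignore_index=True)
        write_table(ranges, out / "integration_ranges.csv")

    # ---- stage 3: survival battery per lag
    for lag in cfg.lags:
        aft_cfg = AFTConfig(
            mcmc=SamplerConfig(seed=stage_seed(cfg.seed, "survival", lag), **cfg.aft_mcmc)
        )
        table, batt_manifest, results = run_model_battery(
            bundle.individuals,
            bundle.demography,
            bundle.covariates,
            est_by_dataset,
            lag=lag,
            config=aft_cfg,
        )
        write_table(table, out / "survival" / f"summary_lag{lag}.csv")
        manifest["stages"][f"battery_lag{lag}"] = batt_manifest
        flagged += [m for m, v in batt_manifest.items() if v.get("status") == "flagged"]
        for name, res in results.items():
            m, s = res.scaling["integration_mean"]
            grid = np.linspace(m - 2.5 * s, m + 2.5 * s, 41)
            curve = predict_death_probability(res, grid, res.scaling)
            write_table(curve, out / "survival" / f"prediction_{name}_lag{lag}.csv")
        if cfg.make_figures and results:
            make_prediction_figure(
                results,
                {k: r.scaling for k, r in results.items()},
                out / "survival" / f"curves_lag{lag}.svg",
            )

    _write_report(out, cfg)

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    manifest["flagged"] = flagged
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
    if cfg.strict and flagged:
        raise RuntimeError(f"convergence flags in strict mode: {flagged}")
    return manifest


def _write_report(out: Path, cfg: PipelineConfig) -> None:
    """Render a Markdown report from the tables the run produced."""
    lines = ["# capsoc pipeline report", ""]
    rng_path = out / "integration_ranges.csv"
    if rng_path.exists():
        ranges = pd.read_csv(rng_path)
        lines += ["## Ranges of individual social-integration measures", ""]
        wide = ranges.pivot_table(
            index=["behavior", "direction"],
            columns="partner_type",
            values=["post_mean_min", "post_mean_max"],
            sort=False,
        )
        lines += ["```", wide.round(2).to_string(), "```", ""]
    for summary in sorted(out.glob("survival/summary_lag*.csv")):
        table = pd.read_csv(summary)
        lines += [f"## Survival battery ({summary.stem})", ""]
        if not table.empty:
            pivot = table[table["term"] == "beta_social"][
                ["behavior", "direction", "partner_type", "formatted"]
            ]
            lines += ["Sociality coefficients (posterior mean, 89% CI):", "", "```",
                      pivot.to_string(index=False), "```", ""]
    (out / "report.md").write_text("\n".join(lines))


def make_prediction_figure(
    results: dict, scalings: dict, out_path: Path
) -> None:
    """Figure-style predicted annual death-probability curves (one panel per
    measure, one line per partner dataset) with 89% bands."""
    import matplotlib

    matplotlib.use("Agg")
    matplotlib.rcParams["svg.hashsalt"] = "capsoc"
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(MEASURES), figsize=(4 * len(MEASURES), 3.2))
    for ax, (behavior, direction) in zip(np.atleast_1d(axes), MEASURES):
        for ptype in PARTNER_TYPES:
            key = f"{behavior}_{direction}__{ptype}"
            if key not in results:
                continue
            res, scaling = results[key], scalings[key]
            m, s = scaling["integration_mean"]
            grid = np.linspace(m - 2.5 * s, m + 2.5 * s, 41)
            curve = predict_death_probability(res, grid, scaling)
            ax.plot(curve["integration"], curve["p_mean"], label=ptype)
            ax.fill_between(curve["integration"], curve["p_lo"], curve["p_hi"], alpha=0.2)
        ax.set_title(f"{behavior} {direction}")
        ax.set_xlabel("integration (logit offset)")
    np.atleast_1d(axes)[0].set_ylabel("annual P(death)")
    np.atleast_1d(axes)[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, metadata={"Date": None} if str(out_path).endswith(".svg") else None)
    plt.close(fig)
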