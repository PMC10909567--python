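"""End-to-end orchestration: simulate -> fit -> kernel -> metrics ->
jackknife -> thermal regimes -> comparative statistics.

A run is driven by a :class:`RunConfig` (constructible from YAML), executes
the stages in dependency order for every region x strategy assemblage, and
writes CSV outputs plus a manifest with the sha256 of every file and the
effective configuration, so that identical configs yield byte-identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparative, environment, resampling, synthetic, transient
from .data_io import read_fecundity, read_recruits, read_survey
from .kernel import build_kernel
from .vital_rates import fit_all

__all__ = ["RunConfig", "run_pipeline"]

TROPICAL = {"AT": "tropical", "JT": "tropical",
            "AS": "subtropical", "JS": "subtropical"}
COUNTRY = {"AT": "Australia", "AS": "Australia",
           "JT": "Japan", "JS": "Japan"}


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    regions: tuple = synthetic.PRESET_REGIONS
    strategies: tuple = synthetic.PRESET_STRATEGIES
    survey_path: str | None = None        # when set, data are read not simulated
    recruits_path: str | None = None
    fecundity_path: str | None = None
    n_colonies: int = 400
    n_years: int = 4
    mesh: int = 200
    growth_degree: int = 2
    frag_degree: int = 2
    jackknife_reps: int = 200
    jackknife_fraction: float = 0.95
    seed: int = 0
    sigma_on_fragmentation: bool = False
    deseasonalize: bool = False
    sst_months: int = 840
    output_dir: str = "pipeline_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        for key in ("regions", "strategies"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def validate(self) -> None:
        for p in (self.survey_path, self.recruits_path, self.fecundity_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if self.mesh < 10 or self.jackknife_reps < 1:
            raise ValueError("mesh must be >= 10 and jackknife_reps >= 1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    t0 = time.perf_counter()

    ss = np.random.SeedSequence(config.seed)
    n_cells = len(config.regions) * len(config.strategies)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(2 * n_cells + len(config.regions))]
    seed_iter = iter(child_seeds)

    use_files = config.survey_path is not None
    if use_files:
        all_obs = read_survey(config.survey_path)
        all_recruits = read_recruits(config.recruits_path)
        all_fec = read_fecundity(config.fecundity_path)
        log.append(f"loaded {len(all_obs)} survey rows from files")

    point_rows = []
    replicate_frames = []
    for region in config.regions:
        for strategy in config.strategies:
            if use_files:
                obs = [o for o in all_obs
                       if o.region == region and o.strategy == strategy]
                recruits = [r for r in all_recruits if r.region == region]
                fec = [f for f in all_fec if f.strategy == strategy]
            else:
                params = synthetic.preset_params(
                    region, strategy, n_colonies=config.n_colonies,
                    n_years=config.n_years, seed=next(seed_iter))
                obs, recruits = synthetic.simulate_survey(params)
                fec = synthetic.simulate_fecundity(params, 400)
            if not obs:
                raise RuntimeError(f"stage fit[{region},{strategy}]: no data")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rates = fit_all(obs, recruits, fec,
                                growth_degree=config.growth_degree,
                                frag_degree=config.frag_degree)
                kern = build_kernel(
                    rates, config.mesh,
                    sigma_on_fragmentation=config.sigma_on_fragmentation)
                dm = transient.compute_all(kern.P, kern.F)
                ens = resampling.jackknife(
                    obs, recruits, fec, reps=config.jackknife_reps,
                    fraction=config.jackknife_fraction,
                    seed=next(seed_iter), mesh=config.mesh,
                    sigma_on_fragmentation=config.sigma_on_fragmentation)
                summary = resampling.summarize(ens)
            point_rows.append({
                "region": region, "strategy": strategy,
                "country": COUNTRY[region], "ecoregion": TROPICAL[region],
                "lambda": dm.lam,
                "lambda_lo": summary.loc["lam", "ci_lo"],
                "lambda_hi": summary.loc["lam", "ci_hi"],
                "damping_ratio": dm.damping_ratio,
                "generation_time": dm.generation_time,
                "transient_envelope": dm.transient_envelope,
                "max_amplification": dm.max_amplification,
                "R0": dm.R0,
            })
            reps = resampling.filter_and_transform(ens)
            reps.insert(0, "strategy", strategy)
            reps.insert(0, "ecoregion", TROPICAL[region])
            reps.insert(0, "country", COUNTRY[region])
            reps.insert(0, "region", region)
            replicate_frames.append(reps)
            log.append(f"fit[{region},{strategy}]: n_rows={len(obs)} "
                       f"lambda={dm.lam:.4f} "
                       f"jackknife_failed={ens.n_failed}")

    points = pd.DataFrame(point_rows)
    ensembles = pd.concat(replicate_frames, ignore_index=True)

    # thermal regimes per region
    sst_rows = []
    for region in config.regions:
        sst = synthetic.simulate_sst(synthetic.preset_sst(
            region, n_months=config.sst_months, seed=next(seed_iter)))
        mean, cv = environment.sst_summary(sst)
        beta = environment.spectral_exponent(
            sst, deseasonalize=config.deseasonalize)
        sst_rows.append({"region": region, "sst_mean": mean, "sst_cv": cv,
                         "sst_beta": beta})
    sst_metrics = pd.DataFrame(sst_rows)

    # assemblage summaries and comparative layer
    summary = points.merge(sst_metrics, on="region")
    trans_means = ensembles.groupby(["region", "strategy"], observed=True)[
        ["rho_t", "TE_t", "DSI", "T_log"]].mean().reset_index()
    summary = summary.merge(trans_means, on=["region", "strategy"])
    X = summary[["sst_mean", "sst_cv", "sst_beta"]]
    Y = summary[["lambda", "rho_t", "TE_t"]].rename(
        columns={"lambda": "lam"})
    pls = comparative.plsr(X, Y, n_components=2)
    rma_lam = comparative.ranged_major_axis(summary["T_log"],
                                            summary["lambda"])
    rma_te = comparative.ranged_major_axis(summary["T_log"], summary["TE_t"])
    anova_lam = comparative.factorial_anova(
        ensembles.rename(columns={"lam": "value"}), value="value")
    anova_dsi = comparative.factorial_anova(
        ensembles.rename(columns={"DSI": "value"}), value="value")

    # outputs (no timestamps anywhere: reruns must be byte-identical)
    files = {
        "assemblage_metrics.csv": lambda p: summary.to_csv(p, index=False),
        "ensembles.csv": lambda p: ensembles.to_csv(p, index=False),
        "sst_metrics.csv": lambda p: sst_metrics.to_csv(p, index=False),
        "anova_lambda.csv": lambda p: anova_lam.table.to_csv(p),
        "anova_dsi.csv": lambda p: anova_dsi.table.to_csv(p),
        "tukey_lambda.csv": lambda p: anova_lam.ecoregion_contrasts.to_csv(
            p, index=False),
    }
    for name, writer in files.items():
        writer(out / name)
    plsr_report = {
        "x_variance": pls.x_variance.tolist(),
        "y_variance": pls.y_variance.tolist(),
        "ry2": pls.ry2,
        "condition_number": pls.condition_number,
        "x_weights": pls.x_weights.tolist(),
        "y_loadings": pls.y_loadings.tolist(),
        "rma_lambda_vs_logT": asdict(rma_lam),
        "rma_TE_vs_logT": asdict(rma_te),
    }
    with open(out / "plsr_report.json", "w", encoding="utf-8") as fh:
        json.dump(plsr_report, fh, indent=1)

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "files": {name: _sha256(out / name)
                  for name in sorted([*files, "plsr_report.json"])},
        "log": log,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    log.append(f"total wall time {time.perf_counter() - t0:.1f}s")
    return manifest
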