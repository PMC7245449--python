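"""End-to-end orchestration: z-scores -> survey estimates -> count panels ->
Moran screen -> space-time model fits -> WHO-2025 target reports.

Every stage reads and writes files only, so the pipeline is resumable and a
rerun with the same seeds is byte-identical.  A run manifest records seeds,
iteration counts, acceptance rates and convergence verdicts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anthropometry import (
    ReferenceTable, classify, compute_zscores, flag_implausible,
    read_child_records, records_to_frame,
)
from .model import CountPanel, McmcConfig, SpaceTimeCARModel, build_count_panel
from .spatial import (
    UndefinedStatisticError, bivariate_morans_i, morans_i, permutation_pvalue,
    read_edge_list,
)
from .survey import SurveyDesign, rao_scott_chi2, weighted_prevalence, weighted_total
from .targets import assess_all_districts, required_interim_fraction

log = logging.getLogger("malnutmap")

OUTCOMES = ("stunting", "thinness_wasting", "obesity")

#: Wave-to-year mapping of the panel survey.
DEFAULT_WAVE_YEARS = {1: 2008, 2: 2010, 3: 2012, 4: 2014, 5: 2017}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    records_path: str = "records.csv"
    reference_path: str = "reference.csv"
    edges_path: str = "edges.csv"
    outdir: str = "output"
    n_districts: int = 52
    n_waves: int = 5
    haz_limit: float = 6.0
    weight_limit: float = 5.0
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    baseline_wave: int = 3
    interim_wave: int = 5
    fraction_rule: str = "paper_constant"
    wasting_threshold: float = 0.05
    moran_n_perm: int = 999
    holdout_fraction: float = 0.1
    alt_hypers: list = field(default_factory=lambda: [[1.0, 0.01]])
    seed: int = 0
    wave_years: dict = field(default_factory=lambda: dict(DEFAULT_WAVE_YEARS))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mcmc = McmcConfig(**raw.pop("mcmc", {}))
        return cls(mcmc=mcmc, **raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def out(self, name: str) -> Path:
        p = Path(self.outdir)
        p.mkdir(parents=True, exist_ok=True)
        return p / name


def _full_precision(df: pd.DataFrame, round_cols: dict) -> pd.DataFrame:
    """Add rounded presentation columns next to the full-precision values."""
    out = df.copy()
    for col, nd in round_cols.items():
        if col in out:
            out[f"{col}_rounded"] = out[col].round(nd)
    return out


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_zscore(cfg: PipelineConfig) -> Path:
    """Per-record z-scores and malnutrition flags -> zscores.csv."""
    records = read_child_records(cfg.records_path)
    table = ReferenceTable.from_csv(cfg.reference_path)
    frame = records_to_frame(records)
    rows = []
    for rec in records:
        z = flag_implausible(
            compute_zscores(rec, table), cfg.haz_limit, cfg.weight_limit
        )
        status = classify(z, rec.age_months)
        rows.append(
            {
                "haz": z.haz,
                "weight_based_z": z.weight_based_z,
                "indicator_used": z.indicator_used,
                "haz_valid": z.haz_valid,
                "weight_z_valid": z.weight_z_valid,
                "stunting": float(status.stunted) if z.haz_valid else np.nan,
                "thinness_wasting": float(status.thin_wasted) if z.weight_z_valid else np.nan,
                "obesity": float(status.obese) if z.weight_z_valid else np.nan,
            }
        )
    out = pd.concat([frame, pd.DataFrame(rows)], axis=1)
    path = cfg.out("zscores.csv")
    out.to_csv(path, index=False)
    log.info("zscore stage: %d records, %d valid haz", len(out), out["haz_valid"].sum())
    return path


def stage_prevalence(cfg: PipelineConfig) -> list[Path]:
    """Survey-weighted national estimates, association tests and per-outcome
    district x wave count panels, from zscores.csv."""
    df = pd.read_csv(cfg.out("zscores.csv"))
    design = SurveyDesign.from_frame(df)
    paths = []

    nat_rows = []
    for outcome in OUTCOMES:
        for wave in sorted(df["wave"].unique()):
            dom = (df["wave"] == wave).to_numpy()
            try:
                est = weighted_prevalence(
                    df[outcome], design, domain=dom, label=f"{outcome}|wave{wave}"
                )
            except Exception:
                continue
            nat_rows.append(
                {
                    "outcome": outcome, "wave": wave,
                    "year": cfg.wave_years.get(int(wave), wave),
                    "estimate": est.p_hat, "se": est.se,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "n": est.n_valid,
                    "weighted_total": weighted_total(df[outcome], design, domain=dom),
                }
            )
    nat = _full_precision(pd.DataFrame(nat_rows), {"estimate": 3, "ci_low": 3, "ci_high": 3})
    p = cfg.out("prevalence_national.csv")
    nat.to_csv(p, index=False)
    paths.append(p)

    # bivariate association screen at the last wave (Table-3 layout)
    last = df[df["wave"] == df["wave"].max()]
    last_design = SurveyDesign.from_frame(last)
    core = {
        "child_id", "wave", "district_id", "age_months", "weight_kg", "height_cm",
        "design_weight", "stratum_id", "psu_id", "haz", "weight_based_z",
        "indicator_used", "haz_valid", "weight_z_valid", *OUTCOMES,
    }
    covariates = [c for c in df.columns if c not in core]
    assoc_rows = []
    for outcome in OUTCOMES:
        ok = last[outcome].notna()
        for cov in covariates:
            sub = last[ok]
            sub_design = SurveyDesign(
                sub["stratum_id"].to_numpy(), sub["psu_id"].to_numpy(),
                sub["design_weight"].to_numpy(),
            )
            try:
                rs = rao_scott_chi2(
                    sub[cov].fillna("Missing"), sub[outcome] > 0.5, sub_design
                )
            except Exception:
                continue
            assoc_rows.append(
                {
                    "outcome": outcome, "covariate": cov,
                    "pearson_chi2": rs.pearson_chi2, "F_statistic": rs.statistic,
                    "df1": rs.df[0], "df2": rs.df[1], "p_value": rs.p_value,
                }
            )
    p = cfg.out("associations.csv")
    pd.DataFrame(assoc_rows).to_csv(p, index=False)
    paths.append(p)

    # per-cell weighted prevalence -> integer binomial count panels
    for outcome in OUTCOMES:
        prev = np.zeros((cfg.n_districts, cfg.n_waves))
        sizes = np.zeros((cfg.n_districts, cfg.n_waves))
        grp = df[df[outcome].notna()].groupby(["district_id", "wave"])
        for (d, w), cell in grp:
            d, w = int(d), int(w)
            if not (1 <= d <= cfg.n_districts and 1 <= w <= cfg.n_waves):
                continue
            wsum = cell["design_weight"].sum()
            prev[d - 1, w - 1] = (cell["design_weight"] * cell[outcome]).sum() / wsum
            sizes[d - 1, w - 1] = len(cell)
        panel = build_count_panel(prev, sizes, outcome=outcome)
        p = cfg.out(f"panel_{outcome}.csv")
        panel.to_csv(p)
        paths.append(p)
    return paths


def stage_moran(cfg: PipelineConfig) -> Path:
    """Univariate and bivariate Moran's I on last-wave crude district
    prevalences, with permutation pseudo p-values."""
    graph = read_edge_list(cfg.edges_path, cfg.n_districts)
    values = {}
    for outcome in OUTCOMES:
        panel = CountPanel.from_csv(cfg.out(f"panel_{outcome}.csv"), outcome)
        with np.errstate(invalid="ignore"):
            crude = np.where(panel.n[:, -1] > 0, panel.Y[:, -1] / np.maximum(panel.n[:, -1], 1), np.nan)
        overall = np.nanmean(crude)
        values[outcome] = np.where(np.isnan(crude), overall, crude)
    rows = []
    for outcome, v in values.items():
        try:
            obs, pval = permutation_pvalue(
                morans_i, v, graph, n_perm=cfg.moran_n_perm, seed=cfg.seed
            )
            rows.append({"test": f"moran_{outcome}", "I": obs, "pseudo_p": pval})
        except UndefinedStatisticError:
            rows.append({"test": f"moran_{outcome}", "I": np.nan, "pseudo_p": np.nan})
    names = list(values)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            try:
                i_ab = bivariate_morans_i(values[names[a]], values[names[b]], graph)
            except UndefinedStatisticError:
                i_ab = np.nan
            rows.append(
                {"test": f"bivariate_{names[a]}_{names[b]}", "I": i_ab, "pseudo_p": np.nan}
            )
    p = cfg.out("moran.csv")
    pd.DataFrame(rows).to_csv(p, index=False)
    return p


def stage_fit(cfg: PipelineConfig) -> dict:
    """Fit the three independent space-time models; write posterior
    summaries, diagnostics and the pooled prevalence draws."""
    graph = read_edge_list(cfg.edges_path, cfg.n_districts)
    info = {}
    for k, outcome in enumerate(OUTCOMES):
        panel = CountPanel.from_csv(cfg.out(f"panel_{outcome}.csv"), outcome)
        mc = dataclasses.replace(cfg.mcmc, seed=cfg.mcmc.seed + 1000 * k)
        res = SpaceTimeCARModel(panel, graph).fit(mc)
        summ = _full_precision(res.summary_frame(), {"median": 3})
        summ.to_csv(cfg.out(f"posterior_{outcome}.csv"), index=False)
        res.diagnostics.to_csv(cfg.out(f"diagnostics_{outcome}.csv"), index=False)
        np.save(cfg.out(f"draws_{outcome}.npy"), res.pi_draws)
        d, pD = res.dic()
        info[outcome] = {
            "converged": bool(res.converged),
            "seed": int(mc.seed),
            "kept_draws_per_chain": int(res.n_kept_per_chain),
            "acceptance_rates": {k2: round(v, 4) for k2, v in res.acceptance_rates.items()},
            "dic": round(d, 2),
            "pD": round(pD, 2),
        }
        log.info("fit %s: converged=%s dic=%.1f", outcome, res.converged, d)
    return info


def stage_targets(cfg: PipelineConfig) -> Path:
    """WHO-2025 target assessment per district plus national roll-ups."""
    frames = []
    summary_rows = []
    fraction = required_interim_fraction(
        baseline_year=cfg.wave_years.get(cfg.baseline_wave, 2012),
        target_year=2025,
        interim_year=cfg.wave_years.get(cfg.interim_wave, 2017),
        rule=cfg.fraction_rule,
    )
    for outcome in OUTCOMES:
        draws_path = cfg.out(f"draws_{outcome}.npy")
        if not draws_path.exists():
            raise FileNotFoundError(
                f"no fitted draws for {outcome!r}; run the fit stage first"
            )
        draws = np.load(draws_path)
        ta = assess_all_districts(
            draws, outcome,
            baseline_wave=cfg.baseline_wave, interim_wave=cfg.interim_wave,
            fraction=fraction, wasting_threshold=cfg.wasting_threshold,
        )
        per = ta.per_district.copy()
        per.insert(0, "outcome", outcome)
        frames.append(per)
        summary_rows.append(
            {
                "outcome": outcome, "count_met": ta.count_met,
                "percent_met": ta.percent_met,
                "count_significant": ta.count_significant,
            }
        )
    p = cfg.out("targets.csv")
    pd.concat(frames, ignore_index=True).to_csv(p, index=False)
    pd.DataFrame(summary_rows).to_csv(cfg.out("targets_summary.csv"), index=False)
    return p


def stage_validate(cfg: PipelineConfig) -> list[Path]:
    """Holdout validation and prior-sensitivity refits for each outcome."""
    from .model import holdout_validation, prior_sensitivity

    graph = read_edge_list(cfg.edges_path, cfg.n_districts)
    paths = []
    hold_rows, sens_frames = [], []
    for k, outcome in enumerate(OUTCOMES):
        panel = CountPanel.from_csv(cfg.out(f"panel_{outcome}.csv"), outcome)
        mc = dataclasses.replace(cfg.mcmc, seed=cfg.mcmc.seed + 2000 * k)
        hv = holdout_validation(
            panel, graph, mc, fraction=cfg.holdout_fraction, seed=cfg.seed + k
        )
        hold_rows.append(
            {"outcome": outcome, "rmse": hv.rmse, "correlation": hv.correlation,
             "coverage": hv.coverage, "n_cells": len(hv.table)}
        )
        sens = prior_sensitivity(
            panel, graph, mc, [tuple(h) for h in cfg.alt_hypers]
        )
        sens.insert(0, "outcome", outcome)
        sens_frames.append(sens)
    p1 = cfg.out("validation.csv")
    pd.DataFrame(hold_rows).to_csv(p1, index=False)
    p2 = cfg.out("sensitivity.csv")
    pd.concat(sens_frames, ignore_index=True).to_csv(p2, index=False)
    paths += [p1, p2]
    return paths


def run_pipeline(cfg: PipelineConfig, validate: bool = False) -> dict:
    """Run all stages in order; abort with the failing stage's name, leaving
    partial outputs plus a FAILED marker."""
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "mcmc_seed": cfg.mcmc.seed,
        "stages": [],
    }
    stages = [
        ("zscore", stage_zscore),
        ("prevalence", stage_prevalence),
        ("moran", stage_moran),
        ("fit", stage_fit),
        ("targets", stage_targets),
    ]
    if validate:
        stages.append(("validate", stage_validate))
    for name, fn in stages:
        try:
            out = fn(cfg)
        except Exception as exc:
            (Path(cfg.outdir) / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise PipelineError(name, exc) from exc
        manifest["stages"].append(name)
        if name == "fit":
            manifest["fit"] = out
    manifest["converged"] = all(v["converged"] for v in manifest.get("fit", {}).values())
    with open(cfg.out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
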