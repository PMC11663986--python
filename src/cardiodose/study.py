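"""End-to-end study orchestration.

Runs the whole design on one synthetic cohort: simulate → perturb contours
→ extract EQD2 dose features per variation → univariable confounder
screening → the 2 x 4 elastic-net / survival-forest model runs → consensus
→ final multivariable Cox → resampled dose threshold, and writes a
consolidated report.  The heavy simulate/feature stage is content-addressed
by a configuration hash so reruns (and the eight model runs, which share
it) skip completed work.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contours import MarginSpec, SegMetrics, margins_from_metrics, perturb_mask
from .dosimetry import (
    ALL_STRUCTURES,
    all3_alpha_beta,
    dose_metrics,
    standard_alpha_beta,
)
from .exceptions import ConfigurationError
from .io import config_hash, jsonable, write_json
from .models import (
    ModelRunConfig,
    bootstrap_elastic_net,
    confounder_design,
    consensus_selection,
    final_multivariable_cox,
    rsf_ensemble,
    screen_confounders,
)
from .synth import CohortSpec, cohort_to_frame, generate_cohort, generate_dose_grid, rasterize_masks
from .threshold import ThresholdResult, resampled_threshold, robustness_report

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "DEFAULT_MARGIN_STATS",
    "default_margins",
    "run_study",
    "compute_variant_features",
    "apply_missing_rule",
    "VARIANTS",
]

#: The four feature-table variations of the robustness design: three
#: contour variations under the standard α/β map, plus the all-3 Gy α/β
#: scenario on the original contours.
VARIANTS: tuple[tuple[str, str], ...] = (
    ("original", "standard"),
    ("expanded", "standard"),
    ("contracted", "standard"),
    ("original", "all3"),
)

#: Plausible auto-contouring agreement statistics (MSD mean, SD in mm) per
#: structure, in the range reported for deep-learning cardiac substructure
#: segmentation that passes the DSC>0.8 / MSD<2 mm inclusion rule.
DEFAULT_MARGIN_STATS: dict[str, tuple[float, float]] = {
    "LA": (1.2, 0.4), "LV": (1.2, 0.4), "RA": (1.3, 0.4), "RV": (1.3, 0.4),
    "aorta": (1.5, 0.5), "SVC": (1.5, 0.5), "IVC": (1.6, 0.5), "PA": (1.5, 0.5),
    "WH": (1.0, 0.35), "LL": (0.8, 0.3), "RL": (0.8, 0.3),
}


def default_margins(policy: str = "symmetric") -> dict[str, MarginSpec]:
    return {
        s: margins_from_metrics(SegMetrics(0.9, 3.0, msd, sd), s, policy=policy)
        for s, (msd, sd) in DEFAULT_MARGIN_STATS.items()
    }


@dataclass
class StudyConfig:
    """Configuration of a full study run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    margins: dict[str, MarginSpec] = field(default_factory=default_margins)
    model: ModelRunConfig = field(default_factory=ModelRunConfig)
    threshold_reps: int = 100
    threshold_frac: float = 2.0 / 3.0
    consensus_tolerance_pct: float = 5.0
    missing_threshold: float = 0.05
    out_dir: str = "study_out"
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        missing = [s for s in ALL_STRUCTURES if s not in self.margins]
        if missing:
            raise ConfigurationError(
                f"margins missing for structures: {', '.join(missing)}")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        cfg = cls()
        if "seed" in d:
            cfg.seed = int(d["seed"])
        if "out_dir" in d:
            cfg.out_dir = str(d["out_dir"])
        for key in ("threshold_reps", "threshold_frac",
                    "consensus_tolerance_pct", "missing_threshold"):
            if key in d:
                setattr(cfg, key, type(getattr(cfg, key))(d[key]))
        co = d.get("cohort", {})
        cohort_kwargs = {}
        for key in ("n_patients", "seed", "dose_falloff_mm"):
            if key in co:
                cohort_kwargs[key] = co[key]
        for key in ("grid_shape", "spacing"):
            if key in co:
                cohort_kwargs[key] = tuple(co[key])
        cfg.cohort = replace(cfg.cohort, **cohort_kwargs)
        if "seed" in d and "seed" not in co:
            cfg.cohort = replace(cfg.cohort, seed=cfg.seed)
        mg = d.get("margins", {})
        policy = mg.get("policy", "symmetric")
        cfg.margins = default_margins(policy)
        for s, stats in mg.items():
            if s == "policy":
                continue
            cfg.margins[s] = margins_from_metrics(
                SegMetrics(0.9, 3.0, float(stats["msd_mm"]),
                           float(stats.get("sd_mm", 0.0))), s, policy=policy)
        mo = d.get("model", {})
        model_kwargs = {k: mo[k] for k in (
            "n_boot", "n_forests", "n_trees", "cv_folds", "n_penalties",
            "importance_threshold", "magnitude_floor", "min_node_size",
        ) if k in mo}
        if "alpha_grid" in mo:
            model_kwargs["alpha_grid"] = tuple(float(a) for a in mo["alpha_grid"])
        cfg.model = replace(cfg.model, seed=cfg.seed, **model_kwargs)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def apply_missing_rule(features: pd.DataFrame, threshold: float = 0.05):
    """Missing-data rule for dose features.

    A feature column with more than ``threshold`` missing values (e.g. a
    small structure emptied by contraction) is dropped from the run;
    otherwise the affected patients are dropped.  Returns the cleaned
    table plus the dropped columns and patient ids.
    """
    frac = features.isna().mean()
    drop_cols = list(frac.index[frac > threshold])
    out = features.drop(columns=drop_cols)
    drop_rows = list(out.index[out.isna().any(axis=1)])
    out = out.drop(index=drop_rows)
    if drop_cols:
        logger.warning("missing-data rule dropped columns: %s", drop_cols)
    if drop_rows:
        logger.warning("missing-data rule dropped %d patients", len(drop_rows))
    return out, drop_cols, drop_rows


def compute_variant_features(records, geometries, margins, falloff_mm: float):
    """Per-patient dose features for all four model variations.

    Streams one patient at a time (masks are rasterized, perturbed, used
    and discarded) and returns ``{(variation, scenario): DataFrame}``.
    """
    ab_maps = {"standard": standard_alpha_beta(), "all3": all3_alpha_beta()}
    tables: dict[tuple[str, str], list[dict]] = {v: [] for v in VARIANTS}
    for rec, geom in zip(records, geometries):
        masks = rasterize_masks(geom, structures=list(ALL_STRUCTURES) + ["PTV"])
        rx = rec.n_fractions * rec.dose_per_fraction
        dose = generate_dose_grid(geom, rx, falloff_mm, rec.n_fractions,
                                  ptv_mask=masks["PTV"])
        variant_masks = {"original": {s: masks[s] for s in ALL_STRUCTURES}}
        variant_masks["expanded"] = {
            s: perturb_mask(masks[s], margins[s].expand_margin_mm)
            for s in ALL_STRUCTURES}
        variant_masks["contracted"] = {
            s: perturb_mask(masks[s], -margins[s].contract_margin_mm)
            for s in ALL_STRUCTURES}
        for variation, scenario in VARIANTS:
            ab = ab_maps[scenario]
            row: dict[str, object] = {"id": rec.id}
            for s in ALL_STRUCTURES:
                dm = dose_metrics(dose, variant_masks[variation][s], ab[s],
                                  variation=variation, alpha_beta_scenario=scenario)
                row[f"{s}_mean_eqd2"] = dm.d_mean
                row[f"{s}_max_eqd2"] = dm.d_0p1cc
            tables[(variation, scenario)].append(row)
    return {v: pd.DataFrame(rows).set_index("id") for v, rows in tables.items()}


def _run_seed(master: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(0xD0, index))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_study(config: StudyConfig) -> dict:
    """Execute the full study and write every stage's outputs to disk.

    Returns the consolidated report dictionary (also written as JSON, CSV
    and a markdown summary under ``config.out_dir``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    # per-stage wall time goes to the log only, so report files are
    # byte-identical across reruns with the same config and seed
    def stage(name):
        logger.info("stage %s", name)
        return time.time()

    def stage_done(name, t0):
        logger.info("stage %s finished in %.2f s", name, time.time() - t0)

    # -- simulate + features (content-addressed cache) ----------------------
    sim_key = config_hash({
        "cohort": config.cohort, "margins": config.margins,
    })
    cache = out / f"simulate_{sim_key}"
    t0 = stage("simulate")
    feature_paths = {v: cache / f"features_{v[0]}_{v[1]}.csv" for v in VARIANTS}
    cohort_path = cache / "cohort.csv"
    if cohort_path.exists() and all(p.exists() for p in feature_paths.values()):
        cohort = pd.read_csv(cohort_path, index_col="id")
        variant_features = {v: pd.read_csv(p, index_col="id")
                            for v, p in feature_paths.items()}
    else:
        try:
            cache.mkdir(exist_ok=True)
            records, geometries = generate_cohort(config.cohort)
            cohort = cohort_to_frame(records)
            variant_features = compute_variant_features(
                records, geometries, config.margins, config.cohort.dose_falloff_mm)
            cohort.to_csv(cohort_path)
            for v, p in feature_paths.items():
                variant_features[v].to_csv(p)
        except Exception as exc:
            raise RuntimeError(f"stage simulate failed: {exc}") from exc
    times = cohort["survival_days"].to_numpy(float)
    events = cohort["event"].to_numpy(int)
    stage_done("simulate", t0)

    # -- univariable confounder screening -----------------------------------
    t0 = stage("uva")
    try:
        design, groups = confounder_design(cohort)
        retained = screen_confounders(design, groups, times, events)
        confounder_cols = [c for g in retained for c in groups[g]]
        write_json({"retained": retained, "columns": confounder_cols},
                   out / "uva.json")
    except Exception as exc:
        raise RuntimeError(f"stage uva failed: {exc}") from exc
    report["uva_retained"] = retained
    stage_done("uva", t0)

    # -- the 2 x 4 model runs ------------------------------------------------
    t0 = stage("model_runs")
    runs_dir = out / "runs"
    runs_dir.mkdir(exist_ok=True)
    en_summaries, rsf_summaries = [], []
    run_index = 0
    run_records = []
    try:
        for variation, scenario in VARIANTS:
            feats_raw = variant_features[(variation, scenario)]
            feats, drop_cols, drop_rows = apply_missing_rule(
                feats_raw, config.missing_threshold)
            keep = feats.index
            t_run = times[cohort.index.get_indexer(keep)]
            e_run = events[cohort.index.get_indexer(keep)]
            for covset in ("dose_only", "complete"):
                X = feats
                if covset == "complete":
                    X = feats.join(design.loc[keep, confounder_cols])
                run_cfg = replace(
                    config.model, variation=variation,
                    alpha_beta_scenario=scenario, covariate_set=covset,
                    seed=_run_seed(config.seed, run_index))
                en = bootstrap_elastic_net(X, t_run, e_run, run_cfg)
                rsf = rsf_ensemble(X, t_run, e_run, run_cfg)
                en_summaries.append(en)
                rsf_summaries.append(rsf)
                label = f"{variation}_{scenario}_{covset}"
                en.selection_pct.rename("selection_pct").to_csv(
                    runs_dir / f"en_{label}.csv")
                rsf.median_importance.rename("median_vimp").to_csv(
                    runs_dir / f"rsf_{label}.csv")
                run_records.append({
                    "label": label, "mean_tuned_alpha": en.mean_tuned_alpha,
                    "dropped_columns": drop_cols, "dropped_patients": len(drop_rows),
                    "seed": run_cfg.seed,
                })
                run_index += 1
    except Exception as exc:
        raise RuntimeError(f"stage model_runs failed: {exc}") from exc
    report["model_runs"] = run_records
    stage_done("model_runs", t0)

    # -- consensus -----------------------------------------------------------
    t0 = stage("consensus")
    consensus = consensus_selection(
        en_summaries, rsf_summaries,
        top_tolerance_pct=config.consensus_tolerance_pct)
    write_json({"consensus": consensus}, out / "consensus.json")
    report["consensus"] = consensus
    stage_done("consensus", t0)

    # -- final Cox + threshold per variation ---------------------------------
    final_cox: dict[str, list] = {}
    thresholds: list[ThresholdResult] = []
    if consensus:
        driver = consensus[0]
        t0 = stage("final_cox")
        try:
            for variation, scenario in VARIANTS:
                feats = variant_features[(variation, scenario)]
                ok = feats[driver].notna()
                data = feats.loc[ok, [driver]].join(
                    design.loc[ok[ok].index, confounder_cols])
                res = final_multivariable_cox(
                    data, driver, confounder_cols,
                    times[cohort.index.get_indexer(data.index)],
                    events[cohort.index.get_indexer(data.index)])
                final_cox[f"{variation}_{scenario}"] = [jsonable(r) for r in res]
        except Exception as exc:
            raise RuntimeError(f"stage final_cox failed: {exc}") from exc
        write_json(final_cox, out / "final_cox.json")
        stage_done("final_cox", t0)

        t0 = stage("threshold")
        try:
            for i, (variation, scenario) in enumerate(VARIANTS):
                feats = variant_features[(variation, scenario)]
                x = feats[driver].dropna()
                res = resampled_threshold(
                    x.to_numpy(float),
                    times[cohort.index.get_indexer(x.index)],
                    events[cohort.index.get_indexer(x.index)],
                    n_reps=config.threshold_reps, frac=config.threshold_frac,
                    seed=_run_seed(config.seed, 100 + i),
                    feature_name=driver, variation=variation,
                    alpha_beta_scenario=scenario)
                thresholds.append(res)
            rob = robustness_report(thresholds)
            rob.to_csv(out / "thresholds.csv", index=False)
            report["thresholds"] = jsonable(rob.to_dict(orient="records"))
            report["threshold_spread_flag"] = bool(rob.attrs["spread_flag"])
        except Exception as exc:
            raise RuntimeError(f"stage threshold failed: {exc}") from exc
        stage_done("threshold", t0)
    report["final_cox"] = final_cox

    # -- consolidated report --------------------------------------------------
    t0 = stage("report")
    table = _consolidated_table(en_summaries, rsf_summaries, config)
    table.to_csv(out / "report.csv")
    write_json(report, out / "report.json")
    (out / "report.md").write_text(_markdown_summary(report, table))
    stage_done("report", t0)
    return report


def _consolidated_table(en_summaries, rsf_summaries, config) -> pd.DataFrame:
    """Model-variation table: approach x covariate-set rows, variation columns."""
    cols = [f"{v}/{s}" for v, s in VARIANTS]
    rows = {}
    for approach, summaries in (("EN", en_summaries), ("RSF", rsf_summaries)):
        for covset in ("dose_only", "complete"):
            label = f"{approach} ({covset})"
            cells = {}
            for s in summaries:
                if s.config.covariate_set != covset:
                    continue
                key = f"{s.config.variation}/{s.config.alpha_beta_scenario}"
                if approach == "EN":
                    pct = s.selection_pct
                    dose = pct[[c for c in pct.index if c.endswith("_eqd2")]]
                    top = dose.idxmax()
                    cells[key] = f"{top} ({dose[top]:.0f}%)"
                else:
                    imp = s.median_importance
                    flagged = imp[s.important]
                    flagged = flagged[[c for c in flagged.index
                                       if c.endswith("_eqd2")]]
                    cells[key] = ", ".join(
                        f"{k} ({v:.3f})" for k, v in
                        flagged.sort_values(ascending=False).items()) or "none"
            rows[label] = [cells.get(c, "") for c in cols]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _markdown_summary(report: dict, table: pd.DataFrame) -> str:
    lines = ["# Study report", ""]
    lines.append(f"Seed: {report['seed']}")
    lines.append(f"Retained confounders: {', '.join(report['uva_retained']) or 'none'}")
    lines.append(f"Consensus dose features: {', '.join(report['consensus']) or 'none'}")
    lines.append("")
    lines.append(table.to_markdown())
    if "thresholds" in report:
        lines.append("")
        lines.append("## Dose thresholds (median optimal split, Gy EQD2)")
        for row in report["thresholds"]:
            lines.append(
                f"- {row['variation']}/{row['alpha_beta_scenario']}: "
                f"{row['median_cutpoint']:.2f} Gy; KM median below/above = "
                f"{row['km_median_below_months']:.1f} / "
                f"{row['km_median_above_months']:.1f} months")
    lines.append("")
    return "\n".join(lines)
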