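"""End-to-end orchestration: simulate/read -> score -> align -> model.

Reproduces the study workflow on synthetic or user data: vulnerability
scoring and quartile grouping, GPA with sliding semi-landmarks,
allometry, the sequential Procrustes MANCOVA, size-adjusted LDA,
morphological disparity, deformation figures and condition models.  All
tables, figures, a machine-readable summary and the echoed config land
in the output directory; outputs are a pure function of (config, input
files).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import condition as cond
from . import deformation as deform
from . import scoring, shape_stats, synthetic, tps_io
from .procrustes import gpa_align

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-loadable)."""

    seed: int
    out_dir: str = "gearmorph_out"
    # either simulate (SynthParams overrides, per gear) or explicit inputs
    simulate: dict | None = None
    inputs: dict | None = None  # keys: tps, sliders, covariates, trials
    gears: list[str] = field(default_factory=lambda: ["trawl", "trap"])
    fraction: float = 0.25
    stratify_by_tank: bool = True
    slide_method: str = "bending_energy"
    gpa_tol: float = 1e-10
    terms: list[str] | None = None
    n_perm: int = 10_000
    lda_train_frac: float = 0.7
    heatmap_magnification: float = 4.0
    grid_magnification: float = 7.0
    figure_format: str = "svg"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set a seed before any computation")
        if self.simulate is None and self.inputs is None:
            self.simulate = {}
        if self.simulate is not None and self.inputs is not None:
            raise ValueError("config sets both simulate and inputs; pick one")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError(f"{path}: config must set a seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _provenance_header(config: RunConfig) -> str:
    return f"# gearmorph config={config.digest()} seed={config.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        df.to_csv(fh, index=index)


def _load_or_simulate(config: RunConfig):
    """Return per-gear dict of (cohort-like inputs, trials table)."""
    out = {}
    if config.simulate is not None:
        for i, gear in enumerate(config.gears):
            params = synthetic.SynthParams(
                seed=(config.seed * 1009 + 13 * i) % (2**31 - 1),
                gear=gear,
                **{k: v for k, v in config.simulate.items() if k not in ("seed", "gear")},
            )
            cohort = synthetic.simulate_cohort(params)
            trials = (
                synthetic.simulate_trawl_trials(cohort)
                if gear == "trawl"
                else synthetic.simulate_trap_trials(cohort)
            )
            out[gear] = (cohort.landmarks, cohort.sliders, cohort.covariates, trials)
    else:
        inp = config.inputs
        template = synthetic.make_template()
        landmarks = tps_io.read_tps(
            inp["tps"],
            landmark_roles=list(template.landmark_roles)
            if "sliders" in inp
            else None,
        )
        sliders = tps_io.read_sliders(inp["sliders"]) if "sliders" in inp else None
        covariates = tps_io.read_covariates(inp["covariates"])
        trials = tps_io.read_trials(inp["trials"])
        for gear in config.gears:
            ids = [
                r.id
                for r in covariates.frame.itertuples()
                if r.gear == gear and r.id in set(landmarks.ids)
            ]
            keep = [c for c in landmarks.configurations if c.specimen_id in set(ids)]
            if not keep:
                continue
            sub = tps_io.LandmarkDataset(
                configurations=keep,
                landmark_roles=landmarks.landmark_roles,
                curve_memberships=landmarks.curve_memberships,
            )
            out[gear] = (
                sub,
                sliders,
                covariates.subset([c.specimen_id for c in keep]),
                trials[trials["gear"] == gear],
            )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also written
    to ``<out_dir>/summary.json``)."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)

    summary: dict = {"seed": config.seed, "config_digest": config.digest(), "gears": {}}
    stage = "load"
    try:
        per_gear = _load_or_simulate(config)

        # --- scoring and quartile groups, per gear -----------------------
        stage = "score"
        scored_frames = []
        groups_by_fish: dict[str, str] = {}
        for gear, (landmarks, sliders, covariates, trials) in per_gear.items():
            indices = scoring.score_trials_table(trials)
            strat = (
                dict(zip(covariates.frame["id"], covariates.frame["tank"]))
                if (config.stratify_by_tank and gear == "trawl")
                else None
            )
            indices = scoring.assign_vulnerability_groups(
                indices, fraction=config.fraction, stratify_by=strat, seed=config.seed
            )
            frame = pd.DataFrame(
                {
                    "fish_id": [i.fish_id for i in indices],
                    "gear": gear,
                    "score": [i.score for i in indices],
                    "group": [i.group for i in indices],
                }
            )
            scored_frames.append(frame)
            groups_by_fish.update({i.fish_id: i.group for i in indices})
        scores = pd.concat(scored_frames, ignore_index=True)
        _write_csv(scores, out_dir / "scores.csv", config)

        # --- combined high/low dataset for the global model ---------------
        stage = "align"
        configs, cov_rows, slider_table = [], [], None
        for gear, (landmarks, sliders, covariates, _) in per_gear.items():
            slider_table = sliders if sliders is not None else slider_table
            chosen = {
                f: g for f, g in groups_by_fish.items() if g in ("high", "low")
            }
            for c in landmarks.configurations:
                if chosen.get(c.specimen_id) in ("high", "low"):
                    uid = f"{gear}:{c.specimen_id}"
                    configs.append(
                        tps_io.LandmarkConfiguration(
                            points=c.points, specimen_id=uid, image_ref=c.image_ref
                        )
                    )
                    row = (
                        covariates.frame.set_index("id")
                        .loc[c.specimen_id]
                        .to_dict()
                    )
                    row["id"] = uid
                    row["vulnerability"] = chosen[c.specimen_id]
                    cov_rows.append(row)
        ref = next(iter(per_gear.values()))[0]
        dataset = tps_io.LandmarkDataset(
            configurations=configs,
            landmark_roles=ref.landmark_roles,
            curve_memberships=ref.curve_memberships,
        )
        cov_df = pd.DataFrame(cov_rows)
        aligned = gpa_align(
            dataset,
            sliders=slider_table,
            slide_method=config.slide_method,
            tol=config.gpa_tol,
        )
        coords = aligned.shape_coordinates
        flat = pd.DataFrame(
            {
                "fish_id": np.repeat(aligned.ids, aligned.k),
                "landmark_index": np.tile(np.arange(1, aligned.k + 1), aligned.n),
                "x": coords[:, :, 0].ravel(),
                "y": coords[:, :, 1].ravel(),
            }
        )
        _write_csv(flat, out_dir / "aligned_coordinates.csv", config)
        _write_csv(
            pd.DataFrame(
                {"fish_id": aligned.ids, "centroid_size": aligned.centroid_sizes}
            ),
            out_dir / "centroid_sizes.csv",
            config,
        )

        # --- allometry and MANCOVA ----------------------------------------
        stage = "anova"
        allom = shape_stats.fit_allometry(
            aligned, n_perm=config.n_perm, seed=config.seed
        )
        _write_csv(allom.table, out_dir / "allometry.csv", config)
        terms = config.terms
        if terms is None:
            terms = ["centroid_size", "vulnerability", "sex"]
            if cov_df["gear"].nunique() > 1:
                terms.append("gear")
            terms.append("vulnerability:sex")
            if cov_df["gear"].nunique() > 1:
                terms.append("vulnerability:gear")
        spec = shape_stats.ModelSpec(terms=terms, n_perm=config.n_perm, seed=config.seed)
        anova = shape_stats.procrustes_anova(aligned, cov_df, spec)
        _write_csv(anova.table, out_dir / "procrustes_anova.csv", config)
        summary["anova"] = anova.table.to_dict(orient="records")

        # --- LDA per gear --------------------------------------------------
        stage = "lda"
        residuals = shape_stats.size_adjust_shapes(aligned, cov_df, per_gear=True)
        lda_reports = {}
        for gear in cov_df["gear"].unique():
            ids = cov_df.loc[cov_df["gear"] == gear, "id"]
            labels = cov_df.set_index("id").loc[ids, "vulnerability"]
            res = shape_stats.lda_classify(
                residuals.loc[ids],
                labels,
                train_frac=config.lda_train_frac,
                seed=config.seed,
            )
            lda_reports[gear] = {
                "accuracy": res.accuracy,
                "class_accuracy": res.class_accuracy,
                "n_dimensions": res.n_dimensions,
                "confusion": res.confusion.to_dict(),
                "train_ids": res.train_ids,
                "test_ids": res.test_ids,
            }
        with open(out_dir / "lda_report.json", "w") as fh:
            json.dump(lda_reports, fh, indent=1)
        summary["lda"] = {g: r["accuracy"] for g, r in lda_reports.items()}

        # --- disparity ------------------------------------------------------
        stage = "disparity"
        disp_groups = (
            cov_df.set_index("id")
            .loc[aligned.ids]
            .apply(lambda r: f"{r['gear']}_{r['vulnerability']}_{r['sex']}", axis=1)
        )
        disp = shape_stats.morphological_disparity(
            aligned, disp_groups, n_perm=config.n_perm, seed=config.seed
        )
        _write_csv(disp.variances.to_frame(), out_dir / "disparity.csv", config, index=True)
        _write_csv(disp.differences, out_dir / "disparity_differences.csv", config, index=True)
        _write_csv(disp.p_values, out_dir / "disparity_pvalues.csv", config, index=True)
        summary["disparity"] = disp.variances.to_dict()

        # --- deformation figures -------------------------------------------
        stage = "deform"
        cov_idx = cov_df.set_index("id")
        figures = []
        for gear in cov_df["gear"].unique():
            for sex in cov_df["sex"].unique():
                def pick(fid, grp, gear=gear, sex=sex):
                    row = cov_idx.loc[fid]
                    return (
                        row["gear"] == gear
                        and row["sex"] == sex
                        and row["vulnerability"] == grp
                    )

                try:
                    low = deform.mean_shape(aligned, lambda i: pick(i, "low"))
                    high = deform.mean_shape(aligned, lambda i: pick(i, "high"))
                except ValueError:
                    continue
                warp = deform.tps_warp(low, high, config.heatmap_magnification)
                path = out_dir / f"deformation_{gear}_{sex}.{config.figure_format}"
                deform.render_deformation(
                    warp, path, style="heatmap", title=f"{gear} {sex}: low -> high"
                )
                figures.append(path.name)
                warp7 = deform.tps_warp(low, high, config.grid_magnification)
                gpath = out_dir / f"grid_{gear}_{sex}.{config.figure_format}"
                deform.render_deformation(warp7, gpath, style="grid")
                figures.append(gpath.name)
        summary["figures"] = figures

        # --- condition models ----------------------------------------------
        stage = "condition"
        cond_df = cov_df.copy()
        smi = cond.scaled_mass_index(cond_df)
        cond_df["smi"] = smi.smi.to_numpy()
        cond_df["caudal_aspect_ratio"] = cond.caudal_aspect_ratio(
            cond_df["caudal_height"].to_numpy(), cond_df["caudal_area"].to_numpy()
        )
        cond_tables = []
        selections = {}
        for response in ("smi", "caudal_area", "caudal_aspect_ratio"):
            sel = cond.fit_condition_models(cond_df, response)
            selections[response] = {
                "formula": sel.selected_formula,
                "aic": sel.aic,
                "df_resid": sel.df_resid,
            }
            tab = sel.coefficients.reset_index(names="term")
            tab.insert(0, "response", response)
            cond_tables.append(tab)
        _write_csv(pd.concat(cond_tables, ignore_index=True), out_dir / "condition_models.csv", config)
        summary["condition"] = selections
        summary["smi"] = {"b_sma": smi.b_sma, "L0": smi.l0}

    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    summary["elapsed_s"] = round(time.time() - t0, 2)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    logger.info("pipeline finished in %.1f s -> %s", summary["elapsed_s"], out_dir)
    return summary
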