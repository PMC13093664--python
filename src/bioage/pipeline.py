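"""End-to-end orchestration: simulate/load -> hygiene -> screen ->
subset -> fit -> score -> contrasts -> dichotomy.

Each stage writes its artifact (CSV/JSON) into the run directory; any
stage failure aborts with the stage name and cause.  All randomness is
routed through the simulation config's seed, so a fixed config gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import SimConfig, generate_cohort, read_cohort
from .preprocess import prepare_training
from .screen import screen_panel, preselect_top_k, marker_age_stats
from .subset import best_subset
from .model import fit_scaler, fit_model, apply_model, save_model
from .groups import subgroup_contrast, hormone_split_contrast, dose_response
from .dichotomy import homa_index, glucose_exclusion, screen_all

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults match the reference settings
    (preselect 30, subset size 10, quantile bounds [0.01, 0.99], IQR
    k = 1.3, alpha 0.05, age cut 50, glucose cut 250 mg/dL)."""

    sim: SimConfig = field(default_factory=SimConfig)
    input_cohort: str | None = None       # CSV path; overrides simulation
    sexes: tuple[str, ...] = ("F", "M")
    preselect_k: int = 30
    subset_size: int = 10
    subset_method: str = "auto"
    iqr_k: float = 1.3
    q_lo: float = 0.01
    q_hi: float = 0.99
    alpha: float = 0.05
    level: float = 0.95
    age_cut: float = 50.0
    glucose_threshold: float = 250.0
    outdir: str = "runs"
    label: str = "run"
    external_markers: tuple[str, ...] | None = None  # default: sim's externals

    def validate(self) -> None:
        if self.input_cohort is None:
            self.sim.validate()
            if self.preselect_k > len(self.sim.panel_spec):
                raise ValueError("preselect_k exceeds panel size")
        if self.subset_size > self.preselect_k:
            raise ValueError("subset_size exceeds preselect_k")
        if not 0 <= self.q_lo < self.q_hi <= 1:
            raise ValueError("quantile bounds must satisfy 0 <= lo < hi <= 1")
        for s in self.sexes:
            if s not in ("F", "M"):
                raise ValueError(f"sexes: unknown sex {s!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sim"]["age_range"] = list(self.sim.age_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("sim", None)
        cfg = cls(**{k: v for k, v in d.items() if k != "sim"})
        if sim is not None:
            from .simulate import MarkerSpec, ExternalMarkerSpec
            sim["panel_spec"] = [MarkerSpec(**m) for m in sim.get("panel_spec", [])]
            sim["external_spec"] = [ExternalMarkerSpec(**m)
                                    for m in sim.get("external_spec", [])]
            sim["age_range"] = tuple(sim["age_range"])
            cfg.sim = SimConfig(**sim)
        if isinstance(cfg.sexes, list):
            cfg.sexes = tuple(cfg.sexes)
        cfg.validate()
        return cfg


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc
        return wrapped
    return deco


@_stage("generate")
def _load_or_generate(config: PipelineConfig):
    if config.input_cohort is not None:
        return read_cohort(config.input_cohort), None
    return generate_cohort(config.sim)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    config.validate()
    rundir = Path(config.outdir) / config.label
    rundir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(rundir / "config.yaml")

    cohort, truth = _load_or_generate(config)
    cohort.to_csv(rundir / "cohort.csv", index=False)
    if truth is not None:
        truth.to_csv(rundir / "truth.csv", index=False)

    panel = (config.sim.panel_names if config.input_cohort is None
             else [c for c in cohort.columns if c.startswith("pm")])
    externals = list(config.external_markers
                     if config.external_markers is not None
                     else (config.sim.external_names
                           if config.input_cohort is None else []))

    summary: dict = {"version": __version__, "python": platform.python_version(),
                     "seed": config.sim.seed, "n_subjects": len(cohort),
                     "sexes": {}}
    scored_parts = []
    for sex in config.sexes:
        sexinfo: dict = {}
        # hygiene
        try:
            train, report, bounds = prepare_training(
                cohort, sex, panel, config.q_lo, config.q_hi)
        except Exception as exc:
            raise PipelineError(f"stage 'preprocess' ({sex}): {exc}") from exc
        if len(train) < config.subset_size + 2:
            raise PipelineError(
                f"stage 'preprocess' ({sex}): only {len(train)} training "
                "subjects remain after filtering; cannot fit the model")
        report.to_json(rundir / f"filter_report_{sex}.json")
        bounds.to_csv(rundir / f"quantile_bounds_{sex}.csv")

        # screen + preselect
        try:
            stats_df = screen_panel(train, panel)
            stats_df.to_csv(rundir / f"marker_stats_{sex}.csv", index=False)
            stats_list = [marker_age_stats(train[m], train["age"], name=m)
                          for m in panel]
            shortlist = preselect_top_k(stats_list, k=config.preselect_k)
        except Exception as exc:
            raise PipelineError(f"stage 'screen' ({sex}): {exc}") from exc

        # subset selection
        try:
            sel = best_subset(train[shortlist], train["age"],
                              size=config.subset_size,
                              method=config.subset_method)
            sel.to_json(rundir / f"subset_{sex}.json")
        except Exception as exc:
            raise PipelineError(f"stage 'select' ({sex}): {exc}") from exc

        # fit + save
        try:
            scaling = fit_scaler(train[list(sel.selected)])
            mod = fit_model(train[list(sel.selected)], train["age"],
                            sex=sex, scaling=scaling)
            save_model(mod, rundir / f"model_{sex}.csv")
        except Exception as exc:
            raise PipelineError(f"stage 'fit' ({sex}): {exc}") from exc

        # score everyone of this sex
        try:
            scored_sex = apply_model(mod, cohort[cohort["sex"] == sex])
            scored_parts.append(scored_sex)
        except Exception as exc:
            raise PipelineError(f"stage 'score' ({sex}): {exc}") from exc

        # training-set calibration identities
        train_scored = apply_model(mod, train)
        ad = train_scored["age_diff"].to_numpy(dtype=float)
        a = train_scored["age"].to_numpy(dtype=float)
        b = train_scored["bioage"].to_numpy(dtype=float)
        slope_b_on_a = float(np.cov(b, a, ddof=1)[0, 1] / np.var(a, ddof=1))
        sexinfo.update({
            "n_train": mod.n_train,
            "r2": mod.r2,
            "r": float(np.sqrt(mod.r2)),
            "mean_age": mod.mean_age,
            "selected": list(sel.selected),
            "selection_method": sel.method,
            "mean_ad_train": float(ad.mean()),
            "slope_b_on_a_train": slope_b_on_a,
            "cov_ad_age_train": float(np.cov(ad, a, ddof=1)[0, 1]),
        })
        summary["sexes"][sex] = sexinfo

    scored = pd.concat(scored_parts, axis=0).sort_index()
    scored.to_csv(rundir / "scored.csv", index=False)

    # contrasts
    try:
        contrast_rows = []
        for sex in config.sexes:
            s = scored[scored["sex"] == sex]
            for ga, gb, name in (("DS", "RASIG", f"DS_vs_RASIG_{sex}"),
                                 ("GO", "SGO", f"GO_vs_SGO_{sex}")):
                if (s["subgroup"] == ga).sum() >= 2 and (s["subgroup"] == gb).sum() >= 2:
                    cr = subgroup_contrast(
                        s, s["subgroup"] == ga, s["subgroup"] == gb,
                        age_match=True, level=config.level,
                        label_a=f"{ga}_{sex}", label_b=f"{gb}_{sex}")
                    row = cr.as_dict()
                    row["contrast"] = name
                    contrast_rows.append(row)
        hsc = hormone_split_contrast(scored, age_cut=config.age_cut,
                                     level=config.level)
        for key in ("below", "above"):
            if hsc[key] is not None:
                row = hsc[key].as_dict()
                row["contrast"] = f"hormone_{key}_{config.age_cut:g}"
                contrast_rows.append(row)
        summary["hormone_warnings"] = hsc["warnings"]
        if contrast_rows:
            pd.DataFrame(contrast_rows).to_csv(rundir / "contrasts.csv",
                                               index=False)
        summary["contrasts"] = contrast_rows

        dr = {}
        for sex in config.sexes:
            s = scored[(scored["sex"] == sex) & (scored["smoker"] == 1)]
            if len(s) >= 3 and np.ptp(s["packs"].to_numpy(dtype=float)) > 0:
                res = dose_response(s["age_diff"], s["packs"])
                dr[sex] = asdict_dataclass(res)
        summary["dose_response"] = dr
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'contrast': {exc}") from exc

    # dichotomy screen
    try:
        if externals:
            cohort_d = cohort.copy()
            if {"glucose", "insulin"}.issubset(cohort_d.columns):
                cohort_d["homa"] = homa_index(cohort_d["glucose"],
                                              cohort_d["insulin"])
                if "homa" not in externals:
                    externals = externals + ["homa"]
            if "glucose" in cohort_d.columns:
                cohort_d, excluded = glucose_exclusion(
                    cohort_d, threshold=config.glucose_threshold)
                summary["glucose_excluded"] = excluded
            report_df = screen_all(cohort_d, scored, externals,
                                   alpha=config.alpha)
            report_df.to_csv(rundir / "dichotomy.csv", index=False)
            summary["dichotomy_classes"] = {
                f"{r.marker}_{r.sex}": r.klass for r in report_df.itertuples()}
    except Exception as exc:
        raise PipelineError(f"stage 'dichotomy': {exc}") from exc

    (rundir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    default=float))
    return rundir


def asdict_dataclass(obj) -> dict:
    return dataclasses.asdict(obj)
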