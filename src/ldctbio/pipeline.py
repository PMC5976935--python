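"""End-to-end orchestration: synthesize -> quantify -> match -> model -> report.

A single :class:`RunConfig` (YAML-loadable) drives the full chain with one
global seed.  Per-stage child seeds are derived by hashing the stage name
with the global seed, so each stage is reproducible in isolation and the
whole bundle is bit-for-bit reproducible (timestamps excluded — none are
written into the CSVs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .body_composition import measure_body_composition
from .cac_scoring import GradeCutpoints, assign_grade, count_calcified_pixels, \
    normalize_background
from .cohort_builder import MatchConfig, apply_exclusions, derive_all, nsm_match
from .emphysema_quant import quantify_emphysema
from .io_formats import records_to_frame, write_roster, write_table
from .stat_models import AnalysisSpec, fit_cox, fit_logistic, stratified_analysis
from .synthetic_data import PhantomConfig, RosterConfig, make_biomarkers, \
    make_phantom, make_roster

logger = logging.getLogger(__name__)


def child_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, with a single global seed."""

    output_dir: str = "ldctbio_run"
    seed: int = 0
    n_phantoms: int = 30
    phantom: dict = field(default_factory=dict)       # PhantomConfig overrides
    roster: dict = field(default_factory=dict)        # RosterConfig overrides
    match: dict = field(default_factory=dict)         # MatchConfig overrides
    cac_threshold: float = 130.0
    cac_cutpoints: tuple[float, float, float] = (10.0, 60.0, 300.0)
    laa_threshold: float = -950.0
    lung_threshold: float = -400.0
    muscle_window: tuple[float, float] = (-29.0, 150.0)
    fat_window: tuple[float, float] = (-120.0, -60.0)

    def validate(self) -> None:
        for name, v in (("cac_threshold", self.cac_threshold),
                        ("laa_threshold", self.laa_threshold),
                        ("lung_threshold", self.lung_threshold),
                        *((f"muscle_window[{i}]", w) for i, w in enumerate(self.muscle_window)),
                        *((f"fat_window[{i}]", w) for i, w in enumerate(self.fat_window))):
            if not -1024.0 <= v <= 3071.0:
                raise ValueError(f"{name}={v} outside the valid HU range [-1024, 3071]")
        if self.n_phantoms < 0:
            raise ValueError("n_phantoms must be >= 0")
        GradeCutpoints(*self.cac_cutpoints)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for tup_field in ("cac_cutpoints", "muscle_window", "fat_window"):
            setattr(cfg, tup_field, tuple(getattr(cfg, tup_field)))
        return cfg


def _quantify_phantoms(cfg: RunConfig, out: Path) -> pd.DataFrame:
    seed0 = child_seed(cfg.seed, "phantoms")
    rows = []
    cuts = GradeCutpoints(*cfg.cac_cutpoints)
    for i in range(cfg.n_phantoms):
        overrides = dict(cfg.phantom)
        overrides.setdefault("n_plaques", i % 7)
        overrides.setdefault("laa_fraction", 0.02 + 0.26 * (i % 10) / 9.0)
        pcfg = PhantomConfig(seed=(seed0 + i) % (2 ** 31), **overrides)
        vol, truth = make_phantom(pcfg)
        if pcfg.background_offset:
            vol, offset = normalize_background(vol)
        else:
            offset = 0.0
        count = count_calcified_pixels(vol, truth.heart_center, truth.heart_radius,
                                       cfg.cac_threshold)
        emph = quantify_emphysema(vol, cfg.lung_threshold, cfg.laa_threshold)
        comp = measure_body_composition(vol, truth.mediastinum_seed,
                                        cfg.muscle_window, cfg.fat_window)
        rows.append({
            "phantom_id": i,
            "cac_pixel_count": count,
            "cac_grade": assign_grade(count, cuts),
            "normalization_offset": offset,
            "laa_fraction": emph.laa_fraction,
            "muscle_area_cm2": comp.muscle_area_cm2,
            "muscle_mean_hu": comp.muscle_mean_hu,
            "fat_mean_hu": comp.fat_mean_hu,
            "truth_cac_pixel_count": truth.calcified_pixel_count,
            "truth_laa_fraction": truth.true_laa_fraction,
            "truth_muscle_area_cm2": truth.true_muscle_area_cm2,
            "truth_muscle_mean_hu": truth.true_muscle_mean_hu,
            "truth_fat_mean_hu": truth.true_fat_mean_hu,
        })
    df = pd.DataFrame(rows)
    write_table(df, out / "phantom_quantification.csv")
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns a manifest of outputs and parameters."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage synth: generating roster")
    roster_cfg = RosterConfig(seed=child_seed(config.seed, "roster"), **config.roster)
    roster = make_roster(roster_cfg)
    write_roster(roster, out / "roster.csv")
    logger.info("stage synth: %d roster rows", len(roster))

    logger.info("stage quantify: %d phantoms", config.n_phantoms)
    _quantify_phantoms(config, out)

    logger.info("stage match")
    survivors, nonsurvivors, excl = apply_exclusions(derive_all(roster))
    cohort = nsm_match(survivors, nonsurvivors, MatchConfig(**config.match))
    write_table(excl.to_frame(), out / "exclusion_log.csv")
    write_table(cohort.pairs, out / "matched_cohort.csv")
    write_table(cohort.balance, out / "balance_table.csv")
    logger.info("stage match: %d pairs", cohort.n_pairs)

    logger.info("stage model")
    bio = make_biomarkers(survivors + nonsurvivors, child_seed(config.seed, "biomarkers"))
    frame = records_to_frame(survivors + nonsurvivors).merge(bio, on="pid")
    matched_pids = set(cohort.survivor_pids) | set(cohort.nonsurvivor_pids)
    frame = frame[frame["pid"].isin(matched_pids)].reset_index(drop=True)
    frame["nonsurvivor"] = (frame["death_lc"] == "lung_cancer_death").astype(int)
    spec = AnalysisSpec()
    logit_res = fit_logistic(frame, spec)
    cox_res = fit_cox(frame, spec)
    write_table(logit_res, out / "logistic_model.csv")
    write_table(cox_res, out / "cox_model.csv")
    strat_frames = {s: stratified_analysis(frame, s) for s in ("stage", "pkyr", "copd")}
    for name, df in strat_frames.items():
        write_table(df, out / f"stratified_muscle_by_{name}.csv")

    manifest = {
        "package": "ldctbio",
        "version": __version__,
        "seed": config.seed,
        "child_seeds": {s: child_seed(config.seed, s)
                        for s in ("roster", "phantoms", "biomarkers")},
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "output_dir"},
        "n_matched_pairs": cohort.n_pairs,
        "logistic_chi2": logit_res.chi2,
        "logistic_df": logit_res.df,
        "cox_chi2": cox_res.chi2,
        "cox_df": cox_res.df,
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return manifest
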