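"""Synthetic thorax phantoms, subject rosters, and effect-planted datasets.

The phantom is a single axial slice laid out like a chest CT at the level of
the pectoralis muscles: exterior air, a body oval, a subcutaneous fat ring,
two rectangular pectoralis compartments, two lung fields with scattered
low-attenuation holes, a heart disk carrying hyperdense calcified plaques,
and a mediastinal soft-tissue bridge in the muscle HU window that the
seeded pectoralis segmentation must exclude.  Every ground-truth quantity
is recomputed by enumerating the painted label map, never copied from the
configuration, so truth is exact by construction.

Label codes: 0 air, 1 body, 2 fat ring, 3 muscle, 4 lung, 5 low-attenuation
hole, 6 heart, 7 plaque, 8 mediastinum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CTVolume, SubjectRecord

AIR, BODY, FAT, MUSCLE, LUNG, LAA, HEART, PLAQUE, MEDIASTINUM = range(9)

LABEL_NAMES = {
    AIR: "air", BODY: "body", FAT: "fat", MUSCLE: "muscle", LUNG: "lung",
    LAA: "laa", HEART: "heart", PLAQUE: "plaque", MEDIASTINUM: "mediastinum",
}


@dataclass
class PhantomConfig:
    """Geometry, HU levels and randomness of the thorax phantom.

    All HU levels must lie in [-1024, 3071].  ``seed`` fixes every random
    element (plaque placement/intensity, hole placement, tissue noise).
    ``background_offset`` shifts the whole image after truth enumeration to
    emulate an uncalibrated scanner; ``blur_sigma`` optionally applies a
    partial-volume blur (off by default so pixel counts stay exact).
    """

    shape: tuple[int, int] = (256, 256)
    pixel_spacing: tuple[float, float] = (0.8, 0.8)
    slice_thickness: float = 2.0
    air_hu: float = -1000.0
    body_hu: float = -45.0
    fat_hu_mean: float = -92.5
    fat_hu_sd: float = 4.0
    muscle_hu_mean: float = 57.0
    muscle_hu_sd: float = 4.0
    muscle_size: tuple[int, int] = (50, 50)   # rows, cols per compartment
    lung_hu: float = -850.0
    laa_hu: float = -1000.0
    laa_fraction: float = 0.13
    heart_hu: float = 30.0
    mediastinum_hu: float = 45.0
    n_plaques: int = 4
    plaque_radius: float = 2.0
    plaque_hu_range: tuple[float, float] = (300.0, 800.0)
    background_offset: float = 0.0
    blur_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        hu_fields = [self.air_hu, self.body_hu, self.fat_hu_mean, self.muscle_hu_mean,
                     self.lung_hu, self.laa_hu, self.heart_hu, self.mediastinum_hu,
                     *self.plaque_hu_range]
        for v in hu_fields:
            if not -1024.0 <= v <= 3071.0:
                raise ValueError(f"HU level {v} outside [-1024, 3071]")
        if not 0.0 <= self.laa_fraction <= 1.0:
            raise ValueError("laa_fraction must lie in [0, 1]")
        if self.shape[0] < 64 or self.shape[1] < 64:
            raise ValueError("phantom grid must be at least 64x64")
        if self.n_plaques < 0 or self.plaque_radius <= 0:
            raise ValueError("invalid plaque parameters")


@dataclass
class PhantomTruth:
    """Ground truth enumerated from the painted label map.

    ``labels`` carries the full label map so tests can use the painted
    masks as exact oracles for the segmentation operators.
    """

    calcified_pixel_count: int
    true_laa_fraction: float
    true_muscle_area_cm2: float
    true_muscle_mean_hu: float
    true_fat_mean_hu: float
    heart_center: tuple[int, int]
    heart_radius: float
    mediastinum_seed: tuple[int, int]
    lung_pixel_count: int
    laa_pixel_count: int
    muscle_pixel_count: int
    labels: np.ndarray = field(repr=False)

    def mask(self, *codes: int) -> np.ndarray:
        return np.isin(self.labels, codes)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "calcified_pixel_count", "true_laa_fraction", "true_muscle_area_cm2",
            "true_muscle_mean_hu", "true_fat_mean_hu", "heart_center",
            "heart_radius", "mediastinum_seed", "lung_pixel_count",
            "laa_pixel_count", "muscle_pixel_count")}
        d["heart_center"] = list(d["heart_center"])
        d["mediastinum_seed"] = list(d["mediastinum_seed"])
        return d


def _ellipse_mask(shape, center, semi_axes):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi_axes[0]) ** 2 + ((cc - center[1]) / semi_axes[1]) ** 2 <= 1.0


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def make_phantom(config: PhantomConfig | None = None) -> tuple[CTVolume, PhantomTruth]:
    """Paint a thorax phantom and enumerate its ground truth.

    Returns a single-slice :class:`CTVolume` and a :class:`PhantomTruth`
    whose fields are computed from the painted label map.  Deterministic
    for a fixed config (seed included).  Raises if the configured regions
    cannot fit the grid.
    """
    cfg = config or PhantomConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.shape
    labels = np.zeros((H, W), dtype=np.int8)

    body_c = (0.5 * H, 0.5 * W)
    body_ax = (0.40 * H, 0.47 * W)
    inner_ax = (0.345 * H, 0.42 * W)
    body = _ellipse_mask((H, W), body_c, body_ax)
    inner = _ellipse_mask((H, W), body_c, inner_ax)
    labels[body] = FAT          # ring = body minus inner
    labels[inner] = BODY

    # lungs
    lung_c = [(0.52 * H, 0.27 * W), (0.52 * H, 0.73 * W)]
    lung_ax = (0.21 * H, 0.135 * W)
    for c in lung_c:
        m = _ellipse_mask((H, W), c, lung_ax)
        if (m & ~inner).any():
            raise ValueError("lung fields do not fit inside the body")
        labels[m] = LUNG

    # pectoralis compartments (rectangles -> exact pixel counts)
    mh, mw = cfg.muscle_size
    r0 = round(0.22 * H)
    gap = max(3, round(W / 64))
    rects = [
        (r0, r0 + mh, W // 2 - gap - mw, W // 2 - gap),
        (r0, r0 + mh, W // 2 + gap, W // 2 + gap + mw),
    ]
    for (ra, rb, ca, cb) in rects:
        if ra < 0 or rb > H or ca < 0 or cb > W:
            raise ValueError("muscle compartments do not fit the grid")
        corners = [(ra, ca), (ra, cb - 1), (rb - 1, ca), (rb - 1, cb - 1)]
        for (r, c) in corners:
            if ((r - body_c[0]) / inner_ax[0]) ** 2 + ((c - body_c[1]) / inner_ax[1]) ** 2 > 1.0:
                raise ValueError("muscle compartments do not fit inside the body")
        labels[ra:rb, ca:cb] = MUSCLE

    # mediastinal bridge between the compartments, reaching the heart
    heart_c = (round(0.60 * H), W // 2)
    heart_r = 0.155 * H
    # bridge half-width leaves >= 1 body column to each muscle compartment
    # so the seeded component stays 4-disjoint from the pectoralis rectangles
    bw = max(1, gap - 2)
    labels[r0: heart_c[0], W // 2 - bw: W // 2 + bw + 1] = MEDIASTINUM

    # heart and plaques
    heart = _disk_mask((H, W), heart_c, heart_r)
    if (heart & ~inner).any():
        raise ValueError("heart disk does not fit inside the body")
    labels[heart] = HEART
    plaque_centers: list[tuple[float, float]] = []
    plaque_hu: list[float] = []
    for _ in range(cfg.n_plaques):
        for _attempt in range(200):
            ang = rng.uniform(0, 2 * math.pi)
            rad = (heart_r - cfg.plaque_radius - 1.5) * math.sqrt(rng.uniform())
            pc = (heart_c[0] + rad * math.sin(ang), heart_c[1] + rad * math.cos(ang))
            if all((pc[0] - q[0]) ** 2 + (pc[1] - q[1]) ** 2 > (2 * cfg.plaque_radius + 1) ** 2
                   for q in plaque_centers):
                break
        else:
            raise ValueError("cannot place non-overlapping plaques in the heart")
        plaque_centers.append(pc)
        plaque_hu.append(float(rng.uniform(*cfg.plaque_hu_range)))
        labels[_disk_mask((H, W), pc, cfg.plaque_radius)] = PLAQUE

    # low-attenuation holes inside lungs
    lung_flat = np.flatnonzero(labels == LUNG)
    n_lung_total = lung_flat.size
    k = int(round(cfg.laa_fraction * n_lung_total))
    hole_idx = rng.choice(lung_flat, size=k, replace=False) if k else np.array([], dtype=int)
    labels.flat[hole_idx] = LAA

    # paint HU image
    img = np.full((H, W), cfg.air_hu, dtype=np.float64)
    img[labels == BODY] = cfg.body_hu
    fat_mask = labels == FAT
    img[fat_mask] = np.clip(
        rng.normal(cfg.fat_hu_mean, cfg.fat_hu_sd, int(fat_mask.sum())), -120.0, -60.0)
    muscle_mask = labels == MUSCLE
    img[muscle_mask] = np.clip(
        rng.normal(cfg.muscle_hu_mean, cfg.muscle_hu_sd, int(muscle_mask.sum())), -29.0, 150.0)
    img[labels == LUNG] = cfg.lung_hu
    img[labels == LAA] = cfg.laa_hu
    img[labels == HEART] = cfg.heart_hu
    img[labels == MEDIASTINUM] = cfg.mediastinum_hu
    for pc, hu in zip(plaque_centers, plaque_hu):
        img[_disk_mask((H, W), pc, cfg.plaque_radius) & (labels == PLAQUE)] = hu

    if cfg.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, cfg.blur_sigma)

    # ground truth by enumeration of the painted masks / calibrated image
    rr, cc = np.ogrid[:H, :W]
    roi = (rr - heart_c[0]) ** 2 + (cc - heart_c[1]) ** 2 <= heart_r ** 2
    calcified = int(np.count_nonzero(roi & (img > 130.0)))
    lung_total = int(np.count_nonzero((labels == LUNG) | (labels == LAA)))
    laa_count = int(np.count_nonzero(labels == LAA))
    muscle_count = int(muscle_mask.sum())
    med_pixels = np.argwhere(labels == MEDIASTINUM)
    centroid = med_pixels.mean(axis=0)
    seed_idx = int(np.argmin(((med_pixels - centroid) ** 2).sum(axis=1)))
    seed_pt = (int(med_pixels[seed_idx, 0]), int(med_pixels[seed_idx, 1]))

    truth = PhantomTruth(
        calcified_pixel_count=calcified,
        true_laa_fraction=laa_count / lung_total if lung_total else 0.0,
        true_muscle_area_cm2=muscle_count * cfg.pixel_spacing[0] * cfg.pixel_spacing[1] / 100.0,
        true_muscle_mean_hu=float(img[muscle_mask].mean()) if muscle_count else float("nan"),
        true_fat_mean_hu=float(img[fat_mask].mean()) if fat_mask.any() else float("nan"),
        heart_center=(int(heart_c[0]), int(heart_c[1])),
        heart_radius=float(heart_r),
        mediastinum_seed=seed_pt,
        lung_pixel_count=lung_total,
        laa_pixel_count=laa_count,
        muscle_pixel_count=muscle_count,
        labels=labels,
    )
    if cfg.background_offset:
        img = img + cfg.background_offset
    volume = CTVolume(img, cfg.pixel_spacing, cfg.slice_thickness)
    return volume, truth


# ---------------------------------------------------------------------------
# Roster generation


@dataclass
class RosterConfig:
    """Stratum counts and marginal distributions of the synthetic roster.

    Defaults reconstruct the screening cohort's printed flow: 623
    screen-detected cancers = 373 survivors (stage I/II/III strata
    296/40/22, 4 stage IV, 11 missing stage) + 216 nonsurvivors (182
    lung-cancer-related deaths with strata 49/19/65 plus 49 stage IV, and
    34 unrelated deaths) + 34 indeterminate-status subjects, plus 30
    non-screen-detected extras.  Marginals follow the printed group
    descriptives (age 64 +/- 5 y, height 1.70 +/- 0.10 m, ...).  Gender is
    allocated per stratum by rounding the 54:36 male fraction so every
    stratum carries the same sex ratio regardless of seed.
    """

    survivor_stage_counts: Mapping[str, int] = field(
        default_factory=lambda: {"I": 296, "II": 40, "III": 22, "IV": 4})
    nonsurvivor_stage_counts: Mapping[str, int] = field(
        default_factory=lambda: {"I": 49, "II": 19, "III": 65, "IV": 49})
    survivor_missing_stage: int = 11
    unrelated_death_count: int = 34
    indeterminate_count: int = 34
    non_screen_detected_count: int = 30
    male_fraction: float = 0.6
    age_mean_sd: tuple[float, float] = (64.0, 5.0)
    age_mean_sd_nonsurv: tuple[float, float] = (64.0, 6.0)
    height_mean_sd: tuple[float, float] = (1.70, 0.10)
    weight_mean_sd: tuple[float, float] = (80.0, 16.0)
    weight_mean_sd_nonsurv: tuple[float, float] = (81.0, 18.0)
    pkyr_mean_sd: tuple[float, float] = (56.0, 24.0)
    survivor_fup_mean_sd_range: tuple[float, float, float, float] = (1660.0, 488.0, 405.0, 2744.0)
    nonsurvivor_fup_mean_sd_range: tuple[float, float, float, float] = (894.0, 542.0, 14.0, 2399.0)
    copd_rate: float = 0.25
    copd_rate_nonsurv: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        for counts in (self.survivor_stage_counts, self.nonsurvivor_stage_counts):
            for k, v in counts.items():
                if v < 0:
                    raise ValueError(f"negative stratum count for stage {k}")
        for v in (self.survivor_missing_stage, self.unrelated_death_count,
                  self.indeterminate_count, self.non_screen_detected_count):
            if v < 0:
                raise ValueError("counts must be >= 0")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")


_HISTOLOGY = ("adenocarcinoma", "squamous_cell", "small_cell", "large_cell", "unspecified")
_HIST_P_SURV = np.array([52, 24, 6, 0, 8], dtype=float)
_HIST_P_NONSURV = np.array([45, 26, 4, 5, 10], dtype=float)


def _stratum_genders(n: int, male_fraction: float, rng: np.random.Generator) -> list[str]:
    n_male = int(round(male_fraction * n))
    genders = ["male"] * n_male + ["female"] * (n - n_male)
    return [genders[i] for i in rng.permutation(n)]


def make_roster(config: RosterConfig | None = None) -> list[SubjectRecord]:
    """Generate a synthetic master-sheet roster with exact stratum counts."""
    cfg = config or RosterConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    records: list[SubjectRecord] = []
    next_pid = [100001]

    def draw_subject(group: str, stage: str | None, death: str | None,
                     screen: bool) -> SubjectRecord:
        nonsurv = group == "nonsurvivor"
        age_m, age_s = cfg.age_mean_sd_nonsurv if nonsurv else cfg.age_mean_sd
        w_m, w_s = cfg.weight_mean_sd_nonsurv if nonsurv else cfg.weight_mean_sd
        fm, fs, flo, fhi = (cfg.nonsurvivor_fup_mean_sd_range if nonsurv
                            else cfg.survivor_fup_mean_sd_range)
        hist_p = _HIST_P_NONSURV if nonsurv else _HIST_P_SURV
        st = float(np.clip(np.round(rng.normal(fm, fs)), flo, fhi))
        candx = float(rng.integers(30, 901))
        rec = SubjectRecord(
            pid=str(next_pid[0]),
            age=float(np.clip(np.round(rng.normal(age_m, age_s)), 55, 74)),
            gender=None,  # filled by stratum allocation
            height=float(np.clip(np.round(rng.normal(*cfg.height_mean_sd), 2), 1.40, 2.10)),
            weight=float(np.clip(np.round(rng.normal(w_m, w_s), 1), 40.0, 160.0)),
            pkyr=float(np.clip(np.round(rng.normal(*cfg.pkyr_mean_sd), 1), 30.0, 150.0)),
            stage=stage,
            screen_detected=screen,
            death_lc=death,
            candx_days=candx,
            fup_days=candx + st,
            copd=bool(rng.uniform() < (cfg.copd_rate_nonsurv if nonsurv else cfg.copd_rate)),
            histology=str(rng.choice(_HISTOLOGY, p=hist_p / hist_p.sum())),
        )
        next_pid[0] += 1
        return rec

    def add_stratum(n: int, group: str, stage: str | None, death: str | None,
                    screen: bool = True) -> None:
        genders = _stratum_genders(n, cfg.male_fraction, rng)
        for g in genders:
            rec = draw_subject(group, stage, death, screen)
            rec.gender = g
            records.append(rec)

    for stage in ("I", "II", "III", "IV"):
        add_stratum(cfg.survivor_stage_counts.get(stage, 0), "survivor", stage, "alive")
    add_stratum(cfg.survivor_missing_stage, "survivor", None, "alive")
    for stage in ("I", "II", "III", "IV"):
        add_stratum(cfg.nonsurvivor_stage_counts.get(stage, 0), "nonsurvivor",
                    stage, "lung_cancer_death")
    # unrelated deaths: stage sampled over I-IV, excluded downstream by outcome
    for _ in range(cfg.unrelated_death_count):
        rec = draw_subject("nonsurvivor", str(rng.choice(("I", "II", "III", "IV"))),
                           "unrelated_death", True)
        rec.gender = "male" if rng.uniform() < cfg.male_fraction else "female"
        records.append(rec)
    for _ in range(cfg.indeterminate_count):
        rec = draw_subject("survivor", str(rng.choice(("I", "II", "III"))), None, True)
        rec.gender = "male" if rng.uniform() < cfg.male_fraction else "female"
        records.append(rec)
    add_stratum(cfg.non_screen_detected_count, "survivor", "I", "alive", screen=False)

    order = rng.permutation(len(records))
    return [records[i] for i in order]


# ---------------------------------------------------------------------------
# Effect-planted datasets for model recovery


CovariateSpec = tuple  # ("normal", mu, sd) or ("binary", p)


def _draw_covariates(n: int, specs: Mapping[str, CovariateSpec],
                     rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, spec in specs.items():
        kind = spec[0]
        if kind == "normal":
            cols[name] = rng.normal(spec[1], spec[2], n)
        elif kind == "binary":
            cols[name] = (rng.uniform(size=n) < spec[1]).astype(float)
        else:
            raise ValueError(f"unknown covariate kind {kind!r}")
    return pd.DataFrame(cols)


def make_survival_data(n: int, true_betas: Mapping[str, float], censor_rate: float,
                       seed: int, covariates: Mapping[str, CovariateSpec] | None = None,
                       baseline_hazard: float = 1e-3) -> pd.DataFrame:
    """Simulate survival data with hazard proportional to ``exp(X @ beta)``.

    Event times are exponential with subject-specific rate
    ``baseline_hazard * exp(x . beta)``; censoring is independent
    exponential, calibrated so the expected censored fraction is
    approximately ``censor_rate``.  Returns columns: covariates, ``time``,
    ``event``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    specs = covariates or {name: ("normal", 0.0, 1.0) for name in true_betas}
    X = _draw_covariates(n, specs, rng)
    lin = np.zeros(n)
    for name, beta in true_betas.items():
        lin += beta * X[name].to_numpy()
    rate = baseline_hazard * np.exp(lin)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        rate_c = censor_rate / (1.0 - censor_rate) * float(np.mean(rate))
        t_cens = rng.exponential(1.0 / rate_c, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    out = X.copy()
    out["time"] = time
    out["event"] = event
    return out


def make_logistic_data(n: int, true_betas: Mapping[str, float], seed: int,
                       covariates: Mapping[str, CovariateSpec] | None = None,
                       intercept: float | None = None) -> pd.DataFrame:
    """Simulate a binary outcome with planted log-odds coefficients.

    If ``intercept`` is None it is set to ``-mean(X @ beta)`` so the
    marginal outcome rate is near 1/2.  Returns covariates plus ``y``.
    """
    rng = np.random.default_rng(seed)
    specs = covariates or {name: ("normal", 0.0, 1.0) for name in true_betas}
    X = _draw_covariates(n, specs, rng)
    lin = np.zeros(n)
    for name, beta in true_betas.items():
        lin += beta * X[name].to_numpy()
    b0 = -float(np.mean(lin)) if intercept is None else intercept
    p = 1.0 / (1.0 + np.exp(-(b0 + lin)))
    out = X.copy()
    out["y"] = (rng.uniform(size=n) < p).astype(int)
    return out


# Group-conditional biomarker profiles echoing the printed survivor /
# nonsurvivor descriptives (muscle cm^2, fat HU, emphysema fraction, CAC
# grade means near 1.0 and 2.0 on the 0-3 scale).
_BIOMARKER_PROFILES = {
    "survivor": dict(muscle=(32.6, 7.9), fat=(-92.5, 4.4), emph=(0.13, 0.12),
                     cac_p=(0.45, 0.25, 0.18, 0.12)),
    "nonsurvivor": dict(muscle=(29.2, 6.4), fat=(-89.9, 4.6), emph=(0.15, 0.14),
                        cac_p=(0.15, 0.20, 0.30, 0.35)),
}


def make_biomarkers(records: Sequence[SubjectRecord], seed: int) -> pd.DataFrame:
    """Draw per-subject imaging biomarkers conditional on outcome group.

    Survivors (``death_lc == 'alive'``) and lung-cancer deaths get
    group-specific distributions; other subjects get the survivor profile.
    Returns a frame keyed by pid with muscle_area, fat_attenuation,
    emphysema, cac_grade.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        prof = _BIOMARKER_PROFILES[
            "nonsurvivor" if rec.death_lc == "lung_cancer_death" else "survivor"]
        rows.append({
            "pid": rec.pid,
            "muscle_area": float(np.clip(rng.normal(*prof["muscle"]), 5.0, 80.0)),
            "fat_attenuation": float(np.clip(rng.normal(*prof["fat"]), -120.0, -60.0)),
            "emphysema": float(np.clip(rng.normal(*prof["emph"]), 0.0, 1.0)),
            "cac_grade": int(rng.choice(4, p=prof["cac_p"])),
        })
    return pd.DataFrame(rows)
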