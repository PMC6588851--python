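"""Seeded synthetic cohorts, activity diaries and UVB intensity series.

The generator emulates the statistical structure a tropical pregnancy
cohort presents to the analysis pipeline, so every stage is testable
without external data:

* n = 204 women; 96/204 wear hijab; covariate margins (age group, parity,
  BMI class, education, occupation, sunscreen use) follow the study's
  published frequency table; covariates are drawn independently.
* 3-day activity diaries of short outdoor bouts (5–10 min), totalling
  69.75 min/day on average of which 29.1 min fall in the 10:00–13:00
  midday window.
* serum 25-OH-D (ng/mL) with a fixed sub-detection mass (42/204 below the
  8.1 ng/mL assay limit, stored as 8.0) and a left-truncated lognormal
  above it, moment-matched so the censored cohort has mean 14.7 and
  SD 6.5 ng/mL.
* a positive rank correlation (target 0.37) between sun-exposed body area
  and serum level, induced through a latent daily UVB dose
  (exposed area × midday outdoor minutes × month-mean MED rate) linked to
  serum via a Gaussian copula: the log-scale serum score is
  weight × standardized-dose + noise, mapped through the calibrated
  marginal so the serum distribution stays exact at any effect size.

All draws flow from a single ``numpy`` Generator seeded per call, so equal
configs and seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .anthropometry import BodyMeasurements, CANONICAL_ENSEMBLES, exposed_area
from .cohort import DETECTION_LIMIT_NG_ML, apply_detection_limit, classify_status
from .dosimetry import IntensitySeries, MedParameters, watt_to_med_rate

__all__ = [
    "CohortGeneratorConfig",
    "IntensityGeneratorConfig",
    "generate_cohort",
    "generate_intensity",
    "simulate_multinomial",
    "load_fixture",
]

_FIXTURE_MONTHS = (
    "September", "October", "November", "December", "January", "February", "March",
)
_MONTH_NUMBER = {
    "January": 1, "February": 2, "March": 3, "April": 4, "May": 5, "June": 6,
    "July": 7, "August": 8, "September": 9, "October": 10, "November": 11,
    "December": 12,
}

# Serum marginal above the detection limit: lognormal(mu, sigma) left-
# truncated at 8.1, solved so that with a 42/204 sub-detection mass the
# censored mixture has mean 14.7 and SD 6.5 ng/mL exactly.
_SERUM_LOGNORM_MU = 2.683270
_SERUM_LOGNORM_SIGMA = 0.392797

# Empirical slope of achieved Spearman rho (exposed % vs serum) per unit
# copula weight at default config and n = 204; the dose→serum weight for a
# target rho is target / slope.  Valid for moderate targets (|rho| < ~0.55).
_RHO_PER_UNIT_WEIGHT = 0.5997


@dataclass(frozen=True)
class CohortGeneratorConfig:
    """Study-condition defaults for the synthetic cohort generator."""

    n: int = 204
    hijab_proportion: float = 96 / 204
    hijab_socks_proportion: float = 0.4
    #: ensemble mix among women without hijab
    nonhijab_ensemble_probs: Mapping[str, float] = field(
        default_factory=lambda: {"long-long": 0.40, "short-long": 0.35, "short-short": 0.25}
    )
    sunscreen_proportion: float = 26 / 204
    age_group_probs: Mapping[str, float] = field(
        default_factory=lambda: {"<20": 12 / 204, "20-34": 161 / 204, ">=35": 31 / 204}
    )
    parity_probs: Mapping[str, float] = field(
        default_factory=lambda: {"0": 80 / 204, "1": 71 / 204, ">=2": 53 / 204}
    )
    bmi_class_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "underweight": 17 / 204, "normal": 119 / 204,
            "overweight": 39 / 204, "obese": 29 / 204,
        }
    )
    education_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "elementary": 59 / 204, "middle": 57 / 204,
            "high": 59 / 204, "diploma/bachelor": 29 / 204,
        }
    )
    occupation_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "housewife": 148 / 204, "civil servant": 40 / 204, "others": 16 / 204,
        }
    )
    height_mean_cm: float = 155.0
    height_sd_cm: float = 5.5
    # diary structure
    diary_days: int = 3
    outdoor_total_mean_min: float = 69.75
    inwindow_mean_min: float = 29.1
    bout_min_minutes: int = 5
    bout_max_minutes: int = 10
    midday_window: tuple[int, int] = (10, 13)
    daytime: tuple[int, int] = (6, 18)
    # serum marginal and dose linkage
    below_detection_mass: float = 42 / 204
    serum_lognorm_mu: float = _SERUM_LOGNORM_MU
    serum_lognorm_sigma: float = _SERUM_LOGNORM_SIGMA
    target_rank_correlation: float = 0.37
    #: direct copula weight; None derives it from target_rank_correlation
    exposure_weight: float | None = None
    med_threshold_j_m2: float = 90_000.0
    months: Sequence[str] = _FIXTURE_MONTHS
    #: optional attrition: draw n from Binomial(n_recruited, retention)
    n_recruited: int | None = None
    retention: float = 204 / 304

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("hijab_proportion", "sunscreen_proportion", "retention",
                     "below_detection_mass", "hijab_socks_proportion"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.resolved_exposure_weight() > 1:
            raise ValueError(
                f"target rank correlation {self.target_rank_correlation} is "
                "infeasible: implied dose weight exceeds 1"
            )

    def resolved_exposure_weight(self) -> float:
        if self.exposure_weight is not None:
            return self.exposure_weight
        return self.target_rank_correlation / _RHO_PER_UNIT_WEIGHT


@dataclass(frozen=True)
class IntensityGeneratorConfig:
    """Smooth unimodal diurnal UVB profiles: zero at night, midday peak."""

    months: Sequence[str] = _FIXTURE_MONTHS
    peak_w_m2: Mapping[str, float] | float = 12.0
    peak_hour: float = 12.5
    spread_hours: float = 3.0
    noise_sd: float = 0.0
    daytime: tuple[int, int] = (6, 18)

    def peak_for(self, month: str) -> float:
        if isinstance(self.peak_w_m2, Mapping):
            return float(self.peak_w_m2[month])
        return float(self.peak_w_m2)

    def __post_init__(self) -> None:
        peaks = (
            self.peak_w_m2.values()
            if isinstance(self.peak_w_m2, Mapping)
            else [self.peak_w_m2]
        )
        if any(p < 0 for p in peaks):
            raise ValueError("peak intensity must be >= 0")


#: short aliases for the packaged tables (first and third data tables of
#: the study design: clothing scoring and hourly intensity)
_FIXTURE_ALIASES = {"table1": "ensembles", "table3": "intensity"}


def load_fixture(name: str):
    """Load a packaged data table.

    ``ensembles`` (alias ``table1``) — the five canonical clothing
    ensembles with exposed segments and percentages (DataFrame);
    ``intensity`` (alias ``table3``) — the measured hourly UVB intensity
    series (IntensitySeries).  Comma decimals in the files are normalized
    to dot decimals on load.
    """
    files = {
        "ensembles": "clothing_ensembles.csv",
        "intensity": "hourly_uvb_intensity.csv",
    }
    name = _FIXTURE_ALIASES.get(name, name)
    if name not in files:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(files)}")
    ref = resources.files("sundose.data").joinpath(files[name])
    with ref.open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh, dtype=str)
    if name == "ensembles":
        frame["exposed_percentage"] = (
            frame["exposed_percentage"].str.replace(",", ".", regex=False).astype(float)
        )
        frame["hijab"] = frame["hijab"].map({"True": True, "False": False})
        frame["socks"] = frame["socks"].map({"True": True, "False": False})
        return frame
    frame["hour_start"] = frame["hour_start"].astype(int)
    frame["intensity_w_m2"] = (
        frame["intensity_w_m2"].str.replace(",", ".", regex=False).astype(float)
    )
    return IntensitySeries.from_frame(frame)


def _draw_levels(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    levels = list(probs)
    p = np.asarray([probs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


_AGE_RANGES = {"<20": (16.0, 20.0), "20-34": (20.0, 35.0), ">=35": (35.0, 44.0)}
_BMI_RANGES = {
    "underweight": (16.0, 18.5), "normal": (18.5, 25.0),
    "overweight": (25.0, 30.0), "obese": (30.0, 36.0),
}


def _month_mean_midday_rate(
    series: IntensitySeries, month: str, window: tuple[int, int], med: MedParameters
) -> float:
    hours = range(window[0], window[1])
    return float(
        np.mean([watt_to_med_rate(series.intensity(month, h), med) for h in hours])
    )


def _serum_marginal_ppf(u: np.ndarray, cfg: CohortGeneratorConfig) -> np.ndarray:
    """Quantile function of the serum marginal (pre-censoring).

    The lowest ``below_detection_mass`` of probability maps linearly into
    (0, 8.1) — the exact sub-detection values are unobservable and are
    floored to 8.0 downstream — and the rest follows the left-truncated
    lognormal component.
    """
    p0 = cfg.below_detection_mass
    dist = stats.lognorm(s=cfg.serum_lognorm_sigma, scale=np.exp(cfg.serum_lognorm_mu))
    fc = dist.cdf(DETECTION_LIMIT_NG_ML)
    out = np.empty_like(u)
    low = u < p0
    out[low] = DETECTION_LIMIT_NG_ML * u[low] / p0
    out[~low] = dist.ppf(fc + (1.0 - fc) * (u[~low] - p0) / (1.0 - p0))
    return out


def _normal_scores(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Blom normal scores of the value ranks (average ranks for ties)."""
    ranks = stats.rankdata(values, method="average")
    n = len(values)
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def generate_cohort(
    config: CohortGeneratorConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cohort table and its activity diary.

    Returns ``(cohort, diary)`` DataFrames.  Cohort columns: id, age,
    age_group, parity, bmi, bmi_class, education, occupation, hijab,
    sunscreen, height_cm, weight_kg, ensemble_id, month, serum_25ohd,
    below_detection, status.  Diary columns: participant_id, date,
    start_time, duration_min, ensemble_id.
    """
    cfg = config or CohortGeneratorConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n
    if cfg.n_recruited is not None:
        n = int(rng.binomial(cfg.n_recruited, cfg.retention))

    ids = [f"P{i:04d}" for i in range(1, n + 1)]
    age_group = _draw_levels(rng, cfg.age_group_probs, n)
    age = np.array([rng.uniform(*_AGE_RANGES[g]) for g in age_group]).round(1)
    parity = _draw_levels(rng, cfg.parity_probs, n)
    bmi_class = _draw_levels(rng, cfg.bmi_class_probs, n)
    bmi = np.array([rng.uniform(*_BMI_RANGES[c]) for c in bmi_class]).round(1)
    education = _draw_levels(rng, cfg.education_probs, n)
    occupation = _draw_levels(rng, cfg.occupation_probs, n)
    hijab = rng.random(n) < cfg.hijab_proportion
    sunscreen = rng.random(n) < cfg.sunscreen_proportion
    height = np.clip(rng.normal(cfg.height_mean_cm, cfg.height_sd_cm, n), 140, 175).round(1)
    weight = (bmi * (height / 100.0) ** 2).round(1)

    nonhijab_ids = list(cfg.nonhijab_ensemble_probs)
    nonhijab_p = np.asarray([cfg.nonhijab_ensemble_probs[k] for k in nonhijab_ids], float)
    nonhijab_p /= nonhijab_p.sum()
    ensemble_id = np.where(
        hijab,
        np.where(rng.random(n) < cfg.hijab_socks_proportion, "hijab-socks", "hijab"),
        rng.choice(nonhijab_ids, size=n, p=nonhijab_p),
    )
    month = rng.choice(list(cfg.months), size=n)

    diary_rows, inwindow_daily_min = _generate_diaries(
        rng, cfg, ids, ensemble_id, month
    )

    # latent daily UVB dose driving serum level
    med = MedParameters(cfg.med_threshold_j_m2)
    series = load_fixture("intensity")
    month_rate = {
        m: _month_mean_midday_rate(series, m, cfg.midday_window, med)
        for m in cfg.months
    }
    area = np.array(
        [
            exposed_area(
                BodyMeasurements(h, w), CANONICAL_ENSEMBLES[e]
            ).exposed_area_m2
            for h, w, e in zip(height, weight, ensemble_id)
        ]
    )
    dose = area * inwindow_daily_min * np.array([month_rate[m] for m in month])

    w = cfg.resolved_exposure_weight()
    z = w * _normal_scores(dose, rng) + np.sqrt(max(0.0, 1.0 - w * w)) * rng.standard_normal(n)
    u = stats.norm.cdf(z)
    raw_serum = _serum_marginal_ppf(u, cfg)
    censored = [apply_detection_limit(v) for v in raw_serum]
    serum = np.array([c[0] for c in censored]).round(1)
    below = np.array([c[1] for c in censored])
    status = [classify_status(v) for v in serum]

    cohort = pd.DataFrame(
        {
            "id": ids,
            "age": age,
            "age_group": age_group,
            "parity": parity,
            "bmi": bmi,
            "bmi_class": bmi_class,
            "education": education,
            "occupation": occupation,
            "hijab": hijab,
            "sunscreen": sunscreen,
            "height_cm": height,
            "weight_kg": weight,
            "ensemble_id": ensemble_id,
            "month": month,
            "serum_25ohd": serum,
            "below_detection": below,
            "status": status,
        }
    )
    diary = pd.DataFrame(
        diary_rows,
        columns=["participant_id", "date", "start_time", "duration_min", "ensemble_id"],
    )
    return cohort, diary


def _generate_diaries(rng, cfg, ids, ensemble_id, month):
    """Bout-structured 3-day diaries; returns rows and mean daily midday minutes."""
    mean_bout = (cfg.bout_min_minutes + cfg.bout_max_minutes) / 2.0
    bouts_per_day = cfg.outdoor_total_mean_min / mean_bout
    p_window = cfg.inwindow_mean_min / cfg.outdoor_total_mean_min
    w0, w1 = cfg.midday_window
    d0, d1 = cfg.daytime
    off_hours = (w0 - d0) + (d1 - w1)
    rows = []
    inwindow = np.zeros(len(ids))
    for i, pid in enumerate(ids):
        mnum = _MONTH_NUMBER[month[i]]
        year = 2016 if mnum >= 7 else 2017
        day0 = int(rng.integers(1, 26))
        total_in = 0.0
        for d in range(cfg.diary_days):
            date = f"{year:04d}-{mnum:02d}-{day0 + d:02d}"
            for _ in range(rng.poisson(bouts_per_day)):
                dur = int(rng.integers(cfg.bout_min_minutes, cfg.bout_max_minutes + 1))
                if rng.random() < p_window:
                    start_h = rng.uniform(w0, w1)
                    total_in += dur
                else:
                    x = rng.uniform(0, off_hours)
                    start_h = d0 + x if x < (w0 - d0) else w1 + (x - (w0 - d0))
                hh = int(start_h)
                mm = int((start_h - hh) * 60)
                rows.append((pid, date, f"{hh:02d}:{mm:02d}", dur, ensemble_id[i]))
        inwindow[i] = total_in / cfg.diary_days
    return rows, inwindow


def generate_intensity(
    config: IntensityGeneratorConfig | None = None, seed: int = 0
) -> IntensitySeries:
    """Generate a synthetic hourly UVB intensity series.

    Daytime bins follow a Gaussian bump centred on ``peak_hour`` (bin
    midpoints), optionally perturbed by truncated Gaussian noise;
    nocturnal bins are exactly zero.
    """
    cfg = config or IntensityGeneratorConfig()
    rng = np.random.default_rng(seed)
    d0, d1 = cfg.daytime
    frame_rows = []
    for m in cfg.months:
        peak = cfg.peak_for(m)
        for h in range(24):
            if d0 <= h < d1:
                centre = h + 0.5
                v = peak * np.exp(-((centre - cfg.peak_hour) ** 2) / (2 * cfg.spread_hours**2))
                if cfg.noise_sd > 0:
                    v = max(0.0, v + rng.normal(0.0, cfg.noise_sd))
            else:
                v = 0.0
            frame_rows.append({"month": m, "hour_start": h, "intensity_w_m2": v})
    return IntensitySeries.from_frame(pd.DataFrame(frame_rows))


def simulate_multinomial(
    n: int,
    coefs: np.ndarray,
    seed: int = 0,
    *,
    categories: Sequence[str] = ("normal", "deficient", "insufficient"),
) -> pd.DataFrame:
    """Draw outcomes from a known multinomial-logit model (base = first category).

    ``coefs`` has shape (1 + k, m): an intercept row plus k covariate rows,
    one column per non-base category.  Covariates are standard normal,
    named x1..xk.  Returns a DataFrame with covariates and a ``status``
    column — the ground truth for parameter-recovery checks.
    """
    coefs = np.asarray(coefs, dtype=float)
    k = coefs.shape[0] - 1
    m = coefs.shape[1]
    if m != len(categories) - 1:
        raise ValueError("coefs must have one column per non-base category")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k))
    design = np.hstack([np.ones((n, 1)), X])
    logits = np.hstack([np.zeros((n, 1)), design @ coefs])
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    codes = (rng.random(n)[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    frame = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(k)])
    frame["status"] = [categories[c] for c in codes]
    return frame
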