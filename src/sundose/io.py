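"""CSV input/output, validation, and the full-pipeline analysis report.

All files are UTF-8 CSVs with a mandatory header row and dot-decimal
numbers; comma decimals (common in source tables from locales that print
"13,5") are normalized on read.  Validation errors carry the 1-based data
row number of the offending value.

``run_full_analysis`` binds the pipeline end to end: read and validate
inputs, derive per-participant exposure covariates, run the descriptive /
contingency / correlation / regression battery, locate the optimal
exposure window, and derive per-ensemble minimum-duration recommendations.
The report embeds every tunable parameter, and regenerating it from the
same inputs and config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anthropometry import CANONICAL_ENSEMBLES
from .cohort import (
    EmptyCohortError,
    STATUS_CATEGORIES,
    apply_detection_limit,
    build_contingency,
    chi_square_test,
    classify_status,
    format_p_value,
    multinomial_logit,
    participant_exposures,
    spearman_correlation,
    summarize_cohort,
)
from .dosimetry import (
    IntensitySeries,
    MedParameters,
    RecommendationParameters,
    adjusted_duration_for_clothing,
    lowest_month,
    minimum_exposure_duration,
    peak_window,
)

__all__ = [
    "ValidationError",
    "PipelineStageError",
    "RunConfig",
    "AnalysisReport",
    "read_intensity",
    "read_diary",
    "read_cohort",
    "write_frame",
    "run_full_analysis",
    "write_report",
]

logger = logging.getLogger("sundose")


class ValidationError(ValueError):
    """An input file failed schema or value validation."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def _to_float(frame: pd.DataFrame, col: str, path) -> pd.Series:
    """Parse a column as float, normalizing comma decimals; row-tagged errors."""
    raw = frame[col].astype(str).str.replace(",", ".", regex=False)
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & frame[col].notna()
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ValidationError(
            f"{path}: column {col!r} row {row}: cannot parse {frame[col][bad.idxmax()]!r}"
        )
    return values.astype(float)


def read_intensity(path, *, strict: bool = False) -> IntensitySeries:
    """Read an hourly intensity CSV (month, hour_start, intensity_w_m2)."""
    frame = pd.read_csv(path, dtype=str)
    _require_columns(frame, ["month", "hour_start", "intensity_w_m2"], path)
    frame["hour_start"] = _to_float(frame, "hour_start", path).astype(int)
    frame["intensity_w_m2"] = _to_float(frame, "intensity_w_m2", path)
    neg = frame["intensity_w_m2"] < 0
    if neg.any():
        raise ValidationError(
            f"{path}: negative intensity at row {int(neg.idxmax()) + 1}"
        )
    return IntensitySeries.from_frame(frame, strict=strict)


def read_diary(path) -> pd.DataFrame:
    """Read an activity diary CSV; validates times, durations and ensembles."""
    frame = pd.read_csv(path, dtype=str)
    _require_columns(
        frame, ["participant_id", "date", "start_time", "duration_min", "ensemble_id"], path
    )
    frame["duration_min"] = _to_float(frame, "duration_min", path)
    bad = frame["duration_min"] <= 0
    if bad.any():
        raise ValidationError(
            f"{path}: non-positive duration at row {int(bad.idxmax()) + 1}"
        )
    ok_time = frame["start_time"].str.match(r"^([01]?\d|2[0-3]):[0-5]\d$")
    if not ok_time.all():
        raise ValidationError(
            f"{path}: invalid start_time at row {int((~ok_time).idxmax()) + 1}"
        )
    unknown = ~frame["ensemble_id"].isin(CANONICAL_ENSEMBLES)
    if unknown.any():
        raise ValidationError(
            f"{path}: unknown ensemble_id "
            f"{frame['ensemble_id'][unknown.idxmax()]!r} at row {int(unknown.idxmax()) + 1}"
        )
    frame["duration_min"] = frame["duration_min"].astype(float)
    return frame


_COHORT_VOCABULARIES: Mapping[str, tuple[str, ...]] = {
    "age_group": ("<20", "20-34", ">=35"),
    "parity": ("0", "1", ">=2"),
    "bmi_class": ("underweight", "normal", "overweight", "obese"),
    "education": ("elementary", "middle", "high", "diploma/bachelor"),
    "occupation": ("housewife", "civil servant", "others"),
}


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV and derive censored serum level and status.

    Raw serum values are passed through the assay detection limit (values
    below 8.1 ng/mL stored as 8.0 and flagged) and classified into status
    categories.  Categorical levels are checked against their declared
    vocabularies.
    """
    frame = pd.read_csv(path, dtype=str)
    _require_columns(frame, ["id", "height_cm", "weight_kg", "serum_25ohd"], path)
    for col in ("height_cm", "weight_kg", "serum_25ohd", "age", "bmi"):
        if col in frame.columns:
            frame[col] = _to_float(frame, col, path)
    for col, vocab in _COHORT_VOCABULARIES.items():
        if col not in frame.columns:
            continue
        bad = ~frame[col].isin(vocab)
        if bad.any():
            raise ValidationError(
                f"{path}: column {col!r} row {int(bad.idxmax()) + 1}: "
                f"unknown level {frame[col][bad.idxmax()]!r} (expected one of {vocab})"
            )
    for col in ("hijab", "sunscreen"):
        if col in frame.columns:
            mapped = frame[col].str.lower().map(
                {"true": True, "false": False, "1": True, "0": False,
                 "yes": True, "no": False}
            )
            if mapped.isna().any():
                raise ValidationError(
                    f"{path}: column {col!r} row {int(mapped.isna().idxmax()) + 1}: "
                    "expected a boolean"
                )
            frame[col] = mapped.astype(bool)
    neg = frame["serum_25ohd"] < 0
    if neg.any():
        raise ValidationError(
            f"{path}: negative serum level at row {int(neg.idxmax()) + 1}"
        )
    censored = frame["serum_25ohd"].map(apply_detection_limit)
    frame["serum_25ohd"] = censored.map(lambda c: c[0])
    frame["below_detection"] = censored.map(lambda c: c[1])
    frame["status"] = frame["serum_25ohd"].map(classify_status)
    return frame


def write_frame(frame: pd.DataFrame, path) -> None:
    """Write a DataFrame as a dot-decimal UTF-8 CSV (round-trips with readers)."""
    frame.to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Inputs and tunables of the full pipeline run."""

    cohort_path: str
    diary_path: str
    intensity_path: str
    med_threshold_j_m2: float | None = None
    med_rate_override: float | None = None
    holick_fraction: float = 0.25
    reference_percentage: float = 22.5
    time_rounding: str = "half-hour-down"
    ridge: float | None = None
    peak_window_hours: int = 3
    confounders: tuple[str, ...] = ("age", "parity", "bmi", "education", "sunscreen")
    exposures: tuple[str, ...] = ("exposed_area_m2", "exposed_pct", "mean_med_rate")

    def __post_init__(self) -> None:
        if (self.med_threshold_j_m2 is None) == (self.med_rate_override is None):
            raise ValueError(
                "exactly one of med_threshold_j_m2 / med_rate_override is required"
            )


@dataclass
class AnalysisReport:
    """Tables mirroring the cohort-study layout plus the recommendation summary."""

    config: dict
    summary: dict
    characteristics: pd.DataFrame
    correlations: pd.DataFrame
    models: pd.DataFrame
    recommendation: dict


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("characteristics")
def _characteristics_table(cohort: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for covariate in ("sunscreen", "age_group", "education", "occupation",
                      "bmi_class", "parity", "hijab"):
        if covariate not in cohort.columns:
            continue
        levels = _COHORT_VOCABULARIES.get(covariate)
        table = build_contingency(cohort, covariate, levels=levels)
        result = chi_square_test(table)
        for level, counts in table.iterrows():
            rows.append(
                {
                    "covariate": covariate,
                    "level": str(level),
                    **{c: int(counts[c]) for c in STATUS_CATEGORIES},
                    "total": int(counts.sum()),
                    "p_value": result.p_value,
                    "p_display": format_p_value(result.p_value),
                    "small_expected": result.small_expected,
                }
            )
    return pd.DataFrame(rows)


@_stage("correlations")
def _correlation_table(cohort, exposures_frame, exposure_cols) -> pd.DataFrame:
    rows = []
    serum = cohort["serum_25ohd"].to_numpy()
    for col in exposure_cols:
        if col not in exposures_frame.columns:
            continue
        res = spearman_correlation(exposures_frame[col].to_numpy(), serum)
        rows.append(
            {
                "exposure": col,
                "rho": res.rho,
                "p_value": res.p_value,
                "p_display": format_p_value(res.p_value),
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


@_stage("models")
def _model_table(cohort, exposures_frame, exposure_cols, confounders, ridge) -> pd.DataFrame:
    merged = cohort.merge(exposures_frame, on="id")
    confounders = [c for c in confounders if c in merged.columns]
    rows = []
    for col in exposure_cols:
        if col not in merged.columns:
            continue
        crude = multinomial_logit(merged, [col], ridge=ridge)
        adjusted = multinomial_logit(merged, [col], confounders, ridge=ridge)
        for cat in [c for c in STATUS_CATEGORIES if c != "normal"]:
            c_row = crude.table.loc[(cat, col)]
            a_row = adjusted.table.loc[(cat, col)]
            rows.append(
                {
                    "exposure": col,
                    "outcome": cat,
                    "cOR": c_row["odds_ratio"],
                    "cOR_ci_low": c_row["ci_low"],
                    "cOR_ci_high": c_row["ci_high"],
                    "cOR_p": c_row["p_value"],
                    "aOR": a_row["odds_ratio"],
                    "aOR_ci_low": a_row["ci_low"],
                    "aOR_ci_high": a_row["ci_high"],
                    "aOR_p": a_row["p_value"],
                    "crude_separation": crude.separation,
                    "adjusted_separation": adjusted.separation,
                }
            )
    return pd.DataFrame(rows)


@_stage("recommendation")
def _recommendation_summary(series, exposures_frame, config) -> dict:
    params = RecommendationParameters(
        holick_fraction=config.holick_fraction,
        reference_percentage=config.reference_percentage,
        time_rounding=config.time_rounding,  # type: ignore[arg-type]
        med_rate_override=config.med_rate_override,
    )
    windows = {
        m: peak_window(series, m, config.peak_window_hours) for m in series.months
    }
    if config.med_rate_override is not None:
        rate = config.med_rate_override
        rate_source = "med_rate_override"
    else:
        rate = float(np.median(exposures_frame["mean_med_rate"]))
        rate_source = "cohort median of diary-window MED rates"
    base = minimum_exposure_duration(rate, params)
    from .anthropometry import exposed_percentage

    durations = {
        eid: adjusted_duration_for_clothing(
            base, exposed_percentage(CANONICAL_ENSEMBLES[eid]), params
        )
        for eid in CANONICAL_ENSEMBLES
    }
    return {
        "peak_window_by_month": {m: list(w) for m, w in windows.items()},
        "lowest_month": lowest_month(series),
        "med_rate_med_per_hour": rate,
        "med_rate_source": rate_source,
        "reference_minimum_minutes": base,
        "minutes_by_ensemble": durations,
    }


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Run the whole pipeline and assemble the analysis report."""
    try:
        cohort = read_cohort(config.cohort_path)
        diary = read_diary(config.diary_path)
        series = read_intensity(config.intensity_path)
    except ValidationError as exc:
        raise PipelineStageError("input", str(exc)) from exc
    if cohort.empty:
        raise PipelineStageError("cohort", "cohort file contains no records")
    logger.info(
        "inputs: cohort=%d diary=%d months=%d", len(cohort), len(diary), len(series.months)
    )

    med = (
        MedParameters(config.med_threshold_j_m2)
        if config.med_threshold_j_m2 is not None
        else None
    )
    try:
        exposures_frame = participant_exposures(cohort, diary, series if med else None, med)
    except EmptyCohortError as exc:
        raise PipelineStageError("exposure", str(exc)) from exc
    if "mean_med_rate" not in exposures_frame.columns:
        exposure_cols = tuple(c for c in config.exposures if c != "mean_med_rate")
    else:
        exposure_cols = config.exposures

    summary = summarize_cohort(cohort)
    characteristics = _characteristics_table(cohort)
    correlations = _correlation_table(cohort, exposures_frame, exposure_cols)
    models = _model_table(cohort, exposures_frame, exposure_cols,
                          config.confounders, config.ridge)
    recommendation = _recommendation_summary(series, exposures_frame, config)
    logger.info(
        "analysis: %d characteristic rows, %d correlations, %d model rows",
        len(characteristics), len(correlations), len(models),
    )
    return AnalysisReport(
        config=asdict(config),
        summary=summary,
        characteristics=characteristics,
        correlations=correlations,
        models=models,
        recommendation=recommendation,
    )


def write_report(report: AnalysisReport, out_dir) -> None:
    """Write the report as CSV tables plus a JSON bundle (deterministic)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.characteristics.to_csv(out / "characteristics.csv", index=False)
    report.correlations.to_csv(out / "correlations.csv", index=False)
    report.models.to_csv(out / "models.csv", index=False)
    bundle = {
        "config": report.config,
        "summary": report.summary,
        "recommendation": report.recommendation,
    }
    (out / "report.json").write_text(
        json.dumps(bundle, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
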