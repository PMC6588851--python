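"""Vitamin D status classification and cohort statistics.

Serum 25-hydroxyvitamin D (ng/mL) is censored at the assay detection limit
(readings below 8.1 ng/mL are stored as 8.0 and flagged) and classified
into deficient (< 20), insufficient (20–30) and normal (>= 30) status.

The statistical battery mirrors a standard observational-cohort analysis:

* covariate-by-status contingency tables with Pearson chi-square tests
  (no continuity correction, with a small-expected-count warning and an
  optional Monte Carlo permutation p-value);
* Spearman rank correlations of exposure measures with the censored serum
  level (average ranks, so the heavy ties produced by the assay floor are
  handled correctly);
* multinomial logistic regression of status on exposure measures, crude
  and adjusted for a priori confounders, with the normal category as base.
  Quasi-separation — a known failure mode when a category has only a
  handful of members — is detected and reported rather than silently
  emitting astronomical odds ratios; an L2 (ridge) penalized fit is
  available as a stabilized alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .anthropometry import (
    BodyMeasurements,
    CANONICAL_ENSEMBLES,
    exposed_area,
)
from .dosimetry import IntensitySeries, MedParameters, accumulate_dose

__all__ = [
    "DETECTION_LIMIT_NG_ML",
    "DETECTION_FLOOR_NG_ML",
    "STATUS_CATEGORIES",
    "ChiSquareResult",
    "CorrelationResult",
    "MultinomialModelResult",
    "EmptyCohortError",
    "DegenerateTableError",
    "apply_detection_limit",
    "classify_status",
    "build_contingency",
    "chi_square_test",
    "spearman_correlation",
    "multinomial_logit",
    "summarize_cohort",
    "participant_exposures",
    "format_p_value",
]

#: Assay detection limit: readings below this are not quantifiable.
DETECTION_LIMIT_NG_ML = 8.1
#: Value stored for sub-detection readings.
DETECTION_FLOOR_NG_ML = 8.0

#: Status categories in severity order; cutoffs are half-open intervals
#: [0, 20), [20, 30), [30, inf) so every nonnegative level is classified.
STATUS_CATEGORIES = ("deficient", "insufficient", "normal")

_SEPARATION_COEF_LIMIT = 15.0  # |log-OR| beyond this flags quasi-separation

MONTH_NAMES = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)


class EmptyCohortError(ValueError):
    """An operation requiring records received an empty cohort."""


class DegenerateTableError(ValueError):
    """A contingency table has a zero row or column margin."""


def apply_detection_limit(raw_level: float) -> tuple[float, bool]:
    """Censor a raw serum 25-OH-D reading at the assay detection limit.

    Readings below 8.1 ng/mL are recorded as 8.0 with ``below_detection``
    True; others pass through unchanged.
    """
    if raw_level < 0:
        raise ValueError(f"serum level must be >= 0, got {raw_level}")
    if raw_level < DETECTION_LIMIT_NG_ML:
        return DETECTION_FLOOR_NG_ML, True
    return raw_level, False


def classify_status(level_ng_ml: float) -> str:
    """Vitamin D status category for a serum 25-OH-D level (ng/mL)."""
    if level_ng_ml < 0:
        raise ValueError(f"serum level must be >= 0, got {level_ng_ml}")
    if level_ng_ml < 20.0:
        return "deficient"
    if level_ng_ml < 30.0:
        return "insufficient"
    return "normal"


def build_contingency(
    records: pd.DataFrame,
    covariate: str,
    *,
    status_col: str = "status",
    levels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Covariate-level × status contingency table of record counts.

    Rows are covariate levels (in ``levels`` order if given, else order of
    first appearance), columns the three status categories; every status
    column is present even when empty.
    """
    if covariate not in records.columns and not records.empty:
        raise KeyError(f"unknown covariate {covariate!r}")
    if records.empty:
        idx = list(levels) if levels else []
        return pd.DataFrame(0, index=idx, columns=list(STATUS_CATEGORIES))
    if levels is None:
        levels = list(pd.unique(records[covariate]))
    table = pd.crosstab(records[covariate], records[status_col])
    table = table.reindex(index=levels, columns=list(STATUS_CATEGORIES), fill_value=0)
    return table.astype(int)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray = field(repr=False)
    small_expected: bool = False
    monte_carlo_p: float | None = None


def chi_square_test(
    table: pd.DataFrame | np.ndarray,
    *,
    monte_carlo: bool = False,
    n_resamples: int = 9999,
    seed: int | None = None,
) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction.

    Warns (and sets ``small_expected``) when any expected count is below 5.
    With ``monte_carlo=True`` an exact-style p-value is additionally
    estimated by resampling tables with fixed margins.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DegenerateTableError("table must have at least 2 rows and 2 columns")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DegenerateTableError("table has a zero row or column margin")
    stat, p, dof, expected = stats.chi2_contingency(counts, correction=False)
    small = bool((expected < 5).any())
    if small:
        warnings.warn(
            "expected count below 5 in at least one cell; the chi-square "
            "approximation may be poor (consider monte_carlo=True)",
            stacklevel=2,
        )
    mc_p = None
    if monte_carlo:
        rng = np.random.default_rng(seed)
        rvs = stats.random_table(
            counts.sum(axis=1).astype(int), counts.sum(axis=0).astype(int)
        ).rvs(n_resamples, random_state=rng)
        row = counts.sum(axis=1, keepdims=True)
        col = counts.sum(axis=0, keepdims=True)
        exp = row @ col / counts.sum()
        sim_stats = ((rvs - exp) ** 2 / exp).sum(axis=(1, 2))
        mc_p = float((1 + (sim_stats >= stat - 1e-12).sum()) / (1 + n_resamples))
    return ChiSquareResult(
        statistic=float(stat),
        df=int(dof),
        p_value=float(p),
        expected=expected,
        small_expected=small,
        monte_carlo_p=mc_p,
    )


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    undefined: bool = False


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Ties — including the heavy lower-tail ties produced by the assay
    detection floor — share average ranks.  A constant vector makes the
    correlation undefined; the result is flagged rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need n >= 3, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(rho=float("nan"), p_value=float("nan"), n=x.size, undefined=True)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=int(x.size))


def format_p_value(p: float) -> str:
    """Report-style p-value: 2 decimals, 3 below 0.01, '<0.001' below that."""
    if np.isnan(p):
        return "NA"
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return f"{p:.3f}"
    return f"{p:.2f}"


# ---------------------------------------------------------------------------
# Multinomial logistic regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MultinomialModelResult:
    """Coefficients and odds ratios per non-base status category.

    ``table`` is indexed by (category, term) with columns coef, odds_ratio,
    ci_low, ci_high, p_value; the base category carries no rows.
    """

    table: pd.DataFrame
    base: str
    converged: bool
    separation: bool
    ridge: float | None = None

    def odds_ratio(self, category: str, term: str) -> float:
        return float(self.table.loc[(category, term), "odds_ratio"])


def _design_matrix(
    records: pd.DataFrame, terms: Sequence[str]
) -> pd.DataFrame:
    """Intercept + numeric columns as-is + dummy-coded categoricals."""
    parts = [pd.Series(1.0, index=records.index, name="intercept")]
    for term in terms:
        col = records[term]
        if pd.api.types.is_bool_dtype(col):
            parts.append(col.astype(float).rename(term))
        elif pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col, prefix=term, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def _penalized_multinomial_fit(
    X: np.ndarray, y_codes: np.ndarray, n_cat: int, ridge: float
):
    """Ridge-penalized multinomial ML fit (base = category 0).

    Minimizes the negative log-likelihood plus ``ridge/2 * ||B||²`` over
    the non-intercept coefficients.  Standard errors come from the inverse
    of the penalized Hessian (a regularized, slightly conservative
    approximation).
    """
    from scipy.optimize import minimize
    from scipy.special import logsumexp

    n, k = X.shape
    m = n_cat - 1
    Y = np.zeros((n, n_cat))
    Y[np.arange(n), y_codes] = 1.0
    pen_mask = np.ones(k)
    pen_mask[0] = 0.0  # intercept unpenalized

    def unpack(theta):
        return theta.reshape(k, m)

    def nll_grad(theta):
        B = unpack(theta)
        logits = np.hstack([np.zeros((n, 1)), X @ B])
        lse = logsumexp(logits, axis=1)
        ll = (logits[np.arange(n), y_codes] - lse).sum()
        P = np.exp(logits - lse[:, None])
        grad = X.T @ (P[:, 1:] - Y[:, 1:]) + ridge * (pen_mask[:, None] * B)
        pen = 0.5 * ridge * ((pen_mask[:, None] * B) ** 2).sum()
        return -ll + pen, grad.ravel()

    res = minimize(
        nll_grad, np.zeros(k * m), jac=True, method="L-BFGS-B",
        options={"maxiter": 5000, "ftol": 1e-10, "gtol": 1e-6},
    )
    B = unpack(res.x)
    # penalized observed information
    logits = np.hstack([np.zeros((n, 1)), X @ B])
    P = np.exp(logits - logsumexp(logits, axis=1)[:, None])
    H = np.zeros((k * m, k * m))
    for a in range(m):
        for b in range(m):
            w = P[:, a + 1] * ((1.0 if a == b else 0.0) - P[:, b + 1])
            H[a * k : (a + 1) * k, b * k : (b + 1) * k] = (X * w[:, None]).T @ X
    H += ridge * np.kron(np.eye(m), np.diag(pen_mask))
    cov = np.linalg.inv(H)
    # cov is ordered category-major (m blocks of k); reshape SEs to (k, m)
    se = np.sqrt(np.diag(cov)).reshape(m, k).T
    return B, se, bool(res.success)


def multinomial_logit(
    records: pd.DataFrame,
    exposures: Sequence[str],
    confounders: Sequence[str] = (),
    *,
    base: str = "normal",
    status_col: str = "status",
    ridge: float | None = None,
) -> MultinomialModelResult:
    """Multinomial logistic regression of status on exposure measures.

    The crude model passes a single exposure and no confounders; the
    adjusted model adds the a priori confounder list.  Categorical
    confounders are dummy-coded against their first observed level.  With
    ``ridge`` set, an L2-penalized fit replaces plain maximum likelihood —
    the stabilized alternative when quasi-separation drives unpenalized
    odds ratios to extremes.
    """
    import statsmodels.api as sm

    present = set(records[status_col].unique()) if len(records) else set()
    missing = [c for c in STATUS_CATEGORIES if c not in present]
    if missing:
        raise EmptyCohortError(
            f"status categories absent from data: {missing}; model inestimable"
        )
    if base not in STATUS_CATEGORIES:
        raise ValueError(f"unknown base category {base!r}")

    categories = [base] + [c for c in STATUS_CATEGORIES if c != base]
    y_codes = pd.Categorical(
        records[status_col], categories=categories
    ).codes.astype(int)
    X = _design_matrix(records, list(exposures) + list(confounders))
    const_cols = [c for c in X.columns[1:] if X[c].nunique() <= 1]
    if const_cols and ridge is None:
        raise ValueError(
            f"zero-variance regressors {const_cols}; design matrix is rank "
            "deficient (a ridge penalty can stabilize this)"
        )

    terms = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if ridge is not None:
        B, se, converged = _penalized_multinomial_fit(Xv, y_codes, len(categories), ridge)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MNLogit(y_codes, Xv)
            fit = model.fit(method="newton", maxiter=200, disp=0)
            B = np.asarray(fit.params)  # (k, m)
            se = np.asarray(fit.bse)
            if se.ndim == 1:
                se = se.reshape(B.shape[::-1]).T
            converged = bool(fit.mle_retvals.get("converged", True))

    z = stats.norm.ppf(0.975)
    rows = []
    with np.errstate(over="ignore", invalid="ignore"):
        for j, cat in enumerate(categories[1:]):
            for i, term in enumerate(terms):
                coef, s = float(B[i, j]), float(se[i, j])
                zstat = coef / s if s > 0 else np.nan
                rows.append(
                    {
                        "category": cat,
                        "term": term,
                        "coef": coef,
                        "se": s,
                        "odds_ratio": float(np.exp(coef)),
                        "ci_low": float(np.exp(coef - z * s)),
                        "ci_high": float(np.exp(coef + z * s)),
                        "p_value": float(2 * stats.norm.sf(abs(zstat))) if s > 0 else np.nan,
                    }
                )
    table = pd.DataFrame(rows).set_index(["category", "term"])
    with np.errstate(invalid="ignore"):
        blown_up = bool((np.abs(B) > _SEPARATION_COEF_LIMIT).any())
    degenerate = bool(np.isnan(B).any() or np.isnan(se).any())
    separation = blown_up or degenerate or not converged
    return MultinomialModelResult(
        table=table, base=base, converged=converged, separation=separation, ridge=ridge
    )


# ---------------------------------------------------------------------------
# Descriptive summary and per-participant exposure covariates
# ---------------------------------------------------------------------------

CATEGORICAL_COLUMNS = (
    "age_group", "parity", "bmi_class", "education", "occupation",
    "hijab", "sunscreen", "ensemble_id",
)
CONTINUOUS_COLUMNS = ("age", "bmi", "height_cm", "weight_kg", "serum_25ohd")


def summarize_cohort(records: pd.DataFrame) -> dict:
    """Descriptive summary: frequencies/proportions, mean (SD), median (IQR).

    Also reports status-category proportions and the below-detection
    proportion when the corresponding columns are present.
    """
    if records.empty:
        raise EmptyCohortError("cannot summarize an empty cohort")
    n = len(records)
    out: dict = {"n": n, "categorical": {}, "continuous": {}}
    for col in CATEGORICAL_COLUMNS:
        if col not in records.columns:
            continue
        counts = records[col].value_counts(sort=False)
        out["categorical"][col] = {
            str(level): {"count": int(c), "proportion": float(c / n)}
            for level, c in counts.items()
        }
    for col in CONTINUOUS_COLUMNS:
        if col not in records.columns:
            continue
        v = records[col].astype(float)
        q1, q3 = v.quantile([0.25, 0.75])
        out["continuous"][col] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if n > 1 else 0.0,
            "median": float(v.median()),
            "iqr": float(q3 - q1),
        }
    if "status" in records.columns:
        counts = records["status"].value_counts()
        out["status"] = {
            cat: {"count": int(counts.get(cat, 0)), "proportion": float(counts.get(cat, 0) / n)}
            for cat in STATUS_CATEGORIES
        }
    if "below_detection" in records.columns:
        out["below_detection_proportion"] = float(records["below_detection"].mean())
    return out


def _month_of(date_str: str) -> str:
    return MONTH_NAMES[int(str(date_str)[5:7]) - 1]


def _parse_clock(t: str) -> float:
    hh, mm = str(t).split(":")
    return int(hh) + int(mm) / 60.0


def participant_exposures(
    cohort: pd.DataFrame,
    diary: pd.DataFrame,
    series: IntensitySeries | None = None,
    med_params: MedParameters | None = None,
) -> pd.DataFrame:
    """Per-participant exposure covariates for the correlation/regression stage.

    For each participant: TBSA (Mosteller), exposed percentage and exposed
    TBSA (m²) from the modal diary clothing ensemble, and — when an
    intensity series and MED threshold are supplied — the duration-weighted
    mean MED/hour rate over the diary's exposure windows.
    """
    if cohort.empty:
        raise EmptyCohortError("cohort is empty")
    rows = []
    diary_by_id = dict(tuple(diary.groupby("participant_id"))) if len(diary) else {}
    for rec in cohort.itertuples(index=False):
        entries = diary_by_id.get(rec.id)
        if entries is None or entries.empty:
            modal = getattr(rec, "ensemble_id", None)
            if modal is None:
                raise ValueError(f"participant {rec.id} has no diary and no ensemble")
        else:
            modal = entries["ensemble_id"].mode(dropna=False).iloc[0]
        profile = exposed_area(
            BodyMeasurements(rec.height_cm, rec.weight_kg), CANONICAL_ENSEMBLES[modal]
        )
        row = {
            "id": rec.id,
            "tbsa_m2": profile.tbsa_m2,
            "exposed_pct": profile.exposed_percentage,
            "exposed_area_m2": profile.exposed_area_m2,
        }
        if series is not None and med_params is not None and entries is not None:
            total_minutes = 0.0
            dose_like = 0.0
            for e in entries.itertuples(index=False):
                start = _parse_clock(e.start_time)
                dur_h = float(e.duration_min) / 60.0
                month = _month_of(e.date)
                dose = accumulate_dose(
                    series, month, start, min(start + dur_h, 24.0), med_params
                )
                dose_like += dose.dose_med
                total_minutes += float(e.duration_min)
            row["mean_med_rate"] = (
                dose_like / (total_minutes / 60.0) if total_minutes > 0 else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)
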