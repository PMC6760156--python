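"""Per-feature inference: outlier screening, twin-clustered mixed models
for the ADHD contrast, and pathway-stratified FDR.

Each recurrence feature is modelled as

    y = b0 + b_ADHD*[ADHD or comorbid] + b_sex*male + b_g*gestational_days
        + b_bw*birth_weight + b_ASD*[ASD or comorbid] + u_pair + e

with a twin-pair random intercept estimated by REML.  ADHD and ASD enter
as two non-exclusive indicators, so a comorbid subject scores 1 on both
and the ADHD coefficient is the ADHD main effect adjusted for ASD.  The
ADHD p-value is a Wald z test on b_ADHD; singletons form their own
clusters.  Raw p-values are then Benjamini-Hochberg adjusted *within*
each pathway stratum (the four measures of one pathway form a stratum),
which preserves more power than pooling all 60 tests.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .errors import (
    InestimableContrastError,
    InsufficientDataError,
    ValidationError,
)
from .synthetic import Diagnosis, SubjectRecord

__all__ = [
    "MixedModelResult",
    "exclude_outliers",
    "fit_twin_mixed_model",
    "fdr_by_stratum",
    "run_feature_scan",
    "scan_frame",
]

logger = logging.getLogger(__name__)

COVARIATES = ("sex", "gestational_days", "birth_weight", "asd")


@dataclass
class MixedModelResult:
    """One feature's ADHD effect from the twin-clustered mixed model."""

    feature: str
    pathway: str
    measure: str
    beta_adhd: float = float("nan")
    se: float = float("nan")
    p_raw: float = float("nan")
    p_fdr: float = float("nan")
    covariate_betas: dict[str, float] = field(default_factory=dict)
    n_used: int = 0
    converged: bool = False
    error: str | None = None


def exclude_outliers(values, k: float = 2.0) -> np.ndarray:
    """Mask values farther than ``k`` sample SDs from the mean.

    Single pass: the mean and SD are computed once over the non-missing
    input (never re-computed after exclusion).  With zero SD nothing is
    excluded.  Returns a float array with outliers set to NaN.
    """
    vals = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(vals)
    if finite.sum() < 3:
        raise InsufficientDataError(
            f"insufficient data: need >= 3 non-missing values, got {int(finite.sum())}"
        )
    if not math.isfinite(k):
        return vals
    mean = vals[finite].mean()
    sd = vals[finite].std(ddof=1)
    if sd > 0:
        vals[finite & (np.abs(vals - mean) > k * sd)] = np.nan
    return vals


def _design_frame(
    feature: Mapping[str, float] | pd.Series, subjects: Sequence[SubjectRecord]
) -> pd.DataFrame:
    rows = []
    for s in subjects:
        y = feature.get(s.subject_id, np.nan)
        rows.append(
            {
                "subject_id": s.subject_id,
                "y": y,
                "adhd": float(s.diagnosis in (Diagnosis.ADHD, Diagnosis.COMORBID)),
                "asd": float(s.diagnosis in (Diagnosis.ASD, Diagnosis.COMORBID)),
                "sex": float(s.sex == "M"),  # female is the reference level
                "gestational_days": s.gestational_days,
                "birth_weight": s.birth_weight,
                "pair_id": s.pair_id,
            }
        )
    df = pd.DataFrame(rows)
    return df[np.isfinite(df["y"])]


def fit_twin_mixed_model(
    feature: Mapping[str, float] | pd.Series,
    subjects: Sequence[SubjectRecord],
    feature_name: str = "feature",
) -> MixedModelResult:
    """REML mixed model of one feature with a pair random intercept.

    ``feature`` maps subject_id to value (missing subjects are dropped).
    Raises ``InestimableContrastError`` for constant responses or cohorts
    without both ADHD-present and ADHD-absent subjects, and
    ``InsufficientDataError`` with fewer than 2 pairs of complete data.
    """
    df = _design_frame(feature, subjects)
    pathway, _, measure = feature_name.rpartition("_")
    result = MixedModelResult(feature_name, pathway or feature_name, measure)
    if df["pair_id"].nunique() < 2:
        raise InsufficientDataError(
            "need complete data in at least 2 twin clusters"
        )
    if df["y"].nunique() <= 1:
        raise InestimableContrastError("inestimable contrast: constant response")
    if df["adhd"].nunique() < 2:
        raise InestimableContrastError(
            "inestimable contrast: cohort has a single ADHD status"
        )
    exog_cols = ["adhd", "sex", "gestational_days", "birth_weight", "asd"]
    exog = df[exog_cols].copy()
    # drop constant covariates (e.g. single-sex cohorts) to keep X full rank
    kept = [c for c in exog_cols if c == "adhd" or exog[c].nunique() > 1]
    exog = exog[kept]
    exog.insert(0, "const", 1.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(df["y"].to_numpy(), exog, groups=df["pair_id"].to_numpy())
        fitted = model.fit(reml=True)

    result.beta_adhd = float(fitted.params["adhd"])
    result.se = float(fitted.bse["adhd"])
    p = float(fitted.pvalues["adhd"])
    result.p_raw = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    result.covariate_betas = {
        c: (float(fitted.params[c]) if c in kept else float("nan"))
        for c in COVARIATES
    }
    result.n_used = int(len(df))
    result.converged = bool(getattr(fitted, "converged", True))
    return result


def fdr_by_stratum(
    p_raw: Mapping[str, float], strata: Mapping[str, str]
) -> dict[str, float]:
    """Benjamini-Hochberg step-up applied independently within each stratum.

    Every feature in ``p_raw`` must have a stratum label; adjusted values
    are capped at 1 and map back to the feature keys.
    """
    missing = [f for f in p_raw if f not in strata]
    if missing:
        raise ValidationError(
            f"unknown stratum for feature(s): {', '.join(sorted(missing))}", "strata"
        )
    for f, p in p_raw.items():
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"p-value for {f} must lie in (0, 1], got {p}", "p_raw")
    by_stratum: dict[str, list[str]] = {}
    for f in p_raw:
        by_stratum.setdefault(strata[f], []).append(f)
    adjusted: dict[str, float] = {}
    for feats in by_stratum.values():
        ps = [p_raw[f] for f in feats]
        adj = multipletests(ps, method="fdr_bh")[1]
        for f, q in zip(feats, adj):
            adjusted[f] = float(min(q, 1.0))
    return adjusted


def _should_screen(vals: np.ndarray, mode: str) -> bool:
    if mode == "none":
        return False
    if mode == "all":
        return True
    finite = vals[np.isfinite(vals)]
    if len(finite) < 3 or np.ptp(finite) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(finite).pvalue < 0.05


def run_feature_scan(
    table: pd.DataFrame,
    subjects: Sequence[SubjectRecord],
    outlier_k: float = 2.0,
    outlier_mode: str = "auto",
) -> list[MixedModelResult]:
    """Outlier screen -> mixed model -> stratified FDR, per feature column.

    ``outlier_mode``: "auto" screens only columns failing a Shapiro-Wilk
    normality check at alpha = 0.05, "all" screens every column, "none"
    skips the screen.  Per-feature failures become flagged rows (with
    ``error`` set) and never abort the scan.  Columns are stratified by
    pathway for the BH adjustment.
    """
    if outlier_mode not in ("auto", "all", "none"):
        raise ValidationError(f"unknown outlier_mode {outlier_mode!r}", "outlier_mode")
    results: list[MixedModelResult] = []
    for col in table.columns:
        pathway, _, measure = col.rpartition("_")
        vals = table[col].to_numpy(dtype=float)
        try:
            if _should_screen(vals, outlier_mode):
                vals = exclude_outliers(vals, outlier_k)
            feature = pd.Series(vals, index=table.index)
            res = fit_twin_mixed_model(feature, subjects, col)
            if not np.isfinite(res.p_raw):
                res.error = "model produced a non-finite p-value"
                res.converged = False
            results.append(res)
        except Exception as exc:  # noqa: BLE001 - per-feature containment
            logger.warning("feature %s failed: %s", col, exc)
            results.append(
                MixedModelResult(col, pathway or col, measure, error=str(exc))
            )
    ok = {r.feature: r.p_raw for r in results if r.error is None}
    strata = {r.feature: r.pathway for r in results}
    if ok:
        adjusted = fdr_by_stratum(ok, strata)
        for r in results:
            if r.feature in adjusted:
                r.p_fdr = adjusted[r.feature]
    return results


def scan_frame(results: Sequence[MixedModelResult]) -> pd.DataFrame:
    """Tidy one-row-per-feature view of a scan, ready for TSV export."""
    rows = []
    for r in results:
        row = {
            "pathway": r.pathway,
            "measure": r.measure,
            "beta_adhd": r.beta_adhd,
            "se": r.se,
            "p_raw": r.p_raw,
            "p_fdr": r.p_fdr,
            "n_used": r.n_used,
            "converged": r.converged,
            "error": r.error or "",
        }
        for c in COVARIATES:
            row[f"beta_{c}"] = r.covariate_betas.get(c, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
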