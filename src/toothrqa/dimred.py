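"""Phenotype-signature analyses: PCA retention + group tests, and 4-class
linear discriminant analysis with correlation-based standardized loadings.

PCA is performed on centered/scaled feature columns (correlation-matrix
PCA, so eigenvalues sum to the number of features).  Components are
retained when their eigenvalue exceeds 1 (Kaiser) *and* they fall within
the smallest leading set whose cumulative variance share exceeds 80%.

LDA finds the Fisher discriminant axes maximizing between- over
within-class scatter for the four diagnosis classes (3 axes).  Axes are
normalized in the within-class metric (w' Sw w = 1), so axis scores are
uncorrelated under that metric.  Variable importance is reported as the
Pearson correlation between each *raw* feature and the discriminant
scores ("standardized loadings"), which is scale-free and bounded in
[-1, 1].  Subjects missing any feature are excluded (complete-case), for
both PCA and LDA.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.formula.api as smf
from sklearn.decomposition import PCA

from .errors import InestimableContrastError, InsufficientDataError
from .synthetic import Diagnosis, SubjectRecord

__all__ = [
    "PCAResult",
    "LDAResult",
    "pca_fit",
    "component_group_tests",
    "lda_fit",
    "lda_loadings",
    "reclassify",
]

logger = logging.getLogger(__name__)

CLASS_ORDER = ("TD", "ADHD", "ASD", "COMORBID")


@dataclass
class PCAResult:
    """Correlation-matrix PCA with the eigenvalue>1 & cumulative>80% rule."""

    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # feature x component correlation loadings
    scores: pd.DataFrame  # subject x component
    retained: list[int]  # 1-based component indices
    dropped_columns: list[str] = field(default_factory=list)
    excluded_subjects: list[str] = field(default_factory=list)

    @property
    def variance_share(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


@dataclass
class LDAResult:
    """Fisher discriminant axes for the four diagnosis classes."""

    axis_count: int
    scores: pd.DataFrame  # subject x axis
    class_means: pd.DataFrame  # class x axis
    standardized_loadings: pd.DataFrame  # feature x axis correlations
    excluded_subjects: list[str]
    classes: list[str]
    priors: dict[str, float]
    weights: np.ndarray  # feature x axis projection, within-metric normalized
    grand_mean: np.ndarray


def _complete_cases(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    complete = table.dropna(axis=0)
    excluded = [s for s in table.index if s not in complete.index]
    if excluded:
        logger.info("complete-case exclusion dropped %d subjects", len(excluded))
    return complete, excluded


def pca_fit(table: pd.DataFrame) -> PCAResult:
    """PCA of the standardized feature table.

    Constant columns are dropped with a logged warning; subjects with any
    missing value are excluded.  Component signs are oriented so each
    component's largest-|loading| feature loads positively.
    """
    data, excluded = _complete_cases(table)
    sds = data.std(ddof=1)
    dropped = list(data.columns[(sds == 0) | ~np.isfinite(sds)])
    if dropped:
        logger.warning("dropping constant feature column(s): %s", ", ".join(dropped))
        data = data.drop(columns=dropped)
    if data.shape[1] < 2:
        raise InsufficientDataError("PCA needs at least 2 informative columns")
    if data.shape[0] < 3:
        raise InsufficientDataError("PCA needs at least 3 complete-case subjects")

    z = (data - data.mean()) / data.std(ddof=1)
    n_comp = min(z.shape[0] - 1, z.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(z.to_numpy())
    eigenvalues = pca.explained_variance_
    # correlation loadings: eigenvector * sqrt(eigenvalue)
    loadings = pca.components_.T * np.sqrt(np.maximum(eigenvalues, 0.0))

    for k in range(n_comp):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0

    share = eigenvalues / eigenvalues.sum()
    k_kaiser = int(np.sum(eigenvalues > 1.0))
    cum = np.cumsum(share)
    k_80 = int(np.searchsorted(cum, 0.80, side="right") + 1)
    retained = list(range(1, max(min(k_kaiser, k_80), 0) + 1))

    comp_names = [f"PC{i}" for i in range(1, n_comp + 1)]
    return PCAResult(
        eigenvalues=eigenvalues,
        loadings=pd.DataFrame(loadings, index=data.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=data.index, columns=comp_names),
        retained=retained,
        dropped_columns=dropped,
        excluded_subjects=excluded,
    )


def component_group_tests(
    scores: pd.DataFrame,
    subjects: Sequence[SubjectRecord],
    components: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Ordinary linear models of component scores on diagnosis.

    TD is the reference level; each retained component yields three
    contrasts (ADHD, ASD, COMORBID vs TD) with OLS betas and p-values.
    """
    dx = {s.subject_id: s.diagnosis.value for s in subjects}
    df = scores.copy()
    df["diagnosis"] = [dx.get(s) for s in scores.index]
    present = set(df["diagnosis"])
    missing = [c for c in CLASS_ORDER if c not in present]
    if missing:
        raise InestimableContrastError(
            f"inestimable contrast: class(es) absent: {', '.join(missing)}"
        )
    if components is None:
        components = list(scores.columns)
    rows = []
    for comp in components:
        sub = df[[comp, "diagnosis"]].rename(columns={comp: "score"})
        fit = smf.ols("score ~ C(diagnosis, Treatment('TD'))", data=sub).fit()
        for cls in ("ADHD", "ASD", "COMORBID"):
            term = f"C(diagnosis, Treatment('TD'))[T.{cls}]"
            rows.append(
                {
                    "component": comp,
                    "contrast": cls,
                    "beta": float(fit.params[term]),
                    "se": float(fit.bse[term]),
                    "p": float(fit.pvalues[term]),
                }
            )
    return pd.DataFrame(rows)


def _scatter_matrices(X: np.ndarray, y: np.ndarray, classes: Sequence[str]):
    n, p = X.shape
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        d = Xc - mu
        Sw += d.T @ d
        m = (mu - grand)[:, None]
        Sb += len(Xc) * (m @ m.T)
    k = len(classes)
    return Sw / (n - k), Sb / (n - k), grand


def lda_fit(
    table: pd.DataFrame,
    subjects: Sequence[SubjectRecord],
    shrinkage: float = 1e-4,
) -> LDAResult:
    """Fisher LDA of the feature table against the four diagnosis classes.

    Complete-case subjects only; every class must retain >= 2 subjects.
    When the pooled within-class covariance is not positive definite
    (plausible with ~60 features and few more subjects) it is shrunk
    toward its diagonal with coefficient ``shrinkage`` and a warning is
    logged.  Class priors are proportional to observed class sizes.
    """
    data, excluded = _complete_cases(table)
    dx = {s.subject_id: s.diagnosis.value for s in subjects}
    y = np.array([dx.get(s, "") for s in data.index])
    classes = [c for c in CLASS_ORDER if c in set(y)]
    for c in CLASS_ORDER:
        if np.sum(y == c) < 2:
            raise InestimableContrastError(
                f"class {c} has fewer than 2 complete-case subjects"
            )
    X = data.to_numpy(dtype=float)
    Sw, Sb, grand = _scatter_matrices(X, y, classes)

    def _solve(swm):
        return scipy.linalg.eigh(Sb, swm)

    try:
        if np.linalg.cond(Sw) > 1e10:
            raise np.linalg.LinAlgError("ill-conditioned within-class covariance")
        evals, evecs = _solve(Sw)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        logger.warning(
            "within-class covariance singular/ill-conditioned; shrinking "
            "toward its diagonal (coefficient %g)", shrinkage,
        )
        Sw = (1.0 - shrinkage) * Sw + shrinkage * np.diag(np.diag(Sw))
        evals, evecs = _solve(Sw)

    axis_count = len(classes) - 1
    order = np.argsort(evals)[::-1][:axis_count]
    W = evecs[:, order]  # eigh(Sb, Sw) gives w' Sw w = 1 normalization
    scores = (X - grand) @ W
    axes = [f"LD{i}" for i in range(1, axis_count + 1)]
    score_df = pd.DataFrame(scores, index=data.index, columns=axes)

    loadings = lda_loadings_frame(score_df, data)
    for k, ax in enumerate(axes):
        col = loadings[ax].to_numpy()
        finite = np.isfinite(col)
        if finite.any():
            j = int(np.argmax(np.where(finite, np.abs(col), -1.0)))
            if col[j] < 0:
                loadings[ax] *= -1.0
                score_df[ax] *= -1.0
                W[:, k] *= -1.0

    n = len(data)
    priors = {c: float(np.sum(y == c)) / n for c in classes}
    class_means = pd.DataFrame(
        [score_df.to_numpy()[y == c].mean(axis=0) for c in classes],
        index=classes,
        columns=axes,
    )
    return LDAResult(
        axis_count=axis_count,
        scores=score_df,
        class_means=class_means,
        standardized_loadings=loadings,
        excluded_subjects=excluded,
        classes=classes,
        priors=priors,
        weights=W,
        grand_mean=grand,
    )


def lda_loadings_frame(scores: pd.DataFrame, data: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each raw feature with each axis's scores.

    Zero-variance features get a missing loading (logged), never 0.
    """
    out = pd.DataFrame(index=data.columns, columns=scores.columns, dtype=float)
    S = scores.to_numpy(dtype=float)
    S = (S - S.mean(axis=0)) / S.std(axis=0, ddof=0)
    for feat in data.columns:
        v = data[feat].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("zero-variance feature %s: loading set to missing", feat)
            out.loc[feat] = np.nan
            continue
        vz = (v - v.mean()) / sd
        out.loc[feat] = (vz @ S) / len(vz)
    return out


def lda_loadings(result: LDAResult, table: pd.DataFrame) -> pd.DataFrame:
    """Standardized loadings of ``table``'s features on fitted LDA axes,
    over the complete-case subjects the fit retained."""
    data = table.loc[result.scores.index]
    return lda_loadings_frame(result.scores, data)


def reclassify(result: LDAResult) -> pd.Series:
    """Assign each retained subject to the nearest class mean in LD space
    (Gaussian with identity covariance in the within-metric, plus
    log-prior), as a descriptive separation check — not a validated
    classifier."""
    Z = result.scores.to_numpy()
    logp = np.stack(
        [
            -0.5 * np.sum((Z - result.class_means.loc[c].to_numpy()) ** 2, axis=1)
            + np.log(result.priors[c])
            for c in result.classes
        ],
        axis=1,
    )
    picks = [result.classes[i] for i in np.argmax(logp, axis=1)]
    return pd.Series(picks, index=result.scores.index, name="predicted")
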