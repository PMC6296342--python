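"""Covariate-adjusted OLS models for indices and single loci, and simple slopes.

The outcome (a composite methylation index, or one locus's beta values) is
regressed on smoking, the moderator, and — in Model 2 — their interaction,
controlling for sex, age, diet, and the five mononuclear cell fractions.
Classical (non-robust) standard errors with t-based two-sided p-values.
Interactions are explicated as simple slopes of outcome on smoking at
moderator values one SD above and below its mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import CELL_TYPES, ValidationError

INDEX_MODEL_COVARIATES = ("male", "age", "diet") + CELL_TYPES


@dataclass
class OLSFit:
    """Least-squares fit: coefficients, classical SEs, t tests, R^2."""

    term_names: list
    coef: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    r_squared: float
    n_obs: int
    df_resid: int

    def coef_table(self) -> dict:
        return {
            name: {"b": float(b), "se": float(se), "t": float(t), "p": float(p)}
            for name, b, se, t, p in zip(
                self.term_names, self.coef, self.bse, self.tvalues, self.pvalues
            )
        }

    def __getitem__(self, term: str) -> float:
        return float(self.coef[self.term_names.index(term)])


@dataclass
class SimpleSlopes:
    """Conditional smoking slopes at moderator = mean -/+ 1 SD."""

    slope_low: float
    slope_high: float
    intercept_low: float
    intercept_high: float
    moderator_sd: float


def fit_ols(y, X, term_names=None) -> OLSFit:
    """Classical OLS of ``y`` on ``X`` (intercept included by the caller)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("design matrix shape does not match response")
    if term_names is None:
        term_names = [f"x{j}" for j in range(X.shape[1])]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(term_names[j])
        raise ValidationError(f"design matrix is rank-deficient; collinear terms: {bad}")
    if X.shape[0] <= X.shape[1]:
        raise ValidationError("need more observations than terms")
    res = sm.OLS(y, X).fit()
    return OLSFit(
        term_names=list(term_names),
        coef=np.asarray(res.params, dtype=float),
        bse=np.asarray(res.bse, dtype=float),
        tvalues=np.asarray(res.tvalues, dtype=float),
        pvalues=np.asarray(res.pvalues, dtype=float),
        r_squared=float(res.rsquared),
        n_obs=int(res.nobs),
        df_resid=int(res.df_resid),
    )


def moderated_index_regression(
    outcome,
    pheno: pd.DataFrame,
    mmthfr: pd.Series,
    smoking_measure: str = "status",
    with_interaction: bool = False,
) -> OLSFit:
    """The index-level model: outcome ~ smoking + moderator (+ interaction)
    + male + age + diet + CD8T + CD4T + NK + B + Mono + constant."""
    if smoking_measure not in ("status", "consumption"):
        raise ValidationError(f"unknown smoking measure: {smoking_measure!r}")
    col = "smoking_status" if smoking_measure == "status" else "consumption"
    outcome = pd.Series(outcome).reindex(pheno.index)
    data = pheno.copy()
    data["_mmthfr"] = mmthfr.reindex(pheno.index)
    needed = [col, "_mmthfr", *INDEX_MODEL_COVARIATES]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValidationError(f"phenotype table missing model covariates: {missing}")
    mask = data[needed].notna().all(axis=1) & outcome.notna()
    data, outcome = data[mask], outcome[mask]
    for c in needed:
        if data[c].nunique() < 2:
            raise ValidationError(f"covariate '{c}' has zero variance")
    s = data[col].to_numpy(dtype=float)
    m = data["_mmthfr"].to_numpy(dtype=float)
    cols = [s, m]
    names = ["smoking", "mmthfr"]
    if with_interaction:
        cols.append(s * m)
        names.append("smoking_x_mmthfr")
    for c in INDEX_MODEL_COVARIATES:
        cols.append(data[c].to_numpy(dtype=float))
        names.append(c)
    cols.append(np.ones(len(data)))
    names.append("const")
    return fit_ols(outcome.to_numpy(dtype=float), np.column_stack(cols), names)


def simple_slopes(fit: OLSFit, moderator_sd: float) -> SimpleSlopes:
    """Smoking slope (and plotting intercept) at moderator = -/+ 1 SD.

    ``slope(m) = b_smoking + b_interaction * m`` with the moderator centered
    at its mean; intercepts are ``b_const + b_mmthfr * m`` for line plots.
    """
    for term in ("smoking", "mmthfr", "smoking_x_mmthfr"):
        if term not in fit.term_names:
            raise ValidationError(f"fit lacks the '{term}' term required for simple slopes")
    b_s = fit["smoking"]
    b_m = fit["mmthfr"]
    b_sm = fit["smoking_x_mmthfr"]
    b0 = fit["const"] if "const" in fit.term_names else 0.0
    lo, hi = -moderator_sd, +moderator_sd
    return SimpleSlopes(
        slope_low=b_s + b_sm * lo,
        slope_high=b_s + b_sm * hi,
        intercept_low=b0 + b_m * lo,
        intercept_high=b0 + b_m * hi,
        moderator_sd=float(moderator_sd),
    )
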