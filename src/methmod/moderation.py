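"""Per-locus two-model interaction scan and sign classification.

For every CpG in a locus panel two beta regressions are fitted:

* Model 1: methylation ~ smoking + moderator + male + age
* Model 2: Model 1 + smoking x moderator

The direction class of a locus (hyper vs hypo) is the sign of its Model 1
smoking coefficient — smokers more methylated than non-smokers, or less.
Loci whose Model 2 interaction passes the chosen significance tier are then
cross-classified by direction and interaction sign; a consistent moderator
produces the characteristic opposite-sign pattern (hyper loci with negative
interactions, hypo loci with positive ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .betareg import ConvergenceError, fit_betareg, wald_pvalues
from .containers import BetaMatrix, ValidationError

MODEL1_TERMS = ("const", "smoking", "mmthfr", "male", "age")
MODEL2_TERMS = MODEL1_TERMS + ("smoking_x_mmthfr",)


@dataclass
class LocusScanRecord:
    """Model 1 / Model 2 results for one locus."""

    probe_id: str
    converged: bool
    direction: str | None = None  # "hyper" | "hypo"
    model1: dict = field(default_factory=dict)  # term -> {b, se, z, p}
    model2: dict = field(default_factory=dict)
    interaction_sign: str | None = None  # "+" | "-"
    interaction_p: float = np.nan
    interaction_p_bonferroni: float = np.nan
    interaction_p_bh: float = np.nan


@dataclass
class ScanResult:
    """Ordered scan records plus the alpha the scan was run at."""

    records: list
    alpha: float = 0.05

    def __len__(self) -> int:
        return len(self.records)

    @property
    def converged_records(self) -> list:
        return [r for r in self.records if r.converged]

    def to_frame(self) -> pd.DataFrame:
        """Table mirroring the published per-locus layout."""
        rows = []
        for r in self.records:
            row = {"probe_id": r.probe_id, "direction": r.direction, "sign": r.interaction_sign}
            for term, pre in (("smoking", "model1_smo"), ("mmthfr", "model1_mmthfr")):
                row[f"{pre}_b"] = r.model1.get(term, {}).get("b", np.nan)
                row[f"{pre}_p"] = r.model1.get(term, {}).get("p", np.nan)
            for term, pre in (("smoking", "model2_smo"), ("mmthfr", "model2_mmthfr")):
                row[f"{pre}_b"] = r.model2.get(term, {}).get("b", np.nan)
                row[f"{pre}_p"] = r.model2.get(term, {}).get("p", np.nan)
            row["int_b"] = r.model2.get("smoking_x_mmthfr", {}).get("b", np.nan)
            row["int_p"] = r.interaction_p
            row["int_p_bonf"] = r.interaction_p_bonferroni
            row["int_p_bh"] = r.interaction_p_bh
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class InteractionClassification:
    """Significant loci cross-classified by direction x interaction sign."""

    counts: dict  # {("hyper","+"): int, ...}
    members: dict  # same keys -> list of probe ids
    alpha: float
    tier: str
    n_scanned: int
    n_excluded: int

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())

    def sign_concordant_fraction(self) -> float:
        """Fraction of classified loci with the dominant opposite-sign
        pattern: hyper with negative interaction or hypo with positive."""
        n = self.n_classified
        if n == 0:
            return np.nan
        return (self.counts[("hyper", "-")] + self.counts[("hypo", "+")]) / n


def _design(pheno: pd.DataFrame, mmthfr: pd.Series, smoking_measure: str, interaction: bool):
    if smoking_measure not in ("status", "consumption"):
        raise ValidationError(f"unknown smoking measure: {smoking_measure!r}")
    col = "smoking_status" if smoking_measure == "status" else "consumption"
    s = pheno[col].to_numpy(dtype=float)
    m = mmthfr.reindex(pheno.index).to_numpy(dtype=float)
    cols = [np.ones(len(pheno)), s, m,
            pheno["male"].to_numpy(dtype=float), pheno["age"].to_numpy(dtype=float)]
    names = list(MODEL1_TERMS)
    if interaction:
        cols.append(s * m)
        names = list(MODEL2_TERMS)
    return np.column_stack(cols), names


def fit_locus_pair(
    y,
    pheno: pd.DataFrame,
    mmthfr: pd.Series,
    smoking_measure: str = "status",
    probe_id: str = "",
) -> LocusScanRecord:
    """Fit Model 1 and Model 2 for one locus; never raises on a bad locus.

    Non-convergence (including degenerate responses) flags the record and
    excludes it from classification instead of propagating an exception.
    """
    y = np.asarray(y, dtype=float)
    record = LocusScanRecord(probe_id=probe_id, converged=False)
    try:
        X1, names1 = _design(pheno, mmthfr, smoking_measure, interaction=False)
        X2, names2 = _design(pheno, mmthfr, smoking_measure, interaction=True)
        fit1 = fit_betareg(y, X1, names1)
        fit2 = fit_betareg(y, X2, names2)
        if not (fit1.converged and fit2.converged):
            return record
        record.model1 = fit1.coef_table()
        record.model2 = fit2.coef_table()
    except (ValidationError, ConvergenceError, FloatingPointError):
        return record
    record.converged = True
    smo_b = record.model1["smoking"]["b"]
    record.direction = "hyper" if smo_b > 0 else "hypo"
    int_term = record.model2["smoking_x_mmthfr"]
    record.interaction_sign = "+" if int_term["b"] > 0 else "-"
    record.interaction_p = int_term["p"]
    return record


def scan_loci(
    matrix: BetaMatrix,
    pheno: pd.DataFrame,
    mmthfr: pd.Series,
    locus_list=None,
    smoking_measure: str = "status",
    alpha: float = 0.05,
) -> ScanResult:
    """Run the two-model scan over ``locus_list`` (input order preserved).

    Responses are assumed already squeezed into (0, 1). Adjusted interaction
    p-values (Bonferroni over the scanned loci, and Benjamini-Hochberg) are
    filled across converged records.
    """
    if locus_list is None:
        locus_list = matrix.probe_ids
    locus_list = list(locus_list)
    missing = [p for p in locus_list if p not in matrix.values.index]
    if missing:
        raise ValidationError(f"locus list not contained in matrix: {missing[:5]}")
    records = []
    for probe in locus_list:
        y = matrix.values.loc[probe].reindex(pheno.index).to_numpy(dtype=float)
        records.append(
            fit_locus_pair(y, pheno, mmthfr, smoking_measure=smoking_measure, probe_id=probe)
        )
    ok = [r for r in records if r.converged]
    if ok:
        m = len(locus_list)  # Bonferroni denominator = loci scanned
        p = np.array([r.interaction_p for r in ok])
        bonf = np.minimum(p * m, 1.0)
        bh = adjust_pvalues(p, method="bh")
        for r, pb, ph in zip(ok, bonf, bh):
            r.interaction_p_bonferroni = float(pb)
            r.interaction_p_bh = float(ph)
    return ScanResult(records=records, alpha=alpha)


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni min(1, m*p) or BH step-up."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    method = method.lower()
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method in ("bh", "fdr_bh"):
        return multipletests(p, method="fdr_bh")[1]
    raise ValidationError(f"unknown adjustment method: {method!r}")


def classify_interactions(
    scan: ScanResult, alpha: float = 0.05, tier: str = "nominal"
) -> InteractionClassification:
    """Cross-classify significant interactions by direction x sign.

    ``tier`` selects which interaction p-value is compared with ``alpha``:
    "nominal", "bonferroni", or "bh". Non-converged loci are counted as
    excluded, never silently dropped.
    """
    attr = {
        "nominal": "interaction_p",
        "bonferroni": "interaction_p_bonferroni",
        "bh": "interaction_p_bh",
    }.get(tier)
    if attr is None:
        raise ValidationError(f"unknown significance tier: {tier!r}")
    counts = {(d, s): 0 for d in ("hyper", "hypo") for s in ("+", "-")}
    members = {k: [] for k in counts}
    n_excluded = 0
    for r in scan.records:
        if not r.converged:
            n_excluded += 1
            continue
        if not (getattr(r, attr) < alpha):
            n_excluded += 1
            continue
        key = (r.direction, r.interaction_sign)
        counts[key] += 1
        members[key].append(r.probe_id)
    return InteractionClassification(
        counts=counts,
        members=members,
        alpha=alpha,
        tier=tier,
        n_scanned=len(scan.records),
        n_excluded=n_excluded,
    )
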