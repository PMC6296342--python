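"""Sample/probe QC filtering, quantile normalization, and boundary handling.

The filters mirror standard 450K array practice: drop samples in which more
than 1% of probes fail detection (p > 0.05), drop probes with a beadcount
below 3 in at least 5% of samples or a failed detection p-value in at least
1% of samples. Normalization aligns the between-sample beta distributions by
mapping each sample's order statistics to their across-sample mean, within
probe design-type strata when the annotation provides one. Beta values of
exactly 0 or 1 are squeezed into the open interval before likelihood work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import BetaMatrix, ValidationError


@dataclass
class QcReport:
    """What a QC step removed and why; removed + retained = input."""

    samples_removed: dict = field(default_factory=dict)
    probes_removed: dict = field(default_factory=dict)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_probes_before: int = 0
    n_probes_after: int = 0

    def to_dict(self) -> dict:
        return {
            "samples_removed": dict(self.samples_removed),
            "probes_removed": dict(self.probes_removed),
            "n_samples_before": self.n_samples_before,
            "n_samples_after": self.n_samples_after,
            "n_probes_before": self.n_probes_before,
            "n_probes_after": self.n_probes_after,
        }


def filter_samples(
    matrix: BetaMatrix,
    p_threshold: float = 0.05,
    max_failed_fraction: float = 0.01,
) -> tuple[BetaMatrix, QcReport]:
    """Remove samples whose detection-failure fraction exceeds the limit.

    A probe fails within a sample when its detection p-value exceeds
    ``p_threshold``; the sample is removed when its failing fraction is
    strictly greater than ``max_failed_fraction``, so a sample sitting
    exactly at the limit is retained.
    """
    if matrix.detection_pvals is None:
        raise ValidationError(
            "sample filter cannot run: detection p-value matrix is absent"
        )
    P = matrix.detection_pvals.to_numpy(dtype=float)
    failed_frac = (P > p_threshold).mean(axis=0)
    drop_mask = failed_frac > max_failed_fraction
    keep = [s for s, d in zip(matrix.sample_ids, drop_mask) if not d]
    report = QcReport(
        samples_removed={
            s: f"detection p > {p_threshold} at {f:.2%} of probes (> {max_failed_fraction:.2%})"
            for s, d, f in zip(matrix.sample_ids, drop_mask, failed_frac)
            if d
        },
        n_samples_before=matrix.n_samples,
        n_samples_after=len(keep),
        n_probes_before=matrix.n_probes,
        n_probes_after=matrix.n_probes,
    )
    return matrix.subset(samples=keep), report


def filter_probes(
    matrix: BetaMatrix,
    beadcount_min: int = 3,
    beadcount_fail_fraction: float = 0.05,
    p_threshold: float = 0.05,
    p_fail_fraction: float = 0.01,
) -> tuple[BetaMatrix, QcReport]:
    """Remove probes failing the beadcount or detection sub-filter.

    A probe is removed when ``beadcount < beadcount_min`` in at least
    ``beadcount_fail_fraction`` of samples, or detection ``p > p_threshold``
    in at least ``p_fail_fraction`` of samples (the "present in x% of
    samples" wording reads as attained, hence >=). Each sub-filter runs only
    when its auxiliary matrix is available; at least one must be.
    """
    if matrix.beadcounts is None and matrix.detection_pvals is None:
        raise ValidationError(
            "probe filter cannot run: neither beadcounts nor detection p-values present"
        )
    n_probes = matrix.n_probes
    reasons: dict[str, str] = {}
    if matrix.beadcounts is not None:
        B = matrix.beadcounts.to_numpy(dtype=float)
        frac = (B < beadcount_min).mean(axis=1)
        for probe, f in zip(matrix.probe_ids, frac):
            if f >= beadcount_fail_fraction - 1e-12:
                reasons[probe] = (
                    f"beadcount < {beadcount_min} in {f:.2%} of samples"
                )
    if matrix.detection_pvals is not None:
        P = matrix.detection_pvals.to_numpy(dtype=float)
        frac = (P > p_threshold).mean(axis=1)
        for probe, f in zip(matrix.probe_ids, frac):
            if f >= p_fail_fraction - 1e-12 and probe not in reasons:
                reasons[probe] = f"detection p > {p_threshold} in {f:.2%} of samples"
    keep = [p for p in matrix.probe_ids if p not in reasons]
    report = QcReport(
        probes_removed=reasons,
        n_samples_before=matrix.n_samples,
        n_samples_after=matrix.n_samples,
        n_probes_before=n_probes,
        n_probes_after=len(keep),
    )
    return matrix.subset(probes=keep), report


def _quantile_normalize_block(X: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a probes x samples array in place-free form.

    Each column's sorted values are replaced by the across-column mean of
    order statistics; within-column ties receive the mean of the reference
    values over the ranks they jointly occupy.
    """
    n_probes, n_samples = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(n_samples):
        col = X[:, j]
        idx = order[:, j]
        assigned = reference.copy()
        sorted_vals = col[idx]
        # collapse runs of tied values to the mean of their reference slots
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_probes]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[s:e] = reference[s:e].mean()
        out[idx, j] = assigned
    return out


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Between-sample quantile normalization of beta values (sklearn-style).

    ``fit`` learns the mean order statistics of the training samples (per
    design-type stratum when requested); ``transform`` maps each sample's
    ranks onto that reference. ``fit_transform`` on a BetaMatrix is the
    usual one-shot normalization in which the reference comes from the data
    being normalized.
    """

    def __init__(self, stratify_by_design_type: bool = True):
        self.stratify_by_design_type = stratify_by_design_type

    def _strata(self, matrix: BetaMatrix) -> dict[str, list]:
        ann = matrix.annotation
        if not self.stratify_by_design_type or ann is None or "design_type" not in ann:
            return {"all": matrix.probe_ids}
        strata: dict[str, list] = {}
        design = ann["design_type"].reindex(matrix.values.index).fillna("all")
        for probe, dt in design.items():
            strata.setdefault(str(dt), []).append(probe)
        return strata

    def fit(self, matrix: BetaMatrix, y=None):
        values = matrix.values
        if values.isna().any().any():
            raise ValidationError("quantile normalization requires complete values")
        self.reference_: dict[str, np.ndarray] = {}
        self.strata_: dict[str, list] = self._strata(matrix)
        for name, probes in self.strata_.items():
            block = values.loc[probes].to_numpy(dtype=float)
            self.reference_[name] = np.sort(block, axis=0).mean(axis=1)
        return self

    def transform(self, matrix: BetaMatrix) -> BetaMatrix:
        values = matrix.values.copy()
        for name, probes in self.strata_.items():
            block = values.loc[probes].to_numpy(dtype=float)
            if block.shape[0] < 2:
                warnings.warn(
                    f"stratum '{name}' has fewer than 2 probes; passed through unchanged"
                )
                continue
            values.loc[probes] = _quantile_normalize_block(block)
        return matrix.with_values(values)


def quantile_normalize(matrix: BetaMatrix, stratify_by_design_type: bool = True) -> BetaMatrix:
    """One-shot between-sample quantile normalization of a BetaMatrix."""
    qn = QuantileNormalizer(stratify_by_design_type=stratify_by_design_type)
    return qn.fit(matrix).transform(matrix)


def squeeze_unit_interval(values, n: int):
    """Map values in [0, 1] strictly into (0, 1): ``(y*(n-1) + 0.5) / n``.

    ``n`` is the effective sample count (Smithson-Verkuilen convention);
    the transform is affine, order-preserving, and fixes the midpoint 0.5.
    """
    if n < 1:
        raise ValidationError("squeeze requires n >= 1")
    arr = np.asarray(values, dtype=float)
    out = (arr * (n - 1) + 0.5) / n
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out
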