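"""Reference-based cell-type deconvolution by constrained projection.

Given a reference matrix R (probes x cell types) of sorted-cell methylation
profiles and a mixed-cell sample profile y over the same probes, the cell
fractions are the constrained least-squares solution

    minimize ||y - R w||^2   subject to  w >= 0,  sum(w) <= 1.

The inequality on the sum (rather than equality) reflects a mononuclear-cell
design: granulocytes are absent from the reference, so the reference types
need not account for the whole sample. With a handful of cell types the QP
is solved exactly by enumerating active sets and checking the KKT
conditions, which meets a 1e-8 optimality tolerance without an iterative
solver.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import BetaMatrix, CellReference, ValidationError


def _solve_constrained_ls(R: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact KKT solution of min ||y - Rw||^2 s.t. w >= 0, 1'w <= 1.

    Enumerates which nonnegativity constraints are active (w_i = 0) and
    whether the sum constraint is active, solves the equality-constrained
    subproblem through the KKT system, and accepts the first candidate that
    is primal and dual feasible. Exponential in the number of cell types,
    which is small by construction.
    """
    K = R.shape[1]
    G = R.T @ R
    h = R.T @ y
    tol = 1e-9
    best = None
    for mask in range(1 << K):
        free = np.array([(mask >> i) & 1 == 0 for i in range(K)])
        nf = int(free.sum())
        for sum_active in (False, True):
            if nf == 0:
                w = np.zeros(K)
                lam = 0.0
                if sum_active:
                    continue
            else:
                Gff = G[np.ix_(free, free)]
                hf = h[free]
                if sum_active:
                    # KKT: [2Gff 1; 1' 0] [w_f; lam] = [2hf; 1]
                    A = np.zeros((nf + 1, nf + 1))
                    A[:nf, :nf] = 2.0 * Gff
                    A[:nf, nf] = 1.0
                    A[nf, :nf] = 1.0
                    rhs = np.concatenate([2.0 * hf, [1.0]])
                    try:
                        sol = np.linalg.solve(A, rhs)
                    except np.linalg.LinAlgError:
                        continue
                    wf, lam = sol[:nf], sol[nf]
                else:
                    try:
                        wf = np.linalg.solve(Gff, hf)
                    except np.linalg.LinAlgError:
                        continue
                    lam = 0.0
                w = np.zeros(K)
                w[free] = wf
            # primal feasibility
            if (w < -tol).any() or w.sum() > 1.0 + tol:
                continue
            if sum_active and abs(w.sum() - 1.0) > 1e-7:
                continue
            # dual feasibility: lam >= 0; for active bounds, mu_i = g_i + lam >= 0
            if lam < -tol:
                continue
            g = 2.0 * (G @ w - h)
            if ((g[~free] + lam) < -1e-6).any():
                continue
            obj = float(y @ y - 2 * h @ w + w @ G @ w)
            if best is None or obj < best[0] - 1e-12:
                best = (obj, np.clip(w, 0.0, None))
    if best is None:  # numerically degenerate; fall back to the origin
        return np.zeros(K)
    return best[1]


def estimate_cell_fractions(sample_profile, reference: CellReference) -> pd.Series:
    """Estimate one sample's cell fractions from its reference-probe betas.

    ``sample_profile`` must cover the reference probes in the same order
    (a pandas Series is aligned on its index first).
    """
    R = reference.values.to_numpy(dtype=float)
    if isinstance(sample_profile, pd.Series):
        missing = [p for p in reference.probe_ids if p not in sample_profile.index]
        if missing:
            raise ValidationError(f"sample profile missing reference probes: {missing[:5]}")
        y = sample_profile.loc[reference.probe_ids].to_numpy(dtype=float)
    else:
        y = np.asarray(sample_profile, dtype=float)
    if y.shape[0] != R.shape[0]:
        raise ValidationError(
            f"profile length {y.shape[0]} does not match reference probes {R.shape[0]}"
        )
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise ValidationError("reference matrix is rank-deficient")
    w = _solve_constrained_ls(R, y)
    return pd.Series(w, index=reference.cell_types)


class CellFractionEstimator(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: beta matrix in, per-sample fractions out.

    ``fit`` stores the reference; ``transform`` deconvolves every sample of
    a BetaMatrix restricted to the reference probes.
    """

    def __init__(self, reference: CellReference | None = None):
        self.reference = reference

    def fit(self, X=None, y=None):
        if self.reference is None:
            raise ValidationError("CellFractionEstimator requires a reference")
        if np.linalg.matrix_rank(self.reference.values.to_numpy(dtype=float)) < len(
            self.reference.cell_types
        ):
            raise ValidationError("reference matrix is rank-deficient")
        self.reference_ = self.reference
        return self

    def transform(self, matrix: BetaMatrix) -> pd.DataFrame:
        ref = self.reference_
        missing = [p for p in ref.probe_ids if p not in matrix.values.index]
        if missing:
            raise ValidationError(
                f"beta matrix missing reference probes: {missing[:5]}"
            )
        block = matrix.values.loc[ref.probe_ids]
        out = {
            sample: _solve_constrained_ls(
                ref.values.to_numpy(dtype=float), block[sample].to_numpy(dtype=float)
            )
            for sample in block.columns
        }
        return pd.DataFrame(out, index=ref.cell_types).T


def estimate_cell_fractions_matrix(matrix: BetaMatrix, reference: CellReference) -> pd.DataFrame:
    """Deconvolve every sample of ``matrix``; rows = samples, cols = cell types."""
    return CellFractionEstimator(reference).fit().transform(matrix)
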