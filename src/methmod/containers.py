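"""Core data containers shared across the pipeline.

Methylation is carried as a probe x sample matrix of beta values (methylated
signal fraction, in [0, 1]) together with the optional per-measurement QC
matrices produced by the array scanner: detection p-values (probability that
signal is indistinguishable from background) and beadcounts (number of beads
interrogating the probe). Phenotypes are a per-sample table with the exposure,
demographic, diet, and optional leukocyte-fraction columns used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Phenotype columns required by the per-locus and index-level models.
PHENOTYPE_COLUMNS = ("smoking_status", "consumption", "male", "age", "diet")

#: Leukocyte subtypes of the mononuclear-cell reference, in canonical order.
CELL_TYPES = ("cd8t", "cd4t", "nk", "bcell", "mono")


class ValidationError(ValueError):
    """Raised when an input container violates its structural contract."""


@dataclass
class BetaMatrix:
    """Probe x sample methylation fractions with optional QC side matrices.

    Parameters
    ----------
    values : pandas.DataFrame
        Beta values in [0, 1]; index = probe ids, columns = sample ids.
    detection_pvals : pandas.DataFrame, optional
        Same shape as ``values``; per-measurement detection p-values in [0, 1].
    beadcounts : pandas.DataFrame, optional
        Same shape as ``values``; nonnegative integer bead counts.
    annotation : pandas.DataFrame, optional
        Per-probe annotation with columns ``gene`` and ``design_type``.
    """

    values: pd.DataFrame
    detection_pvals: pd.DataFrame | None = None
    beadcounts: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValidationError("duplicate probe ids in beta matrix")
        if v.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in beta matrix")
        arr = v.to_numpy(dtype=float)
        if arr.size and (np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0):
            raise ValidationError("beta values must lie within [0, 1]")
        for name in ("detection_pvals", "beadcounts"):
            aux = getattr(self, name)
            if aux is None:
                continue
            if aux.shape != v.shape:
                raise ValidationError(
                    f"{name} shape {aux.shape} does not match values {v.shape}"
                )
            aux.index = v.index
            aux.columns = v.columns

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, probes=None, samples=None) -> "BetaMatrix":
        """Return a copy restricted to the given probes and/or samples."""
        def cut(df):
            if df is None:
                return None
            out = df
            if probes is not None:
                out = out.loc[list(probes)]
            if samples is not None:
                out = out[list(samples)]
            return out.copy()

        ann = self.annotation
        if ann is not None and probes is not None:
            ann = ann.loc[[p for p in probes if p in ann.index]].copy()
        return BetaMatrix(
            values=cut(self.values),
            detection_pvals=cut(self.detection_pvals),
            beadcounts=cut(self.beadcounts),
            annotation=ann,
        )

    def with_values(self, values: pd.DataFrame) -> "BetaMatrix":
        return replace(self, values=values)


def validate_phenotypes(pheno: pd.DataFrame, require_cells: bool = False) -> pd.DataFrame:
    """Validate a phenotype table and return it with a ``sample_id`` index.

    Required columns: smoking_status (0/1), consumption (0-6), male (0/1),
    age (years), diet (1-4). Cell-fraction columns (cd8t, cd4t, nk, bcell,
    mono) are optional unless ``require_cells``.
    """
    df = pheno
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    if df.index.has_duplicates:
        raise ValidationError("duplicate sample ids in phenotype table")
    if len(df):
        smo = df["smoking_status"].to_numpy()
        if not np.isin(smo, (0, 1)).all():
            raise ValidationError("smoking_status must be coded 0/1")
        if ((df["consumption"] < 0) | (df["consumption"] > 6)).any():
            raise ValidationError("consumption must lie in [0, 6]")
    if require_cells:
        missing_cells = [c for c in CELL_TYPES if c not in df.columns]
        if missing_cells:
            raise ValidationError(f"phenotype table missing cell fractions: {missing_cells}")
    return df


def has_cell_fractions(pheno: pd.DataFrame) -> bool:
    return all(c in pheno.columns for c in CELL_TYPES)


@dataclass
class CellReference:
    """Reference methylation profiles of sorted leukocyte subtypes.

    ``values`` is a probe x cell-type DataFrame of beta fractions used for
    constrained-projection deconvolution of mixed-cell samples.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.columns.has_duplicates:
            raise ValidationError("duplicate cell-type labels in reference")
        if v.shape[0] < v.shape[1]:
            raise ValidationError("reference needs at least as many probes as cell types")
        arr = v.to_numpy(dtype=float)
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValidationError("reference beta values must lie within [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)
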