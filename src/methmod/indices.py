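"""Composite methylation indices from standardized probe values.

An index is the per-sample mean of per-probe z-scores. The moderator index
(mMTHFR) averages the seven promoter-associated first-exon MTHFR CpGs;
outcome indices average the sign-concordant significant loci from the
interaction scan (hypo-direction loci with positive interactions, and
hyper-direction loci with negative ones). Standardization uses the n-1
standard-deviation denominator and is computed on the full analysis sample,
smokers and non-smokers together, so every index has mean 0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BetaMatrix, ValidationError
from .moderation import InteractionClassification

#: The seven promoter-associated first-exon MTHFR CpGs of the 450K array
#: whose standardized mean defines the mMTHFR moderator index.
MTHFR_FIRST_EXON_CPGS = (
    "cg02978542",
    "cg08269394",
    "cg12751404",
    "cg14032528",
    "cg23068701",
    "cg23226134",
    "cg23952195",
)


@dataclass
class IndexDefinition:
    """A named composite index: mean of per-probe z-scores over ``probes``."""

    name: str
    probes: tuple

    def __post_init__(self) -> None:
        probes = tuple(self.probes)
        if not probes:
            raise ValidationError(f"index '{self.name}' has an empty probe list")
        if len(set(probes)) != len(probes):
            raise ValidationError(f"index '{self.name}' has duplicate probes")
        self.probes = probes


def zscore_columns(values, ddof: int = 1) -> pd.Series:
    """Standardize a per-sample vector to mean 0, SD 1 (n-1 denominator)."""
    s = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    if len(s) < 2:
        raise ValidationError("standardization requires at least 2 samples")
    sd = s.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError(f"zero variance in probe '{s.name}'")
    return (s - s.mean()) / sd


def build_index(matrix: BetaMatrix, definition: IndexDefinition, ddof: int = 1) -> pd.Series:
    """Per-sample mean of the z-scores of the definition's probes."""
    missing = [p for p in definition.probes if p not in matrix.values.index]
    if missing:
        raise ValidationError(
            f"index '{definition.name}' probes missing from matrix: {missing}"
        )
    z = pd.DataFrame(
        {p: zscore_columns(matrix.values.loc[p]) for p in definition.probes}
    )
    out = z.mean(axis=1)
    out.name = definition.name
    return out


def mmthfr_index(matrix: BetaMatrix, probes=None) -> pd.Series:
    """The moderator index: standardized mean over the MTHFR promoter CpGs
    (or any supplied probe set, e.g. the broader 24-locus MTHFR annotation)."""
    if probes is None:
        probes = [p for p in MTHFR_FIRST_EXON_CPGS if p in matrix.values.index]
        if not probes:  # synthetic cohorts carry their own MTHFR probe names
            probes = [p for p in matrix.probe_ids if str(p).startswith("MTHFR")]
    return build_index(matrix, IndexDefinition("mmthfr", tuple(probes)))


def build_outcome_indices(
    matrix: BetaMatrix, classification: InteractionClassification
) -> tuple[pd.Series | None, pd.Series | None, dict]:
    """Build the hypo and hyper outcome indices from sign-concordant loci.

    The hypo index averages hypo-direction loci with positive interactions;
    the hyper index averages hyper-direction loci with negative interactions.
    An empty sign-concordant class raises for that index; the other is still
    built and the error recorded in the returned definitions dict.
    """
    out = {}
    definitions: dict = {}
    for name, key in (("hypo_index", ("hypo", "+")), ("hyper_index", ("hyper", "-"))):
        probes = tuple(classification.members[key])
        if not probes:
            definitions[name] = None
            out[name] = None
            continue
        definition = IndexDefinition(name, probes)
        definitions[name] = definition
        out[name] = build_index(matrix, definition)
    if out["hypo_index"] is None and out["hyper_index"] is None:
        raise ValidationError("no sign-concordant loci available for either index")
    return out["hypo_index"], out["hyper_index"], definitions
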