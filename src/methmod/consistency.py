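"""Sign-consistency analysis: 2x2 contingency table and Pearson chi-square.

Rows are the direction classes (hyper: smokers > non-smokers; hypo:
non-smokers > smokers), columns the sign of the interaction coefficient.
The Pearson statistic is uncorrected (no Yates continuity correction) and
the upper-tail p-value is evaluated in log space, so associations strong
enough to push p below 1e-300 remain representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ValidationError
from .moderation import InteractionClassification


@dataclass
class ContingencyTable2x2:
    """Direction x interaction-sign counts.

    ``counts[0] = (hyper+, hyper-)``, ``counts[1] = (hypo+, hypo-)``.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 2):
            raise ValidationError("contingency table must be 2x2")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            c = c.astype(float)
            if (c < 0).any() or (c != np.round(c)).any():
                raise ValidationError("contingency counts must be nonnegative integers")
        self.counts = c.astype(int)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())


def contingency_from_classification(
    classification: InteractionClassification,
) -> ContingencyTable2x2:
    """Place classification counts as [[hyper+, hyper-], [hypo+, hypo-]]."""
    c = classification.counts
    return ContingencyTable2x2(
        np.array(
            [
                [c[("hyper", "+")], c[("hyper", "-")]],
                [c[("hypo", "+")], c[("hypo", "-")]],
            ]
        )
    )


def pearson_chi2(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square on 1 df with a log-space upper tail.

    Returns ``(statistic, df, p)`` where ``statistic = sum (O-E)^2 / E`` with
    expectations from the row x column margins.
    """
    O = table.counts.astype(float)
    N = O.sum()
    if N <= 0:
        raise ValidationError("contingency table is empty")
    r = O.sum(axis=1)
    c = O.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise ValidationError("chi-square undefined: a margin of the table is zero")
    E = np.outer(r, c) / N
    stat = float(((O - E) ** 2 / E).sum())
    p = float(np.exp(stats.chi2.logsf(stat, df=1)))
    return stat, 1, p


def row_proportions(table: ContingencyTable2x2) -> np.ndarray:
    """Per-row sign percentages (rows sum to 100 within rounding).

    A zero row total yields NaN for that row rather than an error.
    """
    O = table.counts.astype(float)
    totals = O.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * O / totals
    out[totals[:, 0] == 0] = np.nan
    return out
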