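"""Asymmetry statistics for paralog substitution counts.

For a duplication with posterior-weighted substitution counts N1, N2 over
usable alignment lengths L1, L2, the asymmetry of substitution rates is
measured by the squared normal deviate of the two-proportion comparison

    Z^2 = (p1 - p2)^2 / [ p (1 - p) (1/L1 + 1/L2) ],

with p_i = N_i / L_i and p = (N1 + N2) / (L1 + L2).  Under equal rates and
near-uniform site rates Z^2 is asymptotically chi-square with 1 df, so its
null expectation is 1 regardless of divergence or target size — unlike the
classical A = (N1 - N2)^2 / (N1 + N2), which is related by Z^2 = A / (1 - p)
when L1 = L2.

Z^2 itself (the printed, uncorrected two-proportion statistic) is used as
the asymmetry *measure*; significance uses the Yates-corrected chi-square
of the 2x2 table [sites with / without substitutions x lineage], which is
what the continuity correction is defined on.  Multiple testing across
duplications is handled by Bonferroni (alpha 0.05) and Benjamini-Yekutieli
FDR (q 0.1), the step-up procedure valid under arbitrary dependence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_Q = 0.1


@dataclass
class AsymmetryRecord:
    """Counts, lengths and asymmetry statistics for one duplication."""

    duplication_id: str
    n1: float
    l1: float
    n2: float
    l2: float
    z2: float = field(init=False)
    a: float = field(init=False)
    p_value: float = field(init=False)
    bonferroni_sig: Optional[bool] = None
    fdr_q: Optional[float] = None
    fdr_sig: Optional[bool] = None

    def __post_init__(self):
        self.z2 = z_squared(self.n1, self.l1, self.n2, self.l2)
        self.a = a_statistic(self.n1, self.n2) if self.n1 + self.n2 > 0 else np.nan
        self.p_value = asymmetry_pvalue(self.n1, self.l1, self.n2, self.l2)

    @property
    def p1(self) -> float:
        return self.n1 / self.l1

    @property
    def p2(self) -> float:
        return self.n2 / self.l2

    @property
    def p(self) -> float:
        return (self.n1 + self.n2) / (self.l1 + self.l2)


def _check_counts(n1, l1, n2, l2) -> None:
    if l1 <= 0 or l2 <= 0:
        raise ValueError("lengths must be positive")
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 > l1 or n2 > l2:
        raise ValueError("count exceeds sequence length")


def z_squared(n1: float, l1: float, n2: float, l2: float) -> float:
    """Squared normal deviate of the two-proportion comparison.

    Returns 0 by convention for the degenerate cases n1 + n2 = 0 (no
    substitutions anywhere) and p = 1 (every site substituted in both).
    Symmetric under swapping the two lineages.
    """
    _check_counts(n1, l1, n2, l2)
    p1, p2 = n1 / l1, n2 / l2
    p = (n1 + n2) / (l1 + l2)
    if p == 0.0 or p == 1.0:
        return 0.0
    return (p1 - p2) ** 2 / (p * (1.0 - p) * (1.0 / l1 + 1.0 / l2))


def a_statistic(n1: float, n2: float) -> float:
    """Classical count-based asymmetry A = (N1 - N2)^2 / (N1 + N2).

    Undefined (NaN, with a warning) when N1 + N2 = 0.  Its null
    expectation is divergence-dependent, which is why Z^2 is preferred.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 + n2 == 0:
        warnings.warn("a_statistic undefined for N1 + N2 = 0", RuntimeWarning)
        return np.nan
    return (n1 - n2) ** 2 / (n1 + n2)


def asymmetry_pvalue(n1: float, l1: float, n2: float, l2: float) -> float:
    """Yates-corrected chi-square p-value for rate asymmetry.

    The 2x2 heterogeneity table holds the numbers of sites with and
    without substitutions in each lineage.  Posterior-weighted
    (non-integer) counts are rounded half-to-even to form the table since
    the continuity correction is defined on counts.  Degenerate tables
    (any zero margin) give p = 1.
    """
    _check_counts(n1, l1, n2, l2)
    r1 = int(np.rint(n1))
    r2 = int(np.rint(n2))
    c1 = int(np.rint(l1))
    c2 = int(np.rint(l2))
    r1 = min(r1, c1)
    r2 = min(r2, c2)
    table = np.array([[r1, c1 - r1], [r2, c2 - r2]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    res = stats.chi2_contingency(table, correction=True)
    return float(res.pvalue)


def adjust(records: Sequence[AsymmetryRecord], method: str = "both",
           alpha: float = DEFAULT_ALPHA, q: float = DEFAULT_Q
           ) -> list[AsymmetryRecord]:
    """Annotate records with multiple-testing decisions.

    ``method`` is "bonferroni", "benjamini_yekutieli" or "both".
    Bonferroni controls FWER at ``alpha``; Benjamini-Yekutieli controls
    FDR at ``q`` with the harmonic-sum penalty (valid under arbitrary
    dependence between duplications).
    """
    records = list(records)
    if not records:
        return records
    pvals = np.array([r.p_value for r in records])
    if method in ("bonferroni", "both"):
        rej = pvals * len(pvals) < alpha
        for r, flag in zip(records, rej):
            r.bonferroni_sig = bool(flag)
    if method in ("benjamini_yekutieli", "both"):
        rej, qvals, _, _ = multipletests(pvals, alpha=q, method="fdr_by")
        for r, flag, qv in zip(records, rej, qvals):
            r.fdr_sig = bool(flag)
            r.fdr_q = float(qv)
    if method not in ("bonferroni", "benjamini_yekutieli", "both"):
        raise ValueError(f"unknown adjustment method: {method}")
    return records


def log_z2(values: Iterable) -> np.ndarray:
    """Base-10 log of Z^2 values after removing exact zeros.

    Z^2 = 0 arises for pairs with exactly equal substitution counts and
    has no log transform; those datapoints are dropped (with a warning if
    nothing survives).
    """
    arr = np.asarray(
        [v.z2 if isinstance(v, AsymmetryRecord) else v for v in values],
        dtype=float,
    )
    nonzero = arr[arr > 0]
    if arr.size and not nonzero.size:
        logger.warning("all %d Z^2 values are zero; log_z2 returns empty", arr.size)
    return np.log10(nonzero)


def records_table(records: Sequence[AsymmetryRecord]):
    """AsymmetryRecords as a pandas DataFrame (one row per duplication)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "duplication_id": [r.duplication_id for r in records],
            "n1": [r.n1 for r in records],
            "l1": [r.l1 for r in records],
            "n2": [r.n2 for r in records],
            "l2": [r.l2 for r in records],
            "z2": [r.z2 for r in records],
            "a": [r.a for r in records],
            "p_value": [r.p_value for r in records],
            "bonferroni_sig": [r.bonferroni_sig for r in records],
            "fdr_q": [r.fdr_q for r in records],
            "fdr_sig": [r.fdr_sig for r in records],
        }
    )
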