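"""Conditional-probability ordering of regional DAT abnormality.

A region is abnormal when its zSBR falls strictly below a threshold
(default -1.5). For every ordered region pair (Y, X) the analysis computes

    P(Y+ | X-) = #(Y+ and X-) / #(X-),

the probability that Y is already abnormal among subjects in whom X is
still normal. Asymmetry against P(X+ | Y-) is tested with the exact
McNemar test on the discordant counts b = #(Y+ and X-), c = #(X+ and Y-):

    p = min(1, 2 * P(Bin(b + c, 1/2) <= min(b, c))),    p = 1 when b + c = 0.

A significant asymmetry with b > c is read as "abnormality in Y precedes
abnormality in X". Entries with an empty conditioning set (#X- = 0) are
reported as undefined (NaN plus an explicit mask), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regions import REGIONS

__all__ = [
    "AbnormalityTable",
    "OrderingResult",
    "flag_abnormal",
    "mcnemar_exact",
    "conditional_matrix",
    "infer_order",
]

DEFAULT_THRESHOLD = -1.5
DEFAULT_ALPHA = 0.01


@dataclass
class AbnormalityTable:
    """Per-subject boolean abnormality flags, one column per region."""

    flags: pd.DataFrame
    threshold: float

    @property
    def regions(self):
        return [c for c in self.flags.columns if c in REGIONS]


@dataclass
class OrderingResult:
    """Pairwise conditional probabilities with exact McNemar p-values.

    Matrices are indexed with Y on the rows and X on the columns; the
    diagonal is NaN. ``undefined`` marks entries whose conditioning count
    #(X-) is zero.
    """

    prob: pd.DataFrame          # P(Y+|X-)
    count_b: pd.DataFrame       # #(Y+ and X-)
    count_c: pd.DataFrame       # #(X+ and Y-)
    count_xminus: pd.DataFrame  # #(X-)
    p_value: pd.DataFrame       # exact McNemar, per pair
    undefined: pd.DataFrame     # bool mask
    threshold: float
    n_subjects: int

    def significant(self, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
        return (self.p_value < alpha) & ~self.undefined


def flag_abnormal(ztable: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
                  regions=REGIONS) -> AbnormalityTable:
    """Flag zSBR < threshold (strict inequality: z = threshold is normal)."""
    missing = [r for r in regions if r not in ztable.columns]
    if missing:
        raise ValueError(f"missing region columns: {missing}")
    sub = ztable[list(regions)]
    if sub.isna().any().any():
        bad = sub.isna().stack()
        where = list(bad[bad].index[:5])
        raise ValueError(f"missing z-score values at {where}")
    flags = (sub < threshold)
    keep = [c for c in ("subject_id", "group") if c in ztable.columns]
    out = pd.concat([ztable[keep], flags], axis=1) if keep else flags
    return AbnormalityTable(out, threshold)


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p-value from the discordant counts.

    Doubled smaller binomial tail at p = 1/2, clamped at 1; returns 1.0
    when there are no discordant pairs.
    """
    if b < 0 or c < 0 or b != int(b) or c != int(c):
        raise ValueError("discordant counts must be non-negative integers")
    b, c = int(b), int(c)
    m = b + c
    if m == 0:
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), m, 0.5)))


def conditional_matrix(table: AbnormalityTable) -> OrderingResult:
    """Compute P(Y+|X-), discordant counts and exact McNemar p per pair."""
    regions = table.regions
    F = table.flags[regions].to_numpy(bool)
    n = F.shape[0]
    if n < 1:
        raise ValueError("need at least one subject")
    k = len(regions)
    prob = np.full((k, k), np.nan)
    b_mat = np.zeros((k, k), dtype=int)
    c_mat = np.zeros((k, k), dtype=int)
    xm = np.zeros((k, k), dtype=int)
    pv = np.full((k, k), np.nan)
    undef = np.zeros((k, k), dtype=bool)
    for i in range(k):          # Y
        for j in range(k):      # X
            if i == j:
                continue
            b = int(np.sum(F[:, i] & ~F[:, j]))
            c = int(np.sum(F[:, j] & ~F[:, i]))
            n_xm = int(np.sum(~F[:, j]))
            b_mat[i, j], c_mat[i, j], xm[i, j] = b, c, n_xm
            if n_xm == 0:
                undef[i, j] = True
            else:
                prob[i, j] = b / n_xm
            pv[i, j] = mcnemar_exact(b, c)
    def df(a):
        return pd.DataFrame(a, index=regions, columns=regions)
    return OrderingResult(df(prob), df(b_mat), df(c_mat), df(xm), df(pv),
                          df(undef), table.threshold, n)


@dataclass(frozen=True)
class PrecedenceEdge:
    """'Abnormality in ``before`` precedes abnormality in ``after``'."""

    before: str   # Y
    after: str    # X
    b: int        # #(Y+ and X-)
    c: int        # #(X+ and Y-)
    p_value: float
    prob: float   # P(Y+|X-)


def infer_order(result: OrderingResult, alpha: float = DEFAULT_ALPHA
                ) -> list[PrecedenceEdge]:
    """Emit 'Y precedes X' edges: exact McNemar p < alpha and b > c.

    No transitive closure is applied; only directly supported pairs are
    reported.
    """
    edges = []
    for y in result.prob.index:
        for x in result.prob.columns:
            if y == x:
                continue
            b = int(result.count_b.loc[y, x])
            c = int(result.count_c.loc[y, x])
            p = float(result.p_value.loc[y, x])
            if p < alpha and b > c:
                edges.append(PrecedenceEdge(
                    before=y, after=x, b=b, c=c, p_value=p,
                    prob=float(result.prob.loc[y, x])))
    return edges
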