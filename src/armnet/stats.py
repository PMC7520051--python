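"""Subpopulation x condition contingency tables, odds ratios and Fisher tests.

A 2x2 table counts target-subtype vs other cells in two conditions; the
association is summarized by the cross-product odds ratio ad/bc with a
Woolf (log-OR) 95% confidence interval (Haldane 0.5 correction when a cell
is zero) and a two-sided Fisher exact p-value. ``or_from_proportions`` is
the scale-free counterpart used to check odds ratios reported only as
percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class CrossTab2x2:
    """(cond1: target a, non-target b; cond2: target c, non-target d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cells must be nonnegative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class OddsRatioResult:
    or_point: float
    ci_low: float
    ci_high: float
    p_fisher: float
    method_ci: str = "woolf_log_or_haldane"

    def to_dict(self) -> dict[str, float | str]:
        return dict(self.__dict__)


def cross_tab(
    cell_labels: np.ndarray,
    condition_of_cell: np.ndarray,
    target_subtype: str,
    cond1: str,
    cond2: str,
) -> CrossTab2x2:
    """Count target / non-target cells in each of two conditions."""
    cell_labels = np.asarray(cell_labels).astype(str)
    condition_of_cell = np.asarray(condition_of_cell).astype(str)
    if cell_labels.shape != condition_of_cell.shape:
        raise ValueError("labels and conditions must align")
    known = set(np.unique(condition_of_cell))
    for cond in (cond1, cond2):
        if cond not in known:
            raise ValueError(f"unknown condition {cond!r}; present: {sorted(known)}")
    m1 = condition_of_cell == cond1
    m2 = condition_of_cell == cond2
    tgt = cell_labels == target_subtype
    return CrossTab2x2(
        a=int((m1 & tgt).sum()),
        b=int((m1 & ~tgt).sum()),
        c=int((m2 & tgt).sum()),
        d=int((m2 & ~tgt).sum()),
    )


def cross_tab_or(t: CrossTab2x2, ci_level: float = 0.95) -> OddsRatioResult:
    """Odds ratio, Woolf CI and two-sided Fisher exact p for a 2x2 table.

    The point estimate is the raw cross-product ratio ad/bc; when any cell
    is zero the Haldane 0.5 correction is applied to every cell for both
    the point estimate and the CI (and recorded in ``method_ci``). A zero
    row or column margin leaves the OR undefined and raises.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("zero margin: odds ratio undefined")
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "woolf_log_or_haldane(+0.5)"
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
        method = "woolf_log_or"
    or_point = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    zc = sps.norm.ppf(0.5 + ci_level / 2.0)
    log_or = math.log(or_point)
    ci_low = math.exp(log_or - zc * se)
    ci_high = math.exp(log_or + zc * se)
    _, p = sps.fisher_exact(t.as_array(), alternative="two-sided")
    return OddsRatioResult(
        or_point=or_point,
        ci_low=ci_low,
        ci_high=ci_high,
        p_fisher=float(min(1.0, p)),
        method_ci=method,
    )


def or_from_proportions(p1: float, p2: float) -> float:
    """Odds ratio implied by two proportions: p1(1-p2) / (p2(1-p1)).

    Scale-free check of reported odds ratios when only the percentages are
    available; boundary proportions (0 or 1) leave the OR undefined.
    """
    for p in (p1, p2):
        if not 0.0 < p < 1.0:
            raise ValueError(f"proportions must lie strictly in (0, 1), got {p}")
    return (p1 * (1.0 - p2)) / (p2 * (1.0 - p1))
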