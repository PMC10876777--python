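"""Group statistics: Welch t-tests and point-biserial screens.

Sign convention: with the patient group passed first and the control group
second, t = (mean_2 - mean_1) / SE, so a feature elevated in patients gets a
*negative* t. The point-biserial screen codes patients as 1 and controls as
0, so a unit patients mention less often gets a negative r. Bonferroni
control over the 32 content units puts the screen's significance threshold
at 0.05/32 = 0.0015625 (displayed 0.0016).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .content_units import MentionMatrix
from .types import ValidationError


@dataclass
class GroupSummary:
    """Mean, sample SD (n-1 denominator) and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be nonnegative")
        if self.n < 2:
            raise ValidationError("n must be at least 2")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise ValidationError("need at least 2 values per group")
        return cls(mean=float(values.mean()), sd=float(values.std(ddof=1)), n=int(values.size))


@dataclass
class WelchResult:
    """Welch two-sample t-test: t, Satterthwaite df, two-sided p."""

    t: float
    df: float
    p: float
    direction: str = "second-minus-first"


@dataclass
class PointBiserialResult:
    r: float
    p: float
    n: int


def welch_from_summaries(a: GroupSummary, b: GroupSummary) -> WelchResult:
    """Welch t-test from printed group summaries (first group = patients).

    t = (b.mean - a.mean)/sqrt(a.sd^2/a.n + b.sd^2/b.n); df by the
    Welch-Satterthwaite approximation; p two-sided.
    """
    if a.sd == 0 and b.sd == 0:
        raise ValidationError("both group SDs are zero; Welch test undefined")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    t = (b.mean - a.mean) / math.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(t=t, df=df, p=float(p))


def welch_from_vectors(x, y) -> WelchResult:
    """Welch t-test from raw per-participant vectors (x = patients first).

    Matches :func:`welch_from_summaries` applied to the vectors' exact
    means and n-1 SDs, with the same second-minus-first sign convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise ValidationError("both group SDs are zero; Welch test undefined")
    res = sps.ttest_ind(y, x, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def point_biserial(group, values) -> PointBiserialResult:
    """Point-biserial correlation between a 0/1 group code and values.

    r is the Pearson correlation of the coding with the values; p comes from
    t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom, two-sided.
    """
    g = np.asarray(group, dtype=float)
    v = np.asarray(values, dtype=float)
    if g.size != v.size:
        raise ValidationError("group and values must be the same length")
    if len(np.unique(g)) < 2:
        raise ValidationError("both groups must be represented")
    if np.all(v == v[0]):
        raise ValidationError("values are constant; correlation undefined")
    n = g.size
    gc = g - g.mean()
    vc = v - v.mean()
    r = float(gc @ vc / math.sqrt((gc @ gc) * (vc @ vc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return PointBiserialResult(r=r, p=p, n=int(n))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Exact alpha/m (display rounding is the caller's concern)."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    return alpha / m


def cu_group_screen(
    matrix: MentionMatrix,
    alpha: float = 0.05,
    m_tests: int | None = None,
    positive_group: str = "PCA",
) -> pd.DataFrame:
    """Per-unit point-biserial screen of mention likelihood vs group.

    One correlation per unit column with the group coded 1 for patients.
    Zero-variance columns (units everyone or no one mentions) are flagged
    untestable, not errored. The Bonferroni divisor defaults to the total
    number of units in the dictionary, matching a threshold fixed by the
    instrument rather than by the data at hand; pass ``m_tests`` to override.
    """
    counts = matrix.groups.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValidationError("need at least 2 participants in each group")
    g = (matrix.groups == positive_group).astype(int).to_numpy()
    m = m_tests if m_tests is not None else matrix.data.shape[1]
    threshold = bonferroni_threshold(alpha, m)
    rows = []
    for unit in matrix.data.columns:
        v = matrix.data[unit].to_numpy()
        if np.all(v == v[0]):
            rows.append({"unit": unit, "r": np.nan, "p": np.nan,
                         "significant": False, "testable": False})
            continue
        res = point_biserial(g, v)
        rows.append({"unit": unit, "r": res.r, "p": res.p,
                     "significant": res.p < threshold, "testable": True})
    out = pd.DataFrame(rows).set_index("unit")
    out.attrs["alpha"] = alpha
    out.attrs["m_tests"] = m
    out.attrs["threshold"] = threshold
    return out
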