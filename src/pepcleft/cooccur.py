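"""Within-repertoire association between residue classes at two positions
(e.g. K/R at p1 vs D/E at p4) and cross-allotype correlation of class
frequencies."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import Repertoire
from .positional import PositionLabel, ResidueClass, TestResult, resolve_position, two_proportion_z


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 co-occurrence table: a = both classes, b = A only, c = B only,
    d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)


def contingency(
    rep: Repertoire,
    label_a: PositionLabel,
    cls_a: ResidueClass,
    label_b: PositionLabel,
    cls_b: ResidueClass,
) -> ContingencyTable:
    """Partition the repertoire by class membership at two distinct positions."""
    if str(label_a) == str(label_b):
        raise ValueError("self-association at a single position is undefined")
    a = b = c = d = 0
    for seq in rep.sequences():
        in_a = seq[resolve_position(label_a, len(seq))] in cls_a.members
        in_b = seq[resolve_position(label_b, len(seq))] in cls_b.members
        if in_a and in_b:
            a += 1
        elif in_a:
            b += 1
        elif in_b:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def association(t: ContingencyTable) -> TestResult:
    """Odds ratio with Wald 95% CI; p from the two-proportion Z test on
    P(class B | class A) versus P(class B | not class A).

    Zero cells trigger the Haldane-Anscombe 0.5 correction (flagged in the
    note); the p-value still comes from the uncorrected proportions.
    """
    if t.n == 0:
        return TestResult("odds_ratio", math.nan, 1.0, (math.nan,),
                          degenerate=True, note="empty table")
    corrected = 0 in (t.a, t.b, t.c, t.d)
    a, b, c, d = (
        (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5) if corrected
        else (t.a, t.b, t.c, t.d)
    )
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    ci = (math.exp(log_or - 1.959963984540054 * se),
          math.exp(log_or + 1.959963984540054 * se))
    n1 = t.a + t.b  # class A present
    n2 = t.c + t.d  # class A absent
    if n1 == 0 or n2 == 0:
        return TestResult("odds_ratio", log_or / se, 1.0, (or_,), ci=ci,
                          degenerate=True,
                          note="one conditioning margin empty")
    z = two_proportion_z(t.a, n1, t.c, n2)
    return TestResult(
        "odds_ratio", z.statistic, z.p_value, (or_,), ci=ci,
        degenerate=z.degenerate,
        note=("Haldane-Anscombe 0.5 correction applied" if corrected else z.note),
    )


def cross_allotype_correlation(
    points: Sequence[tuple[float, float]],
) -> tuple[TestResult, TestResult]:
    """Pearson and Spearman correlation of per-allotype class frequencies.

    Each point is one allotype's (freq at position A, freq at position B);
    points are equally weighted. Returns (pearson, spearman) results with
    two-sided p-values (Pearson via the t transform, Spearman on ranks).
    """
    if len(points) < 3:
        raise ValueError("need >= 3 allotype points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        flat = TestResult("pearson_r", math.nan, 1.0, (math.nan,),
                          degenerate=True, note="zero variance in a coordinate")
        return flat, TestResult("spearman_rho", math.nan, 1.0, (math.nan,),
                                degenerate=True,
                                note="zero variance in a coordinate")
    r, p_r = stats.pearsonr(x, y)
    rho, p_rho = stats.spearmanr(x, y)
    n = len(points)
    pearson = TestResult("pearson_r", float(r), float(min(p_r, 1.0)), (float(r),),
                         df=float(n - 2))
    spearman = TestResult("spearman_rho", float(rho), float(min(p_rho, 1.0)),
                          (float(rho),), df=float(n - 2))
    return pearson, spearman
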