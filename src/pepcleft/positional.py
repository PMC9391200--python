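"""Dual-end position indexing, position-specific frequency matrices and the
statistical tests used for repertoire comparisons.

Positions are labelled from both peptide termini: ``p1``..``p5`` count from the
N-terminus, ``pO`` (p-omega, the C-terminal residue) down to ``pO-3`` count
inward from the C-terminus. For 8-mers ``p5`` and ``pO-3`` resolve to the same
residue and are counted under each label independently (labels are views of
the peptide, not a partition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .alphabet import AMINO_ACIDS, encode
from .io import Repertoire

MIN_LENGTH = 8
MAX_LENGTH = 13


@dataclass(frozen=True, slots=True)
class PositionLabel:
    """Anchored position label: ('N', 0) is p1, ('C', 0) is the C-terminus pO."""

    anchor: str  # 'N' or 'C'
    offset: int

    def __post_init__(self) -> None:
        if self.anchor not in ("N", "C"):
            raise ValueError("anchor must be 'N' or 'C'")
        if self.anchor == "N" and not 0 <= self.offset <= 4:
            raise ValueError("N-anchored offsets run 0-4 (p1-p5)")
        if self.anchor == "C" and not 0 <= self.offset <= 3:
            raise ValueError("C-anchored offsets run 0-3 (pO-pO-3)")

    def __str__(self) -> str:
        if self.anchor == "N":
            return f"p{self.offset + 1}"
        return "pO" if self.offset == 0 else f"pO-{self.offset}"

    @classmethod
    def parse(cls, text: str) -> "PositionLabel":
        text = text.strip()
        if text in ("pO", "pOmega", "pW"):
            return cls("C", 0)
        if text.startswith("pO-"):
            return cls("C", int(text[3:]))
        if text.startswith("p"):
            return cls("N", int(text[1:]) - 1)
        raise ValueError(f"unrecognized position label {text!r}")


P1 = PositionLabel("N", 0)
P2 = PositionLabel("N", 1)
P3 = PositionLabel("N", 2)
P4 = PositionLabel("N", 3)
P5 = PositionLabel("N", 4)
POMEGA = PositionLabel("C", 0)

#: The nine dual-end labels resolvable for every 8-13-mer.
DEFAULT_LABELS: tuple[PositionLabel, ...] = (
    P1, P2, P3, P4, P5,
    PositionLabel("C", 3), PositionLabel("C", 2), PositionLabel("C", 1), POMEGA,
)


def resolve_position(label: PositionLabel, length: int) -> int:
    """0-based index of a label within a peptide of the given length."""
    if not MIN_LENGTH <= length <= MAX_LENGTH:
        raise ValueError(f"peptide length {length} outside {MIN_LENGTH}-{MAX_LENGTH}")
    idx = label.offset if label.anchor == "N" else length - 1 - label.offset
    assert 0 <= idx < length
    return idx


@dataclass(frozen=True)
class ResidueClass:
    """A named set of residues at some position, e.g. D/E at p4."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("residue class must be non-empty")
        bad = self.members - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical residues in class: {sorted(bad)}")

    def complement(self) -> "ResidueClass":
        return ResidueClass(f"not-{self.name}", frozenset(AMINO_ACIDS) - self.members)


DE_CLASS = ResidueClass("D/E", frozenset("DE"))
KR_CLASS = ResidueClass("K/R", frozenset("KR"))


@dataclass(frozen=True)
class FrequencyMatrix:
    """Position-label x amino-acid counts with a shared denominator."""

    labels: tuple[PositionLabel, ...]
    counts: pd.DataFrame  # index = str(label), columns = AMINO_ACIDS, int
    n: int

    def __post_init__(self) -> None:
        if self.n > 0:
            row_sums = self.counts.sum(axis=1)
            if not (row_sums == self.n).all():
                raise ValueError("count rows must each sum to n")

    @property
    def freq(self) -> pd.DataFrame:
        if self.n == 0:
            return self.counts.astype(float) * np.nan
        return self.counts / self.n

    @property
    def empty(self) -> bool:
        return self.n == 0

    def to_tsv(self, path) -> None:
        self.freq.to_csv(path, sep="\t", float_format="%.6g")


def frequency_matrix(
    rep: Repertoire, labels: Sequence[PositionLabel] = DEFAULT_LABELS
) -> FrequencyMatrix:
    """Count the residue under every label for every peptide.

    Each peptide contributes exactly one count per label, so every row of the
    count matrix sums to the repertoire size.
    """
    labels = tuple(labels)
    counts = np.zeros((len(labels), len(AMINO_ACIDS)), dtype=np.int64)
    by_length: dict[int, list[np.ndarray]] = {}
    for seq in rep.sequences():
        by_length.setdefault(len(seq), []).append(encode(seq))
    for length, encoded in by_length.items():
        mat = np.stack(encoded)
        for li, label in enumerate(labels):
            idx = resolve_position(label, length)
            np.add.at(counts[li], mat[:, idx], 1)
    df = pd.DataFrame(counts, index=[str(l) for l in labels], columns=list(AMINO_ACIDS))
    return FrequencyMatrix(labels=labels, counts=df, n=len(rep))


def class_frequency(
    rep: Repertoire, label: PositionLabel, cls: ResidueClass
) -> tuple[int, int]:
    """(x, n): peptides whose residue at ``label`` is in ``cls``, out of n.

    For an empty repertoire returns (0, 0); the proportion is undefined.
    """
    x = 0
    for seq in rep.sequences():
        if seq[resolve_position(label, len(seq))] in cls.members:
            x += 1
    return x, len(rep)


def class_proportion(rep: Repertoire, label: PositionLabel, cls: ResidueClass) -> float:
    x, n = class_frequency(rep, label, cls)
    return x / n if n else math.nan


def frequency_difference(a: FrequencyMatrix, b: FrequencyMatrix) -> pd.DataFrame:
    """Elementwise frequency difference a - b. Rows sum to 0 by construction."""
    if [str(l) for l in a.labels] != [str(l) for l in b.labels]:
        raise ValueError("frequency matrices have different label sets")
    if a.empty or b.empty:
        raise ValueError("cannot difference an empty frequency matrix")
    return a.freq - b.freq


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    estimate: tuple[float, ...] = ()
    df: float | tuple[float, ...] | None = None
    ci: tuple[float, float] | None = None
    degenerate: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Two-sample Z test for equality of proportions, no continuity correction.

    The squared statistic equals the Pearson chi-square of the 2x2 table.
    Degenerate pooled proportions (0 or 1) are returned flagged with p = 1.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("require 0 <= x <= n and n >= 1 in both groups")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TestResult(
            method="two_proportion_z", statistic=0.0, p_value=1.0,
            estimate=(p1, p2), degenerate=True,
            note="pooled proportion is 0 or 1; z undefined",
        )
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(method="two_proportion_z", statistic=z, p_value=min(p, 1.0),
                      estimate=(p1, p2))


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t test with Welch-Satterthwaite df, two-sided."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs size >= 2")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if ma == mb:
            return TestResult("welch_t", 0.0, 1.0, (ma, mb), df=float("nan"),
                              degenerate=True, note="zero variance, equal means")
        return TestResult("welch_t", math.inf if ma > mb else -math.inf, 0.0,
                          (ma, mb), df=float("nan"), degenerate=True,
                          note="zero variance, unequal means")
    sa, sb = va / a.size, vb / b.size
    t = (ma - mb) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult("welch_t", t, min(p, 1.0), (ma, mb), df=df)


def _smm_sf(q: float, k: int, df: float, tol: float = 1e-9) -> float:
    """Survival function of the studentized maximum modulus distribution.

    P(max_i |T_i| > q) for k independent |t_df| variables sharing one variance
    estimate, by numerical integration over the chi factor. Used for Dunnett
    T3 adjusted p-values (documented tolerance 1e-6).
    """
    if q <= 0.0:
        return 1.0
    if not math.isfinite(df):
        return 1.0 - (2.0 * stats.norm.cdf(q) - 1.0) ** k

    chi = stats.chi(df)

    def integrand(u: float) -> float:
        # u ~ chi_df / sqrt(df)
        inner = 2.0 * stats.norm.cdf(q * u) - 1.0
        return inner**k * chi.pdf(u * math.sqrt(df)) * math.sqrt(df)

    val, _err = integrate.quad(integrand, 0.0, np.inf, epsabs=tol, epsrel=tol,
                               limit=200)
    return float(min(max(1.0 - val, 0.0), 1.0))


def brown_forsythe_anova(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Brown-Forsythe unequal-variance ANOVA on means (the F* statistic).

    F* = sum n_i (m_i - m)^2 / sum (1 - n_i/N) s_i^2, with a Satterthwaite
    denominator df; suited to comparing multiple means with unequal variances.
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError("omnibus test needs >= 3 groups")
    arrs = [np.asarray(groups[g], dtype=float) for g in names]
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs size >= 2")
    ns = np.array([a.size for a in arrs], dtype=float)
    means = np.array([a.mean() for a in arrs])
    variances = np.array([a.var(ddof=1) for a in arrs])
    N = ns.sum()
    grand = (ns * means).sum() / N
    numer = (ns * (means - grand) ** 2).sum()
    weights = (1.0 - ns / N) * variances
    denom = weights.sum()
    k = len(names)
    if denom == 0.0:
        p = 1.0 if numer == 0.0 else 0.0
        return TestResult("brown_forsythe_anova", math.inf if numer else 0.0, p,
                          tuple(means), df=(float(k - 1), float("nan")),
                          degenerate=True, note="all group variances zero")
    fstar = numer / denom
    c = weights / denom
    inv_df2 = (c**2 / (ns - 1.0)).sum()
    df2 = 1.0 / inv_df2 if inv_df2 > 0 else float("inf")
    p = float(stats.f.sf(fstar, k - 1, df2))
    return TestResult("brown_forsythe_anova", float(fstar), p, tuple(means),
                      df=(float(k - 1), float(df2)))


def dunnett_t3(groups: Mapping[str, Sequence[float]]) -> list[tuple[str, str, TestResult]]:
    """All-pairs Dunnett T3 comparisons: Welch statistics with studentized
    maximum modulus adjusted p-values (k = number of comparisons)."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    k = len(pairs)
    results = []
    for ga, gb in pairs:
        base = welch_t(groups[ga], groups[gb])
        if base.degenerate:
            adj_p = base.p_value
        else:
            adj_p = _smm_sf(abs(base.statistic), k, float(base.df), tol=1e-9)
            adj_p = max(adj_p, base.p_value)  # adjusted p never below unadjusted
        results.append(
            (ga, gb, TestResult("dunnett_t3", base.statistic, adj_p,
                                base.estimate, df=base.df,
                                degenerate=base.degenerate, note=base.note))
        )
    return results


@dataclass(frozen=True)
class GroupTestReport:
    omnibus: TestResult
    pairwise: tuple[tuple[str, str, TestResult], ...]
    group_sizes: Mapping[str, int]


def group_tests(groups: Mapping[str, Sequence[float]]) -> GroupTestReport:
    """Brown-Forsythe omnibus plus Dunnett-T3 all-pairs comparisons."""
    omnibus = brown_forsythe_anova(groups)
    pairwise = tuple(dunnett_t3(groups))
    return GroupTestReport(
        omnibus=omnibus,
        pairwise=pairwise,
        group_sizes={g: len(v) for g, v in groups.items()},
    )


def test_results_to_tsv(rows: Iterable[tuple[str, TestResult]], path) -> None:
    """Flat TSV serialization: label, method, statistic, df, p, estimates."""
    with open(path, "w") as fh:
        fh.write("label\tmethod\tstatistic\tdf\tp_value\testimates\tdegenerate\n")
        for label, r in rows:
            if r.df is None:
                df_txt = ""
            elif isinstance(r.df, tuple):
                df_txt = ",".join(f"{d:.6g}" for d in r.df)
            else:
                df_txt = f"{r.df:.6g}"
            est = ",".join(f"{e:.6g}" for e in r.estimate)
            fh.write(
                f"{label}\t{r.method}\t{r.statistic:.6g}\t{df_txt}\t"
                f"{r.p_value:.6g}\t{est}\t{int(r.degenerate)}\n"
            )
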