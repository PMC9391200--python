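"""Position weight matrices, Kullback-Leibler logo matrices, and motif-based
allotype assignment of eluted peptides."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, encode
from .io import BackgroundComposition, Repertoire
from .positional import FrequencyMatrix, PositionLabel, resolve_position


@dataclass(frozen=True)
class PWM:
    """Log2-odds matrix over a background, pseudocount-regularized."""

    labels: tuple[PositionLabel, ...]
    log_odds: pd.DataFrame  # index = str(label), columns = AMINO_ACIDS

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_odds.to_numpy()).all():
            raise ValueError("PWM entries must be finite (pseudocount > 0 required)")

    def score(self, peptide: str) -> float:
        """Sum of log-odds of the peptide's residue under each label."""
        total = 0.0
        vals = self.log_odds.to_numpy()
        enc = encode(peptide)
        for li, label in enumerate(self.labels):
            idx = resolve_position(label, len(peptide))
            total += vals[li, enc[idx]]
        return total


@dataclass(frozen=True)
class LogoMatrix:
    """KL logo: letter heights are p*log2(p/q) in bits; depleted residues are
    retained with negative scores (rendered below-axis by logo tools)."""

    labels: tuple[PositionLabel, ...]
    letter_score: pd.DataFrame
    position_ic: pd.Series

    def to_tsv(self, path) -> None:
        self.letter_score.to_csv(path, sep="\t", float_format="%.6g")


def build_pwm(
    fm: FrequencyMatrix,
    background: BackgroundComposition,
    pseudocount: float = 1.0,
) -> PWM:
    """log_odds(l, a) = log2((count + pc*q(a)) / (n + pc) / q(a)).

    The total pseudocount mass (default 1.0) is distributed in proportion to
    the background, which keeps sparse matrices finite and unbiased toward q.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if fm.empty:
        raise ValueError("cannot build a PWM from an empty repertoire")
    q = background.as_array()
    if (q <= 0).any():
        raise ValueError("background must be strictly positive for PWM building")
    counts = fm.counts.to_numpy(dtype=float)
    reg = (counts + pseudocount * q) / (fm.n + pseudocount)
    lo = np.log2(reg / q)
    df = pd.DataFrame(lo, index=fm.counts.index, columns=fm.counts.columns)
    return PWM(labels=fm.labels, log_odds=df)


def kl_logo(fm: FrequencyMatrix, background: BackgroundComposition) -> LogoMatrix:
    """Kullback-Leibler logo matrix: letter_score = p*log2(p/q), 0*log(0) = 0."""
    if fm.empty:
        raise ValueError("cannot build a logo from an empty repertoire")
    q = background.as_array()
    p = fm.freq.to_numpy(dtype=float)
    if ((q == 0) & (p > 0)).any():
        raise ValueError("background has zero mass on a residue present in data")
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / np.where(q > 0, q, 1.0)), 0.0)
    letter = pd.DataFrame(score, index=fm.counts.index, columns=fm.counts.columns)
    ic = letter.sum(axis=1)
    return LogoMatrix(labels=fm.labels, letter_score=letter, position_ic=ic)


@dataclass(frozen=True)
class Assignment:
    peptide: str
    best: str
    margin: float
    assigned: bool


def assign_allotype(
    peptides: Repertoire,
    pwms: Mapping[str, PWM],
    min_margin: float = 1.0,
) -> tuple[list[Assignment], list[str]]:
    """Score each peptide against every PWM; assign to the argmax allotype if
    it beats the runner-up by ``min_margin`` bits, else leave unassigned.

    Ties (margin 0 < min_margin, or exactly equal scores) are unassigned:
    peptides are never force-assigned because cells co-express endogenous
    allotypes whose motifs may be close.
    """
    if len(pwms) < 2:
        raise ValueError("need >= 2 PWMs to assign")
    names = list(pwms)
    label_sets = {tuple(str(l) for l in pwm.labels) for pwm in pwms.values()}
    if len(label_sets) != 1:
        raise ValueError("all PWMs must share one label set")
    if min_margin < 0:
        raise ValueError("min_margin must be >= 0")
    assignments: list[Assignment] = []
    unassigned: list[str] = []
    for seq in peptides.sequences():
        scores = sorted(
            ((pwms[name].score(seq), name) for name in names), reverse=True
        )
        margin = scores[0][0] - scores[1][0]
        ok = not math.isinf(min_margin) and margin >= min_margin and margin > 0
        assignments.append(
            Assignment(peptide=seq, best=scores[0][1], margin=margin, assigned=ok)
        )
        if not ok:
            unassigned.append(seq)
    return assignments, unassigned


def assignments_to_tsv(assignments: Sequence[Assignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tbest\tmargin\tassigned\n")
        for a in assignments:
            fh.write(f"{a.peptide}\t{a.best}\t{a.margin:.6g}\t{int(a.assigned)}\n")
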