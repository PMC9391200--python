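"""Reading, QC filtering and deduplication of peptide repertoires; background
compositions; HLA allele sequences under mature-protein numbering.

Peptide positions are 1-based in user-facing labels; internally all indexing is
0-based half-open. Mature numbering of HLA heavy chains is obtained by removing
a configurable signal peptide (default 24 residues for HLA-A).
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .alphabet import AMINO_ACIDS, is_canonical

DEFAULT_SIGNAL_PEPTIDE_LENGTH = 24
#: Minimum mature length covering the alpha-1/alpha-2 platform domains.
MIN_MATURE_LENGTH = 183


@dataclass(frozen=True, slots=True)
class PeptideRecord:
    """One identified peptide with optional search-engine metadata."""

    sequence: str
    allotype: str | None = None
    ion_score: float | None = None
    delta_mass_ppm: float | None = None
    source_tpm: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if not self.sequence.isupper() or not is_canonical(self.sequence):
            raise ValueError(f"non-canonical sequence {self.sequence!r}")


@dataclass(frozen=True)
class Repertoire:
    """Deduplicated peptide set for one allotype/variant."""

    name: str
    peptides: tuple[PeptideRecord, ...]
    length_range: tuple[int, int] = (8, 13)

    def __post_init__(self) -> None:
        seqs = [p.sequence for p in self.peptides]
        if len(seqs) != len(set(seqs)):
            raise ValueError(f"duplicate sequences in repertoire {self.name!r}")
        lo, hi = self.length_range
        for s in seqs:
            if not lo <= len(s) <= hi:
                raise ValueError(
                    f"peptide {s!r} length {len(s)} outside range {lo}-{hi}"
                )

    def __len__(self) -> int:
        return len(self.peptides)

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]


@dataclass(frozen=True)
class QCThresholds:
    """Inclusive quality-control thresholds (pass at the minimum)."""

    min_ion_score: float = 25.0
    min_tpm: float = 0.3
    length_range: tuple[int, int] = (8, 13)
    max_abs_delta_mass_ppm: float | None = None  # off by default: no printed cutoff
    require_ion_score: bool = False
    require_tpm: bool = False

    def __post_init__(self) -> None:
        if self.min_ion_score < 0:
            raise ValueError("min_ion_score must be >= 0")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range lower bound exceeds upper bound")


@dataclass(frozen=True)
class BackgroundComposition:
    """Proportion of each of the 20 residues in a reference proteome."""

    freq: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.freq) != set(AMINO_ACIDS):
            raise ValueError("background must have exactly the 20 canonical residues")
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background proportions sum to {total}, not 1")
        if any(v < 0 or v > 1 for v in self.freq.values()):
            raise ValueError("background proportions must lie in [0, 1]")

    def as_array(self):
        import numpy as np

        return np.array([self.freq[a] for a in AMINO_ACIDS])

    @classmethod
    def uniform(cls) -> "BackgroundComposition":
        return cls({a: 1.0 / 20.0 for a in AMINO_ACIDS})

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "BackgroundComposition":
        total = sum(counts.get(a, 0) for a in AMINO_ACIDS)
        if total == 0:
            raise ValueError("no canonical residues counted")
        return cls({a: counts.get(a, 0) / total for a in AMINO_ACIDS})


@dataclass(frozen=True)
class AllotypeRecord:
    """HLA allele with its mature (signal-peptide-stripped) protein sequence."""

    name: str
    mature_sequence: str

    def __post_init__(self) -> None:
        if len(self.mature_sequence) < MIN_MATURE_LENGTH:
            raise ValueError(
                f"allele {self.name!r}: mature sequence length "
                f"{len(self.mature_sequence)} < {MIN_MATURE_LENGTH}"
            )

    def residue_at(self, mature_position: int) -> str:
        """Residue letter at a 1-based mature position."""
        if not 1 <= mature_position <= len(self.mature_sequence):
            raise ValueError(
                f"position {mature_position} outside mature sequence of "
                f"{self.name!r} (length {len(self.mature_sequence)})"
            )
        return self.mature_sequence[mature_position - 1]


@dataclass
class RejectionReport:
    """Counts of QC rejections keyed by reason, plus row-level parse errors."""

    counts: Counter = field(default_factory=Counter)
    row_errors: list[str] = field(default_factory=list)

    @property
    def total_rejected(self) -> int:
        return sum(self.counts.values())

    def to_json(self) -> str:
        return json.dumps(
            {"rejections": dict(sorted(self.counts.items())),
             "row_errors": self.row_errors},
            indent=2,
        )


class PeptideTableError(ValueError):
    """Configuration-level error reading a peptide table."""


_DEFAULT_COLUMNS = {
    "sequence": ("sequence", "peptide", "peptide_sequence", "seq"),
    "allotype": ("allotype", "allele", "hla"),
    "ion_score": ("ion_score", "mascot_score", "score"),
    "delta_mass_ppm": ("delta_mass_ppm", "delta_mass", "dm_ppm"),
    "source_tpm": ("source_tpm", "tpm", "expression_tpm"),
}


def _sniff_delimiter(sample: str) -> str:
    if "\t" in sample:
        return "\t"
    if "," in sample:
        return ","
    return "\t"


def read_peptide_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> tuple[list[PeptideRecord], RejectionReport]:
    """Parse a delimited peptide table into records.

    ``column_map`` maps logical field names (``sequence``, ``allotype``,
    ``ion_score``, ``delta_mass_ppm``, ``source_tpm``) to header names; common
    header spellings are recognised automatically. Rows with non-canonical
    sequences or unparseable numeric cells are excluded and reported with their
    row number.
    """
    path = Path(path)
    text = path.read_text()
    if delimiter is None:
        delimiter = _sniff_delimiter(text.splitlines()[0] if text else "")
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    if reader.fieldnames is None:
        raise PeptideTableError(f"{path}: empty table")
    headers = {h.strip().lower(): h for h in reader.fieldnames}

    resolved: dict[str, str] = {}
    column_map = dict(column_map or {})
    for logical, aliases in _DEFAULT_COLUMNS.items():
        if logical in column_map:
            wanted = column_map[logical].strip().lower()
            if wanted not in headers:
                raise PeptideTableError(
                    f"{path}: mapped column {column_map[logical]!r} for "
                    f"{logical!r} not found in header"
                )
            resolved[logical] = headers[wanted]
        else:
            for alias in aliases:
                if alias in headers:
                    resolved[logical] = headers[alias]
                    break
    if "sequence" not in resolved:
        raise PeptideTableError(f"{path}: no peptide-sequence column found")

    report = RejectionReport()
    records: list[PeptideRecord] = []
    for rownum, row in enumerate(reader, start=2):  # header is row 1
        raw_seq = (row.get(resolved["sequence"]) or "").strip().upper()
        if not raw_seq:
            report.counts["empty sequence"] += 1
            report.row_errors.append(f"row {rownum}: empty sequence")
            continue
        if not is_canonical(raw_seq):
            bad = next(c for c in raw_seq if c not in AMINO_ACIDS)
            report.counts["non-canonical residue"] += 1
            report.row_errors.append(f"row {rownum}: non-canonical residue {bad}")
            continue
        numeric: dict[str, float | None] = {}
        bad_cell = False
        for logical in ("ion_score", "delta_mass_ppm", "source_tpm"):
            col = resolved.get(logical)
            raw = (row.get(col) or "").strip() if col else ""
            if raw in ("", "NA", "NaN", "nan", "."):
                numeric[logical] = None
            else:
                try:
                    numeric[logical] = float(raw)
                except ValueError:
                    report.counts["unparseable numeric cell"] += 1
                    report.row_errors.append(
                        f"row {rownum}: unparseable {logical} value {raw!r}"
                    )
                    bad_cell = True
                    break
        if bad_cell:
            continue
        allotype = None
        if "allotype" in resolved:
            allotype = (row.get(resolved["allotype"]) or "").strip() or None
        records.append(
            PeptideRecord(
                sequence=raw_seq,
                allotype=allotype,
                ion_score=numeric["ion_score"],
                delta_mass_ppm=numeric["delta_mass_ppm"],
                source_tpm=numeric["source_tpm"],
            )
        )
    return records, report


def qc_filter(
    records: Iterable[PeptideRecord],
    thresholds: QCThresholds = QCThresholds(),
    name: str = "repertoire",
) -> tuple[Repertoire, RejectionReport]:
    """Apply inclusive QC thresholds, then deduplicate by sequence.

    Records missing an optional field pass that check unless the corresponding
    ``require_*`` flag is set. First occurrence wins on duplicates. The report
    satisfies: rejected + duplicates + |repertoire| = |records|.
    """
    report = RejectionReport()
    kept: dict[str, PeptideRecord] = {}
    lo, hi = thresholds.length_range
    for rec in records:
        if not lo <= len(rec.sequence) <= hi:
            report.counts["length outside range"] += 1
            continue
        if rec.ion_score is None:
            if thresholds.require_ion_score:
                report.counts["missing ion score"] += 1
                continue
        elif rec.ion_score < thresholds.min_ion_score:
            report.counts["ion score below minimum"] += 1
            continue
        if rec.source_tpm is None:
            if thresholds.require_tpm:
                report.counts["missing source TPM"] += 1
                continue
        elif rec.source_tpm < thresholds.min_tpm:
            report.counts["source TPM below minimum"] += 1
            continue
        if (
            thresholds.max_abs_delta_mass_ppm is not None
            and rec.delta_mass_ppm is not None
            and abs(rec.delta_mass_ppm) > thresholds.max_abs_delta_mass_ppm
        ):
            report.counts["delta mass outside tolerance"] += 1
            continue
        if rec.sequence in kept:
            report.counts["duplicate sequence"] += 1
            continue
        kept[rec.sequence] = rec
    rep = Repertoire(
        name=name, peptides=tuple(kept.values()), length_range=thresholds.length_range
    )
    return rep, report


def composition_from_fasta(path: str | Path) -> BackgroundComposition:
    """Pooled residue proportions over all sequences in a protein FASTA.

    Non-canonical letters (B, J, O, U, X, Z) are excluded from both numerator
    and denominator.
    """
    counts: Counter = Counter()
    n_seqs = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_seqs += 1
        for c in str(record.seq).upper():
            if c in AMINO_ACIDS:
                counts[c] += 1
    if n_seqs == 0:
        raise ValueError(f"{path}: no FASTA records")
    if sum(counts.values()) == 0:
        raise ValueError(f"{path}: no canonical residues")
    return BackgroundComposition.from_counts(counts)


def read_allele_sequences(
    path: str | Path,
    signal_peptide_length: int = DEFAULT_SIGNAL_PEPTIDE_LENGTH,
) -> list[AllotypeRecord]:
    """Read HLA allele protein sequences and convert to mature numbering.

    ``signal_peptide_length`` residues are stripped from the N-terminus;
    use 0 for sequences that are already mature.
    """
    if signal_peptide_length < 0:
        raise ValueError("signal_peptide_length must be >= 0")
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        name = entry.description.strip() or entry.id
        if len(seq) < signal_peptide_length + MIN_MATURE_LENGTH:
            raise ValueError(
                f"allele {name!r}: sequence length {len(seq)} too short for "
                f"signal peptide {signal_peptide_length} + {MIN_MATURE_LENGTH} "
                "mature residues"
            )
        records.append(AllotypeRecord(name=name, mature_sequence=seq[signal_peptide_length:]))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def cleft_residues(
    record: AllotypeRecord, positions: Sequence[int]
) -> dict[int, str]:
    """Residue letters at 1-based mature positions (e.g. 62, 65, 66, 163)."""
    return {p: record.residue_at(p) for p in positions}


def write_repertoire_tsv(rep: Repertoire, path: str | Path) -> None:
    """Serialize a repertoire as TSV (sequence, allotype, ion_score, tpm)."""
    with open(path, "w") as fh:
        fh.write("sequence\tallotype\tion_score\tdelta_mass_ppm\tsource_tpm\n")
        for p in rep.peptides:
            fields = [
                p.sequence,
                p.allotype or "",
                "" if p.ion_score is None else f"{p.ion_score:.6g}",
                "" if p.delta_mass_ppm is None else f"{p.delta_mass_ppm:.6g}",
                "" if p.source_tpm is None else f"{p.source_tpm:.6g}",
            ]
            fh.write("\t".join(fields) + "\n")


def repertoire_from_sequences(
    name: str,
    sequences: Iterable[str],
    length_range: tuple[int, int] = (8, 13),
    allotype: str | None = None,
) -> Repertoire:
    """Convenience constructor: deduplicate plain sequences into a repertoire."""
    seen: dict[str, PeptideRecord] = {}
    for s in sequences:
        s = s.upper()
        if s not in seen:
            seen[s] = PeptideRecord(sequence=s, allotype=allotype)
    return Repertoire(name=name, peptides=tuple(seen.values()), length_range=length_range)
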