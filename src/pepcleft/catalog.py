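"""Grouping of HLA allotypes by binding-cleft residue configurations and
comparison of grouped ligand class frequencies.

Allotypes (not peptides) are the replicates in group comparisons: each
allotype contributes one class-frequency value to its group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .io import AllotypeRecord, Repertoire, cleft_residues
from .positional import (
    GroupTestReport,
    PositionLabel,
    ResidueClass,
    class_proportion,
    group_tests,
    welch_t,
)

#: Residues counted as basic at cleft positions. Histidine is excluded: the
#: charge argument concerns arginine/lysine specifically.
BASIC_RESIDUES = frozenset("RK")


@dataclass(frozen=True)
class ConfigurationKey:
    """Deterministic cleft-residue configuration, e.g. "62R/66K/163R"."""

    positions: tuple[int, ...]
    residues: tuple[str, ...]

    @property
    def key(self) -> str:
        return "/".join(f"{p}{r}" for p, r in zip(self.positions, self.residues))

    def residue_at(self, position: int) -> str:
        return self.residues[self.positions.index(position)]

    @property
    def has_r62(self) -> bool:
        return 62 in self.positions and self.residue_at(62) == "R"

    @property
    def has_k66(self) -> bool:
        return 66 in self.positions and self.residue_at(66) == "K"

    @property
    def has_r163(self) -> bool:
        return 163 in self.positions and self.residue_at(163) == "R"

    @property
    def basic_count_65_66(self) -> int:
        count = 0
        for p in (65, 66):
            if p in self.positions and self.residue_at(p) in BASIC_RESIDUES:
                count += 1
        return count


def basic_count_65_66(record: AllotypeRecord) -> int:
    """Number of R/K residues at mature positions 65 and 66 (0, 1 or 2)."""
    residues = cleft_residues(record, [65, 66])
    return sum(1 for r in residues.values() if r in BASIC_RESIDUES)


def configuration_key(
    record: AllotypeRecord, positions: Sequence[int] = (62, 66, 163)
) -> ConfigurationKey:
    """Cleft-residue configuration key at the requested mature positions."""
    positions = tuple(positions)
    residues = cleft_residues(record, list(positions))
    return ConfigurationKey(positions=positions,
                            residues=tuple(residues[p] for p in positions))


def group_by_basic_count(record: AllotypeRecord) -> str:
    return f"{basic_count_65_66(record)}-basic"


def group_by_62_66_163(record: AllotypeRecord) -> str:
    return configuration_key(record, (62, 66, 163)).key


@dataclass(frozen=True)
class GroupReport:
    """Per-group allotype class frequencies plus omnibus/pairwise tests."""

    groups: Mapping[str, tuple[tuple[str, float], ...]]  # group -> (allele, freq)
    tests: GroupTestReport

    def group_means(self) -> dict[str, float]:
        return {
            g: sum(f for _, f in vals) / len(vals)
            for g, vals in self.groups.items()
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("group\tallele\tfrequency\n")
            for g in sorted(self.groups):
                for allele, freq in self.groups[g]:
                    fh.write(f"{g}\t{allele}\t{freq:.6g}\n")


def group_class_frequencies(
    reps: Mapping[str, Repertoire],
    records: Mapping[str, AllotypeRecord],
    grouping: Callable[[AllotypeRecord], str],
    label: PositionLabel,
    cls: ResidueClass,
) -> GroupReport:
    """Partition allotypes into groups and compare per-allotype class
    frequencies with a Brown-Forsythe omnibus plus Dunnett-T3 pairs.

    Every repertoire must have a matching allotype record under the same name.
    """
    missing = [name for name in reps if name not in records]
    if missing:
        raise ValueError(f"repertoires without allotype records: {missing}")
    grouped: dict[str, list[tuple[str, float]]] = {}
    for name, rep in reps.items():
        g = grouping(records[name])
        grouped.setdefault(g, []).append((name, class_proportion(rep, label, cls)))
    non_empty = {g: v for g, v in grouped.items() if v}
    if len(non_empty) < 2:
        raise ValueError("need >= 2 non-empty groups for comparison")
    values = {g: [f for _, f in v] for g, v in non_empty.items()}
    if len(values) >= 3:
        tests = group_tests(values)
    else:
        # two groups: the omnibus reduces to the single Welch comparison
        (g1, v1), (g2, v2) = values.items()
        omnibus = welch_t(v1, v2)
        tests = GroupTestReport(
            omnibus=omnibus,
            pairwise=((g1, g2, omnibus),),
            group_sizes={g: len(v) for g, v in values.items()},
        )
    return GroupReport(
        groups={g: tuple(v) for g, v in non_empty.items()},
        tests=tests,
    )
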