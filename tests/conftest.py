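"""Shared fixtures: small hand-checkable repertoires, synthetic allele FASTA
files, and background compositions. All fixtures are generated in-process;
nothing is read from outside the repository."""

from __future__ import annotations

import pytest

from pepcleft import (
    BackgroundComposition,
    repertoire_from_sequences,
)
from pepcleft.simulate import default_background

# Synthetic allele templates. Positions 57-73 (mature numbering) carry the
# documented cleft residues: A2-like has R65/K66, A24-like has G65/K66,
# the consensus-like allele has R65/N66, and the double mutant G65/N66.
# Flanking sequence is filler; only the planted positions matter to tests.
_REGION_57_73 = {
    "A2-like": "PEYWDGETRKVKAHSQT",        # 62=G, 65=R, 66=K
    "A24-like": "PEYWDGETGKVKAHSQT",       # 62=G, 65=G, 66=K
    "consensus-like": "PEYWDGETRNVKAHSQT", # 65=R, 66=N
    "A2-DM-like": "PEYWDGETGNVKAHSQT",     # 65=G, 66=N
}


def make_mature_sequence(region_57_73: str, r163: str = "T") -> str:
    assert len(region_57_73) == 17
    seq = ["A"] * 275
    seq[56:73] = list(region_57_73)
    seq[162] = r163
    return "".join(seq)


@pytest.fixture(scope="session")
def allele_region_map() -> dict[str, str]:
    return dict(_REGION_57_73)


@pytest.fixture(scope="session")
def allele_fasta(tmp_path_factory) -> str:
    """Precursor FASTA (24-residue signal peptide prepended) for 4 templates."""
    path = tmp_path_factory.mktemp("alleles") / "alleles.fasta"
    signal = "M" + "A" * 23
    with open(path, "w") as fh:
        for name, region in _REGION_57_73.items():
            fh.write(f">{name}\n{signal}{make_mature_sequence(region)}\n")
    return str(path)


@pytest.fixture(scope="session")
def uniform_background() -> BackgroundComposition:
    return BackgroundComposition.uniform()


@pytest.fixture(scope="session")
def background() -> BackgroundComposition:
    return default_background()


@pytest.fixture
def tiny_repertoire():
    """Three 9-mers with hand-countable D/E4 content (2 of 3)."""
    return repertoire_from_sequences(
        "tiny", ["GLKEGIPAL", "QFKDNVILL", "VYGFVRACL"])


@pytest.fixture
def cooccur_repertoire():
    """Four 9-mers: K/R1 x D/E4 cells a=2, b=0, c=1, d=1."""
    return repertoire_from_sequences(
        "cooccur", ["KLKEGIPAL", "GLKEGIPAL", "KFKDNVILL", "VYGFVRACL"])
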