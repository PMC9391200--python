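"""Canonical amino-acid alphabet and index helpers."""

from __future__ import annotations

import numpy as np

#: The 20 canonical residues, fixed ordering used by every matrix in the package.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Letters that may appear in protein FASTA but are not canonical residues.
NON_CANONICAL: frozenset[str] = frozenset("BJOUXZ*")

_AA_BYTES = np.frombuffer("".join(AMINO_ACIDS).encode(), dtype=np.uint8)

# uint8 lookup: ASCII byte -> alphabet index, 255 for non-canonical
_BYTE_TO_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _aa in enumerate(AMINO_ACIDS):
    _BYTE_TO_INDEX[ord(_aa)] = _i


def is_canonical(sequence: str) -> bool:
    """True if every character is one of the 20 canonical uppercase letters."""
    return all(c in AA_INDEX for c in sequence)


def encode(sequence: str) -> np.ndarray:
    """Encode a peptide as alphabet indices. Raises on non-canonical letters."""
    arr = _BYTE_TO_INDEX[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sequence[int(np.argmax(arr == 255))]
        raise ValueError(f"non-canonical residue {bad!r} in {sequence!r}")
    return arr.astype(np.intp)


def decode(indices: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _AA_BYTES[np.asarray(indices)].tobytes().decode()


def encode_many(sequences: list[str]) -> list[np.ndarray]:
    return [encode(s) for s in sequences]
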