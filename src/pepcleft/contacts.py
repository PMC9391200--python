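"""Geometric and electrostatic analysis of HLA-peptide complex conformations.

Conformations come from PDB files (multi-model files become ensembles) or from
the synthetic generator. Interaction criteria are purely geometric and fully
configurable; every cutoff used is recorded in output provenance.

Residue selections use the syntax ``chain``, ``chain:resnum`` or
``chain:resnum<icode>`` (e.g. ``"A"``, ``"C:4"``, ``"A:100A"``).
"""

from __future__ import annotations

import hashlib
import json
import math
import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

COULOMB_K = 332.0636  # kcal*A/(mol*e^2)

_BASIC_ATOMS = {
    ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
    ("LYS", "NZ"),
}
_BASIC_ATOMS_HIS = {("HIS", "ND1"), ("HIS", "NE2")}
_ACIDIC_ATOMS = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
}

# Heavy-atom hydrogen-bond donors and acceptors (backbone N/O handled by name).
_DONOR_ATOMS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("TRP", "NE1"), ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
}
_ACCEPTOR_ATOMS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
}

_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}
_GUANIDINIUM_ATOMS = ("CZ", "NH1", "NH2")


@dataclass(frozen=True)
class ContactCriteria:
    """Distance (and optional angle) criteria for interaction detection."""

    salt_bridge_cutoff: float = 4.0
    hbond_da_cutoff: float = 3.5
    hbond_angle_min: float = 120.0  # applied only when an explicit H exists
    pi_cation_cutoff: float = 6.0
    pi_stack_cutoff: float = 5.5
    include_his_basic: bool = False  # protonation unknown in static structures

    def __post_init__(self) -> None:
        for name in ("salt_bridge_cutoff", "hbond_da_cutoff",
                     "pi_cation_cutoff", "pi_stack_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return {
            "salt_bridge_cutoff": self.salt_bridge_cutoff,
            "hbond_da_cutoff": self.hbond_da_cutoff,
            "hbond_angle_min": self.hbond_angle_min,
            "pi_cation_cutoff": self.pi_cation_cutoff,
            "pi_stack_cutoff": self.pi_stack_cutoff,
            "include_his_basic": self.include_his_basic,
        }


@dataclass(frozen=True)
class Conformation:
    """One set of coordinates: parallel per-atom annotation arrays."""

    chain_id: np.ndarray  # str
    res_id: np.ndarray    # int
    icode: np.ndarray     # str ('' when absent)
    res_name: np.ndarray  # str
    atom_name: np.ndarray # str
    element: np.ndarray   # str
    coords: np.ndarray    # (n, 3) float

    def __post_init__(self) -> None:
        n = len(self.chain_id)
        for arr in (self.res_id, self.icode, self.res_name, self.atom_name,
                    self.element):
            if len(arr) != n:
                raise ValueError("annotation arrays must share one length")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.chain_id, self.res_id, self.icode, self.atom_name))
        if len(set(keys)) != n:
            raise ValueError("duplicate (chain, residue, atom) triple")

    def __len__(self) -> int:
        return len(self.chain_id)

    @property
    def topology_hash(self) -> str:
        h = hashlib.sha256()
        for c, r, i, rn, an in zip(self.chain_id, self.res_id, self.icode,
                                   self.res_name, self.atom_name):
            h.update(f"{c}|{r}|{i}|{rn}|{an};".encode())
        return h.hexdigest()

    def with_coords(self, coords: np.ndarray) -> "Conformation":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def residue_key(self, atom_index: int) -> str:
        return (
            f"{self.chain_id[atom_index]}:{self.res_id[atom_index]}"
            f"{self.icode[atom_index]}:{self.res_name[atom_index]}"
        )


@dataclass(frozen=True)
class Ensemble:
    """Ordered conformations sharing one topology."""

    conformations: tuple[Conformation, ...]

    def __post_init__(self) -> None:
        if not self.conformations:
            raise ValueError("ensemble needs >= 1 conformation")
        h0 = self.conformations[0].topology_hash
        for i, conf in enumerate(self.conformations[1:], start=1):
            if conf.topology_hash != h0:
                raise ValueError(f"frame {i} has a different topology")

    def __len__(self) -> int:
        return len(self.conformations)


@dataclass(frozen=True)
class ContactRecord:
    kind: str  # salt_bridge | hbond | pi_cation | pi_stack
    res_a: str
    res_b: str
    atom_a: str  # atom name or "centroid"
    atom_b: str
    distance: float
    frame: int = 0

    @property
    def identity(self) -> tuple[str, str, str]:
        return (self.kind, self.res_a, self.res_b)


@dataclass(frozen=True)
class ChargeSet:
    """Partial charges keyed by (residue name, atom name)."""

    charges: Mapping[tuple[str, str], float]
    k: float = COULOMB_K
    dielectric: float = 1.0
    on_missing: str = "skip"  # skip | warn | error

    def __post_init__(self) -> None:
        if self.dielectric <= 0:
            raise ValueError("dielectric must be > 0")
        if self.on_missing not in ("skip", "warn", "error"):
            raise ValueError("on_missing must be skip, warn, or error")
        if any(not math.isfinite(q) for q in self.charges.values()):
            raise ValueError("charges must be finite")

    @classmethod
    def formal(cls, include_his: bool = False, **kwargs) -> "ChargeSet":
        """Minimal bundled table: unit formal charges split over the
        equivalent terminal atoms of each charged side-chain group."""
        table = {
            ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
            ("LYS", "NZ"): 1.0,
            ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
            ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
        }
        if include_his:
            table[("HIS", "ND1")] = 0.5
            table[("HIS", "NE2")] = 0.5
        return cls(charges=table, **kwargs)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_SEL_RE = re.compile(r"^([^:]+)(?::(-?\d+)([A-Za-z]?))?$")


def resolve_selection(conf: Conformation, selectors: Iterable[str] | str) -> np.ndarray:
    """Atom indices matched by one or more ``chain[:resnum[icode]]`` selectors."""
    if isinstance(selectors, str):
        selectors = [selectors]
    mask = np.zeros(len(conf), dtype=bool)
    for sel in selectors:
        m = _SEL_RE.match(sel.strip())
        if not m:
            raise ValueError(f"bad selection syntax {sel!r}")
        chain, resnum, icode = m.group(1), m.group(2), m.group(3)
        sub = conf.chain_id == chain
        if resnum is not None:
            sub &= conf.res_id == int(resnum)
            sub &= conf.icode == (icode or "")
        mask |= sub
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError(f"selection {list(selectors)!r} matches no atoms")
    return idx


def _require_disjoint(a: np.ndarray, b: np.ndarray) -> None:
    if np.intersect1d(a, b).size:
        raise ValueError("selections must be disjoint")


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _from_atom_array(arr) -> Conformation:
    return Conformation(
        chain_id=np.asarray(arr.chain_id, dtype=object),
        res_id=np.asarray(arr.res_id, dtype=int),
        icode=np.asarray(getattr(arr, "ins_code", np.full(arr.array_length(), "")),
                         dtype=object),
        res_name=np.asarray(arr.res_name, dtype=object),
        atom_name=np.asarray(arr.atom_name, dtype=object),
        element=np.asarray(arr.element, dtype=object),
        coords=np.asarray(arr.coord, dtype=float),
    )


def read_structure(path: str | Path, exclude_hetero: bool = True) -> Ensemble:
    """Read a PDB file into an ensemble (models become frames).

    Altloc resolution keeps the highest-occupancy variant (ties by label
    order); waters and heteroatoms are excluded by default. Models with
    differing atom sets are an error.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # biotite raises on inconsistent models
        raise ValueError(f"{path}: inconsistent models across frames: {exc}") from exc
    if exclude_hetero:
        keep = ~stack.hetero
        stack = stack[..., keep]
    if stack.array_length() == 0:
        raise ValueError(f"{path}: no atoms after filtering")
    frames = [_from_atom_array(stack[i]) for i in range(stack.stack_depth())]
    return Ensemble(conformations=tuple(frames))


def write_structure(ens: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a (multi-model) PDB file."""
    from biotite.structure import AtomArray, AtomArrayStack
    from biotite.structure.io.pdb import PDBFile

    ref = ens.conformations[0]
    n = len(ref)
    template = AtomArray(n)
    template.chain_id = np.asarray(ref.chain_id, dtype="U4")
    template.res_id = np.asarray(ref.res_id, dtype=int)
    template.ins_code = np.asarray(ref.icode, dtype="U1")
    template.res_name = np.asarray(ref.res_name, dtype="U5")
    template.atom_name = np.asarray(ref.atom_name, dtype="U6")
    template.element = np.asarray(ref.element, dtype="U2")
    template.hetero = np.zeros(n, dtype=bool)
    coords = np.stack([c.coords for c in ens.conformations])
    stack = AtomArrayStack(len(ens), n)
    for annot in ("chain_id", "res_id", "ins_code", "res_name", "atom_name",
                  "element", "hetero"):
        stack.set_annotation(annot, template.get_annotation(annot))
    stack.coord = coords.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Contact detection
# ---------------------------------------------------------------------------


def _atoms_by_residue(conf: Conformation, idx: np.ndarray) -> dict[tuple, np.ndarray]:
    out: dict[tuple, list[int]] = {}
    for i in idx:
        key = (conf.chain_id[i], conf.res_id[i], conf.icode[i], conf.res_name[i])
        out.setdefault(key, []).append(int(i))
    return {k: np.array(v) for k, v in out.items()}


def _res_label(key: tuple) -> str:
    chain, res_id, icode, res_name = key
    return f"{chain}:{res_id}{icode}:{res_name}"


def _charged_atoms(conf, idx, table) -> list[int]:
    return [int(i) for i in idx
            if (conf.res_name[i], conf.atom_name[i]) in table]


def _hbond_partners(conf, idx, role: str) -> list[int]:
    out = []
    for i in idx:
        rn, an = conf.res_name[i], conf.atom_name[i]
        if role == "donor":
            if an == "N" and rn != "PRO":
                out.append(int(i))
            elif (rn, an) in _DONOR_ATOMS:
                out.append(int(i))
        else:
            if an in ("O", "OXT"):
                out.append(int(i))
            elif (rn, an) in _ACCEPTOR_ATOMS:
                out.append(int(i))
    return out


def _explicit_hydrogens(conf: Conformation, donor: int) -> list[int]:
    """Hydrogens of the donor's residue within covalent range (1.25 A)."""
    same_res = (
        (conf.chain_id == conf.chain_id[donor])
        & (conf.res_id == conf.res_id[donor])
        & (conf.icode == conf.icode[donor])
        & (conf.element == "H")
    )
    idx = np.nonzero(same_res)[0]
    if idx.size == 0:
        return []
    d = np.linalg.norm(conf.coords[idx] - conf.coords[donor], axis=1)
    return [int(i) for i, dist in zip(idx, d) if dist <= 1.25]


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _ring_centroids(conf: Conformation, idx: np.ndarray) -> list[tuple[tuple, np.ndarray]]:
    """(residue key, centroid) for every complete aromatic ring in selection."""
    out = []
    for key, atoms in _atoms_by_residue(conf, idx).items():
        ring_names = _RING_ATOMS.get(key[3])
        if ring_names is None:
            continue
        name_to_idx = {conf.atom_name[i]: i for i in atoms}
        if all(n in name_to_idx for n in ring_names):
            centroid = conf.coords[[name_to_idx[n] for n in ring_names]].mean(axis=0)
            out.append((key, centroid))
    return out


def _cation_sites(conf: Conformation, idx: np.ndarray,
                  include_his: bool) -> list[tuple[tuple, str, np.ndarray]]:
    """(residue key, descriptor, position) of cationic side-chain sites."""
    out = []
    for key, atoms in _atoms_by_residue(conf, idx).items():
        res_name = key[3]
        name_to_idx = {conf.atom_name[i]: i for i in atoms}
        if res_name == "LYS" and "NZ" in name_to_idx:
            out.append((key, "NZ", conf.coords[name_to_idx["NZ"]]))
        elif res_name == "ARG" and all(n in name_to_idx for n in _GUANIDINIUM_ATOMS):
            pos = conf.coords[[name_to_idx[n] for n in _GUANIDINIUM_ATOMS]].mean(axis=0)
            out.append((key, "guanidinium", pos))
        elif include_his and res_name == "HIS":
            ring = ("CG", "ND1", "CD2", "CE1", "NE2")
            if all(n in name_to_idx for n in ring):
                pos = conf.coords[[name_to_idx[n] for n in ring]].mean(axis=0)
                out.append((key, "imidazolium", pos))
    return out


def detect_contacts(
    conf: Conformation,
    criteria: ContactCriteria,
    sel_a: Iterable[str] | str | np.ndarray,
    sel_b: Iterable[str] | str | np.ndarray,
    frame: int = 0,
) -> list[ContactRecord]:
    """Detect salt bridges, hydrogen bonds, pi-cation and pi-stacking contacts
    between two disjoint selections. Each qualifying atom (or centroid) pair
    is reported once per kind; an atom pair qualifying as a salt bridge is
    classified as salt_bridge only (ionic pairs are not double-reported as
    hydrogen bonds)."""
    idx_a = sel_a if isinstance(sel_a, np.ndarray) else resolve_selection(conf, sel_a)
    idx_b = sel_b if isinstance(sel_b, np.ndarray) else resolve_selection(conf, sel_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("selections must be non-empty")
    _require_disjoint(idx_a, idx_b)

    records: list[ContactRecord] = []

    basic_table = set(_BASIC_ATOMS)
    if criteria.include_his_basic:
        basic_table |= _BASIC_ATOMS_HIS

    def _pair_records(kind, atoms_1, atoms_2, cutoff):
        for i in atoms_1:
            for j in atoms_2:
                d = float(np.linalg.norm(conf.coords[i] - conf.coords[j]))
                if d <= cutoff:
                    yield i, j, d

    # salt bridges: basic nitrogen vs acidic oxygen, either orientation
    basic_a = _charged_atoms(conf, idx_a, basic_table)
    basic_b = _charged_atoms(conf, idx_b, basic_table)
    acid_a = _charged_atoms(conf, idx_a, _ACIDIC_ATOMS)
    acid_b = _charged_atoms(conf, idx_b, _ACIDIC_ATOMS)
    ionic_pairs: set[tuple[int, int]] = set()
    for pairs in ((_pair_records("salt_bridge", basic_a, acid_b,
                                 criteria.salt_bridge_cutoff)),
                  (_pair_records("salt_bridge", acid_a, basic_b,
                                 criteria.salt_bridge_cutoff))):
        for i, j, d in pairs:
            ionic_pairs.add((i, j))
            records.append(ContactRecord("salt_bridge", conf.residue_key(i),
                                         conf.residue_key(j), conf.atom_name[i],
                                         conf.atom_name[j], d, frame))

    # hydrogen bonds: donor->acceptor heavy-atom pairs, either orientation
    don_a = _hbond_partners(conf, idx_a, "donor")
    don_b = _hbond_partners(conf, idx_b, "donor")
    acc_a = _hbond_partners(conf, idx_a, "acceptor")
    acc_b = _hbond_partners(conf, idx_b, "acceptor")

    def _hbond_ok(donor: int, acceptor: int) -> bool:
        hydrogens = _explicit_hydrogens(conf, donor)
        if not hydrogens:
            return True  # heavy-atom criterion only
        return any(
            _angle_deg(conf.coords[donor], conf.coords[h], conf.coords[acceptor])
            >= criteria.hbond_angle_min
            for h in hydrogens
        )

    seen_hb: set[tuple[int, int]] = set()
    for donors, acceptors, a_first in ((don_a, acc_b, True), (acc_a, don_b, False)):
        for i, j, d in _pair_records("hbond", donors, acceptors,
                                     criteria.hbond_da_cutoff):
            donor, acceptor = (i, j) if a_first else (j, i)
            if (i, j) in seen_hb or (i, j) in ionic_pairs:
                # an ionic pair is classified as a salt bridge, not an hbond
                continue
            if _hbond_ok(donor, acceptor):
                seen_hb.add((i, j))
                records.append(ContactRecord("hbond", conf.residue_key(i),
                                             conf.residue_key(j),
                                             conf.atom_name[i],
                                             conf.atom_name[j], d, frame))

    # pi-cation and pi-stacking via ring centroids
    rings_a = _ring_centroids(conf, idx_a)
    rings_b = _ring_centroids(conf, idx_b)
    cations_a = _cation_sites(conf, idx_a, criteria.include_his_basic)
    cations_b = _cation_sites(conf, idx_b, criteria.include_his_basic)

    for cations, rings, a_first in ((cations_a, rings_b, True),
                                    (cations_b, rings_a, False)):
        for (ckey, desc, cpos) in cations:
            for (rkey, rpos) in rings:
                d = float(np.linalg.norm(cpos - rpos))
                if d <= criteria.pi_cation_cutoff:
                    la, lb = (_res_label(ckey), _res_label(rkey))
                    aa, ab = (desc, "centroid")
                    if not a_first:
                        la, lb, aa, ab = lb, la, ab, aa
                    records.append(ContactRecord("pi_cation", la, lb, aa, ab,
                                                 d, frame))

    for (ka, pa) in rings_a:
        for (kb, pb) in rings_b:
            d = float(np.linalg.norm(pa - pb))
            if d <= criteria.pi_stack_cutoff:
                records.append(ContactRecord("pi_stack", _res_label(ka),
                                             _res_label(kb), "centroid",
                                             "centroid", d, frame))
    return records


def contact_prevalence(
    ens: Ensemble,
    criteria: ContactCriteria,
    sel_a: Iterable[str] | str,
    sel_b: Iterable[str] | str,
) -> dict[tuple[str, str, str], float]:
    """Fraction of frames in which each (kind, residue pair) contact occurs."""
    counts: dict[tuple[str, str, str], int] = {}
    n = len(ens)
    for f, conf in enumerate(ens.conformations):
        present = {rec.identity for rec in
                   detect_contacts(conf, criteria, sel_a, sel_b, frame=f)}
        for ident in present:
            counts[ident] = counts.get(ident, 0) + 1
    return {ident: c / n for ident, c in counts.items()}


# ---------------------------------------------------------------------------
# Electrostatics
# ---------------------------------------------------------------------------


def coulomb_pair(
    conf: Conformation,
    res_a: str,
    res_b: str,
    charges: ChargeSet,
) -> float:
    """Pairwise coulombic energy between two residues in kcal/mol
    (negative = attractive): E = k/eps * sum q_i q_j / r_ij."""
    idx_a = resolve_selection(conf, res_a)
    idx_b = resolve_selection(conf, res_b)
    _require_disjoint(idx_a, idx_b)

    def _charged(idx):
        out, missing = [], []
        for i in idx:
            key = (conf.res_name[i], conf.atom_name[i])
            if key in charges.charges:
                out.append((int(i), charges.charges[key]))
            else:
                missing.append(key)
        return out, missing

    qa, miss_a = _charged(idx_a)
    qb, miss_b = _charged(idx_b)
    missing = miss_a + miss_b
    if missing:
        if charges.on_missing == "error":
            raise ValueError(f"atoms without charges: {sorted(set(missing))}")
        if charges.on_missing == "warn":
            warnings.warn(f"{len(missing)} atoms without charges skipped",
                          stacklevel=2)
    energy = 0.0
    for i, qi in qa:
        for j, qj in qb:
            r = float(np.linalg.norm(conf.coords[i] - conf.coords[j]))
            if r == 0.0:
                raise ValueError(f"zero interatomic distance between atoms {i} and {j}")
            energy += qi * qj / r
    return charges.k / charges.dielectric * energy


# ---------------------------------------------------------------------------
# Superposition & RMSD
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transform:
    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_not_degenerate(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError("superposition needs >= 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selection is collinear or degenerate")


def kabsch(ref: np.ndarray, mobile: np.ndarray) -> tuple[Transform, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``ref`` (proper
    rotation enforced); returns the transform and the fitted RMSD."""
    ref = np.asarray(ref, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if ref.shape != mobile.shape:
        raise ValueError("coordinate sets must have identical shape")
    _check_not_degenerate(ref)
    _check_not_degenerate(mobile)
    mu_r = ref.mean(axis=0)
    mu_m = mobile.mean(axis=0)
    h = (mobile - mu_m).T @ (ref - mu_r)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_r - rot @ mu_m
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt(((fitted - ref) ** 2).sum(axis=1).mean()))
    return Transform(rotation=rot, translation=trans), rmsd


def superpose(
    ref: Conformation,
    mobile: Conformation,
    selection: Iterable[str] | str,
) -> tuple[Transform, float]:
    """Kabsch fit of ``mobile`` onto ``ref`` over a shared selection."""
    idx_r = resolve_selection(ref, selection)
    idx_m = resolve_selection(mobile, selection)
    if idx_r.size != idx_m.size:
        raise ValueError("selection resolves to different atom counts")
    return kabsch(ref.coords[idx_r], mobile.coords[idx_m])


def residue_rmsd(
    ens: Ensemble,
    fit_selection: Iterable[str] | str,
    target_residue: Iterable[str] | str,
    reference: int | Conformation = 0,
) -> list[float]:
    """Per-frame RMSD of a target residue after superposing each frame onto
    the reference via ``fit_selection`` (no refitting on the target)."""
    ref = (ens.conformations[reference] if isinstance(reference, int)
           else reference)
    idx_fit_ref = resolve_selection(ref, fit_selection)
    idx_tgt_ref = resolve_selection(ref, target_residue)
    out = []
    for conf in ens.conformations:
        idx_fit = resolve_selection(conf, fit_selection)
        idx_tgt = resolve_selection(conf, target_residue)
        transform, _ = kabsch(ref.coords[idx_fit_ref], conf.coords[idx_fit])
        moved = transform.apply(conf.coords[idx_tgt])
        diff = moved - ref.coords[idx_tgt_ref]
        out.append(float(np.sqrt((diff**2).sum(axis=1).mean())))
    return out


def min_distance(
    conf: Conformation,
    sel_a: Iterable[str] | str,
    sel_b: Iterable[str] | str,
) -> tuple[float, tuple[int, int]]:
    """Minimum cross-pair distance between two disjoint selections, with the
    achieving atom-index pair (ties broken by atom order)."""
    idx_a = resolve_selection(conf, sel_a)
    idx_b = resolve_selection(conf, sel_b)
    _require_disjoint(idx_a, idx_b)
    diffs = conf.coords[idx_a][:, None, :] - conf.coords[idx_b][None, :, :]
    dists = np.sqrt((diffs**2).sum(axis=2))
    flat = int(np.argmin(dists))
    ia, ib = np.unravel_index(flat, dists.shape)
    return float(dists[ia, ib]), (int(idx_a[ia]), int(idx_b[ib]))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def contacts_to_tsv(records: Sequence[ContactRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("frame\tkind\tres_a\tres_b\tatom_a\tatom_b\tdistance\n")
        for r in records:
            fh.write(f"{r.frame}\t{r.kind}\t{r.res_a}\t{r.res_b}\t"
                     f"{r.atom_a}\t{r.atom_b}\t{r.distance:.6g}\n")


def prevalence_to_tsv(prev: Mapping[tuple[str, str, str], float], path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tres_a\tres_b\tprevalence\n")
        for (kind, ra, rb) in sorted(prev):
            fh.write(f"{kind}\t{ra}\t{rb}\t{prev[(kind, ra, rb)]:.6g}\n")


def provenance_json(criteria: ContactCriteria, extra: Mapping | None = None) -> str:
    payload = {"criteria": criteria.to_dict()}
    if extra:
        payload.update(extra)
    return json.dumps(payload, indent=2, sort_keys=True)
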