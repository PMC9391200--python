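"""Synthetic peptide repertoires, WT/mutant pairs, allotype panels and
coordinate ensembles with known ground truth.

Every generator is a pure function of its spec plus seed: rerunning with the
same inputs reproduces byte-identical output. Ground truth is echoed back in a
:class:`TruthRecord` so recovery tests never need the original parameters out
of band.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .alphabet import AMINO_ACIDS, AA_INDEX
from .contacts import Conformation, Ensemble
from .io import AllotypeRecord, BackgroundComposition, PeptideRecord, Repertoire
from .positional import PositionLabel, resolve_position

# Average vertebrate-style proteome composition with the D+E mass pinned to
# 0.117 (D 0.055 / E 0.062); the remaining 18 residues follow the standard
# Swiss-Prot average, renormalized. Configuration values, not claimed results.
_SWISSPROT_PCT = {
    "A": 8.25, "R": 5.53, "N": 4.06, "C": 1.38, "Q": 3.93, "G": 7.07,
    "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84, "M": 2.41, "F": 3.86,
    "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}


def default_background() -> BackgroundComposition:
    rest_total = sum(_SWISSPROT_PCT.values())
    freq = {aa: 0.883 * pct / rest_total for aa, pct in _SWISSPROT_PCT.items()}
    freq["D"] = 0.055
    freq["E"] = 0.062
    total = sum(freq.values())
    return BackgroundComposition({aa: f / total for aa, f in freq.items()})


DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {
    8: 0.10, 9: 0.45, 10: 0.20, 11: 0.12, 12: 0.08, 13: 0.05,
}

# A2-like and A24-like anchor preferences used as ready-made motif presets.
A2_ANCHORS: dict[str, dict[str, float]] = {
    "p2": {"L": 0.85, "M": 0.10, "I": 0.05},
    "pO": {"V": 0.60, "L": 0.30, "I": 0.10},
}
A24_ANCHORS: dict[str, dict[str, float]] = {
    "p2": {"Y": 0.80, "F": 0.15, "W": 0.05},
    "pO": {"F": 0.60, "L": 0.25, "I": 0.15},
}


def solve_joint_2x2(p_a: float, p_b: float, odds_ratio: float) -> np.ndarray:
    """Joint probabilities [[p11, p10], [p01, p00]] of two binary indicators
    with the given margins and odds ratio (exact quadratic solve)."""
    for name, p in (("margin A", p_a), ("margin B", p_b)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} outside [0, 1]")
    if odds_ratio < 0:
        raise ValueError("odds ratio must be >= 0")
    lower = max(0.0, p_a + p_b - 1.0)
    upper = min(p_a, p_b)
    if odds_ratio == 1.0:
        p11 = p_a * p_b
    elif odds_ratio == 0.0:
        p11 = lower
        if lower > 0 and p_a not in (0, 1) and p_b not in (0, 1):
            raise ValueError("odds ratio 0 infeasible with these margins")
    else:
        w = odds_ratio - 1.0
        s = 1.0 + (p_a + p_b) * w
        disc = s * s - 4.0 * odds_ratio * w * p_a * p_b
        if disc < 0:
            raise ValueError("no valid 2x2 table for these margins and OR")
        p11 = (s - math.sqrt(disc)) / (2.0 * w)
    if not (lower - 1e-12 <= p11 <= upper + 1e-12):
        raise ValueError("margins and odds ratio are jointly infeasible")
    p11 = min(max(p11, lower), upper)
    joint = np.array([
        [p11, p_a - p11],
        [p_b - p11, 1.0 - p_a - p_b + p11],
    ])
    if (joint < -1e-12).any():
        raise ValueError("margins and odds ratio are jointly infeasible")
    return np.clip(joint, 0.0, 1.0)


@dataclass(frozen=True)
class RepertoireSpec:
    """Parameters of one synthetic repertoire."""

    n: int
    seed: int
    name: str = "synthetic"
    length_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION))
    background: BackgroundComposition = field(default_factory=default_background)
    anchor_prefs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    p4_DE_freq: float | None = None
    p1_KR_freq: float | None = None
    coupling_or: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        total = sum(self.length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("length distribution must sum to 1")
        for length in self.length_distribution:
            if not 8 <= length <= 13:
                raise ValueError("peptide lengths must lie in 8-13")
        for freq in (self.p4_DE_freq, self.p1_KR_freq):
            if freq is not None and not 0.0 <= freq <= 1.0:
                raise ValueError("class frequency outside [0, 1]")
        if self.coupling_or < 0:
            raise ValueError("coupling odds ratio must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Generator parameters echoed beside the generated data."""

    kind: str
    params: Mapping
    seed: int

    def to_json(self) -> str:
        def _default(obj):
            if isinstance(obj, BackgroundComposition):
                return dict(obj.freq)
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            raise TypeError(f"unserializable {type(obj)}")

        return json.dumps(
            {"kind": self.kind, "seed": self.seed, "params": self.params},
            indent=2, sort_keys=True, default=_default,
        )


_KR = [AA_INDEX["K"], AA_INDEX["R"]]
_DE = [AA_INDEX["D"], AA_INDEX["E"]]


def _class_conditional_probs(background: np.ndarray, members: list[int]):
    """(inside-class, outside-class) conditional sampling distributions."""
    inside = np.zeros_like(background)
    inside[members] = background[members]
    if inside.sum() == 0:
        inside[members] = 1.0
    inside /= inside.sum()
    outside = background.copy()
    outside[members] = 0.0
    outside /= outside.sum()
    return inside, outside


def _sample_columns(rng, m: int, probs: np.ndarray) -> np.ndarray:
    return rng.choice(len(probs), size=m, p=probs)


def _generate_batch(rng, m: int, spec: RepertoireSpec) -> list[str]:
    """Vectorized draw of ``m`` peptides (possibly containing duplicates)."""
    bg = spec.background.as_array()
    lengths = np.array(sorted(spec.length_distribution))
    length_p = np.array([spec.length_distribution[l] for l in lengths])
    drawn = rng.choice(lengths, size=m, p=length_p)

    joint = None
    if spec.p1_KR_freq is not None or spec.p4_DE_freq is not None:
        p_kr = spec.p1_KR_freq if spec.p1_KR_freq is not None else float(bg[_KR].sum())
        p_de = spec.p4_DE_freq if spec.p4_DE_freq is not None else float(bg[_DE].sum())
        joint = solve_joint_2x2(p_kr, p_de, spec.coupling_or)

    kr_in, kr_out = _class_conditional_probs(bg, _KR)
    de_in, de_out = _class_conditional_probs(bg, _DE)

    anchor_cols: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for label_txt, prefs in spec.anchor_prefs.items():
        res = list(prefs)
        p = np.array([prefs[r] for r in res], dtype=float)
        p /= p.sum()
        anchor_cols[label_txt] = (np.array([AA_INDEX[r] for r in res]), p)

    peptides: list[str] = []
    letters = np.frombuffer("".join(AMINO_ACIDS).encode(), dtype=np.uint8)
    for length in np.unique(drawn):
        count = int((drawn == length).sum())
        mat = rng.choice(20, size=(count, int(length)), p=bg)
        for label_txt, (res_idx, p) in anchor_cols.items():
            label = PositionLabel.parse(label_txt)
            col = resolve_position(label, int(length))
            mat[:, col] = res_idx[rng.choice(len(res_idx), size=count, p=p)]
        if joint is not None:
            cells = rng.choice(4, size=count, p=joint.ravel())
            kr_flag = cells < 2  # rows of the joint: (KR & DE), (KR only), ...
            de_flag = (cells == 0) | (cells == 2)
            p1 = resolve_position(PositionLabel("N", 0), int(length))
            p4 = resolve_position(PositionLabel("N", 3), int(length))
            n_in = int(kr_flag.sum())
            mat[kr_flag, p1] = _sample_columns(rng, n_in, kr_in)
            mat[~kr_flag, p1] = _sample_columns(rng, count - n_in, kr_out)
            n_in = int(de_flag.sum())
            mat[de_flag, p4] = _sample_columns(rng, n_in, de_in)
            mat[~de_flag, p4] = _sample_columns(rng, count - n_in, de_out)
        rows = letters[mat]
        peptides.extend(bytes(rows[i]).decode() for i in range(count))
    return peptides


RESAMPLE_CAP_FACTOR = 100


def generate_repertoire(spec: RepertoireSpec) -> tuple[Repertoire, TruthRecord]:
    """Sample ``spec.n`` unique peptides under the spec's composition model.

    Duplicates are resampled until the repertoire holds exactly n unique
    sequences; if 100*n draws do not suffice, an error is raised.
    """
    rng = np.random.default_rng(spec.seed)
    unique: dict[str, None] = {}
    draws = 0
    cap = RESAMPLE_CAP_FACTOR * max(spec.n, 1)
    while len(unique) < spec.n:
        need = spec.n - len(unique)
        batch = max(need + need // 10 + 16, 64)
        if draws + batch > cap:
            batch = cap - draws
            if batch <= 0:
                raise RuntimeError(
                    f"resample cap exceeded: {draws} draws for {spec.n} unique"
                )
        for pep in _generate_batch(rng, batch, spec):
            if pep not in unique:
                unique[pep] = None
                if len(unique) == spec.n:
                    break
        draws += batch
    rep = Repertoire(
        name=spec.name,
        peptides=tuple(PeptideRecord(sequence=s, allotype=spec.name)
                       for s in unique),
    )
    truth = TruthRecord(
        kind="repertoire",
        params={
            "n": spec.n, "name": spec.name,
            "length_distribution": dict(spec.length_distribution),
            "anchor_prefs": {k: dict(v) for k, v in spec.anchor_prefs.items()},
            "p4_DE_freq": spec.p4_DE_freq, "p1_KR_freq": spec.p1_KR_freq,
            "coupling_or": spec.coupling_or,
            "background": spec.background,
        },
        seed=spec.seed,
    )
    return rep, truth


def generate_wt_mutant_pair(
    base: RepertoireSpec,
    shifts: Mapping[str, float],
    size_ratio: float,
) -> tuple[Repertoire, Repertoire, TruthRecord]:
    """WT repertoire plus a mutant with shifted class frequencies and scaled
    size. ``shifts`` keys: ``p4_DE`` and/or ``p1_KR`` (additive deltas)."""
    if size_ratio <= 0:
        raise ValueError("size_ratio must be > 0")
    unknown = set(shifts) - {"p4_DE", "p1_KR"}
    if unknown:
        raise ValueError(f"unknown shift keys: {sorted(unknown)}")
    bg = base.background.as_array()

    def _shifted(current: float | None, members, delta: float) -> float:
        start = current if current is not None else float(bg[members].sum())
        new = start + delta
        if not 0.0 <= new <= 1.0:
            raise ValueError(f"shifted frequency {new:.4g} outside [0, 1]")
        return new

    ss = np.random.SeedSequence(base.seed)
    child_wt, child_mut = ss.spawn(2)
    wt_spec = dataclasses.replace(
        base, name=f"{base.name}-WT", seed=int(child_wt.generate_state(1)[0]))
    mut_kwargs: dict = {
        "name": f"{base.name}-mutant",
        "n": max(int(round(base.n * size_ratio)), 0),
        "seed": int(child_mut.generate_state(1)[0]),
    }
    if "p4_DE" in shifts:
        mut_kwargs["p4_DE_freq"] = _shifted(base.p4_DE_freq, _DE, shifts["p4_DE"])
    if "p1_KR" in shifts:
        mut_kwargs["p1_KR_freq"] = _shifted(base.p1_KR_freq, _KR, shifts["p1_KR"])
    mut_spec = dataclasses.replace(base, **mut_kwargs)
    wt, _ = generate_repertoire(wt_spec)
    mut, _ = generate_repertoire(mut_spec)
    truth = TruthRecord(
        kind="wt_mutant_pair",
        params={
            "base_n": base.n, "size_ratio": size_ratio,
            "shifts": dict(shifts),
            "wt_p4_DE": wt_spec.p4_DE_freq, "wt_p1_KR": wt_spec.p1_KR_freq,
            "mut_p4_DE": mut_spec.p4_DE_freq, "mut_p1_KR": mut_spec.p1_KR_freq,
        },
        seed=base.seed,
    )
    return wt, mut, truth


@dataclass(frozen=True)
class GroupSpec:
    """One allotype group in a synthetic panel."""

    count: int
    mean_freq: float
    sd: float
    cleft: Mapping[int, str]  # residues planted at mature positions

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not 0.0 <= self.mean_freq <= 1.0:
            raise ValueError("mean_freq outside [0, 1]")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


_TEMPLATE_LENGTH = 275


def _synthetic_allele_sequence(cleft: Mapping[int, str]) -> str:
    seq = ["A"] * _TEMPLATE_LENGTH
    for pos, res in cleft.items():
        if not 1 <= pos <= _TEMPLATE_LENGTH:
            raise ValueError(f"cleft position {pos} outside template")
        seq[pos - 1] = res
    return "".join(seq)


def generate_allotype_panel(
    groups: Mapping[str, GroupSpec],
    peptides_per_allotype: int,
    seed: int,
    coupling_or: float = 1.0,
) -> tuple[dict[str, Repertoire], dict[str, AllotypeRecord], TruthRecord]:
    """Panel of synthetic allotypes: per-allotype D/E4 class frequency drawn
    from a truncated normal around its group mean; allele sequences carry the
    group's defining cleft residues."""
    rng = np.random.default_rng(seed)
    reps: dict[str, Repertoire] = {}
    records: dict[str, AllotypeRecord] = {}
    realized: dict[str, list[float]] = {}
    for label in groups:
        gspec = groups[label]
        realized[label] = []
        for i in range(gspec.count):
            if gspec.sd == 0:
                freq = gspec.mean_freq
            else:
                lo = (0.0 - gspec.mean_freq) / gspec.sd
                hi = (1.0 - gspec.mean_freq) / gspec.sd
                freq = float(stats.truncnorm.rvs(
                    lo, hi, loc=gspec.mean_freq, scale=gspec.sd,
                    random_state=rng))
            name = f"{label}-{i:02d}"
            child_seed = int(rng.integers(0, 2**63 - 1))
            rep, _ = generate_repertoire(RepertoireSpec(
                n=peptides_per_allotype, seed=child_seed, name=name,
                p4_DE_freq=freq, coupling_or=coupling_or,
            ))
            reps[name] = rep
            records[name] = AllotypeRecord(
                name=name,
                mature_sequence=_synthetic_allele_sequence(gspec.cleft),
            )
            realized[label].append(freq)
    truth = TruthRecord(
        kind="allotype_panel",
        params={
            "groups": {g: dataclasses.asdict(s) | {"cleft": dict(s.cleft)}
                       for g, s in groups.items()},
            "peptides_per_allotype": peptides_per_allotype,
            "realized_freqs": realized,
        },
        seed=seed,
    )
    return reps, records, truth


# ---------------------------------------------------------------------------
# Coordinate ensembles with planted contacts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantSpec:
    """One planted interaction: its kind, the frames containing it, and the
    planted characteristic distance (defaults leave >= 0.5 A margin)."""

    kind: str  # salt_bridge | hbond | pi_cation | pi_stack
    frames: tuple[int, ...]
    distance: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("salt_bridge", "hbond", "pi_cation", "pi_stack"):
            raise ValueError(f"unknown contact kind {self.kind!r}")


_DEFAULT_PLANT_DISTANCE = {
    "salt_bridge": 3.5, "hbond": 3.0, "pi_cation": 5.0, "pi_stack": 4.5,
}
_PLANT_CUTOFF_ATTR = {
    "salt_bridge": "salt_bridge_cutoff", "hbond": "hbond_da_cutoff",
    "pi_cation": "pi_cation_cutoff", "pi_stack": "pi_stack_cutoff",
}

_RING_OFFSETS = 1.39 * np.array([
    [math.cos(a), math.sin(a), 0.0]
    for a in np.linspace(0.0, 2 * math.pi, 6, endpoint=False)
])
_PHE_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")

_CELL_SPACING = 60.0
_ABSENT_SHIFT = 25.0


def _plant_atoms(kind: str, origin: np.ndarray, distance: float):
    """(chain A atoms, chain B atoms) realizing one planted contact.

    Atoms are (res_name, atom_name, element, xyz) tuples; partner B sits
    ``distance`` along +x from the relevant A site/centroid.
    """
    a_atoms, b_atoms = [], []
    if kind == "salt_bridge":
        a_atoms.append(("ARG", "NH1", "N", origin))
        b_atoms.append(("GLU", "OE1", "O", origin + [distance, 0.0, 0.0]))
    elif kind == "hbond":
        a_atoms.append(("SER", "OG", "O", origin))
        b_atoms.append(("GLN", "OE1", "O", origin + [distance, 0.0, 0.0]))
    elif kind == "pi_cation":
        a_atoms.append(("LYS", "NZ", "N", origin))
        center = origin + [distance, 0.0, 0.0]
        for name, off in zip(_PHE_RING_NAMES, _RING_OFFSETS):
            b_atoms.append(("PHE", name, "C", center + off @ _rot_yz()))
    elif kind == "pi_stack":
        for name, off in zip(_PHE_RING_NAMES, _RING_OFFSETS):
            a_atoms.append(("PHE", name, "C", origin + off))
        center = origin + [0.0, 0.0, distance]
        for name, off in zip(_PHE_RING_NAMES, _RING_OFFSETS):
            b_atoms.append(("PHE", name, "C", center + off))
    return a_atoms, b_atoms


def _rot_yz() -> np.ndarray:
    # stand the acceptor ring perpendicular to the cation approach axis
    return np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])


def generate_ensemble(
    n_frames: int,
    decoy_atoms: int,
    plants: Sequence[PlantSpec],
    jitter_sigma: float = 0.0,
    seed: int = 0,
    criteria=None,
) -> tuple[Ensemble, TruthRecord]:
    """Ensemble with contacts planted in known frames among inert decoys.

    Plants live between chains A and B; frames not listed for a plant have the
    chain-B partner displaced far beyond its cutoff. Gaussian jitter is added
    to every atom; plant partners are re-jittered (bounded retries) so plants
    are present in exactly their listed frames, making prevalence exact.
    Decoy atoms are aliphatic carbons on a wide grid and cannot satisfy any
    interaction criterion.
    """
    from .contacts import ContactCriteria

    criteria = criteria or ContactCriteria()
    if n_frames < 1:
        raise ValueError("need >= 1 frame")
    for plant in plants:
        if any(not 0 <= f < n_frames for f in plant.frames):
            raise ValueError("plant frame index out of range")
    rng = np.random.default_rng(seed)

    chains, res_ids, res_names, atom_names, elements, coords = [], [], [], [], [], []
    plant_a_atoms: list[list[int]] = []  # indices of chain-A partner atoms
    plant_b_atoms: list[list[int]] = []  # indices of chain-B partner atoms
    plant_meta = []
    res_counter = {"A": 0, "B": 0}

    def _add(chain: str, res_id: int, res_name: str, atom_name: str,
             element: str, xyz) -> int:
        chains.append(chain)
        res_ids.append(res_id)
        res_names.append(res_name)
        atom_names.append(atom_name)
        elements.append(element)
        coords.append(np.asarray(xyz, dtype=float))
        return len(chains) - 1

    for pi, plant in enumerate(plants):
        distance = plant.distance
        if distance is None:
            distance = _DEFAULT_PLANT_DISTANCE[plant.kind]
        cutoff = getattr(criteria, _PLANT_CUTOFF_ATTR[plant.kind])
        if distance > cutoff - 0.2:
            raise ValueError(
                f"plant {pi}: distance {distance} leaves < 0.2 A margin "
                f"below cutoff {cutoff}"
            )
        origin = np.array([_CELL_SPACING * pi, 0.0, 0.0])
        a_atoms, b_atoms = _plant_atoms(plant.kind, origin, distance)
        res_counter["A"] += 1
        res_a = res_counter["A"]
        a_idx = [
            _add("A", res_a, rn, an, el, xyz) for rn, an, el, xyz in a_atoms
        ]
        res_counter["B"] += 1
        res_b = res_counter["B"]
        b_idx = [
            _add("B", res_b, rn, an, el, xyz) for rn, an, el, xyz in b_atoms
        ]
        plant_a_atoms.append(a_idx)
        plant_b_atoms.append(b_idx)
        plant_meta.append({
            "kind": plant.kind, "frames": list(plant.frames),
            "distance": distance,
            "res_a": f"A:{res_a}", "res_b": f"B:{res_b}",
        })

    # inert decoys: lone aliphatic carbons on a wide grid away from plants
    grid = int(math.ceil(decoy_atoms ** (1.0 / 3.0))) or 1
    placed = 0
    for gx in range(grid):
        for gy in range(grid):
            for gz in range(grid):
                if placed >= decoy_atoms:
                    break
                chain = "A" if placed % 2 == 0 else "B"
                res_counter[chain] += 1
                _add(chain, res_counter[chain], "ALA", "CB", "C",
                     [-100.0 - 8.0 * gx, -100.0 - 8.0 * gy, -100.0 - 8.0 * gz])
                placed += 1

    base = np.stack(coords)
    frames = []
    for f in range(n_frames):
        xyz = base.copy()
        # displace absent plants before jitter
        for pi, plant in enumerate(plants):
            if f not in plant.frames:
                xyz[plant_b_atoms[pi]] += np.array([_ABSENT_SHIFT, 0.0, 0.0])
        if jitter_sigma > 0:
            xyz = xyz + rng.normal(0.0, jitter_sigma, size=xyz.shape)
            # keep present plants qualifying: bounded re-jitter of partners
            for pi, plant in enumerate(plants):
                if f not in plant.frames:
                    continue
                cutoff = getattr(criteria, _PLANT_CUTOFF_ATTR[plant.kind])
                pair_idx = plant_a_atoms[pi] + plant_b_atoms[pi]
                margin = cutoff - plant_meta[pi]["distance"]
                for _try in range(100):
                    shift = xyz[pair_idx] - base[pair_idx]
                    span = np.linalg.norm(shift, axis=1).max()
                    if span < margin / 2.0:
                        break
                    xyz[pair_idx] = base[pair_idx] + rng.normal(
                        0.0, jitter_sigma, size=(len(pair_idx), 3))
                else:
                    raise RuntimeError("could not keep plant within margin")
        frames.append(Conformation(
            chain_id=np.array(chains, dtype=object),
            res_id=np.array(res_ids, dtype=int),
            icode=np.array([""] * len(chains), dtype=object),
            res_name=np.array(res_names, dtype=object),
            atom_name=np.array(atom_names, dtype=object),
            element=np.array(elements, dtype=object),
            coords=xyz,
        ))
    truth = TruthRecord(
        kind="ensemble",
        params={
            "n_frames": n_frames, "decoy_atoms": decoy_atoms,
            "jitter_sigma": jitter_sigma, "plants": plant_meta,
        },
        seed=seed,
    )
    return Ensemble(conformations=tuple(frames)), truth
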