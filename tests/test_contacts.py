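import math

import numpy as np
import pytest

from pepcleft import (
    ChargeSet,
    Conformation,
    ContactCriteria,
    Ensemble,
    contact_prevalence,
    coulomb_pair,
    detect_contacts,
    min_distance,
    read_structure,
    residue_rmsd,
    superpose,
    write_structure,
)
from pepcleft.contacts import kabsch, resolve_selection
from pepcleft.simulate import PlantSpec, generate_ensemble


def make_conf(atoms):
    """atoms: list of (chain, res_id, res_name, atom_name, element, xyz)."""
    return Conformation(
        chain_id=np.array([a[0] for a in atoms], dtype=object),
        res_id=np.array([a[1] for a in atoms], dtype=int),
        icode=np.array([""] * len(atoms), dtype=object),
        res_name=np.array([a[2] for a in atoms], dtype=object),
        atom_name=np.array([a[3] for a in atoms], dtype=object),
        element=np.array([a[4] for a in atoms], dtype=object),
        coords=np.array([a[5] for a in atoms], dtype=float),
    )


# ---------------------------------------------------------------------------
# Independent brute-force oracle (plain loops, own constant tables)
# ---------------------------------------------------------------------------

_ORACLE_BASIC = {("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"), ("LYS", "NZ")}
_ORACLE_ACID = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_ORACLE_DONORS = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
                  ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"),
                  ("HIS", "NE2"), ("TRP", "NE1"), ("LYS", "NZ"),
                  ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}
_ORACLE_ACCEPT = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"),
                  ("GLU", "OE2"), ("ASN", "OD1"), ("GLN", "OE1"),
                  ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
                  ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD")}
_ORACLE_RINGS = {"PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
                 "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
                 "TRP": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3",
                         "CZ2", "CZ3", "CH2"]}


def oracle_contacts(conf, criteria, chain_a, chain_b):
    """O(n^2) re-derivation of the contact definitions with explicit loops."""
    n = len(conf)
    idx_a = [i for i in range(n) if conf.chain_id[i] == chain_a]
    idx_b = [i for i in range(n) if conf.chain_id[i] == chain_b]

    def dist(i, j):
        return math.dist(conf.coords[i], conf.coords[j])

    found = set()
    ionic = set()
    for i in idx_a:
        for j in idx_b:
            ki = (conf.res_name[i], conf.atom_name[i])
            kj = (conf.res_name[j], conf.atom_name[j])
            is_salt = ((ki in _ORACLE_BASIC and kj in _ORACLE_ACID)
                       or (ki in _ORACLE_ACID and kj in _ORACLE_BASIC))
            if is_salt and dist(i, j) <= criteria.salt_bridge_cutoff:
                found.add(("salt_bridge", conf.residue_key(i),
                           conf.residue_key(j)))
                ionic.add((i, j))
    for i in idx_a:
        for j in idx_b:
            if (i, j) in ionic:
                continue
            ki = (conf.res_name[i], conf.atom_name[i])
            kj = (conf.res_name[j], conf.atom_name[j])
            i_don = ki in _ORACLE_DONORS or (conf.atom_name[i] == "N"
                                             and conf.res_name[i] != "PRO")
            i_acc = kj in _ORACLE_ACCEPT or conf.atom_name[j] in ("O", "OXT")
            j_don = kj in _ORACLE_DONORS or (conf.atom_name[j] == "N"
                                             and conf.res_name[j] != "PRO")
            j_acc = ki in _ORACLE_ACCEPT or conf.atom_name[i] in ("O", "OXT")
            if ((i_don and i_acc) or (j_don and j_acc)) \
                    and dist(i, j) <= criteria.hbond_da_cutoff:
                found.add(("hbond", conf.residue_key(i), conf.residue_key(j)))

    def rings(indices):
        by_res = {}
        for i in indices:
            key = (conf.chain_id[i], conf.res_id[i], conf.icode[i],
                   conf.res_name[i])
            by_res.setdefault(key, {})[conf.atom_name[i]] = i
        out = []
        for key, atoms in by_res.items():
            names = _ORACLE_RINGS.get(key[3])
            if names and all(nm in atoms for nm in names):
                pts = np.array([conf.coords[atoms[nm]] for nm in names])
                out.append((key, pts.mean(axis=0)))
        return out

    def cations(indices):
        by_res = {}
        for i in indices:
            key = (conf.chain_id[i], conf.res_id[i], conf.icode[i],
                   conf.res_name[i])
            by_res.setdefault(key, {})[conf.atom_name[i]] = i
        out = []
        for key, atoms in by_res.items():
            if key[3] == "LYS" and "NZ" in atoms:
                out.append((key, conf.coords[atoms["NZ"]]))
            elif key[3] == "ARG" and all(nm in atoms
                                         for nm in ("CZ", "NH1", "NH2")):
                pts = np.array([conf.coords[atoms[nm]]
                                for nm in ("CZ", "NH1", "NH2")])
                out.append((key, pts.mean(axis=0)))
        return out

    def label(key):
        return f"{key[0]}:{key[1]}{key[2]}:{key[3]}"

    rings_a, rings_b = rings(idx_a), rings(idx_b)
    for ck, cp in cations(idx_a):
        for rk, rp in rings_b:
            if math.dist(cp, rp) <= criteria.pi_cation_cutoff:
                found.add(("pi_cation", label(ck), label(rk)))
    for ck, cp in cations(idx_b):
        for rk, rp in rings_a:
            if math.dist(cp, rp) <= criteria.pi_cation_cutoff:
                found.add(("pi_cation", label(rk), label(ck)))
    for ka, pa in rings_a:
        for kb, pb in rings_b:
            if math.dist(pa, pb) <= criteria.pi_stack_cutoff:
                found.add(("pi_stack", label(ka), label(kb)))
    return found


def quaternion_rmsd(ref, mobile):
    """Independent superposition RMSD via the quaternion eigenvalue method."""
    ref = ref - ref.mean(axis=0)
    mob = mobile - mobile.mean(axis=0)
    r = mob.T @ ref
    f = np.array([
        [r[0, 0] + r[1, 1] + r[2, 2], r[1, 2] - r[2, 1],
         r[2, 0] - r[0, 2], r[0, 1] - r[1, 0]],
        [r[1, 2] - r[2, 1], r[0, 0] - r[1, 1] - r[2, 2],
         r[0, 1] + r[1, 0], r[0, 2] + r[2, 0]],
        [r[2, 0] - r[0, 2], r[0, 1] + r[1, 0],
         -r[0, 0] + r[1, 1] - r[2, 2], r[1, 2] + r[2, 1]],
        [r[0, 1] - r[1, 0], r[0, 2] + r[2, 0],
         r[1, 2] + r[2, 1], -r[0, 0] - r[1, 1] + r[2, 2]],
    ])
    lam = np.linalg.eigvalsh(f)[-1]
    sq = ((ref**2).sum() + (mob**2).sum() - 2.0 * lam) / len(ref)
    return math.sqrt(max(sq, 0.0))


def random_rigid_motion(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-20, 20, size=3)


class TestDetect:
    def test_salt_bridge_within_cutoff(self):
        conf = make_conf([
            ("A", 1, "ARG", "NH1", "N", (0, 0, 0)),
            ("B", 1, "GLU", "OE1", "O", (3.9, 0, 0)),
        ])
        recs = detect_contacts(conf, ContactCriteria(), "A", "B")
        assert len(recs) == 1
        assert recs[0].kind == "salt_bridge"
        assert recs[0].distance == pytest.approx(3.9)

    def test_salt_bridge_outside_cutoff(self):
        conf = make_conf([
            ("A", 1, "ARG", "NH1", "N", (0, 0, 0)),
            ("B", 1, "GLU", "OE1", "O", (4.1, 0, 0)),
        ])
        assert detect_contacts(conf, ContactCriteria(), "A", "B") == []

    def test_hbond_angle_with_explicit_hydrogen(self):
        criteria = ContactCriteria()
        good = make_conf([
            ("A", 1, "SER", "OG", "O", (0, 0, 0)),
            ("A", 1, "SER", "HG", "H", (1.0, 0, 0)),
            ("B", 1, "GLN", "OE1", "O", (3.0, 0, 0)),
        ])
        recs = detect_contacts(good, criteria, "A", "B")
        assert [r.kind for r in recs] == ["hbond"]
        bad = make_conf([
            ("A", 1, "SER", "OG", "O", (0, 0, 0)),
            ("A", 1, "SER", "HG", "H", (-1.0, 0, 0)),  # points away: ~0 deg
            ("B", 1, "GLN", "OE1", "O", (3.0, 0, 0)),
        ])
        assert detect_contacts(bad, criteria, "A", "B") == []

    def test_empty_selection_errors(self):
        conf = make_conf([("A", 1, "ALA", "CB", "C", (0, 0, 0))])
        with pytest.raises(ValueError):
            detect_contacts(conf, ContactCriteria(), "A", "Z")

    def test_planted_set_matches_oracle(self):
        for seed in range(6):
            plants = [
                PlantSpec("salt_bridge", frames=(0,)),
                PlantSpec("hbond", frames=(0,)),
                PlantSpec("pi_cation", frames=(0,)),
                PlantSpec("pi_stack", frames=(0,)),
            ]
            ens, truth = generate_ensemble(1, 200, plants,
                                           jitter_sigma=0.05, seed=seed)
            conf = ens.conformations[0]
            criteria = ContactCriteria()
            detected = {r.identity
                        for r in detect_contacts(conf, criteria, "A", "B")}
            assert detected == oracle_contacts(conf, criteria, "A", "B")
            planted = {(p["kind"],
                        p["res_a"] + ":" + {"salt_bridge": "ARG",
                                            "hbond": "SER",
                                            "pi_cation": "LYS",
                                            "pi_stack": "PHE"}[p["kind"]],
                        p["res_b"] + ":" + {"salt_bridge": "GLU",
                                            "hbond": "GLN",
                                            "pi_cation": "PHE",
                                            "pi_stack": "PHE"}[p["kind"]])
                       for p in truth.params["plants"]}
            assert detected == planted

    def test_rigid_motion_invariance(self):
        ens, _ = generate_ensemble(1, 50, [PlantSpec("salt_bridge", (0,)),
                                           PlantSpec("pi_cation", (0,))],
                                   jitter_sigma=0.05, seed=8)
        conf = ens.conformations[0]
        criteria = ContactCriteria()
        base = detect_contacts(conf, criteria, "A", "B")
        rng = np.random.default_rng(5)
        for _ in range(5):
            rot, trans = random_rigid_motion(rng)
            moved = conf.with_coords(conf.coords @ rot.T + trans)
            got = detect_contacts(moved, criteria, "A", "B")
            assert {r.identity for r in got} == {r.identity for r in base}
            for a, b in zip(sorted(base, key=lambda r: r.identity),
                            sorted(got, key=lambda r: r.identity)):
                assert a.distance == pytest.approx(b.distance, abs=1e-9)


class TestPrevalence:
    def test_always_present(self):
        ens, _ = generate_ensemble(5, 20, [PlantSpec("hbond", (0, 1, 2, 3, 4))],
                                   seed=1)
        prev = contact_prevalence(ens, ContactCriteria(), "A", "B")
        assert list(prev.values()) == [1.0]

    def test_13_of_20(self):
        ens, _ = generate_ensemble(20, 20,
                                   [PlantSpec("salt_bridge",
                                              tuple(range(13)))], seed=2)
        prev = contact_prevalence(ens, ContactCriteria(), "A", "B")
        assert list(prev.values()) == [0.65]

    def test_13_of_20_with_jitter(self):
        for seed in range(25):
            ens, _ = generate_ensemble(
                20, 10, [PlantSpec("salt_bridge", tuple(range(13)))],
                jitter_sigma=0.05, seed=seed)
            prev = contact_prevalence(ens, ContactCriteria(), "A", "B")
            assert list(prev.values()) == [0.65]

    def test_no_contacts_empty_table(self):
        ens, _ = generate_ensemble(3, 10, [], seed=3)
        assert contact_prevalence(ens, ContactCriteria(), "A", "B") == {}


class TestCoulomb:
    def test_unit_charges_at_4A(self):
        conf = make_conf([
            ("A", 1, "LYS", "NZ", "N", (0, 0, 0)),
            ("B", 1, "XXX", "Q1", "X", (4.0, 0, 0)),
        ])
        charges = ChargeSet({("LYS", "NZ"): 1.0, ("XXX", "Q1"): -1.0})
        e = coulomb_pair(conf, "A:1", "B:1", charges)
        assert e == pytest.approx(-83.0159, abs=1e-4)

    def test_dielectric_scaling(self):
        conf = make_conf([
            ("A", 1, "LYS", "NZ", "N", (0, 0, 0)),
            ("B", 1, "ASP", "OD1", "O", (3.0, 0, 0)),
        ])
        e1 = coulomb_pair(conf, "A:1", "B:1", ChargeSet.formal())
        e2 = coulomb_pair(conf, "A:1", "B:1",
                          ChargeSet.formal(dielectric=2.0))
        assert e2 == pytest.approx(e1 / 2.0, rel=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        conf = make_conf([
            ("A", 1, "ARG", "NH1", "N", rng.uniform(-5, 5, 3)),
            ("A", 1, "ARG", "NH2", "N", rng.uniform(-5, 5, 3)),
            ("B", 2, "GLU", "OE1", "O", rng.uniform(6, 10, 3)),
            ("B", 2, "GLU", "OE2", "O", rng.uniform(6, 10, 3)),
        ])
        charges = ChargeSet.formal()
        assert coulomb_pair(conf, "A:1", "B:2", charges) == pytest.approx(
            coulomb_pair(conf, "B:2", "A:1", charges), rel=1e-12)

    def test_bilinearity(self):
        conf = make_conf([
            ("A", 1, "LYS", "NZ", "N", (0, 0, 0)),
            ("B", 1, "ASP", "OD1", "O", (3.0, 0, 0)),
            ("B", 1, "ASP", "OD2", "O", (0, 3.0, 0)),
        ])
        base = {("LYS", "NZ"): 1.0, ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5}
        doubled = {k: 2 * v if k[0] == "LYS" else v for k, v in base.items()}
        e1 = coulomb_pair(conf, "A:1", "B:1", ChargeSet(base))
        e2 = coulomb_pair(conf, "A:1", "B:1", ChargeSet(doubled))
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_zero_distance_errors(self):
        conf = make_conf([
            ("A", 1, "LYS", "NZ", "N", (0, 0, 0)),
            ("B", 1, "ASP", "OD1", "O", (0, 0, 0)),
        ])
        with pytest.raises(ValueError):
            coulomb_pair(conf, "A:1", "B:1", ChargeSet.formal())

    def test_missing_charge_policy_error(self):
        conf = make_conf([
            ("A", 1, "LYS", "NZ", "N", (0, 0, 0)),
            ("B", 1, "GLY", "CA", "C", (3.0, 0, 0)),
        ])
        charges = ChargeSet.formal(on_missing="error")
        with pytest.raises(ValueError):
            coulomb_pair(conf, "A:1", "B:1", charges)


class TestSuperpose:
    def test_self_rmsd_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-10, 10, size=(8, 3))
        _, rmsd = kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-10, 10, size=(10, 3))
        rot, trans = random_rigid_motion(rng)
        _, rmsd = kabsch(pts, pts @ rot.T + trans)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_quaternion_oracle_agreement(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = rng.uniform(-10, 10, size=(10, 3))
            b = rng.uniform(-10, 10, size=(10, 3))
            _, rmsd = kabsch(a, b)
            assert rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-8)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-10, 10, size=(7, 3))
        b = rng.uniform(-10, 10, size=(7, 3))
        assert kabsch(a, b)[1] == pytest.approx(kabsch(b, a)[1], abs=1e-10)

    def test_proper_rotation(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-10, 10, size=(6, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirrored: best proper fit must still have det +1
        transform, _ = kabsch(a, b)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_collinear_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            kabsch(line, line)

    def test_superpose_selection(self):
        ens, _ = generate_ensemble(2, 30, [], jitter_sigma=0.2, seed=5)
        transform, rmsd = superpose(ens.conformations[0],
                                    ens.conformations[1], "A")
        assert rmsd > 0


class TestResidueRMSD:
    def _base(self):
        rng = np.random.default_rng(6)
        atoms = [("A", i + 1, "GLY", "CA", "C", rng.uniform(-10, 10, 3))
                 for i in range(6)]
        atoms += [("B", 1, "LYS", nm, "N", rng.uniform(5, 15, 3))
                  for nm in ("N", "CA", "CB", "NZ")]
        return make_conf(atoms)

    def test_reference_vs_itself(self):
        conf = self._base()
        ens = Ensemble((conf, conf))
        vals = residue_rmsd(ens, "A", "B:1", reference=0)
        assert vals == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_rigid_copies_zero(self):
        conf = self._base()
        rng = np.random.default_rng(7)
        frames = [conf]
        for _ in range(3):
            rot, trans = random_rigid_motion(rng)
            frames.append(conf.with_coords(conf.coords @ rot.T + trans))
        vals = residue_rmsd(Ensemble(tuple(frames)), "A", "B:1")
        assert vals == pytest.approx([0.0] * 4, abs=1e-9)

    def test_jittered_target_expectation(self):
        conf = self._base()
        sigma = 0.3
        rng = np.random.default_rng(8)
        frames = []
        target = resolve_selection(conf, "B:1")
        for _ in range(400):
            xyz = conf.coords.copy()
            xyz[target] += rng.normal(0, sigma, size=(len(target), 3))
            frames.append(conf.with_coords(xyz))
        vals = residue_rmsd(Ensemble(tuple(frames)), "A", "B:1",
                            reference=conf)
        expected = sigma * math.sqrt(3)
        assert abs(np.mean(vals) - expected) / expected < 0.10


class TestMinDistance:
    def test_two_atoms(self):
        conf = make_conf([
            ("A", 1, "GLY", "CA", "C", (0, 0, 0)),
            ("B", 1, "GLY", "CA", "C", (1.5, 2.0, 0)),
        ])
        d, _ = min_distance(conf, "A", "B")
        assert d == pytest.approx(2.5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        atoms = []
        for i in range(250):
            atoms.append(("A", i + 1, "GLY", "CA", "C", rng.uniform(0, 30, 3)))
        for i in range(250):
            atoms.append(("B", i + 1, "GLY", "CA", "C", rng.uniform(0, 30, 3)))
        conf = make_conf(atoms)
        d, (ia, ib) = min_distance(conf, "A", "B")
        brute = min(
            math.dist(conf.coords[i], conf.coords[j])
            for i in range(250) for j in range(250, 500))
        assert d == pytest.approx(brute, abs=1e-12)

    def test_overlapping_selections_error(self):
        conf = make_conf([
            ("A", 1, "GLY", "CA", "C", (0, 0, 0)),
            ("B", 1, "GLY", "CA", "C", (1, 0, 0)),
        ])
        with pytest.raises(ValueError):
            min_distance(conf, "A", ["A", "B"])


_PDB_ALTLOC = """\
ATOM      1  N  AARG A   1      11.104   6.134  -6.504  0.60  0.00           N
ATOM      2  N  BARG A   1      12.104   6.134  -6.504  0.40  0.00           N
ATOM      3  CA  ARG A   1      12.560   6.351  -6.351  1.00  0.00           C
END
"""

_PDB_WATER = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
END
"""


class TestReadStructure:
    def test_single_model(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(_PDB_WATER)
        ens = read_structure(p)
        assert len(ens) == 1

    def test_altloc_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(_PDB_ALTLOC)
        ens = read_structure(p)
        conf = ens.conformations[0]
        n_atoms = conf.atom_name == "N"
        assert n_atoms.sum() == 1
        assert conf.coords[n_atoms][0][0] == pytest.approx(11.104, abs=1e-3)

    def test_waters_excluded_by_default(self, tmp_path):
        p = tmp_path / "wat.pdb"
        p.write_text(_PDB_WATER)
        ens = read_structure(p)
        assert len(ens.conformations[0]) == 1
        ens_all = read_structure(p, exclude_hetero=False)
        assert len(ens_all.conformations[0]) == 2

    def test_multi_model_roundtrip(self, tmp_path):
        ens, _ = generate_ensemble(5, 30, [PlantSpec("hbond", (0, 2, 4))],
                                   jitter_sigma=0.02, seed=10)
        p = tmp_path / "ens.pdb"
        write_structure(ens, p)
        back = read_structure(p)
        assert len(back) == 5
        prev = contact_prevalence(back, ContactCriteria(), "A", "B")
        assert list(prev.values()) == [0.6]

    def test_inconsistent_models_error(self, tmp_path):
        text = ("MODEL        1\n"
                "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
                "ATOM      2  CA  GLY A   2       3.000   0.000   0.000  1.00  0.00           C\n"
                "ENDMDL\n"
                "MODEL        2\n"
                "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
                "ENDMDL\nEND\n")
        p = tmp_path / "bad.pdb"
        p.write_text(text)
        with pytest.raises(ValueError):
            read_structure(p)

    def test_ensemble_topology_enforced(self):
        c1 = make_conf([("A", 1, "GLY", "CA", "C", (0, 0, 0))])
        c2 = make_conf([("A", 2, "GLY", "CA", "C", (0, 0, 0))])
        with pytest.raises(ValueError):
            Ensemble((c1, c2))
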