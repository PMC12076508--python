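import numpy as np
import pytest
from scipy.stats import special_ortho_group

from ohecc import (
    Atom,
    Molecule,
    assign_handedness,
    find_stereocenters,
    make_molecule,
    rank_substituents,
    reflect,
    transform,
)
from ohecc.stereo import DegenerateGeometryError, RankingTieError
from ohecc.synthetic import GeneratorConfig

TETRA = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float) / np.sqrt(3)


def reference_center(order=(0, 1, 2, 3), rotation=None):
    """C bonded to F, OH, NH2, H at tetrahedral vertices (vertex k holds the
    branch named by order[k]); returns (molecule, bonds)."""
    dirs = TETRA[list(order)]
    pos = {
        "C": np.zeros(3),
        "F": dirs[0] * 1.35,
        "O": dirs[1] * 1.40,
        "N": dirs[2] * 1.45,
        "H": dirs[3] * 1.09,
    }
    off1 = np.array([0.3, 0.2, 0.1])
    off2 = np.array([-0.2, 0.3, -0.1])
    pos["HO"] = pos["O"] + 0.96 * (dirs[1] + off1) / np.linalg.norm(dirs[1] + off1)
    pos["HN1"] = pos["N"] + 1.01 * (dirs[2] + off1) / np.linalg.norm(dirs[2] + off1)
    pos["HN2"] = pos["N"] + 1.01 * (dirs[2] + off2) / np.linalg.norm(dirs[2] + off2)
    names = ["C", "F", "O", "HO", "N", "HN1", "HN2", "H"]
    if rotation is not None:
        pos = {k: rotation @ v for k, v in pos.items()}
    atoms = [Atom(n[0], pos[n]) for n in names]
    bonds = [(0, 1), (0, 2), (2, 3), (0, 4), (4, 5), (4, 6), (0, 7)]
    return Molecule(atoms, id="ref-center"), bonds


class TestRanking:
    def test_first_sphere_decides_for_distinct_elements(self):
        mol, bonds = reference_center()
        r = rank_substituents(mol, bonds, 0)
        assert not r.tie
        assert r.ordered == (1, 2, 4, 7)  # F > O-branch > N-branch > H

    def test_identical_branches_tie(self):
        # C bonded to two CH3 groups and two other atoms
        atoms = [Atom("C", [0, 0, 0])]
        bonds = []
        for k, d in enumerate(TETRA):
            if k < 2:  # two methyls
                c = len(atoms)
                atoms.append(Atom("C", d * 1.52))
                bonds.append((0, c))
                for j in range(3):
                    atoms.append(Atom("H", d * 1.52 + np.roll([1.0, 0.2, -0.4], j) * 0.7))
                    bonds.append((c, len(atoms) - 1))
            else:
                atoms.append(Atom(["F", "O"][k - 2], d * 1.4))
                bonds.append((0, len(atoms) - 1))
        r = rank_substituents(Molecule(atoms), bonds, 0)
        assert r.tie

    def test_second_sphere_resolves_carbon_branches(self):
        # C bonded to CH2F, CH2OH, CH3, H: decided at sphere 2 by F > O > H
        atoms = [Atom("C", [0, 0, 0])]
        bonds = []
        firsts = {}
        for name, d in zip(["CH2F", "CH2OH", "CH3"], TETRA[:3]):
            c = len(atoms)
            firsts[name] = c
            atoms.append(Atom("C", d * 1.52))
            bonds.append((0, c))
            heavy = {"CH2F": "F", "CH2OH": "O", "CH3": "H"}[name]
            atoms.append(Atom(heavy, d * 1.52 + [1.3, 0, 0]))
            bonds.append((c, len(atoms) - 1))
            if name == "CH2OH":
                atoms.append(Atom("H", d * 1.52 + [1.8, 0.7, 0]))
                bonds.append((len(atoms) - 2, len(atoms) - 1))
            for j in range(2):
                atoms.append(Atom("H", d * 1.52 + np.roll([0.0, 1.0, -0.5], j) * 0.9))
                bonds.append((c, len(atoms) - 1))
        atoms.append(Atom("H", TETRA[3] * 1.09))
        bonds.append((0, len(atoms) - 1))
        h_idx = len(atoms) - 1
        r = rank_substituents(Molecule(atoms), bonds, 0)
        assert not r.tie
        assert r.ordered == (firsts["CH2F"], firsts["CH2OH"], firsts["CH3"], h_idx)

    def test_wrong_degree_rejected(self):
        mol = Molecule([Atom("C", [0, 0, 0]), Atom("H", [1, 0, 0])])
        with pytest.raises(ValueError, match="degree"):
            rank_substituents(mol, [(0, 1)], 0)


class TestHandedness:
    def test_reflection_flips_and_rotation_preserves(self, rng):
        flips, keeps = 0, 0
        for _ in range(200):
            order = tuple(rng.permutation(4))
            R = special_ortho_group.rvs(3, random_state=rng)
            mol, bonds = reference_center(order, rotation=R)
            ranking = rank_substituents(mol, bonds, 0)
            label = assign_handedness(mol, 0, ranking)
            mirrored = reflect(mol, rng.normal(size=3))
            moved = transform(mol, special_ortho_group.rvs(3, random_state=rng),
                              rng.normal(0, 4, 3))
            flips += assign_handedness(mirrored, 0, ranking) != label
            keeps += assign_handedness(moved, 0, ranking) == label
        assert flips == 200 and keeps == 200

    def test_swapping_two_priorities_flips_label(self, rng):
        mol, bonds = reference_center()
        ranking = rank_substituents(mol, bonds, 0)
        base = assign_handedness(mol, 0, ranking)
        order = list(ranking.ordered)
        for i in range(4):
            for j in range(i + 1, 4):
                swapped = order.copy()
                swapped[i], swapped[j] = swapped[j], swapped[i]
                assert assign_handedness(mol, 0, tuple(swapped)) != base

    def test_coplanar_geometry_rejected(self):
        atoms = [Atom("C", [0, 0, 0]), Atom("F", [1, 0, 0]), Atom("O", [0, 1, 0]),
                 Atom("N", [-1, 0, 0]), Atom("H", [0, -1, 0])]
        mol = Molecule(atoms)
        with pytest.raises(DegenerateGeometryError):
            assign_handedness(mol, 0, (1, 2, 3, 4))

    def test_tied_ranking_rejected(self):
        mol, bonds = reference_center()
        from ohecc.stereo import PriorityRanking
        with pytest.raises(RankingTieError):
            assign_handedness(mol, 0, PriorityRanking((1, 2, 4, 7), tie=True))


class TestRDKitCrossCheck:
    """The sign convention (negative signed volume = R) is frozen against an
    independent CIP perception; this re-runs that cross-check live."""

    @pytest.mark.parametrize("case", range(8))
    def test_against_independent_cip_assignment(self, case):
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        rng = np.random.default_rng(1000 + case)
        order = tuple(rng.permutation(4))
        R = special_ortho_group.rvs(3, random_state=rng)
        mol, bonds = reference_center(order, rotation=R)
        ranking = rank_substituents(mol, bonds, 0)
        ours = assign_handedness(mol, 0, ranking)

        em = Chem.RWMol()
        for a in mol.atoms:
            em.AddAtom(Chem.Atom(a.element))
        for i, j in bonds:
            em.AddBond(i, j, Chem.BondType.SINGLE)
        m = em.GetMol()
        conf = Chem.Conformer(len(mol))
        for i, a in enumerate(mol.atoms):
            conf.SetAtomPosition(i, Point3D(*a.position))
        m.AddConformer(conf)
        Chem.SanitizeMol(m)
        Chem.AssignStereochemistryFrom3D(m)
        theirs = m.GetAtomWithIdx(0).GetPropsAsDict().get("_CIPCode")
        assert ours == theirs


class TestFindStereocenters:
    def test_methane_like_center_has_no_stereocenters(self):
        atoms = [Atom("C", [0, 0, 0])] + [Atom("H", d * 1.09) for d in TETRA]
        bonds = [(0, i) for i in range(1, 5)]
        assert find_stereocenters(Molecule(atoms), bonds) == []

    def test_generator_round_trip_single_center(self, single_center_config):
        sm = make_molecule(single_center_config, 1, seed=5)
        found = find_stereocenters(sm.molecule, sm.bonds)
        assert len(found) == 1
        assert found[0].label == sm.stereocenters[0].label
        assert found[0].center == sm.stereocenters[0].center

    def test_mirror_image_flips_every_label(self):
        cfg = GeneratorConfig(center_distribution={3: 1.0})
        sm = make_molecule(cfg, 3, seed=9)
        mirrored = reflect(sm.molecule, [0.2, 1.0, -0.5])
        orig = {s.center: s.label for s in find_stereocenters(sm.molecule, sm.bonds)}
        flip = {s.center: s.label for s in find_stereocenters(mirrored, sm.bonds)}
        assert orig.keys() == flip.keys() and len(orig) == 3
        assert all(orig[c] != flip[c] for c in orig)
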