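"""Seeded generator of labeled 3D toy molecules with known stereochemistry.

The generator emulates the *structure* of the study inputs -- molecules of at
most 27 atoms over {H, C, N, O, F} with 0-4 tetrahedral stereocenters, known
R/S labels, enantiomer pairs related by exact reflection, and a signed
surrogate "rotation" value -- without any quantum chemistry.  Geometry is
idealized (tetrahedral angles, standard-ish bond lengths) plus Gaussian
jitter; no energetic realism is attempted.

Construction guarantees tie-free CIP-style rankings: every stereocenter is a
carbon whose four branches start with four *different* elements (F, O, N, and
C-or-H), so priority is decided at the first sphere and the intended R/S
label can be realized purely by where each branch is placed on the
tetrahedron.  Multi-center molecules are chains of such carbons joined by
alternating -O- and -NH- bridges, which keeps every center's four first
atoms distinct regardless of chain length.

Orientation.  Each molecule is built, given a random proper rotation and
translation, and then (by default) re-expressed in a *standard orientation*:
charge-weighted centroid at the origin and the principal axes of the nuclear
charge distribution along x/y/z, with axis signs fixed by third moments and
the third axis taken as a cross product so the map is always a proper
rotation (chirality is never touched).  This emulates how quantum-chemistry
programs emit optimized geometries -- the real data this generator stands in
for are canonically oriented, not randomly oriented, and that shared frame is
what makes raw Cartesian features comparable across molecules.  Pass
``orientation="random"`` to keep the random pose instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Atom, Molecule, reflect, write_xyz
from .representations import DEFAULT_MAX_ATOMS, DEFAULT_VOCAB, encode_ohecc
from .stereo import StereoCenter

# unit vectors to the vertices of a regular tetrahedron (109.47 deg apart)
_TETRA = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float) / np.sqrt(3)

_BOND = {"H": 1.09, "C": 1.52, "N": 1.45, "O": 1.40, "F": 1.35}

#: candidate fourth branches (first atom C or H); name -> atom count
_FOURTH_GROUPS = {"H": 1, "CH3": 4, "CH2F": 4, "CH2OH": 5}

#: achiral center templates: each has a repeated substituent, so the sphere
#: ranking ties and the carbon is not a stereocenter
_ACHIRAL_TEMPLATES = [
    ("H", "H", "OH", "NH2"),
    ("F", "F", "OH", "H"),
    ("H", "H", "H", "OH"),
    ("F", "F", "NH2", "H"),
    ("H", "H", "CH3", "F"),
    ("H", "H", "NH2", "NH2"),
]


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic generator.

    ``center_distribution`` gives the relative frequency of molecules with
    0..4 stereocenters; ``jitter_sd`` is the per-coordinate Gaussian noise in
    angstroms; ``rotation_weights`` are the per-center magnitudes w_k of the
    surrogate rotation (distinct values, so no signed sum can cancel to
    exactly zero); ``noise_sd`` is the sd of its additive noise in the same
    (arbitrary) degree-like units.
    """

    n_molecules: int = 1000
    center_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.2, 1: 0.2, 2: 0.2, 3: 0.2, 4: 0.2}
    )
    vocab: tuple[str, ...] = DEFAULT_VOCAB
    max_atoms: int = DEFAULT_MAX_ATOMS
    jitter_sd: float = 0.02
    translation_range: float = 5.0
    rotation_weights: tuple[float, ...] = (10.0, 6.0, 3.5, 2.0)
    noise_sd: float = 1.0
    orientation: str = "standard"  # "standard" | "random"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("standard", "random"):
            raise ValueError(f"orientation must be 'standard' or 'random', got {self.orientation!r}")
        if self.max_atoms > DEFAULT_MAX_ATOMS:
            raise ValueError("max_atoms exceeds the OHECC capacity of 27 rows")
        if any(k not in range(5) for k in self.center_distribution):
            raise ValueError("center_distribution keys must lie in 0..4")


@dataclass
class SyntheticMolecule:
    """A generated molecule with its bond list and ground-truth labels."""

    molecule: Molecule
    bonds: list[tuple[int, int]]
    stereocenters: list[StereoCenter]
    rotation: float | None = None

    @property
    def n_centers(self) -> int:
        return len(self.stereocenters)

    @property
    def labels(self) -> list[str]:
        return [sc.label for sc in self.stereocenters]


class _Builder:
    def __init__(self) -> None:
        self.elements: list[str] = []
        self.positions: list[np.ndarray] = []
        self.bonds: list[tuple[int, int]] = []

    def add(self, element: str, position: np.ndarray, bond_to: int | None = None) -> int:
        self.elements.append(element)
        self.positions.append(np.asarray(position, dtype=float))
        idx = len(self.elements) - 1
        if bond_to is not None:
            self.bonds.append((bond_to, idx))
        return idx

    def __len__(self) -> int:
        return len(self.elements)


def _perp(direction: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random unit vector perpendicular to ``direction``."""
    while True:
        v = rng.normal(size=3)
        v -= v @ direction * direction
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _tetra_frame(rng: np.random.Generator, back_dir: np.ndarray | None = None) -> np.ndarray:
    """Four tetrahedral unit vectors; row 0 equals ``back_dir`` when given."""
    if back_dir is None:
        R = Rotation.random(random_state=rng).as_matrix()
        return _TETRA @ R.T
    back_dir = back_dir / np.linalg.norm(back_dir)
    # rotate the reference frame so vertex 0 lands on back_dir, then spin
    axis = np.cross(_TETRA[0], back_dir)
    s = np.linalg.norm(axis)
    c = float(_TETRA[0] @ back_dir)
    if s < 1e-12:
        R1 = np.eye(3) if c > 0 else Rotation.from_rotvec(np.pi * _perp(_TETRA[0], rng)).as_matrix()
    else:
        R1 = Rotation.from_rotvec(axis / s * np.arctan2(s, c)).as_matrix()
    spin = Rotation.from_rotvec(back_dir * rng.uniform(0, 2 * np.pi)).as_matrix()
    return _TETRA @ (spin @ R1).T


def _place_group(
    b: _Builder, name: str, parent: int, origin: np.ndarray, direction: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """Grow a terminal substituent along ``direction``; return its first atom index."""
    if name == "H" or name == "F":
        return b.add(name, origin + _BOND[name] * direction, bond_to=parent)
    p1 = _perp(direction, rng)
    p2 = np.cross(direction, p1)
    if name == "OH":
        o = b.add("O", origin + _BOND["O"] * direction, bond_to=parent)
        u = direction + 1.6 * p1
        b.add("H", b.positions[o] + 0.96 * u / np.linalg.norm(u), bond_to=o)
        return o
    if name == "NH2":
        n = b.add("N", origin + _BOND["N"] * direction, bond_to=parent)
        for u in (direction + 1.5 * p1, direction - 0.75 * p1 + 1.3 * p2):
            b.add("H", b.positions[n] + 1.01 * u / np.linalg.norm(u), bond_to=n)
        return n
    if name in ("CH3", "CH2F", "CH2OH"):
        c = b.add("C", origin + _BOND["C"] * direction, bond_to=parent)
        hangs = [direction + 2.0 * (np.cos(phi) * p1 + np.sin(phi) * p2)
                 for phi in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)]
        hangs = [u / np.linalg.norm(u) for u in hangs]
        if name == "CH3":
            subs = ["H", "H", "H"]
        elif name == "CH2F":
            subs = ["F", "H", "H"]
        else:
            subs = ["OH", "H", "H"]
        for sub, u in zip(subs, hangs):
            _place_group(b, sub, c, b.positions[c], u, rng)
        return c
    raise ValueError(f"unknown substituent group {name!r}")


def _chain_plan(n_centers: int, max_atoms: int) -> int:
    """Atom count of the chain skeleton before fourth branches are chosen."""
    k = n_centers
    fixed = 2 * k  # center C + F each
    bridges = ["O" if j % 2 == 0 else "NH" for j in range(k - 1)]
    fixed += sum(1 if t == "O" else 2 for t in bridges)
    if k == 1:
        fixed += 2 + 3  # OH + NH2
    elif k >= 2:
        fixed += 3 * 2  # terminal NH2 on both ends
        if bridges and bridges[-1] == "NH":  # last center still needs an O branch
            fixed += 2 - 3  # it gets OH instead of a second NH2
    return fixed


def make_molecule(
    config: GeneratorConfig, n_centers: int, seed: int | np.random.Generator | None = None
) -> SyntheticMolecule:
    """Build one molecule with exactly ``n_centers`` intended stereocenters.

    Ground-truth :class:`StereoCenter` records (with the intended priorities
    and labels) ride along; they are what the detector is checked against.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_centers < 0 or n_centers > 4:
        raise ValueError(f"n_centers must be in 0..4, got {n_centers}")
    if n_centers > 0:
        skeleton = _chain_plan(n_centers, config.max_atoms)
        if skeleton + n_centers > config.max_atoms:
            raise ValueError(
                f"{n_centers} centers need at least {skeleton + n_centers} atoms, "
                f"exceeding max_atoms={config.max_atoms}"
            )
    b = _Builder()
    truth: list[StereoCenter] = []

    if n_centers == 0:
        template = _ACHIRAL_TEMPLATES[rng.integers(len(_ACHIRAL_TEMPLATES))]
        center = b.add("C", np.zeros(3))
        frame = _tetra_frame(rng)
        for name, d in zip(template, frame):
            _place_group(b, name, center, b.positions[center], d, rng)
    else:
        k = n_centers
        labels = ["R" if rng.random() < 0.5 else "S" for _ in range(k)]
        bridges = ["O" if j % 2 == 0 else "NH" for j in range(k - 1)]
        budget = config.max_atoms - _chain_plan(k, config.max_atoms)

        center_idx = b.add("C", np.zeros(3))
        back_dir = None
        back_atom: int | None = None
        for i in range(k):
            frame = _tetra_frame(rng, back_dir=back_dir)
            if back_dir is None:
                free = [0, 1, 2, 3]
            else:
                b.bonds.append((back_atom, center_idx))
                free = [1, 2, 3]
            free = list(rng.permutation(free))

            # branch -> tetrahedron-vertex assignment; back branch is fixed
            left_bridge = bridges[i - 1] if i > 0 else None
            right_bridge = bridges[i] if i < k - 1 else None
            slots: dict[str, int] = {}
            if left_bridge == "O":
                slots["O"] = 0
            elif left_bridge == "NH":
                slots["N"] = 0
            for br in ("F", "O", "N", "fourth"):
                if br not in slots:
                    slots[br] = free.pop()

            # realize the intended label: swap two non-back branches if needed
            dirs = {br: frame[v] for br, v in slots.items()}
            s = float(np.dot(dirs["F"], np.cross(dirs["O"], dirs["N"])))
            want_negative = labels[i] == "R"
            if (s < 0) != want_negative:
                a_br = "F"
                b_br = "fourth" if slots.get("O") == 0 or slots.get("N") == 0 else "O"
                slots[a_br], slots[b_br] = slots[b_br], slots[a_br]
                dirs = {br: frame[v] for br, v in slots.items()}

            origin = b.positions[center_idx]
            f_idx = b.add("F", origin + _BOND["F"] * dirs["F"], bond_to=center_idx)

            # oxygen branch: left bridge, right bridge, or terminal OH
            if left_bridge == "O":
                o_idx = back_atom
            elif right_bridge == "O":
                o_idx = b.add("O", origin + _BOND["O"] * dirs["O"], bond_to=center_idx)
            else:
                o_idx = _place_group(b, "OH", center_idx, origin, dirs["O"], rng)

            # nitrogen branch: left bridge, right bridge, or terminal NH2
            if left_bridge == "NH":
                n_idx = back_atom
            elif right_bridge == "NH":
                n_idx = b.add("N", origin + _BOND["N"] * dirs["N"], bond_to=center_idx)
                u = dirs["N"] + 1.7 * _perp(dirs["N"], rng)
                b.add("H", b.positions[n_idx] + 1.01 * u / np.linalg.norm(u), bond_to=n_idx)
            else:
                n_idx = _place_group(b, "NH2", center_idx, origin, dirs["N"], rng)

            # fourth branch, chosen within the remaining atom budget
            min_later = k - 1 - i  # one atom per remaining fourth branch
            options = [g for g, sz in _FOURTH_GROUPS.items() if sz <= budget - min_later]
            group = options[rng.integers(len(options))] if options else "H"
            budget -= _FOURTH_GROUPS[group]
            fourth_idx = _place_group(b, group, center_idx, origin, dirs["fourth"], rng)

            truth.append(
                StereoCenter(
                    center=center_idx,
                    neighbors=(f_idx, o_idx, n_idx, fourth_idx),
                    priorities=(f_idx, o_idx, n_idx, fourth_idx),
                    label=labels[i],
                )
            )

            if right_bridge is not None:
                bridge_atom = o_idx if right_bridge == "O" else n_idx
                d_out = dirs["O"] if right_bridge == "O" else dirs["N"]
                e = d_out + 1.2 * _perp(d_out, rng)
                e /= np.linalg.norm(e)
                next_pos = b.positions[bridge_atom] + _BOND["C"] * e
                center_idx = b.add("C", next_pos)
                back_atom = bridge_atom
                back_dir = (b.positions[bridge_atom] - next_pos)
                back_dir /= np.linalg.norm(back_dir)

    # jitter, redrawn in the rare case it degrades a center's signed volume
    P0 = np.array(b.positions)
    for _ in range(100):
        P = P0 + rng.normal(0.0, config.jitter_sd, P0.shape) if config.jitter_sd > 0 else P0
        ok = True
        for sc in truth:
            u1, u2, u3 = (P[i] - P[sc.center] for i in sc.priorities[:3])
            s = float(np.dot(u1, np.cross(u2, u3)))
            if abs(s) < 1e-4 or (s < 0) != (sc.label == "R"):
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - jitter_sd would have to be enormous
        raise RuntimeError("could not draw jitter preserving the intended labels")

    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-config.translation_range, config.translation_range, 3)
    P = P @ R.T + t

    mol = Molecule([Atom(el, p) for el, p in zip(b.elements, P)], id=f"syn-{n_centers}c")
    if config.orientation == "standard":
        mol = standard_orientation(mol)
    return SyntheticMolecule(molecule=mol, bonds=b.bonds, stereocenters=truth)


def standard_orientation(molecule: Molecule) -> Molecule:
    """Re-express a molecule in a canonical, chirality-preserving frame.

    The charge-weighted centroid moves to the origin and the principal axes
    of the nuclear charge second-moment tensor become x (largest spread), y,
    z.  Axis signs for x and y are fixed by the sign of the third charge
    moment along each axis (falling back to the first atom's coordinate when
    that moment vanishes); z is the cross product of x and y, so the overall
    map is a proper rotation and R/S labels are untouched.  This mirrors the
    "standard orientation" of quantum-chemistry geometry output.
    """
    Z = molecule.atomic_numbers.astype(float)
    P = molecule.coords
    Q = P - (Z[:, None] * P).sum(axis=0) / Z.sum()
    second = np.einsum("i,ij,ik->jk", Z, Q, Q)
    _, V = np.linalg.eigh(second)
    V = V[:, ::-1]  # descending spread
    for k in range(2):
        m3 = float((Z * (Q @ V[:, k]) ** 3).sum())
        if abs(m3) < 1e-9:
            m3 = float(Q[0] @ V[:, k])
        if m3 < 0:
            V[:, k] = -V[:, k]
    V[:, 2] = np.cross(V[:, 0], V[:, 1])
    return molecule.with_coords(Q @ V)


def make_enantiomer_pair(
    config: GeneratorConfig, seed: int | np.random.Generator | None = None
) -> tuple[SyntheticMolecule, SyntheticMolecule]:
    """A chiral molecule and its exact mirror image (same atom order).

    The second molecule is the reflection of the first through the yz plane;
    every ground-truth label is flipped, nothing else changes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ks = [k for k in sorted(config.center_distribution) if k >= 1 and config.center_distribution[k] > 0]
    if not ks:
        ks = [1]
    p = np.array([config.center_distribution[k] for k in ks], dtype=float)
    n_centers = int(rng.choice(ks, p=p / p.sum()))
    first = make_molecule(config, n_centers, rng)
    flipped = [replace(sc, label="S" if sc.label == "R" else "R") for sc in first.stereocenters]
    mirror_mol = reflect(first.molecule, np.array([1.0, 0.0, 0.0]))
    mirror_mol.id = first.molecule.id + "-mirror"
    second = SyntheticMolecule(molecule=mirror_mol, bonds=list(first.bonds), stereocenters=flipped)
    return first, second


def assign_surrogate_rotation(
    synmol: SyntheticMolecule,
    weights: Sequence[float] = (10.0, 6.0, 3.5, 2.0),
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Signed surrogate rotation: ``sum_k s_k w_k + eps``, s_k = +1 for R, -1 for S.

    Stands in for a computed specific rotation at 589.3 nm: its sign is fully
    determined by the configuration at zero noise, and an achiral molecule
    gets pure noise (exactly 0.0 when ``noise_sd`` is 0).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    value = sum(
        (1.0 if sc.label == "R" else -1.0) * w
        for sc, w in zip(synmol.stereocenters, weights)
    )
    if noise_sd > 0:
        value += rng.normal(0.0, noise_sd)
    return float(value)


@dataclass
class SyntheticDataset:
    """A list of generated molecules with surrogate rotations and features."""

    molecules: list[SyntheticMolecule]
    config: GeneratorConfig

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def ids(self) -> list[str]:
        return [f"syn-{i:06d}" for i in range(len(self.molecules))]

    def features(self) -> np.ndarray:
        """n x 216 matrix of flattened OHECC encodings (default settings)."""
        return np.array(
            [encode_ohecc(sm.molecule, self.config.vocab, self.config.max_atoms).flatten()
             for sm in self.molecules]
        )

    def n_centers(self) -> np.ndarray:
        return np.array([sm.n_centers for sm in self.molecules], dtype=int)

    def rs_labels(self) -> np.ndarray:
        """Per-molecule label of the *first* center ('' when achiral)."""
        return np.array(
            [sm.stereocenters[0].label if sm.stereocenters else "" for sm in self.molecules]
        )

    def rotations(self) -> np.ndarray:
        return np.array([sm.rotation if sm.rotation is not None else np.nan
                         for sm in self.molecules])


def _exact_counts(distribution: dict[int, float], n: int) -> dict[int, int]:
    """Largest-remainder apportionment: requested proportions, delivered exactly."""
    ks = sorted(k for k, v in distribution.items() if v > 0)
    w = np.array([distribution[k] for k in ks], dtype=float)
    w = w / w.sum()
    raw = w * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1
    return dict(zip(ks, counts.tolist()))


def make_dataset(
    config: GeneratorConfig,
    seed: int | None = None,
    counts: dict[int, int] | None = None,
) -> SyntheticDataset:
    """Generate a dataset with exact per-class center counts and rotations."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if counts is None:
        counts = _exact_counts(config.center_distribution, config.n_molecules)
    molecules: list[SyntheticMolecule] = []
    for k in sorted(counts):
        for _ in range(counts[k]):
            sm = make_molecule(config, k, rng)
            sm.rotation = assign_surrogate_rotation(
                sm, config.rotation_weights, config.noise_sd, rng
            )
            molecules.append(sm)
    order = rng.permutation(len(molecules))
    return SyntheticDataset(molecules=[molecules[i] for i in order], config=config)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write ``molecules.xyz`` and ``labels.csv`` (id, n_centers, labels, rotation)."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = dataset.ids
    mols = []
    for mid, sm in zip(ids, dataset.molecules):
        m = sm.molecule
        mols.append(Molecule(m.atoms, id=mid, annotations=m.annotations))
    write_xyz(mols, outdir / "molecules.xyz")
    pd.DataFrame(
        {
            "id": ids,
            "n_centers": dataset.n_centers(),
            "labels": [";".join(sm.labels) for sm in dataset.molecules],
            "rotation": dataset.rotations(),
        }
    ).to_csv(outdir / "labels.csv", index=False)
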