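"""Molecule data model, XYZ input/output, and rigid-motion transforms.

Coordinates are Cartesian, in angstroms, and are used exactly as given: no
centering, re-ordering, or alignment is ever applied by I/O or encoding.
Atom order is significant (it determines the row order of every downstream
feature matrix) and is preserved by read/write round trips.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

#: Atomic numbers for the elements this package routinely sees.  The default
#: working vocabulary is H/C/N/O/F; the extra entries let the lenient XYZ
#: parser keep atoms it cannot encode.
ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "Br": 35, "I": 53,
}


class ParseError(ValueError):
    """Malformed XYZ input; the message names the offending line."""


@dataclass
class Atom:
    """A single atom: element symbol plus Cartesian position in angstroms."""

    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.element}: {self.position}")

    @property
    def atomic_number(self) -> int:
        return ATOMIC_NUMBERS.get(self.element, 0)


@dataclass
class Molecule:
    """An ordered list of atoms with an opaque id and optional annotations.

    ``annotations`` may carry an InChI string, a stereocenter list, the number
    of chiral centers, and/or a ``rotations`` map from wavelength in nm to a
    specific rotation in deg.[dm.(g/cm3)]^-1.
    """

    atoms: list[Atom]
    id: str = ""
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("a molecule must contain at least one atom")
        n = self.annotations.get("n_chiral_centers")
        sc = self.annotations.get("stereocenters")
        if n is not None and sc is not None and n != len(sc):
            raise ValueError(
                f"n_chiral_centers={n} disagrees with {len(sc)} stereocenters"
            )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        """n x 3 array of positions, in atom order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([a.atomic_number for a in self.atoms], dtype=int)

    def distance_matrix(self) -> np.ndarray:
        """Full symmetric interatomic distance matrix in angstroms."""
        if len(self.atoms) == 1:
            return np.zeros((1, 1))
        return squareform(pdist(self.coords))

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Molecule":
        """Copy of this molecule with replaced coordinates (same elements/order)."""
        coords = np.asarray(coords, dtype=float)
        atoms = [Atom(a.element, p) for a, p in zip(self.atoms, coords)]
        return Molecule(atoms, id=self.id if id is None else id,
                        annotations=dict(self.annotations))


def _as_lines(source: str | Path | TextIO) -> list[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    if isinstance(source, Path):
        return source.read_text(encoding="utf-8").splitlines()
    # A plain string is a path if it points at an existing file, else raw text.
    if "\n" not in source and Path(source).is_file():
        return Path(source).read_text(encoding="utf-8").splitlines()
    return source.splitlines()


def read_xyz(
    source: str | Path | TextIO,
    strict_vocab: bool = False,
    vocab: Sequence[str] = ("H", "C", "N", "O", "F"),
) -> list[Molecule]:
    """Parse one or more concatenated XYZ records.

    Standard layout per record: an atom-count line, a comment line (stored as
    the molecule id when nonempty), then ``element x y z`` lines.  Unknown
    elements raise only in ``strict_vocab`` mode; by default the atom is kept
    and a warning is logged.
    """
    lines = _as_lines(source)
    molecules: list[Molecule] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate blank separator lines
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected an atom count, got {lines[i]!r}")
        if count < 1:
            raise ParseError(f"line {i + 1}: atom count must be >= 1, got {count}")
        if i + 1 >= len(lines):
            raise ParseError(f"line {i + 2}: missing comment line")
        comment = lines[i + 1].strip()
        atoms: list[Atom] = []
        for j in range(count):
            ln = i + 2 + j
            if ln >= len(lines) or not lines[ln].strip():
                raise ParseError(
                    f"line {ln + 1}: record declared {count} atoms but only {j} found"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"line {ln + 1}: expected 'element x y z', got {lines[ln]!r}")
            el = parts[0]
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(f"line {ln + 1}: could not parse coordinates in {lines[ln]!r}")
            if el not in vocab:
                if strict_vocab:
                    raise ParseError(f"line {ln + 1}: element {el!r} not in vocabulary {list(vocab)}")
                logger.warning("line %d: element %r outside vocabulary, kept", ln + 1, el)
            atoms.append(Atom(el, np.array(xyz)))
        molecules.append(Molecule(atoms, id=comment))
        i += 2 + count
    return molecules


def write_xyz(
    molecules: Molecule | Iterable[Molecule],
    destination: str | Path | TextIO | None = None,
    decimals: int = 6,
) -> str:
    """Serialize molecules as concatenated XYZ records with fixed decimals.

    Returns the text; additionally writes it to ``destination`` when given.
    """
    if isinstance(molecules, Molecule):
        molecules = [molecules]
    buf = io.StringIO()
    for mol in molecules:
        if not np.all(np.isfinite(mol.coords)):
            raise ValueError(f"molecule {mol.id!r} has non-finite coordinates")
        buf.write(f"{len(mol)}\n{mol.id}\n")
        for a in mol.atoms:
            x, y, z = a.position
            buf.write(f"{a.element} {x:.{decimals}f} {y:.{decimals}f} {z:.{decimals}f}\n")
    text = buf.getvalue()
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            Path(destination).write_text(text, encoding="utf-8")
    return text


def transform(molecule: Molecule, rotation: np.ndarray, translation: np.ndarray) -> Molecule:
    """Apply the proper rigid motion ``p -> R p + t`` to every atom.

    ``rotation`` must be proper orthogonal (det +1 within 1e-8); improper
    operations must go through :func:`reflect` so that handedness changes are
    always explicit.
    """
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or abs(np.linalg.det(R) - 1.0) > 1e-8:
        raise ValueError("rotation must be proper orthogonal (det +1); use reflect() for mirror operations")
    return molecule.with_coords(molecule.coords @ R.T + t)


def reflect(molecule: Molecule, plane_normal: np.ndarray) -> Molecule:
    """Mirror through the plane through the origin with the given normal.

    The Householder map ``p -> (I - 2 n n^T) p`` is an improper isometry: it
    preserves every interatomic distance while inverting handedness, which is
    exactly the operation relating a molecule to its enantiomer.
    """
    n = np.asarray(plane_normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0 or not np.all(np.isfinite(n)):
        raise ValueError("plane normal must be a nonzero finite vector")
    n = n / norm
    H = np.eye(3) - 2.0 * np.outer(n, n)
    return molecule.with_coords(molecule.coords @ H.T)
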