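"""The two molecular encodings: OHECC and the Coulomb matrix.

OHECC (one-hot encoded Cartesian coordinates) stores, for each atom, its raw
xyz coordinates followed by a one-hot element indicator, zero-padded to a
fixed number of rows.  At the defaults (27 atoms, vocabulary H,C,N,O,F) the
matrix is 27 x 8 and flattens to a length-216 feature vector.  Because the
coordinates enter untouched, the encoding is sensitive to reflection: a
molecule and its mirror image get different matrices, which is what lets
classifiers trained on it see chirality.

The Coulomb matrix (0.5 Z^2.4 on the diagonal, Z_i Z_j / |R_i - R_j| off it)
depends only on interatomic distances and charges, so it is invariant under
every isometry -- including the improper one relating two enantiomers.  It is
kept here as the counterexample representation that cannot distinguish them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ATOMIC_NUMBERS, Molecule

#: Element order of the one-hot block.  Changing the vocabulary changes the
#: feature width (3 + len(vocab)); matrices of different widths are never
#: silently mixed.
DEFAULT_VOCAB: tuple[str, ...] = ("H", "C", "N", "O", "F")
DEFAULT_MAX_ATOMS: int = 27


@dataclass
class OHECCMatrix:
    """A zero-padded ``max_atoms x (3 + len(vocab))`` feature matrix."""

    values: np.ndarray
    vocab: tuple[str, ...]
    n_real_atoms: int

    @property
    def max_atoms(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def flatten(self) -> np.ndarray:
        """Row-major flattening, length ``max_atoms * (3 + len(vocab))``."""
        return self.values.ravel(order="C").copy()

    def coords(self) -> np.ndarray:
        """The real-atom coordinate block (bit-for-bit the encoder's input)."""
        return self.values[: self.n_real_atoms, :3].copy()


@dataclass
class CoulombMatrix:
    """Symmetric n x n Coulomb matrix with its atomic-number list."""

    values: np.ndarray
    atomic_numbers: np.ndarray


def encode_ohecc(
    molecule: Molecule,
    vocab: Sequence[str] = DEFAULT_VOCAB,
    max_atoms: int = DEFAULT_MAX_ATOMS,
) -> OHECCMatrix:
    """Encode a molecule as an OHECC matrix.

    Row ``i`` of the result is ``(x_i, y_i, z_i, onehot(element_i))`` in the
    molecule's atom order; rows past the real atom count are all zero.
    """
    vocab = tuple(vocab)
    n = len(molecule)
    if n > max_atoms:
        raise ValueError(
            f"molecule {molecule.id!r} has {n} atoms, exceeding max_atoms={max_atoms}"
        )
    col = {el: i for i, el in enumerate(vocab)}
    M = np.zeros((max_atoms, 3 + len(vocab)))
    for i, atom in enumerate(molecule.atoms):
        if atom.element not in col:
            raise ValueError(
                f"element {atom.element!r} (atom {i} of {molecule.id!r}) not in vocabulary {list(vocab)}"
            )
        M[i, :3] = atom.position
        M[i, 3 + col[atom.element]] = 1.0
    return OHECCMatrix(values=M, vocab=vocab, n_real_atoms=n)


def flatten_ohecc(m: OHECCMatrix) -> np.ndarray:
    """Row-major flattening of an OHECC matrix (length 216 at defaults)."""
    return m.flatten()


def encode_coulomb(molecule: Molecule, min_distance: float = 1e-6) -> CoulombMatrix:
    """Coulomb matrix: ``M_ii = 0.5 Z_i^2.4``, ``M_ij = Z_i Z_j / d_ij`` (d in angstroms).

    Atom order is preserved; no row sorting or spectral canonicalization is
    applied (compare order-robustly via :func:`coulomb_spectrum` if needed).
    """
    Z = molecule.atomic_numbers.astype(float)
    D = molecule.distance_matrix()
    n = len(Z)
    off = ~np.eye(n, dtype=bool)
    if n > 1 and D[off].min() < min_distance:
        i, j = np.unravel_index(np.argmin(np.where(off, D, np.inf)), D.shape)
        raise ValueError(
            f"atoms {i} and {j} are {D[i, j]:.2e} A apart (< {min_distance:g}); "
            "Coulomb matrix would diverge"
        )
    M = np.zeros((n, n))
    M[off] = np.outer(Z, Z)[off] / np.where(off, D, 1.0)[off]
    np.fill_diagonal(M, 0.5 * Z**2.4)
    return CoulombMatrix(values=M, atomic_numbers=molecule.atomic_numbers.copy())


def coulomb_spectrum(cm: CoulombMatrix) -> np.ndarray:
    """Eigenvalues sorted descending -- an atom-order-robust summary."""
    return np.sort(np.linalg.eigvalsh(cm.values))[::-1]


# ---------------------------------------------------------------------------
# serialization: one flattened row per molecule plus an id column

def ohecc_to_frame(ids: Iterable[str], matrices: Iterable[OHECCMatrix]) -> pd.DataFrame:
    rows = [m.flatten() for m in matrices]
    width = len(rows[0]) if rows else DEFAULT_MAX_ATOMS * (3 + len(DEFAULT_VOCAB))
    df = pd.DataFrame(rows, columns=[f"f{i}" for i in range(width)])
    df.insert(0, "id", list(ids))
    return df


def save_ohecc(ids: Iterable[str], matrices: Iterable[OHECCMatrix], path: str | Path) -> None:
    """Write flattened OHECC rows to CSV (``.csv``) or NPZ (anything else)."""
    path = Path(path)
    df = ohecc_to_frame(ids, matrices)
    if path.suffix == ".csv":
        df.to_csv(path, index=False)
    else:
        np.savez(path, ids=np.array(df["id"], dtype=str),
                 features=df.drop(columns="id").to_numpy())


def load_ohecc(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load ``(ids, features)`` from a file written by :func:`save_ohecc`."""
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        return df["id"].to_numpy(dtype=str), df.drop(columns="id").to_numpy()
    with np.load(path) as z:
        return z["ids"], z["features"]
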