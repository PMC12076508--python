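"""OR-QM9-style archive I/O and the six classification-task builders.

The deposited archive accompanying the study stores, per molecule: an index,
an InChI string, the OHECC representation, the number/location/type of chiral
centers, and computed specific rotations at 355, 589.3 and 633 nm.  The
reader here is schema-driven (a small mapping from field names to array names
inside the NPZ), because archives in the wild differ in internal naming; the
writer emits the same layout so everything round-trips offline.

Task builders turn a record list into one of six balanced, seeded, split
classification problems:

==================== ==========================================+=============
task                 classes (declaration order = positive first)
==================== =============================================+==========
existence            {0} vs {>=1 centers}
zero_vs_one          {0} vs {1}
R_vs_S               (R) vs (S), molecules with exactly one center
sign_one_center      (-) vs (+) rotation sign at 589.3 nm, one center
sign_all             (-) vs (+) rotation sign at 589.3 nm, any count
n_centers_multiclass {0} vs {1} vs {2} vs {3} vs {4}
==================== ========================================================

Balancing is exact per class (seeded downsampling without replacement), the
80-20 split is stratified by label, and records whose rotation is exactly
zero are excluded from the sign tasks with a log record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

WAVELENGTHS = (355.0, 589.3, 633.0)
SODIUM_D = 589.3

TASKS = (
    "existence",
    "zero_vs_one",
    "R_vs_S",
    "sign_one_center",
    "sign_all",
    "n_centers_multiclass",
)

TASK_CLASSES: dict[str, tuple] = {
    "existence": (0, 1),
    "zero_vs_one": (0, 1),
    "R_vs_S": ("R", "S"),
    "sign_one_center": ("-", "+"),
    "sign_all": ("-", "+"),
    "n_centers_multiclass": (0, 1, 2, 3, 4),
}

#: NPZ field -> array-name mapping used by both reader and writer by default.
DEFAULT_SCHEMA = {
    "index": "index",
    "inchi": "inchi",
    "ohecc": "ohecc",
    "n_chiral_centers": "n_chiral_centers",
    "center_info": "center_info",
    "rotations": "rotations",
    "wavelengths": "wavelengths",
}

_REQUIRED_FIELDS = ("index", "ohecc", "n_chiral_centers")


@dataclass
class ORQM9Record:
    """One molecule of an OR-QM9-style archive."""

    index: int
    ohecc: np.ndarray  # flattened feature vector (216 at defaults)
    n_chiral_centers: int
    inchi: str = ""
    center_info: list[tuple[int, str]] = field(default_factory=list)
    rotations: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_chiral_centers < 0:
            raise ValueError("n_chiral_centers must be >= 0")

    @property
    def n_atoms(self) -> int:
        """Real-atom count, recovered from the nonzero OHECC rows."""
        M = np.asarray(self.ohecc).reshape(-1, 8)
        return int((np.abs(M).sum(axis=1) > 0).sum())


def load_schema(path: str | Path) -> dict[str, str]:
    """Read a YAML manifest mapping record fields to NPZ array names."""
    with open(path, encoding="utf-8") as fh:
        schema = yaml.safe_load(fh)
    return {**DEFAULT_SCHEMA, **(schema or {})}


def save_orqm9(records: list[ORQM9Record], path: str | Path,
               schema: dict[str, str] | None = None) -> None:
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    arrays = {
        schema["index"]: np.array([r.index for r in records], dtype=np.int64),
        schema["inchi"]: np.array([r.inchi for r in records], dtype=str),
        schema["ohecc"]: np.array([np.asarray(r.ohecc, dtype=float) for r in records]),
        schema["n_chiral_centers"]: np.array([r.n_chiral_centers for r in records], dtype=np.int64),
        schema["center_info"]: np.array(
            [";".join(f"{loc}:{lab}" for loc, lab in r.center_info) for r in records], dtype=str
        ),
        schema["rotations"]: np.array(
            [[r.rotations.get(w, np.nan) for w in WAVELENGTHS] for r in records]
        ),
        schema["wavelengths"]: np.array(WAVELENGTHS),
    }
    np.savez(path, **arrays)


def load_orqm9(path: str | Path, schema: dict[str, str] | str | Path | None = None) -> list[ORQM9Record]:
    """Load an archive; missing optional fields are tolerated and logged."""
    if isinstance(schema, (str, Path)):
        schema = load_schema(schema)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    with np.load(path, allow_pickle=False) as z:
        names = set(z.files)
        for f in _REQUIRED_FIELDS:
            if schema[f] not in names:
                raise ValueError(
                    f"archive {path} is missing required field {f!r} (array {schema[f]!r})"
                )
        index = z[schema["index"]]
        ohecc = z[schema["ohecc"]]
        ncc = z[schema["n_chiral_centers"]]
        n = len(index)
        inchi = z[schema["inchi"]] if schema["inchi"] in names else np.array([""] * n)
        if schema["center_info"] in names:
            cinfo_raw = z[schema["center_info"]]
        else:
            logger.info("archive has no center_info field; labels unavailable")
            cinfo_raw = np.array([""] * n)
        if schema["rotations"] in names and schema["wavelengths"] in names:
            rot = z[schema["rotations"]]
            wl = z[schema["wavelengths"]]
        else:
            logger.info("archive has no rotation data")
            rot, wl = np.full((n, 0), np.nan), np.array([])

    records = []
    for i in range(n):
        cinfo = []
        if cinfo_raw[i]:
            for part in str(cinfo_raw[i]).split(";"):
                loc, lab = part.split(":")
                cinfo.append((int(loc), lab))
        rotations = {
            float(w): float(v) for w, v in zip(wl, rot[i]) if np.isfinite(v)
        }
        records.append(
            ORQM9Record(
                index=int(index[i]),
                ohecc=np.asarray(ohecc[i], dtype=float),
                n_chiral_centers=int(ncc[i]),
                inchi=str(inchi[i]),
                center_info=cinfo,
                rotations=rotations,
            )
        )
    return records


# Deterministic wavelength scaling for the synthetic surrogate rotations: a
# crude normal-dispersion shape (larger magnitude at shorter wavelength).
_SYNTH_WAVELENGTH_SCALE = {355.0: 2.8, 589.3: 1.0, 633.0: 0.85}


def records_from_dataset(dataset) -> list[ORQM9Record]:
    """Convert a :class:`~ohecc.synthetic.SyntheticDataset` into records."""
    feats = dataset.features()
    records = []
    for i, sm in enumerate(dataset.molecules):
        rot = sm.rotation
        rotations = (
            {w: rot * s for w, s in _SYNTH_WAVELENGTH_SCALE.items()} if rot is not None else {}
        )
        records.append(
            ORQM9Record(
                index=i,
                ohecc=feats[i],
                n_chiral_centers=sm.n_centers,
                center_info=[(sc.center, sc.label) for sc in sm.stereocenters],
                rotations=rotations,
            )
        )
    return records


@dataclass
class TaskSpec:
    """One of the six classification problems, fully determined by its fields."""

    task: str
    per_class: int
    split: float = 0.8
    seed: int = 0
    size_filter: str | None = None  # None | "small" | "large"
    size_threshold: int = 17

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; choose from {TASKS}")
        if not 0.0 < self.split < 1.0:
            raise ValueError(f"split must be in (0, 1), got {self.split}")
        if self.per_class < 1:
            raise ValueError("per_class must be >= 1")
        if self.size_filter not in (None, "small", "large"):
            raise ValueError(f"size_filter must be None, 'small' or 'large', got {self.size_filter!r}")


@dataclass
class TaskData:
    """Balanced, split task data.  Class order follows the task declaration."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    classes: tuple
    train_ids: np.ndarray
    test_ids: np.ndarray

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            X_train=self.X_train, y_train=np.array(self.y_train, dtype=str),
            X_test=self.X_test, y_test=np.array(self.y_test, dtype=str),
            classes=np.array(self.classes, dtype=str),
            train_ids=self.train_ids, test_ids=self.test_ids,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TaskData":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                X_train=z["X_train"], y_train=z["y_train"],
                X_test=z["X_test"], y_test=z["y_test"],
                classes=tuple(z["classes"]),
                train_ids=z["train_ids"], test_ids=z["test_ids"],
            )


def _task_label(record: ORQM9Record, task: str):
    """The record's class for ``task``, or None when ineligible."""
    n = record.n_chiral_centers
    if task == "existence":
        return 0 if n == 0 else 1
    if task == "zero_vs_one":
        return n if n in (0, 1) else None
    if task == "R_vs_S":
        if n == 1 and record.center_info and record.center_info[0][1] in ("R", "S"):
            return record.center_info[0][1]
        return None
    if task in ("sign_one_center", "sign_all"):
        if task == "sign_one_center" and n != 1:
            return None
        rot = record.rotations.get(SODIUM_D)
        if rot is None or not np.isfinite(rot):
            return None
        if rot == 0.0:
            logger.info("record %d excluded from %s: exactly zero rotation", record.index, task)
            return None
        return "-" if rot < 0 else "+"
    if task == "n_centers_multiclass":
        return n if n in (0, 1, 2, 3, 4) else None
    raise ValueError(f"unknown task {task!r}")


def build_task(records: list[ORQM9Record], spec: TaskSpec) -> TaskData:
    """Downsample each class to ``per_class``, pool, and split 80-20 (stratified).

    Sampling and splitting are uniform without replacement under
    ``numpy.random.default_rng(spec.seed)``, so identical specs yield
    identical membership.
    """
    if spec.size_filter == "small":
        records = [r for r in records if r.n_atoms <= spec.size_threshold]
    elif spec.size_filter == "large":
        records = [r for r in records if r.n_atoms > spec.size_threshold]

    classes = TASK_CLASSES[spec.task]
    by_class: dict = {c: [] for c in classes}
    for i, r in enumerate(records):
        lab = _task_label(r, spec.task)
        if lab is not None:
            by_class[lab].append(i)

    for c in classes:
        if len(by_class[c]) < spec.per_class:
            raise ValueError(
                f"class {c!r} of task {spec.task!r} has {len(by_class[c])} records, "
                f"{spec.per_class - len(by_class[c])} short of per_class={spec.per_class}"
            )

    rng = np.random.default_rng(spec.seed)
    n_train = int(round(spec.split * spec.per_class))
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in classes:
        chosen = rng.choice(len(by_class[c]), size=spec.per_class, replace=False)
        chosen = [by_class[c][j] for j in chosen]
        train_idx.extend(chosen[:n_train])
        test_idx.extend(chosen[n_train:])
    train_idx = [train_idx[i] for i in rng.permutation(len(train_idx))]
    test_idx = [test_idx[i] for i in rng.permutation(len(test_idx))]

    X = np.array([records[i].ohecc for i in train_idx + test_idx])
    y = np.array([_task_label(records[i], spec.task) for i in train_idx + test_idx])
    ids = np.array([records[i].index for i in train_idx + test_idx], dtype=np.int64)
    nt = len(train_idx)
    return TaskData(
        X_train=X[:nt], y_train=y[:nt], X_test=X[nt:], y_test=y[nt:],
        classes=classes, train_ids=ids[:nt], test_ids=ids[nt:],
    )


def size_partition(
    records: list[ORQM9Record], threshold: int = 17
) -> tuple[list[ORQM9Record], list[ORQM9Record]]:
    """Split records into (small, large) by atom count; 17 atoms is small."""
    small = [r for r in records if r.n_atoms <= threshold]
    large = [r for r in records if r.n_atoms > threshold]
    return small, large
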