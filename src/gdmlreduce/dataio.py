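"""Dataset containers, extended-XYZ / HDF5 I/O, and reproducible splits.

A :class:`LabeledDataset` holds thermally sampled configurations of a single
molecule together with reference energies (kcal mol⁻¹) and per-atom forces
(kcal (mol Å)⁻¹) — the substrate for training and evaluating force fields.

Extended-XYZ dialect: the frame comment line carries ``key=value`` entries
including ``energy=<float>`` and a ``Properties=species:S:1:pos:R:3:forces:R:3``
declaration; the last three per-atom columns are the force components.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy.spatial.distance import pdist

from .constants import ATOMIC_SYMBOLS, EV_TO_KCAL_MOL, SYMBOL_TO_Z


class ParseError(ValueError):
    """Malformed frame in an extended-XYZ file."""


class DatasetError(ValueError):
    """Structurally inconsistent dataset."""


@dataclass
class AtomicConfiguration:
    """One molecular geometry: atomic numbers and Cartesian coordinates (Å)."""

    atomic_numbers: np.ndarray
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.int64)
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.atomic_numbers.ndim != 1 or self.atomic_numbers.size < 2:
            raise DatasetError("need at least two atoms")
        if self.coordinates.shape != (self.atomic_numbers.size, 3):
            raise DatasetError(
                f"coordinate shape {self.coordinates.shape} does not match "
                f"{self.atomic_numbers.size} atoms"
            )
        if np.any(pdist(self.coordinates) <= 0.0):
            raise DatasetError("coincident atoms (zero pairwise distance)")

    @property
    def n_atoms(self) -> int:
        return self.atomic_numbers.size

    def max_extent(self) -> float:
        """Largest interatomic distance (Å) — the molecular 'extent'."""
        return float(pdist(self.coordinates).max())


@dataclass
class LabeledDataset:
    """Configurations of one molecule with reference energies and forces."""

    configurations: list
    energies: np.ndarray
    forces: np.ndarray
    name: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=np.float64)
        self.forces = np.asarray(self.forces, dtype=np.float64)
        n = len(self.configurations)
        if n == 0:
            raise DatasetError("dataset has no configurations")
        n_atoms = self.configurations[0].n_atoms
        z0 = self.configurations[0].atomic_numbers
        for i, c in enumerate(self.configurations):
            if c.n_atoms != n_atoms or not np.array_equal(c.atomic_numbers, z0):
                raise DatasetError(f"configuration {i} has inconsistent atoms")
        if self.energies.shape != (n,):
            raise DatasetError("energies shape mismatch")
        if self.forces.shape != (n, n_atoms, 3):
            raise DatasetError("forces shape mismatch")
        if not np.all(np.isfinite(self.energies)):
            raise DatasetError("non-finite energies")

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def n_atoms(self) -> int:
        return self.configurations[0].n_atoms

    @property
    def atomic_numbers(self) -> np.ndarray:
        return self.configurations[0].atomic_numbers

    @property
    def coordinates(self) -> np.ndarray:
        """All coordinates stacked, shape (n_configs, n_atoms, 3)."""
        return np.stack([c.coordinates for c in self.configurations])


@dataclass
class SplitIndices:
    """Disjoint train/validation/test index sets, reproducible from ``seed``."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=np.int64)
        self.validation = np.asarray(self.validation, dtype=np.int64)
        self.test = np.asarray(self.test, dtype=np.int64)
        a, b, c = set(self.train), set(self.validation), set(self.test)
        if (a & b) or (a & c) or (b & c):
            raise DatasetError("split index sets overlap")


_KV_RE = re.compile(r'(\w[\w_-]*)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(line)}


def _symbol_to_z(tok: str) -> int:
    if tok in SYMBOL_TO_Z:
        return SYMBOL_TO_Z[tok]
    try:
        return int(tok)
    except ValueError:
        raise ParseError(f"unknown chemical species {tok!r}") from None


def read_extxyz(path, units: str = "kcal") -> LabeledDataset:
    """Read a labeled dataset from an extended-XYZ file.

    Parameters
    ----------
    path : path-like
    units : {"kcal", "ev"}
        Units of the energies/forces stored in the file. ``"ev"`` converts
        eV / eV Å⁻¹ to the canonical kcal mol⁻¹ / kcal (mol Å)⁻¹ on read.
    """
    if units not in ("kcal", "ev"):
        raise ValueError(f"unknown units {units!r}")
    scale = EV_TO_KCAL_MOL if units == "ev" else 1.0
    path = Path(path)
    lines = path.read_text().splitlines()
    configs, energies, forces = [], [], []
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise ParseError(f"frame {frame}: bad atom-count line {lines[pos]!r}")
        if pos + 1 + n > len(lines):
            raise ParseError(f"frame {frame}: truncated ({n} atoms declared)")
        meta = _parse_comment(lines[pos + 1])
        if "energy" not in meta:
            raise ParseError(f"frame {frame}: missing energy field")
        z = np.empty(n, dtype=np.int64)
        r = np.empty((n, 3))
        f = np.empty((n, 3))
        for a in range(n):
            toks = lines[pos + 2 + a].split()
            if len(toks) < 7:
                raise ParseError(
                    f"frame {frame}: atom line {a} has {len(toks)} columns, "
                    "expected species + 3 positions + 3 forces"
                )
            z[a] = _symbol_to_z(toks[0])
            try:
                r[a] = [float(t) for t in toks[1:4]]
                f[a] = [float(t) for t in toks[-3:]]
            except ValueError:
                raise ParseError(f"frame {frame}: non-numeric atom line {a}")
        configs.append(AtomicConfiguration(z, r))
        energies.append(float(meta["energy"]) * scale)
        forces.append(f * scale)
        pos += 2 + n
        frame += 1
    if not configs:
        raise ParseError(f"{path}: no frames found")
    n_atoms = configs[0].n_atoms
    for i, c in enumerate(configs):
        if c.n_atoms != n_atoms:
            raise DatasetError(f"frame {i}: atom count {c.n_atoms} != {n_atoms}")
    return LabeledDataset(configs, np.array(energies), np.array(forces),
                          name=path.stem, provenance=f"read_extxyz:{path}")


def write_extxyz(dataset: LabeledDataset, path) -> None:
    """Write a dataset as extended XYZ (lossless to double precision)."""
    path = Path(path)
    out = []
    fmt = "%.17g"  # lossless for IEEE doubles
    for i, config in enumerate(dataset.configurations):
        n = config.n_atoms
        out.append(str(n))
        out.append(
            f'energy={fmt % dataset.energies[i]} '
            f'Properties=species:S:1:pos:R:3:forces:R:3'
        )
        for a in range(n):
            sym = ATOMIC_SYMBOLS.get(int(config.atomic_numbers[a]),
                                     str(int(config.atomic_numbers[a])))
            row = np.concatenate([config.coordinates[a],
                                  dataset.forces[i, a]])
            out.append(sym + " " + " ".join(fmt % v for v in row))
    path.write_text("\n".join(out) + "\n")


def write_hdf5(dataset: LabeledDataset, path) -> None:
    """Write the binary container: groups /Z, /R, /E, /F, /meta."""
    with h5py.File(path, "w") as h:
        h["Z"] = dataset.atomic_numbers
        h["R"] = dataset.coordinates
        h["E"] = dataset.energies
        h["F"] = dataset.forces
        meta = h.create_group("meta")
        meta.attrs["name"] = dataset.name
        meta.attrs["provenance"] = dataset.provenance
        meta.attrs["units"] = "angstrom;kcal/mol;kcal/mol/angstrom"


def read_hdf5(path) -> LabeledDataset:
    with h5py.File(path, "r") as h:
        z = h["Z"][...]
        r = h["R"][...]
        e = h["E"][...]
        f = h["F"][...]
        name = h["meta"].attrs.get("name", "")
        prov = h["meta"].attrs.get("provenance", "")
    configs = [AtomicConfiguration(z, r[i]) for i in range(r.shape[0])]
    return LabeledDataset(configs, e, f, name=str(name), provenance=str(prov))


def read_dataset(path, **kw) -> LabeledDataset:
    """Dispatch on extension: .xyz/.extxyz → extended XYZ, .h5/.hdf5 → HDF5."""
    suffix = Path(path).suffix.lower()
    if suffix in (".xyz", ".extxyz"):
        return read_extxyz(path, **kw)
    if suffix in (".h5", ".hdf5"):
        return read_hdf5(path)
    raise ValueError(f"unrecognized dataset extension {suffix!r}")


def write_dataset(dataset: LabeledDataset, path) -> None:
    suffix = Path(path).suffix.lower()
    if suffix in (".xyz", ".extxyz"):
        write_extxyz(dataset, path)
    elif suffix in (".h5", ".hdf5"):
        write_hdf5(dataset, path)
    else:
        raise ValueError(f"unrecognized dataset extension {suffix!r}")


def split_dataset(dataset: LabeledDataset, n_train: int, n_valid: int,
                  n_test: int = -1, seed: int = 0) -> SplitIndices:
    """Uniform without-replacement train/validation/test split.

    ``n_test = -1`` assigns every remaining configuration to the test set
    ("all remaining"); a nonnegative ``n_test`` samples that many.
    Uses numpy's PCG64 generator seeded with ``seed``; identical seeds give
    identical splits.
    """
    n = len(dataset)
    want_rest = n_test < 0
    n_test_eff = n - n_train - n_valid if want_rest else n_test
    if n_train + n_valid + n_test_eff > n:
        raise DatasetError(
            f"requested {n_train}+{n_valid}+{n_test_eff} > {n} configurations"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = np.sort(perm[:n_train])
    valid = np.sort(perm[n_train:n_train + n_valid])
    test = np.sort(perm[n_train + n_valid:n_train + n_valid + n_test_eff])
    return SplitIndices(train, valid, test, seed=seed)


def split_by_extent(dataset: LabeledDataset, threshold: float):
    """Partition by molecular extent: extended iff max pair distance > threshold.

    Returns ``(compact, extended)`` index arrays.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    extents = np.array([c.max_extent() for c in dataset.configurations])
    idx = np.arange(len(dataset))
    return idx[extents <= threshold], idx[extents > threshold]
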