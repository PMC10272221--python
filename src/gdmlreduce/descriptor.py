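"""Global inverse-pairwise-distance descriptor and its analytic Jacobian.

The descriptor of an N-atom geometry is the vector of all 1/r_ij over the
N(N−1)/2 atom pairs (a simplified Coulomb matrix, no nuclear-charge
weighting).  A boolean mask over pairs selects the *active* features; a
reduced descriptor is the coordinate projection onto the active set — masked
features are dropped from both values and Jacobian.  Features are ordered
lexicographically in (i, j), i < j, 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataio import AtomicConfiguration, LabeledDataset


@dataclass(frozen=True)
class PairIndexMap:
    """Bijection between feature index and atom pair (i, j), i < j."""

    n_atoms: int
    pairs: np.ndarray  # (n_pairs, 2) int

    @classmethod
    def for_atoms(cls, n_atoms: int) -> "PairIndexMap":
        if n_atoms < 2:
            raise ValueError(f"need at least 2 atoms, got {n_atoms}")
        i, j = np.triu_indices(n_atoms, k=1)
        return cls(n_atoms=n_atoms, pairs=np.column_stack([i, j]))

    @property
    def n_features(self) -> int:
        return self.pairs.shape[0]


@dataclass
class DescriptorSpec:
    """A pair map plus the boolean active-feature mask (global or reduced)."""

    pair_map: PairIndexMap
    active: np.ndarray  # (n_pairs,) bool

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.shape != (self.pair_map.n_features,):
            raise ValueError("mask length does not match pair map")
        if not self.active.any():
            raise ValueError("descriptor must keep at least one active feature")

    @classmethod
    def global_spec(cls, n_atoms: int) -> "DescriptorSpec":
        pm = PairIndexMap.for_atoms(n_atoms)
        return cls(pm, np.ones(pm.n_features, dtype=bool))

    @property
    def n_atoms(self) -> int:
        return self.pair_map.n_atoms

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def active_indices(self) -> np.ndarray:
        """Global feature indices (into the full pair map) that are active."""
        return np.flatnonzero(self.active)

    @property
    def active_pairs(self) -> np.ndarray:
        return self.pair_map.pairs[self.active]

    def restrict(self, keep_features: np.ndarray) -> "DescriptorSpec":
        """New spec keeping only the given global feature indices."""
        mask = np.zeros(self.pair_map.n_features, dtype=bool)
        mask[np.asarray(keep_features, dtype=np.int64)] = True
        if not np.all(self.active[mask]):
            raise ValueError("cannot keep a feature that is already inactive")
        return DescriptorSpec(self.pair_map, mask)

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "n_atoms": self.pair_map.n_atoms,
            "active_pairs": self.active_pairs.tolist(),
        }, indent=0)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json_file(cls, path) -> "DescriptorSpec":
        return cls.from_json(Path(path).read_text())

    @classmethod
    def from_json(cls, text: str) -> "DescriptorSpec":
        obj = json.loads(text)
        pm = PairIndexMap.for_atoms(obj["n_atoms"])
        lut = {(int(i), int(j)): k for k, (i, j) in enumerate(pm.pairs)}
        mask = np.zeros(pm.n_features, dtype=bool)
        for i, j in obj["active_pairs"]:
            mask[lut[(int(i), int(j))]] = True
        return cls(pm, mask)


@dataclass
class DescriptorValue:
    """Descriptor values (Å⁻¹) and Jacobian w.r.t. Cartesian coordinates."""

    values: np.ndarray    # (n_active,)
    jacobian: np.ndarray  # (n_active, 3N)


@dataclass
class FeatureDistanceStats:
    """Per-feature min/mean/max interatomic distance over a dataset (Å)."""

    spec: DescriptorSpec
    min: np.ndarray
    mean: np.ndarray
    max: np.ndarray


def _pair_vectors(coords: np.ndarray, pairs: np.ndarray):
    diff = coords[pairs[:, 0]] - coords[pairs[:, 1]]  # r_i − r_j
    r = np.linalg.norm(diff, axis=1)
    return diff, r


def descriptor_values(coords: np.ndarray, spec: DescriptorSpec) -> np.ndarray:
    """Active-feature values for one (N,3) or many (n,N,3) geometries."""
    pairs = spec.active_pairs
    if coords.ndim == 2:
        _, r = _pair_vectors(coords, pairs)
        if np.any(r == 0.0):
            raise ZeroDivisionError("coincident atoms in descriptor evaluation")
        return 1.0 / r
    diff = coords[:, pairs[:, 0]] - coords[:, pairs[:, 1]]
    r = np.linalg.norm(diff, axis=2)
    if np.any(r == 0.0):
        raise ZeroDivisionError("coincident atoms in descriptor evaluation")
    return 1.0 / r


def descriptor_jacobian(coords: np.ndarray, spec: DescriptorSpec) -> np.ndarray:
    """Analytic Jacobian, shape (n_active, 3N).

    Row for pair (i, j) is nonzero only in the six columns of atoms i and j:
    ∂(1/r_ij)/∂r_i = −(r_i − r_j)/r_ij³ and the atom-j block is its negative.
    """
    pairs = spec.active_pairs
    n_atoms = spec.n_atoms
    diff, r = _pair_vectors(coords, pairs)
    if np.any(r == 0.0):
        raise ZeroDivisionError("coincident atoms in descriptor evaluation")
    grad_i = -diff / (r ** 3)[:, None]  # (n_active, 3)
    jac = np.zeros((pairs.shape[0], 3 * n_atoms))
    rows = np.arange(pairs.shape[0])[:, None]
    cols_i = 3 * pairs[:, 0:1] + np.arange(3)
    cols_j = 3 * pairs[:, 1:2] + np.arange(3)
    jac[rows, cols_i] = grad_i
    jac[rows, cols_j] = -grad_i
    return jac


def compute_descriptor(config: AtomicConfiguration,
                       spec: DescriptorSpec) -> DescriptorValue:
    """Descriptor values and Jacobian for one configuration."""
    if config.n_atoms != spec.n_atoms:
        raise ValueError(
            f"configuration has {config.n_atoms} atoms, spec expects "
            f"{spec.n_atoms}"
        )
    coords = config.coordinates
    return DescriptorValue(values=descriptor_values(coords, spec),
                           jacobian=descriptor_jacobian(coords, spec))


def feature_distance_stats(dataset: LabeledDataset,
                           spec: DescriptorSpec) -> FeatureDistanceStats:
    """Exact per-feature min/mean/max of r_ij over all configurations."""
    pairs = spec.active_pairs
    coords = dataset.coordinates
    diff = coords[:, pairs[:, 0]] - coords[:, pairs[:, 1]]
    r = np.linalg.norm(diff, axis=2)  # (n_configs, n_active)
    return FeatureDistanceStats(spec=spec, min=r.min(axis=0),
                                mean=r.mean(axis=0), max=r.max(axis=0))
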