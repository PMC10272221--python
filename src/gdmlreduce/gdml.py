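"""Gradient-domain kernel force field on the inverse-distance descriptor.

The force predictor is kernel ridge regression in the gradient domain:
training targets are the 3N-component force vectors of M configurations, the
kernel matrix is assembled from Hessian blocks of a Matérn 5/2 kernel on
descriptor-space Euclidean distance, propagated to Cartesian coordinates
through the descriptor Jacobians.  The energy predictor is the exact
antiderivative of the force predictor (same kernel-derivative code path), so
F̂ = −∇Ê holds analytically, up to a single trained offset constant.

For the Matérn 5/2 kernel k(d) = (1 + u + u²/3)·exp(−u), u = √5·d/σ, the
descriptor-space cross Hessian has the closed form

    ∇_x ∇_{x'}ᵀ k = −g1(d)·I − c2(d)·δδᵀ,      δ = x − x',

with g1 = −(5/3σ²)(1+u)e^{−u} and c2 = (25/3σ⁴)e^{−u}; both are smooth at
d = 0.  All kernel assembly and prediction below exploits this rank-1
structure instead of forming dense feature-space Hessians.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist

from .dataio import AtomicConfiguration, LabeledDataset
from .descriptor import (DescriptorSpec, descriptor_jacobian,
                         descriptor_values)

SQRT5 = np.sqrt(5.0)


class ConditioningError(np.linalg.LinAlgError):
    """Kernel system numerically singular; raise the regularization λ."""


def kernel_value(d, sigma: float):
    """Matérn ν=5/2 kernel on descriptor distance; k(0)=1, C²-smooth."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    u = SQRT5 * np.asarray(d, dtype=np.float64) / sigma
    return (1.0 + u + u * u / 3.0) * np.exp(-u)


def _g1(d, sigma: float):
    """k'(d)/d — finite at d=0 where it equals −5/(3σ²)."""
    u = SQRT5 * np.asarray(d, dtype=np.float64) / sigma
    return -(5.0 / (3.0 * sigma * sigma)) * (1.0 + u) * np.exp(-u)


def _c2(d, sigma: float):
    """Coefficient of the δδᵀ term of the descriptor-space Hessian."""
    u = SQRT5 * np.asarray(d, dtype=np.float64) / sigma
    return (25.0 / (3.0 * sigma ** 4)) * np.exp(-u)


@dataclass
class EvaluationReport:
    energy_rmse: float
    force_rmse: float
    n_eval: int


@dataclass
class GDMLModel:
    """Trained force/energy predictor (Matérn 5/2 gradient-domain model)."""

    spec: DescriptorSpec
    atomic_numbers: np.ndarray
    training_coords: np.ndarray  # (M, N, 3)
    alphas: np.ndarray           # (M, 3N)
    sigma: float
    lam: float
    energy_offset: float = 0.0
    provenance: str = ""
    # caches: training descriptors and v_i = J_i α_i (filled on first use)
    _X: np.ndarray = field(default=None, repr=False, compare=False)
    _V: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        m, n_atoms = self.training_coords.shape[:2]
        if self.alphas.shape != (m, 3 * n_atoms):
            raise ValueError("coefficient array shape mismatch")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")

    @property
    def n_train(self) -> int:
        return self.training_coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.training_coords.shape[1]

    def _ensure_caches(self) -> None:
        if self._X is None:
            self._X = descriptor_values(self.training_coords, self.spec)
            self._V = np.stack([
                descriptor_jacobian(self.training_coords[i], self.spec)
                @ self.alphas[i]
                for i in range(self.n_train)
            ])


def _pairwise_block(JTa, Jb, delta, g1, c2):
    """One 3N×3N Hessian-kernel block J_aᵀ(−g1·I − c2·δδᵀ)J_b."""
    ua = JTa @ delta
    ub = Jb.T @ delta
    return -g1 * (JTa @ Jb) - c2 * np.outer(ua, ub)


def assemble_force_kernel(coords: np.ndarray, spec: DescriptorSpec,
                          sigma: float) -> np.ndarray:
    """Dense (M·3N × M·3N) force-force kernel matrix; symmetric PSD."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    m, n_atoms = coords.shape[:2]
    dim = 3 * n_atoms
    X = descriptor_values(coords, spec)
    J = np.stack([descriptor_jacobian(coords[i], spec) for i in range(m)])
    JT = J.transpose(0, 2, 1)
    K = np.empty((m * dim, m * dim))
    for a in range(m):
        for b in range(a, m):
            delta = X[a] - X[b]
            d = np.linalg.norm(delta)
            blk = _pairwise_block(JT[a], J[b], delta,
                                  float(_g1(d, sigma)), float(_c2(d, sigma)))
            K[a * dim:(a + 1) * dim, b * dim:(b + 1) * dim] = blk
            if b != a:
                K[b * dim:(b + 1) * dim, a * dim:(a + 1) * dim] = blk.T
    # enforce exact symmetry of the diagonal blocks against rounding
    K = 0.5 * (K + K.T)
    return K


def default_sigma(coords: np.ndarray, spec: DescriptorSpec) -> float:
    """Median pairwise descriptor distance of the given configurations.

    A deterministic length-scale heuristic used when no grid search is
    requested; falls back to 1.0 for a single configuration.
    """
    X = descriptor_values(np.asarray(coords), spec)
    if X.shape[0] < 2:
        return 1.0
    d = pdist(X)
    med = float(np.median(d))
    return med if med > 0 else 1.0


def train(dataset: LabeledDataset, indices, spec: DescriptorSpec,
          sigma: float | None = None, lam: float = 1e-10) -> GDMLModel:
    """Fit the gradient-domain model on the indexed training configurations.

    Solves (K + λ·s̄·I)α = y with s̄ the mean kernel diagonal (so λ is
    dimensionless) and y the stacked reference forces.  The energy offset is
    set so the mean predicted energy over the training points matches the
    mean reference energy — energies enter training nowhere else.
    """
    indices = np.asarray(indices, dtype=np.int64)
    if indices.size == 0:
        raise ValueError("empty training set")
    coords = dataset.coordinates[indices]
    m, n_atoms = coords.shape[:2]
    K = assemble_force_kernel(coords, spec, sigma := (
        default_sigma(coords, spec) if sigma is None else float(sigma)))
    if not np.all(np.isfinite(K)):
        raise ConditioningError("non-finite kernel matrix")
    y = dataset.forces[indices].reshape(m * 3 * n_atoms)
    scale = float(np.mean(np.diag(K)))
    A = K + (lam * scale) * np.eye(K.shape[0])
    try:
        cf = scipy.linalg.cho_factor(A, lower=True, check_finite=False)
        alpha = scipy.linalg.cho_solve(cf, y, check_finite=False)
    except np.linalg.LinAlgError:
        if lam == 0:
            # singular but possibly consistent (e.g. M=1): minimum-norm
            # solution interpolates iff y lies in the kernel's range
            alpha, *_ = scipy.linalg.lstsq(A, y, check_finite=False)
            resid = np.linalg.norm(A @ alpha - y)
            if resid > 1e-6 * max(np.linalg.norm(y), 1.0):
                raise ConditioningError(
                    "kernel system numerically singular at λ=0 and "
                    "inconsistent; raise the regularization λ"
                ) from None
        else:
            alpha = scipy.linalg.solve(A, y, assume_a="sym",
                                       check_finite=False)
    model = GDMLModel(spec=spec, atomic_numbers=dataset.atomic_numbers.copy(),
                      training_coords=coords, alphas=alpha.reshape(m, -1),
                      sigma=sigma, lam=lam,
                      provenance=f"train:M={m};dataset={dataset.name}")
    e_raw = np.array([_raw_energy(model, coords[i]) for i in range(m)])
    model.energy_offset = float(np.mean(dataset.energies[indices] - e_raw))
    return model


def _prediction_terms(model: GDMLModel, coords: np.ndarray):
    """Shared quantities for force/energy prediction at one geometry."""
    model._ensure_caches()
    x = descriptor_values(coords, model.spec)
    D = x[None, :] - model._X            # (M, F): δ_i = x − x_i
    d = np.linalg.norm(D, axis=1)
    g1 = _g1(d, model.sigma)
    c2 = _c2(d, model.sigma)
    s = np.einsum("mf,mf->m", D, model._V)
    return x, D, d, g1, c2, s


def _raw_energy(model: GDMLModel, coords: np.ndarray) -> float:
    _, _, _, g1, _, s = _prediction_terms(model, coords)
    return float(g1 @ s)


def predict_forces(model: GDMLModel,
                   config: AtomicConfiguration) -> np.ndarray:
    """Predicted per-atom forces, shape (N, 3), kcal (mol Å)⁻¹."""
    if config.n_atoms != model.n_atoms:
        raise ValueError("atom count does not match model")
    return _predict_forces_coords(model, config.coordinates)


def _predict_forces_coords(model: GDMLModel, coords: np.ndarray) -> np.ndarray:
    _, D, _, g1, c2, s = _prediction_terms(model, coords)
    w = -(g1 @ model._V + (c2 * s) @ D)  # (F,)
    J = descriptor_jacobian(coords, model.spec)
    return (J.T @ w).reshape(-1, 3)


def predict_energy(model: GDMLModel,
                   config: AtomicConfiguration) -> float:
    """Predicted total energy (kcal mol⁻¹); −∇Ê equals predict_forces."""
    if config.n_atoms != model.n_atoms:
        raise ValueError("atom count does not match model")
    return model.energy_offset + _raw_energy(model, config.coordinates)


def predict_energy_forces(model: GDMLModel, coords: np.ndarray):
    """Energy and forces in one pass (the MD hot path)."""
    _, D, _, g1, c2, s = _prediction_terms(model, coords)
    w = -(g1 @ model._V + (c2 * s) @ D)
    J = descriptor_jacobian(coords, model.spec)
    energy = model.energy_offset + float(g1 @ s)
    return energy, (J.T @ w).reshape(-1, 3)


def evaluate_rmse(model: GDMLModel, dataset: LabeledDataset,
                  indices) -> EvaluationReport:
    """Force RMSE pooled over all 3N·n components; energy RMSE per config."""
    indices = np.asarray(indices, dtype=np.int64)
    if indices.size == 0:
        raise ValueError("empty evaluation index list")
    f_err2 = 0.0
    e_err2 = 0.0
    n_comp = 0
    for i in indices:
        coords = dataset.configurations[i].coordinates
        e_hat, f_hat = predict_energy_forces(model, coords)
        df = f_hat - dataset.forces[i]
        f_err2 += float(np.sum(df * df))
        n_comp += df.size
        e_err2 += (e_hat - dataset.energies[i]) ** 2
    return EvaluationReport(
        energy_rmse=float(np.sqrt(e_err2 / indices.size)),
        force_rmse=float(np.sqrt(f_err2 / n_comp)),
        n_eval=int(indices.size),
    )


def select_sigma(dataset: LabeledDataset, splits, spec: DescriptorSpec,
                 sigma_grid, lam: float = 1e-10):
    """Grid search σ on the validation split; ties resolved to smaller σ.

    Returns ``(best_sigma, reports)`` with one `EvaluationReport` per unique
    grid value (dict keyed by σ).
    """
    grid = sorted(set(float(s) for s in sigma_grid))
    if not grid:
        raise ValueError("empty sigma grid")
    reports: dict[float, EvaluationReport] = {}
    failures = []
    for s in grid:
        try:
            model = train(dataset, splits.train, spec, sigma=s, lam=lam)
            reports[s] = evaluate_rmse(model, dataset, splits.validation)
        except (ConditioningError, ValueError) as exc:  # pragma: no cover
            failures.append((s, exc))
    if not reports:
        raise ConditioningError(f"all sigma candidates failed: {failures}")
    best = min(reports, key=lambda s: (reports[s].force_rmse, s))
    return best, reports


SCHEMA_VERSION = 1


def save_model(model: GDMLModel, path) -> None:
    """Single-file npz archive: spec JSON, training data, α, σ, λ, offset."""
    prov_hash = hashlib.sha256(model.provenance.encode()).hexdigest()
    np.savez(Path(path),
             schema_version=SCHEMA_VERSION,
             spec_json=model.spec.to_json(),
             atomic_numbers=model.atomic_numbers,
             training_coords=model.training_coords,
             alphas=model.alphas,
             sigma=model.sigma, lam=model.lam,
             energy_offset=model.energy_offset,
             provenance=model.provenance,
             provenance_hash=prov_hash)


def load_model(path) -> GDMLModel:
    with np.load(Path(path), allow_pickle=False) as z:
        spec = DescriptorSpec.from_json(str(z["spec_json"]))
        return GDMLModel(spec=spec,
                         atomic_numbers=z["atomic_numbers"],
                         training_coords=z["training_coords"],
                         alphas=z["alphas"],
                         sigma=float(z["sigma"]), lam=float(z["lam"]),
                         energy_offset=float(z["energy_offset"]),
                         provenance=str(z["provenance"]))
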