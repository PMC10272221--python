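"""Interaction decomposition and feature-statistics analyses.

The gradient-domain predictor is linear in the training coefficients, so it
admits two exact partitions:

* by **training atom**: restricting the coefficient sum to the three
  Cartesian components of atom k yields F^k, atom k's contribution to the
  force on every atom; the (k, l) norm of F^k gives the interaction map.
* by **query descriptor feature**: the predicted force is J_xᵀw, so channel
  n contributes w_n·J_x[n, :]; its magnitude versus the pair distance
  separates "linear" (power-law, Coulombic-like slope ≈ −2) from
  "stochastic" features.

Both partitions sum to the full prediction to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .constants import mass_of
from .dataio import AtomicConfiguration, LabeledDataset
from .descriptor import (DescriptorSpec, FeatureDistanceStats,
                         descriptor_jacobian, descriptor_values)
from .gdml import GDMLModel, _c2, _g1


@dataclass
class InteractionMap:
    """N×N averaged pairwise force contributions and their log-normalized map."""

    contributions: np.ndarray  # (N, N), ≥ 0, kcal (mol Å)⁻¹
    normalized: np.ndarray     # (N, N) in [0, 1]
    n_configs: int


@dataclass
class ScalingFit:
    points: np.ndarray  # (k, 2): (n_atoms, n_features_kept)
    slope: float
    intercept: float
    r_squared: float
    r_squared_quadratic: float  # same points explained by n(n−1)/2


def _query_geometry(model: GDMLModel, coords: np.ndarray):
    model._ensure_caches()
    x = descriptor_values(coords, model.spec)
    Jx = descriptor_jacobian(coords, model.spec)
    D = x[None, :] - model._X
    d = np.linalg.norm(D, axis=1)
    return Jx, D, _g1(d, model.sigma), _c2(d, model.sigma)


def _force_from_channels(Jx, D, g1, c2, V):
    """Force (rows of V are per-training-point feature-space channels)."""
    s = np.einsum("mf,mf->m", D, V)
    w = -(g1 @ V + (c2 * s) @ D)
    return Jx.T @ w


def _per_atom_V(model: GDMLModel) -> np.ndarray:
    """(N, M, F): channel vectors v_i^k = J_i[:, atom k] α_i[atom k]."""
    m, n_atoms = model.training_coords.shape[:2]
    f = model.spec.n_active
    out = np.empty((n_atoms, m, f))
    for i in range(m):
        Ji = descriptor_jacobian(model.training_coords[i], model.spec)
        out[:, i, :] = np.einsum("fkc,kc->kf", Ji.reshape(f, n_atoms, 3),
                                 model.alphas[i].reshape(n_atoms, 3))
    return out


def atom_contribution(model: GDMLModel, config: AtomicConfiguration,
                      k: int) -> np.ndarray:
    """Contribution F^k of training atom k to the forces on all atoms, (N, 3).

    The coefficient sum is restricted to the three components of atom k of
    every training point; summing over k recovers the full prediction
    exactly.
    """
    if not 0 <= k < model.n_atoms:
        raise IndexError(f"atom index {k} out of range")
    Jx, D, g1, c2 = _query_geometry(model, config.coordinates)
    f = model.spec.n_active
    Vk = np.empty((model.n_train, f))
    for i in range(model.n_train):
        Ji = descriptor_jacobian(model.training_coords[i], model.spec)
        Vk[i] = Ji[:, 3 * k:3 * k + 3] @ model.alphas[i, 3 * k:3 * k + 3]
    return _force_from_channels(Jx, D, g1, c2, Vk).reshape(-1, 3)


def interaction_map(model: GDMLModel, dataset: LabeledDataset,
                    config_indices) -> InteractionMap:
    """Averaged pairwise contribution matrix F̄_l^k with log normalization.

    Entry (k, l) is the mean over configurations of the norm of the atom-l
    components of F^k.  Normalization: t = log(F̄ + ε), ε = 1e-12·max(F̄),
    mapped min–max to [0, 1].
    """
    config_indices = np.asarray(config_indices, dtype=np.int64)
    if config_indices.size == 0:
        raise ValueError("empty configuration list")
    n = model.n_atoms
    V_atoms = _per_atom_V(model)  # (N, M, F)
    acc = np.zeros((n, n))
    for ci in config_indices:
        coords = dataset.configurations[ci].coordinates
        Jx, D, g1, c2 = _query_geometry(model, coords)
        S = np.einsum("mf,kmf->km", D, V_atoms)
        W = -(np.einsum("m,kmf->kf", g1, V_atoms)
              + np.einsum("km,mf->kf", c2 * S, D))
        Fk = (W @ Jx).reshape(n, n, 3)
        acc += np.linalg.norm(Fk, axis=2)
    contrib = acc / config_indices.size
    top = contrib.max()
    if top == contrib.min():
        warnings.warn("degenerate all-equal interaction map; normalized to 0")
        normalized = np.zeros_like(contrib)
    else:
        t = np.log(contrib + 1e-12 * top)
        normalized = (t - t.min()) / (t.max() - t.min())
    return InteractionMap(contributions=contrib, normalized=normalized,
                          n_configs=int(config_indices.size))


def feature_channel_forces(model: GDMLModel, coords: np.ndarray) -> np.ndarray:
    """(n_active, 3N) matrix of per-feature force channels F_(n) = w_n·J_x[n].

    Rows sum to the full force prediction exactly (chain-rule completeness).
    """
    Jx, D, g1, c2 = _query_geometry(model, coords)
    model._ensure_caches()
    s = np.einsum("mf,mf->m", D, model._V)
    w = -(g1 @ model._V + (c2 * s) @ D)
    return w[:, None] * Jx


def feature_contributions(model: GDMLModel, dataset: LabeledDataset,
                          config_indices) -> np.ndarray:
    """Mean over configurations of ‖F_(n)‖ per active feature."""
    config_indices = np.asarray(config_indices, dtype=np.int64)
    if config_indices.size == 0:
        raise ValueError("empty configuration list")
    acc = np.zeros(model.spec.n_active)
    for ci in config_indices:
        channels = feature_channel_forces(
            model, dataset.configurations[ci].coordinates)
        acc += np.linalg.norm(channels, axis=1)
    return acc / config_indices.size


def classify_features(distances, contributions,
                      r2_threshold: float = 0.9) -> pd.DataFrame:
    """Log–log OLS of contribution on distance per feature.

    ``distances`` and ``contributions`` are (n_features, n_samples) arrays
    of per-configuration series.  A feature is labeled ``linear`` iff the
    log–log r² reaches the threshold, ``stochastic`` otherwise; features
    with fewer than 3 positive samples are labeled ``skipped`` (with a
    warning) since no fit is possible.
    """
    distances = np.atleast_2d(np.asarray(distances, dtype=np.float64))
    contributions = np.atleast_2d(np.asarray(contributions, dtype=np.float64))
    if distances.shape != contributions.shape:
        raise ValueError("distance and contribution series shapes differ")
    rows = []
    n_skipped = 0
    for n in range(distances.shape[0]):
        dist, contrib = distances[n], contributions[n]
        valid = (dist > 0) & (contrib > 0)
        n_excluded = int((~valid).sum())
        if valid.sum() < 3:
            n_skipped += 1
            rows.append({"feature": n, "mean_distance": float(dist.mean()),
                         "mean_contribution": float(contrib.mean()),
                         "slope": np.nan, "r_squared": np.nan,
                         "label": "skipped", "n_excluded": n_excluded})
            continue
        fit = linregress(np.log(dist[valid]), np.log(contrib[valid]))
        r2 = float(fit.rvalue ** 2)
        rows.append({"feature": n, "mean_distance": float(dist.mean()),
                     "mean_contribution": float(contrib.mean()),
                     "slope": float(fit.slope), "r_squared": r2,
                     "label": "linear" if r2 >= r2_threshold else "stochastic",
                     "n_excluded": n_excluded})
    if n_skipped:
        warnings.warn(f"{n_skipped} feature(s) had <3 positive samples "
                      "and were skipped")
    return pd.DataFrame(rows)


def short_long_decomposition(stats: FeatureDistanceStats,
                             mask: DescriptorSpec, cutoff: float = 5.0,
                             criterion: str = "max"):
    """Count short- vs long-range features of a mask.

    ``criterion="max"``: short iff the pair stays below the cutoff in every
    configuration (the stricter, text-based reading); ``"mean"``: short iff
    the average distance is below the cutoff.  Counts sum to the mask's
    active-feature count.
    """
    if criterion not in ("max", "mean"):
        raise ValueError(f"unknown criterion {criterion!r}")
    stat_idx = stats.spec.active_indices
    lut = {int(g): i for i, g in enumerate(stat_idx)}
    try:
        sel = np.array([lut[int(g)] for g in mask.active_indices])
    except KeyError:
        raise ValueError("distance stats do not cover all mask features")
    values = stats.max[sel] if criterion == "max" else stats.mean[sel]
    n_short = int((values < cutoff).sum())
    return n_short, mask.n_active - n_short


def scaling_fit(points) -> ScalingFit:
    """Least-squares line of kept-feature count versus atom count.

    Includes the coefficient of determination of the same points against
    the full quadratic descriptor size n(n−1)/2 for comparison.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least two (n_atoms, n_kept) points")
    n, y = pts[:, 0], pts[:, 1]
    if np.unique(n).size < 2:
        raise ValueError("need at least two distinct atom counts")
    fit = linregress(n, y)
    quad = n * (n - 1) / 2.0
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - quad) ** 2))
    r2_quad = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return ScalingFit(points=pts, slope=float(fit.slope),
                      intercept=float(fit.intercept),
                      r_squared=float(fit.rvalue ** 2),
                      r_squared_quadratic=r2_quad)


def gyration_radius(config: AtomicConfiguration,
                    mass_weighted: bool = False) -> float:
    """R_g = √(Σ w_i‖r_i − r̄‖²/Σ w_i), r̄ the w-weighted centroid (Å)."""
    coords = config.coordinates
    if mass_weighted:
        w = np.array([mass_of(z) for z in config.atomic_numbers])
    else:
        w = np.ones(config.n_atoms)
    centroid = (w[:, None] * coords).sum(axis=0) / w.sum()
    dev = coords - centroid
    return float(np.sqrt((w * np.einsum("ij,ij->i", dev, dev)).sum() / w.sum()))


def gyration_radius_coords(coords: np.ndarray) -> float:
    """Unweighted R_g straight from an (N, 3) coordinate array (MD hot path)."""
    dev = coords - coords.mean(axis=0)
    return float(np.sqrt(np.einsum("ij,ij->", dev, dev) / coords.shape[0]))
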