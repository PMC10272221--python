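"""Kernel machinery, training/prediction contracts, hyperparameter search."""

import numpy as np
import pytest
import sympy

from conftest import random_configuration
from gdmlreduce.dataio import (AtomicConfiguration, LabeledDataset,
                               SplitIndices, split_dataset)
from gdmlreduce.descriptor import DescriptorSpec
from gdmlreduce.gdml import (assemble_force_kernel, evaluate_rmse,
                             kernel_value, load_model, predict_energy,
                             predict_energy_forces, predict_forces,
                             save_model, select_sigma, train)


def harmonic_diatomic_dataset(n=20, k=150.0, r0=1.5, lo=1.3, hi=1.7):
    """Analytic toy PES: E = k(r−r0)², exact forces along the bond."""
    rs = np.linspace(lo, hi, n)
    configs, energies, forces = [], [], []
    for r in rs:
        coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
        configs.append(AtomicConfiguration([6, 6], coords))
        energies.append(k * (r - r0) ** 2)
        f = 2.0 * k * (r - r0)  # force on atom 0 along +x
        forces.append([[f, 0.0, 0.0], [-f, 0.0, 0.0]])
    return LabeledDataset(configs, np.array(energies), np.array(forces),
                          name="harmonic-diatomic")


def all_indices(ds):
    return np.arange(len(ds))


class TestKernelValue:
    def test_normalization_at_zero(self):
        assert kernel_value(0.0, 2.0) == 1.0

    @pytest.mark.parametrize("c", [0.1, 1.0, 7.3])
    def test_scale_invariance(self, c):
        assert kernel_value(0.4, 1.3) == pytest.approx(
            kernel_value(c * 0.4, c * 1.3), rel=1e-14)

    def test_value_at_sigma_matches_symbolic_form(self):
        # independent high-precision evaluation of (1+u+u²/3)e^{−u}, u=√5
        u = sympy.sqrt(5)
        exact = float(((1 + u + u ** 2 / sympy.Integer(3))
                       * sympy.exp(-u)).evalf(30))
        assert kernel_value(1.7, 1.7) == pytest.approx(exact, rel=1e-14)

    def test_strictly_decreasing(self):
        d = np.linspace(0, 10, 200)
        k = kernel_value(d, 1.0)
        assert np.all(np.diff(k) < 0)

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            kernel_value(1.0, 0.0)


class TestForceKernel:
    def test_single_point_block_symmetric_psd(self, rng):
        spec = DescriptorSpec.global_spec(4)
        coords = random_configuration(rng, 4)
        K = assemble_force_kernel(coords[None], spec, sigma=1.0)
        assert K.shape == (12, 12)
        np.testing.assert_array_equal(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8 * np.linalg.norm(K)

    def test_blocks_match_double_finite_differences(self, rng):
        """Each entry is ∂²κ/∂R_a∂R_b of the scalar kernel (independent FD)."""
        from gdmlreduce.descriptor import descriptor_values
        spec = DescriptorSpec.global_spec(4)
        ra = random_configuration(rng, 4)
        rb = random_configuration(rng, 4)
        sigma = 2.0

        def kappa(ca, cb):
            delta = descriptor_values(ca, spec) - descriptor_values(cb, spec)
            return kernel_value(np.linalg.norm(delta), sigma)

        K = assemble_force_kernel(np.stack([ra, rb]), spec, sigma)
        block = K[:12, 12:]
        h = 1e-4
        fd = np.zeros((12, 12))
        for i in range(12):
            for j in range(12):
                pa, ma = ra.copy().reshape(-1), ra.copy().reshape(-1)
                pa[i] += h
                ma[i] -= h
                pb, mb = rb.copy().reshape(-1), rb.copy().reshape(-1)
                pb[j] += h
                mb[j] -= h
                fd[i, j] = (kappa(pa.reshape(-1, 3), pb.reshape(-1, 3))
                            - kappa(pa.reshape(-1, 3), mb.reshape(-1, 3))
                            - kappa(ma.reshape(-1, 3), pb.reshape(-1, 3))
                            + kappa(ma.reshape(-1, 3), mb.reshape(-1, 3))
                            ) / (4 * h * h)
        assert np.abs(block - fd).max() / np.abs(block).max() < 1e-5

    def test_identical_configurations_share_block(self, rng):
        spec = DescriptorSpec.global_spec(4)
        coords = random_configuration(rng, 4)
        K = assemble_force_kernel(np.stack([coords, coords]), spec, 1.5)
        np.testing.assert_allclose(K[:12, 12:], K[:12, :12], atol=1e-14)

    def test_symmetric_psd_many_points(self, chain8_dataset, chain8_splits,
                                       chain8_spec, chain8_model):
        coords = chain8_dataset.coordinates[chain8_splits.train[:12]]
        K = assemble_force_kernel(coords, chain8_spec, chain8_model.sigma)
        assert np.abs(K - K.T).max() == 0.0
        assert np.linalg.eigvalsh(K).min() >= -1e-8 * np.linalg.norm(K)


class TestTraining:
    def test_interpolation_on_harmonic_diatomic(self):
        ds = harmonic_diatomic_dataset(20)
        spec = DescriptorSpec.global_spec(2)
        m = train(ds, all_indices(ds), spec, lam=1e-12)
        for i in range(len(ds)):
            f = predict_forces(m, ds.configurations[i])
            assert np.abs(f - ds.forces[i]).max() < 1e-6

    def test_duplicated_training_set_equivalent(self):
        ds = harmonic_diatomic_dataset(12)
        spec = DescriptorSpec.global_spec(2)
        idx = all_indices(ds)
        m1 = train(ds, idx, spec, sigma=0.2, lam=1e-8)
        m2 = train(ds, np.concatenate([idx, idx]), spec, sigma=0.2, lam=1e-8)
        for r in (1.33, 1.51, 1.68):
            c = AtomicConfiguration([6, 6], [[0, 0, 0], [r, 0, 0]])
            np.testing.assert_allclose(predict_forces(m2, c),
                                       predict_forces(m1, c), atol=1e-8)

    def test_single_point_interpolates_at_lambda_zero(self):
        ds = harmonic_diatomic_dataset(3)
        spec = DescriptorSpec.global_spec(2)
        m = train(ds, [0], spec, sigma=0.3, lam=0.0)
        f = predict_forces(m, ds.configurations[0])
        assert np.abs(f - ds.forces[0]).max() < 1e-8

    def test_training_order_invariance(self, chain8_dataset, chain8_splits,
                                       chain8_spec):
        idx = chain8_splits.train[:10]
        m1 = train(chain8_dataset, idx, chain8_spec, sigma=0.05)
        m2 = train(chain8_dataset, idx[::-1], chain8_spec, sigma=0.05)
        c = chain8_dataset.configurations[int(chain8_splits.test[0])]
        np.testing.assert_allclose(predict_forces(m2, c),
                                   predict_forces(m1, c), atol=1e-8)

    def test_empty_training_set_rejected(self, chain8_dataset, chain8_spec):
        with pytest.raises(ValueError):
            train(chain8_dataset, [], chain8_spec)


class TestPrediction:
    def test_translation_invariance(self, chain8_model, chain8_dataset,
                                    chain8_splits):
        cfg = chain8_dataset.configurations[int(chain8_splits.test[1])]
        f0 = predict_forces(chain8_model, cfg)
        moved = AtomicConfiguration(cfg.atomic_numbers,
                                    cfg.coordinates + [11.0, -4.0, 0.5])
        np.testing.assert_allclose(predict_forces(chain8_model, moved), f0,
                                   atol=1e-10 * np.abs(f0).max())

    def test_rotation_covariance(self, chain8_model, chain8_dataset,
                                 chain8_splits):
        from scipy.stats import ortho_group
        cfg = chain8_dataset.configurations[int(chain8_splits.test[2])]
        q = ortho_group.rvs(3, random_state=3)
        f0 = predict_forces(chain8_model, cfg)
        rotated = AtomicConfiguration(cfg.atomic_numbers,
                                      cfg.coordinates @ q.T)
        fr = predict_forces(chain8_model, rotated)
        np.testing.assert_allclose(fr, f0 @ q.T, atol=1e-8 * np.abs(f0).max())

    def test_energy_offset_linearity(self, chain8_dataset, chain8_splits,
                                     chain8_spec):
        idx = chain8_splits.train[:10]
        m1 = train(chain8_dataset, idx, chain8_spec, sigma=0.05)
        shifted = LabeledDataset(chain8_dataset.configurations,
                                 chain8_dataset.energies + 100.0,
                                 chain8_dataset.forces)
        m2 = train(shifted, idx, chain8_spec, sigma=0.05)
        cfg = chain8_dataset.configurations[int(chain8_splits.test[0])]
        assert predict_energy(m2, cfg) - predict_energy(m1, cfg) \
            == pytest.approx(100.0, abs=1e-8)

    def test_energy_curve_matches_analytic_parabola(self):
        k, r0 = 150.0, 1.5
        ds = harmonic_diatomic_dataset(20, k=k, r0=r0)
        spec = DescriptorSpec.global_spec(2)
        # σ ≈ 2× the sampled descriptor span for smooth interpolation
        m = train(ds, all_indices(ds), spec, sigma=0.4, lam=1e-12)
        rs = np.linspace(1.32, 1.68, 30)
        pred = [predict_energy(m, AtomicConfiguration(
            [6, 6], [[0, 0, 0], [r, 0, 0]])) for r in rs]
        exact = k * (rs - r0) ** 2
        rmse = np.sqrt(np.mean((np.array(pred) - exact) ** 2))
        # labels are noise-free; the curve must match far below the
        # ~6 kcal/mol sampled energy range
        assert rmse < 5e-4

    def test_atom_count_mismatch(self, chain8_model):
        c = AtomicConfiguration([6, 6], [[0, 0, 0], [1.5, 0, 0]])
        with pytest.raises(ValueError):
            predict_forces(chain8_model, c)


class TestEnergyForceConsistency:
    def test_forces_are_negative_energy_gradient(self, chain8_model,
                                                 chain8_dataset,
                                                 chain8_splits):
        h = 1e-5
        for ci in chain8_splits.test[:5]:
            coords = chain8_dataset.configurations[int(ci)].coordinates
            _, f = predict_energy_forces(chain8_model, coords)
            fd = np.zeros_like(f)
            for i in range(coords.shape[0]):
                for c in range(3):
                    rp, rm = coords.copy(), coords.copy()
                    rp[i, c] += h
                    rm[i, c] -= h
                    fd[i, c] = -(predict_energy_forces(chain8_model, rp)[0]
                                 - predict_energy_forces(chain8_model,
                                                         rm)[0]) / (2 * h)
            assert np.abs(f - fd).max() / np.abs(f).max() < 1e-6


class TestEvaluation:
    def test_zero_residuals_give_zero_rmse(self, chain8_model,
                                           chain8_dataset, chain8_splits):
        idx = chain8_splits.test[:5]
        preds_f = np.stack([predict_forces(
            chain8_model, chain8_dataset.configurations[int(i)])
            for i in idx])
        preds_e = np.array([predict_energy(
            chain8_model, chain8_dataset.configurations[int(i)])
            for i in idx])
        configs = [chain8_dataset.configurations[int(i)] for i in idx]
        exact = LabeledDataset(configs, preds_e, preds_f)
        rep = evaluate_rmse(chain8_model, exact, np.arange(5))
        assert rep.force_rmse == pytest.approx(0.0, abs=1e-12)
        assert rep.energy_rmse == pytest.approx(0.0, abs=1e-12)

    def test_known_residual_arithmetic(self, chain8_model, chain8_dataset,
                                       chain8_splits):
        """Unit residual on one atom of one of two diatomic-sized configs:
        RMSE = 1/√(total components)."""
        idx = chain8_splits.test[:2]
        configs = [chain8_dataset.configurations[int(i)] for i in idx]
        preds_f = np.stack([predict_forces(chain8_model, c) for c in configs])
        preds_e = np.array([predict_energy(chain8_model, c) for c in configs])
        refs = preds_f.copy()
        refs[0, 0, 0] += 1.0  # residual (1,0,0) on atom 0 of config 0
        ds = LabeledDataset(configs, preds_e, refs)
        rep = evaluate_rmse(chain8_model, ds, [0, 1])
        n_comp = refs.size
        assert rep.force_rmse == pytest.approx(1.0 / np.sqrt(n_comp))

    def test_training_points_interpolated(self):
        ds = harmonic_diatomic_dataset(15)
        spec = DescriptorSpec.global_spec(2)
        m = train(ds, all_indices(ds), spec, lam=1e-12)
        rep = evaluate_rmse(m, ds, all_indices(ds))
        assert rep.force_rmse < 1e-6


class TestSigmaSelection:
    def test_single_grid_value_returned(self, chain8_dataset, chain8_splits,
                                        chain8_spec):
        small = SplitIndices(chain8_splits.train[:10],
                             chain8_splits.validation[:10], [], seed=0)
        best, reports = select_sigma(chain8_dataset, small, chain8_spec,
                                     [0.05])
        assert best == 0.05
        assert list(reports) == [0.05]

    def test_argmin_of_validation_rmse(self, chain8_dataset, chain8_splits,
                                       chain8_spec):
        small = SplitIndices(chain8_splits.train[:15],
                             chain8_splits.validation[:15], [], seed=0)
        grid = [0.005, 0.05, 0.5]
        best, reports = select_sigma(chain8_dataset, small, chain8_spec, grid)
        brute = min(reports, key=lambda s: (reports[s].force_rmse, s))
        assert best == brute

    def test_duplicates_deduplicated(self, chain8_dataset, chain8_splits,
                                     chain8_spec):
        small = SplitIndices(chain8_splits.train[:8],
                             chain8_splits.validation[:8], [], seed=0)
        _, reports = select_sigma(chain8_dataset, small, chain8_spec,
                                  [0.05, 0.05, 0.05])
        assert len(reports) == 1


class TestLearningCurve:
    def test_median_test_rmse_nonincreasing_in_training_size(self):
        """More training data should not hurt (median over 5 seeds)."""
        from gdmlreduce.simulate import build_toy_molecule, generate_dataset
        sizes = [25, 50, 100, 200]
        curves = []
        for seed in range(5):
            top = build_toy_molecule("chain", 6, seed=seed)
            ds = generate_dataset(top, n_samples=320, stride=5, dt=0.5,
                                  seed=seed)
            spec = DescriptorSpec.global_spec(6)
            splits = split_dataset(ds, 200, 0, 100, seed=seed)
            row = []
            for m_size in sizes:
                m = train(ds, splits.train[:m_size], spec)
                row.append(evaluate_rmse(m, ds, splits.test).force_rmse)
            curves.append(row)
        med = np.median(np.array(curves), axis=0)
        assert np.all(np.diff(med) <= 0)


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path, chain8_model,
                                              chain8_dataset, chain8_splits):
        p = tmp_path / "model.npz"
        save_model(chain8_model, p)
        back = load_model(p)
        cfg = chain8_dataset.configurations[int(chain8_splits.test[0])]
        np.testing.assert_allclose(predict_forces(back, cfg),
                                   predict_forces(chain8_model, cfg),
                                   rtol=1e-15)
        assert predict_energy(back, cfg) == pytest.approx(
            predict_energy(chain8_model, cfg), rel=1e-15)
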