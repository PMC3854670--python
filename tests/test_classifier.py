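"""Dictionary sampling, SCI, and minimal-residual class decisions."""

import math
import warnings

import numpy as np
import pytest

import mfishsparse as mf
from mfishsparse.classifier import _class_residuals


def two_class_orthogonal_dictionary():
    """Class 1 spans the first axis, class 2 the second."""
    A = np.array(
        [[1.0, 2.0, 0.0, 0.0],
         [0.0, 0.0, 1.0, 3.0],
         [0.0, 0.0, 0.0, 0.0]]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mf.Dictionary(A, [1, 1, 2, 2])


class TestSci:
    def _solution_with_mass(self, masses):
        coeff = np.asarray(masses, dtype=float)[:, None]
        return mf.RowSparseSolution(
            coefficients=coeff,
            support=np.flatnonzero(coeff[:, 0]),
            residual_norm=0.0,
            iterations=int(np.count_nonzero(coeff)),
        )

    def test_fully_concentrated_mass_gives_one(self):
        D = two_class_orthogonal_dictionary()
        sol = self._solution_with_mass([0.4, 0.6, 0.0, 0.0])
        assert mf.sci(sol, D) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_spread_gives_zero(self):
        D = two_class_orthogonal_dictionary()
        sol = self._solution_with_mass([0.25, 0.25, 0.25, 0.25])
        assert mf.sci(sol, D) == pytest.approx(0.0, abs=1e-12)

    def test_three_class_closed_form(self):
        rng = np.random.default_rng(0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            D = mf.Dictionary(rng.normal(size=(4, 6)), [1, 1, 2, 2, 3, 3])
        # l1 masses 0.5 / 0.3 / 0.2 -> (3 * 0.5 - 1) / 2 = 0.25
        sol = self._solution_with_mass([0.5, 0.0, -0.3, 0.0, 0.2, 0.0])
        assert mf.sci(sol, D) == pytest.approx(0.25, abs=1e-12)

    def test_zero_solution_is_an_error(self):
        D = two_class_orthogonal_dictionary()
        sol = self._solution_with_mass([0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="all-zero"):
            mf.sci(sol, D)


class TestBuildDictionary:
    def test_exhaustive_sampling_uses_every_labelled_pixel(self, noiseless_cell):
        D, test_coords = mf.build_dictionary(
            noiseless_cell.channels, noiseless_cell.truth, fraction=1.0, seed=0
        )
        truth = noiseless_cell.truth
        n_labelled = int(np.sum((truth != 0) & (truth != 255)))
        assert D.N == n_labelled
        assert test_coords.shape == (0, 2)

    def test_per_class_counts_and_seed_reproducibility(self, noiseless_cell):
        truth = noiseless_cell.truth
        D1, t1 = mf.build_dictionary(noiseless_cell.channels, truth, 0.10, seed=5)
        D2, t2 = mf.build_dictionary(noiseless_cell.channels, truth, 0.10, seed=5)
        assert np.array_equal(D1.matrix, D2.matrix)
        assert np.array_equal(t1, t2)
        for c, size in D1.class_sizes.items():
            assert size == math.ceil(0.10 * np.sum(truth == c))

    def test_training_and_test_partition_is_complete(self, noiseless_cell):
        truth = noiseless_cell.truth
        D, test_coords = mf.build_dictionary(noiseless_cell.channels, truth, 0.3, seed=2)
        n_labelled = int(np.sum((truth != 0) & (truth != 255)))
        assert D.N + test_coords.shape[0] == n_labelled
        held_out = truth[test_coords[:, 0], test_coords[:, 1]]
        assert np.all((held_out != 0) & (held_out != 255))

    def test_missing_requested_class_warns(self, noiseless_cell):
        with pytest.warns(UserWarning, match="class 25"):
            mf.build_dictionary(
                noiseless_cell.channels, noiseless_cell.truth, 0.5, seed=0,
                classes=list(range(1, 26)),
            )

    def test_bad_fraction_rejected(self, noiseless_cell):
        for fraction in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="fraction"):
                mf.build_dictionary(
                    noiseless_cell.channels, noiseless_cell.truth, fraction, seed=0
                )

    def test_fraction_grid_preset(self):
        assert mf.DEFAULT_FRACTION_GRID == (
            0.01, 0.03, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.50,
        )

    def test_sci_screening_runs_and_stays_deterministic(self, noiseless_cell):
        kwargs = dict(fraction=0.02, seed=9, sci_threshold=0.2)
        D1, _ = mf.build_dictionary(noiseless_cell.channels, noiseless_cell.truth, **kwargs)
        D2, _ = mf.build_dictionary(noiseless_cell.channels, noiseless_cell.truth, **kwargs)
        assert np.array_equal(D1.matrix, D2.matrix)


def test_minmax_scaling_maps_each_channel_to_unit_range():
    rng = np.random.default_rng(6)
    stack = rng.uniform(2, 9, size=(10, 10, 3))
    stack[..., 2] = 4.0  # constant channel
    scaled = mf.minmax_scale_channels(stack)
    assert scaled[..., 0].min() == 0.0 and scaled[..., 0].max() == 1.0
    assert np.all(scaled[..., 2] == 0.0)


class TestClassDecisions:
    def test_pixel_equal_to_training_column(self, noiseless_cell):
        D, _ = mf.build_dictionary(noiseless_cell.channels, noiseless_cell.truth, 0.5, seed=1)
        col = D.columns_of_class(3)[0]
        y = D.matrix[:, col] * D.scales[col]
        decision = mf.classify_pixel(D, y, mf.SolverConfig(sparsity_level=1))
        assert decision.predicted_class == 3
        assert decision.residual_by_class[3] == pytest.approx(0.0, abs=1e-10)
        assert all(v >= 0 for v in decision.residual_by_class.values())

    def test_orthogonal_classes_decide_by_axis(self):
        D = two_class_orthogonal_dictionary()
        d1 = mf.classify_pixel(D, np.array([2.5, 0.0, 0.0]), mf.SolverConfig(sparsity_level=1))
        d2 = mf.classify_pixel(D, np.array([0.0, 1.5, 0.0]), mf.SolverConfig(sparsity_level=1))
        assert d1.predicted_class == 1
        assert d2.predicted_class == 2

    def test_perturbed_pixel_keeps_class_with_smallest_residual(self):
        rng = np.random.default_rng(4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            D = mf.Dictionary(rng.normal(size=(5, 40)), (np.arange(40) % 4) + 1)
        col = D.columns_of_class(3)[1]
        y = D.matrix[:, col] + 1e-4 * rng.normal(size=5)
        decision = mf.classify_pixel(D, y, mf.SolverConfig(sparsity_level=2))
        assert decision.predicted_class == 3
        r3 = decision.residual_by_class[3]
        assert all(r3 < v for c, v in decision.residual_by_class.items() if c != 3)

    def test_patch_of_identical_atoms_gets_that_class(self, noiseless_cell):
        D, _ = mf.build_dictionary(noiseless_cell.channels, noiseless_cell.truth, 0.5, seed=1)
        col = D.columns_of_class(7)[0]
        Y = np.tile((D.matrix[:, col] * D.scales[col])[:, None], (1, 9))
        decision = mf.classify_patch(D, Y, mf.SolverConfig(sparsity_level=1))
        assert decision.predicted_class == 7
        assert decision.residual_by_class[7] == pytest.approx(0.0, abs=1e-9)

    def test_single_column_patch_reduces_to_pixel_decision(self, gaussian_dictionary):
        rng = np.random.default_rng(12)
        cfg = mf.SolverConfig(sparsity_level=3)
        for _ in range(20):
            y = rng.normal(size=8)
            dp = mf.classify_pixel(gaussian_dictionary, y, cfg)
            dm = mf.classify_patch(gaussian_dictionary, y[:, None], cfg)
            assert dp.predicted_class == dm.predicted_class
            assert dp.residual_by_class == dm.residual_by_class

    def test_majority_structure_dominates_joint_decision(self):
        # two well-separated classes; 8 class-2 columns and one outlier
        rng = np.random.default_rng(8)
        A = np.concatenate(
            [np.array([[1, 0, 0, 0, 0]] * 12).T + 0.01 * rng.normal(size=(5, 12)),
             np.array([[0, 0, 0, 0, 1]] * 12).T + 0.01 * rng.normal(size=(5, 12))],
            axis=1,
        )
        D = mf.Dictionary(A, [1] * 12 + [2] * 12)
        Y = np.concatenate(
            [np.tile(np.array([0.0, 0, 0, 0, 1.0])[:, None], (1, 8)),
             np.array([1.0, 0, 0, 0, 0])[:, None]],
            axis=1,
        )
        decision = mf.classify_patch(D, Y, mf.SolverConfig(sparsity_level=2))
        assert decision.predicted_class == 2
        # verify against per-class residuals computed directly on the support
        sol = mf.somp_solve(D, Y, mf.SolverConfig(sparsity_level=2))
        direct = _class_residuals(D, Y, sol, refit=False)
        assert decision.residual_by_class == direct

    def test_each_class_residual_bounds_full_residual(self, gaussian_dictionary):
        rng = np.random.default_rng(23)
        cfg = mf.SolverConfig(sparsity_level=4)
        for _ in range(10):
            Y = rng.normal(size=(8, 5))
            decision = mf.classify_patch(gaussian_dictionary, Y, cfg)
            full = decision.solution.residual_norm
            for v in decision.residual_by_class.values():
                assert v >= full - 1e-9


class TestClassifyImage:
    def test_all_background_mask_yields_all_zero_labels(self, noiseless_cell):
        D, _ = mf.build_dictionary(noiseless_cell.channels, noiseless_cell.truth, 0.5, seed=1)
        mask = np.zeros(noiseless_cell.truth.shape, dtype=bool)
        pred = mf.classify_image(noiseless_cell.channels, mask, D, mf.SolverConfig(), s=9)
        assert pred.dtype == np.uint8
        assert np.all(pred == 0)

    def test_mask_shape_mismatch_rejected(self, noiseless_cell):
        D, _ = mf.build_dictionary(noiseless_cell.channels, noiseless_cell.truth, 0.5, seed=1)
        with pytest.raises(ValueError, match="shapes differ"):
            mf.classify_image(noiseless_cell.channels, np.ones((4, 4), bool), D)

    def test_label_hygiene_and_determinism_on_noisy_cell(self):
        cell = mf.simulate_cell(
            mf.SimulationConfig(seed=3, image_size=(48, 48), m=6, noise_sd=0.3)
        )
        D, _ = mf.build_dictionary(cell.channels, cell.truth, 0.2, seed=3)
        cfg = mf.SolverConfig(sparsity_level=3)
        p1 = mf.classify_image(cell.channels, cell.mask, D, cfg, s=9)
        p2 = mf.classify_image(cell.channels, cell.mask, D, cfg, s=9)
        assert np.array_equal(p1, p2)
        assert set(np.unique(p1).tolist()) <= {0, 1, 2, 3, 4, 5, 6}
        assert 255 not in np.unique(p1)
        assert np.all(p1[cell.mask] > 0)
        assert np.all(p1[~cell.mask] == 0)

    def test_s1_equals_pixelwise_classification(self):
        cell = mf.simulate_cell(
            mf.SimulationConfig(seed=5, image_size=(40, 40), m=5, noise_sd=0.2)
        )
        D, _ = mf.build_dictionary(cell.channels, cell.truth, 0.3, seed=6)
        cfg = mf.SolverConfig(sparsity_level=2)
        pred = mf.classify_image(cell.channels, cell.mask, D, cfg, s=1)
        rows, cols = np.nonzero(cell.mask)
        for r, c in list(zip(rows.tolist(), cols.tolist()))[::17]:
            d = mf.classify_pixel(D, cell.channels[r, c], cfg)
            assert pred[r, c] == d.predicted_class
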