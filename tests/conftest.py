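import numpy as np
import pytest

import mfishsparse as mf


def make_gaussian_dictionary(rng, n, N, n_classes):
    """Random Gaussian dictionary with classes assigned round-robin."""
    A = rng.normal(size=(n, N))
    labels = (np.arange(N) % n_classes) + 1
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mf.Dictionary(A, labels)


@pytest.fixture
def gaussian_dictionary():
    rng = np.random.default_rng(7)
    return make_gaussian_dictionary(rng, n=8, N=24, n_classes=4)


@pytest.fixture(scope="session")
def noiseless_cell():
    """Default-sized noiseless cell: every class-c pixel equals its code."""
    return mf.simulate_cell(mf.SimulationConfig(seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def model_comparison():
    """Pixelwise vs joint model over 20 cells at the calibration noise level.

    Shared by the model-comparison and isolated-spot analyses; computing it
    once keeps the suite fast.  Returns per-cell RCC lists and isolated-spot
    counts for both models.
    """
    cfg = mf.SolverConfig(sparsity_level=3)
    rcc_pixel, rcc_joint, spots_pixel, spots_joint = [], [], [], []
    for seed in range(20):
        cell = mf.simulate_cell(
            mf.SimulationConfig(seed=seed, noise_sd=mf.CALIBRATION_NOISE_SD)
        )
        dictionary, test_coords = mf.build_dictionary(
            cell.channels, cell.truth, fraction=0.1, seed=seed + 1000
        )
        mask = cell.mask
        p1 = mf.classify_image(cell.channels, mask, dictionary, cfg, s=1)
        p9 = mf.classify_image(cell.channels, mask, dictionary, cfg, s=9)
        rcc_pixel.append(mf.rcc(p1, cell.truth, test_coords).overall_rcc)
        rcc_joint.append(mf.rcc(p9, cell.truth, test_coords).overall_rcc)
        spots_pixel.append(mf.isolated_spot_count(p1, cell.truth, mask))
        spots_joint.append(mf.isolated_spot_count(p9, cell.truth, mask))
    return {
        "rcc_pixel": rcc_pixel,
        "rcc_joint": rcc_joint,
        "spots_pixel": spots_pixel,
        "spots_joint": spots_joint,
    }
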