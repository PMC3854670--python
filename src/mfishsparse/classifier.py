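"""Dictionary construction and minimal-residual classification.

A training dictionary is built by randomly sampling labelled pixels per
chromosome class; a test pixel (or the joint matrix of its neighborhood) is
then sparsely coded over the dictionary and assigned to the class whose
columns reconstruct it with the smallest residual.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .neighborhood import PatchMatrix, WindowSpec, extract_patch
from .solvers import Dictionary, RowSparseSolution, SolverConfig, omp_solve, somp_solve

__all__ = [
    "PixelFeature",
    "ClassDecision",
    "build_dictionary",
    "sci",
    "classify_pixel",
    "classify_patch",
    "classify_image",
    "minmax_scale_channels",
    "DEFAULT_FRACTION_GRID",
]

#: Training-sample fractions of the standard parameter sweep.
DEFAULT_FRACTION_GRID = (
    0.01, 0.03, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.50,
)

BACKGROUND_LABEL = 0
OVERLAP_LABEL = 255


@dataclass(frozen=True)
class PixelFeature:
    """One pixel's multichannel intensity vector and its image coordinate."""

    values: np.ndarray
    coordinates: tuple[int, int]


@dataclass
class ClassDecision:
    """Outcome of a minimal-residual class decision."""

    predicted_class: int
    residual_by_class: dict[int, float]
    solution: RowSparseSolution


def minmax_scale_channels(channels: np.ndarray) -> np.ndarray:
    """Optionally rescale each channel to [0, 1] over the image.

    Off by default throughout the pipeline (intensities are used raw); apply
    it to a stack before ``build_dictionary`` and ``classify_image`` when
    channels come from detectors with very different dynamic ranges.
    Constant channels are left at 0.
    """
    channels = np.asarray(channels, dtype=float)
    lo = channels.min(axis=(0, 1), keepdims=True)
    span = channels.max(axis=(0, 1), keepdims=True) - lo
    span = np.where(span == 0, 1.0, span)
    return (channels - lo) / span


def _as_cells(channels, labels):
    """Normalize (stack, labels) or lists thereof to parallel lists."""
    if isinstance(channels, np.ndarray):
        channels = [channels]
        labels = [labels]
    channels = [np.asarray(ch, dtype=float) for ch in channels]
    labels = [np.asarray(lb) for lb in labels]
    if len(channels) != len(labels):
        raise ValueError("number of image stacks and label images differ")
    for ch, lb in zip(channels, labels):
        if ch.shape[:2] != lb.shape:
            raise ValueError(f"stack shape {ch.shape[:2]} does not match labels {lb.shape}")
    return channels, labels


def build_dictionary(
    channels,
    labels,
    fraction: float,
    seed: int,
    sci_threshold: float | None = None,
    *,
    classes=None,
    sci_config: SolverConfig | None = None,
    sci_max_rounds: int = 5,
):
    """Sample training pixels per class and assemble the dictionary.

    For every chromosome class present in the label image(s), ``ceil(fraction
    * count)`` pixels are drawn uniformly at random (without replacement)
    from that class; background (0) and overlap (255) pixels never enter the
    dictionary.  The complement of the training sample — every other labelled
    pixel — is returned as the test partition.

    Parameters
    ----------
    channels, labels
        One ``H x W x n`` stack with its label image, or parallel lists of
        them for a multi-cell dictionary.
    fraction
        Fraction of labelled pixels per class to use for training, in (0, 1].
    seed
        Seed for the sampling RNG; the same seed reproduces the same
        dictionary exactly.
    sci_threshold
        When set, each candidate training pixel is coded over the other
        candidates (leave-one-out) and kept only if its sparsity
        concentration index reaches the threshold; rejected pixels are
        resampled for up to ``sci_max_rounds`` rounds.
    classes
        Optional explicit class list; requested classes with no labelled
        pixels are omitted with a warning.

    Returns
    -------
    (Dictionary, test_coords)
        ``test_coords`` is an ``(k, 2)`` integer array of held-out pixel
        coordinates for a single cell, or a list of such arrays for a list
        input.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    single = isinstance(channels, np.ndarray)
    channels, labels = _as_cells(channels, labels)
    rng = np.random.default_rng(seed)

    all_labels = np.unique(np.concatenate([np.unique(lb) for lb in labels]))
    present = [int(c) for c in all_labels if c not in (BACKGROUND_LABEL, OVERLAP_LABEL)]
    if classes is None:
        classes = present
    else:
        classes = [int(c) for c in classes]
        for c in classes:
            if c not in present:
                warnings.warn(f"class {c} has no labelled pixels and is omitted", stacklevel=2)
        classes = [c for c in classes if c in present]
    if not classes:
        raise ValueError("no labelled chromosome pixels available for training")

    # (cell, row, col) coordinates per class, in deterministic scan order;
    # pixels that are exactly zero in every channel carry no signal and would
    # make degenerate (all-zero) atoms, so they never enter the training pool
    coords_by_class: dict[int, np.ndarray] = {}
    for c in classes:
        parts = []
        for idx, lb in enumerate(labels):
            rr, cc = np.nonzero(lb == c)
            if rr.size:
                nonzero = np.linalg.norm(channels[idx][rr, cc], axis=1) > 0
                parts.append(np.column_stack([np.full(rr.size, idx), rr, cc])[nonzero])
        pool = np.concatenate(parts, axis=0)
        if pool.shape[0] == 0:
            warnings.warn(
                f"class {c}: every labelled pixel is zero in all channels; class omitted",
                stacklevel=2,
            )
            continue
        coords_by_class[c] = pool
    classes = [c for c in classes if c in coords_by_class]
    if not classes:
        raise ValueError("no usable (nonzero) labelled pixels available for training")

    chosen: dict[int, np.ndarray] = {}
    for c in classes:
        pool = coords_by_class[c]
        k = math.ceil(fraction * pool.shape[0])
        pick = rng.choice(pool.shape[0], size=k, replace=False)
        chosen[c] = np.sort(pick)

    if sci_threshold is not None:
        _sci_screen(
            chosen, coords_by_class, channels, rng,
            sci_threshold, sci_config or SolverConfig(), sci_max_rounds,
        )

    cols, col_classes, train_keys = [], [], set()
    for c in classes:
        for cell_idx, r, cc_ in coords_by_class[c][chosen[c]]:
            cols.append(channels[cell_idx][r, cc_])
            col_classes.append(c)
            train_keys.add((cell_idx, r, cc_))
    dictionary = Dictionary(np.stack(cols, axis=1), col_classes)

    test_coords = []
    for idx, lb in enumerate(labels):
        rr, cc = np.nonzero((lb != BACKGROUND_LABEL) & (lb != OVERLAP_LABEL))
        keep = [(r, c_) for r, c_ in zip(rr.tolist(), cc.tolist()) if (idx, r, c_) not in train_keys]
        test_coords.append(np.asarray(keep, dtype=int).reshape(-1, 2))
    return dictionary, (test_coords[0] if single else test_coords)


def _sci_screen(chosen, coords_by_class, channels, rng, threshold, config, max_rounds):
    """Leave-one-out SCI screening: resample poorly concentrated candidates."""
    for _ in range(max_rounds):
        cols, col_classes, owners = [], [], []
        for c, pick in chosen.items():
            for local_idx, (cell_idx, r, cc_) in enumerate(coords_by_class[c][pick]):
                cols.append(channels[cell_idx][r, cc_])
                col_classes.append(c)
                owners.append((c, local_idx))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            provisional = Dictionary(np.stack(cols, axis=1), col_classes)
        rejected: dict[int, list[int]] = {}
        for j, (c, local_idx) in enumerate(owners):
            y = np.asarray(cols[j], dtype=float)
            sol = omp_solve(provisional, y, config, exclude=[j])
            if np.abs(sol.coefficients).sum() == 0 or sci(sol, provisional) < threshold:
                rejected.setdefault(c, []).append(local_idx)
        if not rejected:
            return
        for c, local_idxs in rejected.items():
            pool_size = coords_by_class[c].shape[0]
            unused = np.setdiff1d(np.arange(pool_size), chosen[c])
            for li in local_idxs:
                if unused.size == 0:
                    warnings.warn(
                        f"class {c}: no unused pixels left for SCI resampling; "
                        "keeping a below-threshold training pixel",
                        stacklevel=3,
                    )
                    break
                take = rng.integers(unused.size)
                new = chosen[c].copy()
                new[li] = unused[take]
                chosen[c] = new
                unused = np.delete(unused, take)
    warnings.warn("SCI screening did not converge within the retry budget", stacklevel=3)


def sci(solution: RowSparseSolution, dictionary: Dictionary) -> float:
    """Sparsity concentration index of a solution's coefficient mass.

    ``(m * max_i ||x on class i||_1 / ||x||_1 - 1) / (m - 1)``: 1 when all
    l1 mass lies in a single class, 0 when spread uniformly over all m
    classes.
    """
    x = np.abs(solution.coefficients).sum(axis=1)
    total = x.sum()
    if total == 0:
        raise ValueError("SCI is undefined for an all-zero solution")
    m = dictionary.m
    if m == 1:
        return 1.0
    frac = max(x[dictionary.columns_of_class(c)].sum() for c in dictionary.classes) / total
    return float((m * frac - 1.0) / (m - 1.0))


def _class_residuals(
    dictionary: Dictionary, Y: np.ndarray, solution: RowSparseSolution, refit: bool
) -> dict[int, float]:
    """||Y - A_i X_i||_F per class, with X_i the solution rows on class i.

    With ``refit=True`` the class-i coefficients are re-estimated by least
    squares on the class-i support columns instead of reusing the joint
    solution's values.
    """
    A = dictionary.matrix
    support = solution.support
    sup_classes = dictionary.class_of_column[support] if support.size else np.empty(0, int)
    base = float(np.linalg.norm(Y))
    out: dict[int, float] = {}
    for c in dictionary.classes:
        rows = support[sup_classes == c]
        if rows.size == 0:
            out[int(c)] = base
            continue
        A_sub = A[:, rows]
        if refit:
            coef, *_ = np.linalg.lstsq(A_sub, Y, rcond=None)
        else:
            coef = solution.coefficients[rows]
        out[int(c)] = float(np.linalg.norm(Y - A_sub @ coef))
    return out


def _decide(residuals: dict[int, float]) -> int:
    # lowest class label wins ties, deterministically
    return min(residuals, key=lambda c: (residuals[c], c))


def classify_pixel(
    dictionary: Dictionary,
    pixel: PixelFeature | np.ndarray,
    config: SolverConfig | None = None,
    *,
    refit: bool = False,
) -> ClassDecision:
    """Sparse-code one pixel by OMP and assign the minimal-residual class."""
    y = pixel.values if isinstance(pixel, PixelFeature) else np.asarray(pixel, dtype=float)
    solution = omp_solve(dictionary, y, config)
    residuals = _class_residuals(dictionary, y[:, None], solution, refit)
    return ClassDecision(_decide(residuals), residuals, solution)


def classify_patch(
    dictionary: Dictionary,
    patch: PatchMatrix | np.ndarray,
    config: SolverConfig | None = None,
    *,
    refit: bool = False,
) -> ClassDecision:
    """Jointly sparse-code a neighborhood by SOMP; label the central pixel.

    The decision is ``argmin_i ||Y - A_i X_i||_F`` over classes; it applies
    to the patch's central pixel only.
    """
    Y = patch.Y if isinstance(patch, PatchMatrix) else np.asarray(patch, dtype=float)
    solution = somp_solve(dictionary, Y, config)
    residuals = _class_residuals(dictionary, Y, solution, refit)
    return ClassDecision(_decide(residuals), residuals, solution)


def classify_image(
    channels: np.ndarray,
    mask: np.ndarray,
    dictionary: Dictionary,
    config: SolverConfig | None = None,
    s: int = 9,
    *,
    boundary_policy: str = "shrink",
    refit: bool = False,
    return_residual: bool = False,
):
    """Label every in-mask pixel; out-of-mask pixels get 0.

    ``s`` is the nominal neighborhood size (an odd square: 1, 9, 25, ...);
    ``s=1`` is the plain pixelwise classifier.  Returns a uint8 label image
    with values in {0} and the dictionary's classes — never 255, which is a
    ground-truth-only code for chromosome overlap.  With
    ``return_residual=True`` also returns the winning class's residual norm
    per pixel (a float map, 0 outside the mask).
    """
    channels = np.asarray(channels, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if channels.shape[:2] != mask.shape:
        raise ValueError(
            f"channel stack {channels.shape[:2]} and mask {mask.shape} shapes differ"
        )
    window = WindowSpec.from_size(s, boundary_policy)
    predicted = np.zeros(mask.shape, dtype=np.uint8)
    residual = np.zeros(mask.shape, dtype=float)
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows.tolist(), cols.tolist()):
        if window.side == 1:
            decision = classify_pixel(dictionary, channels[r, c], config, refit=refit)
        else:
            patch = extract_patch(channels, mask, (r, c), window)
            decision = classify_patch(dictionary, patch, config, refit=refit)
        predicted[r, c] = decision.predicted_class
        residual[r, c] = decision.residual_by_class[decision.predicted_class]
    if return_residual:
        return predicted, residual
    return predicted
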