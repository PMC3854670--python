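"""Classification accuracy metrics and model-comparison statistics.

The central metric is the ratio of correct classification (RCC): correctly
labelled pixels over all evaluated pixels in the chromosomal region.
Background (0) and overlap (255) pixels are never evaluated, and training
pixels are excluded by passing the held-out coordinate set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .classifier import BACKGROUND_LABEL, OVERLAP_LABEL, build_dictionary, classify_image
from .solvers import SolverConfig

__all__ = [
    "RCCReport",
    "rcc",
    "PairedTestResult",
    "paired_model_test",
    "isolated_spot_count",
    "parameter_sweep",
    "DEFAULT_K0_GRID",
    "DEFAULT_S_GRID",
]

#: Sparsity levels of the standard parameter sweep.
DEFAULT_K0_GRID = tuple(range(1, 11))
#: Neighborhood sizes (odd squares) of the standard parameter sweep.
DEFAULT_S_GRID = (1, 9, 25, 49, 81, 121, 169)


@dataclass
class RCCReport:
    """Overall and per-class correct-classification ratios."""

    overall_rcc: float
    per_class_rcc: dict[int, float]
    n_evaluated: int
    confusion: pd.DataFrame  # rows: truth class, columns: predicted class


def rcc(predicted: np.ndarray, truth: np.ndarray, evaluated_pixels: np.ndarray) -> RCCReport:
    """Ratio of correct classification over the evaluated pixel set.

    ``evaluated_pixels`` is a ``(k, 2)`` array of (row, col) coordinates —
    typically the held-out test partition from dictionary construction.
    Pixels whose ground truth is background or overlap are dropped
    defensively even if passed in.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: predicted {predicted.shape} vs truth {truth.shape}")
    evaluated_pixels = np.asarray(evaluated_pixels, dtype=int).reshape(-1, 2)
    t = truth[evaluated_pixels[:, 0], evaluated_pixels[:, 1]].astype(int)
    keep = (t != BACKGROUND_LABEL) & (t != OVERLAP_LABEL)
    if not np.any(keep):
        raise ValueError("evaluated pixel set is empty after excluding background/overlap")
    t = t[keep]
    p = predicted[evaluated_pixels[keep, 0], evaluated_pixels[keep, 1]].astype(int)

    labels = np.unique(np.concatenate([t, p]))
    lut = {int(c): i for i, c in enumerate(labels)}
    conf = np.zeros((labels.size, labels.size), dtype=int)
    for ti, pi in zip(t, p):
        conf[lut[ti], lut[pi]] += 1
    confusion = pd.DataFrame(conf, index=labels.astype(int), columns=labels.astype(int))

    per_class = {}
    for c in np.unique(t):
        sel = t == c
        per_class[int(c)] = float(np.mean(p[sel] == c))
    return RCCReport(
        overall_rcc=float(np.mean(p == t)),
        per_class_rcc=per_class,
        n_evaluated=int(t.size),
        confusion=confusion,
    )


@dataclass
class PairedTestResult:
    """Paired-sample t-test between two models' per-cell RCC lists.

    Means and standard deviations are reported in percent; inputs are RCC
    fractions in [0, 1].
    """

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    n: int


def paired_model_test(rcc_model_a, rcc_model_b) -> PairedTestResult:
    """Two-sided paired t-test on per-cell RCC differences.

    Degenerate cases are reported explicitly: all-zero differences give
    t = 0, p = 1; a constant nonzero difference gives t = +/-inf, p = 0.
    """
    a = np.asarray(rcc_model_a, dtype=float)
    b = np.asarray(rcc_model_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 1 or a.size < 2:
        raise ValueError("need at least two paired per-cell values")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, float(d.mean())), 0.0
    else:
        t, p = stats.ttest_rel(a, b)
    return PairedTestResult(
        mean_a=float(a.mean() * 100),
        sd_a=float(a.std(ddof=1) * 100),
        mean_b=float(b.mean() * 100),
        sd_b=float(b.std(ddof=1) * 100),
        t_statistic=float(t),
        p_value=float(p),
        n=int(a.size),
    )


def isolated_spot_count(predicted: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> int:
    """Number of single-pixel (8-connected) misclassification components.

    Pixelwise classifiers leave salt-and-pepper errors inside chromosome
    regions; this counts those isolated wrong pixels.  Background and
    overlap ground-truth pixels are excluded, consistent with RCC scoring.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    mask = np.asarray(mask, dtype=bool)
    if not (predicted.shape == truth.shape == mask.shape):
        raise ValueError("predicted, truth and mask shapes must match")
    scored = mask & (truth != BACKGROUND_LABEL) & (truth != OVERLAP_LABEL)
    errors = scored & (predicted != truth)
    labelled = measure.label(errors, connectivity=2)
    if labelled.max() == 0:
        return 0
    sizes = np.bincount(labelled.ravel())[1:]
    return int(np.sum(sizes == 1))


def parameter_sweep(
    cells,
    grid: dict,
    seeds,
    *,
    base_config: SolverConfig | None = None,
    boundary_policy: str = "shrink",
) -> pd.DataFrame:
    """Run dictionary building + classification + RCC over a parameter grid.

    ``cells`` is a list of objects with ``channels``, ``truth`` and a mask
    (``SimulatedCell`` works directly; any object exposing those attributes
    does).  ``grid`` maps any of ``"K0"``, ``"s"``, ``"fraction"`` to value
    lists; omitted keys default to the recommended settings (K0=3 within the
    K0 <= 5 recommendation, s=9, fraction=0.1).  Per-run failures are
    recorded as rows with an ``error`` message; the sweep never aborts.

    Returns a long-format table with columns
    ``cell, K0, s, fraction, seed, rcc, error``.
    """
    k0_list = list(grid.get("K0", [3]))
    s_list = list(grid.get("s", [9]))
    fr_list = list(grid.get("fraction", [0.1]))
    if not (k0_list and s_list and fr_list):
        raise ValueError("parameter grid must be non-empty")
    rows = []
    for cell_idx, cell in enumerate(cells):
        mask = getattr(cell, "mask", None)
        if mask is None:
            mask = (np.asarray(cell.truth) != BACKGROUND_LABEL)
        for seed in seeds:
            for fraction in fr_list:
                try:
                    dictionary, test_coords = build_dictionary(
                        cell.channels, cell.truth, fraction, seed
                    )
                except Exception as exc:  # noqa: BLE001 — recorded, not raised
                    for K0 in k0_list:
                        for s in s_list:
                            rows.append((cell_idx, K0, s, fraction, seed, np.nan, str(exc)))
                    continue
                for K0 in k0_list:
                    cfg = SolverConfig(
                        sparsity_level=K0,
                        q=(base_config.q if base_config else 2.0),
                        residual_tol=(base_config.residual_tol if base_config else None),
                    )
                    for s in s_list:
                        try:
                            pred = classify_image(
                                cell.channels, mask, dictionary, cfg, s=s,
                                boundary_policy=boundary_policy,
                            )
                            report = rcc(pred, cell.truth, test_coords)
                            rows.append(
                                (cell_idx, K0, s, fraction, seed, report.overall_rcc, None)
                            )
                        except Exception as exc:  # noqa: BLE001
                            warnings.warn(f"sweep point failed: {exc}", stacklevel=2)
                            rows.append((cell_idx, K0, s, fraction, seed, np.nan, str(exc)))
    return pd.DataFrame(
        rows, columns=["cell", "K0", "s", "fraction", "seed", "rcc", "error"]
    )
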