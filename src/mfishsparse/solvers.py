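"""Greedy sparse-recovery solvers: OMP and its multi-measurement variant SOMP.

Both solvers code a test sample (a single pixel feature vector, or the
``n x s`` matrix of a pixel neighborhood) over a dictionary of labelled
training columns.  SOMP enforces *row* sparsity: all s measurement vectors
share one support of at most ``K0`` atoms, selected greedily by the
q-norm (default q = 2) of each atom's correlation with the current residual
matrix, followed by a least-squares refit over the selected atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Dictionary",
    "RowSparseSolution",
    "SolverConfig",
    "omp_solve",
    "somp_solve",
    "residual_trace",
]


@dataclass(frozen=True)
class SolverConfig:
    """Parameters of the greedy solvers.

    Parameters
    ----------
    sparsity_level
        K0, the maximum number of atoms (nonzero rows) the solver may select.
        Small values (<= 5) are recommended for pixel classification.
    q
        Norm index used to score atom/residual correlations; 2 selects the
        atom with the largest l2 row norm of ``A.T @ R``.
    residual_tol
        Early-stop threshold on the Frobenius norm of the residual.  ``None``
        means ``1e-10 * ||Y||_F``, which stops cleanly on exactly
        representable inputs instead of selecting atoms against a zero
        residual.
    """

    sparsity_level: int = 3
    q: float = 2.0
    residual_tol: float | None = None

    def __post_init__(self) -> None:
        if self.sparsity_level < 1:
            raise ValueError(f"sparsity_level must be >= 1, got {self.sparsity_level}")
        if self.residual_tol is not None and self.residual_tol < 0:
            raise ValueError("residual_tol must be non-negative")


class Dictionary:
    """Training feature matrix partitioned into per-class column blocks.

    Columns are unit l2-normalized at construction (atom selection by
    correlation magnitude is scale sensitive); the original column norms are
    kept in :attr:`scales`.  Class labels follow the chromosome convention
    1..24 and need not be contiguous in the column order.
    """

    def __init__(self, matrix, class_of_column, *, normalize: bool = True):
        matrix = np.ascontiguousarray(matrix, dtype=float)
        if matrix.ndim != 2:
            raise ValueError(f"dictionary matrix must be 2-D, got shape {matrix.shape}")
        class_of_column = np.asarray(class_of_column, dtype=int)
        if class_of_column.shape != (matrix.shape[1],):
            raise ValueError(
                f"class_of_column length {class_of_column.shape} does not match "
                f"{matrix.shape[1]} columns"
            )
        if not np.all(np.isfinite(matrix)):
            raise ValueError("dictionary matrix contains non-finite entries")
        norms = np.linalg.norm(matrix, axis=0)
        if np.any(norms == 0):
            bad = np.flatnonzero(norms == 0)
            raise ValueError(f"all-zero dictionary columns at indices {bad[:10].tolist()}")
        if normalize:
            matrix = matrix / norms
            self.scales = norms
        else:
            self.scales = np.ones_like(norms)
        self.matrix = matrix
        self.class_of_column = class_of_column
        self.classes = np.unique(class_of_column)
        self._cols_by_class = {
            int(c): np.flatnonzero(class_of_column == c) for c in self.classes
        }
        for c, cols in self._cols_by_class.items():
            if cols.size <= self.n:
                warnings.warn(
                    f"class {c} has only {cols.size} training columns "
                    f"(<= feature dimension {self.n}); the per-class block is rank "
                    "deficient for representation",
                    stacklevel=2,
                )

    @property
    def n(self) -> int:
        """Feature dimension (number of fluorochrome channels)."""
        return self.matrix.shape[0]

    @property
    def N(self) -> int:
        """Total number of training columns."""
        return self.matrix.shape[1]

    @property
    def m(self) -> int:
        """Number of classes present."""
        return self.classes.size

    @property
    def class_sizes(self) -> dict[int, int]:
        return {c: cols.size for c, cols in self._cols_by_class.items()}

    def columns_of_class(self, label: int) -> np.ndarray:
        """Column indices belonging to ``label``."""
        return self._cols_by_class[int(label)]

    def __repr__(self) -> str:  # pragma: no cover
        return f"Dictionary(n={self.n}, N={self.N}, m={self.m})"


@dataclass
class RowSparseSolution:
    """Result of a greedy solve: estimate, support and residual history."""

    coefficients: np.ndarray  # N x s; rows outside `support` are exactly zero
    support: np.ndarray  # selected row indices, in selection order
    residual_norm: float
    iterations: int
    _trace: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def residual_trace(solution: RowSparseSolution) -> list[float]:
    """Per-iteration Frobenius residual norms recorded during the solve."""
    return list(solution._trace)


def _validate_inputs(dictionary: Dictionary, Y: np.ndarray, config: SolverConfig) -> None:
    if Y.shape[0] != dictionary.n:
        raise ValueError(
            f"measurement matrix has {Y.shape[0]} rows but dictionary expects "
            f"n={dictionary.n} (Y shape {Y.shape}, A shape {dictionary.matrix.shape})"
        )
    if Y.shape[1] < 1:
        raise ValueError("Y must contain at least one column")
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y contains non-finite entries")
    if config.sparsity_level > dictionary.N:
        raise ValueError(
            f"sparsity level K0={config.sparsity_level} exceeds the number of "
            f"dictionary columns N={dictionary.N}"
        )


def somp_solve(
    dictionary: Dictionary,
    Y: np.ndarray,
    config: SolverConfig | None = None,
    *,
    exclude: np.ndarray | None = None,
) -> RowSparseSolution:
    """Simultaneous OMP over the columns of ``Y`` (shared row support).

    At each step the atom maximizing ``||a_k^T R||_q`` over unselected columns
    is appended to the support (ties broken by lowest column index), the
    coefficients on the support are refit by least squares, and the residual
    ``R = Y - A_S X_S`` is recomputed.  Stops at ``|support| == K0`` or when
    the residual Frobenius norm falls to ``residual_tol``.

    Parameters
    ----------
    exclude
        Optional column indices never to select — used e.g. for
        leave-one-out screening of training pixels.
    """
    if config is None:
        config = SolverConfig()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError(f"Y must be 2-D (n x s), got shape {Y.shape}")
    _validate_inputs(dictionary, Y, config)

    A = dictionary.matrix
    N, s = dictionary.N, Y.shape[1]
    y_norm = float(np.linalg.norm(Y))
    tol = config.residual_tol if config.residual_tol is not None else 1e-10 * y_norm

    R = Y
    support: list[int] = []
    trace: list[float] = []
    X = np.zeros((N, s))
    res = y_norm
    forbidden = np.zeros(N, dtype=bool)
    if exclude is not None:
        forbidden[np.asarray(exclude, dtype=int)] = True

    while len(support) < config.sparsity_level and res > tol:
        corr = np.linalg.norm(A.T @ R, ord=config.q, axis=1)
        corr[support] = -np.inf
        corr[forbidden] = -np.inf
        w = int(np.argmax(corr))  # argmax takes the lowest index on ties
        if not np.isfinite(corr[w]):
            break  # every remaining column is excluded
        support.append(w)
        A_sub = A[:, support]
        coef, *_ = np.linalg.lstsq(A_sub, Y, rcond=None)
        X = np.zeros((N, s))
        X[support] = coef
        R = Y - A_sub @ coef
        res = float(np.linalg.norm(R))
        trace.append(res)

    return RowSparseSolution(
        coefficients=X,
        support=np.asarray(support, dtype=int),
        residual_norm=trace[-1] if trace else y_norm,
        iterations=len(trace),
        _trace=np.asarray(trace),
    )


def omp_solve(
    dictionary: Dictionary,
    y: np.ndarray,
    config: SolverConfig | None = None,
    *,
    exclude: np.ndarray | None = None,
) -> RowSparseSolution:
    """OMP for a single measurement vector.

    Delegates to :func:`somp_solve` on the ``n x 1`` matrix ``[y]``, so the
    two solvers agree bit for bit on single-column inputs.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError(f"y must be a 1-D vector, got shape {y.shape}")
    return somp_solve(dictionary, y[:, None], config, exclude=exclude)
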