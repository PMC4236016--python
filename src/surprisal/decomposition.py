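"""Maximum-entropy (surprisal) decomposition of log-expression matrices.

Surprisal analysis writes the natural-log expression of gene *i* at
condition *T* as a sum over transcription patterns alpha::

    ln X_i(T) = sum_alpha  G_{i,alpha} * lam_alpha(T)

where ``G[:, alpha]`` is the time-independent extent of participation of
each gene in pattern alpha and ``lam[alpha, T]`` is the Lagrange
multiplier — the condition-dependent weight of the pattern.  Pattern
``alpha = 0`` is the steady (balanced) state: the maximal-entropy
expression distribution free of disease constraints.  Patterns
``alpha >= 1`` are the deviations that hold the system away from balance.

The fit is computed by singular value decomposition of the m x t log
matrix.  Two numerically independent routes are provided: a direct SVD of
the rectangular matrix, and the small-matrix route that eigendecomposes
the t x t Gram matrix ``Y.T @ Y`` and back-projects — exploiting that the
rank is at most the number of conditions, so solving the small matrix
suffices even for tens of thousands of genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "LogExpressionMatrix",
    "SurprisalDecomposition",
    "DecompositionError",
    "log_transform",
    "decompose",
    "reconstruct",
    "steady_state_residual",
]

#: relative threshold below which a singular value counts as numerically zero
RANK_TOL = 1e-10


class DecompositionError(ValueError):
    """Invalid input to the surprisal decomposition."""


@dataclass(frozen=True)
class LogExpressionMatrix:
    """Natural-log expression values with the same naming contract as
    :class:`~surprisal.expression.ExpressionMatrix`."""

    gene_names: tuple[str, ...]
    condition_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        object.__setattr__(self, "condition_names", tuple(self.condition_names))
        if not np.all(np.isfinite(values)):
            raise DecompositionError("log-expression entries must be finite")
        m, t = values.shape
        if len(self.gene_names) != m or len(self.condition_names) != t:
            raise DecompositionError("names do not match matrix shape")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SurprisalDecomposition:
    """Result of the surprisal fit.

    Attributes
    ----------
    G
        ``(m, t)`` gene participation weights; column ``alpha`` has unit
        Euclidean norm.  The most stable transcripts carry the lowest
        (most negative) ``G[:, 0]``.
    lam
        ``(t, t)`` Lagrange multipliers; ``lam[alpha, T]`` is the weight of
        pattern alpha at condition T, in log-expression units.  Row norms
        equal the singular values.
    omega
        Singular values, non-increasing, length t.  The scale factors of
        the decomposition; all t patterns are retained (zero singular
        values yield zero patterns) so ``lam`` is always t x t.
    """

    gene_names: tuple[str, ...]
    condition_names: tuple[str, ...]
    G: np.ndarray = field(repr=False)
    lam: np.ndarray = field(repr=False)
    omega: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        object.__setattr__(self, "condition_names", tuple(self.condition_names))

    @property
    def n_genes(self) -> int:
        return self.G.shape[0]

    @property
    def n_patterns(self) -> int:
        return self.G.shape[1]

    def pattern_weights(self, alpha: int) -> np.ndarray:
        """Participation weights ``G[:, alpha]`` for one pattern."""
        self._check_alpha(alpha)
        return self.G[:, alpha]

    def _check_alpha(self, alpha: int) -> None:
        if not 0 <= alpha < self.n_patterns:
            raise DecompositionError(
                f"pattern index {alpha} out of range 0..{self.n_patterns - 1}"
            )

    def effective_rank(self, tol: float = RANK_TOL) -> int:
        """Number of patterns whose singular value exceeds ``tol * omega[0]``."""
        if self.omega[0] == 0:
            return 0
        return int(np.sum(self.omega > tol * self.omega[0]))

    # -- serialization -------------------------------------------------

    def g_frame(self) -> pd.DataFrame:
        cols = [f"G{a}" for a in range(self.n_patterns)]
        return pd.DataFrame(self.G, index=list(self.gene_names), columns=cols)

    def lam_frame(self) -> pd.DataFrame:
        idx = [f"lambda{a}" for a in range(self.n_patterns)]
        return pd.DataFrame(self.lam, index=idx, columns=list(self.condition_names))

    def save(self, directory: str | Path) -> dict[str, Path]:
        """Write G, lambda and singular-value tables as TSV; return paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "G": directory / "gene_weights.tsv",
            "lam": directory / "lagrange_multipliers.tsv",
            "omega": directory / "singular_values.tsv",
        }
        gf = self.g_frame()
        gf.index.name = "Gene"
        gf.to_csv(paths["G"], sep="\t")
        lf = self.lam_frame()
        lf.index.name = "Pattern"
        lf.to_csv(paths["lam"], sep="\t")
        pd.Series(self.omega, index=[f"omega{a}" for a in range(self.n_patterns)]).to_csv(
            paths["omega"], sep="\t", header=False
        )
        return paths

    @classmethod
    def load(cls, directory: str | Path) -> "SurprisalDecomposition":
        directory = Path(directory)
        gf = pd.read_csv(
            directory / "gene_weights.tsv", sep="\t", index_col=0,
            float_precision="round_trip",
        )
        lf = pd.read_csv(
            directory / "lagrange_multipliers.tsv", sep="\t", index_col=0,
            float_precision="round_trip",
        )
        om = pd.read_csv(
            directory / "singular_values.tsv", sep="\t", index_col=0, header=None,
            float_precision="round_trip",
        )
        return cls(
            gene_names=tuple(str(g) for g in gf.index),
            condition_names=tuple(str(c) for c in lf.columns),
            G=gf.to_numpy(),
            lam=lf.to_numpy(),
            omega=om.iloc[:, 0].to_numpy(),
        )


def log_transform(x: ExpressionMatrix) -> LogExpressionMatrix:
    """Elementwise natural logarithm of the expression signals."""
    if np.any(x.values <= 0):
        raise DecompositionError(
            "non-positive expression value reached log_transform; read-time flooring was bypassed"
        )
    return LogExpressionMatrix(x.gene_names, x.condition_names, np.log(x.values))


def _orthonormal_completion(G: np.ndarray, n_missing: int) -> np.ndarray:
    """Deterministic orthonormal columns spanning part of the complement of G."""
    m = G.shape[0]
    cols = []
    k = 0
    basis = G
    while len(cols) < n_missing and k < m:
        e = np.zeros(m)
        e[k] = 1.0
        k += 1
        r = e - basis @ (basis.T @ e)
        for c in cols:
            r -= c * (c @ r)
        norm = np.linalg.norm(r)
        if norm > 1e-8:
            cols.append(r / norm)
    if len(cols) < n_missing:  # pragma: no cover - m >= t guarantees success
        raise DecompositionError("could not complete orthonormal basis")
    return np.column_stack(cols)


def _apply_sign_convention(G: np.ndarray, lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix the per-pattern sign ambiguity of the SVD deterministically.

    Pattern 0: flip so the gene weights sum negative — the steady-state
    convention under which the most stable transcripts have the lowest
    G_i0 while G_i0 * lam_0(T) still reproduces the (positive) log
    expression.  Patterns >= 1: flip so the Lagrange-multiplier entry of
    largest magnitude is positive, ties broken toward the earliest
    condition.
    """
    G = G.copy()
    lam = lam.copy()
    t = G.shape[1]
    for alpha in range(t):
        if alpha == 0:
            s = np.sum(G[:, 0])
            if s > 0:
                flip = True
            elif s < 0:
                flip = False
            else:  # degenerate zero-sum column: fall back to the lam rule
                flip = _lam_says_flip(lam[0])
        else:
            flip = _lam_says_flip(lam[alpha])
        if flip:
            G[:, alpha] = -G[:, alpha]
            lam[alpha] = -lam[alpha]
    return G, lam


def _lam_says_flip(lam_row: np.ndarray) -> bool:
    a = np.abs(lam_row)
    if np.all(a == 0):
        return False
    # earliest condition wins magnitude ties
    idx = int(np.flatnonzero(a == a.max())[0])
    return lam_row[idx] < 0


def decompose(
    y: LogExpressionMatrix,
    method: Literal["full_svd", "small_matrix"] = "small_matrix",
) -> SurprisalDecomposition:
    """Fit the surprisal decomposition of a log-expression matrix.

    Parameters
    ----------
    y
        m x t log-expression matrix with m >= t.
    method
        ``"full_svd"`` factorizes the rectangular matrix directly;
        ``"small_matrix"`` eigendecomposes the t x t Gram matrix and
        back-projects (the route of choice when m is tens of thousands).
        Both agree to ~1e-8 after the sign convention.
    """
    Y = y.values
    m, t = Y.shape
    if t > m:
        raise DecompositionError(
            f"matrix has more conditions ({t}) than genes ({m}); "
            "transpose the input so genes run along rows"
        )
    if method == "full_svd":
        U, s, Vt = np.linalg.svd(Y, full_matrices=False)
        G = U
        omega = s
        lam = s[:, None] * Vt
    elif method == "small_matrix":
        gram = Y.T @ Y  # t x t; rank at most t
        evals, evecs = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # squaring doubles the condition number: eigenvalues at the numerical
        # noise floor of the Gram matrix are true zeros, so report them as such
        if evals[0] > 0:
            evals[evals < 64 * np.finfo(float).eps * evals[0]] = 0.0
        omega = np.sqrt(evals)
        tol = RANK_TOL * omega[0] if omega[0] > 0 else 0.0
        G = np.zeros((m, t))
        nonzero = omega > tol
        if np.any(nonzero):
            G[:, nonzero] = (Y @ evecs[:, nonzero]) / omega[nonzero]
        n_zero = int(np.sum(~nonzero))
        if n_zero:
            # zero singular values: fill G with an orthonormal completion so
            # the invariant G.T @ G = I holds; the patterns carry zero weight
            G[:, ~nonzero] = _orthonormal_completion(G[:, nonzero], n_zero)
        lam = omega[:, None] * evecs.T
    else:
        raise ValueError(f"unknown method {method!r}")

    # exactly tied singular values span a non-identifiable subspace; order
    # the tied patterns by the first condition's multiplier for determinism
    order = np.lexsort((-lam[:, 0], -omega))
    G, lam, omega = G[:, order], lam[order], omega[order]

    G, lam = _apply_sign_convention(G, lam)
    return SurprisalDecomposition(
        gene_names=y.gene_names,
        condition_names=y.condition_names,
        G=G,
        lam=lam,
        omega=omega,
    )


def reconstruct(d: SurprisalDecomposition, k: int) -> LogExpressionMatrix:
    """Partial reconstruction ``sum_{alpha < k} G[:, alpha] lam[alpha, :]``.

    With ``k`` equal to the number of conditions this reproduces the
    decomposed log matrix to machine precision; ``k = 1`` is the
    steady-state-only prediction.
    """
    if not 1 <= k <= d.n_patterns:
        raise DecompositionError(f"k={k} out of range 1..{d.n_patterns}")
    values = d.G[:, :k] @ d.lam[:k, :]
    return LogExpressionMatrix(d.gene_names, d.condition_names, values)


def steady_state_residual(d: SurprisalDecomposition) -> np.ndarray:
    """Per-gene deviation of the log expression from its steady-state term.

    For each gene the maximum over conditions of
    ``|ln X_i(T) - G_i0 lam_0(T)|`` — the log-fold-change magnitude left
    unexplained by the balanced state.  Stable transcripts, whose
    expression is well reproduced by the steady-state term alone, have
    small residuals; transcripts driving the transformation have large
    ones.
    """
    deviation = d.G[:, 1:] @ d.lam[1:, :]
    return np.max(np.abs(deviation), axis=1)
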