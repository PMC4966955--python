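"""EOF engine: delay embedding, SVD decomposition and truncated reconstruction.

An empirical-orthogonal-function (EOF) analysis factors a mean-removed
space-time matrix ``A`` (P pixels x N steps) by singular value
decomposition, ``A = Z S Hᵀ``: the columns of ``Z`` are the spatial
patterns (EOFs), the columns of ``H`` the associated temporal principal
components, and the squared singular values the variance carried by each
mode.

To let the decomposition see temporal lag structure, the series of every
pixel can first be *delay embedded*: arranged into a Hankel block of ``W``
overlapping lagged copies (the multichannel-SSA construction). The per-pixel
blocks are stacked vertically into a ``(P·W) x (N-W+1)`` matrix; ``W = 1``
reduces to the plain EOF analysis. De-embedding averages the Hankel
anti-diagonals, which is exact on consistent Hankel matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import NumericError, ParameterError, ValidationError
from .field import SpaceTimeField

__all__ = [
    "DelayEmbeddedMatrix",
    "EOFDecomposition",
    "delay_embed",
    "de_embed",
    "svd_decompose",
    "select_components",
    "reconstruct",
]

MatrixLike = Union[np.ndarray, "DelayEmbeddedMatrix", SpaceTimeField]


@dataclass
class DelayEmbeddedMatrix:
    """A vertically stacked Hankel embedding of a ``P x N`` matrix.

    ``data`` has shape ``(P·W, N-W+1)``; rows ``p·W .. p·W+W-1`` are the
    Hankel block of pixel ``p``, with entry ``(lag w, col j)`` equal to the
    source series at time ``j + w``.
    """

    data: np.ndarray
    W: int
    P: int
    N: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = (self.P * self.W, self.N - self.W + 1)
        if self.data.shape != expected:
            raise ValidationError(
                f"embedded data shape {self.data.shape} inconsistent with "
                f"metadata (P={self.P}, N={self.N}, W={self.W}): expected {expected}"
            )


@dataclass
class EOFDecomposition:
    """SVD of a mean-removed matrix: ``X - mean = Z diag(S) Hᵀ``.

    ``Z``: left singular vectors (spatial/lag modes, columns orthonormal);
    ``S``: singular values, descending; ``H``: right singular vectors
    (temporal PCs, columns orthonormal); ``mean_row``: per-row mean removed
    before decomposition; ``variance_fraction``: per-mode share of total
    variance (squared singular values normalised to sum 1).
    """

    Z: np.ndarray
    S: np.ndarray
    H: np.ndarray
    mean_row: np.ndarray
    variance_fraction: np.ndarray

    @property
    def rank(self) -> int:
        """Numerical rank: singular values above 1e-10 of the largest."""
        if self.S.size == 0 or self.S[0] == 0.0:
            return 0
        return int(np.sum(self.S > 1e-10 * self.S[0]))

    @property
    def n_modes(self) -> int:
        return self.S.size


def _as_matrix(matrix: MatrixLike) -> np.ndarray:
    if isinstance(matrix, DelayEmbeddedMatrix):
        return matrix.data
    if isinstance(matrix, SpaceTimeField):
        if not matrix.is_gap_free:
            raise ValidationError(
                "field has masked entries; gap-fill before decomposition"
            )
        return matrix.values
    return np.asarray(matrix, dtype=np.float64)


def delay_embed(field: SpaceTimeField | np.ndarray, W: int) -> DelayEmbeddedMatrix:
    """Delay-embed each pixel series with window ``W`` and stack vertically.

    ``W = 1`` returns the source ``P x N`` matrix unchanged (no temporal
    information used). Requires a gap-free field for ``W > 1``.
    """
    if isinstance(field, SpaceTimeField):
        if W > 1 and not field.is_gap_free:
            raise ValidationError(
                "cannot delay-embed a field with masked entries; "
                "gap-fill first (or use W=1)"
            )
        values = field.values
    else:
        values = np.asarray(field, dtype=np.float64)
        if values.ndim != 2:
            raise ParameterError("expected a 2-D (P, N) array")
    P, N = values.shape
    if not (1 <= W <= N):
        raise ParameterError(f"window W={W} outside [1, N={N}]")
    # windows[p, j, w] = values[p, j + w]  ->  blocks (P, W, N-W+1)
    windows = sliding_window_view(values, W, axis=1)
    blocks = windows.transpose(0, 2, 1)
    data = blocks.reshape(P * W, N - W + 1).copy()
    return DelayEmbeddedMatrix(data=data, W=W, P=P, N=N)


def de_embed(matrix: DelayEmbeddedMatrix) -> np.ndarray:
    """Invert the delay embedding by Hankel anti-diagonal averaging.

    For each pixel and time ``t`` the result is the mean of all embedded
    entries representing ``t`` (between 1 and ``W`` of them). Exact inverse
    of :func:`delay_embed` on consistent Hankel matrices; the averaging also
    makes it the natural projection back to field space after a truncated
    reconstruction, where anti-diagonals need no longer agree.
    """
    W, P, N = matrix.W, matrix.P, matrix.N
    M = N - W + 1
    blocks = matrix.data.reshape(P, W, M)
    acc = np.zeros((P, N))
    counts = np.zeros(N)
    for w in range(W):
        acc[:, w:w + M] += blocks[:, w, :]
        counts[w:w + M] += 1.0
    return acc / counts


def svd_decompose(matrix: MatrixLike) -> EOFDecomposition:
    """Decompose a matrix by SVD after per-row mean removal.

    Row means (per pixel, or per pixel-lag row of an embedded matrix) carry
    the local climatology and are restored on reconstruction. Mode signs are
    normalised so each mode's largest-magnitude spatial loading is positive,
    making the factorisation deterministic.
    """
    X = _as_matrix(matrix)
    if not np.all(np.isfinite(X)):
        raise NumericError("matrix contains non-finite entries")
    mean_row = X.mean(axis=1)
    C = X - mean_row[:, None]
    Z, S, Ht = np.linalg.svd(C, full_matrices=False)
    H = Ht.T
    # deterministic sign: leading-magnitude loading of each mode non-negative
    lead = np.argmax(np.abs(Z), axis=0)
    signs = np.sign(Z[lead, np.arange(Z.shape[1])])
    signs[signs == 0] = 1.0
    Z = Z * signs
    H = H * signs
    total = float(np.sum(S**2))
    if total > 0.0:
        variance_fraction = S**2 / total
    else:
        variance_fraction = np.zeros_like(S)
    return EOFDecomposition(Z=Z, S=S, H=H, mean_row=mean_row,
                            variance_fraction=variance_fraction)


def select_components(decomp: EOFDecomposition, cumulative_threshold: float) -> int:
    """Smallest mode count whose cumulative variance fraction meets the threshold.

    ``cumulative_threshold`` must lie in (0, 1]; a threshold of 1.0 returns
    the numerical rank.
    """
    if not (0.0 < cumulative_threshold <= 1.0):
        raise ParameterError(
            f"cumulative_threshold must be in (0, 1], got {cumulative_threshold}"
        )
    cum = np.cumsum(decomp.variance_fraction)
    # small slack absorbs float rounding at thresholds like 1.0
    k = int(np.searchsorted(cum, cumulative_threshold - 1e-12) + 1)
    return min(k, max(decomp.rank, 1))


def reconstruct(decomp: EOFDecomposition,
                component_indices: Iterable[int] | Sequence[int],
                include_mean: bool = True) -> np.ndarray:
    """Sum of the given modes, ``Σ_k S_k Z_k H_kᵀ``, plus the removed mean.

    Component indices are 0-based. An empty index set returns the mean
    field alone (or zeros with ``include_mean=False``).
    """
    idx = np.asarray(sorted(set(int(i) for i in component_indices)), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= decomp.n_modes):
        raise ParameterError(
            f"component indices {idx.tolist()} outside [0, {decomp.n_modes})"
        )
    out = np.zeros((decomp.Z.shape[0], decomp.H.shape[0]))
    if idx.size:
        out += (decomp.Z[:, idx] * decomp.S[idx]) @ decomp.H[:, idx].T
    if include_mean:
        out += decomp.mean_row[:, None]
    return out
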