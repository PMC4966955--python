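"""DINEOF-style iterative gap filling of a space-time field.

Missing entries are initialised at the removed-mean baseline (equivalently,
zero after mean subtraction) and then updated by alternating a truncated
``k``-mode SVD reconstruction of the mean-removed matrix with a refresh of
the missing entries, until the RMS change on the missing set falls below a
tolerance. Observed entries are never touched. The subtracted row mean is
recomputed every iteration from the current completed matrix, since a mean
over a gappy matrix is otherwise ill-defined.

Gap filling operates on the plain ``P x N`` matrix (no delay embedding):
embedding a gappy series would smear every gap across ``W`` columns, so
filling happens first and embedding downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ParameterError, ValidationError
from .field import SpaceTimeField

__all__ = ["GapfillResult", "gapfill", "choose_k_crossval", "KSelection"]


@dataclass
class GapfillResult:
    """Outcome of the iterative reconstruction.

    ``filled`` is gap-free (all-false mask); ``convergence_trace`` holds the
    RMS change (W/m²) on the missing set at each iteration.
    """

    filled: SpaceTimeField
    n_iterations: int
    convergence_trace: np.ndarray
    k_used: int


def _check_coverage(mask: np.ndarray) -> None:
    empty_rows = np.flatnonzero(mask.all(axis=1))
    if empty_rows.size:
        raise ValidationError(
            f"pixel row(s) {empty_rows[:5].tolist()} have no observed entries"
        )
    empty_cols = np.flatnonzero(mask.all(axis=0))
    if empty_cols.size:
        raise ValidationError(
            f"time column(s) {empty_cols[:5].tolist()} have no observed entries"
        )


def gapfill(field: SpaceTimeField, k: int, tol: float = 0.01,
            max_iter: int = 500) -> GapfillResult:
    """Fill missing entries with the converged ``k``-mode EOF reconstruction.

    Parameters
    ----------
    field
        Input stack; every pixel row and time column must have at least one
        observed entry.
    k
        Number of leading modes used in the truncated reconstruction,
        ``1 <= k <= min(P, N)``.
    tol
        Stop when the RMS change (W/m²) of the filled entries between
        successive iterations drops to ``tol`` (default 0.01 W/m²).
    max_iter
        Iteration cap (default 500).

    Observed entries of the output are bit-identical to the input.
    """
    P, N = field.values.shape
    if not (1 <= k <= min(P, N)):
        raise ParameterError(f"k={k} outside [1, min(P, N)={min(P, N)}]")
    mask = field.mask
    if not mask.any():
        return GapfillResult(
            filled=field.copy(), n_iterations=1,
            convergence_trace=np.array([0.0]), k_used=k,
        )
    _check_coverage(mask)

    X = field.values.copy()
    # initialise missing entries at the observed per-pixel mean: zero after
    # mean subtraction, matching the zero-start of the reference iteration
    obs_mean = np.where(mask, 0.0, X).sum(axis=1) / (~mask).sum(axis=1)
    X[mask] = np.broadcast_to(obs_mean[:, None], X.shape)[mask]

    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = X.mean(axis=1)
        C = X - mu[:, None]
        Z, S, Ht = np.linalg.svd(C, full_matrices=False)
        recon = (Z[:, :k] * S[:k]) @ Ht[:k] + mu[:, None]
        delta = float(np.sqrt(np.mean((recon[mask] - X[mask]) ** 2)))
        X[mask] = recon[mask]
        trace.append(delta)
        if delta <= tol:
            break
    trace_arr = np.asarray(trace)
    if trace_arr.size > 2 and np.any(np.diff(trace_arr[1:]) > 1e-9):
        warnings.warn("gapfill convergence trace not monotone", RuntimeWarning,
                      stacklevel=2)
    filled = field.with_values(X, mask=np.zeros_like(mask))
    return GapfillResult(filled=filled, n_iterations=n_iter,
                         convergence_trace=trace_arr, k_used=k)


class KSelection(NamedTuple):
    """Cross-validated mode count and the held-out RMS curve behind it."""

    k: int
    heldout_rms: np.ndarray  # indexed k-1 for k = 1..k_max


def choose_k_crossval(field: SpaceTimeField, holdout_fraction: float,
                      k_max: int, seed: int, tol: float = 0.01,
                      max_iter: int = 500) -> KSelection:
    """Pick the mode count minimising held-out RMS error.

    A random ``holdout_fraction`` of the observed entries is hidden, the
    field is gap-filled for each ``k`` in ``1..k_max``, and the ``k`` with
    the lowest RMS error on the hidden entries wins. Deterministic given
    ``seed``.
    """
    obs = ~field.mask
    n_obs = int(obs.sum())
    obs_fraction = n_obs / field.mask.size
    if not (0.0 < holdout_fraction < obs_fraction):
        raise ParameterError(
            f"holdout_fraction={holdout_fraction} must be in (0, observed "
            f"fraction={obs_fraction:.3f})"
        )
    if k_max < 1:
        raise ParameterError("k_max must be >= 1")
    rng = np.random.default_rng(seed)
    flat_obs = np.flatnonzero(obs.ravel())
    n_hold = max(1, int(round(holdout_fraction * field.mask.size)))
    held = rng.choice(flat_obs, size=min(n_hold, n_obs - 1), replace=False)
    trial_mask = field.mask.copy()
    trial_mask.ravel()[held] = True
    trial = field.with_values(field.values.copy(), mask=trial_mask)
    truth_held = field.values.ravel()[held]

    rms = np.empty(k_max)
    for k in range(1, k_max + 1):
        result = gapfill(trial, k=k, tol=tol, max_iter=max_iter)
        pred_held = result.filled.values.ravel()[held]
        rms[k - 1] = np.sqrt(np.mean((pred_held - truth_held) ** 2))
    return KSelection(k=int(np.argmin(rms) + 1), heldout_rms=rms)
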