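"""EOF component-mixing fusion of two LE products, plus the simple-average baseline.

The fusion merges a primary product A (trusted for its dominant space-time
patterns) with a secondary product B (contributing complementary minor
patterns). Per spatial tile:

1. both products are gap-filled;
2. each is delay-embedded with window ``W`` and decomposed by SVD;
3. A keeps its leading modes up to a cumulative-variance threshold
   ``tau_primary`` (default 0.80) — ``k_a`` modes;
4. from B, modes are taken starting at position ``k_a + 1`` until they sum
   to a variance share ``tau_secondary`` (default 0.20) of B's spectrum,
   capped at ``k_secondary_cap`` modes;
5. the fused matrix is A's truncated reconstruction plus B's selected
   components *without* B's mean (A's mean already carries the
   climatology);
6. the result is de-embedded back to field space;
7. negative cells — a known artifact of truncated reconstruction in the
   low-flux season — are replaced by the secondary product's main-pattern
   reconstruction (and clamped to zero if that is negative too).

The mixing happens in reconstructed field space: principal components of
two different decompositions live in different bases and cannot be spliced
as coefficient matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .eof import de_embed, delay_embed, reconstruct, select_components, svd_decompose
from .errors import ParameterError, ValidationError
from .field import SpaceTimeField
from .gapfill import gapfill
from .tiling import extract_tile, insert_tile, make_layout

__all__ = [
    "FusionConfig",
    "eof_fuse",
    "replace_negatives",
    "simple_average",
    "ReplacementStats",
]


@dataclass
class FusionConfig:
    """Tunable parameters of the EOF fusion.

    Defaults follow the reference configuration: window ``W = 4``, 80% of
    the variance from the primary product, a 20% variance share from the
    secondary capped at 12 modes, and 200 x 200-pixel tiles.
    """

    W: int = 4
    tau_primary: float = 0.80
    tau_secondary: float = 0.20
    k_secondary_cap: int = 12
    tile_rows: int = 200
    tile_cols: int = 200
    gapfill_k: int | None = None  # None: pick by tau_primary on the initial fill
    gapfill_tol: float = 0.01
    gapfill_max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.W < 1:
            raise ParameterError(f"W must be >= 1, got {self.W}")
        if not (0.0 < self.tau_primary <= 1.0):
            raise ParameterError(f"tau_primary must be in (0, 1], got {self.tau_primary}")
        if not (0.0 <= self.tau_secondary < 1.0):
            raise ParameterError(
                f"tau_secondary must be in [0, 1), got {self.tau_secondary}"
            )
        if self.k_secondary_cap < 0:
            raise ParameterError("k_secondary_cap must be >= 0")


class ReplacementStats(NamedTuple):
    """Diagnostics of the negative-value replacement."""

    replaced: int         # negative fused cells replaced from the fallback
    double_negative: int  # cells where the fallback was negative too -> 0


class FusionResult(NamedTuple):
    fused: SpaceTimeField
    replacement: ReplacementStats


def _ensure_filled(field: SpaceTimeField, config: FusionConfig) -> SpaceTimeField:
    if field.is_gap_free:
        return field
    if config.gapfill_k is not None:
        k = config.gapfill_k
    else:
        # provisional decomposition of the baseline-initialised matrix picks
        # enough modes to cover the primary variance threshold
        X = field.values.copy()
        obs = ~field.mask
        mu = np.where(field.mask, 0.0, X).sum(axis=1) / np.maximum(obs.sum(axis=1), 1)
        X[field.mask] = np.broadcast_to(mu[:, None], X.shape)[field.mask]
        k = select_components(svd_decompose(X), config.tau_primary)
        k = max(1, min(k, min(field.values.shape)))
    return gapfill(field, k=k, tol=config.gapfill_tol,
                   max_iter=config.gapfill_max_iter).filled


def _secondary_count(variance_fraction: np.ndarray, start: int,
                     tau: float, cap: int, rank: int) -> int:
    """Smallest run of modes from ``start`` summing to ``tau``, capped."""
    avail = max(0, min(rank, variance_fraction.size) - start)
    limit = min(cap, avail)
    if limit == 0 or tau == 0.0:
        return 0
    cum = np.cumsum(variance_fraction[start:start + limit])
    hit = np.searchsorted(cum, tau - 1e-12) + 1
    return int(min(hit, limit))


def _fuse_tile(tile_a: SpaceTimeField, tile_b: SpaceTimeField,
               config: FusionConfig) -> tuple[SpaceTimeField, ReplacementStats]:
    fa = _ensure_filled(tile_a, config)
    fb = _ensure_filled(tile_b, config)
    da = svd_decompose(delay_embed(fa, config.W))
    db = svd_decompose(delay_embed(fb, config.W))
    k_a = select_components(da, config.tau_primary)

    if k_a >= da.rank:
        warnings.warn(
            "primary product is full rank at the requested variance threshold; "
            "falling back to its truncated reconstruction",
            RuntimeWarning, stacklevel=3,
        )
        fused_emb = reconstruct(da, range(k_a))
    else:
        k_b = _secondary_count(db.variance_fraction, start=k_a,
                               tau=config.tau_secondary,
                               cap=config.k_secondary_cap, rank=db.rank)
        fused_emb = reconstruct(da, range(k_a)) + reconstruct(
            db, range(k_a, k_a + k_b), include_mean=False)

    emb_meta = delay_embed(fa, config.W)
    emb_meta.data = fused_emb
    fused_vals = de_embed(emb_meta)

    k_b_main = select_components(db, config.tau_primary)
    fb_emb = delay_embed(fb, config.W)
    fb_emb.data = reconstruct(db, range(k_b_main))
    fallback_vals = de_embed(fb_emb)

    fused_field = tile_a.with_values(fused_vals)
    fallback_field = tile_a.with_values(fallback_vals)
    return replace_negatives(fused_field, fallback_field)


def eof_fuse(product_a: SpaceTimeField, product_b: SpaceTimeField,
             config: FusionConfig | None = None) -> SpaceTimeField:
    """Fuse two co-registered LE products by EOF component mixing.

    Product A is the primary (its leading patterns and climatology are
    kept); product B contributes minor components. Both products may carry
    gaps, which are DINEOF-filled per tile before decomposition. The output
    is gap-free, non-negative, and deterministic given the config.
    """
    config = config or FusionConfig()
    if product_a.grid_shape != product_b.grid_shape:
        raise ValidationError(
            f"grids differ: {product_a.grid_shape} vs {product_b.grid_shape}"
        )
    if (product_a.n_times != product_b.n_times
            or not np.array_equal(product_a.times, product_b.times)):
        raise ValidationError("time axes differ between products")

    layout = make_layout(product_a.grid_shape, config.tile_rows, config.tile_cols)
    values_out = np.empty_like(product_a.values)
    mask_out = np.zeros_like(product_a.mask)
    for tile in layout.tiles:
        ta = extract_tile(product_a, tile)
        tb = extract_tile(product_b, tile)
        fused_tile, _stats = _fuse_tile(ta, tb, config)
        insert_tile(values_out, mask_out, product_a.grid_shape, tile, fused_tile)
    return product_a.with_values(values_out, mask=mask_out)


def replace_negatives(fused: SpaceTimeField,
                      fallback: SpaceTimeField) -> tuple[SpaceTimeField, ReplacementStats]:
    """Replace negative fused cells with the fallback's value.

    Cells where the fallback is negative too are set to zero and counted
    separately. Returns the repaired field and a :class:`ReplacementStats`.
    """
    if fused.values.shape != fallback.values.shape:
        raise ValidationError(
            f"shape mismatch: {fused.values.shape} vs {fallback.values.shape}"
        )
    neg = fused.values < 0.0
    out = np.where(neg, fallback.values, fused.values)
    double = neg & (fallback.values < 0.0)
    out = np.where(double, 0.0, out)
    stats = ReplacementStats(replaced=int(neg.sum()),
                             double_negative=int(double.sum()))
    return fused.with_values(out, mask=fused.mask.copy()), stats


def simple_average(product_a: SpaceTimeField, product_b: SpaceTimeField,
                   weight: float = 0.5) -> SpaceTimeField:
    """Constant-weight average baseline: ``weight·A + (1-weight)·B``.

    Cells missing in one product take the other product's value; cells
    missing in both stay missing.
    """
    if not (0.0 <= weight <= 1.0):
        raise ParameterError(f"weight must be in [0, 1], got {weight}")
    if product_a.grid_shape != product_b.grid_shape:
        raise ValidationError("grids differ")
    if not np.array_equal(product_a.times, product_b.times):
        raise ValidationError("time axes differ")
    a, b = product_a.values, product_b.values
    ma, mb = product_a.mask, product_b.mask
    out = weight * a + (1.0 - weight) * b
    out = np.where(ma & ~mb, b, out)
    out = np.where(mb & ~ma, a, out)
    both = ma & mb
    out = np.where(both, 0.0, out)
    return product_a.with_values(out, mask=both)
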