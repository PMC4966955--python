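"""Synthetic truth fields, product pairs and tower records.

Every other module is testable without downloads: this module emulates the
statistical structure of a one-year, 8-day-composite LE record and of the
two satellite products being fused.

*Truth* is a low-rank separable field: ``rank`` smooth spatial patterns
(a broad meridional gradient plus Gaussian-filtered random surfaces) times
seasonal harmonics (1, 2, 3 … cycles per year), shifted to be
non-negative. The default amplitudes give the leading mode just over half
of the variance, so an 80% cumulative-variance cut retains the seasonal
modes and discards noise.

*Products* corrupt the truth with a gain, an additive bias, noise that is
either white or confined to the truth's trailing EOF modes
("mode-aligned", mimicking structured retrieval error), and random gaps.
Both default products are biased high against ground truth, the secondary
less so than the primary — the qualitative error structure reported for
PT-JPL-like and MOD16-like products: the primary is noisier but its
dominant seasonal patterns are robust; the secondary is cleaner but gappy
with structured error.

*Towers* impose an energy-balance closure deficit: the turbulent fluxes
are scaled down so that ``H_ori + LE_ori = (1 - deficit)·(Rn - G)`` while
the Bowen ratio is fixed, making the closure correction recover the truth
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ParameterError
from .field import SpaceTimeField
from .towers import TowerRecord

__all__ = [
    "ProductSpec",
    "SyntheticConfig",
    "generate_truth",
    "derive_product",
    "generate_towers",
    "default_benchmark",
]

_BIOME_CYCLE = ("CRO", "GRA", "DBF", "EBF", "ENF", "MF", "SAW", "SHR")


@dataclass(frozen=True)
class ProductSpec:
    """Error model of one derived product: ``gain·truth + bias + noise``, then gaps."""

    gain: float = 1.0
    bias: float = 0.0          # W/m²
    noise_sd: float = 0.0      # W/m²
    gap_fraction: float = 0.0
    noise_mode: str = "white"  # "white" | "mode_aligned"

    def __post_init__(self) -> None:
        if not (0.0 <= self.gap_fraction <= 0.9):
            raise ParameterError(f"gap_fraction must be in [0, 0.9], got {self.gap_fraction}")
        if self.noise_sd < 0.0:
            raise ParameterError("noise_sd must be >= 0")
        if self.noise_mode not in ("white", "mode_aligned"):
            raise ParameterError(f"unknown noise_mode {self.noise_mode!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    One year of 8-day composites (46 steps) on a 40 x 40 grid, truth rank
    3 with mode amplitudes 26/16/13 W/m² RMS and a 70 W/m² base level —
    a seasonal LE field spanning roughly 0–150 W/m². Product A emulates a
    continuous primary with white retrieval noise (sd 10, bias +5);
    product B a secondary of comparable overall quality but structured,
    truth-orthogonal error and gaps (mode-aligned noise sd 9, bias +2,
    10% missing). Both products are biased high, the secondary less so,
    and their total errors are of similar size with the secondary slightly
    better.
    """

    grid_shape: tuple[int, int] = (40, 40)
    n_times: int = 46
    rank: int = 3
    mode_amplitudes: tuple[float, ...] = (26.0, 16.0, 13.0)
    base_level: float = 70.0
    min_level: float = 2.0
    product_a: ProductSpec = ProductSpec(gain=1.0, bias=5.0, noise_sd=10.0,
                                         gap_fraction=0.0, noise_mode="white")
    product_b: ProductSpec = ProductSpec(gain=1.0, bias=2.0, noise_sd=9.0,
                                         gap_fraction=0.10,
                                         noise_mode="mode_aligned")
    closure_deficit: float = 0.2
    bowen_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ParameterError("rank must be >= 1")
        if self.n_times < 2:
            raise ParameterError("n_times must be >= 2")
        if not (0.0 <= self.closure_deficit < 1.0):
            raise ParameterError("closure_deficit must be in [0, 1)")

    def amplitudes(self) -> np.ndarray:
        """Per-mode RMS amplitudes, extended geometrically beyond the defaults."""
        amps = list(self.mode_amplitudes)
        while len(amps) < self.rank:
            amps.append(amps[-1] * 0.7)
        return np.asarray(amps[: self.rank], dtype=np.float64)


def _times(config: SyntheticConfig) -> np.ndarray:
    start = np.datetime64("2005-01-01")
    return start + 8 * np.arange(config.n_times, dtype=np.int64).astype("timedelta64[D]")


def _spatial_modes(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """``(P, rank)`` orthonormal-column smooth spatial patterns, RMS-1 scaled."""
    rows, cols = config.grid_shape
    P = rows * cols
    modes = np.empty((P, config.rank))
    # leading mode: meridional gradient with a moist "hot spot"
    rr, cc = np.meshgrid(np.linspace(-1, 1, rows), np.linspace(-1, 1, cols),
                         indexing="ij")
    r0, c0 = rng.uniform(-0.5, 0.5, size=2)
    bump = np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / 0.3))
    modes[:, 0] = (1.0 - 0.6 * rr + 0.8 * bump).ravel()
    sigma = max(min(rows, cols) / 8.0, 1.0)
    for p in range(1, config.rank):
        surf = gaussian_filter(rng.standard_normal((rows, cols)), sigma=sigma)
        modes[:, p] = surf.ravel()
    # orthonormalise (QR) so the modes are exactly independent, then RMS-1 scale
    q, _ = np.linalg.qr(modes)
    return q * np.sqrt(P)


def _temporal_modes(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """``(N, rank)`` seasonal harmonics at 1, 2, 3… cycles/year, RMS-1 scaled."""
    n = config.n_times
    frac_year = (8.0 * np.arange(n)) / 365.0
    modes = np.empty((n, config.rank))
    for p in range(config.rank):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        modes[:, p] = np.cos(2.0 * np.pi * (p + 1) * frac_year + phase)
    return modes / np.sqrt(np.mean(modes**2, axis=0))


def generate_truth(config: SyntheticConfig) -> SpaceTimeField:
    """Generate the low-rank seasonal truth field (non-negative, rank exact)."""
    rng = np.random.default_rng(config.seed)
    spatial = _spatial_modes(config, rng)
    temporal = _temporal_modes(config, rng)
    amps = config.amplitudes()
    values = config.base_level + (spatial * amps) @ temporal.T
    lo = values.min()
    if lo < config.min_level:
        values = values - lo + config.min_level
    P, N = values.shape
    return SpaceTimeField(
        values=values, mask=np.zeros((P, N), dtype=bool),
        grid_shape=config.grid_shape, times=_times(config),
    )


def derive_product(truth: SpaceTimeField, spec: ProductSpec,
                   seed: int) -> SpaceTimeField:
    """Corrupt the truth with the product's gain/bias/noise/gap model."""
    rng = np.random.default_rng(seed)
    P, N = truth.values.shape
    values = spec.gain * truth.values + spec.bias
    if spec.noise_sd > 0.0:
        noise = rng.standard_normal((P, N))
        if spec.noise_mode == "mode_aligned":
            # confine noise to the orthogonal complement of the truth's
            # leading spatial modes (structured, truth-orthogonal error)
            centered = truth.values - truth.values.mean(axis=1, keepdims=True)
            U, s, _ = np.linalg.svd(centered, full_matrices=False)
            r = int(np.sum(s > 1e-10 * s[0])) if s.size else 0
            if r:
                noise -= U[:, :r] @ (U[:, :r].T @ noise)
        noise *= spec.noise_sd / np.sqrt(np.mean(noise**2))
        values = values + noise
    mask = rng.random((P, N)) < spec.gap_fraction
    # keep the gap-fill precondition: no fully missing pixel or time step
    full_rows = np.flatnonzero(mask.all(axis=1))
    mask[full_rows, rng.integers(0, N, size=full_rows.size)] = False
    full_cols = np.flatnonzero(mask.all(axis=0))
    mask[rng.integers(0, P, size=full_cols.size), full_cols] = False
    return truth.with_values(values, mask=mask)


def generate_towers(truth: SpaceTimeField,
                    pixel_locations: Sequence[tuple[int, int]],
                    closure_deficit: float = 0.2,
                    bowen_ratio: float = 0.5,
                    seed: int = 0) -> list[TowerRecord]:
    """Build tower records whose closure correction recovers the truth exactly.

    At each ``(row, col)`` location the true LE is read off the truth
    field; ``H_ori = bowen_ratio · LE_ori``; available energy is set so
    that the turbulent fluxes under-close it by ``closure_deficit``:
    ``H_ori + LE_ori = (1 - closure_deficit)·(Rn - G)``.
    """
    if not (0.0 <= closure_deficit < 1.0):
        raise ParameterError(f"closure_deficit must be in [0, 1), got {closure_deficit}")
    rng = np.random.default_rng(seed)
    rows, cols = truth.grid_shape
    records: list[TowerRecord] = []
    for i, (r, c) in enumerate(pixel_locations):
        if not (0 <= r < rows and 0 <= c < cols):
            raise ParameterError(f"pixel location ({r}, {c}) outside grid {truth.grid_shape}")
        biome = _BIOME_CYCLE[i % len(_BIOME_CYCLE)]
        lat = 60.0 - 0.01 * r + rng.normal(0, 1e-3)
        lon = -100.0 + 0.01 * c + rng.normal(0, 1e-3)
        p = r * cols + c
        for t in range(truth.n_times):
            le_true = float(truth.values[p, t])
            le_ori = (1.0 - closure_deficit) * le_true
            h_ori = bowen_ratio * le_ori
            available = le_true * (1.0 + bowen_ratio)  # = (H+LE)/(1-deficit)
            rn = available / 0.9                        # G fixed at 10% of Rn
            g = 0.1 * rn
            records.append(TowerRecord(
                time=truth.times[t], Rn=rn, G=g, H_ori=h_ori, LE_ori=le_ori,
                biome=biome, lat=lat, lon=lon, row=r, col=c,
            ))
    return records


def default_benchmark(config: SyntheticConfig | None = None,
                      seed: int | None = None):
    """Truth and both default products under one seed; the standard testbed.

    Returns ``(truth, product_a, product_b)``. Per-stage seeds are split
    deterministically from the configured seed.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    base = np.random.SeedSequence(config.seed).spawn(3)
    truth = generate_truth(replace(config, seed=int(base[0].generate_state(1)[0] % (2**31))))
    product_a = derive_product(truth, config.product_a,
                               seed=int(base[1].generate_state(1)[0] % (2**31)))
    product_b = derive_product(truth, config.product_b,
                               seed=int(base[2].generate_state(1)[0] % (2**31)))
    return truth, product_a, product_b
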