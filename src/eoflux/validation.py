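"""Tower-based validation: closure correction, 8-day compositing, metrics.

Eddy-covariance towers rarely close the surface energy budget:
``H_ori + LE_ori < Rn - G``. The Bowen-ratio-preserving correction scales
both turbulent fluxes by the closure factor,

    LE = (Rn - G) / (LE_ori + H_ori) * LE_ori,

which restores ``H + LE = Rn - G`` exactly while keeping ``H/LE``
unchanged. Corrected tower LE is then composited to 8-day means and
compared with predictions through R² (squared Pearson correlation),
bias (mean predicted - observed) and RMSE, pooled and per biome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    UndefinedCorrectionError,
    ValidationError,
)
from .towers import TowerRecord

__all__ = [
    "MetricReport",
    "closure_correct",
    "closure_correct_records",
    "composite_8day",
    "compute_metrics",
    "group_metrics",
    "metrics_to_csv",
]


@dataclass
class MetricReport:
    """Validation statistics for one group of prediction/observation pairs."""

    group: str
    n: int
    r_squared: float
    bias: float  # W/m², mean(predicted - observed)
    rmse: float  # W/m²


def closure_correct(record: TowerRecord) -> float:
    """Closure-corrected latent heat flux (W/m²) for one tower record.

    Raises :class:`UndefinedCorrectionError` when ``H_ori + LE_ori == 0``
    (the record should be excluded, never silently zeroed) and
    :class:`ValidationError` on incomplete records.
    """
    if record.incomplete:
        raise ValidationError("cannot closure-correct an incomplete record")
    turbulent = record.LE_ori + record.H_ori
    if turbulent == 0.0:
        raise UndefinedCorrectionError(
            "H_ori + LE_ori is zero; closure factor undefined"
        )
    return (record.Rn - record.G) / turbulent * record.LE_ori


def closure_correct_records(records: Sequence[TowerRecord]) -> pd.DataFrame:
    """Correct a batch of records, excluding undefined/incomplete ones.

    Returns a DataFrame with columns ``time, biome, row, col, LE`` (the
    corrected flux); excluded records are simply absent.
    """
    rows = []
    for r in records:
        if r.incomplete or (r.LE_ori + r.H_ori) == 0.0:
            continue
        rows.append({"time": r.time, "biome": r.biome, "row": r.row,
                     "col": r.col, "LE": closure_correct(r)})
    return pd.DataFrame(rows, columns=["time", "biome", "row", "col", "LE"])


def composite_8day(series: np.ndarray, times: np.ndarray | None = None,
                   modis_calendar: bool = False) -> np.ndarray:
    """Average a daily series into consecutive non-overlapping 8-day blocks.

    Blocks anchor at the series start (the final block may be shorter);
    with ``modis_calendar=True`` and a datetime ``times`` axis they anchor
    at day-of-year 1, 9, 17, … instead, matching the MODIS compositing
    convention. Block means skip NaN; a fully missing block stays NaN.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or series.size == 0:
        raise ValidationError("series must be 1-D and non-empty")
    if modis_calendar:
        if times is None:
            raise ValidationError("modis_calendar compositing needs a time axis")
        doy = pd.DatetimeIndex(times).dayofyear.to_numpy()
        bins = (doy - 1) // 8
        # keep period order as encountered (handles a series crossing new year)
        _, first_idx, inv = np.unique(bins, return_index=True, return_inverse=True)
        order = np.argsort(first_idx)
        remap = np.empty_like(order)
        remap[order] = np.arange(order.size)
        bins = remap[inv]
    else:
        bins = np.arange(series.size) // 8
    n_blocks = bins.max() + 1
    out = np.full(n_blocks, np.nan)
    for b in range(n_blocks):
        vals = series[bins == b]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[b] = vals.mean()
    return out


def compute_metrics(predicted: np.ndarray, observed: np.ndarray,
                    group: str = "all") -> MetricReport:
    """R² (squared Pearson correlation), bias and RMSE of paired series.

    Pairs with a missing value on either side are excluded; fewer than two
    valid pairs raises :class:`InsufficientDataError`.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if predicted.shape != observed.shape:
        raise ValidationError(
            f"length mismatch: {predicted.shape} vs {observed.shape}"
        )
    ok = np.isfinite(predicted) & np.isfinite(observed)
    p, o = predicted[ok], observed[ok]
    if p.size < 2:
        raise InsufficientDataError(
            f"need >= 2 valid pairs for metrics, have {p.size}"
        )
    if np.ptp(p) == 0.0 or np.ptp(o) == 0.0:
        r2 = np.nan  # correlation undefined for a constant series
    else:
        r2 = float(stats.pearsonr(p, o).statistic ** 2)
    bias = float(np.mean(p - o))
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    return MetricReport(group=group, n=int(p.size), r_squared=r2,
                        bias=bias, rmse=rmse)


def group_metrics(predicted: np.ndarray, observed: np.ndarray,
                  biomes: Sequence[str]) -> list[MetricReport]:
    """Per-biome metric reports plus one pooled ``"all"`` report."""
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    biomes_arr = np.asarray(biomes)
    if not (predicted.shape == observed.shape == biomes_arr.shape):
        raise ValidationError("predicted, observed and biomes must align")
    reports = []
    for biome in sorted(set(biomes_arr.tolist())):
        sel = biomes_arr == biome
        reports.append(compute_metrics(predicted[sel], observed[sel], group=biome))
    reports.append(compute_metrics(predicted, observed, group="all"))
    return reports


def metrics_to_csv(reports: Sequence[MetricReport], path: str | Path) -> None:
    """Write metric reports as CSV (group, n, r_squared, bias, rmse)."""
    pd.DataFrame(
        [{"group": r.group, "n": r.n, "r_squared": r.r_squared,
          "bias": r.bias, "rmse": r.rmse} for r in reports]
    ).to_csv(path, index=False)
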