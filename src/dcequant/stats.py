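"""Histogram summaries and cross-modality / cross-timepoint agreement.

Conventions: sample SD (ddof=1); Fisher-Pearson skewness and excess
kurtosis, both bias-uncorrected (a normal sample gives 0 for each);
Bland-Altman limits of agreement reported as the half-width 1.96 * SD of
the paired differences; Pearson p-values are two-sided from the
t-distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .core import EmptyMaskError
from .kinetics import ParameterMaps

__all__ = [
    "HistogramSummary",
    "AgreementResult",
    "histogram_moments",
    "pearson",
    "bland_altman",
    "voxelwise_compare",
    "percent_change",
    "normalize_iauc",
    "interday_variance",
    "resample_to_grid",
]


@dataclass
class HistogramSummary:
    """Shape summary of one parameter's voxel histogram inside a mask."""

    parameter: str
    n_voxels: int
    median: float
    sd: float
    skewness: float
    kurtosis: float


@dataclass
class AgreementResult:
    """Pearson + Bland-Altman agreement between two paired samples."""

    r: float
    p_value: float
    bias: float
    loa: float           # 1.96 * SD of differences (half-width)
    n: int


def histogram_moments(
    values: np.ndarray, mask: np.ndarray | None = None, parameter: str = ""
) -> HistogramSummary:
    """Median, sample SD, skewness and excess kurtosis inside a mask."""
    values = np.asarray(values, dtype=float)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise EmptyMaskError("no finite voxels selected for histogram moments")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    if sd == 0.0:
        skew = kurt = 0.0  # degenerate (constant) sample
    else:
        skew = float(sps.skew(values, bias=True))
        kurt = float(sps.kurtosis(values, fisher=True, bias=True))
    return HistogramSummary(
        parameter=parameter,
        n_voxels=int(values.size),
        median=float(np.median(values)),
        sd=sd,
        skewness=skew,
        kurtosis=kurt,
    )


def pearson(x: np.ndarray, y: np.ndarray) -> AgreementResult:
    """Sample Pearson correlation with a two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return AgreementResult(
        r=float(res.statistic), p_value=float(res.pvalue),
        bias=float("nan"), loa=float("nan"), n=int(x.size),
    )


def bland_altman(x: np.ndarray, y: np.ndarray) -> AgreementResult:
    """Bias = mean(x - y); LoA = 1.96 * sample SD(x - y) (half-width)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = x - y
    return AgreementResult(
        r=float("nan"), p_value=float("nan"),
        bias=float(np.mean(d)), loa=float(1.96 * np.std(d, ddof=1)),
        n=int(x.size),
    )


def _agreement(x: np.ndarray, y: np.ndarray) -> AgreementResult:
    pr = pearson(x, y)
    ba = bland_altman(x, y)
    return AgreementResult(r=pr.r, p_value=pr.p_value, bias=ba.bias,
                           loa=ba.loa, n=pr.n)


# --------------------------------------------------------------------------
# Common-grid voxel-wise comparison
# --------------------------------------------------------------------------

def resample_to_grid(
    volume: np.ndarray, grid_shape: tuple[int, int, int], order: int = 1
) -> np.ndarray:
    """Resample a 3D volume to a target shape over the same field of view.

    ``order=1`` (linear) for parameter maps, ``order=0`` (nearest) for
    masks.  Voxel centres are aligned so a volume already on the target
    grid is returned unchanged.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape == tuple(grid_shape):
        return volume.copy()
    coords = np.meshgrid(
        *[
            (np.arange(g) + 0.5) * (s / g) - 0.5
            for g, s in zip(grid_shape, volume.shape)
        ],
        indexing="ij",
    )
    filled = np.nan_to_num(volume, nan=np.nan)  # keep NaN; map_coordinates spreads it
    out = ndimage.map_coordinates(filled, coords, order=order, mode="nearest")
    return out


def voxelwise_compare(
    maps_a: ParameterMaps,
    maps_b: ParameterMaps,
    mask: np.ndarray | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    parameters: tuple[str, ...] = ("ktrans", "kep", "ve", "vb", "iauc"),
) -> tuple[dict[str, AgreementResult], pd.DataFrame]:
    """Paired voxel-wise agreement between two parameter-map sets.

    Both map sets (and the mask) are resampled to a common grid — linear
    interpolation for maps, nearest-neighbour for the mask — and agreement
    is computed over paired voxels that are finite in both.  Returns per-
    parameter :class:`AgreementResult` plus the paired voxel table (for
    density/scatter export).
    """
    if grid_shape is None:
        grid_shape = maps_a.shape
    results: dict[str, AgreementResult] = {}
    if mask is not None:
        mask_g = resample_to_grid(
            np.asarray(mask, dtype=float), grid_shape, order=0
        ) > 0.5
    else:
        mask_g = np.ones(grid_shape, dtype=bool)

    resampled: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    common = mask_g.copy()
    for p in parameters:
        if p not in maps_a.maps or p not in maps_b.maps:
            continue
        a = resample_to_grid(maps_a.maps[p], grid_shape, order=1)
        b = resample_to_grid(maps_b.maps[p], grid_shape, order=1)
        ok = mask_g & np.isfinite(a) & np.isfinite(b)
        if not ok.any():
            raise EmptyMaskError(f"no paired finite voxels for {p!r}")
        resampled[p] = (a, b)
        results[p] = _agreement(a[ok], b[ok])
        common &= ok
    idx = np.argwhere(common)
    table = pd.DataFrame({"i": idx[:, 0], "j": idx[:, 1], "k": idx[:, 2]})
    for p, (a, b) in resampled.items():
        table[f"{p}_a"] = a[common]
        table[f"{p}_b"] = b[common]
    return results, table


# --------------------------------------------------------------------------
# Longitudinal summaries
# --------------------------------------------------------------------------

def percent_change(summary_t: HistogramSummary, summary_0: HistogramSummary) -> float:
    """Percent change of the median relative to baseline."""
    if summary_0.median == 0:
        raise ValueError("baseline median is zero; percent change undefined")
    return 100.0 * (summary_t.median - summary_0.median) / summary_0.median


def normalize_iauc(summary: HistogramSummary, dose: float) -> HistogramSummary:
    """Divide location/scale moments by the injected dose.

    Skewness and kurtosis are scale-invariant and unchanged.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    return replace(summary, median=summary.median / dose, sd=summary.sd / dose)


def interday_variance(values_per_day: list[np.ndarray]) -> dict:
    """One-way random-effects variance components across repeated days.

    Moment (ANOVA) estimators: the within-day component is the pooled
    within-group mean square; the between-day component is
    ``(MSB - MSW) / n0`` with ``n0`` the effective group size, truncated at
    zero (flagged) when the moment estimate is negative.
    """
    groups = [np.asarray(g, dtype=float) for g in values_per_day]
    if len(groups) < 2:
        raise ValueError("need at least two days")
    if any(g.size < 2 for g in groups):
        raise ValueError("need at least two observations per day")
    k = len(groups)
    ns = np.array([g.size for g in groups], dtype=float)
    n_tot = ns.sum()
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssw = sum(float(np.sum((g - m) ** 2)) for g, m in zip(groups, means))
    msw = ssw / (n_tot - k)
    msb = float(np.sum(ns * (means - grand) ** 2)) / (k - 1)
    n0 = (n_tot - float(np.sum(ns**2)) / n_tot) / (k - 1)
    between = (msb - msw) / n0
    truncated = between < 0
    return {
        "within_day_var": float(msw),
        "between_day_var": float(max(between, 0.0)),
        "truncated": bool(truncated),
    }
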