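"""Wall-shear-stress indices: TAWSS, OSI, RRT, and thrombus-prone areas.

Given the WSS vector time series over one cardiac cycle ``T``:

* ``TAWSS = (1/T) integral_0^T |WSS| dt`` - time-averaged magnitude, Pa;
* ``OSI = 1/2 (1 - |integral WSS dt| / integral |WSS| dt)`` - in [0, 1/2],
  0 for flow with a fixed direction, 1/2 when the cycle-averaged vector
  vanishes;
* ``RRT = 1 / ((1 - 2 OSI) TAWSS)`` - relative residence time, 1/Pa,
  infinite where OSI = 1/2.

Low TAWSS (< 0.4 Pa), high OSI (> 0.3) and high RRT (> 10 1/Pa) flag
thrombus-prone wall regions; the indices' area percentages above/below
those thresholds are the headline screening quantities.

Time integrals use the periodic rectangle rule by default (the samples are
a uniform grid over one period, on which it coincides with the periodic
trapezoid rule).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (OSI_HIGH_THRESHOLD, RRT_HIGH_THRESHOLD,
                        TAWSS_LOW_THRESHOLD)
from .core import SurfaceWSSField

__all__ = ["IndexMaps", "IndexSummary", "tawss", "osi", "rrt",
           "compute_maps", "threshold_percentages", "summarize"]


@dataclass(frozen=True)
class IndexMaps:
    """Per-element index maps. ``rrt`` is ``inf`` where OSI = 1/2 and NaN
    where the WSS magnitude vanishes identically (indices undefined)."""

    tawss: np.ndarray
    osi: np.ndarray
    rrt: np.ndarray


@dataclass(frozen=True)
class IndexSummary:
    """Area-weighted summary of the index maps plus threshold percentages."""

    tawss_ave: float
    tawss_min: float
    tawss_max: float
    osi_ave: float
    osi_min: float
    osi_max: float
    rrt_ave: float
    rrt_min: float
    rrt_max: float
    pct_tawss_low: float
    pct_osi_high: float
    pct_rrt_high: float


def _mean_abs_and_vec(field: SurfaceWSSField):
    mag = np.linalg.norm(field.wss, axis=2)          # (n, m)
    return mag.mean(axis=1), field.wss.mean(axis=1)  # rectangle rule / T


def tawss(field: SurfaceWSSField) -> np.ndarray:
    """Time-averaged WSS magnitude per element, Pa."""
    return _mean_abs_and_vec(field)[0]


def osi(field: SurfaceWSSField) -> np.ndarray:
    """Oscillatory shear index per element, in [0, 1/2].

    NaN where the magnitude integral vanishes (undefined, not 0.5).
    """
    mean_mag, mean_vec = _mean_abs_and_vec(field)
    out = np.full(mean_mag.shape, np.nan)
    ok = mean_mag > 0
    ratio = np.linalg.norm(mean_vec[ok], axis=1) / mean_mag[ok]
    out[ok] = 0.5 * (1.0 - np.clip(ratio, 0.0, 1.0))
    return out


def rrt(tawss_map: np.ndarray, osi_map: np.ndarray) -> np.ndarray:
    """Relative residence time ``1/((1 - 2 OSI) TAWSS)``, 1/Pa.

    ``inf`` where OSI = 1/2; NaN where TAWSS = 0 or OSI undefined.
    """
    t = np.asarray(tawss_map, dtype=float)
    o = np.asarray(osi_map, dtype=float)
    out = np.full(t.shape, np.nan)
    with np.errstate(divide="ignore"):
        denom = (1.0 - 2.0 * o) * t
        ok = (t > 0) & ~np.isnan(o)
        out[ok] = np.where(denom[ok] > 0, 1.0 / denom[ok], np.inf)
    return out


def compute_maps(field: SurfaceWSSField) -> IndexMaps:
    """All three index maps in one pass."""
    t = tawss(field)
    o = osi(field)
    return IndexMaps(tawss=t, osi=o, rrt=rrt(t, o))


def threshold_percentages(maps: IndexMaps, areas: np.ndarray,
                          tawss_low: float = TAWSS_LOW_THRESHOLD,
                          osi_high: float = OSI_HIGH_THRESHOLD,
                          rrt_high: float = RRT_HIGH_THRESHOLD):
    """Area percentages in the thrombus-prone bands (strict inequalities).

    Infinite RRT counts as above threshold; undefined (NaN) elements never
    qualify.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.shape != maps.tawss.shape:
        raise ValueError("areas and index maps must have matching lengths")
    total = areas.sum()

    def pct(mask):
        return 100.0 * areas[mask].sum() / total

    with np.errstate(invalid="ignore"):
        return (pct(maps.tawss < tawss_low),
                pct(maps.osi > osi_high),
                pct(maps.rrt > rrt_high))


def summarize(maps: IndexMaps, areas: np.ndarray,
              area_weighted: bool = True) -> IndexSummary:
    """Averages, minima and maxima of the maps plus threshold percentages.

    Averages are area-weighted by default (set ``area_weighted=False`` for
    plain element-wise means).  Non-finite RRT values are excluded from the
    RRT average and maximum; min/max are over elements.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.shape != maps.tawss.shape:
        raise ValueError("areas and index maps must have matching lengths")

    def ave(x, mask=None):
        if mask is None:
            mask = np.isfinite(x)
        if not mask.any():
            return float("nan")
        if area_weighted:
            return float(areas[mask] @ x[mask] / areas[mask].sum())
        return float(x[mask].mean())

    fin_rrt = np.isfinite(maps.rrt)
    p_tawss, p_osi, p_rrt = threshold_percentages(maps, areas)
    return IndexSummary(
        tawss_ave=ave(maps.tawss), tawss_min=float(np.min(maps.tawss)),
        tawss_max=float(np.max(maps.tawss)),
        osi_ave=ave(maps.osi), osi_min=float(np.nanmin(maps.osi)),
        osi_max=float(np.nanmax(maps.osi)),
        rrt_ave=ave(maps.rrt, fin_rrt),
        rrt_min=float(np.min(maps.rrt[fin_rrt])) if fin_rrt.any()
        else float("nan"),
        rrt_max=float(np.max(maps.rrt[fin_rrt])) if fin_rrt.any()
        else float("nan"),
        pct_tawss_low=p_tawss, pct_osi_high=p_osi, pct_rrt_high=p_rrt,
    )
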