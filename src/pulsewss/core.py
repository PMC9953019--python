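"""Core data containers: waveforms, surface WSS fields, plane velocity fields.

All containers are thin validated wrappers over numpy arrays with long-CSV
round-trip helpers; pandas is the interchange layer.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["Waveform", "SurfaceWSSField", "PlaneVelocityField"]


@dataclass(frozen=True)
class Waveform:
    """A periodically sampled mean-velocity signal over one cardiac cycle.

    ``times`` is a strictly increasing uniform grid covering ``[0, period)``
    (the sample at ``t = period`` is implied by periodicity and not stored).
    """

    times: np.ndarray      # s
    values: np.ndarray     # m/s
    period: float          # s

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if t.size < 8:
            raise ValueError("need at least 8 samples per period")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[-1] >= self.period:
            raise ValueError("last sample must precede the period "
                             "(periodic convention)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def mean(self) -> float:
        """Cycle-averaged value (exact for a uniform periodic grid)."""
        return float(self.values.mean())

    @property
    def peak(self) -> float:
        return float(self.values.max())

    @property
    def t_peak(self) -> float:
        """Time of maximum value - peak systole."""
        return float(self.times[int(np.argmax(self.values))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "u_mean": self.values})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, period: Optional[float] = None
                   ) -> "Waveform":
        if not {"t", "u_mean"} <= set(df.columns):
            raise ValueError("waveform table needs columns 't' and 'u_mean'")
        t = df["t"].to_numpy(dtype=float)
        if period is None:
            # infer from uniform spacing: grid covers exactly one period
            period = float(t[-1] + (t[1] - t[0]))
        return cls(times=t, values=df["u_mean"].to_numpy(dtype=float),
                   period=period)


@dataclass(frozen=True)
class SurfaceWSSField:
    """Per-element wall-shear-stress vector time series over one cycle.

    ``wss`` has shape ``(n_elements, n_times, 3)`` in Pa; ``areas`` are the
    element areas in m2; ``times`` is a uniform grid over ``[0, period)``.
    """

    element_ids: np.ndarray
    areas: np.ndarray
    times: np.ndarray
    wss: np.ndarray
    period: float
    #: optional analytic ground truth attached by generators (per-element
    #: dicts of expected index values; NaN where no closed form applies)
    expected: Optional[dict] = None

    def __post_init__(self):
        a = np.asarray(self.areas, dtype=float)
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.wss, dtype=float)
        if np.any(a <= 0):
            raise ValueError("element areas must be positive")
        if t.size < 8:
            raise ValueError("need at least 8 time samples")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-8):
            raise ValueError("time grid must be uniform and increasing")
        if w.shape != (a.size, t.size, 3):
            raise ValueError(
                f"wss must have shape (n_elements, n_times, 3); got {w.shape}")
        object.__setattr__(self, "areas", a)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "wss", w)
        object.__setattr__(self, "element_ids",
                           np.asarray(self.element_ids))

    @property
    def n_elements(self) -> int:
        return self.areas.size

    def to_frame(self) -> pd.DataFrame:
        """Long format: ``element, area, t, wss_x, wss_y, wss_z``."""
        n, m = self.n_elements, self.times.size
        return pd.DataFrame({
            "element": np.repeat(self.element_ids, m),
            "area": np.repeat(self.areas, m),
            "t": np.tile(self.times, n),
            "wss_x": self.wss[:, :, 0].ravel(),
            "wss_y": self.wss[:, :, 1].ravel(),
            "wss_z": self.wss[:, :, 2].ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   period: Optional[float] = None) -> "SurfaceWSSField":
        need = {"element", "area", "t", "wss_x", "wss_y", "wss_z"}
        if not need <= set(df.columns):
            raise ValueError(f"WSS table needs columns {sorted(need)}")
        piv = df.sort_values(["element", "t"])
        ids = piv["element"].unique()
        times = np.sort(df["t"].unique())
        n, m = ids.size, times.size
        if len(df) != n * m:
            raise ValueError("WSS table is not a complete element x time grid")
        w = piv[["wss_x", "wss_y", "wss_z"]].to_numpy().reshape(n, m, 3)
        areas = piv.groupby("element", sort=True)["area"].first()
        areas = areas.loc[ids].to_numpy()
        if period is None:
            period = float(times[-1] + (times[1] - times[0]))
        return cls(element_ids=ids, areas=areas, times=times, wss=w,
                   period=period)


@dataclass(frozen=True)
class PlaneVelocityField:
    """Planar cells with coordinates, areas and peak-systole speeds.

    The plane centroid is the area-weighted mean of the cell coordinates and
    ``Req = sqrt(total area / pi)`` is the radius of the equivalent circle.
    """

    cell_ids: np.ndarray
    coords: np.ndarray     # (n, 3) m
    areas: np.ndarray      # m2
    speed: np.ndarray      # m/s
    #: analytic ground truth attached by generators ({"fA": %, "fD": %})
    truth: Optional[dict] = None

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        s = np.asarray(self.speed, dtype=float)
        if a.size == 0:
            raise ValueError("plane has no cells")
        if c.shape != (a.size, 3) or s.shape != a.shape:
            raise ValueError("coords/areas/speed shapes are inconsistent")
        if np.any(a <= 0):
            raise ValueError("cell areas must be positive")
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "areas", a)
        object.__setattr__(self, "speed", s)
        object.__setattr__(self, "cell_ids", np.asarray(self.cell_ids))

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def centroid(self) -> np.ndarray:
        return self.areas @ self.coords / self.total_area

    @property
    def req(self) -> float:
        """Equivalent radius of a circle with the plane's area, m."""
        return float(np.sqrt(self.total_area / np.pi))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell": self.cell_ids,
            "x": self.coords[:, 0], "y": self.coords[:, 1],
            "z": self.coords[:, 2],
            "area": self.areas, "speed": self.speed,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlaneVelocityField":
        need = {"cell", "x", "y", "z", "area", "speed"}
        if not need <= set(df.columns):
            raise ValueError(f"plane table needs columns {sorted(need)}")
        return cls(cell_ids=df["cell"].to_numpy(),
                   coords=df[["x", "y", "z"]].to_numpy(dtype=float),
                   areas=df["area"].to_numpy(dtype=float),
                   speed=df["speed"].to_numpy(dtype=float))
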