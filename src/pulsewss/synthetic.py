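"""Synthetic-data generators with analytic ground truth.

These generators stand in for the CFD solver: they produce cardiac
waveforms, surface WSS vector time series, cross-sectional velocity planes,
and factorial response tables whose index values, centroids and effects are
known in closed form, so every downstream stage can be exercised against an
oracle.  All generators are pure functions of their spec (and seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import (CARDIAC_PERIOD, MEAN_INLET_SPEED, N_TIME_SAMPLES,
                        PEAK_TO_MEAN_RATIO)
from .core import PlaneVelocityField, SurfaceWSSField, Waveform
from .datasets import INLETS, RHEOLOGIES

__all__ = [
    "make_waveform", "max_peak_ratio",
    "SyntheticWSSSpec", "make_wss_field", "make_random_wss_field",
    "make_plane_field",
    "FactorialDesignSpec", "make_factorial_table",
]


# ---------------------------------------------------------------------------
# Cardiac waveform
# ---------------------------------------------------------------------------

def max_peak_ratio(n_harmonics: int) -> float:
    """Largest peak/mean ratio attainable by the cosine-power pulse while
    keeping the waveform non-negative: ``4**m / C(2m, m)``."""
    if n_harmonics == 0:
        return 1.0
    return 4.0 ** n_harmonics / comb(2 * n_harmonics, n_harmonics)


def make_waveform(mean: float = MEAN_INLET_SPEED,
                  peak_ratio: float = PEAK_TO_MEAN_RATIO,
                  period: float = CARDIAC_PERIOD,
                  n_samples: int = N_TIME_SAMPLES,
                  n_harmonics: int = 8,
                  peak_phase: float = 0.15) -> Waveform:
    """Deterministic pulse-like waveform with exact mean and peak ratio.

    The shape is a raised-cosine power pulse
    ``b(t) = cos(pi (t - tp)/T) ** (2 m)`` - a trigonometric polynomial with
    ``m = n_harmonics`` harmonics, whose cycle average ``C(2m, m)/4**m`` is
    known exactly - rescaled so that the cycle mean equals ``mean`` and the
    maximum equals ``peak_ratio * mean``.  On a uniform grid with
    ``n_samples > 2 m`` the discrete mean is exact (trigonometric
    polynomials integrate exactly), and the peak time ``tp`` is snapped to
    the grid so the sampled maximum is exact as well.

    Parameters
    ----------
    mean:
        Cycle-averaged speed, m/s.
    peak_ratio:
        Peak/mean ratio (>= 1).  Bounded by :func:`max_peak_ratio` for the
        requested harmonic count so the flow never reverses.
    peak_phase:
        Fraction of the cycle at which peak systole occurs.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if peak_ratio < 1:
        raise ValueError("peak_ratio must be >= 1")
    if n_samples < 8:
        raise ValueError("need at least 8 samples per period")
    if n_samples <= 2 * n_harmonics:
        raise ValueError("n_samples must exceed twice the harmonic count")
    times = np.arange(n_samples) * (period / n_samples)
    if peak_ratio == 1.0:
        return Waveform(times=times, values=np.full(n_samples, mean),
                        period=period)
    if n_harmonics < 1:
        raise ValueError("peak_ratio > 1 requires at least one harmonic")
    if peak_ratio > max_peak_ratio(n_harmonics) + 1e-12:
        raise ValueError(
            f"peak_ratio {peak_ratio} unattainable with {n_harmonics} "
            f"harmonics without flow reversal (max "
            f"{max_peak_ratio(n_harmonics):.3f})")
    tp = times[int(round(peak_phase * n_samples)) % n_samples]
    b = np.cos(np.pi * (times - tp) / period) ** (2 * n_harmonics)
    b_mean = comb(2 * n_harmonics, n_harmonics) / 4.0 ** n_harmonics
    amp = (peak_ratio - 1.0) / (1.0 - b_mean)
    values = mean * (1.0 + amp * (b - b_mean))
    return Waveform(times=times, values=values, period=period)


# ---------------------------------------------------------------------------
# Surface WSS fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticWSSSpec:
    """Recipe for a synthetic per-element WSS vector time series.

    Element ``i`` carries
    ``WSS_i(t) = m_i * d_hat + a_i * sin(2 pi t / T + phi_i) * e_hat``
    where ``d_hat = x_hat`` and ``e_hat`` equals ``d_hat`` in ``aligned``
    mode or ``y_hat`` in ``orthogonal`` mode.  Scalars broadcast over
    elements; arrays left ``None`` are drawn reproducibly from ``seed``.
    """

    n_elements: int
    steady_magnitudes: Optional[Sequence[float]] = None   # Pa
    oscillation_amplitudes: Optional[Sequence[float]] = None  # Pa
    phase_offsets: Optional[Sequence[float]] = None       # rad
    direction_mode: str = "aligned"
    seed: int = 0

    def __post_init__(self):
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if self.direction_mode not in ("aligned", "orthogonal"):
            raise ValueError("direction_mode must be 'aligned' or "
                             "'orthogonal'")
        for name in ("steady_magnitudes", "oscillation_amplitudes"):
            v = getattr(self, name)
            if v is not None and np.any(np.asarray(v, dtype=float) < 0):
                raise ValueError(f"{name} must be non-negative")

    def resolve(self):
        """Return (m, a, phi) arrays of length ``n_elements``."""
        rng = np.random.default_rng(self.seed)
        n = self.n_elements

        def broadcast(v, draw):
            if v is None:
                return draw()
            arr = np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
            return arr

        m = broadcast(self.steady_magnitudes, lambda: rng.uniform(0, 2, n))
        a = broadcast(self.oscillation_amplitudes,
                      lambda: rng.uniform(0, 2, n))
        phi = broadcast(self.phase_offsets,
                        lambda: rng.uniform(0, 2 * np.pi, n))
        return m, a, phi


def make_wss_field(spec: SyntheticWSSSpec,
                   times: Optional[np.ndarray] = None,
                   period: float = CARDIAC_PERIOD,
                   areas: Optional[np.ndarray] = None) -> SurfaceWSSField:
    """Build a synthetic surface WSS field with closed-form index targets.

    For ``aligned`` elements the expected indices are attached where a
    closed form exists: with ``m >= a`` the magnitude never changes sign, so
    TAWSS = m and OSI = 0; with ``m = 0`` the signal is a pure sinusoid, so
    TAWSS = 2 a / pi and OSI = 1/2.  Other elements carry NaN targets.
    """
    if times is None:
        times = np.arange(N_TIME_SAMPLES) * (period / N_TIME_SAMPLES)
    times = np.asarray(times, dtype=float)
    m, a, phi = spec.resolve()
    n = spec.n_elements
    if areas is None:
        areas = np.full(n, 1.0 / n)
    osc = a[:, None] * np.sin(2 * np.pi * times[None, :] / period
                              + phi[:, None])
    wss = np.zeros((n, times.size, 3))
    wss[:, :, 0] = m[:, None]
    if spec.direction_mode == "aligned":
        wss[:, :, 0] += osc
    else:
        wss[:, :, 1] = osc

    exp_tawss = np.full(n, np.nan)
    exp_osi = np.full(n, np.nan)
    if spec.direction_mode == "aligned":
        steady = m >= a
        exp_tawss[steady] = m[steady]
        exp_osi[steady] = 0.0
        pure = m == 0
        exp_tawss[pure] = 2.0 * a[pure] / np.pi
        exp_osi[pure] = np.where(a[pure] > 0, 0.5, np.nan)
    expected = {"tawss": exp_tawss, "osi": exp_osi}
    return SurfaceWSSField(element_ids=np.arange(n), areas=areas,
                           times=times, wss=wss, period=period,
                           expected=expected)


def make_random_wss_field(n_elements: int, n_times: int = 64,
                          seed: int = 0,
                          period: float = CARDIAC_PERIOD) -> SurfaceWSSField:
    """Unstructured random WSS vectors - for property tests (no oracle)."""
    rng = np.random.default_rng(seed)
    times = np.arange(n_times) * (period / n_times)
    wss = rng.normal(scale=1.0, size=(n_elements, n_times, 3))
    areas = rng.uniform(0.5, 1.5, n_elements)
    return SurfaceWSSField(element_ids=np.arange(n_elements), areas=areas,
                           times=times, wss=wss, period=period)


# ---------------------------------------------------------------------------
# Plane velocity fields
# ---------------------------------------------------------------------------

def make_plane_field(kind: str, radius: float = 0.01, n_across: int = 101,
                     vmax: float = 1.0, offset_frac: float = 0.4,
                     sigma_frac: float = 0.2,
                     seed: int = 0) -> PlaneVelocityField:
    """Tessellated disc with a known high-velocity core.

    Parameters
    ----------
    kind:
        ``centered_parabolic`` - Poiseuille-like profile, core centred on the
        plane centroid (true asymmetry 0, true dispersion 15 for the default
        85%-of-max band);
        ``offset_jet`` - Gaussian jet displaced by ``offset_frac * Req``
        along +x (true asymmetry ``100 * offset_frac``);
        ``uniform`` - constant speed (asymmetry 0, dispersion 100).
    n_across:
        Cells across the diameter of the square tessellation grid.
    sigma_frac:
        Gaussian jet width as a fraction of the radius.

    The continuum ground-truth asymmetry/dispersion percentages for the
    default 0.15 band fraction are attached as ``field.truth``; tessellated
    values converge to them as ``n_across`` grows.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_across < 3:
        raise ValueError("n_across too small to tessellate the disc")
    h = 2.0 * radius / n_across
    c = (np.arange(n_across) + 0.5) * h - radius
    X, Y = np.meshgrid(c, c, indexing="ij")
    inside = X ** 2 + Y ** 2 <= radius ** 2
    if not inside.any():
        raise ValueError("degenerate geometry: no cells inside the disc")
    x, y = X[inside], Y[inside]
    r2 = x ** 2 + y ** 2
    band = 0.15  # default top-band fraction for recorded ground truth
    if kind == "centered_parabolic":
        speed = vmax * (1.0 - r2 / radius ** 2)
        truth = {"fA": 0.0, "fD": 100.0 * band}
    elif kind == "uniform":
        speed = np.full(x.shape, vmax)
        truth = {"fA": 0.0, "fD": 100.0}
    elif kind == "offset_jet":
        # jet displaced along +x by offset_frac * Req (continuum Req = R)
        x0 = offset_frac * radius
        sig = sigma_frac * radius
        d2 = (x - x0) ** 2 + y ** 2
        speed = vmax * np.exp(-d2 / (2.0 * sig ** 2))
        # band edge: exp(-d^2/(2 sig^2)) = 1 - band  =>  disc of radius rb
        rb = sig * np.sqrt(-2.0 * np.log(1.0 - band))
        truth = {"fA": 100.0 * offset_frac,
                 "fD": 100.0 * rb ** 2 / radius ** 2}
    else:
        raise ValueError(f"unknown plane kind {kind!r}")
    n = x.size
    coords = np.column_stack([x, y, np.zeros(n)])
    return PlaneVelocityField(cell_ids=np.arange(n), coords=coords,
                              areas=np.full(n, h * h), speed=speed,
                              truth=truth)


# ---------------------------------------------------------------------------
# Factorial response tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorialDesignSpec:
    """Two-way factorial design with heteroscedastic, contaminated errors.

    Emulates the balanced 5 rheology x 3 inlet design of the study:
    ``y_ijk = mu + a_i + b_j + (ab)_ij + eps_ijk`` with per-cell noise
    scales, and each observation independently replaced by a gross outlier
    (noise inflated by ``outlier_scale``) with probability ``outlier_rate``.
    Effects must sum to zero within each factor.
    """

    grand_mean: float = 0.0
    factor_a_effects: Sequence[float] = (0.0,) * 5
    factor_b_effects: Sequence[float] = (0.0,) * 3
    interaction_effects: Optional[Sequence[Sequence[float]]] = None
    noise_scales: float | Sequence[Sequence[float]] = 1.0
    outlier_rate: float = 0.0
    outlier_scale: float = 10.0
    n_per_cell: int = 7
    seed: int = 0
    factor_a_levels: Sequence[str] = RHEOLOGIES
    factor_b_levels: Sequence[str] = INLETS

    def __post_init__(self):
        a = np.asarray(self.factor_a_effects, dtype=float)
        b = np.asarray(self.factor_b_effects, dtype=float)
        if a.size != len(self.factor_a_levels):
            raise ValueError("factor A effects/levels length mismatch")
        if b.size != len(self.factor_b_levels):
            raise ValueError("factor B effects/levels length mismatch")
        tol = 1e-9 * max(1.0, np.abs(a).max(), np.abs(b).max())
        if abs(a.sum()) > tol or abs(b.sum()) > tol:
            raise ValueError("main effects must sum to zero within each "
                             "factor")
        if not (0.0 <= self.outlier_rate < 1.0):
            raise ValueError("outlier_rate must lie in [0, 1)")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        scales = np.broadcast_to(np.asarray(self.noise_scales, dtype=float),
                                 (a.size, b.size))
        if np.any(scales <= 0):
            raise ValueError("noise scales must be positive")

    def cell_means(self) -> np.ndarray:
        a = np.asarray(self.factor_a_effects, dtype=float)
        b = np.asarray(self.factor_b_effects, dtype=float)
        ab = (np.zeros((a.size, b.size))
              if self.interaction_effects is None
              else np.asarray(self.interaction_effects, dtype=float))
        if ab.shape != (a.size, b.size):
            raise ValueError("interaction effects must be J x K")
        return self.grand_mean + a[:, None] + b[None, :] + ab


def make_factorial_table(spec: FactorialDesignSpec) -> pd.DataFrame:
    """Draw a long-format factorial table (reproducible under the seed).

    Columns match the packaged response tables:
    ``case, rheology, inlet, variable, value`` with
    ``variable = "synthetic"``.
    """
    rng = np.random.default_rng(spec.seed)
    means = spec.cell_means()
    J, K = means.shape
    scales = np.broadcast_to(np.asarray(spec.noise_scales, dtype=float),
                             (J, K))
    rows = []
    for i, la in enumerate(spec.factor_a_levels):
        for j, lb in enumerate(spec.factor_b_levels):
            eps = rng.normal(scale=scales[i, j], size=spec.n_per_cell)
            if spec.outlier_rate > 0:
                bad = rng.random(spec.n_per_cell) < spec.outlier_rate
                eps = np.where(bad, eps * spec.outlier_scale, eps)
            for k, e in enumerate(eps):
                rows.append((f"g{k + 1}", la, lb, "synthetic",
                             means[i, j] + e))
    return pd.DataFrame(rows, columns=["case", "rheology", "inlet",
                                       "variable", "value"])
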