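"""Pulsatile inlet velocity profiles: Parabolic, Plug, and Womersley.

The three profiles share the same prescribed mean-velocity waveform, so a
simulation's inlet flow rate is identical across profile choices; only the
spatial distribution differs.  The Womersley profile is the analytic
oscillatory pipe-flow solution: each Fourier mode ``n`` of the waveform
drives an annular mode shape built from complex Bessel functions
``J0(alpha_n i**(3/2) r/R)``, with ``alpha_n = alpha sqrt(n)`` and
``alpha = R sqrt(omega rho / mu)`` the Womersley number.  Mode amplitudes
are calibrated by inverting the mode-wise flow-rate relation, so the
disc-averaged velocity reproduces the waveform mode by mode; mode 0 is
steady Poiseuille flow carrying the waveform mean.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import jv

from .constants import MU_REFERENCE, N_FOURIER_MODES, RHO_BLOOD
from .core import Waveform

__all__ = [
    "womersley_alpha", "reynolds",
    "fourier_decompose", "reconstruct_waveform",
    "InletProfile", "WomersleySpec",
    "parabolic_profile", "plug_profile", "womersley_profile",
    "disc_average",
]

_I32 = np.exp(0.75j * np.pi)  # i**(3/2)


def womersley_alpha(R: float, omega: float, rho: float = RHO_BLOOD,
                    mu: float = MU_REFERENCE) -> float:
    """Womersley number ``alpha = R sqrt(omega rho / mu)``."""
    if min(R, omega, rho, mu) <= 0:
        raise ValueError("all arguments must be positive")
    return R * np.sqrt(omega * rho / mu)


def reynolds(rho: float, U: float, R: float, mu: float) -> float:
    """Diameter-based Reynolds number ``Re = 2 rho U R / mu``."""
    if min(rho, R, mu) <= 0:
        raise ValueError("rho, R and mu must be positive")
    if U < 0:
        raise ValueError("speed must be non-negative")
    return 2.0 * rho * U * R / mu


# ---------------------------------------------------------------------------
# Fourier analysis of the waveform
# ---------------------------------------------------------------------------

def fourier_decompose(w: Waveform, n_modes: int = N_FOURIER_MODES
                      ) -> np.ndarray:
    """Complex Fourier coefficients ``c[0..n_modes]`` of a waveform.

    The convention is ``u(t) = c0 + sum_n Re[c_n exp(i n omega t)]`` with
    ``omega = 2 pi / T``; ``c0`` is the cycle mean.  Requires a uniform
    grid and ``n_modes <= n_samples // 2``.
    """
    n = w.times.size
    if n_modes < 0 or n_modes > n // 2:
        raise ValueError(f"n_modes must lie in [0, {n // 2}] for "
                         f"{n} samples")
    dt = np.diff(w.times)
    if not np.allclose(dt, dt[0], rtol=1e-9):
        raise ValueError("waveform samples must be uniformly spaced")
    spec = np.fft.rfft(w.values) / n
    coeffs = np.zeros(n_modes + 1, dtype=complex)
    coeffs[0] = spec[0].real
    upper = min(n_modes, n // 2)
    for k in range(1, upper + 1):
        # conjugate pairs fold into a single real-part mode; the Nyquist
        # bin (even n) is its own conjugate and keeps weight 1
        coeffs[k] = spec[k] * (1.0 if (2 * k == n) else 2.0)
    return coeffs


def reconstruct_waveform(coeffs: np.ndarray, times: np.ndarray,
                         period: float) -> np.ndarray:
    """Evaluate ``c0 + sum_n Re[c_n exp(i n omega t)]`` on ``times``."""
    times = np.asarray(times, dtype=float)
    omega = 2.0 * np.pi / period
    out = np.full(times.shape, float(coeffs[0].real))
    for k in range(1, len(coeffs)):
        out += (coeffs[k] * np.exp(1j * k * omega * times)).real
    return out


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InletProfile:
    """Axial speed sampled on an ``(radius, time)`` grid."""

    radii: np.ndarray     # m, in [0, R]
    times: np.ndarray     # s
    speed: np.ndarray     # m/s, shape (n_radii, n_times)
    kind: str
    R: float              # inlet radius, m


@dataclass(frozen=True)
class WomersleySpec:
    """Geometry, pulsation and fluid parameters of a Womersley inlet."""

    R: float
    omega: float
    rho: float = RHO_BLOOD
    mu: float = MU_REFERENCE
    n_modes: int = N_FOURIER_MODES
    modal_coefficients: Optional[np.ndarray] = None  # complex, per mode

    def __post_init__(self):
        if min(self.R, self.omega, self.rho, self.mu) <= 0:
            raise ValueError("R, omega, rho, mu must be positive")
        if self.n_modes < 1:
            raise ValueError("need at least one mode")

    @property
    def alpha(self) -> float:
        return womersley_alpha(self.R, self.omega, self.rho, self.mu)

    @classmethod
    def from_waveform(cls, w: Waveform, R: float, rho: float = RHO_BLOOD,
                      mu: float = MU_REFERENCE,
                      n_modes: int = N_FOURIER_MODES) -> "WomersleySpec":
        coeffs = fourier_decompose(w, n_modes)
        return cls(R=R, omega=2.0 * np.pi / w.period, rho=rho, mu=mu,
                   n_modes=n_modes, modal_coefficients=coeffs)


def _default_radii(R: float, n: int = 64) -> np.ndarray:
    return np.linspace(0.0, R, n)


def parabolic_profile(w: Waveform, R: float,
                      radii: Optional[Sequence[float]] = None
                      ) -> InletProfile:
    """Poiseuille-shaped profile ``2 Umean(t) (1 - (r/R)**2)``."""
    radii = _default_radii(R) if radii is None else np.asarray(radii, float)
    if np.any((radii < 0) | (radii > R)):
        raise ValueError("radii must lie in [0, R]")
    shape = 2.0 * (1.0 - (radii / R) ** 2)
    return InletProfile(radii=radii, times=w.times,
                        speed=np.outer(shape, w.values), kind="Parabolic",
                        R=R)


def plug_profile(w: Waveform, R: float,
                 radii: Optional[Sequence[float]] = None) -> InletProfile:
    """Uniform profile ``U(t)`` at all radii."""
    radii = _default_radii(R) if radii is None else np.asarray(radii, float)
    if np.any((radii < 0) | (radii > R)):
        raise ValueError("radii must lie in [0, R]")
    speed = np.broadcast_to(w.values, (radii.size, w.times.size)).copy()
    return InletProfile(radii=radii, times=w.times, speed=speed,
                        kind="Plug", R=R)


def _mode_shape(alpha_n: float, x: np.ndarray) -> np.ndarray:
    """Oscillatory mode shape, normalized to unit disc average.

    ``x = r/R``.  Returns the complex profile
    ``(1 - J0(L x)/J0(L)) / (1 - 2 J1(L)/(L J0(L)))`` with
    ``L = alpha_n i**(3/2)``; its area average over the unit disc is 1 and
    it vanishes at ``x = 1`` (no-slip).
    """
    L = alpha_n * _I32
    j0L = jv(0, L)
    profile = 1.0 - jv(0, L * x) / j0L
    flow = 1.0 - 2.0 * jv(1, L) / (L * j0L)
    out = profile / flow
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            f"Bessel evaluation overflowed at alpha_n = {alpha_n:.3g}; "
            "reduce the Womersley number or the number of modes")
    return out


def womersley_profile(w: Waveform, R: float,
                      radii: Optional[Sequence[float]] = None,
                      times: Optional[Sequence[float]] = None,
                      n_modes: int = N_FOURIER_MODES,
                      rho: float = RHO_BLOOD,
                      mu: float = MU_REFERENCE) -> InletProfile:
    """Analytic pulsatile pipe-flow profile matching the waveform mean.

    Mode 0 is steady Poiseuille flow with the waveform's cycle mean; each
    oscillatory mode is the annular Womersley solution scaled so its disc
    average equals the corresponding waveform Fourier mode.  No-slip is
    exact at ``r = R``.
    """
    spec = WomersleySpec.from_waveform(w, R, rho=rho, mu=mu,
                                       n_modes=n_modes)
    radii = _default_radii(R) if radii is None else np.asarray(radii, float)
    if np.any((radii < 0) | (radii > R)):
        raise ValueError("radii must lie in [0, R]")
    times = w.times if times is None else np.asarray(times, dtype=float)
    c = spec.modal_coefficients
    x = radii / R
    omega = spec.omega
    speed = np.outer(2.0 * c[0].real * (1.0 - x ** 2),
                     np.ones(times.size))
    for n in range(1, spec.n_modes + 1):
        if c[n] == 0:
            continue
        shape = _mode_shape(spec.alpha * np.sqrt(n), x)
        speed += np.real(np.outer(c[n] * shape,
                                  np.exp(1j * n * omega * times)))
    return InletProfile(radii=radii, times=times, speed=speed,
                        kind="Womersley", R=R)


def disc_average(profile: InletProfile) -> np.ndarray:
    """Cross-sectional (area) average of a profile at each time.

    Radial trapezoid quadrature of ``2/R**2 * integral(u r dr)``; the radii
    must span ``[0, R]``.
    """
    r = profile.radii
    if not (np.isclose(r[0], 0.0) and np.isclose(r[-1], profile.R)):
        raise ValueError("radii must span [0, R] for a disc average")
    return 2.0 / profile.R ** 2 * np.trapezoid(
        profile.speed * r[:, None], r, axis=0)
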