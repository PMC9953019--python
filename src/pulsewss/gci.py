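"""Grid Convergence Index (GCI) verification.

Richardson-extrapolation-based discretization-error estimation from a
triplet of solutions on systematically refined meshes.  With ``f1, f2, f3``
the fine/medium/coarse solutions and refinement ratio ``r``:

* observed order of convergence ``p = ln((f3 - f2)/(f2 - f1)) / ln(r)``;
* ``GCI_ij = Fs * e_ij / (r**p - 1)`` with safety factor ``Fs`` (default
  1.25) and fine-grid-referenced relative error
  ``e_ij = 100 |f_i - f_j| / f_i`` in percent;
* mesh triplets in the asymptotic convergence range satisfy
  ``GCI_23 / (r**p GCI_12) ~ 1``.

Note that with ``p`` estimated from the same triplet and the errors
referenced to the finer grid of each pair, the diagnostic ratio reduces
algebraically to ``f1/f2``: its deviation from unity measures the relative
fine-medium solution change, and it tends to 1 as the grids enter the
asymptotic range.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridTriplet", "GciResult", "order_of_convergence", "gci_pair",
           "asymptotic_ratio", "gci_report"]


@dataclass(frozen=True)
class GridTriplet:
    """Solutions on fine (``f1``), medium (``f2``) and coarse (``f3``)
    meshes with constant refinement ratio ``r`` and safety factor ``Fs``."""

    f1: float
    f2: float
    f3: float
    r: float = 2.0
    fs: float = 1.25

    def __post_init__(self):
        if self.r <= 1:
            raise ValueError("refinement ratio must exceed 1")
        if self.fs < 1:
            raise ValueError("safety factor must be >= 1")


@dataclass(frozen=True)
class GciResult:
    p_order: float
    e12: float       # %
    e23: float       # %
    gci12: float     # %
    gci23: float     # %
    asymptotic_ratio: float


def order_of_convergence(t: GridTriplet) -> float:
    """Observed order ``p``; requires monotone convergence."""
    d32 = t.f3 - t.f2
    d21 = t.f2 - t.f1
    if d32 == 0 or d21 == 0 or np.sign(d32) != np.sign(d21):
        raise ValueError("non-monotone or stalled triplet: cannot estimate "
                         "an order of convergence")
    return float(np.log(d32 / d21) / np.log(t.r))


def gci_pair(t: GridTriplet, p: float | None = None):
    """``(GCI_12, GCI_23)`` in percent between successive refinements."""
    if p is None:
        p = order_of_convergence(t)
    if t.f1 == 0 or t.f2 == 0:
        raise ValueError("relative error undefined for a zero solution")
    e12 = 100.0 * abs(t.f1 - t.f2) / abs(t.f1)
    e23 = 100.0 * abs(t.f2 - t.f3) / abs(t.f2)
    fac = t.fs / (t.r ** p - 1.0)
    return fac * e12, fac * e23


def asymptotic_ratio(gci12: float, gci23: float, r: float, p: float
                     ) -> float:
    """Convergence diagnostic ``GCI_23 / (r**p GCI_12)`` (tends to 1)."""
    denom = r ** p * gci12
    if denom == 0:
        raise ValueError("zero denominator in asymptotic ratio")
    return gci23 / denom


def gci_report(t: GridTriplet) -> GciResult:
    """Full verification report for a grid triplet."""
    p = order_of_convergence(t)
    g12, g23 = gci_pair(t, p)
    e12 = 100.0 * abs(t.f1 - t.f2) / abs(t.f1)
    e23 = 100.0 * abs(t.f2 - t.f3) / abs(t.f2)
    return GciResult(p_order=p, e12=e12, e23=e23, gci12=g12, gci23=g23,
                     asymptotic_ratio=asymptotic_ratio(g12, g23, t.r, p))
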