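"""Generalized-Newtonian constitutive laws for blood.

Five apparent-viscosity specifications are provided: Carreau-Yasuda (CY),
Casson (Cs), Herschel-Bulkley (HB), Newtonian (N), and Power law (P), with
literature parameter values for blood.  The stress tensor follows the
generalized-Newtonian closure ``tau = 2 mu(gamma_dot) D`` where ``D`` is the
rate-of-deformation tensor and ``gamma_dot = sqrt(2 D:D)`` the scalar shear
rate.

The yield-stress models (Cs, HB) and the power law diverge as the shear rate
vanishes; their apparent viscosity is capped at a configurable ``mu_max``
(default 10 Pa*s), the usual solver-style regularization.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RheologySpec",
    "BLOOD_MODELS",
    "get_model",
    "apparent_viscosity",
    "shear_rate_from_D",
    "stress_tensor",
    "MU_MAX_DEFAULT",
]

#: Default regularization cap on apparent viscosity, Pa*s.
MU_MAX_DEFAULT = 10.0


@dataclass(frozen=True)
class RheologySpec:
    """A named constitutive law and its parameters.

    Only the parameters used by the named law are set; the rest stay ``None``.

    Parameters
    ----------
    name:
        One of ``{"CY", "Cs", "HB", "N", "P"}``.
    mu_inf, mu_0:
        Infinite- and zero-shear viscosities, Pa*s (CY; ``mu_inf`` also N).
    lambda_:
        Relaxation time, s (CY).
    n_index:
        Flow behaviour index (CY, HB, P).
    a_index:
        Carreau-Yasuda transition exponent.
    k_consistency:
        Consistency, Pa*s**n (HB, P) or Casson viscosity, Pa*s (Cs).
    tau_0:
        Yield stress, Pa (Cs, HB).
    """

    name: str
    mu_inf: Optional[float] = None
    mu_0: Optional[float] = None
    lambda_: Optional[float] = None
    n_index: Optional[float] = None
    a_index: Optional[float] = None
    k_consistency: Optional[float] = None
    tau_0: Optional[float] = None

    def __post_init__(self):
        if self.name not in ("CY", "Cs", "HB", "N", "P"):
            raise ValueError(f"unknown rheology model {self.name!r}")
        for f_ in ("mu_inf", "mu_0", "lambda_", "n_index", "a_index",
                   "k_consistency", "tau_0"):
            v = getattr(self, f_)
            if v is not None and v <= 0:
                raise ValueError(f"{f_} must be positive, got {v}")


#: Blood parameter sets for the five models.
BLOOD_MODELS = {
    "CY": RheologySpec("CY", mu_inf=0.00345, mu_0=0.056, lambda_=1.902,
                       n_index=0.22, a_index=1.25),
    "Cs": RheologySpec("Cs", k_consistency=0.00345, tau_0=0.005),
    "HB": RheologySpec("HB", tau_0=0.00345, k_consistency=0.008,
                       n_index=0.8375),
    "N": RheologySpec("N", mu_inf=0.00345),
    "P": RheologySpec("P", k_consistency=0.01467, n_index=0.7755),
}

#: Long names, for reports.
MODEL_NAMES = {
    "CY": "Carreau-Yasuda",
    "Cs": "Casson",
    "HB": "Herschel-Bulkley",
    "N": "Newtonian",
    "P": "Power law",
}


def get_model(name: str) -> RheologySpec:
    """Return the blood parameter set for a model abbreviation."""
    try:
        return BLOOD_MODELS[name]
    except KeyError:
        raise ValueError(
            f"unknown rheology model {name!r}; choose from "
            f"{sorted(BLOOD_MODELS)}") from None


def apparent_viscosity(spec: RheologySpec | str, gamma_dot,
                       mu_max: float = MU_MAX_DEFAULT):
    """Apparent viscosity ``mu(gamma_dot)`` in Pa*s.

    Vectorized over ``gamma_dot`` (1/s, non-negative).  Divergent laws are
    capped at ``mu_max``; in particular all models return a finite value at
    zero shear rate.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    scalar = g.ndim == 0
    g = np.atleast_1d(g)

    with np.errstate(divide="ignore", invalid="ignore"):
        if spec.name == "N":
            mu = np.full_like(g, spec.mu_inf)
        elif spec.name == "CY":
            mu = spec.mu_inf + (spec.mu_0 - spec.mu_inf) * (
                1.0 + (spec.lambda_ * g) ** spec.a_index
            ) ** ((spec.n_index - 1.0) / spec.a_index)
        elif spec.name == "P":
            mu = spec.k_consistency * g ** (spec.n_index - 1.0)
        elif spec.name == "HB":
            mu = spec.k_consistency * g ** (spec.n_index - 1.0) + spec.tau_0 / g
        elif spec.name == "Cs":
            mu = (np.sqrt(spec.k_consistency) + np.sqrt(spec.tau_0 / g)) ** 2
        else:  # pragma: no cover
            raise AssertionError(spec.name)
    mu = np.where(np.isfinite(mu), mu, np.inf)
    mu = np.minimum(mu, mu_max)
    return float(mu[0]) if scalar else mu


def shear_rate_from_D(D) -> float:
    """Scalar shear rate ``sqrt(2 D:D)`` from a symmetric 3x3 tensor, 1/s."""
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3):
        raise ValueError("D must be a 3x3 tensor")
    if not np.allclose(D, D.T, atol=1e-12 * max(1.0, np.abs(D).max())):
        raise ValueError("rate-of-deformation tensor must be symmetric")
    return float(np.sqrt(2.0 * np.tensordot(D, D)))


def stress_tensor(spec: RheologySpec | str, D,
                  mu_max: float = MU_MAX_DEFAULT) -> np.ndarray:
    """Viscous stress ``tau = 2 mu(gamma_dot(D)) D`` in Pa."""
    D = np.asarray(D, dtype=float)
    gd = shear_rate_from_D(D)
    return 2.0 * apparent_viscosity(spec, gd, mu_max=mu_max) * D
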