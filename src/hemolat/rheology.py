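"""Blood rheology: Newtonian and Carreau-Yasuda constitutive laws.

Whole blood is shear-thinning: its apparent viscosity falls from a
zero-shear plateau eta0 to an infinite-shear plateau eta_inf as the shear
rate increases.  The Carreau-Yasuda (CY) model interpolates smoothly
between the plateaus,

    (eta(gdot) - eta_inf) / (eta0 - eta_inf) = (1 + (lambda gdot)^a)^((n-1)/a),

with relaxation time lambda [s] and dimensionless exponents a and n.  The
default parameter set is the one commonly used for cerebral blood flow:
eta0 = 0.16 Pa s, eta_inf = 0.0035 Pa s, lambda = 8.2 s, a = 0.64,
n = 0.2128.  The Newtonian reference viscosity for blood is 0.004 Pa s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RheologySpec",
    "carreau_yasuda_viscosity",
    "NEWTONIAN_BLOOD_VISCOSITY",
    "CY_DEFAULTS",
]

#: dynamic viscosity of blood under the Newtonian assumption, Pa s
NEWTONIAN_BLOOD_VISCOSITY = 0.004

#: default Carreau-Yasuda parameters (eta0, eta_inf [Pa s], lambda [s], a, n)
CY_DEFAULTS = dict(eta0=0.16, eta_inf=0.0035, lambda_cy=8.2, a_cy=0.64, n_cy=0.2128)


@dataclass(frozen=True)
class RheologySpec:
    """Constitutive law selection plus its parameters (SI units)."""

    model: str  # "newtonian" | "carreau_yasuda"
    eta: float | None = None
    eta0: float | None = None
    eta_inf: float | None = None
    lambda_cy: float | None = None
    a_cy: float | None = None
    n_cy: float | None = None

    def __post_init__(self):
        if self.model == "newtonian":
            if self.eta is None or self.eta <= 0:
                raise ValueError("newtonian model requires eta > 0")
        elif self.model == "carreau_yasuda":
            for name in ("eta0", "eta_inf", "lambda_cy", "a_cy", "n_cy"):
                if getattr(self, name) is None:
                    raise ValueError(f"carreau_yasuda model requires {name}")
            if self.eta0 <= 0 or self.eta_inf <= 0:
                raise ValueError("viscosities must be positive")
            if self.eta0 < self.eta_inf:
                raise ValueError("eta0 must be >= eta_inf")
        else:
            raise ValueError(f"unknown rheology model {self.model!r}")

    @classmethod
    def newtonian(cls, eta: float = NEWTONIAN_BLOOD_VISCOSITY) -> "RheologySpec":
        return cls(model="newtonian", eta=eta)

    @classmethod
    def carreau_yasuda(cls, **overrides) -> "RheologySpec":
        params = {**CY_DEFAULTS, **overrides}
        return cls(model="carreau_yasuda", **params)

    def viscosity(self, gamma_dot):
        """Dynamic viscosity [Pa s] at shear rate(s) ``gamma_dot`` [1/s]."""
        if self.model == "newtonian":
            return np.broadcast_to(self.eta, np.shape(gamma_dot)).copy() \
                if np.ndim(gamma_dot) else self.eta
        return carreau_yasuda_viscosity(gamma_dot, self)


def carreau_yasuda_viscosity(gamma_dot, spec: RheologySpec):
    """Evaluate the Carreau-Yasuda viscosity curve.

    Parameters
    ----------
    gamma_dot : float or array
        Shear rate [1/s]; must be non-negative.
    spec : RheologySpec
        Must have ``model == "carreau_yasuda"``.

    Returns
    -------
    Dynamic viscosity [Pa s], bounded by [eta_inf, eta0] and
    non-increasing in shear rate for n < 1.
    """
    if spec.model != "carreau_yasuda":
        raise ValueError("spec.model must be 'carreau_yasuda'")
    g = np.asarray(gamma_dot, dtype=np.float64)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    exponent = (spec.n_cy - 1.0) / spec.a_cy
    eta = spec.eta_inf + (spec.eta0 - spec.eta_inf) * (
        1.0 + (spec.lambda_cy * g) ** spec.a_cy
    ) ** exponent
    return float(eta) if np.ndim(gamma_dot) == 0 else eta
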