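"""Baseline hazard families sharing the proportional-hazards property.

Among the standard parametric survival families, only the exponential,
Weibull, and Gompertz distributions are closed under proportional scaling of
the hazard, which is what makes them usable as Cox-model baselines.  Each is
parameterized by a rate-scale parameter ``lam`` (> 0, per unit time) plus a
shape parameter: the Weibull shape ``nu`` (> 0; ``nu = 1`` recovers the
exponential) or the Gompertz shape ``alpha`` (any real; ``alpha = 0`` recovers
the exponential, ``alpha < 0`` gives a defective distribution whose total
hazard saturates at ``lam / -alpha``, i.e. a cured fraction).

The class exposes the hazard ``h0(t)``, the cumulative hazard ``H0(t)``, its
inverse, and the classical inverse-transform generator for time-invariant
covariates: ``T = H0^{-1}( -log(u) * exp(-eta) )`` with ``u ~ U(0,1)`` and
``eta`` the linear predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BaselineHazard",
    "hazard_at",
    "cumulative_hazard_at",
    "inverse_cumulative_hazard",
    "simulate_invariant_time",
]

_FAMILIES = ("exponential", "weibull", "gompertz")


@dataclass(frozen=True)
class BaselineHazard:
    """One of the three proportional-hazards baseline families.

    Parameters
    ----------
    family : {"exponential", "weibull", "gompertz"}
    lam : float
        Rate-scale parameter lambda > 0 (per unit time).
    nu : float, optional
        Weibull shape nu > 0; required iff ``family == "weibull"``.
    alpha : float, optional
        Gompertz shape alpha (any real, per unit time); required iff
        ``family == "gompertz"``.
    """

    family: str
    lam: float
    nu: float | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        if not (self.lam > 0 and math.isfinite(self.lam)):
            raise ValueError(f"lam > 0 required, got {self.lam}")
        if self.family == "weibull":
            if self.nu is None or not (self.nu > 0 and math.isfinite(self.nu)):
                raise ValueError(f"nu > 0 required for the weibull family, got {self.nu}")
            if self.alpha is not None:
                raise ValueError("alpha is a gompertz parameter; not allowed for weibull")
        elif self.family == "gompertz":
            if self.alpha is None or not math.isfinite(self.alpha):
                raise ValueError(f"finite alpha required for the gompertz family, got {self.alpha}")
            if self.nu is not None:
                raise ValueError("nu is a weibull parameter; not allowed for gompertz")
        else:
            if self.nu is not None or self.alpha is not None:
                raise ValueError("exponential family takes only lam")

    # -- constructors ------------------------------------------------------

    @classmethod
    def exponential(cls, lam: float) -> "BaselineHazard":
        return cls("exponential", lam)

    @classmethod
    def weibull(cls, lam: float, nu: float) -> "BaselineHazard":
        return cls("weibull", lam, nu=nu)

    @classmethod
    def gompertz(cls, lam: float, alpha: float) -> "BaselineHazard":
        return cls("gompertz", lam, alpha=alpha)

    # -- hazard functions --------------------------------------------------

    def hazard(self, t: float) -> float:
        """h0(t): lam; lam*nu*t^(nu-1); lam*exp(alpha*t)."""
        if t < 0:
            raise ValueError(f"t >= 0 required, got {t}")
        if self.family == "exponential":
            return self.lam
        if self.family == "weibull":
            if t == 0 and self.nu < 1:
                raise ValueError("weibull hazard diverges at t=0 for nu < 1")
            return self.lam * self.nu * t ** (self.nu - 1)
        return self.lam * math.exp(self.alpha * t)

    def cumulative_hazard(self, t: float) -> float:
        """H0(t): lam*t; lam*t^nu; (lam/alpha)*(exp(alpha*t)-1)."""
        if t < 0:
            raise ValueError(f"t >= 0 required, got {t}")
        if self.family == "exponential":
            return self.lam * t
        if self.family == "weibull":
            return self.lam * t**self.nu
        if self.alpha == 0.0:
            return self.lam * t
        x = self.alpha * t
        if x > 700.0:  # expm1 overflows; the cumulative hazard is effectively infinite
            return math.inf
        if abs(x) < 1e-250:  # subnormal range: use the analytic alpha -> 0 limit
            return self.lam * t
        return self.lam * math.expm1(x) / self.alpha

    def inverse_cumulative_hazard(self, h: float) -> float:
        """H0^{-1}(h); +inf when h is beyond a saturating total hazard.

        For gompertz with alpha < 0 the total hazard saturates at
        ``lam / -alpha``; any h at or above that bound maps to +inf
        (the never-event sentinel).
        """
        if h < 0:
            raise ValueError(f"h >= 0 required, got {h}")
        if h == math.inf:
            return math.inf
        if self.family == "exponential":
            return h / self.lam
        if self.family == "weibull":
            return (h / self.lam) ** (1.0 / self.nu)
        if self.alpha == 0.0:
            return h / self.lam
        x = self.alpha * h / self.lam
        if x <= -1.0:  # alpha < 0 and h >= lam/-alpha: saturated
            return math.inf
        if abs(x) < 1e-250:  # subnormal range: use the analytic alpha -> 0 limit
            return h / self.lam
        return math.log1p(x) / self.alpha

    def total_hazard_bound(self) -> float:
        """sup_t H0(t): finite only for gompertz with alpha < 0."""
        if self.family == "gompertz" and self.alpha < 0:
            return self.lam / -self.alpha
        return math.inf

    def simulate_invariant_time(self, eta: float, u: float) -> float:
        """Inverse-transform draw under time-invariant covariates.

        ``T = H0^{-1}( -log(u) / exp(eta) )``, the classical generator for
        proportional-hazards event times with linear predictor ``eta``.
        """
        if not (0.0 < u < 1.0):
            raise ValueError(f"u in (0, 1) required, got {u}")
        return self.inverse_cumulative_hazard(-math.log(u) * math.exp(-eta))


# Thin functional aliases mirroring the class surface.

def hazard_at(b: BaselineHazard, t: float) -> float:
    return b.hazard(t)


def cumulative_hazard_at(b: BaselineHazard, t: float) -> float:
    return b.cumulative_hazard(t)


def inverse_cumulative_hazard(b: BaselineHazard, h: float) -> float:
    return b.inverse_cumulative_hazard(h)


def simulate_invariant_time(b: BaselineHazard, eta: float, u: float) -> float:
    return b.simulate_invariant_time(eta, u)
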