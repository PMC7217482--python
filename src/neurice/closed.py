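"""Closed-form voltage statistics for a sealed dendrite of length L.

A single passive cable of length L, sealed (zero axial current) at both
ends, driven everywhere by temporally filtered, spatially white synaptic
noise, has stationary Gaussian voltage fluctuations whose variance and
rate-of-change variance are available in closed form through the boundary
kernel

    C(x, eta) = cosh((L-x) sqrt(eta)/lambda) cosh(x sqrt(eta)/lambda)
                / (sqrt(eta) sinh(L sqrt(eta)/lambda)),

evaluated at eta = 1 and at eta = kappa = 1 + tau_v/tau_s:

    sigma_v^2(x)    = 2 sigma_s^2 (tau_s/tau_v) [C(x,1) - C(x,kappa)]
    sigma_vdot^2(x) = 2 sigma_s^2 / (tau_v tau_s) * C(x,kappa)

The second length constant lambda/sqrt(kappa) shortens the boundary layer
of the derivative variance.  In the semi-infinite limit L/lambda -> inf,
C(0,eta) -> 1/sqrt(eta) and C(L/2,eta) -> 1/(2 sqrt(eta)), giving the
one-dendrite (sealed-end) and two-dendrite (bulk/junction) statistics:

    one dendrite:  sigma_v^2 = 2 sigma_s^2 (tau_s/tau_v) (1 - sqrt(tau_s/(tau_s+tau_v)))
                   sigma_vdot^2 = (2 sigma_s^2/(tau_v tau_s)) sqrt(tau_s/(tau_s+tau_v))
    two dendrites: exactly half of each.

Both are independent of lambda — position enters only through x/lambda in
the finite-L profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .params import DriveParams

__all__ = [
    "ClosedDendriteSpec",
    "VoltageStats",
    "boundary_kernel",
    "variance_profile",
    "dvariance_profile",
    "profile_table",
    "one_dendrite_stats",
    "two_dendrite_stats",
]


@dataclass(frozen=True)
class VoltageStats:
    """The (mean, sigma_v, sigma_vdot) triple at the trigger point.

    This is the sole input to the level-crossing rate formula.  Units:
    mV, mV, mV/ms.
    """

    mean: float
    sigma_v: float
    sigma_vdot: float

    def __post_init__(self) -> None:
        if self.sigma_v <= 0 or self.sigma_vdot <= 0:
            raise InvalidParameterError(
                "sigma_v and sigma_vdot must be positive "
                f"(got {self.sigma_v}, {self.sigma_vdot})"
            )

    @property
    def variance(self) -> float:
        return self.sigma_v ** 2

    @property
    def dvariance(self) -> float:
        return self.sigma_vdot ** 2


@dataclass(frozen=True)
class ClosedDendriteSpec:
    """Finite sealed dendrite with its drive parameters.

    kappa = 1 + tau_v / tau_s is derived once at construction so that all
    formulas share a single definition site.
    """

    L: float        # um
    lam: float      # um
    tau_v: float    # ms
    tau_s: float    # ms
    sigma_s: float  # mV
    kappa: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("L", "lam", "tau_v", "tau_s"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.sigma_s < 0:
            raise InvalidParameterError("sigma_s must be >= 0")
        object.__setattr__(self, "kappa", 1.0 + self.tau_v / self.tau_s)


def boundary_kernel(x, eta: float, spec: ClosedDendriteSpec):
    """Boundary kernel C(x, eta) of the sealed cable.

    Evaluated in log space via exponential-difference forms so that
    arguments L*sqrt(eta)/lambda up to 1e4 and beyond neither overflow nor
    lose the reflection symmetry C(x, eta) = C(L-x, eta).  Accepts scalar
    or array ``x``.
    """
    if eta <= 0:
        raise InvalidParameterError(f"eta must be positive, got {eta}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > spec.L):
        raise InvalidParameterError("x must lie in [0, L]")
    q = math.sqrt(eta) / spec.lam
    a = (spec.L - x) * q
    b = x * q
    Lq = spec.L * q
    # log C = log cosh(a) + log cosh(b) - log sinh(Lq) - 0.5 log eta
    #       = [a + b - Lq] + log1p(e^-2a) + log1p(e^-2b) - log1p(-e^-2Lq) - log 2 ...
    # and a + b == Lq exactly, so the large terms cancel analytically.
    log_c = (np.log1p(np.exp(-2.0 * a)) + np.log1p(np.exp(-2.0 * b))
             - np.log1p(-np.exp(-2.0 * Lq)) - math.log(2.0)
             - 0.5 * math.log(eta))
    out = np.exp(log_c)
    return out if out.ndim else float(out)


def variance_profile(x, spec: ClosedDendriteSpec):
    """Stationary voltage variance sigma_v^2(x) in mV^2."""
    pref = 2.0 * spec.sigma_s ** 2 * spec.tau_s / spec.tau_v
    return pref * (boundary_kernel(x, 1.0, spec)
                   - boundary_kernel(x, spec.kappa, spec))


def dvariance_profile(x, spec: ClosedDendriteSpec):
    """Stationary variance of the voltage rate of change, mV^2/ms^2."""
    pref = 2.0 * spec.sigma_s ** 2 / (spec.tau_v * spec.tau_s)
    return pref * boundary_kernel(x, spec.kappa, spec)


def profile_table(x, spec: ClosedDendriteSpec) -> pd.DataFrame:
    """Columnar (x, variance, dvariance) table for a vector of positions."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return pd.DataFrame({
        "x": x,
        "variance": variance_profile(x, spec),
        "dvariance": dvariance_profile(x, spec),
    })


def _semi_infinite(drive: DriveParams, tau_v: float) -> tuple[float, float]:
    """(sigma_v^2, sigma_vdot^2) at the sealed end of a semi-infinite cable."""
    if tau_v <= 0:
        raise InvalidParameterError("tau_v must be positive")
    root = math.sqrt(drive.tau_s / (drive.tau_s + tau_v))  # = 1/sqrt(kappa)
    var = 2.0 * drive.sigma_s ** 2 * (drive.tau_s / tau_v) * (1.0 - root)
    dvar = 2.0 * drive.sigma_s ** 2 / (tau_v * drive.tau_s) * root
    return var, dvar


def one_dendrite_stats(drive: DriveParams, tau_v: float) -> VoltageStats:
    """Statistics at the sealed end of a single semi-infinite dendrite.

    Independent of the electrotonic length lambda: once L/lambda -> inf,
    no quantity with units of length survives.
    """
    var, dvar = _semi_infinite(drive, tau_v)
    return VoltageStats(mean=drive.mu, sigma_v=math.sqrt(var),
                        sigma_vdot=math.sqrt(dvar))


def two_dendrite_stats(drive: DriveParams, tau_v: float) -> VoltageStats:
    """Statistics at the junction of two identical semi-infinite dendrites.

    Both variances are exactly half the one-dendrite values: the bulk of
    the closed cable instead of its sealed end.
    """
    var, dvar = _semi_infinite(drive, tau_v)
    return VoltageStats(mean=drive.mu, sigma_v=math.sqrt(var / 2.0),
                        sigma_vdot=math.sqrt(dvar / 2.0))
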