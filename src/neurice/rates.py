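"""Rice's level-crossing rate and experiment-level derived quantities.

For a stationary Gaussian process v(t) with mean <v>, standard deviation
sigma_v and rate-of-change standard deviation sigma_vdot, the rate of
positive-going crossings of a level v_th is

    r_uc = (1/2 pi) (sigma_vdot / sigma_v) exp(-(v_th - <v>)^2 / (2 sigma_v^2)).

Because the statistics are those of the *non-resetting* voltage, r_uc
approximates the integrate-and-fire firing rate in the low-rate,
fluctuation-driven regime, where the memory of the previous reset has
faded before the next threshold passage.

Rates are computed internally in kHz (all times are in ms) and reported
in Hz at a single conversion site (``KHZ_TO_HZ``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .closed import VoltageStats, one_dendrite_stats, two_dendrite_stats
from .exceptions import BracketError, InvalidParameterError
from .params import DriveParams, MorphologySpec, with_radius_ratio
from .spectral import SpectrumGrid, stats_from_psd

__all__ = [
    "RateResult",
    "KHZ_TO_HZ",
    "rice_rate",
    "model_rate",
    "deterministic_lif_rate",
    "calibrate_sigma_s",
    "peak_radius_ratio",
    "n_max",
]

KHZ_TO_HZ = 1000.0


@dataclass(frozen=True)
class RateResult:
    """A firing or upcrossing rate with its provenance.

    ``rate`` is in kHz (the internal unit); ``rate_hz`` is the reported
    value.  ``uncertainty_hz`` is present only for simulated rates.
    """

    rate: float
    method: str  # "upcrossing" | "simulation" | "deterministic"
    stats: Optional[VoltageStats] = None
    uncertainty_hz: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise InvalidParameterError("rate must be >= 0")
        if (self.uncertainty_hz is not None) != (self.method == "simulation"):
            raise InvalidParameterError(
                "uncertainty is reported exactly for simulated rates"
            )

    @property
    def rate_hz(self) -> float:
        return self.rate * KHZ_TO_HZ

    def to_record(self) -> dict:
        """JSON-style record of the result."""
        rec = {"rate_hz": self.rate_hz, "method": self.method}
        if self.stats is not None:
            rec.update(mean=self.stats.mean, sigma_v=self.stats.sigma_v,
                       sigma_vdot=self.stats.sigma_vdot)
        if self.uncertainty_hz is not None:
            rec["uncertainty_hz"] = self.uncertainty_hz
        rec.update(self.provenance)
        return rec


def rice_rate(stats: VoltageStats, v_th: float) -> float:
    """Rice's upcrossing rate in kHz.

    Invariant under joint rescaling of (sigma_v, sigma_vdot, v_th - <v>);
    monotone increasing in <v> below threshold.
    """
    return (stats.sigma_vdot / (2.0 * math.pi * stats.sigma_v)
            * math.exp(-(v_th - stats.mean) ** 2 / (2.0 * stats.variance)))


def _closed_form_route(morph: MorphologySpec) -> bool:
    """Morphologies whose trigger statistics have elementary closed forms:
    n identical semi-infinite dendrites at a nominal soma, trigger at the
    junction (sealed end for n = 1)."""
    return (not morph.has_axon and not morph.has_soma
            and morph.threshold.x_th == 0)


def trigger_stats(morph: MorphologySpec, drive: DriveParams,
                  grid: SpectrumGrid | None = None) -> tuple[VoltageStats, str]:
    """(VoltageStats, route) at the trigger point.

    Routes to the closed forms where they exist (the junction variance of
    n identical dendrites is the sealed-end variance divided by n),
    otherwise to PSD quadrature.
    """
    if _closed_form_route(morph):
        n = morph.n_dendrites
        if n == 1:
            return one_dendrite_stats(drive, morph.dendrite.tau), "closed-form"
        if n == 2:
            return two_dendrite_stats(drive, morph.dendrite.tau), "closed-form"
        one = one_dendrite_stats(drive, morph.dendrite.tau)
        return VoltageStats(mean=drive.mu,
                            sigma_v=one.sigma_v / math.sqrt(n),
                            sigma_vdot=one.sigma_vdot / math.sqrt(n)), "closed-form"
    return stats_from_psd(morph, drive, grid=grid), "spectral"


def model_rate(morph: MorphologySpec, drive: DriveParams,
               grid: SpectrumGrid | None = None) -> RateResult:
    """Upcrossing approximation of the firing rate for a morphology."""
    stats, route = trigger_stats(morph, drive, grid=grid)
    r = rice_rate(stats, morph.threshold.v_th)
    return RateResult(rate=r, method="upcrossing", stats=stats,
                      provenance={"route": route})


def deterministic_lif_rate(mean_at_trigger: float, tau_v: float,
                           v_th: float, v_re: float) -> float:
    """Noise-free integrate-and-fire rate in kHz.

    Zero when the stationary mean at the trigger is at or below threshold;
    otherwise the leaky integrate-and-fire charging time from reset to
    threshold sets the period."""
    if mean_at_trigger <= v_th:
        return 0.0
    return 1.0 / (tau_v * math.log((mean_at_trigger - v_re)
                                   / (mean_at_trigger - v_th)))


def calibrate_sigma_s(morph: MorphologySpec, drive: DriveParams,
                      target_hz: float,
                      bracket: tuple[float, float] = (0.1, 10.0),
                      rtol: float = 1e-6,
                      grid: SpectrumGrid | None = None) -> float:
    """Noise amplitude sigma_s at which the upcrossing rate hits a target.

    The rate is strictly monotone in sigma_s in the subthreshold regime,
    so the root is unique.  The bracket expands geometrically (up to 6
    doublings each way) before failing."""
    from dataclasses import replace

    if target_hz <= 0:
        raise InvalidParameterError("target rate must be positive")

    def gap(sigma_s: float) -> float:
        d = replace(drive, sigma_s=sigma_s)
        return model_rate(morph, d, grid=grid).rate_hz - target_hz

    lo, hi = bracket
    f_lo, f_hi = gap(lo), gap(hi)
    for _ in range(6):
        if f_lo < 0 < f_hi:
            break
        if f_lo > 0:
            lo /= 2.0
            f_lo = gap(lo)
        if f_hi < 0:
            hi *= 2.0
            f_hi = gap(hi)
    if not f_lo < 0 < f_hi:
        raise BracketError(
            f"target rate {target_hz} Hz not bracketed on sigma_s in "
            f"[{lo:.3g}, {hi:.3g}] mV"
        )
    root = brentq(gap, lo, hi, xtol=1e-12, rtol=rtol)
    return float(root)


def _quadratic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through the three points around index i."""
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # flat or non-concave triple: keep grid argmax
        return float(x1)
    return float(x1 - 0.5 * (y2 - y0) / denom * (x1 - x0))


def peak_radius_ratio(morph: MorphologySpec, drive: DriveParams,
                      ratios: Optional[Sequence[float]] = None,
                      grid: SpectrumGrid | None = None) -> float:
    """Axon/dendrite radius ratio maximizing the upcrossing rate.

    Scans a fixed grid of ratios (default: 50 points on (0, 1]),
    rebuilding the axon for each one (lambda_alpha = lambda_1
    sqrt(eps * ratio), tau_alpha = eps * tau_1), then refines the argmax
    with a local quadratic fit.  Requires a trigger down the axon
    (x_th > 0): at the junction itself the rate decreases monotonically
    with the ratio and no interior peak exists.
    """
    if morph.threshold.x_th <= 0:
        raise InvalidParameterError(
            "an interior peak requires a trigger at x_th > 0 on the axon"
        )
    scan = (np.asarray(ratios, dtype=float) if ratios is not None
            else np.linspace(0.02, 1.0, 50))
    rates = np.array([
        model_rate(with_radius_ratio(morph, drive, a), drive, grid=grid).rate
        for a in scan
    ])
    i = int(np.argmax(rates))
    if i == 0 or i == len(scan) - 1:
        raise InvalidParameterError(
            "monotone rate profile over the scanned ratios: no interior peak"
        )
    return _quadratic_refine(scan, rates, i)


def n_max(morph: MorphologySpec, drive: DriveParams,
          n_range: Sequence[int] = range(1, 33),
          grid: SpectrumGrid | None = None) -> int:
    """Dendrite count maximizing the upcrossing rate (ties -> smaller n)."""
    from dataclasses import replace

    ns = list(n_range)
    rates = [model_rate(replace(morph, n_dendrites=int(n)), drive,
                        grid=grid).rate for n in ns]
    return int(ns[int(np.argmax(rates))])
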