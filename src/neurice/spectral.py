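"""Frequency-domain voltage statistics at the spike trigger point.

For composite morphologies (dendrite + axon, n dendrites + axon, with or
without a lumped soma) the stationary voltage variance and rate-of-change
variance at the trigger position have no elementary closed form, but are
integrals of the voltage power spectral density

    sigma_v^2    = (1/pi) * int_0^inf S(omega) d omega
    sigma_vdot^2 = (1/pi) * int_0^inf omega^2 S(omega) d omega.

The PSD at a point x_th down the (undriven) axon decomposes as

    S(omega; x_th) = n |f(omega)|^2 exp(-2 x_th Re gamma_a(omega)/lambda_a)
                     * S_end(omega),

where S_end is the sealed-end PSD of a single semi-infinite driven
dendrite, f is the relative input admittance of one dendrite within the
whole neuron, gamma_j(omega) = sqrt(1 + i omega tau_j) is the cable
frequency factor and the exponential is the two-sided spatial attenuation
of fluctuations along the axon.  Each of the n dendrites feeds the
junction independently; sources on one dendrite reach the junction with
transfer proportional to f, and integrating the squared transfer over the
driven half-line reproduces |f|^2 * S_end per dendrite.

Admittance weights follow G_lambda ~ g^2 lambda^3 (the radius is tied to
the conductance at fixed per-area parameters, a ~ g lambda^2), so with
the dendrite carrying the mean synaptic load (g_1/g_alpha = epsilon):

    no soma:  f_n(omega) = W_1 g_1 / (n W_1 g_1 + W_a g_a),
              W_1 = eps^2 lambda_1^3, W_a = lambda_alpha^3
    soma:     f_n0(omega) = rho_1 g_1 / (gamma_0^2 + n rho_1 g_1 + rho_a g_a),
              gamma_0^2 = 1 + i omega tau_0

(g_j shorthand for gamma_j(omega); rho_k = G_lambda_k / G_0).  As
rho_1 -> inf at fixed rho_alpha/rho_1 the soma model converges to the
nominal-soma model.

Quadrature uses Gauss-Legendre panels, geometric up to a cutoff, plus an
inverse-square-root substitution u = omega^(-1/2) that maps the slowly
decaying tail (omega^(-7/2) for S, omega^(-3/2) for omega^2 S) onto a
finite panel where the transformed integrand is smooth, so the tail is
integrated to quadrature accuracy rather than truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .closed import VoltageStats
from .exceptions import (ConvergenceError, InconsistentMorphologyError,
                         UnsupportedMorphologyError)
from .params import DriveParams, MorphologySpec

__all__ = [
    "SpectrumGrid",
    "gamma_factor",
    "rel_admittance",
    "sealed_end_psd",
    "trigger_psd",
    "mean_at_trigger",
    "stats_from_psd",
    "spectrum_table",
]


def gamma_factor(omega, tau: float):
    """Cable frequency factor sqrt(1 + i omega tau), principal branch.

    Re gamma >= 1 for all real omega; gamma(0) = 1; gamma(-omega) is the
    complex conjugate.  ``omega`` in rad/ms, ``tau`` in ms.
    """
    return np.sqrt(1.0 + 1j * np.asarray(omega, dtype=float) * tau)


# ---------------------------------------------------------------------------
# quadrature grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumGrid:
    """Quadrature abscissae/weights over omega in [0, inf).

    ``omega`` beyond ``omega_max`` are the images of the tail substitution
    u = omega^(-1/2); their weights already include the Jacobian, so plain
    weighted sums integrate over the full half-line.
    """

    omega: np.ndarray
    weights: np.ndarray
    omega_max: float
    tail: str = "inverse-sqrt substitution"

    def __post_init__(self) -> None:
        if np.any(self.weights <= 0):
            raise ValueError("quadrature weights must be positive")

    @classmethod
    def build(cls, tau_ref: float = 10.0, omega_max: float = 1e4,
              n_panels: int = 24, n_nodes: int = 48) -> "SpectrumGrid":
        """Geometric Gauss-Legendre panels from ~1e-4/tau_ref to omega_max
        plus the transformed tail panel."""
        edges = np.concatenate([[0.0],
                                np.geomspace(1e-4 / tau_ref, omega_max, n_panels)])
        xg, wg = np.polynomial.legendre.leggauss(n_nodes)
        nodes, wts = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            nodes.append(0.5 * (b - a) * xg + 0.5 * (a + b))
            wts.append(0.5 * (b - a) * wg)
        uc = omega_max ** -0.5
        un = 0.5 * uc * xg + 0.5 * uc
        nodes.append(un ** -2.0)
        wts.append(0.5 * uc * wg * 2.0 * un ** -3.0)
        return cls(omega=np.concatenate(nodes), weights=np.concatenate(wts),
                   omega_max=omega_max)

    def refined(self) -> "SpectrumGrid":
        """Same construction with 1.5x the panels and nodes (error estimation)."""
        return SpectrumGrid.build(omega_max=self.omega_max,
                                  n_panels=36, n_nodes=72)

    def integrate(self, values: np.ndarray) -> float:
        return float(np.dot(self.weights, values))


_DEFAULT_GRID = SpectrumGrid.build()


# ---------------------------------------------------------------------------
# admittance and PSD
# ---------------------------------------------------------------------------

def rel_admittance(morph: MorphologySpec, omega):
    """Relative input admittance f(omega) of one driven dendrite.

    Dispatches on the morphology: a bare (multi-)dendrite neuron gives
    1/n at every frequency, an axon adds its admittance to the
    denominator, and a lumped soma adds gamma_0^2 = 1 + i omega tau_0.
    """
    omega = np.asarray(omega, dtype=float)
    n = morph.n_dendrites
    g1 = gamma_factor(omega, morph.dendrite.tau)
    if morph.has_soma:
        soma = morph.soma
        if morph.has_axon and soma.rho_alpha <= 0:
            raise InconsistentMorphologyError(
                "soma present with an axon requires rho_alpha > 0"
            )
        g0sq = 1.0 + 1j * omega * soma.tau_0
        denom = g0sq + n * soma.rho_1 * g1
        if morph.has_axon:
            denom = denom + soma.rho_alpha * gamma_factor(omega, morph.axon.tau)
        return soma.rho_1 * g1 / denom
    w1 = morph.dendrite.admittance_weight
    denom = n * w1 * g1
    if morph.has_axon:
        denom = denom + morph.axon.admittance_weight * gamma_factor(
            omega, morph.axon.tau)
    return w1 * g1 / denom


def sealed_end_psd(omega, drive: DriveParams, tau_v: float):
    """Two-sided voltage PSD at the sealed end of one driven dendrite.

    S_end(omega) = 2 sigma_s^2 tau_s /
                   [(1 + omega^2 tau_s^2) sqrt(1 + omega^2 tau_v^2) Re gamma_v]

    in mV^2 ms.  S_end(0) = 2 sigma_s^2 tau_s; the high-frequency decay is
    omega^(-7/2), which keeps sigma_vdot finite (colored, not white,
    drive).  Its integrals reproduce the sealed-end closed forms exactly.
    """
    omega = np.asarray(omega, dtype=float)
    re_g = np.real(gamma_factor(omega, tau_v))
    return (2.0 * drive.sigma_s ** 2 * drive.tau_s
            / ((1.0 + omega ** 2 * drive.tau_s ** 2)
               * np.sqrt(1.0 + omega ** 2 * tau_v ** 2) * re_g))


def _check_trigger(morph: MorphologySpec) -> None:
    thr = morph.threshold
    if thr.x_th > 0 and thr.trigger_neurite != "axon":
        raise UnsupportedMorphologyError(
            "trigger points at x_th > 0 are only supported on the axon"
        )


def trigger_psd(morph: MorphologySpec, drive: DriveParams, omega):
    """Voltage PSD at the trigger point of a composite morphology.

    S(omega; x_th) = n |f|^2 exp(-2 x_th Re gamma_a / lambda_a) S_end.
    """
    _check_trigger(morph)
    omega = np.asarray(omega, dtype=float)
    f = rel_admittance(morph, omega)
    S = morph.n_dendrites * np.abs(f) ** 2 * sealed_end_psd(
        omega, drive, morph.dendrite.tau)
    x_th = morph.threshold.x_th
    if x_th > 0:
        ga = gamma_factor(omega, morph.axon.tau)
        S = S * np.exp(-2.0 * x_th * np.real(ga) / morph.axon.lam)
    return S


def mean_at_trigger(morph: MorphologySpec, drive: DriveParams) -> float:
    """Stationary mean voltage at the trigger point, mV above leak.

    n mu f(0) exp(-x_th/lambda_alpha): each dendrite contributes its
    DC-transferred mean, attenuated along the axon.  For a bare
    (multi-)dendrite neuron this reduces to mu.
    """
    _check_trigger(morph)
    f0 = float(np.real(rel_admittance(morph, 0.0)))
    mean = morph.n_dendrites * drive.mu * f0
    if morph.threshold.x_th > 0:
        mean *= math.exp(-morph.threshold.x_th / morph.axon.lam)
    return mean


def stats_from_psd(morph: MorphologySpec, drive: DriveParams,
                   grid: SpectrumGrid | None = None,
                   tol: float = 1e-8) -> VoltageStats:
    """Voltage statistics at the trigger point by PSD quadrature.

    Integrates S and omega^2 S over the default (or supplied) grid and a
    refined grid; if the two disagree by more than ``tol`` relative the
    quadrature has not converged and a ConvergenceError is raised.
    """
    grid = grid if grid is not None else _DEFAULT_GRID
    fine = grid.refined()
    results = []
    for g in (grid, fine):
        S = trigger_psd(morph, drive, g.omega)
        results.append((g.integrate(S) / math.pi,
                        g.integrate(g.omega ** 2 * S) / math.pi))
    (v_c, dv_c), (v_f, dv_f) = results
    err = max(abs(v_f - v_c) / abs(v_f), abs(dv_f - dv_c) / abs(dv_f))
    if err > tol:
        raise ConvergenceError(
            f"PSD quadrature self-estimate {err:.3e} exceeds tol {tol:.1e}"
        )
    return VoltageStats(mean=mean_at_trigger(morph, drive),
                        sigma_v=math.sqrt(v_f), sigma_vdot=math.sqrt(dv_f))


def spectrum_table(morph: MorphologySpec, drive: DriveParams,
                   grid: SpectrumGrid | None = None) -> pd.DataFrame:
    """Columnar (omega, S, omega2S) table for debugging and plotting."""
    grid = grid if grid is not None else _DEFAULT_GRID
    order = np.argsort(grid.omega)
    om = grid.omega[order]
    S = trigger_psd(morph, drive, om)
    return pd.DataFrame({"omega": om, "S": S, "omega2S": om ** 2 * S})
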