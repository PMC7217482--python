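"""Model parameters, derived-parameter relations and morphology validation.

The analytic pipeline is parametrized entirely by ratios and per-neurite
constants: the effective drive (mu, sigma_s, tau_s), the per-neurite
electrotonic constants (lambda, tau), the dendrite-to-axon conductance ratio
epsilon, the axon/dendrite radius ratio and the somatic dominance factors
rho.  Absolute conductances and radii never enter; every formula of the
effective model depends only on these combinations.

Conventions
-----------
* Voltages are measured in mV relative to the leak reversal ``E_L`` (so the
  effective resting potential is ``mu`` and threshold ``v_th`` are small
  positive numbers).
* Times are in ms, lengths in um.  Rates are therefore in kHz internally.
* The dendritic membrane carries the mean synaptic conductance, so its
  total conductance per area relative to leak is ``epsilon``; the axon and
  soma are passive (relative conductance 1).  This makes the passive time
  constant ``tau_alpha = epsilon * tau_1``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from .exceptions import InconsistentMorphologyError, InvalidParameterError

__all__ = [
    "DriveParams",
    "NeuriteSpec",
    "SomaSpec",
    "ThresholdSpec",
    "MorphologySpec",
    "MicroscopicSynapseParams",
    "derive_epsilon",
    "axonal_time_constant",
    "lambda_from_radius_ratio",
    "radius_ratio_from_lambda",
    "rho_alpha_from_rho1",
    "relative_input_conductance",
    "effective_from_microscopic",
    "build_morphology",
    "from_config",
    "to_config",
    "read_config",
    "write_config",
    "CONFIG_KEYS",
]


# ---------------------------------------------------------------------------
# derived-parameter relations
# ---------------------------------------------------------------------------

def derive_epsilon(E_L: float, E_s: float, mu: float) -> float:
    """Total-to-leak conductance ratio epsilon implied by the mean drive.

    epsilon = (E_L - E_s) / (E_L + mu - E_s).  Under the effective model
    this equals g / g_L, the factor by which the mean synaptic conductance
    load scales the membrane conductance of a driven dendrite.

    Raises
    ------
    InvalidParameterError
        If ``mu >= E_s - E_L`` (the denominator changes sign: the mean
        voltage cannot sit at or beyond the synaptic reversal).
    """
    if mu < 0:
        raise InvalidParameterError(f"mu must be non-negative, got {mu}")
    if mu >= E_s - E_L:
        raise InvalidParameterError(
            f"mu={mu} must be below E_s - E_L = {E_s - E_L}"
        )
    return (E_L - E_s) / (E_L + mu - E_s)


def axonal_time_constant(epsilon: float, tau_1: float) -> float:
    """Passive (axonal/somatic) time constant ``epsilon * tau_1``.

    The dendritic time constant ``tau_1`` is shortened by the mean synaptic
    load; an undriven neurite with the same per-area capacitance and leak
    relaxes more slowly by the factor epsilon.
    """
    if epsilon < 1:
        raise InvalidParameterError(f"epsilon must be >= 1, got {epsilon}")
    if tau_1 <= 0:
        raise InvalidParameterError(f"tau_1 must be positive, got {tau_1}")
    return epsilon * tau_1


def lambda_from_radius_ratio(radius_ratio: float, lambda_1: float,
                             epsilon: float) -> float:
    """Axonal length constant from the axon/dendrite radius ratio.

    With equal per-area leak and axial resistivity, lambda ~ sqrt(a / g),
    so ``lambda_alpha = lambda_1 * sqrt(epsilon * radius_ratio)`` (the
    dendrite's conductance is epsilon times the axon's).
    """
    if radius_ratio < 0:
        raise InvalidParameterError("radius_ratio must be >= 0")
    return lambda_1 * math.sqrt(epsilon * radius_ratio)


def radius_ratio_from_lambda(lambda_alpha: float, lambda_1: float,
                             epsilon: float) -> float:
    """Inverse of :func:`lambda_from_radius_ratio`."""
    return lambda_alpha ** 2 / (epsilon * lambda_1 ** 2)


def rho_alpha_from_rho1(rho_1: float, lambda_alpha: float, lambda_1: float,
                        epsilon: float) -> float:
    """Axonal dominance factor from the dendritic one.

    rho_alpha = rho_1 * lambda_alpha^3 / (lambda_1^3 * epsilon^2), i.e. the
    ratio of characteristic input conductances G_lambda of axon and
    dendrite (G_lambda ~ g^2 lambda^3 with radius tied to g lambda^2).
    """
    return rho_1 * lambda_alpha ** 3 / (lambda_1 ** 3 * epsilon ** 2)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriveParams:
    """Effective synaptic drive of a dendrite.

    Parameters
    ----------
    mu : float
        Effective resting potential above leak, mV.
    sigma_s : float
        Synaptic noise amplitude, mV.
    tau_s : float
        Synaptic filter time constant, ms.
    E_L, E_s : float
        Leak and synaptic reversal potentials, mV.
    """

    mu: float
    sigma_s: float
    tau_s: float
    E_L: float = -70.0
    E_s: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_s < 0:
            raise InvalidParameterError(f"sigma_s must be >= 0, got {self.sigma_s}")
        if self.tau_s <= 0:
            raise InvalidParameterError(f"tau_s must be positive, got {self.tau_s}")
        if self.E_s <= self.E_L:
            raise InvalidParameterError("E_s must exceed E_L")
        if not 0 <= self.mu < self.E_s - self.E_L:
            raise InvalidParameterError(
                f"mu={self.mu} must lie in [0, E_s - E_L = {self.E_s - self.E_L})"
            )

    @property
    def epsilon(self) -> float:
        """Conductance ratio implied by the mean drive."""
        return derive_epsilon(self.E_L, self.E_s, self.mu)


@dataclass(frozen=True)
class NeuriteSpec:
    """A single cable: a synaptically driven dendrite or a passive axon.

    ``g_rel`` is the membrane conductance per area relative to leak
    (epsilon for a driven dendrite, exactly 1 for a passive axon);
    ``radius_rel`` is the radius relative to the reference dendrite.
    """

    role: str  # "driven-dendrite" | "passive-axon"
    lam: float  # electrotonic length constant, um
    tau: float  # membrane time constant, ms
    g_rel: float = 1.0
    radius_rel: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ("driven-dendrite", "passive-axon"):
            raise InvalidParameterError(f"unknown neurite role {self.role!r}")
        if self.lam <= 0:
            raise InvalidParameterError(f"lambda must be positive, got {self.lam}")
        if self.tau <= 0:
            raise InvalidParameterError(f"tau must be positive, got {self.tau}")
        if self.g_rel < 1:
            raise InvalidParameterError(f"g_rel must be >= 1, got {self.g_rel}")
        if self.role == "passive-axon" and self.g_rel != 1.0:
            raise InvalidParameterError("a passive axon has g_rel = 1 (leak only)")

    @property
    def admittance_weight(self) -> float:
        """Characteristic input conductance G_lambda ~ g^2 lambda^3 (leak units)."""
        return self.g_rel ** 2 * self.lam ** 3


@dataclass(frozen=True)
class SomaSpec:
    """Lumped somatic load at the junction point."""

    rho_1: float   # dendritic dominance factor G_lambda1 / G_0
    rho_alpha: float  # axonal dominance factor G_lambda_alpha / G_0
    tau_0: float   # somatic time constant, ms

    def __post_init__(self) -> None:
        if self.rho_1 <= 0:
            raise InvalidParameterError(f"rho_1 must be positive, got {self.rho_1}")
        if self.rho_alpha < 0:
            raise InvalidParameterError(f"rho_alpha must be >= 0, got {self.rho_alpha}")
        if self.tau_0 <= 0:
            raise InvalidParameterError(f"tau_0 must be positive, got {self.tau_0}")


@dataclass(frozen=True)
class ThresholdSpec:
    """Integrate-and-fire trigger description."""

    v_th: float = 10.0  # threshold, mV above E_L
    v_re: float = 0.0   # reset, mV above E_L
    x_th: float = 0.0   # trigger position along the trigger neurite, um
    trigger_neurite: str = "dendrite"  # "dendrite" | "axon"

    def __post_init__(self) -> None:
        if self.v_th <= self.v_re:
            raise InvalidParameterError("v_th must exceed v_re")
        if self.x_th < 0:
            raise InvalidParameterError(f"x_th must be >= 0, got {self.x_th}")
        if self.trigger_neurite not in ("dendrite", "axon"):
            raise InvalidParameterError(
                f"unknown trigger neurite {self.trigger_neurite!r}"
            )


@dataclass(frozen=True)
class MorphologySpec:
    """A neuron: n identical driven dendrites, optional axon and soma.

    ``closed_length`` marks the finite closed-dendrite variant (a single
    cable of length L sealed at both ends); all other morphologies treat
    neurites as semi-infinite.
    """

    n_dendrites: int
    dendrite: NeuriteSpec
    threshold: ThresholdSpec
    axon: Optional[NeuriteSpec] = None
    soma: Optional[SomaSpec] = None
    closed_length: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_dendrites < 1:
            raise InvalidParameterError("n_dendrites must be >= 1")
        if self.dendrite.role != "driven-dendrite":
            raise InconsistentMorphologyError("the dendrite field must be a driven-dendrite")
        if self.axon is not None and self.axon.role != "passive-axon":
            raise InconsistentMorphologyError("the axon field must be a passive-axon")
        if self.threshold.trigger_neurite == "axon" and self.axon is None:
            raise InconsistentMorphologyError("trigger on the axon requires an axon")
        if self.closed_length is not None:
            if self.closed_length <= 0:
                raise InvalidParameterError("closed_length must be positive")
            if self.axon is not None or self.soma is not None or self.n_dendrites != 1:
                raise InconsistentMorphologyError(
                    "the closed-dendrite model is a single finite cable"
                )

    @property
    def has_axon(self) -> bool:
        return self.axon is not None

    @property
    def has_soma(self) -> bool:
        return self.soma is not None

    def neurites(self) -> list[NeuriteSpec]:
        """All neurites, dendrites first, axon (if any) last."""
        out = [self.dendrite] * self.n_dendrites
        if self.axon is not None:
            out.append(self.axon)
        return out


@dataclass(frozen=True)
class MicroscopicSynapseParams:
    """Per-synapse biophysical parameters (convenience helper only).

    Units: c_m uF/cm^2 equivalents, g_L conductance per area, gamma_s
    conductance increment per event, rho_dens synapses per area, r_s
    events/ms per synapse, r_a axial resistivity, a radius.  Only ratios
    enter the effective description, so any consistent unit system works.
    """

    c_m: float
    g_L: float
    gamma_s: float
    rho_dens: float
    r_s: float
    r_a: float
    a: float

    def __post_init__(self) -> None:
        for name in ("c_m", "g_L", "gamma_s", "rho_dens", "r_a", "a"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.r_s < 0:
            raise InvalidParameterError("r_s must be >= 0")


# ---------------------------------------------------------------------------
# conductance bookkeeping
# ---------------------------------------------------------------------------

def relative_input_conductance(morph: MorphologySpec,
                               lambda_ref: Optional[float] = None) -> float:
    """Total input conductance in units of one reference driven dendrite.

    G_in = n * G_lambda1 + G_lambda_alpha with G_lambda ~ g^2 lambda^3
    (radius tied to conductance at fixed lambda), normalized by the
    G_lambda of a driven dendrite with length constant ``lambda_ref``
    (default: this morphology's own dendrite).  The conductance-matched
    rescaling lambda_1(n) = lambda_1(1) / n^(1/3) keeps this value fixed.
    """
    g1 = morph.dendrite.g_rel
    ref = (lambda_ref if lambda_ref is not None else morph.dendrite.lam)
    unit = g1 ** 2 * ref ** 3
    total = morph.n_dendrites * morph.dendrite.admittance_weight
    if morph.axon is not None:
        total += morph.axon.admittance_weight
    return total / unit


def effective_from_microscopic(p: MicroscopicSynapseParams, E_s: float,
                               mean_V: float,
                               tau_s: float = 5.0) -> tuple[float, DriveParams]:
    """Map microscopic synaptic parameters to the effective drive.

    Returns the mean synaptic conductance per area
    ``<g_s> = tau_s * gamma_s * r_s * rho_dens`` and the implied effective
    ``DriveParams``.  ``tau_s`` is the synaptic channel closing time.

    The noise amplitude follows from matching the shot-noise variance of
    Poisson arrivals, discretized per membrane patch, to the effective
    synaptic field equation:

        sigma_s = gamma_s (E_s - <V>) / (2 g) * sqrt(rho_dens r_s tau_s / (2 pi a lambda))

    An alternative reading places the factor 2 inside the root
    (``gamma_s / g * sqrt(rho_dens r_s tau_s / (4 pi a lambda))``, a factor
    sqrt(2) larger); the form above is the one consistent with the
    Gaussian approximation of the conductance increments.  This helper is
    a documented convenience: the analytic pipeline is parametrized
    directly by (mu, sigma_s, tau_s) and never depends on it.
    """
    g_s_mean = tau_s * p.gamma_s * p.r_s * p.rho_dens
    g = p.g_L + g_s_mean
    E_L = -70.0
    E_eff = (p.g_L * E_L + g_s_mean * E_s) / g
    mu = E_eff - E_L
    lam = math.sqrt(p.a / (2.0 * g * p.r_a))
    if p.r_s == 0:
        sigma_s = 0.0
    else:
        sigma_s = (p.gamma_s * (E_s - mean_V) / (2.0 * g)
                   * math.sqrt(p.rho_dens * p.r_s * tau_s / (2.0 * math.pi * p.a * lam)))
    return g_s_mean, DriveParams(mu=mu, sigma_s=sigma_s, tau_s=tau_s,
                                 E_L=E_L, E_s=E_s)


# ---------------------------------------------------------------------------
# morphology construction
# ---------------------------------------------------------------------------

def build_morphology(
    mu: float,
    sigma_s: float = 1.0,
    tau_s: float = 5.0,
    tau_1: float = 10.0,
    lambda_1: float = 200.0,
    n: int = 1,
    a_ratio: Optional[float] = None,
    lambda_alpha: Optional[float] = None,
    rho_1: Optional[float] = None,
    tau_0: Optional[float] = None,
    v_th: float = 10.0,
    v_re: float = 0.0,
    x_th: float = 0.0,
    E_L: float = -70.0,
    E_s: float = 0.0,
    closed_length: Optional[float] = None,
) -> tuple[MorphologySpec, DriveParams]:
    """Assemble a validated (MorphologySpec, DriveParams) pair.

    The axon is present when ``a_ratio`` or ``lambda_alpha`` is given and
    positive; its time constant is ``epsilon * tau_1`` and its length
    constant follows from the radius ratio (or vice versa).  A soma is
    present when ``rho_1`` is given; ``rho_alpha`` is derived and
    ``tau_0`` defaults to the axonal time constant.
    """
    drive = DriveParams(mu=mu, sigma_s=sigma_s, tau_s=tau_s, E_L=E_L, E_s=E_s)
    eps = drive.epsilon
    dendrite = NeuriteSpec(role="driven-dendrite", lam=lambda_1, tau=tau_1,
                           g_rel=eps, radius_rel=1.0)

    axon = None
    if a_ratio is not None and lambda_alpha is not None:
        implied = lambda_from_radius_ratio(a_ratio, lambda_1, eps)
        if not math.isclose(implied, lambda_alpha, rel_tol=1e-9, abs_tol=1e-12):
            raise InconsistentMorphologyError(
                f"a_ratio={a_ratio} implies lambda_alpha={implied:.6g}, "
                f"got {lambda_alpha}"
            )
    if a_ratio is None and lambda_alpha is not None:
        a_ratio = radius_ratio_from_lambda(lambda_alpha, lambda_1, eps)
    if a_ratio is not None and a_ratio > 0:
        lam_a = lambda_from_radius_ratio(a_ratio, lambda_1, eps)
        axon = NeuriteSpec(role="passive-axon", lam=lam_a,
                           tau=axonal_time_constant(eps, tau_1),
                           g_rel=1.0, radius_rel=a_ratio)

    soma = None
    if rho_1 is not None:
        rho_a = (rho_alpha_from_rho1(rho_1, axon.lam, lambda_1, eps)
                 if axon is not None else 0.0)
        soma = SomaSpec(rho_1=rho_1, rho_alpha=rho_a,
                        tau_0=tau_0 if tau_0 is not None
                        else axonal_time_constant(eps, tau_1))

    trigger_neurite = "axon" if axon is not None else "dendrite"
    threshold = ThresholdSpec(v_th=v_th, v_re=v_re, x_th=x_th,
                              trigger_neurite=trigger_neurite)
    morph = MorphologySpec(n_dendrites=n, dendrite=dendrite, axon=axon,
                           soma=soma, threshold=threshold,
                           closed_length=closed_length)
    return morph, drive


def with_radius_ratio(morph: MorphologySpec, drive: DriveParams,
                      a_ratio: float) -> MorphologySpec:
    """Return a copy of ``morph`` with the axonal radius ratio replaced.

    ``a_ratio = 0`` removes the axon (and moves the trigger to the
    dendrite at x = 0, the no-axon reference used in relative-rate
    experiments)."""
    eps = drive.epsilon
    if a_ratio == 0:
        thr = replace(morph.threshold, x_th=0.0, trigger_neurite="dendrite")
        soma = morph.soma
        if soma is not None:
            soma = replace(soma, rho_alpha=0.0)
        return replace(morph, axon=None, soma=soma, threshold=thr)
    lam_a = lambda_from_radius_ratio(a_ratio, morph.dendrite.lam, eps)
    axon = NeuriteSpec(role="passive-axon", lam=lam_a,
                       tau=axonal_time_constant(eps, morph.dendrite.tau),
                       g_rel=1.0, radius_rel=a_ratio)
    soma = morph.soma
    if soma is not None:
        soma = replace(soma, rho_alpha=rho_alpha_from_rho1(
            soma.rho_1, lam_a, morph.dendrite.lam, eps))
    thr = replace(morph.threshold, trigger_neurite="axon")
    return replace(morph, axon=axon, soma=soma, threshold=thr)


# ---------------------------------------------------------------------------
# flat key-value config document
# ---------------------------------------------------------------------------

CONFIG_KEYS = ("E_L", "E_s", "mu", "tau_1", "tau_s", "lambda_1",
               "lambda_alpha", "a_ratio", "rho_1", "tau_0", "sigma_s",
               "v_th", "v_re", "x_th", "n", "L")

_LINE = re.compile(r"^\s*([A-Za-z_][A-Za-z0-9_]*)\s*[:=]\s*(\S+)\s*$")


def parse_config(text: str) -> dict:
    """Parse a flat ``key = value`` (or ``key: value``) document."""
    out: dict = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _LINE.match(line)
        if m is None:
            raise InvalidParameterError(f"cannot parse config line {lineno}: {raw!r}")
        key, val = m.group(1), m.group(2)
        if key not in CONFIG_KEYS:
            raise InvalidParameterError(f"unknown parameter key {key!r}")
        out[key] = int(val) if key == "n" else float(val)
    return out


def read_config(path) -> dict:
    with open(path) as fh:
        return parse_config(fh.read())


def to_config(morph: MorphologySpec, drive: DriveParams) -> dict:
    """Flatten a (morphology, drive) pair back to config keys."""
    cfg = {
        "E_L": drive.E_L, "E_s": drive.E_s, "mu": drive.mu,
        "tau_1": morph.dendrite.tau, "tau_s": drive.tau_s,
        "lambda_1": morph.dendrite.lam, "sigma_s": drive.sigma_s,
        "v_th": morph.threshold.v_th, "v_re": morph.threshold.v_re,
        "x_th": morph.threshold.x_th, "n": morph.n_dendrites,
    }
    if morph.axon is not None:
        cfg["lambda_alpha"] = morph.axon.lam
        cfg["a_ratio"] = morph.axon.radius_rel
    if morph.soma is not None:
        cfg["rho_1"] = morph.soma.rho_1
        cfg["tau_0"] = morph.soma.tau_0
    if morph.closed_length is not None:
        cfg["L"] = morph.closed_length
    return cfg


def write_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        for key in CONFIG_KEYS:
            if key in cfg:
                fh.write(f"{key} = {cfg[key]}\n")


def from_config(cfg: Mapping) -> tuple[MorphologySpec, DriveParams]:
    """Build a validated (MorphologySpec, DriveParams) from config keys."""
    kw = dict(cfg)
    L = kw.pop("L", None)
    return build_morphology(
        mu=kw.get("mu", 0.0),
        sigma_s=kw.get("sigma_s", 1.0),
        tau_s=kw.get("tau_s", 5.0),
        tau_1=kw.get("tau_1", 10.0),
        lambda_1=kw.get("lambda_1", 200.0),
        n=int(kw.get("n", 1)),
        a_ratio=kw.get("a_ratio"),
        lambda_alpha=kw.get("lambda_alpha"),
        rho_1=kw.get("rho_1"),
        tau_0=kw.get("tau_0"),
        v_th=kw.get("v_th", 10.0),
        v_re=kw.get("v_re", 0.0),
        x_th=kw.get("x_th", 0.0),
        E_L=kw.get("E_L", -70.0),
        E_s=kw.get("E_s", 0.0),
        closed_length=L,
    )
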