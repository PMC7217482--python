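"""Euler-Maruyama simulator of the stochastic threshold-reset cable model.

The cable equation per neurite,

    tau_v dv/dt = mu - v + lambda^2 d2v/dx2 + s,
    tau_s ds/dt = -s + 2 sigma_s sqrt(lambda tau_s) xi(x, t),

is discretized on a staggered lattice: v and s live at half-integer
positions (k + 1/2) dx, the spatial derivative dv/dx at integer
positions k dx.  One explicit step is

    v_{k+1/2}^{i+1} = v_{k+1/2}^i + (dt/tau_v) [mu - v + (lambda^2/dx)
                      (dxv_{k+1} - dxv_k) + s],
    dxv_k^{i+1}     = (v_{k+1/2}^{i+1} - v_{k-1/2}^{i+1}) / dx,
    s_{k+1/2}^{i+1} = s + (dt/tau_s) [-s + 2 sigma_s
                      sqrt(lambda tau_s/(dx dt)) psi],

with psi an independent standard Gaussian per site and step.  Passive
(axonal) compartments receive no drive.  Sealed ends impose a zero
derivative node; neurites meeting at a nominal soma share one junction
voltage chosen so that the weighted fluxes sum to zero; a lumped soma
advances its own voltage by tau_0 dv0/dt = -v0 + sum_k rho_k lambda_k
dv_k/dx|_0 with the neurite-end voltages continuous with v0.

When the voltage at the trigger node reaches v_th, the whole structure
(including the soma) is reset to v_re; the synaptic field is untouched.
In "no-reset" mode positive-going crossings are counted instead, which is
the direct Monte-Carlo estimate of the upcrossing rate.

Semi-infinite neurites are truncated at L = max(1000 um, 10 lambda) with
a sealed far end; with the default dx = 20 um the boundary sits several
length constants beyond any trigger point.  The stepping kernel is
compiled with numba when available and falls back to a vectorized numpy
path otherwise; both produce identical trajectories for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .closed import VoltageStats
from .exceptions import (InvalidParameterError, MisalignedTriggerError,
                         NumericalBlowupError, StabilityError)
from .params import DriveParams, MorphologySpec, ThresholdSpec

__all__ = [
    "LatticeSpec",
    "LatticeState",
    "SpikeRecord",
    "SimulationResult",
    "build_lattice",
    "init_state",
    "em_step",
    "apply_boundaries",
    "detect_and_reset",
    "run_simulation",
]

_V_SANITY = 1.0e3  # mV; beyond this the scheme has blown up

# junction kinds
_J_NONE, _J_NOMINAL, _J_SOMA = 0, 1, 2


@dataclass(frozen=True)
class LatticeSpec:
    """Discretization of a morphology.

    ``n_nodes`` holds the voltage-node count per neurite (dendrites
    first, axon last); ``junction`` is "none", "nominal" or "soma";
    ``trigger_neurite``/``trigger_node`` locate the monitored voltage
    (``trigger_node = -1`` monitors the junction/soma voltage itself).
    """

    dx: float
    dt: float
    n_nodes: tuple[int, ...]
    junction: str
    trigger_neurite: int
    trigger_node: int
    seed: int = 0

    @property
    def total_nodes(self) -> int:
        return sum(self.n_nodes)


@dataclass
class LatticeState:
    """Discretized fields: v, s at half-integer nodes, dv/dx at integer
    nodes (per-neurite blocks of length n_nodes + 1), soma voltage."""

    v: np.ndarray
    s: np.ndarray
    dxv: np.ndarray
    v0: float = 0.0
    time_index: int = 0

    def copy(self) -> "LatticeState":
        return LatticeState(self.v.copy(), self.s.copy(), self.dxv.copy(),
                            self.v0, self.time_index)


@dataclass(frozen=True)
class SpikeRecord:
    """Spike (or upcrossing) times from one run, all beyond the transient."""

    times: np.ndarray       # ms
    duration: float         # total simulated time, ms
    transient: float        # discarded initial interval, ms

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] <= self.transient):
            raise InvalidParameterError(
                "spike times must be strictly increasing and beyond the transient"
            )

    @property
    def count(self) -> int:
        return int(np.asarray(self.times).size)

    @property
    def effective_time(self) -> float:
        return self.duration - self.transient


@dataclass(frozen=True)
class SimulationResult:
    """Rate and trigger-point moments from one stochastic run.

    ``stats`` holds the measured (mean, sigma_v, sigma_vdot) at the
    trigger; sigma_vdot comes from forward differences of the stored
    trigger voltage and is biased at O(dt) — it is used for oracle
    comparisons only.  Standard errors are batch-means estimates over
    ``n_batches`` equal subdivisions of the post-transient run.
    """

    spikes: SpikeRecord
    rate_hz: float
    rate_se_hz: float
    mode: str
    seed: int
    stats: Optional[VoltageStats] = None
    mean_se: float = 0.0
    var: float = 0.0
    var_se: float = 0.0
    dvar: float = 0.0
    dvar_se: float = 0.0
    node_means: Optional[np.ndarray] = None
    node_vars: Optional[np.ndarray] = None
    trace: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# lattice construction
# ---------------------------------------------------------------------------

def build_lattice(morph: MorphologySpec, dx: float = 20.0, dt: float = 0.02,
                  seed: int = 0, min_length: float = 1000.0) -> LatticeSpec:
    """Discretize a morphology, checking stability and trigger alignment.

    Semi-infinite neurites are truncated at L = max(min_length,
    10 lambda), rounded up to a whole number of steps, with sealed far
    ends.  The trigger position must fall on a voltage node
    ((k + 1/2) dx); x_th = 0 maps to the junction voltage when a junction
    exists and to the first node (x = dx/2) of a sealed-end cable
    otherwise.
    """
    if dx <= 0 or dt <= 0:
        raise InvalidParameterError("dx and dt must be positive")

    neurites = morph.neurites()
    n_nodes = []
    for nr in neurites:
        L = (morph.closed_length if morph.closed_length is not None
             else max(min_length, 10.0 * nr.lam))
        n_nodes.append(int(math.ceil(L / dx - 1e-9)))

    # explicit-scheme stability: the stiffest lattice mode of neurite k
    # decays by 1 - (dt/tau_k)(1 + 4 lambda_k^2/dx^2) per step
    for nr in neurites:
        growth = (dt / nr.tau) * (1.0 + 4.0 * nr.lam ** 2 / dx ** 2)
        if growth >= 2.0:
            raise StabilityError(
                f"dt={dt} exceeds the stability bound for lambda={nr.lam}, "
                f"tau={nr.tau}, dx={dx} (factor {growth:.2f} >= 2)"
            )
    junction = _junction_kind(morph)
    if junction == "soma":
        soma = morph.soma
        rho_lam = soma.rho_1 * morph.n_dendrites * morph.dendrite.lam
        if morph.has_axon:
            rho_lam += soma.rho_alpha * morph.axon.lam
        growth = (dt / soma.tau_0) * (1.0 + 2.0 * rho_lam / dx)
        if growth >= 2.0:
            raise StabilityError(
                f"dt={dt} exceeds the somatic stability bound (factor {growth:.2f})"
            )

    k_trig = (len(neurites) - 1
              if morph.threshold.trigger_neurite == "axon" else 0)
    x_th = morph.threshold.x_th
    if x_th == 0:
        trig_node = -1 if junction != "none" else 0
    else:
        j = round(x_th / dx - 0.5)
        if not math.isclose((j + 0.5) * dx, x_th, rel_tol=0, abs_tol=1e-9 * dx):
            raise MisalignedTriggerError(
                f"x_th={x_th} um is not a voltage node (nodes at (k+1/2)*{dx} um)"
            )
        if not 0 <= j < n_nodes[k_trig]:
            raise MisalignedTriggerError("x_th lies beyond the truncated neurite")
        trig_node = int(j)

    return LatticeSpec(dx=dx, dt=dt, n_nodes=tuple(n_nodes),
                       junction=junction, trigger_neurite=k_trig,
                       trigger_node=trig_node, seed=seed)


def _junction_kind(morph: MorphologySpec) -> str:
    if morph.has_soma:
        return "soma"
    if morph.n_dendrites > 1 or morph.has_axon:
        return "nominal"
    return "none"


@dataclass(frozen=True)
class _SimArrays:
    """Per-neurite coefficient arrays compiled for the stepping kernel."""

    off: np.ndarray        # voltage-node offset per neurite
    nn: np.ndarray         # node count per neurite
    doff: np.ndarray       # derivative-node offset per neurite
    drv: np.ndarray        # noise column offset (-1 for passive)
    dt_tau: np.ndarray
    lam2dx: np.ndarray     # lambda^2 / dx
    mu: np.ndarray
    amp: np.ndarray        # 2 sigma_s sqrt(lambda tau_s / (dx dt))
    wj: np.ndarray         # junction flux weight  lambda G_lambda ~ g^2 lambda^4
    rho_lam: np.ndarray    # rho_k lambda_k (soma flux weights)
    joined: np.ndarray     # 1 if the neurite's x=0 end meets the junction
    jkind: int
    tau0: float
    n_driven: int
    trig_idx: int          # global voltage-node index, or -1 for junction


@lru_cache(maxsize=128)
def _compile(morph: MorphologySpec, drive: DriveParams,
             lattice: LatticeSpec) -> _SimArrays:
    neurites = morph.neurites()
    K = len(neurites)
    nn = np.asarray(lattice.n_nodes, dtype=np.int64)
    off = np.concatenate([[0], np.cumsum(nn)[:-1]]).astype(np.int64)
    doff = off + np.arange(K, dtype=np.int64)  # dxv blocks are nn+1 long
    jkind = {"none": _J_NONE, "nominal": _J_NOMINAL, "soma": _J_SOMA}[lattice.junction]

    dt, dx = lattice.dt, lattice.dx
    dt_tau = np.array([dt / nr.tau for nr in neurites])
    lam2dx = np.array([nr.lam ** 2 / dx for nr in neurites])
    driven = np.array([nr.role == "driven-dendrite" for nr in neurites])
    mu = np.where(driven, drive.mu, 0.0).astype(float)
    amp = np.array([
        2.0 * drive.sigma_s * math.sqrt(nr.lam * drive.tau_s / (dx * dt))
        if d else 0.0
        for nr, d in zip(neurites, driven)
    ])
    drv = np.full(K, -1, dtype=np.int64)
    col = 0
    for k in range(K):
        if driven[k]:
            drv[k] = col
            col += int(nn[k])

    wj = np.array([nr.g_rel ** 2 * nr.lam ** 4 for nr in neurites])
    if morph.has_soma:
        rhos = ([morph.soma.rho_1] * morph.n_dendrites
                + ([morph.soma.rho_alpha] if morph.has_axon else []))
        rho_lam = np.array([r * nr.lam for r, nr in zip(rhos, neurites)])
        tau0 = morph.soma.tau_0
    else:
        rho_lam = np.zeros(K)
        tau0 = 1.0
    joined = np.full(K, 1 if jkind != _J_NONE else 0, dtype=np.int64)

    if lattice.trigger_node < 0:
        trig_idx = -1
    else:
        trig_idx = int(off[lattice.trigger_neurite] + lattice.trigger_node)

    return _SimArrays(off=off, nn=nn, doff=doff, drv=drv, dt_tau=dt_tau,
                      lam2dx=lam2dx, mu=mu, amp=amp, wj=wj, rho_lam=rho_lam,
                      joined=joined, jkind=jkind, tau0=tau0,
                      n_driven=col, trig_idx=trig_idx)


def init_state(lattice: LatticeSpec) -> LatticeState:
    nv = lattice.total_nodes
    nd = nv + len(lattice.n_nodes)
    return LatticeState(v=np.zeros(nv), s=np.zeros(nv), dxv=np.zeros(nd))


# ---------------------------------------------------------------------------
# reference (numpy) single step
# ---------------------------------------------------------------------------

def _junction_voltage(v: np.ndarray, arr: _SimArrays) -> float:
    num = den = 0.0
    for k in range(len(arr.off)):
        if arr.joined[k]:
            num += arr.wj[k] * v[arr.off[k]]
            den += arr.wj[k]
    return num / den if den > 0 else 0.0


def apply_boundaries(state: LatticeState, lattice: LatticeSpec,
                     morph: MorphologySpec, drive: DriveParams,
                     advance_soma: bool = False) -> LatticeState:
    """Impose boundary/junction conditions on the derivative field.

    Recomputes dv/dx from the current voltage field: sealed ends get a
    zero derivative node; joined ends share the junction voltage (the
    flux-weighted average for a nominal soma, the somatic voltage for a
    lumped soma).  With ``advance_soma`` the somatic ODE is stepped first
    using the pre-update fluxes, as in the full scheme.
    """
    arr = _compile(morph, drive, lattice)
    out = state.copy()
    if arr.jkind == _J_SOMA and advance_soma:
        flux = sum(arr.rho_lam[k] * state.dxv[arr.doff[k]]
                   for k in range(len(arr.off)))
        out.v0 = state.v0 + (lattice.dt / arr.tau0) * (-state.v0 + flux)
    _recompute_dxv(out, arr, lattice.dx)
    return out


def _recompute_dxv(state: LatticeState, arr: _SimArrays, dx: float) -> None:
    if arr.jkind == _J_NOMINAL:
        vJ = _junction_voltage(state.v, arr)
    elif arr.jkind == _J_SOMA:
        vJ = state.v0
    else:
        vJ = 0.0
    for k in range(len(arr.off)):
        o, d, n = arr.off[k], arr.doff[k], arr.nn[k]
        state.dxv[d] = 2.0 * (state.v[o] - vJ) / dx if arr.joined[k] else 0.0
        state.dxv[d + 1:d + n] = np.diff(state.v[o:o + n]) / dx
        state.dxv[d + n] = 0.0


def em_step(state: LatticeState, lattice: LatticeSpec, morph: MorphologySpec,
            drive: DriveParams, noise: Optional[np.ndarray] = None,
            rng: Optional[np.random.Generator] = None) -> LatticeState:
    """One explicit Euler-Maruyama step (reference implementation).

    ``noise`` supplies the standard-normal draws for the driven sites (one
    per site); if absent they are drawn from ``rng``.  Raises
    NumericalBlowupError if any voltage leaves +-1e3 mV.
    """
    arr = _compile(morph, drive, lattice)
    if noise is None:
        rng = rng if rng is not None else np.random.default_rng(lattice.seed)
        noise = rng.standard_normal(arr.n_driven)
    out = state.copy()
    # voltage update from the old derivative and synaptic fields
    for k in range(len(arr.off)):
        o, d, n = arr.off[k], arr.doff[k], arr.nn[k]
        lap = arr.lam2dx[k] * np.diff(state.dxv[d:d + n + 1])
        out.v[o:o + n] = state.v[o:o + n] + arr.dt_tau[k] * (
            arr.mu[k] - state.v[o:o + n] + lap + state.s[o:o + n])
    # somatic ODE (explicit, pre-update fluxes), then boundary conditions
    if arr.jkind == _J_SOMA:
        flux = sum(arr.rho_lam[k] * state.dxv[arr.doff[k]]
                   for k in range(len(arr.off)))
        out.v0 = state.v0 + (lattice.dt / arr.tau0) * (-state.v0 + flux)
    _recompute_dxv(out, arr, lattice.dx)
    # synaptic field update
    dt_ts = lattice.dt / drive.tau_s
    for k in range(len(arr.off)):
        if arr.drv[k] >= 0:
            o, n, c = arr.off[k], arr.nn[k], arr.drv[k]
            out.s[o:o + n] = state.s[o:o + n] + dt_ts * (
                -state.s[o:o + n] + arr.amp[k] * noise[c:c + n])
    out.time_index = state.time_index + 1
    if np.any(np.abs(out.v) > _V_SANITY):
        raise NumericalBlowupError("voltage exceeded 1e3 mV")
    return out


def detect_and_reset(state: LatticeState, lattice: LatticeSpec,
                     morph: MorphologySpec, drive: DriveParams,
                     threshold: Optional[ThresholdSpec] = None
                     ) -> tuple[LatticeState, bool]:
    """Threshold test at the trigger; on a spike, reset every voltage
    (including the soma) to v_re, leaving the synaptic field untouched."""
    thr = threshold if threshold is not None else morph.threshold
    arr = _compile(morph, drive, lattice)
    vm = _monitored(state, arr)
    if vm < thr.v_th:
        return state, False
    out = state.copy()
    out.v[:] = thr.v_re
    out.v0 = thr.v_re
    _recompute_dxv(out, arr, lattice.dx)
    return out, True


def _monitored(state: LatticeState, arr: _SimArrays) -> float:
    if arr.trig_idx >= 0:
        return float(state.v[arr.trig_idx])
    if arr.jkind == _J_SOMA:
        return state.v0
    return _junction_voltage(state.v, arr)


# ---------------------------------------------------------------------------
# compiled chunk kernel
# ---------------------------------------------------------------------------

def _kernel_impl(v, s, dxv, v0, vn, noise, spikes, trace, sel, sel_sum,
                 sel_sumsq, off, nn, doff, drv, dt_tau, lam2dx, mu, amp, wj,
                 rho_lam, joined, dx, dt, tau_s, tau0, jkind, trig_idx,
                 v_th, v_re, do_reset):
    K = off.shape[0]
    chunk = noise.shape[0]
    nsp = 0
    wsum = 0.0
    for k in range(K):
        if joined[k] == 1:
            wsum += wj[k]
    dt_ts = dt / tau_s
    for i in range(chunk):
        for k in range(K):
            o = off[k]
            d = doff[k]
            for j in range(nn[k]):
                lap = lam2dx[k] * (dxv[d + j + 1] - dxv[d + j])
                vn[o + j] = v[o + j] + dt_tau[k] * (mu[k] - v[o + j] + lap + s[o + j])
        if jkind == 2:
            flux = 0.0
            for k in range(K):
                flux += rho_lam[k] * dxv[doff[k]]
            v0[0] = v0[0] + (dt / tau0) * (-v0[0] + flux)
        vJ = 0.0
        if jkind == 1:
            acc = 0.0
            for k in range(K):
                if joined[k] == 1:
                    acc += wj[k] * vn[off[k]]
            vJ = acc / wsum
        elif jkind == 2:
            vJ = v0[0]
        for k in range(K):
            o = off[k]
            d = doff[k]
            if joined[k] == 1:
                dxv[d] = 2.0 * (vn[o] - vJ) / dx
            else:
                dxv[d] = 0.0
            for j in range(1, nn[k]):
                dxv[d + j] = (vn[o + j] - vn[o + j - 1]) / dx
            dxv[d + nn[k]] = 0.0
        for k in range(K):
            if drv[k] >= 0:
                o = off[k]
                c = drv[k]
                for j in range(nn[k]):
                    s[o + j] = s[o + j] + dt_ts * (-s[o + j] + amp[k] * noise[i, c + j])
        if trig_idx >= 0:
            vm = vn[trig_idx]
        else:
            vm = vJ
        trace[i] = vm
        if do_reset == 1 and vm >= v_th:
            for q in range(vn.shape[0]):
                vn[q] = v_re
            v0[0] = v_re
            for q in range(dxv.shape[0]):
                dxv[q] = 0.0
            spikes[nsp] = i
            nsp += 1
        for q in range(vn.shape[0]):
            v[q] = vn[q]
        for q in range(sel.shape[0]):
            sel_sum[q] += v[sel[q]]
            sel_sumsq[q] += v[sel[q]] * v[sel[q]]
        if vm > _V_SANITY or vm < -_V_SANITY:
            return nsp, 1
    return nsp, 0


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _kernel = njit(_kernel_impl, cache=False)
except Exception:  # pragma: no cover
    _kernel = _kernel_impl


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def run_simulation(morph: MorphologySpec, drive: DriveParams,
                   lattice: Optional[LatticeSpec] = None,
                   duration: float = 20000.0,
                   mode: str = "reset",
                   transient: Optional[float] = None,
                   seed: Optional[int] = None,
                   n_batches: int = 20,
                   chunk_steps: int = 16384,
                   record_nodes: Optional[Sequence[int]] = None,
                   record_trace: bool = False) -> SimulationResult:
    """Simulate the threshold-reset (or free) cable model.

    Parameters
    ----------
    duration : float
        Total simulated time in ms, including the discarded transient
        (default 10 * max time constant).
    mode : str
        "reset": integrate-and-fire with whole-structure reset.
        "no-reset": free process; positive-going crossings of v_th are
        counted instead (the Monte-Carlo upcrossing rate).
    record_nodes : sequence of int, optional
        Global voltage-node indices whose running mean/variance are
        accumulated (e.g. to trace the decay of the mean along the axon).

    Returns the rate with a Poisson-approximate standard error and the
    measured trigger-point moments with batch-means standard errors.
    """
    if mode not in ("reset", "no-reset"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if lattice is None:
        lattice = build_lattice(morph, seed=seed if seed is not None else 0)
    if seed is None:
        seed = lattice.seed
    arr = _compile(morph, drive, lattice)
    taus = [nr.tau for nr in morph.neurites()] + [drive.tau_s]
    if morph.has_soma:
        taus.append(morph.soma.tau_0)
    if transient is None:
        transient = 10.0 * max(taus)
    if duration <= transient:
        raise InvalidParameterError("duration must exceed the transient")

    dt = lattice.dt
    n_total = int(round(duration / dt))
    n_trans = int(round(transient / dt))
    rng = np.random.default_rng(seed)
    state = init_state(lattice)
    v0_arr = np.array([state.v0])
    vn = np.empty_like(state.v)
    spikes_buf = np.empty(chunk_steps, dtype=np.int64)
    trace_buf = np.empty(chunk_steps)
    sel = (np.asarray(record_nodes, dtype=np.int64)
           if record_nodes is not None else np.empty(0, dtype=np.int64))
    sel_sum = np.zeros(sel.size)
    sel_sumsq = np.zeros(sel.size)
    do_reset = 1 if mode == "reset" else 0

    spike_steps: list[int] = []
    traces: list[np.ndarray] = []
    # accumulated post-transient moments
    n_acc = 0
    sum_v = sum_v2 = 0.0
    sum_dv = sum_dv2 = 0.0
    n_dv = 0
    batch_stats: list[tuple[int, float, float, float, float, int]] = []
    prev_vm: Optional[float] = None
    crossings = 0

    step0 = 0
    while step0 < n_total:
        m = min(chunk_steps, n_total - step0)
        noise = rng.standard_normal((m, arr.n_driven))
        nsp, blew = _kernel(
            state.v, state.s, state.dxv, v0_arr, vn, noise, spikes_buf,
            trace_buf, sel, sel_sum, sel_sumsq, arr.off, arr.nn, arr.doff,
            arr.drv, arr.dt_tau, arr.lam2dx, arr.mu, arr.amp, arr.wj,
            arr.rho_lam, arr.joined, lattice.dx, dt, drive.tau_s, arr.tau0,
            arr.jkind, arr.trig_idx, morph.threshold.v_th,
            morph.threshold.v_re, do_reset)
        if blew:
            raise NumericalBlowupError("voltage exceeded 1e3 mV during run")
        tr = trace_buf[:m]
        for q in range(nsp):
            step = step0 + int(spikes_buf[q])
            if step >= n_trans:
                spike_steps.append(step)
        # post-transient accumulation
        lo = max(n_trans - step0, 0)
        if lo < m:
            seg = tr[lo:]
            if do_reset == 0:
                full = (np.concatenate([[prev_vm], seg])
                        if prev_vm is not None else seg)
                crossings += int(np.sum(
                    (full[:-1] < morph.threshold.v_th)
                    & (full[1:] >= morph.threshold.v_th)))
            dv = np.diff(np.concatenate([[prev_vm], seg])
                         if prev_vm is not None else seg) / dt
            prev_vm = float(seg[-1])
            n_acc += seg.size
            sum_v += float(seg.sum())
            sum_v2 += float(seg @ seg)
            n_dv += dv.size
            sum_dv += float(dv.sum())
            sum_dv2 += float(dv @ dv)
            batch_stats.append((seg.size, float(seg.sum()), float(seg @ seg),
                                float((dv * dv).sum()), float(dv.sum()),
                                dv.size))
            if record_trace:
                traces.append(seg.copy())
        step0 += m
    state.v0 = float(v0_arr[0])
    state.time_index = n_total

    eff_time = (n_total - n_trans) * dt
    spike_times = (np.asarray(spike_steps, dtype=float) + 1.0) * dt
    if mode == "reset":
        count = len(spike_steps)
    else:
        count = crossings
        spike_times = np.empty(0)
    rate_khz = count / eff_time
    rate_se_khz = math.sqrt(max(count, 1)) / eff_time

    mean = sum_v / n_acc
    var = sum_v2 / n_acc - mean ** 2
    dvar = sum_dv2 / n_dv - (sum_dv / n_dv) ** 2
    mean_se, var_se, dvar_se = _batch_errors(batch_stats, n_batches)
    stats = None
    if var > 0 and dvar > 0:
        stats = VoltageStats(mean=mean, sigma_v=math.sqrt(var),
                             sigma_vdot=math.sqrt(dvar))
    node_means = node_vars = None
    if sel.size:
        node_means = sel_sum / n_total
        node_vars = sel_sumsq / n_total - node_means ** 2

    return SimulationResult(
        spikes=SpikeRecord(times=spike_times, duration=duration,
                           transient=transient),
        rate_hz=rate_khz * 1000.0, rate_se_hz=rate_se_khz * 1000.0,
        mode=mode, seed=seed, stats=stats, mean_se=mean_se,
        var=var, var_se=var_se, dvar=dvar, dvar_se=dvar_se,
        node_means=node_means, node_vars=node_vars,
        trace=np.concatenate(traces) if record_trace and traces else None)


def _batch_errors(chunks, n_batches: int) -> tuple[float, float, float]:
    """Batch-means standard errors of the mean, variance and derivative
    variance from per-chunk partial sums."""
    if len(chunks) < 2:
        return math.nan, math.nan, math.nan
    n_batches = min(n_batches, len(chunks))
    per_batch = max(len(chunks) // n_batches, 1)
    means, varis, dvaris = [], [], []
    for b in range(0, len(chunks) - per_batch + 1, per_batch):
        grp = chunks[b:b + per_batch]
        n = sum(g[0] for g in grp)
        sv = sum(g[1] for g in grp)
        sv2 = sum(g[2] for g in grp)
        sd2 = sum(g[3] for g in grp)
        sd = sum(g[4] for g in grp)
        nd = sum(g[5] for g in grp)
        m = sv / n
        means.append(m)
        varis.append(sv2 / n - m ** 2)
        if nd > 1:
            dvaris.append(sd2 / nd - (sd / nd) ** 2)
    B = len(means)
    if B < 2:
        return math.nan, math.nan, math.nan
    se = lambda xs: float(np.std(xs, ddof=1) / math.sqrt(len(xs)))
    return se(means), se(varis), se(dvaris) if len(dvaris) >= 2 else math.nan
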