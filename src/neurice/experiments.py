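"""Config-driven parameter sweeps and the scripted figure-style experiments.

Every experiment is a cross-product sweep over Table-style parameter keys
(the flat config vocabulary of :mod:`neurice.params`), evaluated with the
analytic upcrossing engine, the stochastic simulator, or both, and
emitted as a plain CSV plus a JSON run manifest.  Rows are deterministic
in content and order for a given config and seed; analytic rows do not
depend on the seed at all.

``reproduce`` packages the package's standard experiments: sealed-cable
variance profiles, rate-vs-drive curves for the one/two-dendrite models,
electrotonic-length independence, axonal-load and trigger-position
effects, dendrite-number optima, and somatic-load effects, each written
as one CSV per panel.
"""

from __future__ import annotations

import itertools
import json
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .closed import ClosedDendriteSpec, profile_table
from .exceptions import InvalidParameterError
from .params import CONFIG_KEYS, build_morphology, from_config
from .rates import (calibrate_sigma_s, deterministic_lif_rate, model_rate,
                    n_max, peak_radius_ratio)
from .sim import build_lattice, run_simulation
from .spectral import mean_at_trigger

__all__ = ["ExperimentConfig", "run_experiment", "reproduce", "FIGURE_IDS"]

#: baseline parameter values for sweeps (standard in vivo-like drive)
DEFAULTS: dict = {
    "E_L": -70.0, "E_s": 0.0, "mu": 5.0, "tau_1": 10.0, "tau_s": 5.0,
    "lambda_1": 200.0, "sigma_s": 1.0, "v_th": 10.0, "v_re": 0.0,
    "x_th": 0.0, "n": 1,
}

#: publication-scale simulated duration per grid point, ms
PUBLICATION_DURATION_MS = 100_000.0


@dataclass(frozen=True)
class ExperimentConfig:
    """One sweep: a parameter grid over the flat config keys.

    ``scale`` multiplies the publication-scale simulation duration
    (default 0.1, so the full suite runs on one CPU in minutes).
    """

    name: str
    grid: dict = field(default_factory=dict)
    base: dict = field(default_factory=dict)
    engine: str = "analytic"  # "analytic" | "simulation" | "both"
    seed: int = 0
    scale: float = 0.1

    def __post_init__(self) -> None:
        if self.engine not in ("analytic", "simulation", "both"):
            raise InvalidParameterError(f"unknown engine {self.engine!r}")
        if not 0 < self.scale <= 1:
            raise InvalidParameterError("scale must lie in (0, 1]")
        for key in list(self.grid) + list(self.base):
            if key not in CONFIG_KEYS:
                raise InvalidParameterError(f"unknown parameter key {key!r}")


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Evaluate the cross-product sweep, one row per grid point.

    Rows carry the swept inputs, the trigger-point statistics, the rates
    per engine (with simulation uncertainty), and an ``error`` column; a
    failing point is recorded and the sweep continues.
    """
    keys = list(cfg.grid)
    combos = (itertools.product(*(cfg.grid[k] for k in keys))
              if keys else [()])
    rows = []
    for idx, values in enumerate(combos):
        point = dict(zip(keys, values))
        params = {**DEFAULTS, **cfg.base, **point}
        row: dict = {k: params[k] for k in keys}
        try:
            morph, drive = from_config(params)
            if cfg.engine in ("analytic", "both"):
                res = model_rate(morph, drive)
                row.update(
                    mean=res.stats.mean, sigma_v=res.stats.sigma_v,
                    sigma_vdot=res.stats.sigma_vdot,
                    rate_uc_hz=res.rate_hz, route=res.provenance["route"],
                    rate_det_hz=deterministic_lif_rate(
                        mean_at_trigger(morph, drive), morph.dendrite.tau,
                        morph.threshold.v_th, morph.threshold.v_re) * 1000.0,
                )
            if cfg.engine in ("simulation", "both"):
                lat = build_lattice(morph, seed=cfg.seed + idx)
                sim = run_simulation(
                    morph, drive, lat,
                    duration=cfg.scale * PUBLICATION_DURATION_MS,
                    mode="reset", seed=cfg.seed + idx)
                row.update(rate_sim_hz=sim.rate_hz,
                           rate_sim_se_hz=sim.rate_se_hz,
                           var_sim=sim.var, seed=cfg.seed + idx)
            row["error"] = ""
        except Exception as exc:  # per-row failure: record, continue
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        frame = pd.DataFrame(columns=list(cfg.grid) + ["error"])
    return frame


def _write(outdir: Path, name: str, frame: pd.DataFrame,
           manifest: dict) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{name}.csv"
    frame.to_csv(path, index=False)
    mpath = outdir / f"{name}.manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    return path


FIGURE_IDS = ("fig2", "fig3", "fig4", "fig5", "fig6", "fig7")


def reproduce(figure_id: str, outdir, seed: int = 0, scale: float = 0.1,
              engine: str = "analytic") -> list[Path]:
    """Write the data tables behind one of the scripted experiments.

    Returns the list of CSV paths written.  ``engine="both"`` adds
    simulated rates where a panel calls for them (slower).
    """
    outdir = Path(outdir)
    if figure_id not in FIGURE_IDS:
        raise InvalidParameterError(
            f"unknown figure id {figure_id!r}; choose from {FIGURE_IDS}")
    manifest = {"figure": figure_id, "seed": seed, "scale": scale,
                "engine": engine, "version": __version__,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    builder = {
        "fig2": _fig2, "fig3": _fig3, "fig4": _fig4,
        "fig5": _fig5, "fig6": _fig6, "fig7": _fig7,
    }[figure_id]
    written = []
    for name, frame in builder(seed=seed, scale=scale, engine=engine):
        written.append(_write(outdir, name, frame, manifest))
    return written


# ---------------------------------------------------------------------------
# panel builders
# ---------------------------------------------------------------------------

def _fig2(seed, scale, engine):
    """Sealed-cable variance profiles vs lambda and tau_v/tau_s."""
    x = np.linspace(0.0, 1000.0, 101)
    out_a = pd.DataFrame({"x": x})
    for lam in (100.0, 200.0, 400.0):
        spec = ClosedDendriteSpec(L=1000.0, lam=lam, tau_v=10.0, tau_s=5.0,
                                  sigma_s=1.0)
        out_a[f"variance_lambda{lam:g}"] = profile_table(x, spec)["variance"].values
    out_b = pd.DataFrame({"x": x})
    for tau_v in (5.0, 10.0, 20.0):
        spec = ClosedDendriteSpec(L=1000.0, lam=200.0, tau_v=tau_v,
                                  tau_s=5.0, sigma_s=1.0)
        prof = profile_table(x, spec)["variance"].values
        out_b[f"norm_variance_tauv{tau_v:g}"] = prof / prof[0]
    return [("fig2a_profiles", out_a), ("fig2b_normalized", out_b)]


def _fig3(seed, scale, engine):
    """Rate vs mean drive for the one/two-dendrite models."""
    mus = [round(m, 2) for m in np.arange(4.0, 12.01, 0.5)]
    out = []
    for n in (1, 2):
        cfg = ExperimentConfig(
            name=f"fig3_n{n}",
            grid={"mu": mus, "sigma_s": [1.0, 2.0, 3.0]},
            base={"n": n}, engine=engine, seed=seed, scale=scale)
        out.append((cfg.name, run_experiment(cfg)))
    return out


def _fig4(seed, scale, engine):
    """Electrotonic-length independence and matched-variance identity."""
    mus = [round(m, 2) for m in np.arange(4.0, 12.01, 0.5)]
    cfg_a = ExperimentConfig(
        name="fig4a_lambda",
        grid={"mu": mus, "lambda_1": [100.0, 400.0]},
        base={"sigma_s": 1.0}, engine=engine, seed=seed, scale=scale)
    rows = []
    for mu in mus:
        m1, d1 = build_morphology(mu=mu, sigma_s=1.0, n=1)
        m2, d2 = build_morphology(mu=mu, sigma_s=math.sqrt(2.0), n=2)
        rows.append({"mu": mu,
                     "rate_one_hz": model_rate(m1, d1).rate_hz,
                     "rate_two_matched_hz": model_rate(m2, d2).rate_hz})
    return [("fig4a_lambda", run_experiment(cfg_a)),
            ("fig4b_matched", pd.DataFrame(rows))]


def _fig5(seed, scale, engine):
    """Axonal load: relative rate at the junction; peak at x_th = 30 um."""
    ratios = np.linspace(0.0, 1.0, 51)
    rows_a = []
    m0, d0 = build_morphology(mu=5.0, sigma_s=3.0)
    r_sealed = model_rate(m0, d0).rate_hz
    for a in ratios:
        if a == 0:
            rows_a.append({"a_ratio": 0.0, "rate_hz": r_sealed, "relative": 1.0})
            continue
        m, d = build_morphology(mu=5.0, sigma_s=3.0, a_ratio=float(a), x_th=0.0)
        r = model_rate(m, d).rate_hz
        rows_a.append({"a_ratio": float(a), "rate_hz": r,
                       "relative": r / r_sealed})
    rows_b = []
    for mu in (4.0, 5.0, 6.0, 7.0, 8.0):
        morph, drive = build_morphology(mu=mu, sigma_s=3.0, a_ratio=0.3,
                                        x_th=30.0)
        peak = peak_radius_ratio(morph, drive)
        for a in ratios[1:]:
            m, d = build_morphology(mu=mu, sigma_s=3.0, a_ratio=float(a),
                                    x_th=30.0)
            rows_b.append({"mu": mu, "a_ratio": float(a),
                           "rate_hz": model_rate(m, d).rate_hz,
                           "peak_a_ratio": peak})
    return [("fig5a_junction", pd.DataFrame(rows_a)),
            ("fig5b_xth30", pd.DataFrame(rows_b))]


def _fig6(seed, scale, engine):
    """Dendrite number: fixed-lambda_alpha rate curves, n_max map,
    conductance-matched rescaling."""
    out = []
    for lam_a, tag in ((100.0, "fig6a_lam100"), (150.0, "fig6b_lam150")):
        rows = []
        for mu in (8.0, 9.0, 10.0, 11.0):
            for n in range(1, 9):
                m, d = build_morphology(mu=mu, sigma_s=3.0,
                                        lambda_alpha=lam_a, x_th=30.0, n=n)
                rows.append({"mu": mu, "n": n,
                             "rate_hz": model_rate(m, d).rate_hz})
        out.append((tag, pd.DataFrame(rows)))
    rows = []
    for mu in (8.0, 9.0, 10.0, 11.0, 12.0):
        for a in (0.1, 0.2, 0.3, 0.4):
            m, d = build_morphology(mu=mu, sigma_s=3.0, a_ratio=a, x_th=30.0)
            rows.append({"mu": mu, "a_ratio": a,
                         "n_max": n_max(m, d, range(1, 33))})
    out.append(("fig6c_nmax", pd.DataFrame(rows)))
    rows = []
    for n in range(1, 9):
        lam_1 = 200.0 / n ** (1.0 / 3.0)
        m, d = build_morphology(mu=9.0, sigma_s=3.0, lambda_1=lam_1,
                                lambda_alpha=100.0, x_th=30.0, n=n)
        rows.append({"n": n, "lambda_1": lam_1,
                     "rate_hz": model_rate(m, d).rate_hz})
    out.append(("fig6d_matched_conductance", pd.DataFrame(rows)))
    return out


def _fig7(seed, scale, engine):
    """Somatic load: rate vs drive per rho_1, calibrated axonal-load
    ratio, rate vs n, and the n_max map."""
    out = []
    rows = []
    for rho_1 in (1.0, 4.0, 16.0):
        for mu in np.arange(8.0, 12.01, 0.5):
            m, d = build_morphology(mu=float(mu), sigma_s=3.0, a_ratio=0.25,
                                    rho_1=rho_1, x_th=30.0)
            rows.append({"rho_1": rho_1, "mu": float(mu),
                         "rate_hz": model_rate(m, d).rate_hz})
    out.append(("fig7a_soma", pd.DataFrame(rows)))
    rows = []
    for rho_1 in (1.0, 4.0, 16.0):
        m0, d0 = build_morphology(mu=5.0, sigma_s=3.0, rho_1=rho_1, x_th=0.0)
        sig = calibrate_sigma_s(m0, d0, target_hz=1.0)
        d_cal = replace(d0, sigma_s=sig)
        r0 = model_rate(m0, d_cal).rate_hz
        for a in np.linspace(0.0, 0.5, 26):
            if a == 0:
                rows.append({"rho_1": rho_1, "sigma_s": sig, "a_ratio": 0.0,
                             "relative": 1.0})
                continue
            m, d = build_morphology(mu=5.0, sigma_s=sig, a_ratio=float(a),
                                    rho_1=rho_1, x_th=0.0)
            rows.append({"rho_1": rho_1, "sigma_s": sig, "a_ratio": float(a),
                         "relative": model_rate(m, d).rate_hz / r0})
    out.append(("fig7b_calibrated", pd.DataFrame(rows)))
    rows = []
    for rho_1 in (1.0, 4.0, 16.0):
        for n in range(1, 17):
            m, d = build_morphology(mu=12.0, sigma_s=3.0, a_ratio=0.25,
                                    rho_1=rho_1, x_th=30.0, n=n)
            rows.append({"rho_1": rho_1, "n": n,
                         "rate_hz": model_rate(m, d).rate_hz})
    out.append(("fig7c_soma_n", pd.DataFrame(rows)))
    rows = []
    for rho_1 in (1.0, 2.0, 4.0, 8.0, 16.0):
        for mu in (10.0, 11.0, 12.0):
            m, d = build_morphology(mu=mu, sigma_s=3.0, a_ratio=0.25,
                                    rho_1=rho_1, x_th=30.0)
            rows.append({"rho_1": rho_1, "mu": mu,
                         "n_max": n_max(m, d, range(1, 33))})
    out.append(("fig7d_nmax", pd.DataFrame(rows)))
    return out
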