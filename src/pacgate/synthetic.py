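"""Synthetic whole-cell patch-clamp summary datasets.

Generates concentration-response, G-V, current-pH and time-course tables
with the statistical structure the analysis assumes: a smooth generating
model per condition, per-cell amplitude variability (lognormal), a
multiplicative per-point noise term (coefficient of variation), and an
additive baseline term.  Datasets are long-format tables (one row per
cell x point) that are byte-reproducible under a seed, written as CSV with
a '#'-prefixed metadata header so every file is self-describing.

The shipped fixtures are keyed to published summary parameters via
the :data:`pacgate.presets.LEGEND` registry; quantities that the legends do
not print are the package's own synthetic choices and say so in their
provenance notes.  Only summary-level points are generated (no kHz current
waveforms).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import presets
from .equilibrium import EquilibriumParams, dose_response
from .fitting import boltzmann_curve, hill_curve, ph_curve
from .kinetics import (
    Protocol,
    RateSet,
    Segment,
    calibrate_scales,
    rates_from_equilibrium,
    simulate_protocol,
)

__all__ = [
    "NoiseModel",
    "Fixture",
    "FIXTURES",
    "gen_dose_response",
    "gen_gv",
    "gen_ph_curve",
    "gen_timecourse",
    "generate_fixture",
    "write_table",
    "read_table",
]


@dataclass(frozen=True)
class NoiseModel:
    """Noise structure of a synthetic dataset.

    cv : multiplicative Gaussian noise per point (fraction)
    baseline_sd : additive baseline noise, as a fraction of the curve max
    amp_sigma : lognormal sigma of the per-cell amplitude factor
    seed : PRNG seed; identical seeds give identical datasets
    """

    cv: float = 0.10
    baseline_sd: float = 0.02
    amp_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cv, self.baseline_sd, self.amp_sigma) < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(
    rng: np.random.Generator,
    y_true: np.ndarray,
    n_cells: int,
    noise: NoiseModel,
) -> np.ndarray:
    """(n_cells, n_points) noisy replicates of a generating curve."""
    n = len(y_true)
    amp = (
        rng.lognormal(0.0, noise.amp_sigma, size=(n_cells, 1))
        if noise.amp_sigma > 0
        else np.ones((n_cells, 1))
    )
    mult = 1.0 + noise.cv * rng.standard_normal((n_cells, n))
    base = noise.baseline_sd * np.abs(y_true).max() * rng.standard_normal(
        (n_cells, n)
    )
    return amp * y_true[None, :] * mult + base


def _long(x: np.ndarray, xname: str, ys: np.ndarray) -> pd.DataFrame:
    n_cells, n = ys.shape
    return pd.DataFrame(
        {
            "cell": np.repeat(np.arange(1, n_cells + 1), n),
            xname: np.tile(x, n_cells),
            "response": ys.ravel(),
        }
    )


def gen_dose_response(
    truth,
    conc_grid,
    n_cells: int,
    noise: NoiseModel,
    pH: float | None = None,
) -> pd.DataFrame:
    """Noisy concentration-response replicates plus the generating curve.

    ``truth`` is either a dict of Hill parameters
    (``{"x50", "nH", "direction", "bottom", "top"}``) or an
    :class:`EquilibriumParams`, in which case ``pH`` selects the condition
    and the generating curve is the model's normalized dose-response.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    conc_grid = np.asarray(conc_grid, dtype=float)
    if conc_grid.size == 0:
        raise ValueError("empty concentration grid")
    if isinstance(truth, EquilibriumParams):
        if pH is None:
            raise ValueError("pH required for equilibrium-model truth")
        grid = conc_grid if conc_grid[0] == 0 else np.insert(conc_grid, 0, 0.0)
        curve = dose_response(truth, pH, grid, "to_untreated")
        y_true = np.interp(conc_grid, curve.x, curve.y)
    else:
        y_true = hill_curve(
            conc_grid,
            truth["x50"],
            truth["nH"],
            truth.get("bottom", 0.0),
            truth.get("top", 1.0),
            truth.get("direction", "rising"),
        )
    ys = _apply_noise(noise.rng(), y_true, n_cells, noise)
    df = _long(conc_grid, "conc_uM", ys)
    df["truth"] = np.tile(y_true, n_cells)
    return df


def gen_gv(truth, V_grid, n_cells: int, noise: NoiseModel) -> pd.DataFrame:
    """Noisy normalized G-V replicates from Boltzmann ground truth."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    V_grid = np.asarray(V_grid, dtype=float)
    y_true = boltzmann_curve(
        V_grid,
        truth["V_half"],
        truth["K"],
        truth.get("y_max", 1.0),
        truth.get("y_min", 0.0),
    )
    ys = _apply_noise(noise.rng(), y_true, n_cells, noise)
    df = _long(V_grid, "V_mV", ys)
    df["truth"] = np.tile(y_true, n_cells)
    return df


def gen_ph_curve(truth, pH_grid, n_cells: int, noise: NoiseModel) -> pd.DataFrame:
    """Noisy current-pH replicates from pH-equation ground truth."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    pH_grid = np.asarray(pH_grid, dtype=float)
    y_true = ph_curve(
        pH_grid,
        truth["pH50"],
        truth["nH"],
        truth.get("Y0", 0.0),
        truth.get("Y_steady", 1.0),
    )
    ys = _apply_noise(noise.rng(), y_true, n_cells, noise)
    df = _long(pH_grid, "pH", ys)
    df["truth"] = np.tile(y_true, n_cells)
    return df


def gen_line(truth, x_grid, n_cells: int, noise: NoiseModel,
             xname: str = "pH") -> pd.DataFrame:
    """Noisy replicates of a straight line (log-linear current-pH branch)."""
    x_grid = np.asarray(x_grid, dtype=float)
    y_true = truth["intercept"] + truth["slope"] * x_grid
    ys = _apply_noise(noise.rng(), y_true, n_cells, noise)
    df = _long(x_grid, xname, ys)
    df["truth"] = np.tile(y_true, n_cells)
    return df


def gen_timecourse(
    rates: RateSet, protocol: Protocol, noise: NoiseModel
) -> pd.DataFrame:
    """Noisy normalized current time course from a kinetic simulation.

    The deterministic open-state occupancy is sampled on the protocol's
    grid, multiplicative noise is applied, and the trace is normalized to
    time point 0 (so a noise-free trace starts at exactly 1.0).
    """
    trace = simulate_protocol(rates, protocol)
    y = trace.open_occupancy.copy()
    rng = noise.rng()
    y = y * (1.0 + noise.cv * rng.standard_normal(len(y)))
    if abs(y[0]) > 1e-12:
        y = y / y[0]
    return pd.DataFrame(
        {"time_s": trace.time, "response": y, "segment": trace.segment_index}
    )


# ---------------------------------------------------------------------------
# Fixture registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    """A named synthetic dataset whose truth traces to the legend registry."""

    name: str
    kind: str  # dose_response | gv | ph_curve | line | timecourse
    params: dict = field(default_factory=dict)
    provenance: str = ""


def _half_log_grid(lo: float, hi: float, n: int = 8) -> list[float]:
    return list(np.logspace(math.log10(lo), math.log10(hi), n))


def _dose_fixtures() -> dict[str, Fixture]:
    out = {}
    act = presets.LEGEND["activation_potency"]
    for ph in (5.8, 5.6, 5.34):
        ec50, _se, nh, n = act[ph]
        out[f"activation_pH{ph}"] = Fixture(
            f"activation_pH{ph}",
            "dose_response",
            {
                "truth": {"x50": ec50, "nH": nh, "direction": "rising"},
                "conc_grid": _half_log_grid(0.01, 30.0),
                "n_cells": n,
                "noise": {"cv": 0.10, "baseline_sd": 0.0, "amp_sigma": 0.0},
            },
            "activation-branch legend potencies; noise model synthetic",
        )
    inh = presets.LEGEND["inhibition_potency"]
    for ph in (5.8, 5.6, 5.34, 5.0, 4.8, 4.6):
        ic50, _se, nh, n = inh[ph]
        out[f"inhibition_pH{ph}"] = Fixture(
            f"inhibition_pH{ph}",
            "dose_response",
            {
                "truth": {"x50": ic50, "nH": nh, "direction": "falling"},
                "conc_grid": _half_log_grid(0.3, 300.0),
                "n_cells": n,
                "noise": {"cv": 0.10, "baseline_sd": 0.0, "amp_sigma": 0.0},
            },
            "inhibition-branch legend potencies; noise model synthetic",
        )
    return out


def _build_fixtures() -> dict[str, Fixture]:
    fx = _dose_fixtures()
    gv = presets.LEGEND["voltage_gate_wt"]
    fx["gv_wt_pH7.3"] = Fixture(
        "gv_wt_pH7.3",
        "gv",
        {
            "truth": {"V_half": gv["V_half"], "K": gv["K"]},
            "V_grid": gv["V_grid"],
            "n_cells": gv["n"],
            "noise": {"cv": 0.05, "baseline_sd": 0.0, "amp_sigma": 0.0},
        },
        "steady-state G-V parameters at pH 7.3; noise model synthetic",
    )
    s4g = presets.LEGEND["ph_curve_F196A_R237A"]
    fx["ph_F196A_R237A"] = Fixture(
        "ph_F196A_R237A",
        "ph_curve",
        {
            "truth": {
                "pH50": s4g["pH50"],
                "nH": s4g["nH"],
                "Y0": s4g["BOP"],
                "Y_steady": 1.0,
            },
            "pH_grid": list(np.round(np.linspace(7.3, 4.0, 9), 4)),
            "n_cells": s4g["n"],
            "noise": {"cv": 0.03, "baseline_sd": 0.0, "amp_sigma": 0.0},
        },
        "double-mutant pH50/BOP legend values; nH and noise synthetic",
    )
    slopes = presets.LEGEND["ph_loglinear_slopes"]
    for branch, n_pts in (("acidic", 3), ("alkaline", 3)):
        s = slopes[branch]
        lo, hi = s["range"]
        fx[f"slope_{branch}"] = Fixture(
            f"slope_{branch}",
            "line",
            {
                "truth": {
                    "slope": s["slope"],
                    "intercept": 1.0 - s["slope"] * lo,
                },
                "x_grid": list(np.linspace(lo, hi, n_pts)),
                "n_cells": 5,
                "noise": {"cv": 0.05, "baseline_sd": 0.0, "amp_sigma": 0.0},
            },
            "log-linear current-pH slope; anchored to 1 at the acid end "
            "(intercept and noise synthetic)",
        )
    kin = presets.LEGEND["compound_kinetics"]
    fx["washin_pH5.8"] = Fixture(
        "washin_pH5.8",
        "timecourse",
        {
            "pH": 5.8,
            "conc": kin["activation_ph5.8"]["conc"],
            "tau_on": kin["activation_ph5.8"]["tau_on"],
            "duration": 30.0,
            "noise": {"cv": 0.02, "baseline_sd": 0.0, "amp_sigma": 0.0},
        },
        "wash-in activation time constant; rates calibrated to the legend tau",
    )
    fx["washout_pH4.6"] = Fixture(
        "washout_pH4.6",
        "timecourse",
        {
            "pH": 4.6,
            "conc": kin["inhibition_ph4.6"]["conc"],
            "tau_off": kin["inhibition_ph4.6"]["tau_off"],
            "duration": 300.0,
            "noise": {"cv": 0.02, "baseline_sd": 0.0, "amp_sigma": 0.0},
        },
        "post-inhibition washout recovery time constant",
    )
    return fx


FIXTURES: dict[str, Fixture] = _build_fixtures()


def calibrated_rates(
    tau_on: float | None = None,
    tau_off: float | None = None,
) -> RateSet:
    """Wild-type rate set with modulator scales tied to the legend taus.

    The site-1 association rate is pinned by the wash-in relaxation at
    pH 5.8 with 5 uM compound (``tau_on``), the site-2 rate by the
    compound-free recovery after inhibition at pH 4.6 (``tau_off``), using
    the same monoexponential-fit observable the published constants report.
    """
    eq = presets.equilibrium_preset("wt")
    kin = presets.LEGEND["compound_kinetics"]
    act, inh = kin["activation_ph5.8"], kin["inhibition_ph4.6"]
    tau_on = tau_on if tau_on is not None else act["tau_on"]
    tau_off = tau_off if tau_off is not None else inh["tau_off"]
    scales = calibrate_scales(
        eq, tau_on, (5.8, act["conc"]), tau_off, (4.6, inh["conc"])
    )
    return rates_from_equilibrium(eq, scales)


def generate_fixture(name: str, seed: int = 0) -> pd.DataFrame:
    """Generate one registered fixture dataset (deterministic under seed)."""
    try:
        fx = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    p = fx.params
    if fx.kind in ("dose_response", "gv", "ph_curve", "line"):
        noise = NoiseModel(**p["noise"], seed=seed)
    if fx.kind == "dose_response":
        return gen_dose_response(
            p["truth"], p["conc_grid"], p["n_cells"], noise
        )
    if fx.kind == "gv":
        return gen_gv(p["truth"], p["V_grid"], p["n_cells"], noise)
    if fx.kind == "ph_curve":
        return gen_ph_curve(p["truth"], p["pH_grid"], p["n_cells"], noise)
    if fx.kind == "line":
        return gen_line(p["truth"], p["x_grid"], p["n_cells"], noise)
    if fx.kind == "timecourse":
        noise = NoiseModel(**p["noise"], seed=seed)
        rates = calibrated_rates()
        if "tau_on" in p:  # wash-in: equilibrate drug-free, then step drug in
            proto = Protocol(
                [
                    Segment(2.0, p["pH"], 0.0),
                    Segment(p["duration"], p["pH"], p["conc"]),
                ],
                sampling=0.1,
            )
        else:  # washout: equilibrate in drug, then step drug out
            proto = Protocol(
                [
                    Segment(2.0, p["pH"], p["conc"]),
                    Segment(p["duration"], p["pH"], 0.0),
                ],
                sampling=0.5,
            )
        return gen_timecourse(rates, proto, noise)
    raise AssertionError(f"unhandled fixture kind {fx.kind}")


# ---------------------------------------------------------------------------
# Self-describing CSV I/O
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a table as CSV with a '#'-prefixed metadata header block."""
    buf = io.StringIO()
    for k, v in (meta or {}).items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_table`; returns (table, metadata)."""
    meta: dict[str, str] = {}
    lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                lines.append(line)
    df = pd.read_csv(io.StringIO("".join(lines)))
    return df, meta
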