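"""Voltage dependence and current generation.

The channel shows protonation-independent voltage activation that arises
from the permeant ion's interaction with the selectivity filter (ion-flux
gating) rather than from a charged voltage sensor.  This is modelled
phenomenologically as a Boltzmann voltage gate whose voltage axis is
sign-flipped by the orientation of the conducting branch: the anion-selective
wild type is opened by depolarization (chloride influx), the cation-selective
selectivity-filter mutants K319E/K319Q by hyperpolarization (sodium influx),
and K319H carries both branches.  Driving force and rectification of the
open pore follow the Goldman-Hodgkin-Katz constant-field flux equation.

The voltage gate and the chemical (proton/modulator) gate act as parallel
pathways to pore opening, combined as P = 1 - (1 - P_chem)(1 - g_V); their
synergy enters through the protonation dependence of the gate's half-
activation voltage, which slides from its resting value (~ +199 mV at
neutral pH) toward 0 mV as the proton sites load.  Ramp simulation is
quasi-steady-state: the slow activation of the cationic mutants during fast
ramps is not modelled.
"""

from __future__ import annotations


from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .equilibrium import EquilibriumParams, open_probability, protonation_fraction
from . import fitting

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "DEFAULT_TEMPERATURE",
    "IonSpecies",
    "VoltageGateParams",
    "Branch",
    "VariantConfig",
    "ghk_current",
    "voltage_gate",
    "combined_open_fraction",
    "simulate_ramp",
    "ion_substitution",
    "conductance_curve",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446  # J/(mol K)
DEFAULT_TEMPERATURE = 296.0  # K


@dataclass(frozen=True)
class IonSpecies:
    """A permeant species with its transmembrane concentrations (mM)."""

    name: str
    z: int
    permeability: float = 1.0
    conc_in: float = 0.0
    conc_out: float = 0.0

    def __post_init__(self) -> None:
        if self.conc_in < 0 or self.conc_out < 0:
            raise ValueError("concentrations must be >= 0")
        if self.z == 0:
            raise ValueError("permeant species must be charged")


@dataclass(frozen=True)
class VoltageGateParams:
    """Phenomenological ion-flux voltage gate.

    V_half_rest : half-activation voltage of the unprotonated channel (mV)
    V_half_prot : half-activation voltage when fully protonated (mV)
    K_slope : Boltzmann slope factor (mV, > 0)
    orientation : +1 for the anion-conducting (depolarization-activated)
        branch, -1 for the cation-conducting (hyperpolarization-activated)
        branch
    alkaline_attenuation : fractional current loss per pH unit above 7.3,
        reproducing the shallow alkaline limb of the current-pH relation
    """

    V_half_rest: float = 198.7
    V_half_prot: float = 0.0
    K_slope: float = 31.7
    orientation: int = +1
    alkaline_attenuation: float = 0.11

    def __post_init__(self) -> None:
        if not self.K_slope > 0:
            raise ValueError("K_slope must be > 0")
        if self.orientation not in (+1, -1):
            raise ValueError("orientation must be +1 or -1")


def ghk_current(
    species: IonSpecies, V_mV, T: float = DEFAULT_TEMPERATURE
) -> np.ndarray | float:
    """Constant-field (GHK) current of one species; outward positive.

    I = P z^2 (F^2 V / RT) ([S]_i - [S]_o exp(-zFV/RT)) / (1 - exp(-zFV/RT)),
    with the analytic limit P z F ([S]_i - [S]_o) at V = 0.  Current is in
    arbitrary units (permeability absorbs the area/unit conversion).
    """
    V = np.asarray(V_mV, dtype=float) * 1e-3
    z, P = species.z, species.permeability
    ci, co = species.conc_in, species.conc_out
    if ci == 0.0 and co == 0.0:
        out = np.zeros_like(V)
        return float(out) if out.ndim == 0 else out
    u = z * FARADAY * V / (GAS_CONSTANT * T)
    small = np.abs(u) < 1e-6
    with np.errstate(over="ignore", invalid="ignore"):
        e = np.exp(-u)
        denom = np.where(small, 1.0, 1.0 - e)
        # first-order expansion around u = 0: (ci - co) + u (ci + co)/2
        body = np.where(
            small,
            (ci - co) + 0.5 * u * (ci + co),
            u * (ci - co * e) / denom,
        )
    out = P * z * FARADAY * 1e-6 * body
    return float(out) if out.ndim == 0 else out


def voltage_gate(
    params: VoltageGateParams, V_mV, protonation: float, pH: float = 7.3
) -> np.ndarray | float:
    """Open fraction of the ion-flux voltage gate in [0, 1].

    The half-activation voltage interpolates linearly with the protonation
    fraction p between the resting and fully protonated values; the
    orientation sign flips the voltage axis for cation-conducting branches;
    alkalization scales the gate down linearly above pH 7.3.
    """
    if not 0.0 <= protonation <= 1.0:
        raise ValueError("protonation fraction must be in [0, 1]")
    V = np.asarray(V_mV, dtype=float)
    v_half = params.V_half_rest + protonation * (
        params.V_half_prot - params.V_half_rest
    )
    g = 1.0 / (1.0 + np.exp((v_half - params.orientation * V) / params.K_slope))
    scale = max(0.0, 1.0 - params.alkaline_attenuation * max(0.0, pH - 7.3))
    out = g * scale
    return float(out) if out.ndim == 0 else out


def combined_open_fraction(
    eq: EquilibriumParams,
    gate: VoltageGateParams,
    V_mV,
    pH: float,
    conc: float,
) -> np.ndarray | float:
    """Chemical and voltage gating as parallel activation pathways."""
    p_chem = open_probability(eq, pH, conc)
    p = protonation_fraction(eq, pH, conc)
    g = voltage_gate(gate, V_mV, p, pH)
    return 1.0 - (1.0 - p_chem) * (1.0 - g)


@dataclass(frozen=True)
class Branch:
    """One conducting branch: a permeant species and its voltage gate."""

    species: IonSpecies
    gate: VoltageGateParams


@dataclass(frozen=True)
class VariantConfig:
    """A channel variant: equilibrium preset plus conducting branches."""

    name: str
    eq: EquilibriumParams
    branches: tuple[Branch, ...]
    density: float = 1.0  # channel count scale N; 0 for knockout

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.density > 0 and not self.branches:
            raise ValueError("at least one permeant branch required")

    def with_bath(self, name: str, conc_out: float) -> "VariantConfig":
        """Return a copy with one external species concentration replaced."""
        if not any(b.species.name == name for b in self.branches):
            raise KeyError(f"no permeant species {name!r} in this variant")
        new = tuple(
            Branch(replace(b.species, conc_out=conc_out), b.gate)
            if b.species.name == name
            else b
            for b in self.branches
        )
        return replace(self, branches=new)


def simulate_ramp(
    variant: VariantConfig,
    pH: float,
    conc: float = 0.0,
    v_start: float = -195.0,
    v_end: float = 195.0,
    speed_mv_per_ms: float = 0.5,
    T: float = DEFAULT_TEMPERATURE,
) -> pd.DataFrame:
    """Quasi-steady-state I-V sweep over a voltage ramp.

    Returns a frame with time (ms), voltage (mV), per-branch and total
    current (arbitrary units).  I(V) sums N * P_open(V, pH, conc) * GHK
    over conducting branches, with P_open combining the chemical gate and
    each branch's ion-flux voltage gate in parallel.
    """
    if speed_mv_per_ms <= 0:
        raise ValueError("ramp speed must be > 0")
    n_pts = max(int(abs(v_end - v_start) / 1.0) + 1, 2)  # ~1 mV resolution
    V = np.linspace(v_start, v_end, n_pts)
    t_ms = (V - v_start) / speed_mv_per_ms
    out = pd.DataFrame({"time_ms": t_ms, "V_mV": V})
    total = np.zeros_like(V)
    if variant.density > 0:
        p_chem = open_probability(variant.eq, pH, conc)
        p_prot = protonation_fraction(variant.eq, pH, conc)
        for b in variant.branches:
            g = voltage_gate(b.gate, V, p_prot, pH)
            p_open = 1.0 - (1.0 - p_chem) * (1.0 - g)
            i = variant.density * p_open * ghk_current(b.species, V, T)
            out[f"I_{b.species.name}"] = i
            total = total + i
    out["I_total"] = total
    return out


def ion_substitution(
    variant: VariantConfig,
    pH: float,
    species_name: str,
    new_conc_out: float,
    conc: float = 0.0,
    **ramp_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired I-V traces before/after replacing one external species."""
    before = simulate_ramp(variant, pH, conc, **ramp_kwargs)
    after = simulate_ramp(
        variant.with_bath(species_name, new_conc_out), pH, conc, **ramp_kwargs
    )
    return before, after


def conductance_curve(
    V_mV,
    I,
    V_rev: float = 0.0,
    exclusion_mV: float = 5.0,
) -> tuple[pd.DataFrame, "fitting.FitResult"]:
    """G-V relation G = I/(V - V_rev), normalized by the fitted G_max.

    Voltages within ``exclusion_mV`` of the reversal potential are dropped,
    except that when -20 and +20 mV are both sampled the conductance at
    0 mV is estimated as the average of those two values.  Because the
    conductance need not saturate within the sampled range, G_max comes
    from a Boltzmann fit rather than from the data maximum.
    """
    V = np.asarray(V_mV, dtype=float)
    I = np.asarray(I, dtype=float)
    if not (V.min() <= V_rev <= V.max()):
        raise ValueError("V_rev must lie within the sampled voltage range")
    keep = np.abs(V - V_rev) >= exclusion_mV
    v_list = list(V[keep])
    g_list = list(I[keep] / (V[keep] - V_rev))
    has20 = np.any(np.isclose(V, V_rev - 20.0)) and np.any(
        np.isclose(V, V_rev + 20.0)
    )
    if has20:
        g_m = I[np.isclose(V, V_rev - 20.0)][0] / (-20.0)
        g_p = I[np.isclose(V, V_rev + 20.0)][0] / (+20.0)
        v_list.append(V_rev)
        g_list.append(0.5 * (g_m + g_p))
    if not v_list:
        raise ValueError("all voltages excluded around V_rev")
    order = np.argsort(v_list)
    v_arr = np.asarray(v_list)[order]
    g_arr = np.asarray(g_list)[order]
    fit = fitting.fit_boltzmann(v_arr, g_arr)
    g_max = fit.params.get("y_max", g_arr.max()) if fit.params else g_arr.max()
    df = pd.DataFrame({"V_mV": v_arr, "G": g_arr, "G_norm": g_arr / g_max})
    return df, fit
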