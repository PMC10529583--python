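"""End-to-end recovery analyses on synthetic datasets.

Each function generates the synthetic dataset prescribed by the study
conditions (grids, replicate counts and noise levels from the published-value
registry), runs the corresponding fit, and returns the recovered quantity
with its uncertainty.  These are the computations behind the package's
headline numbers; they are deliberately thin compositions of the
synthetic-data generators and the fitting module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fitting, presets, synthetic
from .kinetics import measured_washin_tau, measured_washout_tau

__all__ = [
    "Recovery",
    "pooled_activation_ec50",
    "pooled_inhibition_ic50",
    "gv_boltzmann_recovery",
    "mutant_ph_curve_recovery",
    "washin_time_constant",
    "washout_time_constant",
    "acidic_ph_slope",
    "derive_seeds",
]


@dataclass(frozen=True)
class Recovery:
    """A recovered quantity next to its generating truth."""

    name: str
    value: float
    se: float
    truth: float
    truth_se: float | None
    n: int

    @property
    def error(self) -> float:
        return self.value - self.truth


def derive_seeds(master_seed: int, n: int = 10) -> list[int]:
    """Independent child seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def pooled_activation_ec50(seed: int = 1) -> Recovery:
    """EC50 recovered from pooled synthetic activation curves at pH 5.34.

    16 replicate rising concentration-response curves over 8 half-log
    concentrations (0.01-30 uM) with 10% multiplicative noise, generated
    from the published activation potency, fitted as one pooled Hill curve
    with relative-error weighting (the noise is multiplicative).
    """
    truth, truth_se, _nh, n_cells = presets.LEGEND["activation_potency"][5.34]
    df = synthetic.generate_fixture("activation_pH5.34", seed=seed)
    fit = fitting.fit_hill(
        df["conc_uM"], df["response"], error_model="relative"
    )
    return Recovery(
        "EC50_pH5.34_uM", fit.params["EC50"], fit.se("EC50"),
        truth, truth_se, n_cells,
    )


def pooled_inhibition_ic50(seed: int = 2) -> Recovery:
    """IC50 recovered from pooled synthetic inhibition curves at pH 4.6.

    6 replicate falling curves over 8 half-log concentrations (0.3-300 uM)
    with 10% multiplicative noise, pooled Hill fit as above.
    """
    truth, truth_se, _nh, n_cells = presets.LEGEND["inhibition_potency"][4.6]
    df = synthetic.generate_fixture("inhibition_pH4.6", seed=seed)
    fit = fitting.fit_hill(
        df["conc_uM"], df["response"], error_model="relative"
    )
    return Recovery(
        "IC50_pH4.6_uM", fit.params["IC50"], fit.se("IC50"),
        truth, truth_se, n_cells,
    )


def gv_boltzmann_recovery(seed: int = 3) -> tuple[Recovery, Recovery]:
    """Mean per-cell Boltzmann V1/2 and K from the synthetic wt G-V set.

    9 cells on -100..+200 mV in 20 mV steps with 5% multiplicative noise,
    fitted per cell (as each recording is in practice); the mean and SEM
    across cells are reported.
    """
    gv = presets.LEGEND["voltage_gate_wt"]
    df = synthetic.generate_fixture("gv_wt_pH7.3", seed=seed)
    v_halves, slopes = [], []
    for _, sub in df.groupby("cell"):
        fit = fitting.fit_boltzmann(sub["V_mV"], sub["response"])
        v_halves.append(fit.params["V_half"])
        slopes.append(fit.params["K"])
    n = len(v_halves)
    sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v)))  # noqa: E731
    return (
        Recovery("V_half_mV", float(np.mean(v_halves)), sem(v_halves),
                 gv["V_half"], gv["V_half_se"], n),
        Recovery("K_slope_mV", float(np.mean(slopes)), sem(slopes),
                 gv["K"], gv["K_se"], n),
    )


def mutant_ph_curve_recovery(seed: int = 4) -> tuple[Recovery, Recovery]:
    """Mean per-cell pH50 and basal opening of the double-mutant pH curves.

    7 cells on a 9-point pH grid 7.3-4.0 with 3% multiplicative noise,
    generated from the published pH50/BOP of the activation-site double
    mutant, fitted per cell with the pH-current equation.
    """
    s4 = presets.LEGEND["ph_curve_F196A_R237A"]
    df = synthetic.generate_fixture("ph_F196A_R237A", seed=seed)
    ph50s, bops = [], []
    for _, sub in df.groupby("cell"):
        fit = fitting.fit_ph_curve(sub["pH"], sub["response"])
        ph50s.append(fit.params["pH50"])
        bops.append(fit.params["Y0"])
    n = len(ph50s)
    sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v)))  # noqa: E731
    return (
        Recovery("pH50", float(np.mean(ph50s)), sem(ph50s),
                 s4["pH50"], s4["pH50_se"], n),
        Recovery("BOP", float(np.mean(bops)), sem(bops),
                 s4["BOP"], s4["BOP_se"], n),
    )


def washin_time_constant() -> Recovery:
    """Monoexponential tau of the simulated wash-in at pH 5.8, 5 uM.

    The rate set is calibrated so the fitted wash-in relaxation matches
    the published activation time constant; the 30 s wash-in segment is
    then re-simulated and re-fitted from scratch (deterministic).
    """
    kin = presets.LEGEND["compound_kinetics"]["activation_ph5.8"]
    rates = synthetic.calibrated_rates()
    tau = measured_washin_tau(rates, 5.8, kin["conc"], duration=30.0)
    return Recovery("tau_washin_s", tau, 0.0, kin["tau_on"],
                    kin["tau_on_se"], 1)


def washout_time_constant() -> Recovery:
    """Monoexponential tau of the recovery after inhibition at pH 4.6.

    Inhibition is simulated to steady state at 50 uM, followed by a 300 s
    compound-free washout; the recovering open occupancy is fitted with a
    single exponential (deterministic).
    """
    kin = presets.LEGEND["compound_kinetics"]["inhibition_ph4.6"]
    rates = synthetic.calibrated_rates()
    tau = measured_washout_tau(rates, 4.6, kin["conc"], duration=300.0)
    return Recovery("tau_washout_s", tau, 0.0, kin["tau_off"],
                    kin["tau_off_se"], 1)


def acidic_ph_slope(seed: int = 5) -> Recovery:
    """OLS slope of normalized current vs pH on the acidic branch (5.0-6.0).

    5 cells at 3 pH points with 5% multiplicative noise, generated from the
    published acidic-branch slope, pooled ordinary least squares.
    """
    truth = presets.LEGEND["ph_loglinear_slopes"]["acidic"]["slope"]
    df = synthetic.generate_fixture("slope_acidic", seed=seed)
    fit = fitting.fit_loglinear_slope(df["pH"], df["response"])
    return Recovery(
        "slope_acidic_per_pH", fit.params["slope"], fit.se("slope"),
        truth, None, int(df["cell"].nunique()),
    )
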