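"""Parameter presets and the experimental-value registry.

``LEGEND`` collects the published summary values that parameterize the
synthetic datasets and calibrations (potencies, slope factors, time
constants, Boltzmann parameters); every synthetic fixture traces its
generating truth back to an entry here.  ``equilibrium_preset`` and
``variant`` return frozen parameter sets per channel variant.

The wild-type equilibrium preset was produced by the calibration procedure
in :mod:`pacgate.calibrate` (least squares of the model's apparent EC50s
and IC50s against the published potencies, with a penalty enforcing
monotone inhibition at pH <= 5.0) and then rounded.  Presets for variants
whose parameters are not published numerically (A321C, F196A, D289R) are
qualitative and marked ``synthetic``.
"""

from __future__ import annotations

import json
from dataclasses import asdict

from .equilibrium import EquilibriumParams
from .biophysics import Branch, IonSpecies, VoltageGateParams, VariantConfig

__all__ = [
    "PRESETS_VERSION",
    "LEGEND",
    "BATH",
    "equilibrium_preset",
    "variant",
    "list_variants",
    "presets_json",
]

PRESETS_VERSION = "1"

#: Published summary values, keyed by the quantity they describe.  Each
#: entry carries a ``source`` note saying where the value was reported; entries marked synthetic are this package's own choices.
LEGEND: dict[str, dict] = {
    "activation_potency": {
        # pH -> (EC50 uM, published SE, hill slope, n cells)
        5.8: (2.9, 0.9, 1.6, 19),
        5.6: (1.8, 0.6, 1.9, 8),
        5.34: (0.6, 0.2, 2.1, 16),
        "source": "concentration-response legend, activation branch",
    },
    "inhibition_potency": {
        # pH -> (IC50 uM, published SE, hill slope, n cells)
        5.8: (26.9, 2.6, 1.9, 19),
        5.6: (20.2, 1.5, 2.5, 8),
        5.34: (15.5, 1.1, 2.6, 15),
        5.0: (7.9, 0.5, 2.0, 8),
        4.8: (6.2, 0.8, 1.8, 7),
        4.6: (8.3, 1.0, 1.5, 6),
        "source": "concentration-response legend, inhibition branch",
    },
    "compound_kinetics": {
        # activation/recovery taus at pH 5.8; inhibition/recovery at pH 4.6
        "activation_ph5.8": {
            "tau_on": 4.5, "tau_on_se": 1.3,
            "tau_off": 15.9, "tau_off_se": 2.5, "conc": 5.0,
        },
        "inhibition_ph4.6": {
            "tau_on": 15.9, "tau_on_se": 2.3,
            "tau_off": 82.7, "tau_off_se": 12.9, "conc": 50.0,
        },
        "source": "wash-in/wash-out time-course legend",
    },
    "voltage_gate_wt": {
        "V_half": 198.7,
        "V_half_se": 13.4,
        "K": 31.7,
        "K_se": 3.4,
        "n": 9,
        "V_grid": list(range(-100, 201, 20)),
        "source": "steady-state G-V at pH 7.3",
    },
    "ph_curve_F196A_R237A": {
        "pH50": 5.47,
        "pH50_se": 0.1,
        "BOP": 0.15,
        "BOP_se": 0.02,
        "nH": 1.3,  # synthetic: legend prints no slope for the double mutant
        "n": 7,
        "source": "double-mutant current-pH legend (nH synthetic)",
    },
    "ph_loglinear_slopes": {
        "alkaline": {"slope": -0.22, "range": (7.3, 9.3)},
        "acidic": {"slope": -0.95, "range": (5.0, 6.0)},
        "source": "current-pH linear fits in the two pH ranges",
    },
    "compound_pKa": {
        "pKa": 3.64,
        "source": "computed carboxy-group ionization",
    },
}

#: Recording-solution ion concentrations (mM).  External: NaCl-based bath;
#: internal: CsCl pipette.  Chloride totals include the divalent salts.
BATH = {
    "Cl": {"out": 154.0, "in": 141.0},
    "Na": {"out": 145.0, "in": 0.0},
}

_WT = EquilibriumParams(
    pK_H=5.08, n_H=2.5, L=3.8, K1=24.0, gamma=3.3, phi=5.5, K2=6.3, K2p=6.6
)

_EQ_PRESETS: dict[str, EquilibriumParams] = {
    "wt": _WT,
    # A321C: basally open at pH 7.3 and alkaline-shifted proton gating so
    # the compound is purely inhibitory at 7.3 yet bifunctional at pH 6.2
    # (synthetic quantities).
    "A321C": EquilibriumParams(
        pK_H=5.9, n_H=2.5, L=3.8, K1=24.0, gamma=3.3, phi=5.5,
        K2=6.3, K2p=6.6, L0=0.3,
    ),
    # F196A: activation site 1 destroyed (no coupling/efficacy) with a
    # large basal opening (~39% of the acid-evoked maximum).
    "F196A": EquilibriumParams(
        pK_H=5.08, n_H=2.5, L=3.8, K1=24.0, gamma=1.0, phi=1.0,
        K2=6.3, K2p=6.6, L0=0.447,
    ),
    # F196A/R237A: smaller basal opening; pK_H solved so the model pH curve
    # has pH50 = pK_H + log10((1+L)/(1+L0))/n_H = 5.47 and BOP = 0.15.
    "F196A/R237A": EquilibriumParams(
        pK_H=5.219, n_H=2.5, L=3.8, K1=24.0, gamma=1.0, phi=1.0,
        K2=6.3, K2p=6.6, L0=0.135,
    ),
    # D289R: considerable basal opening without a pH50 shift (synthetic L0).
    "D289R": EquilibriumParams(
        pK_H=5.08, n_H=2.5, L=3.8, K1=24.0, gamma=3.3, phi=5.5,
        K2=6.3, K2p=6.6, L0=0.3,
    ),
}
for _name in ("K319E", "K319Q", "K319H"):
    _EQ_PRESETS[_name] = _WT  # selectivity-filter mutants keep wt proton gating

_ANION_GATE = VoltageGateParams(
    V_half_rest=198.7, V_half_prot=0.0, K_slope=31.7,
    orientation=+1, alkaline_attenuation=0.11,
)
_CATION_GATE = VoltageGateParams(
    V_half_rest=198.7, V_half_prot=0.0, K_slope=31.7,
    orientation=-1, alkaline_attenuation=0.11,
)


def _cl() -> IonSpecies:
    return IonSpecies("Cl", -1, 1.0, BATH["Cl"]["in"], BATH["Cl"]["out"])


def _na() -> IonSpecies:
    return IonSpecies("Na", +1, 1.0, BATH["Na"]["in"], BATH["Na"]["out"])


def equilibrium_preset(name: str) -> EquilibriumParams:
    try:
        return _EQ_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown variant {name!r}; known: {sorted(_EQ_PRESETS)}"
        ) from None


def variant(name: str) -> VariantConfig:
    """Full variant configuration: equilibrium preset + conducting branches."""
    if name == "knockout":
        return VariantConfig("knockout", _WT, (Branch(_cl(), _ANION_GATE),), 0.0)
    eq = equilibrium_preset(name)
    if name in ("K319E", "K319Q"):
        branches = (Branch(_na(), _CATION_GATE),)
    elif name == "K319H":
        branches = (Branch(_cl(), _ANION_GATE), Branch(_na(), _CATION_GATE))
    else:
        branches = (Branch(_cl(), _ANION_GATE),)
    return VariantConfig(name, eq, branches)


def list_variants() -> list[str]:
    return sorted(_EQ_PRESETS) + ["knockout"]


def presets_json() -> str:
    """Versioned JSON dump of all equilibrium presets."""
    return json.dumps(
        {
            "version": PRESETS_VERSION,
            "equilibrium": {k: asdict(v) for k, v in _EQ_PRESETS.items()},
        },
        indent=1,
    )
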