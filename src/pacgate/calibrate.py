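"""Reproducible calibration of the wild-type equilibrium preset.

The preset shipped in :mod:`pacgate.presets` was produced by this
procedure: bounded least squares matching the model's apparent potencies
(EC50 of the ascending limb, IC50 of the descending limb of normalized
dose-response curves) to the published values at each pH, with a penalty
driving the ascending limb to extinction at pH <= 5.0 (where inhibition is
monotone), followed by rounding to two significant decimals.

Run via ``pacgate calibrate`` or :func:`calibrate_wt`.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from . import presets
from .equilibrium import EquilibriumParams, apparent_markers, dose_response

__all__ = ["calibrate_wt", "potency_table"]

_GRID = np.concatenate([[0.0], np.logspace(-3, 3, 121)])


def _markers(p: EquilibriumParams, pH: float):
    return apparent_markers(dose_response(p, pH, _GRID, "to_untreated"))


def _unpack(x) -> EquilibriumParams:
    pK, nH, L, K1, g, f, K2, K2p = x
    return EquilibriumParams(
        pK_H=pK, n_H=nH, L=L, K1=K1, gamma=g, phi=f, K2=K2, K2p=K2p
    )


def calibrate_wt(monotone_weight: float = 30.0) -> EquilibriumParams:
    """Fit the wt preset to the published EC50/IC50 table (unrounded)."""
    ec = {
        ph: v[0]
        for ph, v in presets.LEGEND["activation_potency"].items()
        if isinstance(ph, float)
    }
    ic = {
        ph: v[0]
        for ph, v in presets.LEGEND["inhibition_potency"].items()
        if isinstance(ph, float)
    }

    def resid(x):
        p = _unpack(x)
        r = []
        for ph, t in ec.items():
            m = _markers(p, ph)
            r.append(np.log((m.ec50 or 1e3) / t))
        for ph, t in ic.items():
            m = _markers(p, ph)
            r.append(np.log((m.ic50 or 1e-3) / t))
        for ph in (5.0, 4.8, 4.6):
            m = _markers(p, ph)
            r.append(
                0.0
                if m.ec50 is None
                else monotone_weight * np.log(m.peak_amplitude)
            )
        return np.array(r)

    x0 = np.array([5.3, 2.0, 2.0, 3.0, 4.0, 8.0, 8.0, 25.0])
    lb = np.array([4.8, 1.2, 0.5, 0.3, 1.0, 1.0, 2.0, 5.0])
    ub = np.array([5.7, 3.0, 6.0, 50.0, 40.0, 40.0, 20.0, 80.0])
    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-12)
    return _unpack(sol.x)


def potency_table(p: EquilibriumParams) -> list[dict]:
    """Model EC50/IC50 per pH next to the published values."""
    rows = []
    act = presets.LEGEND["activation_potency"]
    inh = presets.LEGEND["inhibition_potency"]
    for ph in sorted(
        {k for k in act if isinstance(k, float)}
        | {k for k in inh if isinstance(k, float)},
        reverse=True,
    ):
        m = _markers(p, ph)
        rows.append(
            {
                "pH": ph,
                "model_EC50": m.ec50,
                "published_EC50": act.get(ph, (None,))[0],
                "model_IC50": m.ic50,
                "published_IC50": inh.get(ph, (None,))[0],
                "bell": m.is_bell,
            }
        )
    return rows
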