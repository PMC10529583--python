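"""Equilibrium open probability of the 8-state gating scheme.

Each achievable state gets a statistical weight built from an effective
Hill-weighted protonation variable h = 10^(n_H*(pK_H - pH)) and the
modulator occupancies of the activation site (site 1) and the open-channel
block site (site 2):

    w(C0) = 1             w(C1) = h            w(C2) = c1
    w(C3) = h*c1*gamma    w(O1) = h*L          w(O2) = h*c1*gamma*L*phi
    w(C4) = w(O1)*conc/K2 w(C5) = w(O2)*conc/K2p

with c1 = conc/K1.  Site-1 binding both promotes protonation (coupling
factor gamma) and pore opening (efficacy factor phi); this is the minimal
scheme that shifts the pH50 to the alkaline direction without changing the
slope factor.  Open probability is the weight share of the open states.

Variants with constitutive (proton-independent) opening carry an extra
unprotonated-open weight L0, which extends the weight set by four
non-canonical states: O0 = L0, O0s1 = L0*c1 and their blocked
counterparts B0 = L0*conc/K2, B0s1 = L0*c1*conc/K2p.  Site-1 efficacy
(phi) acts only through the proton-gating pathway, so the modulator cannot
activate a basally open channel at neutral pH -- it only blocks it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np

__all__ = [
    "EquilibriumParams",
    "ResponseCurve",
    "Markers",
    "DegenerateNormalizationError",
    "CANONICAL_STATE_ORDER",
    "BASAL_STATE_ORDER",
    "state_weights",
    "open_probability",
    "protonation_fraction",
    "dose_response",
    "ph_response",
    "apparent_markers",
]

#: Canonical deterministic order (binary occupancy code, closed before open).
CANONICAL_STATE_ORDER: tuple[str, ...] = (
    "C0", "C2", "C1", "O1", "C4", "C3", "O2", "C5",
)
#: Extra states appended for basal-open (L0 > 0) variants.
BASAL_STATE_ORDER: tuple[str, ...] = ("O0", "O0s1", "B0", "B0s1")

OPEN_LABELS = frozenset({"O1", "O2", "O0", "O0s1"})
PROTONATED_LABELS = frozenset({"C1", "C3", "O1", "O2", "C4", "C5"})


class DegenerateNormalizationError(ValueError):
    """Raised when a normalization denominator is numerically zero."""


@dataclass(frozen=True)
class EquilibriumParams:
    """Statistical-weight parameters of one channel variant.

    pK_H : effective proton half-occupancy (pH units)
    n_H : effective protonation Hill exponent (dimensionless)
    L : open/closed equilibrium constant of the protonated, drug-free channel
    L0 : unprotonated-open weight (0 for wild type)
    K1 : site-1 dissociation constant (uM, closed unprotonated reference)
    gamma : proton-site1 coupling factor (>= 1 for net coupling)
    phi : site-1 opening efficacy factor
    K2 : site-2 dissociation constant from O1 (uM)
    K2p : site-2 dissociation constant from O2 (uM)
    """

    pK_H: float
    n_H: float
    L: float
    K1: float
    gamma: float
    phi: float
    K2: float
    K2p: float
    L0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pK_H", "n_H", "L", "K1", "gamma", "phi", "K2", "K2p"):
            v = getattr(self, name)
            if not math.isfinite(v) and name not in ("K1", "K2", "K2p"):
                raise ValueError(f"{name} must be finite, got {v}")
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not (math.isfinite(self.L0) and self.L0 >= 0):
            raise ValueError(f"L0 must be finite and >= 0, got {self.L0}")

    @property
    def has_basal_opening(self) -> bool:
        return self.L0 > 0

    def state_order(self) -> tuple[str, ...]:
        if self.has_basal_opening:
            return CANONICAL_STATE_ORDER + BASAL_STATE_ORDER
        return CANONICAL_STATE_ORDER

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EquilibriumParams":
        return cls(**json.loads(text))


def _check_conditions(pH: float, conc: float) -> None:
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if not (0.0 < pH < 14.0):
        raise ValueError(f"pH must lie in (0, 14), got {pH}")


def state_weights(
    params: EquilibriumParams, pH: float, conc: float
) -> dict[str, float]:
    """Unnormalized statistical weight of every state at (pH, conc)."""
    _check_conditions(pH, conc)
    h = 10.0 ** (params.n_H * (params.pK_H - pH))
    c1 = conc / params.K1
    g, f, L = params.gamma, params.phi, params.L
    w = {
        "C0": 1.0,
        "C2": c1,
        "C1": h,
        "O1": h * L,
        "C4": h * L * conc / params.K2,
        "C3": h * c1 * g,
        "O2": h * c1 * g * L * f,
        "C5": h * c1 * g * L * f * conc / params.K2p,
    }
    if params.has_basal_opening:
        w["O0"] = params.L0
        w["O0s1"] = params.L0 * c1
        w["B0"] = params.L0 * conc / params.K2
        w["B0s1"] = params.L0 * c1 * conc / params.K2p
    for k, v in w.items():
        if not math.isfinite(v):
            raise ValueError(f"non-finite weight for state {k}")
    return w


def open_probability(params: EquilibriumParams, pH: float, conc: float) -> float:
    """Equilibrium probability of the conducting (open) states."""
    w = state_weights(params, pH, conc)
    total = sum(w.values())
    return sum(v for k, v in w.items() if k in OPEN_LABELS) / total


def protonation_fraction(
    params: EquilibriumParams, pH: float, conc: float
) -> float:
    """Weight share of site-0-protonated states; feeds the voltage gate."""
    w = state_weights(params, pH, conc)
    total = sum(w.values())
    return sum(v for k, v in w.items() if k in PROTONATED_LABELS) / total


NORMALIZATIONS = ("to_untreated", "to_max_compound", "to_ph46_max", "none")


@dataclass
class ResponseCurve:
    """A normalized response versus concentration or pH."""

    x: np.ndarray
    y: np.ndarray
    normalization: str
    xname: str = "conc"  # "conc" (uM) or "pH"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        dx = np.diff(self.x)
        if len(self.x) > 1 and not (np.all(dx > 0) or np.all(dx < 0)):
            raise ValueError("grid must be strictly monotone")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")


def dose_response(
    params: EquilibriumParams,
    pH: float,
    conc_grid,
    normalization: str = "to_untreated",
) -> ResponseCurve:
    """Open probability across a concentration grid, normalized.

    ``to_untreated`` divides by the drug-free response (grid must start at
    0); ``to_max_compound`` divides by the curve maximum; ``to_ph46_max``
    divides by the drug-free response at pH 4.6 (the saturating acid
    stimulus used to scale weak-acid currents).
    """
    conc_grid = np.asarray(conc_grid, dtype=float)
    if conc_grid.size == 0:
        raise ValueError("empty concentration grid")
    p = np.array([open_probability(params, pH, c) for c in conc_grid])
    if normalization == "to_untreated":
        if conc_grid[0] != 0:
            raise ValueError("to_untreated normalization needs conc_grid[0]=0")
        denom = p[0]
        if denom < 1e-9:
            raise DegenerateNormalizationError(
                "untreated response is ~0; cannot normalize to it"
            )
    elif normalization == "to_max_compound":
        denom = float(np.max(p))
        if denom < 1e-12:
            raise DegenerateNormalizationError("flat zero response")
    elif normalization == "to_ph46_max":
        denom = open_probability(params, 4.6, 0.0)
        if denom < 1e-9:
            raise DegenerateNormalizationError("pH 4.6 reference response ~0")
    elif normalization == "none":
        denom = 1.0
    curve = ResponseCurve(
        conc_grid, p / denom, normalization, "conc", {"pH": pH}
    )
    return curve


def ph_response(
    params: EquilibriumParams,
    conc: float,
    pH_grid,
) -> ResponseCurve:
    """Open probability across a pH grid, normalized to the acidic plateau.

    The plateau is taken analytically far below pK_H at the same modulator
    concentration, so each curve is scaled to its own saturating-acid
    response, as when currents are normalized to the maximal acid-evoked
    current of the same cell.
    """
    pH_grid = np.asarray(pH_grid, dtype=float)
    if pH_grid.size == 0:
        raise ValueError("empty pH grid")
    acid_ref = max(params.pK_H - 6.0 / params.n_H, 0.5)
    denom = open_probability(params, acid_ref, conc)
    if denom < 1e-9:
        raise DegenerateNormalizationError("acidic-plateau response is ~0")
    p = np.array([open_probability(params, x, conc) for x in pH_grid])
    return ResponseCurve(pH_grid, p / denom, "none", "pH", {"conc": conc})


@dataclass
class Markers:
    """Apparent potencies read off a dose-response curve."""

    ec50: float | None
    ic50: float | None
    peak_conc: float | None
    peak_amplitude: float

    @property
    def is_bell(self) -> bool:
        return self.ec50 is not None and self.ic50 is not None


def _crossing(x: np.ndarray, y: np.ndarray, level: float) -> float:
    """First x where y crosses ``level`` (log-x linear interpolation)."""
    for i in range(len(y) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            lx0 = math.log10(max(x[i], 1e-12))
            lx1 = math.log10(max(x[i + 1], 1e-12))
            t = (level - y0) / (y1 - y0)
            return 10.0 ** (lx0 + t * (lx1 - lx0))
    return float("nan")


def apparent_markers(
    curve: ResponseCurve, rel_tol: float = 0.02, n_dense: int = 2001
) -> Markers:
    """EC50/IC50/peak of a dose-response curve by dense log-grid bisection.

    The ascending-limb EC50 is the concentration of half-maximal rise from
    the zero-concentration baseline; the descending-limb IC50 is the
    half-decay point between the peak and the high-concentration tail.
    A limb flatter than ``rel_tol`` (relative to the peak) is "absent".
    """
    if curve.xname != "conc":
        raise ValueError("markers are defined for concentration curves")
    x, y = curve.x, curve.y
    if np.any(np.diff(x) <= 0):
        raise ValueError("concentration grid must be strictly increasing")
    # dense resample on a log grid (keep an exact 0 baseline point if present)
    x_pos = x[x > 0]
    dense_x = np.logspace(
        math.log10(x_pos[0]), math.log10(x_pos[-1]), n_dense
    )
    dense_y = np.interp(np.log10(dense_x), np.log10(x_pos), y[x > 0])
    y_base = y[0]
    i_peak = int(np.argmax(dense_y))
    y_peak = float(dense_y[i_peak])
    y_peak = max(y_peak, y_base)
    peak_conc = float(dense_x[i_peak]) if y_peak > y_base else None

    ec50 = ic50 = None
    if y_peak - y_base > rel_tol * max(y_peak, 1e-12):
        level = 0.5 * (y_base + y_peak)
        ec50 = _crossing(dense_x[: i_peak + 1], dense_y[: i_peak + 1], level)
        ec50 = None if math.isnan(ec50) else ec50
    y_tail = float(dense_y[-1])
    if y_peak - y_tail > rel_tol * max(y_peak, 1e-12):
        level = 0.5 * (y_peak + y_tail)
        seg_x, seg_y = dense_x[i_peak:], dense_y[i_peak:]
        ic50 = _crossing(seg_x, seg_y, level)
        ic50 = None if math.isnan(ic50) else ic50
    if peak_conc is not None and ec50 is None and ic50 is not None:
        peak_conc = None  # pure-inhibition curve: peak is just the baseline
    return Markers(ec50, ic50, peak_conc, y_peak)
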