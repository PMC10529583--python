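"""Curve fitting for patch-clamp summary data.

Implements the parameterizations used throughout the analysis: the Hill
logistic for concentration-response potencies (EC50/IC50), the pH-current
relationship with a basal-opening term, the Boltzmann conductance-voltage
relation, monoexponential relaxations, an ordinary least-squares
current-pH slope, and Henderson-Hasselbalch ionization.

All nonlinear fits use bounded least squares with a small multi-start
(data-driven heuristics), because Hill- and Boltzmann-type objectives are
multimodal under noise.  Standard errors are asymptotic, from the Jacobian
at the optimum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "fit_hill",
    "fit_ph_curve",
    "fit_boltzmann",
    "fit_monoexp",
    "fit_loglinear_slope",
    "ionized_fraction",
    "hill_curve",
    "ph_curve",
    "boltzmann_curve",
]


@dataclass
class FitResult:
    model: str
    params: dict[str, float]
    stderr: dict[str, float]
    rss: float
    converged: bool
    n: int
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return self.params[key]

    def se(self, key: str) -> float:
        return self.stderr.get(key, float("nan"))

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "params": self.params,
                "stderr": self.stderr,
                "rss": self.rss,
                "converged": self.converged,
                "n": self.n,
                "flags": self.flags,
            },
            indent=1,
        )

    def summary(self) -> str:
        terms = "  ".join(
            f"{k}={v:.4g}+/-{self.stderr.get(k, float('nan')):.2g}"
            for k, v in self.params.items()
        )
        tag = "" if self.converged else "  [UNRELIABLE]"
        return f"{self.model}: {terms}  rss={self.rss:.3g}{tag}"


def _lsq_multistart(residual, starts, bounds, names, n_obs, model):
    """Bounded least squares from several starts; asymptotic SEs."""
    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0] + 1e-12, bounds[1] - 1e-12)
        try:
            sol = optimize.least_squares(
                residual, x0, bounds=bounds, xtol=1e-14, ftol=1e-14,
                gtol=1e-14, max_nfev=20000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    flags: list[str] = []
    if best is None:
        return FitResult(model, {}, {}, math.nan, False, n_obs, ["no-fit"])
    rss = float(2 * best.cost)
    dof = max(n_obs - len(names), 1)
    s2 = rss / dof
    try:
        jtj = best.jac.T @ best.jac
        cov = s2 * np.linalg.pinv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except Exception:
        se = np.full(len(names), np.nan)
        flags.append("no-covariance")
    converged = bool(best.success) and np.all(np.isfinite(se))
    if not np.all(np.isfinite(se)) or np.any(
        se > 1e3 * np.maximum(np.abs(best.x), 1e-12)
    ):
        flags.append("unidentifiable")
        converged = False
    params = dict(zip(names, map(float, best.x)))
    stderr = dict(zip(names, map(float, se)))
    return FitResult(model, params, stderr, rss, bool(converged), n_obs, flags)


# ---------------------------------------------------------------------------
# Hill logistic
# ---------------------------------------------------------------------------

def hill_curve(x, x50, nh, bottom=0.0, top=1.0, direction="rising"):
    """Hill logistic; at x=0 returns the zero-concentration asymptote."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        if direction == "rising":
            frac = np.where(x > 0, 1.0 / (1.0 + (x50 / np.maximum(x, 1e-300)) ** nh), 0.0)
        else:
            frac = np.where(x > 0, 1.0 / (1.0 + (np.maximum(x, 1e-300) / x50) ** nh), 1.0)
    return bottom + (top - bottom) * frac


def fit_hill(
    conc,
    response,
    direction: str = "auto",
    fix_bottom: float | None = None,
    error_model: str = "absolute",
):
    """Fit Y = bottom + (top-bottom)/(1 + (X50/X)^nH) (or the falling form).

    Direction (rise/fall) is inferred from the data unless given; the
    half-potency is reported as ``EC50`` (rising) or ``IC50`` (falling).
    Top and bottom are free by default; ``fix_bottom`` pins the bottom.

    ``error_model="relative"`` reweights residuals by the inverse fitted
    response (two-pass), the appropriate estimator when the measurement
    noise is multiplicative, as in normalized whole-cell currents.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if len(np.unique(conc[conc >= 0])) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    span = response.max() - response.min()
    if span < 1e-12 * max(1.0, abs(response.mean())):
        return FitResult("hill", {}, {}, 0.0, False, len(conc), ["degenerate"])
    if direction == "auto":
        pos = conc > 0
        r = stats.spearmanr(np.log(conc[pos]), response[pos]).statistic
        direction = "rising" if r >= 0 else "falling"

    pos = conc > 0
    x_lo, x_hi = conc[pos].min(), conc[pos].max()
    # heuristic X50: concentration nearest the half-crossing
    half = 0.5 * (response.min() + response.max())
    order = np.argsort(conc)
    x50_guess = float(
        np.interp(
            half,
            response[order] if direction == "rising" else response[order][::-1],
            conc[order] if direction == "rising" else conc[order][::-1],
            left=x_lo, right=x_hi,
        )
    )
    x50_guess = min(max(x50_guess, x_lo), x_hi)

    free_bottom = fix_bottom is None
    names = ["x50", "nh", "top"] + (["bottom"] if free_bottom else [])
    weights = np.ones_like(response)

    def residual(theta):
        x50, nh, top = theta[0], theta[1], theta[2]
        bottom = theta[3] if free_bottom else fix_bottom
        return weights * (
            hill_curve(conc, 10.0 ** x50, nh, bottom, top, direction) - response
        )

    lo = [math.log10(x_lo) - 3, 0.2, -np.inf] + ([-np.inf] if free_bottom else [])
    hi = [math.log10(x_hi) + 3, 10.0, np.inf] + ([np.inf] if free_bottom else [])
    y_top = response.max()
    y_bot = response.min()
    starts = [
        np.array([math.log10(x50_guess), nh0, y_top] + ([y_bot] if free_bottom else []))
        for nh0 in (1.0, 2.0, 0.5)
    ]
    res = _lsq_multistart(residual, starts, (np.array(lo), np.array(hi)),
                          names, len(conc), "hill")
    if error_model == "relative" and res.params:
        theta = [res.params["x50"], res.params["nh"], res.params["top"]]
        if free_bottom:
            theta.append(res.params["bottom"])
        yhat = hill_curve(
            conc, 10.0 ** theta[0], theta[1],
            theta[3] if free_bottom else fix_bottom, theta[2], direction,
        )
        weights = 1.0 / np.maximum(np.abs(yhat), 0.05 * np.abs(yhat).max())
        res = _lsq_multistart(residual, [np.asarray(theta)],
                              (np.array(lo), np.array(hi)),
                              names, len(conc), "hill")
    elif error_model != "absolute":
        raise ValueError(f"unknown error model {error_model!r}")
    if res.params:
        x50 = 10.0 ** res.params.pop("x50")
        se_log = res.stderr.pop("x50")
        key = "EC50" if direction == "rising" else "IC50"
        res.params[key] = x50
        res.stderr[key] = x50 * math.log(10) * se_log  # delta method
        res.params["nH"] = res.params.pop("nh")
        res.stderr["nH"] = res.stderr.pop("nh")
        if not free_bottom:
            res.params["bottom"] = fix_bottom
        res.flags.append(f"direction:{direction}")
    return res


# ---------------------------------------------------------------------------
# pH-current relationship
# ---------------------------------------------------------------------------

def ph_curve(pH, ph50, nh, y0, y_steady):
    """Current-pH relationship with a basal-opening floor.

    Y = Y0 + (Ysteady - Y0)/(1 + 10^((pH - pH50)*nH)) with nH > 0: the
    response approaches the acidic plateau Ysteady below pH50 and the
    neutral-pH basal level Y0 (the basal opening proportion) above it.
    """
    pH = np.asarray(pH, dtype=float)
    return y0 + (y_steady - y0) / (1.0 + 10.0 ** ((pH - ph50) * nh))


def fit_ph_curve(pH, y):
    """Fit pH50, nH, Y0 (basal opening proportion, bounded to [0,1]), Ysteady."""
    pH = np.asarray(pH, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(pH)) < 5:
        raise ValueError("need at least 5 pH points spanning the transition")
    names = ["ph50", "nh", "y0", "y_steady"]

    def residual(theta):
        return ph_curve(pH, *theta) - y

    half = 0.5 * (y.min() + y.max())
    order = np.argsort(pH)
    ph50_guess = float(np.interp(half, y[order][::-1], pH[order][::-1],
                                 left=pH.min(), right=pH.max()))
    lo = np.array([pH.min() - 2.0, 0.2, 0.0, -np.inf])
    hi = np.array([pH.max() + 2.0, 10.0, 1.0, np.inf])
    starts = [np.array([ph50_guess, nh0, max(min(y[np.argmax(pH)], 1.0), 0.0),
                        y.max()]) for nh0 in (1.0, 2.0, 3.0)]
    res = _lsq_multistart(residual, starts, (lo, hi), names, len(pH), "ph_curve")
    if res.params:
        res.params["pH50"] = res.params.pop("ph50")
        res.stderr["pH50"] = res.stderr.pop("ph50")
        res.params["nH"] = res.params.pop("nh")
        res.stderr["nH"] = res.stderr.pop("nh")
        res.params["Y0"] = res.params.pop("y0")
        res.stderr["Y0"] = res.stderr.pop("y0")
        res.params["Y_steady"] = res.params.pop("y_steady")
        res.stderr["Y_steady"] = res.stderr.pop("y_steady")
        if not (pH.min() <= res.params["pH50"] <= pH.max()):
            res.flags.append("extrapolated")
    return res


# ---------------------------------------------------------------------------
# Boltzmann G-V
# ---------------------------------------------------------------------------

def boltzmann_curve(V, v_half, k, y_max=1.0, y_min=0.0):
    """(Y - Ymin)/(Ymax - Ymin) = 1/(1 + exp((V1/2 - V)/K))."""
    V = np.asarray(V, dtype=float)
    u = np.clip((v_half - V) / k, -700.0, 700.0)
    return y_min + (y_max - y_min) / (1.0 + np.exp(u))


def fit_boltzmann(V, G):
    """Fit V_half, K, Y_max, Y_min.

    Incomplete activation is handled by the fit itself: when the
    conductance does not saturate within the sampled voltages, Y_max is an
    extrapolated fit parameter (the maximum conductance cannot be measured
    directly), and V_half may exceed the sampled range.
    """
    V = np.asarray(V, dtype=float)
    G = np.asarray(G, dtype=float)
    if len(np.unique(V)) < 6:
        raise ValueError("need at least 6 voltages")
    names = ["v_half", "k", "y_max", "y_min"]

    def residual(theta):
        return boltzmann_curve(V, *theta) - G

    span = V.max() - V.min()
    half = 0.5 * (G.min() + G.max())
    order = np.argsort(V)
    v_half_guess = float(np.interp(half, G[order], V[order],
                                   left=V.min(), right=V.max()))
    lo = np.array([V.min() - 3 * span, 1e-3, -np.inf, -np.inf])
    hi = np.array([V.max() + 3 * span, 10 * span, np.inf, np.inf])
    starts = [np.array([v_half_guess, k0 * span, G.max(), G.min()])
              for k0 in (0.1, 0.25, 0.5)]
    res = _lsq_multistart(residual, starts, (lo, hi), names, len(V), "boltzmann")
    if res.params:
        res.params["V_half"] = res.params.pop("v_half")
        res.stderr["V_half"] = res.stderr.pop("v_half")
        res.params["K"] = res.params.pop("k")
        res.stderr["K"] = res.stderr.pop("k")
        if not (V.min() <= res.params["V_half"] <= V.max()):
            res.flags.append("extrapolated")
    return res


# ---------------------------------------------------------------------------
# Monoexponential relaxation
# ---------------------------------------------------------------------------

def fit_monoexp(t, y):
    """Fit y = A*exp(-t/tau) + C.

    A < 0 describes a rising relaxation (e.g. recovery from inhibition).
    An input without a significant relaxing component is flagged
    ``degenerate``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 samples")
    span = float(y.max() - y.min())
    scale = max(abs(y).max(), 1e-12)
    if span < 1e-9 * scale:
        return FitResult("monoexp", {}, {}, 0.0, False, len(t), ["degenerate"])
    names = ["a", "log_tau", "c"]
    t_span = t.max() - t.min()

    def residual(theta):
        a, log_tau, c = theta
        return a * np.exp(-(t - t[0]) / (10.0 ** log_tau)) + c - y

    a0 = y[0] - y[-1]
    lo = np.array([-np.inf, math.log10(t_span) - 4, -np.inf])
    hi = np.array([np.inf, math.log10(t_span) + 3, np.inf])
    starts = [np.array([a0, math.log10(tau0 * t_span), y[-1]])
              for tau0 in (0.1, 0.3, 1.0)]
    res = _lsq_multistart(residual, starts, (lo, hi), names, len(t), "monoexp")
    if res.params:
        tau = 10.0 ** res.params.pop("log_tau")
        se_log = res.stderr.pop("log_tau")
        res.params["tau"] = tau
        res.stderr["tau"] = tau * math.log(10) * se_log
        res.params["A"] = res.params.pop("a")
        res.stderr["A"] = res.stderr.pop("a")
        res.params["C"] = res.params.pop("c")
        res.stderr["C"] = res.stderr.pop("c")
        if abs(res.params["A"]) < 1e-6 * scale:
            res.flags.append("degenerate")
            res.converged = False
    return res


# ---------------------------------------------------------------------------
# Log-linear current-pH slope and ionization
# ---------------------------------------------------------------------------

def fit_loglinear_slope(pH, y):
    """Ordinary least-squares slope of normalized current versus pH."""
    pH = np.asarray(pH, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(pH) < 3:
        raise ValueError("need at least 3 points")
    lr = stats.linregress(pH, y)
    rss = float(np.sum((lr.intercept + lr.slope * pH - y) ** 2))
    return FitResult(
        "loglinear_slope",
        {"slope": float(lr.slope), "intercept": float(lr.intercept)},
        {"slope": float(lr.stderr), "intercept": float(lr.intercept_stderr)},
        rss,
        True,
        len(pH),
    )


def ionized_fraction(pKa: float, pH) -> np.ndarray | float:
    """Henderson-Hasselbalch deprotonated fraction 1/(1 + 10^(pKa - pH))."""
    pH = np.asarray(pH, dtype=float)
    out = 1.0 / (1.0 + 10.0 ** (pKa - pH))
    return float(out) if out.ndim == 0 else out
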