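"""Equilibrium weights, open probability and response-curve behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pacgate.equilibrium import (
    DegenerateNormalizationError,
    EquilibriumParams,
    apparent_markers,
    dose_response,
    open_probability,
    ph_response,
    protonation_fraction,
    state_weights,
)
from pacgate.fitting import fit_ph_curve
from pacgate import presets


def brute_force_open_probability(p: EquilibriumParams, pH, conc):
    """Independent oracle: enumerate all states and their weight factors.

    Built from first principles (per-site occupancy factors applied
    multiplicatively), not from the packaged weight table.
    """
    h = 10.0 ** (p.n_H * (p.pK_H - pH))
    total = 0.0
    open_total = 0.0
    for s0 in (0, 1):
        for s1 in (0, 1):
            for s2 in (0, 1):
                for pore in ("closed", "open"):
                    # canonical achievability rules
                    if s2 and (not s0 or pore == "open"):
                        continue
                    if pore == "open" and not s0:
                        continue
                    if pore == "open" and s1 and not s0:
                        continue
                    w = 1.0
                    if s0:
                        w *= h
                    if s1:
                        w *= conc / p.K1
                    if s0 and s1:
                        w *= p.gamma
                    if pore == "open":
                        w *= p.L
                        if s1:
                            w *= p.phi
                    if s2:
                        # blocked states descend from the open state
                        w *= p.L * (p.phi if s1 else 1.0)
                        w *= conc / (p.K2p if s1 else p.K2)
                    total += w
                    open_total += w if pore == "open" else 0.0
    return open_total / total


params_strategy = st.builds(
    EquilibriumParams,
    pK_H=st.floats(4.5, 6.0),
    n_H=st.floats(1.0, 3.0),
    L=st.floats(0.1, 10.0),
    K1=st.floats(0.5, 100.0),
    gamma=st.floats(1.0, 10.0),
    phi=st.floats(1.0, 10.0),
    K2=st.floats(0.5, 100.0),
    K2p=st.floats(0.5, 100.0),
)


class TestStateWeights:
    def test_zero_concentration_zeroes_modulator_states(self, wt_params):
        w = state_weights(wt_params, 5.0, 0.0)
        for label in ("C2", "C3", "O2", "C4", "C5"):
            assert w[label] == 0.0

    def test_high_ph_leaves_only_unprotonated_closed(self, wt_params):
        w = state_weights(wt_params, 12.0, 10.0)
        protonated = ("C1", "C3", "O1", "O2", "C4", "C5")
        assert all(w[k] < 1e-12 for k in protonated)
        assert w["C0"] == 1.0 and w["C2"] > 0

    def test_midpoint_protonation(self, wt_params):
        w = state_weights(wt_params, wt_params.pK_H, 0.0)
        assert w["C1"] == pytest.approx(1.0)
        assert w["O1"] == pytest.approx(wt_params.L)

    def test_input_validation(self, wt_params):
        with pytest.raises(ValueError):
            state_weights(wt_params, 5.0, -1.0)
        with pytest.raises(ValueError):
            state_weights(wt_params, -2.0, 1.0)
        with pytest.raises(ValueError):
            EquilibriumParams(
                pK_H=5.0, n_H=float("nan"), L=1, K1=1, gamma=1, phi=1,
                K2=1, K2p=1,
            )

    @given(params_strategy, st.floats(3.0, 9.0), st.floats(0.0, 300.0))
    def test_weights_nonnegative_and_probability_normalizes(self, p, pH, conc):
        w = state_weights(p, pH, conc)
        assert all(np.isfinite(v) and v >= 0 for v in w.values())
        po = open_probability(p, pH, conc)
        assert 0.0 <= po <= 1.0
        pf = protonation_fraction(p, pH, conc)
        assert 0.0 <= pf <= 1.0


class TestOpenProbability:
    @given(params_strategy, st.floats(3.0, 9.0), st.floats(0.0, 300.0))
    def test_matches_brute_force_partition_function(self, p, pH, conc):
        assert open_probability(p, pH, conc) == pytest.approx(
            brute_force_open_probability(p, pH, conc), rel=1e-9
        )

    def test_neutral_ph_without_compound_is_closed(self, wt_params):
        assert open_probability(wt_params, 7.3, 0.0) < 1e-3

    def test_saturating_protons_closed_form(self, wt_params):
        p = open_probability(wt_params, 1.0, 0.0)
        L = wt_params.L
        assert p == pytest.approx(L / (1 + L), rel=1e-6)

    def test_saturating_compound_blocks(self, wt_params):
        assert open_probability(wt_params, 5.0, 1e6) < 1e-4


class TestDoseResponse:
    GRID = np.concatenate([[0.0], np.logspace(-3, 3, 200)])

    def test_bell_shape_at_weak_acid(self, wt_params):
        m = apparent_markers(dose_response(wt_params, 5.6, self.GRID))
        assert m.is_bell
        assert m.ec50 < m.peak_conc < m.ic50
        assert m.peak_amplitude > 1.05

    def test_monotone_inhibition_at_strong_acid(self, wt_params):
        for pH in (5.0, 4.8, 4.6):
            m = apparent_markers(dose_response(wt_params, pH, self.GRID))
            assert m.ec50 is None
            assert m.ic50 is not None

    def test_inhibition_weaker_than_activation(self, wt_params):
        """Apparent blocking potency is many-fold weaker than activation."""
        m = apparent_markers(dose_response(wt_params, 5.6, self.GRID))
        assert m.ic50 / m.ec50 >= 9.0

    def test_no_block_gives_monotone_rise(self, wt_params):
        import dataclasses

        p = dataclasses.replace(wt_params, K2=math.inf, K2p=math.inf)
        curve = dose_response(p, 5.6, self.GRID)
        assert np.all(np.diff(curve.y) >= -1e-12)

    def test_no_activation_gives_monotone_fall(self, wt_params):
        import dataclasses

        p = dataclasses.replace(wt_params, K1=math.inf)
        curve = dose_response(p, 5.6, self.GRID)
        assert np.all(np.diff(curve.y) <= 1e-12)
        m = apparent_markers(curve)
        assert m.ec50 is None and m.ic50 is not None

    def test_degenerate_normalization_refused(self, wt_params):
        # far-alkaline pH: the untreated open probability underflows to ~0
        with pytest.raises(DegenerateNormalizationError):
            dose_response(wt_params, 9.5, self.GRID, "to_untreated")

    def test_untreated_normalization_needs_zero_point(self, wt_params):
        with pytest.raises(ValueError):
            dose_response(wt_params, 5.6, np.logspace(-2, 2, 10))

    def test_markers_reject_non_monotone_grid(self, wt_params):
        curve = dose_response(wt_params, 5.6, self.GRID)
        curve.x = curve.x[::-1].copy()
        with pytest.raises(ValueError):
            apparent_markers(curve)


class TestPhResponse:
    GRID = np.linspace(4.0, 7.3, 150)

    def test_alkaline_shift_with_invariant_slope(self, wt_params):
        fits = {}
        for conc in (0.0, 5.0, 10.0):
            curve = ph_response(wt_params, conc, self.GRID)
            fits[conc] = fit_ph_curve(curve.x, curve.y)
        ph50 = {c: f.params["pH50"] for c, f in fits.items()}
        assert ph50[0.0] < ph50[5.0] < ph50[10.0]
        nh0 = fits[0.0].params["nH"]
        for conc in (5.0, 10.0):
            assert fits[conc].params["nH"] == pytest.approx(nh0, rel=0.05)

    def test_basal_variant_floor_at_neutral_ph(self):
        p = presets.equilibrium_preset("F196A/R237A")
        curve = ph_response(p, 0.0, self.GRID)
        y_neutral = curve.y[-1]
        assert y_neutral == pytest.approx(0.15, abs=0.02)

    def test_midpoint_value(self, wt_params):
        curve = ph_response(wt_params, 0.0, np.array([wt_params.pK_H]))
        L = wt_params.L
        expected = (L / (1 + 1 + L)) / (L / (1 + L))
        assert curve.y[0] == pytest.approx(expected, rel=1e-6)

    def test_basal_variant_monotone_block_at_neutral_bell_at_weak_acid(self):
        p = presets.equilibrium_preset("A321C")
        grid = np.concatenate([[0.0], np.logspace(-2, 3, 200)])
        neutral = apparent_markers(dose_response(p, 7.3, grid))
        assert neutral.ec50 is None and neutral.ic50 is not None
        acid = apparent_markers(dose_response(p, 6.2, grid))
        assert acid.is_bell


class TestMarkersShapes:
    def test_single_limb_cases(self):
        from pacgate.equilibrium import ResponseCurve

        x = np.concatenate([[0.0], np.logspace(-3, 3, 120)])
        falling = ResponseCurve(x, 1.0 / (1.0 + x / 3.0), "none")
        m = apparent_markers(falling)
        assert m.ec50 is None and m.ic50 is not None
        rising = ResponseCurve(x, x / (x + 3.0), "none")
        m = apparent_markers(rising)
        assert m.ic50 is None and m.ec50 == pytest.approx(3.0, rel=0.05)
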