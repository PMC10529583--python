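"""GHK flux, the ion-flux voltage gate, ramps, substitutions, G-V."""

import numpy as np
import pytest

from pacgate import presets
from pacgate.biophysics import (
    DEFAULT_TEMPERATURE,
    FARADAY,
    GAS_CONSTANT,
    IonSpecies,
    VoltageGateParams,
    conductance_curve,
    ghk_current,
    ion_substitution,
    simulate_ramp,
    voltage_gate,
)
from pacgate.fitting import boltzmann_curve, fit_loglinear_slope

CL = IonSpecies("Cl", -1, 1.0, 141.0, 154.0)
NA = IonSpecies("Na", +1, 1.0, 0.0, 145.0)


class TestGHK:
    def test_zero_at_equilibrium(self):
        sym = IonSpecies("X", +1, 1.0, 100.0, 100.0)
        assert ghk_current(sym, 0.0) == 0.0

    def test_zero_at_nernst_potential(self):
        v_nernst = (
            GAS_CONSTANT * DEFAULT_TEMPERATURE / (CL.z * FARADAY)
            * np.log(CL.conc_out / CL.conc_in) * 1e3
        )
        assert abs(ghk_current(CL, v_nernst)) < 1e-6 * abs(ghk_current(CL, 100.0))

    def test_continuity_at_zero(self):
        # straddle the series-expansion switchover with a fine voltage grid
        V = np.linspace(-1e-3, 1e-3, 401)
        I = ghk_current(CL, V)
        assert np.all(np.isfinite(I))
        steps = np.abs(np.diff(I))
        assert steps.max() < 3.0 * np.median(steps)  # no jump at the switch
        assert ghk_current(CL, 1e-7) == pytest.approx(ghk_current(CL, 0.0),
                                                      abs=1e-7)

    def test_anion_influx_is_outward_current(self):
        # [Cl]out > [Cl]in and depolarization: chloride flows in => outward I
        assert ghk_current(CL, 100.0) > 0

    def test_monotone_in_driving_force(self):
        V = np.linspace(-150.0, 150.0, 61)
        I = ghk_current(CL, V)
        assert np.all(np.diff(I) > 0)

    def test_both_concentrations_zero_gives_zero(self):
        empty = IonSpecies("X", +1, 1.0, 0.0, 0.0)
        assert ghk_current(empty, 80.0) == 0.0


class TestVoltageGate:
    GATE = VoltageGateParams()

    def test_half_activation_midpoint(self):
        g = voltage_gate(self.GATE, self.GATE.V_half_rest, 0.0)
        assert g == pytest.approx(0.5, rel=1e-9)

    def test_protonation_slides_v_half(self):
        g = voltage_gate(self.GATE, 0.0, 1.0)  # fully protonated: V1/2 -> 0
        assert g == pytest.approx(0.5, rel=1e-9)

    def test_orientation_flip(self):
        cation = VoltageGateParams(orientation=-1)
        g_hyper = voltage_gate(cation, -250.0, 0.0)
        g_depol = voltage_gate(cation, +250.0, 0.0)
        assert g_hyper > 0.8 > 0.01 > g_depol

    def test_strong_depolarization_at_neutral_ph(self):
        assert voltage_gate(self.GATE, 195.0, 0.0) > 100 * voltage_gate(
            self.GATE, -195.0, 0.0
        )

    def test_alkaline_attenuation(self):
        g73 = voltage_gate(self.GATE, 195.0, 0.0, pH=7.3)
        g93 = voltage_gate(self.GATE, 195.0, 0.0, pH=9.3)
        assert 0.5 * g73 < g93 < g73

    def test_protonation_bounds(self):
        with pytest.raises(ValueError):
            voltage_gate(self.GATE, 0.0, 1.5)


class TestRamps:
    def test_wildtype_outward_rectification(self):
        df = simulate_ramp(presets.variant("wt"), 7.3)
        assert df["I_total"].iloc[-1] > 50 * abs(df["I_total"].iloc[0])

    @pytest.mark.parametrize("name", ["K319E", "K319Q"])
    def test_cation_mutants_inward_rectification(self, name):
        df = simulate_ramp(presets.variant(name), 7.3)
        assert df["I_total"].iloc[0] < 0
        assert abs(df["I_total"].iloc[0]) > 50 * abs(df["I_total"].iloc[-1])

    def test_histidine_mutant_conducts_both_ways(self):
        df = simulate_ramp(presets.variant("K319H"), 7.3)
        assert df["I_total"].iloc[0] < -1.0 and df["I_total"].iloc[-1] > 1.0

    def test_knockout_is_flat_zero(self):
        df = simulate_ramp(presets.variant("knockout"), 7.3)
        assert np.allclose(df["I_total"], 0.0)

    def test_proton_activation_persists_when_hyperpolarized(self):
        """Acid-evoked inward chloride current at -150 mV is nonzero."""
        df = simulate_ramp(presets.variant("wt"), 4.6)
        i = np.interp(-150.0, df["V_mV"], df["I_total"])
        assert i < -1.0

    def test_current_pH_slopes_shallow_alkaline_steep_acidic(self):
        wt = presets.variant("wt")

        def endpoint_current(pH):
            df = simulate_ramp(wt, pH)
            return df["I_total"].iloc[-1]

        acid_ph = [5.0, 5.5, 6.0]
        alk_ph = [7.3, 8.3, 9.3]
        acid = np.array([endpoint_current(p) for p in acid_ph])
        alk = np.array([endpoint_current(p) for p in alk_ph])
        s_acid = fit_loglinear_slope(acid_ph, acid / acid[0]).params["slope"]
        s_alk = fit_loglinear_slope(alk_ph, alk / alk[0]).params["slope"]
        assert abs(s_alk) < 0.3 * abs(s_acid)

    def test_ramp_validation(self):
        with pytest.raises(ValueError):
            simulate_ramp(presets.variant("wt"), 7.3, speed_mv_per_ms=0.0)


class TestIonSubstitution:
    def test_sulfate_substitution_cuts_outward_chloride_current(self):
        before, after = ion_substitution(presets.variant("wt"), 7.3, "Cl", 9.0)
        assert after["I_total"].iloc[-1] < 0.3 * before["I_total"].iloc[-1]

    def test_nmdg_substitution_cuts_inward_sodium_current(self):
        before, after = ion_substitution(
            presets.variant("K319E"), 7.3, "Na", 0.0
        )
        assert abs(after["I_total"].iloc[0]) < 0.05 * abs(
            before["I_total"].iloc[0]
        )

    def test_identical_solution_is_a_noop(self):
        v = presets.variant("wt")
        before, after = ion_substitution(
            v, 7.3, "Cl", v.branches[0].species.conc_out
        )
        assert np.allclose(before["I_total"], after["I_total"])

    def test_replacing_absent_species_errors(self):
        with pytest.raises(KeyError):
            presets.variant("wt").with_bath("K", 0.0)


class TestConductance:
    def test_ohmic_trace_gives_constant_conductance(self):
        V = np.arange(-100.0, 201.0, 20.0)
        I = 2.5 * (V - 0.0)
        df, _fit = conductance_curve(V, I, V_rev=0.0)
        assert np.allclose(df["G"], 2.5)

    def test_boltzmann_roundtrip_through_fitter(self):
        V = np.arange(-100.0, 201.0, 20.0)
        g_true = boltzmann_curve(V, 120.0, 25.0)
        I = g_true * (V - 0.0)
        df, fit = conductance_curve(V, I, V_rev=0.0)
        assert fit.params["V_half"] == pytest.approx(120.0, rel=1e-3)
        assert fit.params["K"] == pytest.approx(25.0, rel=1e-3)
        assert df["G_norm"].max() <= 1.05

    def test_zero_mv_conductance_from_pm20_average(self):
        V = np.arange(-100.0, 201.0, 20.0)
        I = 3.0 * (V - 0.0)
        df, _ = conductance_curve(V, I, V_rev=0.0)
        assert 0.0 in set(df["V_mV"])
        g0 = df.loc[df["V_mV"] == 0.0, "G"].iloc[0]
        assert g0 == pytest.approx(3.0)

    def test_reversal_outside_range_errors(self):
        V = np.arange(0.0, 101.0, 20.0)
        with pytest.raises(ValueError):
            conductance_curve(V, V.copy(), V_rev=-50.0)
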