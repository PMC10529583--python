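"""Master-equation kinetics: detailed balance, relaxation, protocols."""

import numpy as np
import pytest

from pacgate import presets
from pacgate.kinetics import (
    Protocol,
    RateScales,
    RateSet,
    Segment,
    calibrate_site1_on_rate,
    measured_washout_tau,
    preincubation_assay,
    rates_from_equilibrium,
    simulate_protocol,
)


class TestRateConstruction:
    @pytest.mark.parametrize("condition", [(5.8, 5.0), (4.6, 50.0), (7.3, 0.0),
                                           (6.5, 0.3)])
    def test_detailed_balance_on_all_cycles(self, calibrated_rates, condition):
        assert calibrated_rates.check_detailed_balance(*condition) < 1e-12

    @pytest.mark.parametrize("condition", [(5.8, 5.0), (4.6, 50.0), (7.3, 0.0)])
    def test_stationary_distribution_matches_equilibrium(
        self, calibrated_rates, condition
    ):
        q = calibrated_rates.generator(*condition)
        pi = calibrated_rates.equilibrium_distribution(*condition)
        assert np.abs(pi @ q).max() < 1e-10

    def test_basal_variant_extended_graph_also_balances(self):
        rs = RateSet(presets.equilibrium_preset("A321C"))
        assert len(rs.labels) == 12
        assert rs.check_detailed_balance(6.2, 2.0) < 1e-12
        q = rs.generator(7.3, 100.0)
        pi = rs.equilibrium_distribution(7.3, 100.0)
        assert np.abs(pi @ q).max() < 1e-10

    def test_pseudo_first_order_closed_form(self, wt_params):
        """An isolated binding step relaxes at kon*conc + koff."""
        kon = calibrate_site1_on_rate(wt_params, 5.8, 5.0, 4.5)
        h = 10.0 ** (wt_params.n_H * (wt_params.pK_H - 5.8))
        g, f, L = wt_params.gamma, wt_params.phi, wt_params.L
        koff = (
            kon * wt_params.K1 * (1 + h + h * L) / (1 + h * g + h * g * L * f)
        )
        assert 1.0 / (kon * 5.0 + koff) == pytest.approx(4.5, rel=1e-12)

    def test_scale_validation(self):
        with pytest.raises(ValueError):
            RateScales(proton=-1.0)


class TestSimulation:
    def test_constant_conditions_from_equilibrium_stay_constant(
        self, calibrated_rates
    ):
        proto = Protocol([Segment(10.0, 5.6, 5.0)], sampling=0.2)
        tr = simulate_protocol(calibrated_rates, proto)
        assert np.ptp(tr.open_occupancy) < 1e-10

    def test_occupancy_conserved_at_every_sample(self, calibrated_rates):
        proto = Protocol(
            [Segment(5.0, 7.3, 0.0), Segment(20.0, 5.6, 50.0),
             Segment(20.0, 5.6, 0.0)],
            sampling=0.1,
        )
        tr = simulate_protocol(calibrated_rates, proto)
        assert np.abs(tr.occupancy.sum(axis=1) - 1.0).max() < 1e-8
        assert tr.occupancy.min() >= 0.0

    def test_long_time_limit_equals_equilibrium(self, calibrated_rates):
        """Relaxation from a remote initial condition reaches the
        equilibrium module's distribution (oracle equivalence)."""
        start = calibrated_rates.equilibrium_distribution(7.3, 0.0)
        proto = Protocol([Segment(3000.0, 5.34, 10.0)], sampling=50.0)
        tr = simulate_protocol(calibrated_rates, proto, init=start)
        target = calibrated_rates.equilibrium_distribution(5.34, 10.0)
        assert np.abs(tr.occupancy[-1] - target).max() < 1e-8

    def test_expm_and_ode_paths_agree(self, calibrated_rates):
        proto = Protocol(
            [Segment(5.0, 5.8, 0.0), Segment(10.0, 5.8, 5.0)], sampling=0.25
        )
        a = simulate_protocol(calibrated_rates, proto, method="expm")
        b = simulate_protocol(calibrated_rates, proto, method="ode")
        assert np.abs(a.occupancy - b.occupancy).max() < 1e-6

    def test_transient_activation_then_inhibition_at_high_dose(
        self, calibrated_rates
    ):
        """A 50 uM step at weak acid first boosts then suppresses opening."""
        proto = Protocol(
            [Segment(5.0, 5.6, 0.0), Segment(120.0, 5.6, 50.0)], sampling=0.1
        )
        tr = simulate_protocol(calibrated_rates, proto)
        seg = tr.segment_index == 1
        y = tr.open_occupancy[seg]
        y0, peak, end = y[0], y.max(), y[-1]
        assert peak > 1.2 * y0          # transient activation
        assert end < 0.8 * peak         # subsequent inhibition
        assert np.argmax(y) < 0.5 * len(y)

    def test_pretreatment_suppresses_transient_peak(self, calibrated_rates):
        """Activating pretreatment converts the biphasic 50 uM response
        toward direct inhibition: the transient shrinks with site-1
        pre-occupancy and disappears once the site is saturated."""
        def rel_peak(pre_conc):
            proto = Protocol(
                [Segment(300.0, 5.6, pre_conc), Segment(120.0, 5.6, 50.0)],
                sampling=0.1,
            )
            tr = simulate_protocol(calibrated_rates, proto)
            y = tr.open_occupancy[tr.segment_index == 1]
            return y.max() / y[0]

        naive, pre1, pre5 = rel_peak(0.0), rel_peak(1.0), rel_peak(5.0)
        assert naive > 1.5               # biphasic without pretreatment
        assert pre1 < naive and pre5 < pre1
        # the excess transient shrinks to a small fraction of the naive one
        assert (pre5 - 1.0) < 0.2 * (naive - 1.0)

    def test_init_validation(self, calibrated_rates):
        proto = Protocol([Segment(1.0, 5.6, 0.0)])
        bad = np.ones(len(calibrated_rates.labels))
        with pytest.raises(ValueError):
            simulate_protocol(calibrated_rates, proto, init=bad)
        with pytest.raises(ValueError):
            simulate_protocol(calibrated_rates, proto, init="nonsense")

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            Protocol([])
        with pytest.raises(ValueError):
            Segment(-1.0, 5.0)

    def test_protocol_json_roundtrip(self):
        proto = Protocol([Segment(5.0, 5.6, 1.0), Segment(2.0, 7.3)], 0.05)
        back = Protocol.from_json(proto.to_json())
        assert back == proto


class TestRelaxationOrdering:
    def test_activation_reverses_faster_than_inhibition(self, calibrated_rates):
        """Washout of activation (site 1) is quicker than recovery from
        block (site 2), matching the observed asymmetry."""
        tau_act_off = measured_washout_tau(calibrated_rates, 5.8, 1.0)
        tau_inh_off = measured_washout_tau(calibrated_rates, 4.6, 50.0)
        assert tau_act_off < tau_inh_off


class TestPreincubation:
    def test_resting_wildtype_is_protected(self, calibrated_rates):
        assert preincubation_assay(calibrated_rates) == pytest.approx(1.0, abs=0.05)

    def test_basally_open_variant_is_blocked(self, calibrated_rates):
        rs = RateSet(presets.equilibrium_preset("A321C"), calibrated_rates.scales)
        assert preincubation_assay(rs) < 0.7

    def test_compound_free_control(self, calibrated_rates):
        rs = RateSet(presets.equilibrium_preset("A321C"), calibrated_rates.scales)
        assert preincubation_assay(rs, conc_pre=0.0) == pytest.approx(1.0, abs=0.01)
        assert preincubation_assay(calibrated_rates, conc_pre=0.0) == pytest.approx(
            1.0, abs=0.01
        )


def test_rates_from_equilibrium_verifies_construction(wt_params):
    rs = rates_from_equilibrium(wt_params)
    assert rs.check_detailed_balance(5.5, 2.0) < 1e-12
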