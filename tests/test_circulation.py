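"""Closed-loop circulation with LVAD: unit physics, conservation, scenarios."""

import numpy as np
import pandas as pd
import pytest

from cardioem import circulation as circ
from cardioem.exceptions import InvalidParameterError


@pytest.fixture(scope="module")
def params():
    return circ.load_default_params()


class TestVentriclePressure:
    def test_zero_activation_is_passive(self, params):
        p = params.lv
        v = p.v0 + 50.0
        expected = p.edp_a * np.expm1(p.edp_b * 50.0)
        assert circ.ventricle_pressure(v, 0.0, p) == pytest.approx(expected)

    def test_full_activation_at_v0_is_zero(self, params):
        assert circ.ventricle_pressure(params.lv.v0, 1.0, params.lv) == pytest.approx(0.0)

    def test_weaker_activation_lower_isovolumic_pressure(self, params):
        v = params.lv.v0 + 60.0
        strong = circ.ventricle_pressure(v, 0.9, params.lv)
        weak = circ.ventricle_pressure(v, 0.6, params.lv)
        assert weak < strong

    def test_activation_bounds_checked(self, params):
        with pytest.raises(InvalidParameterError):
            circ.ventricle_pressure(100.0, 1.5, params.lv)


class TestValveFlow:
    def test_no_gradient_no_flow(self):
        assert circ.valve_flow(10.0, 10.0, 0.05) == 0.0

    def test_ohmic_forward_flow(self):
        assert circ.valve_flow(20.0, 10.0, 0.05) == pytest.approx(200.0)

    def test_reverse_gradient_closed(self):
        assert circ.valve_flow(5.0, 10.0, 0.05) == 0.0


class TestLvadFlow:
    def test_four_lpm_conversion(self, params):
        from dataclasses import replace
        p = replace(params, lvad_flow_lpm=4.0)
        assert circ.lvad_flow(0.0, p) == pytest.approx(66.6667, rel=1e-4)

    def test_zero_setting(self, params):
        from dataclasses import replace
        p = replace(params, lvad_flow_lpm=0.0)
        assert circ.lvad_flow(123.0, p) == 0.0

    def test_time_independent(self, params):
        assert circ.lvad_flow(0.0, params) == circ.lvad_flow(1e6, params)


class TestSimulatePhysics:
    def test_no_activation_relaxes_toward_equilibrium(self, params):
        act = np.zeros(801)
        traces = circ.simulate(params, act, act, 1.0, n_cycles=25)
        head = traces[traces.time_ms < 800.0]
        tail = traces[traces.time_ms > traces.time_ms.max() - 800.0]
        f0 = np.abs(head[["q_mi", "q_ao", "q_tr", "q_pu"]].to_numpy()).max()
        f1 = np.abs(tail[["q_mi", "q_ao", "q_tr", "q_pu"]].to_numpy()).max()
        # flows decay toward the static state (venous time constants are long,
        # so full equilibrium takes longer than 25 cycles)
        assert f1 < 0.1 * f0
        # upstream/downstream pressures equalize along the open mitral path
        assert abs(tail["p_la"].iloc[-1] - tail["p_lv"].iloc[-1]) < 0.05

    def test_blood_volume_conserved(self, params):
        act = np.zeros(801)
        act[50:350] = np.sin(np.linspace(0, np.pi, 300)) * 0.9
        traces = circ.simulate(params, act, act, 1.0, n_cycles=25)
        vols = traces[["v_la", "v_lv", "v_ra", "v_rv", "v_sa", "v_sv", "v_pa", "v_pv"]]
        total = vols.sum(axis=1).to_numpy()
        assert np.ptp(total) / total[0] < 1e-4  # 0.01%

    def test_volume_conserved_with_lvad(self, params):
        from dataclasses import replace
        p = replace(params, lvad_flow_lpm=4.0)
        act = np.zeros(801)
        act[50:350] = np.sin(np.linspace(0, np.pi, 300)) * 0.5
        traces = circ.simulate(p, act, act, 1.0, n_cycles=25)
        vols = traces[["v_la", "v_lv", "v_ra", "v_rv", "v_sa", "v_sv", "v_pa", "v_pv"]]
        total = vols.sum(axis=1).to_numpy()
        assert np.ptp(total) / total[0] < 1e-4

    def test_lvad_keeps_aorta_above_idle_lv(self, params):
        from dataclasses import replace
        p = replace(params, lvad_flow_lpm=4.0)
        act = np.zeros(801)
        traces = circ.simulate(p, act, act, 1.0, n_cycles=15)
        tail = traces[traces.time_ms > traces.time_ms.max() - 1600.0]
        assert tail["p_ao"].mean() > tail["p_lv"].mean()

    def test_valve_complementarity(self, scenarios):
        for cond, res in scenarios.items():
            b = res.last_beat()
            for q, up, dn in (("q_mi", "p_la", "p_lv"), ("q_ao", "p_lv", "p_ao"),
                              ("q_tr", "p_ra", "p_rv"), ("q_pu", "p_rv", "p_pa")):
                flow = b[q].to_numpy()
                grad = (b[up] - b[dn]).to_numpy()
                assert (flow >= 0.0).all()
                # closed-valve leakage is below the diode smoothing scale
                assert np.abs(flow[grad < -0.5]).max(initial=0.0) < 1e-3


class TestScenarios:
    def test_unknown_condition(self):
        with pytest.raises(InvalidParameterError):
            circ.run_scenario("hypertension")

    def test_steady_state_attained(self, scenarios):
        for cond, res in scenarios.items():
            assert res.steady_state_metric < 0.01, cond

    def test_lvad_off_conditions_have_zero_pump_flow(self, scenarios):
        for cond in ("normal", "hf"):
            assert scenarios[cond].traces["q_lvad"].abs().max() == 0.0

    def test_lvad_mean_outflow_is_set_flow(self, scenarios):
        beat = scenarios["hf_lvad"].last_beat()
        lpm = beat["q_lvad"].mean() * 60.0 / 1000.0
        assert lpm == pytest.approx(4.0, rel=0.01)

    def test_hf_depresses_left_heart(self, summaries):
        n, h = summaries["normal"], summaries["hf"]
        assert h.lv.esp < n.lv.esp
        assert h.lv.edp > n.lv.edp

    def test_hf_congests_right_heart(self, summaries):
        n, h = summaries["normal"], summaries["hf"]
        assert h.raesp > n.raesp
        assert h.rv.esp > n.rv.esp
        assert h.paesp > n.paesp

    def test_lvad_degenerate_zero_flow_equals_hf(self, params):
        hf = circ.run_scenario("hf", n_cycles=12, params=params)
        lv0 = circ.run_scenario("hf_lvad", n_cycles=12, params=params, lvad_flow_lpm=0.0)
        a = hf.last_beat().reset_index(drop=True)
        b = lv0.last_beat().reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, atol=1e-9, rtol=1e-9)

    def test_reruns_identical(self, params):
        a = circ.run_scenario("normal", n_cycles=6, params=params).traces
        b = circ.run_scenario("normal", n_cycles=6, params=params).traces
        pd.testing.assert_frame_equal(a, b)


class TestCalibration:
    def test_self_consistency_round_trip(self, params):
        """Fitting against the model's own output recovers the perturbed params."""
        from cardioem.hemodynamics import summarize_beat

        res = circ.run_scenario("normal", n_cycles=12, params=params)
        summ = summarize_beat(res.last_beat(), 800.0).as_dict()
        targets = {k: summ[k] for k in ("lvesp", "lvedv", "lvco")}
        from dataclasses import replace
        perturbed = circ.CirculationParams.from_dict(
            {**params.to_dict(), "r_sa": params.r_sa * 1.15})
        fitted, report = circ.calibrate_normal(
            targets=targets, free=["r_sa"], base_params=perturbed,
            n_cycles=12, residual_threshold=0.2)
        assert fitted.r_sa == pytest.approx(params.r_sa, rel=0.05)

    def test_calibrated_normal_hits_headline_targets(self, summaries):
        n = summaries["normal"]
        assert abs(n.lv.ef - 46.0) <= 5.0
        assert abs(n.lv.co - 3.8) / 3.8 <= 0.15
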