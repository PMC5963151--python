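"""PV-loop summarization, percent changes, isovolumetric detection, fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardioem.exceptions import InsufficientDataError, InvalidParameterError
from cardioem.hemodynamics import (
    compare_conditions,
    isovolumetric_phases,
    percent_change,
    segment_last_beat,
    summarize_beat,
    summarize_pv,
    synth_pv_fixture,
)

# Printed reference rows for the normal / HF / HF+LVAD conditions
NORMAL_LV = dict(esp=110.0, edp=5.0, edv=112.0, esv=61.0)
NORMAL_RV = dict(esp=16.0, edp=1.0, edv=136.0, esv=85.0)


def beatify(fx: pd.DataFrame) -> pd.DataFrame:
    """Extend a single-ventricle fixture with the columns summarize_beat needs."""
    out = fx.copy()
    out["p_rv"] = out["p_lv"]
    out["v_rv"] = out["v_lv"]
    out["p_ra"] = 0.0
    out["p_pa"] = 0.0
    return out


class TestSummarizePv:
    def test_table_row_arithmetic(self):
        fx = synth_pv_fixture(**NORMAL_LV)
        s = summarize_pv(fx["p_lv"].to_numpy(), fx["v_lv"].to_numpy(), 800.0)
        assert s.sv == pytest.approx(51.0)
        assert round(s.ef) == 46
        assert round(s.co, 1) == 3.8
        assert s.pp == pytest.approx(105.0)

    def test_rv_row_arithmetic(self):
        fx = synth_pv_fixture(**NORMAL_RV)
        s = summarize_pv(fx["p_lv"].to_numpy(), fx["v_lv"].to_numpy(), 800.0)
        assert s.sv == pytest.approx(51.0)
        assert round(s.ef) == 38

    def test_rectangular_loop_stroke_work(self):
        # hand shoelace: rectangle 100 mmHg x 50 mL = 5000 mmHg*mL
        v = np.array([100.0, 100.0, 50.0, 50.0])
        p = np.array([0.0, 100.0, 100.0, 0.0])
        s = summarize_pv(p, v, 800.0)
        assert s.sw == pytest.approx(5000.0)

    def test_esp_modes(self):
        fx = synth_pv_fixture(**NORMAL_LV)
        peak = summarize_pv(fx["p_lv"].to_numpy(), fx["v_lv"].to_numpy(), 800.0, "peak")
        at_esv = summarize_pv(fx["p_lv"].to_numpy(), fx["v_lv"].to_numpy(), 800.0, "at_esv")
        assert peak.esp >= at_esv.esp


class TestSynthFixtureRoundTrip:
    @given(
        esp=st.floats(20.0, 200.0),
        edp=st.floats(-3.0, 20.0),
        edv=st.floats(80.0, 250.0),
        sv=st.floats(10.0, 70.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_exact(self, esp, edp, edv, sv):
        fx = synth_pv_fixture(esp=esp, edp=edp, edv=edv, esv=edv - sv)
        s = summarize_pv(fx["p_lv"].to_numpy(), fx["v_lv"].to_numpy(), 800.0)
        assert s.esp == pytest.approx(esp, abs=1e-12)
        assert s.edp == pytest.approx(edp, abs=1e-12)
        assert s.edv == pytest.approx(edv, abs=1e-12)
        assert s.esv == pytest.approx(edv - sv, abs=1e-12)

    def test_negative_edp_preserved(self):
        fx = synth_pv_fixture(esp=43.0, edp=-1.0, edv=89.0, esv=69.0)
        s = summarize_pv(fx["p_lv"].to_numpy(), fx["v_lv"].to_numpy(), 800.0)
        assert s.edp == pytest.approx(-1.0)

    def test_seeded_noise_deterministic(self):
        a = synth_pv_fixture(**NORMAL_LV, noise_sd=0.5, seed=3)
        b = synth_pv_fixture(**NORMAL_LV, noise_sd=0.5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_stroke_work_matches_polygon_area(self):
        # independent oracle: shapely polygon area of the constructed loop
        from shapely.geometry import Polygon

        fx = synth_pv_fixture(**NORMAL_LV)
        s = summarize_pv(fx["p_lv"].to_numpy(), fx["v_lv"].to_numpy(), 800.0)
        poly = Polygon(zip(fx["v_lv"], fx["p_lv"]))
        assert s.sw == pytest.approx(poly.area, rel=1e-3)

    def test_edv_must_exceed_esv(self):
        with pytest.raises(InvalidParameterError):
            synth_pv_fixture(esp=100, edp=5, edv=60, esv=60)


class TestPercentChange:
    # printed LV/RV comparisons: baseline, new, rounded percent
    @pytest.mark.parametrize("baseline,new,expected", [
        (73.0, 43.0, -41),   # LV end-systolic pressure, HF -> HF+LVAD
        (7.0, 5.0, -29),     # RA end-systolic pressure
        (17.0, 5.0, -71),    # PA end-systolic pressure
        (21.0, 32.0, 52),    # RV ejection fraction
        (2.5, 3.5, 40),      # RV cardiac output
        (411.0, 137.0, -67), # RV stroke work
    ])
    def test_printed_comparisons(self, baseline, new, expected):
        assert round(percent_change(baseline, new)) == expected

    def test_zero_change(self):
        assert percent_change(5.0, 5.0) == 0.0

    def test_plus_forty(self):
        assert percent_change(2.5, 3.5) == pytest.approx(40.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(InvalidParameterError):
            percent_change(0.0, 1.0)

    @given(baseline=st.floats(0.5, 500.0), pct=st.floats(-90.0, 300.0))
    @settings(max_examples=50, deadline=None)
    def test_inverse_identity(self, baseline, pct):
        new = baseline * (1 + pct / 100.0)
        assert percent_change(baseline, new) == pytest.approx(pct, abs=1e-9)


class TestSegmentLastBeat:
    def test_slice_duration(self):
        fx = pd.concat(
            [synth_pv_fixture(**NORMAL_LV).assign(time_ms=lambda d: d.time_ms + i * 800.0)
             for i in range(25)],
            ignore_index=True)
        beat = segment_last_beat(fx, 800.0)
        assert beat["time_ms"].iloc[-1] - beat["time_ms"].iloc[0] == pytest.approx(
            800.0 - (fx.time_ms[1] - fx.time_ms[0]))

    def test_deterministic_and_tail_invariant(self):
        fx = pd.concat(
            [synth_pv_fixture(**NORMAL_LV).assign(time_ms=lambda d: d.time_ms + i * 800.0)
             for i in range(3)],
            ignore_index=True)
        b1 = segment_last_beat(fx, 800.0)
        b2 = segment_last_beat(fx, 800.0)
        pd.testing.assert_frame_equal(b1, b2)
        # only the final two cycles matter for the result
        tail = fx[fx.time_ms >= 800.0].reset_index(drop=True)
        b3 = segment_last_beat(tail, 800.0)
        pd.testing.assert_frame_equal(b1, b3)

    def test_too_short_rejected(self):
        fx = synth_pv_fixture(**NORMAL_LV)
        with pytest.raises(InsufficientDataError):
            segment_last_beat(fx, 800.0)


class TestCompareConditions:
    def test_identical_summaries_all_zero(self):
        fx = beatify(synth_pv_fixture(**NORMAL_LV))
        s = summarize_beat(fx, 800.0)
        table = compare_conditions({"normal": s, "hf": s, "hf_lvad": s})
        assert (table["percent_change"].dropna() == 0).all()

    def test_missing_condition_raises(self):
        fx = beatify(synth_pv_fixture(**NORMAL_LV))
        s = summarize_beat(fx, 800.0)
        with pytest.raises(KeyError):
            compare_conditions({"normal": s})


class TestIsovolumetricPhases:
    def test_classic_loop_has_two_phases(self):
        fx = synth_pv_fixture(**NORMAL_LV)
        phases = isovolumetric_phases(fx)
        assert len(phases) >= 2

    def test_flat_everything_has_none(self):
        t = np.arange(0, 800.0)
        df = pd.DataFrame({"time_ms": t, "v_lv": np.full_like(t, 100.0),
                           "p_lv": np.full_like(t, 10.0)})
        assert isovolumetric_phases(df) == []

    def test_pump_drained_ramp_not_isovolumetric(self):
        # volume falling at the 4 L/min pump drain rate while pressure rises
        t = np.arange(0, 200.0)
        df = pd.DataFrame({"time_ms": t, "v_lv": 120.0 - 0.0667 * t,
                           "p_lv": 5.0 + 0.4 * t})
        assert isovolumetric_phases(df) == []

    def test_threshold_must_be_positive(self):
        fx = synth_pv_fixture(**NORMAL_LV)
        with pytest.raises(InvalidParameterError):
            isovolumetric_phases(fx, dv_threshold_ml_per_10ms=0.0)
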