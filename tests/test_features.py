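import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cld4 import (FeatureKey, SensorSeries, build_feature_table,
                  derived_rates, extract_series_features, load_plan,
                  windowed_average)


def _series(values, interval_s=90.0, variable="pH"):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) * interval_s
    return SensorSeries("V1", variable, t, values, unit="-")


def _grid(days=16, interval_s=90.0):
    return np.arange(0, days * 86400 + 1, interval_s)


PH_KEYS = [FeatureKey.parse(k) for k in
           ("pH:max", "pH:min", "pH:end_point", "pH:avg", "pH:std",
            "pH:time_above_sp", "pH:time_below_sp")]


def test_constant_series_at_setpoint_spends_no_time_off_setpoint():
    t = _grid()
    s = SensorSeries("V1", "pH", t, np.full(t.size, 7.0))
    out = extract_series_features(s, PH_KEYS, setpoint=7.0)
    assert out["pH:time_above_sp"] == 0.0
    assert out["pH:time_below_sp"] == 0.0
    assert len(out) == 7  # the seven ticked pH statistics


def test_series_just_above_setpoint_counts_full_run_hours():
    t = _grid(16, 90.0)
    s = SensorSeries("V1", "pH", t, np.full(t.size, 7.05))
    out = extract_series_features(s, PH_KEYS, setpoint=7.0)
    assert out["pH:time_above_sp"] == pytest.approx(16 * 24, abs=1e-9)


def test_time_partition_sums_to_run_duration():
    rng = np.random.default_rng(0)
    t = _grid(4, 300.0)
    v = 7.0 + rng.normal(0, 0.05, t.size)
    v[::7] = 7.0  # some samples exactly at setpoint
    s = SensorSeries("V1", "pH", t, v)
    out = extract_series_features(
        s, [FeatureKey.parse("pH:time_above_sp"),
            FeatureKey.parse("pH:time_below_sp")], setpoint=7.0)
    at = (t[1:] - t[:-1])[v[:-1] == 7.0].sum() / 3600.0
    total = out["pH:time_above_sp"] + out["pH:time_below_sp"] + at
    assert total == pytest.approx(4 * 24)


def test_windowed_average_constant_and_piecewise():
    t = _grid(14, 3600.0)
    assert windowed_average(
        SensorSeries("V1", "pH", t, np.full(t.size, 7.05)), (0, 7)
    ) == pytest.approx(7.05)
    v = np.where(t / 86400.0 < 7, 7.1, 6.9)
    s = SensorSeries("V1", "pH", t, v)
    assert windowed_average(s, (0, 7)) == pytest.approx(7.1)
    # final window is closed on the right, so it includes the last sample
    assert windowed_average(s, (7, 14)) == pytest.approx(6.9)


def test_full_run_window_equals_plain_average():
    rng = np.random.default_rng(1)
    t = _grid(6, 1800.0)
    s = SensorSeries("V1", "pH", t, 7 + rng.normal(0, 0.02, t.size))
    full = windowed_average(s, (0, 6))
    plain = extract_series_features(
        s, [FeatureKey.parse("pH:avg")])["pH:avg"]
    assert full == pytest.approx(plain)


def test_empty_window_rejected():
    s = _series([7.0, 7.0])
    with pytest.raises(ValueError):
        windowed_average(s, (3, 3))


def test_cumulative_trapezoid_of_constant_rate_is_exact():
    t = _grid(16, 90.0)
    s = SensorSeries("V1", "Flow_O2", t, np.full(t.size, 0.5))
    out = extract_series_features(s, [FeatureKey.parse("Flow_O2:cumul")])
    assert out["Flow_O2:cumulative"] == pytest.approx(0.5 * 16.0)


def test_cumulative_variable_reports_final_value():
    t = _grid(2, 3600.0)
    s = SensorSeries("V1", "Base", t, np.linspace(0, 3.5, t.size))
    out = extract_series_features(s, [FeatureKey.parse("Base:cumul")])
    assert out["Base:cumulative"] == pytest.approx(3.5)


def test_empty_series_rejected():
    s = SensorSeries("V1", "pH", np.array([]), np.array([]))
    with pytest.raises(ValueError):
        extract_series_features(s, [FeatureKey.parse("pH:max")])
    with pytest.raises(ValueError, match="setpoint"):
        extract_series_features(_series([7.0, 7.1]),
                                [FeatureKey.parse("pH:time_above_sp")])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=-100, max_value=100), min_size=2,
                max_size=200))
def test_summary_statistic_ordering(values):
    s = _series(values)
    out = extract_series_features(
        s, [FeatureKey.parse(k) for k in ("pH:max", "pH:min", "pH:avg",
                                          "pH:std")])
    assert out["pH:max"] >= out["pH:avg"] >= out["pH:min"]
    assert out["pH:std"] >= 0.0


def test_qp_unit_conversion_hand_calculation():
    # constant VCD of 1e6 cells/mL, titre rising 10 mg/L over one day
    vcd = SensorSeries("V1", "VCD", np.array([0.0, 86400, 2 * 86400]),
                       np.array([1.0, 1.0, 1.0]))
    titre = SensorSeries("V1", "Titre", np.array([86400.0, 2 * 86400]),
                         np.array([5.0, 15.0]))
    rates = derived_rates(vcd, titre)
    q = rates["q_antibody"]
    assert q.values[-1] == pytest.approx(10.0)   # pg / cell / day
    assert q.unit == "pg/cell/day"


def test_growth_rate_of_doubling_is_ln2_and_zero_titre_change_gives_zero_q():
    vcd = SensorSeries("V1", "VCD", np.array([0.0, 86400.0]),
                       np.array([1.0, 2.0]))
    titre = SensorSeries("V1", "Titre", np.array([0.0, 86400.0]),
                         np.array([4.0, 4.0]))
    rates = derived_rates(vcd, titre, include_initial=False)
    assert rates["Spec_Growth_Rate"].values[0] == pytest.approx(np.log(2))
    assert rates["q_antibody"].values[0] == pytest.approx(0.0)


def test_derived_rates_error_cases():
    bad_vcd = SensorSeries("V1", "VCD", np.array([0.0, 86400.0]),
                           np.array([1.0, 0.0]))
    titre = SensorSeries("V1", "Titre", np.array([0.0, 86400.0]),
                         np.array([0.0, 5.0]))
    with pytest.raises(ValueError):
        derived_rates(bad_vcd, titre, include_initial=False)


def test_feature_table_shape_and_masking(small_features, small_config):
    assert len(small_features.clone_ids) == small_config.n_clones
    assert len(small_features.feature_names) == 20
    assert not small_features.mask.any().any()


def test_feature_table_round_trip(small_features, tmp_path):
    from cld4 import FeatureTable
    path = tmp_path / "feat.csv"
    small_features.to_csv(path)
    back = FeatureTable.from_csv(path)
    assert np.allclose(back.values, small_features.values, rtol=1e-7)
    assert back.feature_names == small_features.feature_names


def test_duplicate_feature_names_rejected():
    import pandas as pd

    from cld4 import FeatureTable
    df = pd.DataFrame([[1, 2]], columns=["a", "a"])
    with pytest.raises(ValueError):
        FeatureTable(df)


def test_analytics_plan_has_24_features():
    assert len(load_plan("analytics")) == 24
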