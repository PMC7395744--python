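"""Event ingestion, hourly binning, imputation, and preprocessing state."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earlywarn.ehr import Preprocessor, bin_hourly, impute, read_events
from tests.conftest import T0, make_timeline


@pytest.fixture()
def events_csv(tmp_path):
    path = tmp_path / "events.csv"
    path.write_text(
        "patient_id,admission_id,timestamp,parameter,value\n"
        "P1,A1,2020-03-01T02:00:00,Pulse rate,80\n"
        "P2,A2,2020-03-01T01:00:00,Pulse rate,70\n"
        "P1,A1,2020-03-01T00:00:00,Pulse rate,75\n"
        "P1,A1,2020-03-01T01:00:00,Temperature,37.1\n"
        "P2,A2,2020-03-01T03:00:00,SpO2,97\n"
    )
    return path


class TestReadEvents:
    def test_groups_and_sorts_interleaved_admissions(self, events_csv):
        timelines = {tl.admission_id: tl for tl in read_events(events_csv)}
        assert set(timelines) == {"A1", "A2"}
        a1 = timelines["A1"]
        assert len(a1.events) == 3
        assert a1.events["timestamp"].is_monotonic_increasing
        assert a1.patient_id == "P1"

    def test_non_numeric_value_error_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "patient_id,admission_id,timestamp,parameter,value\n"
            "P1,A1,2020-03-01T00:00:00,Pulse rate,75\n"
            "P1,A1,2020-03-01T01:00:00,Pulse rate,oops\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            read_events(path)

    def test_unknown_parameter_warns_and_drops_or_errors(self, tmp_path):
        path = tmp_path / "unk.csv"
        path.write_text(
            "patient_id,admission_id,timestamp,parameter,value\n"
            "P1,A1,2020-03-01T00:00:00,Pulse rate,75\n"
            "P1,A1,2020-03-01T01:00:00,Flux capacitance,1.21\n"
        )
        with pytest.warns(UserWarning, match="Flux capacitance"):
            (tl,) = read_events(path)
        assert len(tl.events) == 1
        with pytest.raises(ValueError, match="Flux capacitance"):
            read_events(path, strict=True)


class TestBinHourly:
    def test_default_window_has_24_bins(self, param_names):
        tl = make_timeline([(1, "Pulse rate", 80)])
        m = bin_hourly(tl, T0 + pd.Timedelta(hours=24), 24, param_names)
        assert m.values.shape == (24, len(param_names))
        assert m.n_bins == 24
        assert m.prediction_time == T0 + pd.Timedelta(hours=24)

    def test_same_hour_observations_average(self, param_names):
        tl = make_timeline([(0.25, "Pulse rate", 80), (0.75, "Pulse rate", 100)])
        m = bin_hourly(tl, T0 + pd.Timedelta(hours=24), 24, param_names)
        col = param_names.index("Pulse rate")
        assert m.values[0, col] == pytest.approx(90.0)
        assert m.mask[0, col]

    def test_unobserved_parameter_is_all_missing(self, param_names):
        tl = make_timeline([(1, "Pulse rate", 80)])
        m = bin_hourly(tl, T0 + pd.Timedelta(hours=24), 24, param_names)
        col = param_names.index("Temperature")
        assert np.isnan(m.values[:, col]).all()
        assert not m.mask[:, col].any()

    def test_empty_parameter_list_rejected(self):
        tl = make_timeline([(1, "Pulse rate", 80)])
        with pytest.raises(ValueError, match="empty"):
            bin_hourly(tl, T0 + pd.Timedelta(hours=24), 24, [])

    def test_boundary_event_at_prediction_time_included_future_excluded(self, param_names):
        tl = make_timeline(
            [(24, "Pulse rate", 90), (24.01, "Pulse rate", 500)],
            discharge=T0 + pd.Timedelta(hours=30),
        )
        m = bin_hourly(tl, T0 + pd.Timedelta(hours=24), 24, param_names)
        col = param_names.index("Pulse rate")
        assert m.values[23, col] == pytest.approx(90.0)

    def test_no_future_leakage(self, param_names, rng):
        """Events after the prediction time never change the window."""
        base = [(float(h), "Pulse rate", float(60 + h)) for h in range(1, 24)]
        future = [(25.0, "Pulse rate", 999.0), (40.0, "Temperature", 45.0)]
        pred = T0 + pd.Timedelta(hours=24)
        m1 = bin_hourly(make_timeline(base, discharge=T0 + pd.Timedelta(hours=50)), pred, 24, param_names)
        m2 = bin_hourly(make_timeline(base + future, discharge=T0 + pd.Timedelta(hours=50)), pred, 24, param_names)
        np.testing.assert_array_equal(np.nan_to_num(m1.values), np.nan_to_num(m2.values))

    def test_rebinning_hourly_regular_series_is_identity(self, param_names):
        """An already hourly-regular series is reproduced exactly."""
        vals = [70.0 + i for i in range(24)]
        tl = make_timeline([(i + 0.5, "Pulse rate", v) for i, v in enumerate(vals)])
        m = bin_hourly(tl, T0 + pd.Timedelta(hours=24), 24, param_names)
        col = param_names.index("Pulse rate")
        np.testing.assert_allclose(m.values[:, col], vals)

    @settings(deadline=None, max_examples=30)
    @given(perm=st.permutations(list(range(5))))
    def test_within_hour_permutation_invariance(self, perm, param_names):
        values = [80.0, 85.0, 90.0, 95.0, 100.0]
        minutes = [5, 15, 25, 35, 55]
        tl = make_timeline(
            [(minutes[i] / 60.0, "Pulse rate", values[perm[i]]) for i in range(5)]
        )
        m = bin_hourly(tl, T0 + pd.Timedelta(hours=24), 24, param_names)
        col = param_names.index("Pulse rate")
        assert m.values[0, col] == pytest.approx(np.mean(values))


class TestImpute:
    names = ["Pulse rate", "Temperature"]

    def _matrix(self, values):
        from earlywarn.ehr import HourlyMatrix

        values = np.asarray(values, dtype=float)
        return HourlyMatrix(
            values=values,
            mask=~np.isnan(values),
            bin_end_times=pd.date_range(T0, periods=len(values), freq="1h"),
            parameter_names=self.names,
        )

    def test_carry_forward_then_median(self):
        nan = np.nan
        m = self._matrix([[nan, 37.0], [nan, nan], [80.0, nan], [nan, nan], [nan, 38.0], [90.0, nan]])
        out = impute(m, {"Pulse rate": 75.0, "Temperature": 36.5})
        np.testing.assert_allclose(out.values[:, 0], [75, 75, 80, 80, 80, 90])
        np.testing.assert_allclose(out.values[:, 1], [37, 37, 37, 37, 38, 38])
        np.testing.assert_array_equal(out.mask, m.mask)

    def test_fully_observed_column_unchanged(self):
        m = self._matrix([[80.0, 37.0], [82.0, 37.5]])
        out = impute(m, {"Pulse rate": 0.0, "Temperature": 0.0})
        np.testing.assert_allclose(out.values, m.values)

    def test_fully_missing_column_gets_population_median(self):
        m = self._matrix([[np.nan, 37.0], [np.nan, 37.5]])
        out = impute(m, {"Pulse rate": 75.0, "Temperature": 0.0})
        np.testing.assert_allclose(out.values[:, 0], [75.0, 75.0])

    def test_missing_median_table_instructs_to_fit(self):
        m = self._matrix([[np.nan, 37.0]])
        with pytest.raises(ValueError, match="fit"):
            impute(m, {"Pulse rate": 75.0})


class TestPreprocessor:
    def test_round_trip_serialization_and_transform(self, param_names):
        tl = make_timeline(
            [(h, "Pulse rate", 70 + h) for h in range(24)]
            + [(h, "Temperature", 37.0) for h in range(0, 24, 6)]
        )
        w = bin_hourly(tl, T0 + pd.Timedelta(hours=24), 24, param_names)
        pre = Preprocessor(param_names).fit([w])
        x = pre.transform(w)
        assert x.shape == (24, len(param_names))
        assert np.isfinite(x).all()
        pre2 = Preprocessor.from_json(pre.to_json())
        np.testing.assert_allclose(pre2.transform(w), x)

    def test_transform_requires_fit(self, param_names):
        tl = make_timeline([(1, "Pulse rate", 80)])
        w = bin_hourly(tl, T0 + pd.Timedelta(hours=24), 24, param_names)
        with pytest.raises(ValueError, match="fit"):
            Preprocessor(param_names).transform(w)

    def test_winsorization_bounds_standardized_values(self, param_names):
        tl1 = make_timeline([(h, "P-C-reactive protein", 5.0) for h in range(24)])
        w1 = bin_hourly(tl1, T0 + pd.Timedelta(hours=24), 24, param_names)
        tl2 = make_timeline([(h, "P-C-reactive protein", 5.0 + h) for h in range(24)])
        w2 = bin_hourly(tl2, T0 + pd.Timedelta(hours=24), 24, param_names)
        pre = Preprocessor(param_names).fit([w1, w2])
        spike = make_timeline([(1, "P-C-reactive protein", 1e6)])
        ws = bin_hourly(spike, T0 + pd.Timedelta(hours=24), 24, param_names)
        assert np.abs(pre.transform(ws)).max() <= pre.clip_sigma + 1e-12
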