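import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cprtutor.mlt_io import (
    AnnotationInterval,
    AnnotationRecording,
    SensorFrame,
    SensorRecording,
)
from cprtutor.pipeline import build_features
from cprtutor.preprocessing import (
    FeatureTensor,
    MaskedSeries,
    PreprocessingError,
    assemble_tensor,
    build_attribute_table,
    build_interval_table,
    mask_by_intervals,
    resample_to_bins,
    sanitize_name,
)


# --------------------------------------------------------------------------
# independent brute-force oracle, written first: assign every raw sample to
# its bin by linear scan, average, then linearly interpolate empty bins
# (edge bins take the nearest non-empty value)


def oracle_resample(times, values, start, end, n_bins):
    bins = [[] for _ in range(n_bins)]
    width = (end - start) / n_bins
    for t, v in zip(times, values):
        if np.isnan(v):
            continue
        k = int((t - start) / width)
        if k == n_bins:  # t can sit just below end; guard float edge
            k -= 1
        bins[k].append(v)
    means = np.array([np.mean(b) if b else np.nan for b in bins])
    if np.isnan(means).all():
        return means
    filled = np.flatnonzero(~np.isnan(means))
    for k in np.flatnonzero(np.isnan(means)):
        below = filled[filled < k]
        above = filled[filled > k]
        if below.size == 0:
            means[k] = means[above[0]]
        elif above.size == 0:
            means[k] = means[below[-1]]
        else:
            lo, hi = below[-1], above[0]
            w = (k - lo) / (hi - lo)
            means[k] = (1 - w) * means[lo] + w * means[hi]
    return means


def _masked(times, values, start, end, name="a0"):
    frame = pd.DataFrame({name: values}, index=times)
    return MaskedSeries(start=start, end=end, frame=frame)


class TestIntervalTable:
    def test_duration_forced_subtraction(self):
        rec = AnnotationRecording(
            "s", "Annotation", [AnnotationInterval(7.070, 7.730, {"compDepth": 59.520001})]
        )
        table = build_interval_table([rec])
        assert table.loc[0, "duration"] == pytest.approx(0.660)

    def test_empty_recording_gives_empty_table(self):
        table = build_interval_table([AnnotationRecording("s", "Annotation", [])])
        assert len(table) == 0

    def test_two_sessions_same_relative_times_distinct_rows(self):
        intervals = [AnnotationInterval(1.0, 1.5), AnnotationInterval(2.0, 2.5)]
        rec_a = AnnotationRecording("a", "Annotation", list(intervals))
        rec_b = AnnotationRecording("b", "Annotation", list(intervals))
        table = build_interval_table([(rec_a, 0.0), (rec_b, 3600.0)])
        assert len(table) == 4
        assert table["abs_start"].nunique() == 4

    def test_label_and_measurement_columns_present(self):
        rec = AnnotationRecording(
            "s",
            "Annotation",
            [AnnotationInterval(0.0, 0.5, {"compDepth": 55.0}, {"classRate": 1})],
        )
        table = build_interval_table([rec])
        assert table.loc[0, "compDepth"] == 55.0
        assert table.loc[0, "classRate"] == 1

    def test_datetime_offset_accepted(self):
        from datetime import datetime

        rec = AnnotationRecording("s", "Annotation", [AnnotationInterval(1.0, 1.5)])
        table = build_interval_table([(rec, datetime(2019, 1, 1))])
        assert table.loc[0, "abs_start"] == datetime(2019, 1, 1).timestamp() + 1.0


class TestAttributeTable:
    def _recording(self, rows, names, name="Sensor"):
        frames = [
            SensorFrame(t, dict(zip(names, values))) for t, *values in rows
        ]
        return SensorRecording("id", name, frames)

    def test_all_zero_column_dropped(self):
        rec = self._recording([(0.0, 1.0, 0.0), (0.1, 2.0, 0.0)], ["a", "zero"])
        table = build_attribute_table([rec])
        assert list(table.columns) == ["a"]

    def test_excluded_joint_dropped(self):
        rec = self._recording(
            [(0.0, 1.99, 0.5), (0.1, 2.00, 0.6)], ["Kinect.HeadZ", "Kinect.HandLeftY"]
        )
        table = build_attribute_table([rec])
        assert "KinectHeadZ" not in table.columns
        assert "KinectHandLeftY" in table.columns

    def test_duplicate_timestamp_keeps_first(self):
        rec = self._recording([(0.5, 1.0), (0.5, 2.0), (0.6, 3.0)], ["a"])
        table = build_attribute_table([rec])
        assert len(table) == 2
        assert table.loc[0.5, "a"] == 1.0

    def test_name_sanitisation(self):
        assert sanitize_name("Myo.EMG_Pod0") == "MyoEMGPod0"
        rec = self._recording([(0.0, 1.0)], ["Myo.EMG_Pod0"])
        assert list(build_attribute_table([rec]).columns) == ["MyoEMGPod0"]

    def test_nothing_survives_is_hard_error(self):
        rec = self._recording([(0.0, 0.0), (0.1, 0.0)], ["zero"])
        with pytest.raises(PreprocessingError):
            build_attribute_table([rec])

    def test_streams_interleave_with_nan(self):
        a = self._recording([(0.0, 1.0), (0.2, 2.0)], ["a"], name="A")
        b = self._recording([(0.1, 5.0)], ["b"], name="B")
        table = build_attribute_table([a, b])
        assert list(table.index) == [0.0, 0.1, 0.2]
        assert np.isnan(table.loc[0.1, "a"])  # missing update is absent, not zero
        assert table.loc[0.1, "b"] == 5.0

    def test_time_offset_applied(self):
        rec = self._recording([(0.0, 1.0)], ["a"])
        rec.time_offset = 2.5
        table = build_attribute_table([rec])
        assert list(table.index) == [2.5]


class TestMasking:
    def _table(self, times):
        return pd.DataFrame({"a": np.arange(len(times), dtype=float)}, index=times)

    def test_half_open_convention(self):
        table = self._table([7.0, 7.5, 7.730, 7.8])
        intervals = build_interval_table(
            [AnnotationRecording("s", "A", [AnnotationInterval(7.070, 7.730)])]
        )
        (masked,) = mask_by_intervals(table, intervals)
        assert list(masked.frame.index) == [7.5]  # 7.730 == end excluded

    def test_start_included(self):
        table = self._table([7.070, 7.5])
        intervals = build_interval_table(
            [AnnotationRecording("s", "A", [AnnotationInterval(7.070, 7.730)])]
        )
        (masked,) = mask_by_intervals(table, intervals)
        assert list(masked.frame.index) == [7.070, 7.5]

    def test_empty_interval_flagged_not_raised(self):
        table = self._table([1.0])
        intervals = build_interval_table(
            [AnnotationRecording("s", "A", [AnnotationInterval(2.0, 2.5)])]
        )
        (masked,) = mask_by_intervals(table, intervals)
        assert masked.is_empty

    def test_masking_partitions_updates(self, small_cohort):
        # every raw update belongs to at most one compression
        labeled, _ = small_cohort
        session, intervals = labeled[0]
        table = build_attribute_table(session.sensor_recordings)
        interval_table = build_interval_table(
            [AnnotationRecording("s", "A", list(intervals))]
        )
        masked = mask_by_intervals(table, interval_table)
        total = sum(len(m.frame) for m in masked)
        starts = interval_table["start"].to_numpy()
        ends = interval_table["end"].to_numpy()
        t = table.index.to_numpy()
        in_any = ((t[:, None] >= starts) & (t[:, None] < ends)).sum(axis=1)
        assert in_any.max() <= 1
        assert total == int(in_any.sum())

    def test_kinect_updates_present_for_all_compressions(self, clean_session):
        # >= 1 update per interval at 30 Hz for intervals >= 0.44 s
        session, truth, _ = clean_session
        table = build_attribute_table(session.sensor_recordings)
        interval_table = build_interval_table(
            [AnnotationRecording("s", "A", list(truth.intervals))]
        )
        masked = mask_by_intervals(table, interval_table)
        assert all(not m.is_empty for m in masked)
        assert len(masked) == len(truth)


class TestResampler:
    def test_constant_series_preserved(self):
        times = np.linspace(0.0, 0.99, 17)
        out = resample_to_bins(_masked(times, np.full(17, 5.0), 0.0, 1.0), 8)
        np.testing.assert_allclose(out[:, 0], 5.0)

    def test_single_bin_is_global_mean(self):
        times = np.array([0.1, 0.3, 0.6])
        values = np.array([1.0, 2.0, 6.0])
        out = resample_to_bins(_masked(times, values, 0.0, 1.0), 1)
        assert out[0, 0] == pytest.approx(3.0)

    def test_linear_ramp_matches_oracle(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0.0, 1.0, 23))
        values = 2.0 * times + 1.0
        out = resample_to_bins(_masked(times, values, 0.0, 1.0), 8)
        expected = oracle_resample(times, values, 0.0, 1.0, 8)
        np.testing.assert_allclose(out[:, 0], expected)

    def test_all_empty_raises(self):
        with pytest.raises(PreprocessingError):
            resample_to_bins(_masked(np.array([]), np.array([]), 0.0, 1.0), 8)

    def test_single_empty_attribute_filled_with_zero(self):
        frame = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [np.nan, np.nan]}, index=[0.1, 0.2]
        )
        with pytest.warns(UserWarning, match="'b'"):
            out = resample_to_bins(MaskedSeries(0.0, 1.0, frame), 4)
        np.testing.assert_allclose(out[:, 1], 0.0)

    def test_invalid_bins(self):
        with pytest.raises(ValueError):
            resample_to_bins(_masked(np.array([0.1]), np.array([1.0]), 0.0, 1.0), 0)

    @settings(max_examples=300, deadline=None)
    @given(
        st.integers(min_value=1, max_value=40),
        st.integers(min_value=0, max_value=2**31 - 1),
        st.integers(min_value=1, max_value=12),
    )
    def test_oracle_equivalence_random_series(self, n_samples, seed, n_bins):
        rng = np.random.default_rng(seed)
        start, span = rng.uniform(0.0, 10.0), rng.uniform(0.1, 5.0)
        end = start + span
        times = np.sort(rng.uniform(start, end - 1e-9, n_samples))
        values = rng.normal(0.0, 10.0, n_samples)
        # knock out random entries to emulate sparse updates
        values[rng.random(n_samples) < 0.3] = np.nan
        expected = oracle_resample(times, values, start, end, n_bins)
        if np.isnan(expected).all():
            # every attribute empty -> hard error, caller decides drop-vs-fill
            with pytest.raises(PreprocessingError):
                resample_to_bins(_masked(times, values, start, end), n_bins)
        else:
            out = resample_to_bins(_masked(times, values, start, end), n_bins)
            np.testing.assert_allclose(out[:, 0], expected, rtol=1e-12, atol=1e-12)

    def test_mean_preservation_when_all_bins_filled(self):
        rng = np.random.default_rng(4)
        n_bins = 8
        times = np.concatenate(
            [rng.uniform(k / n_bins, (k + 1) / n_bins, 3) for k in range(n_bins)]
        )
        values = rng.normal(0.0, 1.0, times.size)
        out = resample_to_bins(_masked(np.sort(times), values, 0.0, 1.0), n_bins)
        expected = oracle_resample(np.sort(times), values, 0.0, 1.0, n_bins)
        assert out[:, 0].mean() == pytest.approx(expected.mean())


class TestAssembleTensor:
    def test_shape(self):
        arrays = [np.random.default_rng(i).random((8, 2)) for i in range(3)]
        tensor = assemble_tensor(arrays, ["a", "b"])
        assert tensor.shape == (3, 8, 2)

    def test_constant_attribute_scales_to_zero(self):
        arrays = [np.stack([np.full(8, 7.0), np.arange(8.0)], axis=1) for _ in range(2)]
        tensor = assemble_tensor(arrays, ["const", "ramp"])
        np.testing.assert_allclose(tensor.values[..., 0], 0.0)

    def test_nonconstant_attributes_hit_zero_and_one(self):
        rng = np.random.default_rng(1)
        arrays = [rng.random((8, 3)) * 10 - 5 for _ in range(4)]
        tensor = assemble_tensor(arrays, ["a", "b", "c"])
        for q in range(3):
            assert tensor.values[..., q].min() == pytest.approx(0.0)
            assert tensor.values[..., q].max() == pytest.approx(1.0)
        assert tensor.values.min() >= 0.0 and tensor.values.max() <= 1.0

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(PreprocessingError):
            assemble_tensor([np.zeros((8, 2)), np.zeros((8, 3))], ["a", "b"])

    def test_name_count_mismatch_rejected(self):
        with pytest.raises(PreprocessingError):
            assemble_tensor([np.zeros((8, 2))], ["a"])

    def test_scaling_metadata_round_trips(self, tmp_path):
        arrays = [np.random.default_rng(2).random((4, 2)) for _ in range(3)]
        tensor = assemble_tensor(arrays, ["a", "b"])
        tensor.save(tmp_path / "t")
        back = FeatureTensor.load(tmp_path / "t")
        np.testing.assert_array_equal(back.values, tensor.values)
        assert back.attribute_names == tensor.attribute_names
        np.testing.assert_allclose(back.scale_min, tensor.scale_min)


class TestEndToEnd:
    def test_tensor_n_matches_ground_truth_count(self, clean_session):
        session, truth, _ = clean_session
        tensor, table, log = build_features([(session, truth.intervals)])
        assert tensor.shape[0] == len(truth)
        assert tensor.shape[1] == 8
        assert log["intervals_dropped_empty"] == 0

    def test_arms_locked_separability_in_tensor(self):
        # cohort-level guarantee that the classification task is learnable
        from cprtutor.simulate import SimulationParams, simulate_session
        from datetime import datetime, timedelta

        sessions = []
        for i, locked in enumerate([True, False]):
            params = SimulationParams(arms_locked=locked, duration_s=10.0, seed=3)
            s, t = simulate_session(
                params,
                session_id=f"al-{i}",
                recording_datetime=datetime(2019, 1, 1) + timedelta(hours=i),
            )
            sessions.append((s, t.intervals))
        tensor, table, _ = build_features(sessions, scale=False)
        q = tensor.attribute_names.index("KinectElbowLeftY")
        n0 = len(sessions[0][1])
        locked_mean = tensor.values[:n0, :, q]
        unlocked_mean = tensor.values[n0:, :, q]
        diff = np.abs(locked_mean.mean(axis=0) - unlocked_mean.mean(axis=0)).mean()
        assert diff > 0.0
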