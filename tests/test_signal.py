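"""Recording model, rectification, adjacent windowing, and session I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from emglove.signal import (
    EmgRecording,
    GestureLabel,
    SignalError,
    read_session,
    rectify,
    samples_per_window,
    segment,
    window_labels,
    write_session,
)

signals = arrays(
    float,
    st.tuples(st.just(8), st.integers(60, 200)),
    elements=st.floats(-1.0, 1.0, allow_nan=False, width=32),
)


def make_recording(data, **kw):
    return EmgRecording(data=np.asarray(data, dtype=float), **kw)


class TestRecordingInvariants:
    def test_rejects_non_finite(self):
        with pytest.raises(SignalError, match="non-finite"):
            make_recording([[0.1, np.nan]])

    def test_rejects_out_of_range(self):
        with pytest.raises(SignalError, match="normalized range"):
            make_recording([[0.0, 1.5]])

    def test_rejects_overlapping_timeline(self):
        with pytest.raises(SignalError, match="overlap"):
            make_recording(
                np.zeros((8, 100)),
                timeline=[(0.0, 0.3, GestureLabel.RELAX), (0.2, 0.5, GestureLabel.FIST)],
            )


class TestRectify:
    @pytest.mark.parametrize(
        "data,expected",
        [([[0.5, -0.5]], [[0.5, 0.5]]), ([[0.0, 0.0, 0.0]], [[0.0, 0.0, 0.0]])],
    )
    def test_absolute_value(self, data, expected):
        out = rectify(make_recording(data))
        np.testing.assert_array_equal(out.data, expected)

    @settings(deadline=None, max_examples=25)
    @given(signals)
    def test_idempotent(self, data):
        once = rectify(make_recording(data))
        twice = rectify(once)
        np.testing.assert_array_equal(once.data, twice.data)

    @settings(deadline=None, max_examples=10)
    @given(signals)
    def test_commutes_with_segmentation(self, data):
        rec = make_recording(data)
        a = [w.data for w in segment(rectify(rec))]
        b = [np.abs(w.data) for w in segment(rec)]
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa, wb)


class TestSegment:
    def test_window_length_300ms_at_200hz(self):
        assert samples_per_window(300, 200) == 60

    @pytest.mark.parametrize("n_samples,n_windows", [(120, 2), (150, 2), (60, 1)])
    def test_adjacent_windows_with_floor_rule(self, n_samples, n_windows):
        rec = make_recording(np.zeros((8, n_samples)))
        ws = segment(rec)
        assert len(ws) == n_windows
        assert all(w.data.shape == (8, 60) for w in ws)
        assert [w.source_offset for w in ws] == [60 * i for i in range(n_windows)]

    def test_too_short_raises(self):
        with pytest.raises(SignalError, match="shorter than one"):
            segment(make_recording(np.zeros((8, 59))))

    def test_concatenation_reproduces_prefix(self):
        rng = np.random.default_rng(0)
        rec = make_recording(rng.uniform(-1, 1, (8, 150)))
        ws = segment(rec)
        np.testing.assert_array_equal(
            np.concatenate([w.data for w in ws], axis=1), rec.data[:, :120]
        )


class TestWindowLabels:
    def test_majority_with_tie_to_earlier_gesture(self):
        # 0.45 s relax + 0.45 s fist: second window splits 30/30 -> earlier label
        rec = make_recording(
            np.zeros((8, 180)),
            timeline=[(0.0, 0.45, GestureLabel.RELAX), (0.45, 0.9, GestureLabel.FIST)],
        )
        labels, boundary = window_labels(rec, segment(rec))
        assert labels == [GestureLabel.RELAX, GestureLabel.RELAX, GestureLabel.FIST]
        assert boundary.tolist() == [False, True, False]

    def test_majority_label(self):
        # boundary at 0.40 s: window [0.3, 0.6) is 1/3 relax, 2/3 fist
        rec = make_recording(
            np.zeros((8, 120)),
            timeline=[(0.0, 0.4, GestureLabel.RELAX), (0.4, 0.6, GestureLabel.FIST)],
        )
        labels, boundary = window_labels(rec, segment(rec))
        assert labels == [GestureLabel.RELAX, GestureLabel.FIST]
        assert boundary.tolist() == [False, True]


class TestSessionIO:
    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        rec = make_recording(rng.uniform(-1, 1, (8, 120)), label=GestureLabel.GRIP)
        path = tmp_path / "s.csv"
        write_session(rec, path)
        back = read_session(path)
        assert back.sample_rate == rec.sample_rate
        assert back.label == GestureLabel.GRIP
        np.testing.assert_allclose(back.data, rec.data, atol=1e-9)

    def test_hdf5_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(2)
        rec = make_recording(
            rng.uniform(-1, 1, (8, 200)),
            timeline=[(0.0, 0.5, GestureLabel.RELAX), (0.5, 1.0, GestureLabel.FIST)],
        )
        path = tmp_path / "s.h5"
        write_session(rec, path)
        back = read_session(path)
        np.testing.assert_array_equal(back.data, rec.data)
        assert back.timeline == rec.timeline

    def test_missing_header_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ch1,ch2\n0.0,0.0\n")
        with pytest.raises(SignalError, match="sample_rate"):
            read_session(path)

    def test_channel_count_mismatch_raises(self, tmp_path):
        rec = make_recording(np.zeros((4, 120)))
        path = tmp_path / "s.csv"
        write_session(rec, path)
        with pytest.raises(SignalError, match="channels"):
            read_session(path, channel_count=8)

    def test_out_of_range_amplitudes_raise(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# sample_rate: 200\nch1\n2.5\n")
        with pytest.raises(SignalError, match="normalized range"):
            read_session(path)
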