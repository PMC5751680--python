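"""Temporal variable derivation: durations, IOI, IPI, short subsets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sealrhythm.features import (
    CallRecord,
    IntervalSeries,
    durations,
    filter_short,
    inter_onset_intervals,
    inter_peak_intervals,
    read_series_csv,
    short_threshold,
    write_series_csv,
)
from sealrhythm.textgrid import CallAnnotation


def _call(onset, offset, peak=None):
    peak = onset + 0.3 * (offset - onset) if peak is None else peak
    return CallRecord(CallAnnotation("MAC", onset, offset), peak, 75.0)


def _calls_from_onsets(onsets, dur=0.9, peak_offset=0.3):
    return [_call(o, o + dur, o + peak_offset) for o in onsets]


def test_durations_single_call():
    s = durations([_call(1.0, 1.9761)])
    assert s.kind == "duration"
    assert s.values == pytest.approx([976.1])


def test_durations_empty_and_constant():
    assert len(durations([])) == 0
    s = durations(_calls_from_onsets([0.0, 2.0, 4.0], dur=1.0))
    assert s.values == pytest.approx([1000.0, 1000.0, 1000.0])


def test_ioi_basic():
    s = inter_onset_intervals(_calls_from_onsets([0.0, 1.0, 2.5]))
    assert s.kind == "IOI"
    assert s.values == pytest.approx([1000.0, 1500.0])


def test_ioi_lengths():
    assert len(inter_onset_intervals([])) == 0
    assert len(inter_onset_intervals(_calls_from_onsets([3.0]))) == 0
    onsets = np.arange(100) * 2.0
    s = inter_onset_intervals(_calls_from_onsets(onsets))
    assert len(s) == 99
    assert np.all(s.values == pytest.approx(2000.0))


def test_duplicate_onsets_rejected():
    calls = [_call(1.0, 1.5), _call(1.0, 1.8)]
    with pytest.raises(ValueError, match="non-positive|duplicate"):
        inter_onset_intervals(calls)


def test_unsorted_calls_rejected():
    with pytest.raises(ValueError, match="sorted"):
        durations(_calls_from_onsets([2.0, 0.0]))


def test_ipi_equals_ioi_for_constant_peak_offset():
    calls = _calls_from_onsets([0.0, 1.3, 4.1, 4.9], peak_offset=0.3)
    assert inter_peak_intervals(calls).values == pytest.approx(
        inter_onset_intervals(calls).values
    )


def test_ipi_from_explicit_peaks():
    calls = [_call(0.0, 1.0, 0.3), _call(2.0, 3.0, 2.4)]
    assert inter_peak_intervals(calls).values == pytest.approx([2100.0])


def test_ipi_minus_ioi_is_peak_offset_difference():
    rng = np.random.default_rng(3)
    onsets = np.cumsum(rng.uniform(1.5, 3.0, 20))
    offsets = rng.uniform(0.1, 0.8, 20)
    calls = [_call(o, o + 1.0, o + po) for o, po in zip(onsets, offsets)]
    ipi = inter_peak_intervals(calls).values
    ioi = inter_onset_intervals(calls).values
    assert ipi - ioi == pytest.approx(np.diff(offsets) * 1000.0)


def test_non_increasing_peaks_rejected():
    calls = [_call(0.0, 3.0, 2.9), _call(2.95, 4.0, 2.951)]
    inter_peak_intervals(calls)  # increasing: fine
    bad = [_call(0.0, 3.0, 2.9), _call(2.5, 4.0, 2.6)]
    with pytest.raises(ValueError, match="non-increasing"):
        inter_peak_intervals(bad)


# ---------------------------------------------------------------------------
# short-interval filtering


def test_short_threshold_matches_observed_rule():
    s = IntervalSeries("IOI", np.array([975.0, 2000.0, 8000.0]))
    assert short_threshold(s, 4) == pytest.approx(3900.0)
    assert short_threshold(s, 1) == pytest.approx(975.0)


def test_short_threshold_homogeneity():
    s = IntervalSeries("IOI", np.array([800.0, 1600.0]))
    assert short_threshold(s, 4) * 2.5 == pytest.approx(
        short_threshold(IntervalSeries("IOI", s.values * 2.5), 4)
    )


def test_short_threshold_empty_errors():
    with pytest.raises(ValueError):
        short_threshold(IntervalSeries("IOI"))


def test_filter_short_boundary_inclusive():
    s = IntervalSeries("IOI", np.array([975.0, 2000.0, 5000.0, 3900.0]))
    out = filter_short(s, 3900.0)
    assert out.kind == "IOI_short"
    assert out.values == pytest.approx([975.0, 2000.0, 3900.0])
    strict = filter_short(s, 3900.0, inclusive=False)
    assert strict.values == pytest.approx([975.0, 2000.0])


def test_filter_short_extremes():
    s = IntervalSeries("IPI", np.array([1000.0, 2000.0]))
    assert len(filter_short(s, 10.0)) == 0
    assert filter_short(s, 1e9).values == pytest.approx(s.values)
    assert filter_short(s, 1e9).kind == "IPI_short"


def test_filter_short_rejects_non_interval_kinds():
    with pytest.raises(ValueError):
        filter_short(IntervalSeries("duration", np.array([1.0])), 10.0)


@given(scale=st.floats(min_value=0.01, max_value=100.0))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_time_unit_homogeneity(scale):
    onsets = [0.0, 1.7, 3.1, 8.4]
    a = inter_onset_intervals(_calls_from_onsets(onsets, dur=0.5))
    b = inter_onset_intervals(
        _calls_from_onsets(
            [o * scale for o in onsets], dur=0.5 * scale, peak_offset=0.3 * scale
        )
    )
    assert b.values == pytest.approx(a.values * scale, rel=1e-9)


# ---------------------------------------------------------------------------
# CSV round trip


def test_series_csv_round_trip(tmp_path):
    s = IntervalSeries("IOI", np.array([975.04, 2000.0, 3899.96]))
    p = tmp_path / "IOI_all.csv"
    write_series_csv(s, p)
    back = read_series_csv(p)
    assert back.kind == "IOI"
    assert back.values == pytest.approx([975.0, 2000.0, 3900.0])


def test_series_csv_non_numeric_cell_names_row(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("IOI\n1000\nbogus\n")
    with pytest.raises(ValueError, match="row 3"):
        read_series_csv(p)


def test_headerless_csv_readable(tmp_path):
    p = tmp_path / "plain.csv"
    p.write_text("1000.0\n2000.0\n")
    s = read_series_csv(p, kind="IPI")
    assert s.kind == "IPI"
    assert len(s) == 2


def test_interval_series_rejects_nonpositive():
    with pytest.raises(ValueError):
        IntervalSeries("IOI", np.array([1000.0, 0.0]))
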