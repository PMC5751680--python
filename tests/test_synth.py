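"""Synthetic call-sequence generator: determinism, geometry, statistics."""

import json

import numpy as np
import pytest

from sealrhythm.intensity import intensity_contour, peak_in_interval
from sealrhythm.synth import (
    BetaDist,
    Fixed,
    GroundTruth,
    LogNormal,
    ShiftedPoisson,
    SyntheticSpec,
    TruncNormal,
    emit_fixture,
    render_audio,
    sample_sequence,
    truth_to_tier,
)
from sealrhythm.textgrid import read_textgrid, select_calls


def _degenerate_spec(**kw):
    defaults = dict(
        n_bouts=1,
        calls_per_bout=3,
        within_ioi=Fixed(2000.0),
        duration=Fixed(1000.0),
        peak_rel_pos=0.3,
        rate=8000.0,
        seed=1,
    )
    defaults.update(kw)
    return SyntheticSpec(**defaults)


def test_degenerate_sequence_geometry():
    truth = sample_sequence(_degenerate_spec())
    onsets = [c.onset for c in truth.calls]
    t0 = onsets[0]
    assert onsets == pytest.approx([t0, t0 + 2.0, t0 + 4.0])
    for c in truth.calls:
        assert c.peak_time == pytest.approx(c.onset + 0.3)
        assert c.offset == pytest.approx(c.onset + 1.0)


def test_same_seed_same_truth():
    spec = SyntheticSpec(n_bouts=4, seed=99, rate=8000.0)
    t1, t2 = sample_sequence(spec), sample_sequence(spec)
    assert t1.calls == t2.calls


def test_different_seed_different_truth():
    a = sample_sequence(SyntheticSpec(n_bouts=2, seed=1, rate=8000.0))
    b = sample_sequence(SyntheticSpec(n_bouts=2, seed=2, rate=8000.0))
    assert a.calls != b.calls


def test_calls_never_overlap_and_bouts_are_separated():
    truth = sample_sequence(SyntheticSpec(n_bouts=12, seed=5, rate=8000.0))
    for a, b in zip(truth.calls, truth.calls[1:]):
        assert b.onset > a.offset
        gap_ms = (b.onset - a.onset) * 1000.0
        if b.bout != a.bout:
            assert gap_ms > 5000.0  # between-bout gaps clear the cutoff regime


def test_within_bout_ioi_mean_near_calibration_target():
    # realized within-bout IOIs should land near the observed 1983.2 ms;
    # CLT bound uses the observed SD 722.1
    truth = sample_sequence(SyntheticSpec(n_bouts=50, calls_per_bout=5, seed=17))
    within = [
        (b.onset - a.onset) * 1000.0
        for a, b in zip(truth.calls, truth.calls[1:])
        if a.bout == b.bout
    ]
    assert len(within) == 50 * 4
    bound = 3 * 722.1 / np.sqrt(len(within))
    assert abs(np.mean(within) - 1983.2) < bound


def test_duration_mean_recovers_spec_value():
    truth = sample_sequence(SyntheticSpec(n_bouts=50, calls_per_bout=5, seed=23))
    durs = [(c.offset - c.onset) * 1000.0 for c in truth.calls]
    bound = 3 * 205.7 / np.sqrt(len(durs))
    assert abs(np.mean(durs) - 976.1) < bound


def test_two_timescale_signature():
    # pooled interval CV well above within-bout CV, as in the study animal
    truth = sample_sequence(SyntheticSpec(n_bouts=30, calls_per_bout=5, seed=31))
    onsets = np.array([c.onset for c in truth.calls])
    bouts = np.array([c.bout for c in truth.calls])
    ioi = np.diff(onsets) * 1000.0
    within = ioi[bouts[1:] == bouts[:-1]]
    cv = lambda x: x.std(ddof=1) / x.mean()
    assert cv(ioi) > cv(within)
    assert cv(ioi) > 0.6


def test_infeasible_spec_errors():
    spec = _degenerate_spec(within_ioi=Fixed(500.0), duration=Fixed(1000.0))
    with pytest.raises(ValueError, match="infeasible"):
        sample_sequence(spec)


def test_stochastic_count_and_peak_distributions():
    spec = SyntheticSpec(
        n_bouts=20,
        calls_per_bout=ShiftedPoisson(3.0, shift=1),
        peak_rel_pos=BetaDist(2.0, 4.0),
        seed=41,
        rate=8000.0,
    )
    truth = sample_sequence(spec)
    per_bout = np.bincount([c.bout for c in truth.calls])
    assert per_bout.min() >= 1
    rels = [
        (c.peak_time - c.onset) / (c.offset - c.onset) for c in truth.calls
    ]
    assert 0.0 < min(rels) and max(rels) < 1.0
    assert np.std(rels) > 0.01  # actually drawn, not constant


# ---------------------------------------------------------------------------
# audio rendering


def test_zero_call_recording_is_silence():
    spec = _degenerate_spec(n_bouts=0)
    truth = sample_sequence(spec)
    w = render_audio(truth, spec)
    assert len(w.samples) > 0
    assert np.all(w.samples == 0.0)


def test_rendered_peak_matches_truth():
    spec = _degenerate_spec(n_bouts=1, calls_per_bout=1)
    truth = sample_sequence(spec)
    w = render_audio(truth, spec)
    c = intensity_contour(w)
    call = truth.calls[0]
    lead = spec.lead_in_s
    t, _ = peak_in_interval(c, lead + call.onset, lead + call.offset)
    assert abs(t - (lead + call.peak_time)) <= c.step


def test_envelope_gain_invariance():
    spec = _degenerate_spec(n_bouts=1, calls_per_bout=1)
    truth = sample_sequence(spec)
    w = render_audio(truth, spec)
    c1 = intensity_contour(w)
    c2 = intensity_contour(type(w)(w.samples * 2.0, w.rate))
    call = truth.calls[0]
    lead = spec.lead_in_s
    t1, _ = peak_in_interval(c1, lead + call.onset, lead + call.offset)
    t2, _ = peak_in_interval(c2, lead + call.onset, lead + call.offset)
    assert t1 == t2


def test_noise_floor_stays_60db_below_calls():
    spec = _degenerate_spec(noise_floor_db=-70.0)
    truth = sample_sequence(spec)
    w = render_audio(truth, spec)
    c = intensity_contour(w)
    call_db = max(
        peak_in_interval(c, spec.lead_in_s + x.onset, spec.lead_in_s + x.offset)[1]
        for x in truth.calls
    )
    # frames before the first call carry only the floor
    pre = c.values[c.times < spec.lead_in_s - 0.05]
    assert call_db - pre.max() >= 60.0


# ---------------------------------------------------------------------------
# fixture emission


def test_fixture_files_and_annotation(tmp_path):
    spec = _degenerate_spec(n_bouts=2)
    paths = emit_fixture(spec, tmp_path / "fix")
    assert all(p.exists() for p in paths.values())
    tiers = read_textgrid(paths["textgrid"])
    macs = select_calls(tiers[0], {"MAC"})
    assert len(macs) == 6  # 2 bouts x 3 calls


def test_truth_json_round_trip(tmp_path):
    spec = SyntheticSpec(n_bouts=3, seed=13, rate=8000.0,
                         peak_rel_pos=BetaDist(2.0, 2.0),
                         calls_per_bout=ShiftedPoisson(2.0))
    paths = emit_fixture(spec, tmp_path / "fix")
    text = paths["truth"].read_text()
    back = GroundTruth.from_json(text)
    assert back.spec == spec
    assert back.calls == sample_sequence(spec).calls
    json.loads(text)  # valid JSON document


def test_distractor_calls_are_labelled_other(tmp_path):
    spec = SyntheticSpec(n_bouts=4, n_distractors=2, seed=3, rate=8000.0)
    truth = sample_sequence(spec)
    labels = {c.label for c in truth.calls}
    assert "other" in labels
    tier = truth_to_tier(truth)
    assert len(select_calls(tier, {"MAC"})) == len(truth.mac_calls)
    assert len(select_calls(tier, {"MAC", "other"})) == len(truth.calls)
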