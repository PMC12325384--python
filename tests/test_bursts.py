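"""Burst classification and analysis-window extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lfpdecode as L
from lfpdecode.bursts import BurstMask, candidate_windows


def test_window_sd_constant_signal_is_zero():
    sd = L.window_sd(np.full((3, 1000), 4.2))
    assert sd.shape == (3, 10)
    assert np.all(sd == 0)


def test_window_sd_of_full_sine_cycle_is_inverse_sqrt2():
    t = np.arange(1000) / 1000.0
    sd = L.window_sd(np.sin(2 * np.pi * 10 * t)[None, :])
    assert sd == pytest.approx(1 / np.sqrt(2), rel=1e-9)


def test_window_sd_discards_partial_trailing_window():
    assert L.window_sd(np.zeros((2, 1057))).shape == (2, 10)
    with pytest.raises(ValueError):
        L.window_sd(np.zeros((2, 0)))
    with pytest.raises(ValueError, match="shorter"):
        L.window_sd(np.zeros((2, 50)))


def test_classify_all_quiet_gives_empty_mask():
    mask = L.classify_bursts(np.zeros((30, 50)), site_count_threshold=24)
    assert len(mask.intervals) == 0
    assert mask.total_burst_ms == 0


def _sd_with_runs(run_windows, n_sites=30, n_win=60):
    """SD series: baseline 1 everywhere, 10x at the given window indices."""
    rng = np.random.default_rng(0)
    sd = 1.0 + 0.01 * rng.random((n_sites, n_win))
    for j in run_windows:
        sd[:, j] = 10.0
    return sd


def test_single_window_run_fails_the_150ms_rule():
    mask = L.classify_bursts(_sd_with_runs([10]), site_count_threshold=24,
                             min_duration_ms=150)
    assert len(mask.intervals) == 0


def test_two_window_run_becomes_one_interval():
    mask = L.classify_bursts(_sd_with_runs([10, 11]), site_count_threshold=24)
    assert np.array_equal(mask.intervals, [[1000.0, 1200.0]])


def test_site_count_threshold_is_strict():
    """'More than 24 sites' means 25 trigger, 24 do not."""
    sd = _sd_with_runs([], n_sites=30)
    sd[:24, 10:12] = 10.0
    assert len(L.classify_bursts(sd, site_count_threshold=24).intervals) == 0
    sd[:25, 10:12] = 10.0
    assert len(L.classify_bursts(sd, site_count_threshold=24).intervals) == 1


@given(st.integers(0, 2 ** 31 - 1))
def test_mask_invariant_under_site_permutation(seed):
    rng = np.random.default_rng(seed)
    sd = np.abs(rng.lognormal(0, 1, size=(12, 40)))
    sd[:, 5:8] *= 50
    a = L.classify_bursts(sd, site_count_threshold=3)
    b = L.classify_bursts(sd[rng.permutation(12)], site_count_threshold=3)
    assert np.array_equal(a.intervals, b.intervals)


def test_lower_sd_threshold_never_shrinks_burst_duration(rng):
    sd = np.abs(rng.lognormal(0, 1, size=(30, 100)))
    sd[:, 20:24] *= 30
    sd[:, 60:62] *= 8
    totals = [L.classify_bursts(sd, site_count_threshold=24, sd_multiplier=m
                                ).total_burst_ms for m in (5.0, 3.0, 2.0, 1.0, 0.5)]
    assert all(b >= a for a, b in zip(totals, totals[1:]))


# ---------------------------------------------------------------------------
# analysis-window extraction (on a handcrafted silent session)
# ---------------------------------------------------------------------------


def _flat_session(tone_s=29.0, gap_s=1.0, reps=7):
    grid = L.make_grid(3, 3, False)
    sched = L.TrialSchedule.make(tone_frequencies=(8000, 16000), repetitions=reps,
                                 tone_duration_s=tone_s, gap_duration_s=gap_s, seed=2)
    n = int(sched.total_duration_s * 1000)
    return L.RecordingSession("flat", np.zeros((9, n), dtype=np.float32), 1000,
                              grid, sched)


def _empty_mask():
    return BurstMask(intervals=np.empty((0, 2)), sd_series=np.zeros((9, 1)),
                     exceed_counts=np.zeros(1), sd_thresholds=np.zeros(9),
                     site_count_threshold=2, min_duration_ms=150.0)


def test_candidate_tiling_of_29s_tones():
    """29-s tone, 1-s onset exclusion, 1-s windows: 28 candidates per trial,
    196 per label over 7 repetitions."""
    sess = _flat_session()
    cands = candidate_windows(sess)
    per_trial = [w for w in cands if w.trial_index == 0]
    assert len(per_trial) == 28
    assert len([w for w in cands if w.label_hz == 8000]) == 196


def test_exactly_n_per_label_selected():
    sess = _flat_session()
    windows = L.extract_analysis_windows(sess, _empty_mask(), n_per_label=70)
    labels, counts = np.unique([w.label_hz for w in windows], return_counts=True)
    assert list(labels) == [8000, 16000]
    assert np.all(counts == 70)


def test_shortfall_raises_named_error():
    sess = _flat_session()
    with pytest.raises(L.WindowShortfallError, match="8000 Hz.*196.*200"):
        L.extract_analysis_windows(sess, _empty_mask(), n_per_label=200)


def test_burst_spanning_trial_removes_its_candidates():
    sess = _flat_session()
    first_freq = sess.schedule.trials[0][0]
    mask = _empty_mask()
    mask.intervals = np.array([[0.0, 30000.0]])  # covers trial 0 entirely
    cands = [w for w in candidate_windows(sess)
             if not mask.overlaps(w.start_ms, w.start_ms + w.length_ms)]
    assert len([w for w in cands if w.trial_index == 0]) == 0
    assert len([w for w in cands if w.label_hz == first_freq]) == 168  # 6 trials


def test_window_length_must_match_sample_grid():
    sess = _flat_session()
    with pytest.raises(ValueError, match="multiple of the sample period"):
        candidate_windows(sess, window_ms=10.5)


def test_no_retained_window_overlaps_a_burst(desk_session, desk_mask, desk_windows):
    assert len(desk_mask.intervals) > 0  # the default generator plants bursts
    for w in desk_windows:
        assert not desk_mask.overlaps(w.start_ms, w.start_ms + w.length_ms)
    for w in desk_windows:  # and each window sits >= 1 s into its tone
        _, onset_s, dur_s = desk_session.schedule.trials[w.trial_index]
        assert w.start_ms >= onset_s * 1000 + 1000
        assert w.start_ms + w.length_ms <= (onset_s + dur_s) * 1000


def test_interval_jaccard_basics():
    a = [[0, 100], [200, 300]]
    assert L.interval_jaccard(a, a) == 1.0
    assert L.interval_jaccard(a, [[0, 100]]) == pytest.approx(0.5)
    assert L.interval_jaccard([], []) == 1.0
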