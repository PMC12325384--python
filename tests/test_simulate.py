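"""Synthetic LFP generator: geometry, determinism, planted ground truth."""

import dataclasses

import numpy as np
import pytest

import lfpdecode as L
from lfpdecode.features import BANDS, analytic_phase, bandpass, plv_matrix
from lfpdecode.simulate import BandParams, GeneratorParams, _default_bands


@pytest.mark.parametrize("rows,cols,corners_off,expected", [
    (10, 10, True, 96),
    (2, 2, True, 0),
    (10, 10, False, 100),
    (5, 5, True, 21),
])
def test_grid_active_site_counts(rows, cols, corners_off, expected):
    assert L.make_grid(rows, cols, corners_off).n_active == expected


def test_grid_rejects_degenerate_dimensions():
    with pytest.raises(ValueError, match="2x2"):
        L.make_grid(1, 10)


def test_grid_positions_unique_and_within_extent():
    g = L.make_grid(10, 10, True)
    pos = g.positions_mm
    assert len(np.unique(pos, axis=0)) == 96
    assert pos.min() >= 0 and pos.max() <= g.extent_mm


def test_schedule_balance_and_total_duration():
    s = L.TrialSchedule.make(seed=3)
    counts = np.bincount(np.asarray(s.order))
    assert np.all(counts == 7)
    assert s.total_duration_s == 35 * 58
    with pytest.raises(ValueError, match="exactly"):
        L.TrialSchedule(order=(0,) * 35)


def _silent_params():
    bands = {n: BandParams(0.0, 0.0, 0.5) for n in _default_bands()}
    return GeneratorParams(bands=bands, noise_rms_uv=0.0, burst_rate_per_min=0.0)


def test_silence_when_everything_is_zero(desk_grid, desk_schedule):
    sess = L.simulate_session(desk_grid, desk_schedule, _silent_params(), 0)
    assert np.all(sess.lfp == 0)


def test_session_determinism(desk_grid, desk_schedule):
    p = GeneratorParams()
    a = L.simulate_session(desk_grid, desk_schedule, p, 42)
    b = L.simulate_session(desk_grid, desk_schedule, p, 42)
    c = L.simulate_session(desk_grid, desk_schedule, p, 43)
    assert np.array_equal(a.lfp, b.lfp)
    assert not np.array_equal(a.lfp, c.lfp)


def test_full_coupling_yields_unit_plv(desk_grid):
    """kappa = 1 (zero jitter) makes all sites share one phase: PLV = 1."""
    bands = {n: BandParams(0.0, 0.0, 0.5) for n in _default_bands()}
    bands["high-gamma"] = BandParams(5.0, 0.0, 1.0)
    p = GeneratorParams(bands=bands, noise_rms_uv=0.0, burst_rate_per_min=0.0)
    sched = L.TrialSchedule.make(repetitions=1, tone_duration_s=5.0,
                                 gap_duration_s=1.0, seed=0)
    sess = L.simulate_session(desk_grid, sched, p, 5)
    filt = bandpass(sess.lfp[:, 2000:3000], BANDS["high-gamma"])
    plv = plv_matrix(analytic_phase(filt))
    assert np.all(plv > 0.999)


def test_planted_burst_log_is_poisson_and_well_formed(desk_grid):
    """2 events/min over 10 min: the ground-truth log holds ~20 events,
    non-overlapping, lattice-aligned, with durations inside the range."""
    sched = L.TrialSchedule.make(repetitions=2, tone_duration_s=30.0,
                                 gap_duration_s=30.0, seed=0)
    assert sched.total_duration_s == 600
    sess = L.simulate_session(desk_grid, sched, GeneratorParams(), 99)
    events = np.asarray(sess.ground_truth["bursts"])
    n = len(events)
    assert 7 <= n <= 38  # 99.9% Poisson(20) envelope
    durations = events[:, 1] - events[:, 0]
    assert np.all(durations >= 200) and np.all(durations <= 500)
    assert np.all(events[:, 0] % 100 == 0)
    assert np.all(events[1:, 0] >= events[:-1, 1])  # sorted, disjoint


def test_apply_vns_effect_identity_and_arithmetic():
    p = GeneratorParams()
    ident = L.apply_vns_effect(p, L.VnsEffect())
    assert ident.bands == p.bands
    doubled = L.apply_vns_effect(p, L.VnsEffect(contrast_mult={"theta": 2.0}))
    assert doubled.bands["theta"].contrast == pytest.approx(
        2.0 * p.bands["theta"].contrast)
    assert doubled.bands["alpha"] == p.bands["alpha"]


def test_apply_vns_effect_clips_coupling_with_warning(caplog):
    p = GeneratorParams()
    with caplog.at_level("WARNING"):
        out = L.apply_vns_effect(p, L.VnsEffect(coupling_mult={"high-gamma": 5.0}))
    assert out.bands["high-gamma"].coupling == 1.0
    assert any("clipped" in r.message for r in caplog.records)


def test_effect_rejects_nonpositive_multipliers():
    with pytest.raises(ValueError, match="> 0"):
        L.VnsEffect(contrast_mult={"theta": 0.0})


def test_params_validation_rejects_inconsistent_geometry(desk_grid, desk_schedule):
    bad_focus = dataclasses.replace(
        GeneratorParams(),
        focus_layouts={**GeneratorParams().focus_layouts,
                       8000: [(9.0, 1.0, 1.0)]})
    with pytest.raises(ValueError, match="outside"):
        L.simulate_session(desk_grid, desk_schedule, bad_focus, 0)
    long_burst = dataclasses.replace(GeneratorParams(),
                                     burst_duration_ms=(150.0, 20000.0))
    with pytest.raises(ValueError, match="shorter than a tone"):
        L.simulate_session(desk_grid, desk_schedule, long_burst, 0)
    with pytest.raises(ValueError, match="kappa"):
        BandParams(1.0, 0.5, 1.5)


def test_cohort_determinism_distinct_animals(desk_grid):
    sk = dict(repetitions=1, tone_duration_s=5.0, gap_duration_s=1.0)
    kwargs = dict(grid=desk_grid, schedule_kwargs=sk)
    a = L.simulate_cohort(2, "L5/6", GeneratorParams(), L.VnsEffect(), 8, **kwargs)
    b = L.simulate_cohort(2, "L5/6", GeneratorParams(), L.VnsEffect(), 8, **kwargs)
    assert all(np.array_equal(x[0].lfp, y[0].lfp) and np.array_equal(x[1].lfp, y[1].lfp)
               for x, y in zip(a, b))
    assert not np.array_equal(a[0][0].lfp, a[1][0].lfp)  # animals differ
    # identity effect: pre/post parameters identical, realizations differ
    pre, post = a[0]
    assert pre.ground_truth["params"].bands == post.ground_truth["params"].bands
    assert not np.array_equal(pre.lfp, post.lfp)
    with pytest.raises(ValueError, match=">= 1"):
        L.simulate_cohort(0, "L4", GeneratorParams(), L.VnsEffect(), 1, **kwargs)
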