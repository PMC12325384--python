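"""Burst-suppression screening and extraction of non-burst analysis windows.

Under isoflurane anesthesia the LFP alternates between high-amplitude
bursts that are synchronized across the array and low-amplitude
quiescence.  Bursts carry no stimulus information and are excluded:
an epoch is classified as bursting when the per-100-ms standard
deviation exceeds a per-site threshold at more than ``site_count_threshold``
recording sites and the run persists for at least ``min_duration_ms``.
The surviving recording is tiled into non-overlapping 1,000-ms analysis
windows that start at least one second after tone onset (the transient
onset response is excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import RecordingSession


class WindowShortfallError(RuntimeError):
    """Raised when a label has fewer surviving candidate windows than requested."""

    def __init__(self, label_hz: int, available: int, requested: int):
        self.label_hz = label_hz
        self.available = available
        self.requested = requested
        super().__init__(
            f"label {label_hz} Hz: only {available} non-burst candidate windows "
            f"available, {requested} requested")


def window_sd(lfp: np.ndarray, win_ms: int = 100, fs: int = 1000) -> np.ndarray:
    """Per-site SD of consecutive non-overlapping windows.

    Returns an (n_sites, n_windows) array; a partial trailing window is
    discarded.  Population SD (ddof=0) is used.
    """
    lfp = np.asarray(lfp)
    if lfp.ndim != 2 or lfp.shape[1] == 0:
        raise ValueError("lfp must be a non-empty (sites x samples) array")
    win = int(round(win_ms * fs / 1000))
    n_win = lfp.shape[1] // win
    if n_win < 1:
        raise ValueError(f"signal shorter than one {win_ms}-ms window")
    x = lfp[:, : n_win * win].reshape(lfp.shape[0], n_win, win)
    return x.std(axis=-1)


@dataclass
class BurstMask:
    """Burst intervals plus the diagnostics that produced them.

    ``intervals`` is a (k, 2) array of [start, end) times in ms, sorted
    and non-overlapping, snapped to the SD-window grid.
    """

    intervals: np.ndarray
    sd_series: np.ndarray
    exceed_counts: np.ndarray
    sd_thresholds: np.ndarray
    site_count_threshold: int
    min_duration_ms: float
    win_ms: int = 100

    @property
    def total_burst_ms(self) -> float:
        if len(self.intervals) == 0:
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def overlaps(self, start_ms: float, end_ms: float) -> bool:
        """True if [start, end) intersects any burst interval."""
        for a, b in self.intervals:
            if a < end_ms and b > start_ms:
                return True
        return False


def classify_bursts(sd_series: np.ndarray, *, site_count_threshold: int = 24,
                    min_duration_ms: float = 150.0, sd_multiplier: float = 3.0,
                    win_ms: int = 100) -> BurstMask:
    """Classify bursting epochs from the per-window SD series.

    A window is supra-threshold when strictly more than
    ``site_count_threshold`` sites exceed their per-site threshold
    (``sd_multiplier`` x the median of that site's window SDs over the
    whole recording — a median so bursts themselves do not inflate it).
    Contiguous supra-threshold runs spanning >= ``min_duration_ms`` are
    emitted as burst intervals; on the 100-ms grid this means at least
    two consecutive windows.
    """
    sd_series = np.asarray(sd_series)
    if sd_series.ndim != 2 or sd_series.shape[0] == 0:
        raise ValueError("sd_series must be a non-empty (sites x windows) array")
    if site_count_threshold < 0 or min_duration_ms <= 0 or sd_multiplier <= 0:
        raise ValueError("thresholds must be positive")
    thresholds = sd_multiplier * np.median(sd_series, axis=1)
    exceed = sd_series > thresholds[:, None]
    counts = exceed.sum(axis=0)
    supra = counts > site_count_threshold

    intervals = []
    start = None
    for j, flag in enumerate(np.append(supra, False)):
        if flag and start is None:
            start = j
        elif not flag and start is not None:
            span_ms = (j - start) * win_ms
            if span_ms >= min_duration_ms:
                intervals.append((start * win_ms, j * win_ms))
            start = None
    intervals = (np.asarray(intervals, dtype=float)
                 if intervals else np.empty((0, 2)))
    return BurstMask(intervals=intervals, sd_series=sd_series,
                     exceed_counts=counts, sd_thresholds=thresholds,
                     site_count_threshold=site_count_threshold,
                     min_duration_ms=min_duration_ms, win_ms=win_ms)


def screen_session(session: RecordingSession, *, site_count_threshold: int | None = None,
                   min_duration_ms: float = 150.0, sd_multiplier: float = 3.0,
                   win_ms: int = 100) -> BurstMask:
    """Convenience wrapper: SD series + burst classification for a session.

    When ``site_count_threshold`` is None it is scaled to the array size
    as round(0.25 * n_active_sites), which reproduces the canonical 24
    on a 96-site array.
    """
    if site_count_threshold is None:
        site_count_threshold = int(round(0.25 * session.grid.n_active))
    sd = window_sd(session.lfp, win_ms=win_ms, fs=session.fs)
    return classify_bursts(sd, site_count_threshold=site_count_threshold,
                           min_duration_ms=min_duration_ms,
                           sd_multiplier=sd_multiplier, win_ms=win_ms)


@dataclass(frozen=True)
class AnalysisWindow:
    """One 1,000-ms non-burst analysis window inside a tone presentation."""

    session_id: str
    trial_index: int
    label_hz: int
    start_ms: float
    length_ms: float = 1000.0


def candidate_windows(session: RecordingSession, *, onset_exclusion_s: float = 1.0,
                      window_ms: float = 1000.0) -> list[AnalysisWindow]:
    """Tile each tone presentation into non-overlapping candidate windows.

    Candidates start at tone onset + the onset exclusion and step in
    whole window lengths, never extending past tone offset.
    """
    if window_ms <= 0 or (window_ms * session.fs / 1000.0) % 1 != 0:
        raise ValueError("window length must be a positive multiple of the sample period")
    out = []
    for idx, (tone_hz, onset_s, dur_s) in enumerate(session.schedule.trials):
        t = (onset_s + onset_exclusion_s) * 1000.0
        stop = (onset_s + dur_s) * 1000.0
        while t + window_ms <= stop + 1e-9:
            out.append(AnalysisWindow(session.session_id, idx, int(tone_hz), t, window_ms))
            t += window_ms
    return out


def extract_analysis_windows(session: RecordingSession, mask: BurstMask, *,
                             onset_exclusion_s: float = 1.0, window_ms: float = 1000.0,
                             n_per_label: int = 70, seed: int = 0) -> list[AnalysisWindow]:
    """Select exactly ``n_per_label`` burst-free windows per tone frequency.

    Candidates overlapping any burst interval are dropped.  The
    survivors of each label (in acquisition order) are thinned by a
    deterministic even stride so the retained windows stay balanced
    across trials; ``seed`` is reserved for tie-breaking and does not
    otherwise influence the selection.  If a label has fewer survivors
    than requested a :class:`WindowShortfallError` is raised — there is
    no silent padding.
    """
    del seed  # deterministic stride selection; no ties to break on a fixed grid
    cands = candidate_windows(session, onset_exclusion_s=onset_exclusion_s,
                              window_ms=window_ms)
    survivors: dict[int, list[AnalysisWindow]] = {
        int(f): [] for f in session.schedule.tone_frequencies}
    for w in cands:
        if not mask.overlaps(w.start_ms, w.start_ms + w.length_ms):
            survivors[w.label_hz].append(w)
    selected: list[AnalysisWindow] = []
    for label in sorted(survivors):
        pool = sorted(survivors[label], key=lambda w: w.start_ms)
        if len(pool) < n_per_label:
            raise WindowShortfallError(label, len(pool), n_per_label)
        idx = np.floor(np.arange(n_per_label) * len(pool) / n_per_label).astype(int)
        selected.extend(pool[i] for i in idx)
    selected.sort(key=lambda w: w.start_ms)
    return selected


def interval_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap between two interval sets (each (k, 2), in ms)."""
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    if len(a) == 0 and len(b) == 0:
        return 1.0
    lo = min([x[0] for x in a] + [x[0] for x in b])
    hi = max([x[1] for x in a] + [x[1] for x in b])
    # 1-ms resolution indicator vectors are exact for grid-aligned intervals
    n = int(np.ceil(hi - lo))
    ia = np.zeros(n, dtype=bool)
    ib = np.zeros(n, dtype=bool)
    for s, e in a:
        ia[int(s - lo): int(e - lo)] = True
    for s, e in b:
        ib[int(s - lo): int(e - lo)] = True
    union = np.logical_or(ia, ib).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(ia, ib).sum() / union)
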