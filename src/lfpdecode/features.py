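"""Band-specific power and phase-locking-value features.

For each analysis window and frequency band the pipeline computes either
(i) the band power per recording site — the root mean square of the
band-pass-filtered LFP — or (ii) the phase-locking value (PLV) between
every unordered pair of sites::

    PLV(m, n) = (1 / T) * | sum_t exp(i (theta_m(t) - theta_n(t))) |

where theta is the instantaneous angle from the Hilbert transform of the
filtered signal and T is the window length in samples.  PLV lies in
[0, 1]; 1 means the two sites are perfectly phase locked.  Pairs are
ordered lexicographically over active-site indices (m < n), so feature
columns are comparable across sessions: a 96-site array yields
C(96, 2) = 4,560 PLV features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bursts import AnalysisWindow
from .simulate import RecordingSession


@dataclass(frozen=True)
class Band:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError(f"band edges must satisfy 0 < low < high, got {self}")


#: The canonical analysis bands.  Bands are deliberately narrow so that
#: the Hilbert transform yields well-defined instantaneous angles.
CANONICAL_BANDS = (
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 14.0),
    Band("beta", 14.0, 30.0),
    Band("low-gamma", 30.0, 40.0),
    Band("high-gamma", 60.0, 80.0),
)

BANDS = {b.name: b for b in CANONICAL_BANDS}


def bandpass(x: np.ndarray, band: Band, fs: int = 1000, order: int = 4,
             allow_wide: bool = False) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    A 4th-order design applied forward-backward (effective 8th order)
    preserves phase, which matters for the Hilbert step.  Bands above
    30 Hz wider than one octave are rejected unless ``allow_wide`` is
    set, because instantaneous phase is only meaningful for narrowband
    signals.
    """
    nyq = fs / 2.0
    if band.high >= nyq:
        raise ValueError(f"band edge {band.high} Hz at/above Nyquist ({nyq} Hz)")
    if not allow_wide and band.low >= 30.0 and band.high > 2.0 * band.low:
        raise ValueError(
            f"band {band.name} ({band.low}-{band.high} Hz) is wider than one "
            "octave; pass allow_wide=True to override")
    sos = sps.butter(order, (band.low, band.high), btype="bandpass",
                     fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def band_power(x: np.ndarray) -> np.ndarray:
    """Root mean square over the last axis (µV for µV input)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] == 0:
        raise ValueError("empty window")
    return np.sqrt(np.mean(x ** 2, axis=-1))


def analytic_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous angle of the analytic signal, per sample (last axis).

    All-zero traces have no defined phase: their angles are returned as
    NaN so degenerate windows can be flagged and excluded upstream of
    any PLV computation.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("window must contain at least 2 samples")
    phases = np.angle(sps.hilbert(x, axis=-1))
    flat = np.all(x == 0, axis=-1)
    if np.any(flat):
        phases = phases.copy()
        phases[flat] = np.nan
    return phases


def pair_order(n_sites: int) -> np.ndarray:
    """(n_pairs, 2) lexicographic unordered pairs m < n."""
    iu = np.triu_indices(n_sites, k=1)
    return np.column_stack(iu)


def plv_matrix(phases: np.ndarray) -> np.ndarray:
    """PLV for every unordered site pair, in lexicographic pair order.

    ``phases`` is (n_sites, T).  Returns a length C(n_sites, 2) vector
    in [0, 1].  NaN phases are rejected: degenerate windows must be
    excluded before this point.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 2:
        raise ValueError("phases must be (sites x samples)")
    T = phases.shape[1]
    if T == 0:
        raise ValueError("empty phase window")
    if np.isnan(phases).any():
        raise ValueError("NaN phases: flagged degenerate windows must be excluded")
    z = np.exp(1j * phases)
    coh = np.abs(z @ z.conj().T) / T
    iu = np.triu_indices(phases.shape[0], k=1)
    return np.minimum(coh[iu], 1.0)


def plv_matrix_naive(phases: np.ndarray) -> np.ndarray:
    """Reference double loop over pairs and time; oracle for plv_matrix."""
    phases = np.asarray(phases, dtype=float)
    S, T = phases.shape
    out = []
    for m in range(S):
        for n in range(m + 1, S):
            acc = 0j
            for t in range(T):
                acc += np.exp(1j * (phases[m, t] - phases[n, t]))
            out.append(abs(acc) / T)
    return np.asarray(out)


@dataclass
class FeatureTable:
    """Per-window feature vectors with labels and provenance.

    ``X`` is (n_windows, n_features): 96 band powers (µV RMS) or 4,560
    PLVs on the canonical array.  Rows are ordered by acquisition time.
    """

    X: np.ndarray
    labels_hz: np.ndarray
    band: str
    kind: str  # "power" | "plv"
    session_id: str
    starts_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    trial_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels_hz = np.asarray(self.labels_hz, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.labels_hz):
            raise ValueError("X must be (n_windows x n_features) matching labels")
        if self.kind not in ("power", "plv"):
            raise ValueError(f"kind must be 'power' or 'plv', got {self.kind!r}")

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def subset_labels(self, labels) -> "FeatureTable":
        """Rows whose label is in ``labels`` (acquisition order kept)."""
        keep = np.isin(self.labels_hz, np.asarray(labels, dtype=int))
        return FeatureTable(self.X[keep], self.labels_hz[keep], self.band,
                            self.kind, self.session_id,
                            self.starts_ms[keep] if len(self.starts_ms) else self.starts_ms,
                            self.trial_index[keep] if len(self.trial_index) else self.trial_index)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"f{j}" for j in range(self.X.shape[1])])
        df.insert(0, "label_hz", self.labels_hz)
        if len(self.starts_ms):
            df.insert(1, "start_ms", self.starts_ms)
        return df


def build_feature_table(session: RecordingSession, windows: list[AnalysisWindow],
                        band: Band, kind: str, *, order: int = 4) -> FeatureTable:
    """Compute one feature row per analysis window.

    The whole recording is band-pass filtered once (zero phase); for PLV
    the analytic signal is then taken over the full filtered trace so
    the windows cropped from it are free of transform edge effects —
    every window is guaranteed hundreds of ms of context on both sides
    by the window-extraction rules.  Degenerate all-zero windows are
    excluded (with a log of how many) rather than given arbitrary phases.
    """
    if kind not in ("power", "plv"):
        raise ValueError(f"kind must be 'power' or 'plv', got {kind!r}")
    ids = {w.session_id for w in windows}
    if ids and ids != {session.session_id}:
        raise ValueError(f"windows from sessions {ids} do not match {session.session_id!r}")
    windows = sorted(windows, key=lambda w: w.start_ms)
    filt = bandpass(session.lfp, band, fs=session.fs, order=order)
    if kind == "plv":
        analytic = sps.hilbert(filt, axis=-1)

    rows, labels, starts, trials = [], [], [], []
    for w in windows:
        a = int(round(w.start_ms * session.fs / 1000.0))
        b = a + int(round(w.length_ms * session.fs / 1000.0))
        seg = filt[:, a:b]
        if np.all(seg == 0):
            continue  # degenerate window: no phase/power information
        if kind == "power":
            rows.append(band_power(seg))
        else:
            rows.append(plv_matrix(np.angle(analytic[:, a:b])))
        labels.append(w.label_hz)
        starts.append(w.start_ms)
        trials.append(w.trial_index)

    n_feat = session.grid.n_active if kind == "power" else len(pair_order(session.grid.n_active))
    X = np.asarray(rows) if rows else np.empty((0, n_feat))
    return FeatureTable(X=X, labels_hz=np.asarray(labels, dtype=int),
                        band=band.name, kind=kind, session_id=session.session_id,
                        starts_ms=np.asarray(starts, dtype=float),
                        trial_index=np.asarray(trials, dtype=int))
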