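"""Synthetic multichannel LFP sessions with known ground truth.

Emulates dense microelectrode-array recordings from the anesthetized
auditory cortex: narrowband oscillations whose spatial gain follows a
tonotopic map, controllable inter-site phase coupling, a pink-noise
floor, and intermittent high-amplitude bursts that are synchronous
across the array (burst suppression).  Every stochastic element is
seeded and the generator keeps a ground-truth log (planted burst
intervals, per-animal parameters) so downstream detection and decoding
stages can be tested by parameter recovery.

The generative model per active site ``s`` is::

    x_s(t) = sum_b  a_b * g_b(s, tone(t)) * cos(phi_b(t) + eps_{b,s}(t))
             + pink_s(t) + burst(t)

where ``phi_b`` is a latent band phase (integrated slowly wandering
instantaneous frequency centred mid-band), ``eps_{b,s}`` is a smooth
wrapped-normal phase jitter whose circular concentration is mapped from
the coupling parameter ``kappa`` (kappa = 1 -> zero jitter -> PLV 1),
and ``g_b`` is a tonotopic gain: one or two Gaussian activation foci per
test frequency, scaled by the band's tonotopic contrast.  Tone identity
enters *only* through the gains, so decodable information is controlled
by a single contrast knob per band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Sampling rate of the emulated acquisition system (samples / s).
FS = 1000

#: Canonical test frequencies (Hz).
CANONICAL_FREQS = (8000, 10000, 13000, 16000, 32000)

BAND_NAMES = ("theta", "alpha", "beta", "low-gamma", "high-gamma")

#: Centre frequency (Hz) of each canonical band used by the generator.
_BAND_CENTER = {
    "theta": 6.0,
    "alpha": 11.0,
    "beta": 22.0,
    "low-gamma": 35.0,
    "high-gamma": 70.0,
}


# ---------------------------------------------------------------------------
# site grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteGrid:
    """Rectangular electrode grid over a square cortical patch.

    Active sites are ordered row-major with offline sites skipped; that
    ordering is the feature-vector ordering used everywhere downstream.
    """

    rows: int
    cols: int
    offline_sites: tuple[tuple[int, int], ...] = ()
    extent_mm: float = 4.0

    def __post_init__(self):
        if self.rows < 2 or self.cols < 2:
            raise ValueError(f"grid must be at least 2x2, got {self.rows}x{self.cols}")
        for (r, c) in self.offline_sites:
            if not (0 <= r < self.rows and 0 <= c < self.cols):
                raise ValueError(f"offline site {(r, c)} outside {self.rows}x{self.cols} grid")

    @property
    def n_active(self) -> int:
        return self.rows * self.cols - len(set(self.offline_sites))

    @property
    def active_rc(self) -> np.ndarray:
        """(n_active, 2) row/col indices, row-major, offline skipped."""
        off = set(self.offline_sites)
        rc = [(r, c) for r in range(self.rows) for c in range(self.cols) if (r, c) not in off]
        return np.asarray(rc, dtype=int)

    @property
    def positions_mm(self) -> np.ndarray:
        """(n_active, 2) (x, y) positions in mm over the square extent."""
        rc = self.active_rc
        x = rc[:, 1] * self.extent_mm / (self.cols - 1)
        y = rc[:, 0] * self.extent_mm / (self.rows - 1)
        return np.column_stack([x, y])


def make_grid(rows: int = 10, cols: int = 10, offline_corners: bool = True) -> SiteGrid:
    """Build the recording grid; the four corner sites can be flagged offline.

    The default 10x10 grid with offline corners yields 96 active sites.
    """
    if rows < 2 or cols < 2:
        raise ValueError(f"grid must be at least 2x2, got {rows}x{cols}")
    corners: tuple[tuple[int, int], ...] = ()
    if offline_corners:
        corners = ((0, 0), (0, cols - 1), (rows - 1, 0), (rows - 1, cols - 1))
    return SiteGrid(rows=rows, cols=cols, offline_sites=corners)


# ---------------------------------------------------------------------------
# trial schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialSchedule:
    """Sequence of long pure tones interleaved with equal silent gaps.

    ``order`` holds one label index (into ``tone_frequencies``) per
    trial; every frequency appears exactly ``repetitions`` times.  The
    session layout is tone, gap, tone, gap, ... with a trailing gap, so
    each tone has contiguous recording on both sides.
    """

    tone_frequencies: tuple[int, ...] = CANONICAL_FREQS
    repetitions: int = 7
    tone_duration_s: float = 29.0
    gap_duration_s: float = 29.0
    order: tuple[int, ...] = ()

    def __post_init__(self):
        if len(set(self.tone_frequencies)) != len(self.tone_frequencies):
            raise ValueError("tone frequencies must be distinct")
        if self.tone_duration_s <= 0 or self.gap_duration_s < 0:
            raise ValueError("durations must be positive")
        counts = np.bincount(np.asarray(self.order, dtype=int),
                             minlength=len(self.tone_frequencies))
        if self.order and not np.all(counts == self.repetitions):
            raise ValueError("each frequency must appear exactly `repetitions` times")

    @classmethod
    def make(cls, tone_frequencies=CANONICAL_FREQS, repetitions: int = 7,
             tone_duration_s: float = 29.0, gap_duration_s: float = 29.0,
             seed: int = 0) -> "TrialSchedule":
        """Pseudorandomize the trial order from a seed."""
        rng = np.random.default_rng(seed)
        order = rng.permutation(np.repeat(np.arange(len(tone_frequencies)),
                                          repetitions))
        return cls(tuple(tone_frequencies), repetitions, tone_duration_s,
                   gap_duration_s, tuple(int(i) for i in order))

    @property
    def n_trials(self) -> int:
        return len(self.tone_frequencies) * self.repetitions

    @property
    def total_duration_s(self) -> float:
        return self.n_trials * (self.tone_duration_s + self.gap_duration_s)

    @property
    def trials(self) -> list[tuple[int, float, float]]:
        """List of (tone_hz, onset_s, duration_s) in presentation order."""
        period = self.tone_duration_s + self.gap_duration_s
        return [(self.tone_frequencies[lab], i * period, self.tone_duration_s)
                for i, lab in enumerate(self.order)]


# ---------------------------------------------------------------------------
# generator parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandParams:
    """Per-band oscillation settings.

    amplitude_uv
        Peak amplitude of the band oscillation (µV) at unit gain.
    contrast
        Tonotopic contrast c >= 0: how strongly the site gain depends on
        the presented tone.  0 removes all tone information from the band.
    coupling
        kappa in [0, 1]: circular concentration of each site's phase
        around the latent band phase; 1 means perfectly locked (PLV 1).
    """

    amplitude_uv: float
    contrast: float
    coupling: float

    def __post_init__(self):
        if self.amplitude_uv < 0:
            raise ValueError("amplitude must be >= 0")
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling kappa must lie in [0, 1]")


def default_focus_layouts(freqs=CANONICAL_FREQS, extent_mm: float = 4.0):
    """Tonotopic activation foci per test frequency.

    Low frequencies activate two foci (posterior-dorsal and
    anterior-ventral), high frequencies a single anterior-medial focus,
    with the intermediate frequency a single central focus.  Centers are
    in mm over the grid extent; each focus is (cx, cy, width_mm).
    """
    e = extent_mm
    layouts = {
        8000: [(0.20 * e, 0.80 * e, 0.25 * e), (0.80 * e, 0.20 * e, 0.25 * e)],
        10000: [(0.30 * e, 0.70 * e, 0.25 * e), (0.70 * e, 0.30 * e, 0.25 * e)],
        13000: [(0.50 * e, 0.50 * e, 0.25 * e)],
        16000: [(0.70 * e, 0.70 * e, 0.20 * e)],
        32000: [(0.85 * e, 0.85 * e, 0.20 * e)],
    }
    return {f: layouts.get(f, [(0.5 * e, 0.5 * e, 0.25 * e)]) for f in freqs}


def _default_bands() -> dict:
    return {
        "theta": BandParams(10.0, 0.35, 0.70),
        "alpha": BandParams(8.0, 0.30, 0.60),
        "beta": BandParams(7.0, 0.30, 0.50),
        "low-gamma": BandParams(6.0, 0.40, 0.50),
        "high-gamma": BandParams(4.0, 0.80, 0.80),
    }


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameter set of the synthetic-session generator.

    Defaults emulate the recording conditions the pipeline is designed
    for: band RMS of order 10 µV over a 15 µV pink-noise floor, global
    bursts at 2 events/min with a 10x amplitude multiplier, and a
    tonotopic contrast profile that puts most tone information in the
    high-gamma band (mid-range five-choice decodability) with weaker,
    clearly above-chance information in the lower bands.
    """

    bands: dict = field(default_factory=_default_bands)
    focus_layouts: dict = field(default_factory=default_focus_layouts)
    noise_rms_uv: float = 15.0
    burst_rate_per_min: float = 2.0
    burst_duration_ms: tuple[float, float] = (150.0, 500.0)
    burst_amplitude_mult: float = 10.0
    layer: str = "L5/6"

    def __post_init__(self):
        for name in self.bands:
            if name not in BAND_NAMES:
                raise ValueError(f"unknown band {name!r}; expected one of {BAND_NAMES}")
        if self.noise_rms_uv < 0:
            raise ValueError("noise RMS must be >= 0")
        if self.burst_rate_per_min < 0:
            raise ValueError("burst rate must be >= 0")
        lo, hi = self.burst_duration_ms
        if not (0 < lo <= hi):
            raise ValueError("burst duration range must satisfy 0 < lo <= hi")

    def validate_against(self, grid: SiteGrid, schedule: TrialSchedule) -> None:
        """Reject layouts inconsistent with the grid/schedule geometry."""
        lo, hi = self.burst_duration_ms
        if hi >= schedule.tone_duration_s * 1000.0:
            raise ValueError("burst durations must be shorter than a tone presentation")
        for f, foci in self.focus_layouts.items():
            for (cx, cy, w) in foci:
                if not (0 <= cx <= grid.extent_mm and 0 <= cy <= grid.extent_mm):
                    raise ValueError(
                        f"focus center ({cx}, {cy}) for {f} Hz outside "
                        f"grid extent 0..{grid.extent_mm} mm")
                if w <= 0:
                    raise ValueError("focus width must be positive")
        for f in schedule.tone_frequencies:
            if f not in self.focus_layouts:
                raise ValueError(f"no focus layout for scheduled tone {f} Hz")

    @property
    def background_sd_uv(self) -> float:
        """Typical non-burst signal SD implied by the parameters."""
        osc_var = sum(bp.amplitude_uv ** 2 / 2.0 for bp in self.bands.values())
        return math.sqrt(self.noise_rms_uv ** 2 + osc_var)


@dataclass(frozen=True)
class VnsEffect:
    """Ground-truth perturbation applied between pre and post sessions.

    Multiplicative changes to per-band tonotopic contrast and phase
    coupling; the identity effect (all multipliers 1) leaves parameters
    untouched.
    """

    contrast_mult: dict = field(default_factory=dict)
    coupling_mult: dict = field(default_factory=dict)

    def __post_init__(self):
        for d in (self.contrast_mult, self.coupling_mult):
            for name, m in d.items():
                if name not in BAND_NAMES:
                    raise ValueError(f"unknown band {name!r}")
                if m <= 0:
                    raise ValueError("effect multipliers must be > 0")


def apply_vns_effect(params: GeneratorParams, effect: VnsEffect) -> GeneratorParams:
    """Return a copy of ``params`` with the per-band multipliers applied.

    Coupling values that leave [0, 1] are clipped back with a warning.
    """
    new_bands = {}
    for name, bp in params.bands.items():
        contrast = bp.contrast * effect.contrast_mult.get(name, 1.0)
        coupling = bp.coupling * effect.coupling_mult.get(name, 1.0)
        if coupling > 1.0:
            logger.warning("coupling for %s clipped from %.3f to 1.0", name, coupling)
            coupling = 1.0
        new_bands[name] = BandParams(bp.amplitude_uv, contrast, coupling)
    return replace(params, bands=new_bands)


# ---------------------------------------------------------------------------
# session container
# ---------------------------------------------------------------------------


@dataclass
class RecordingSession:
    """One recording session: LFP matrix, grid, schedule, ground truth.

    ``lfp`` is (n_active_sites, n_samples) float32 in µV at ``fs`` Hz,
    site order matching ``grid.active_rc``.
    """

    session_id: str
    lfp: np.ndarray
    fs: int
    grid: SiteGrid
    schedule: TrialSchedule
    ground_truth: dict | None = None

    def __post_init__(self):
        if self.lfp.ndim != 2:
            raise ValueError("lfp must be a 2-D (sites x samples) array")
        if self.lfp.shape[0] != self.grid.n_active:
            raise ValueError(
                f"lfp has {self.lfp.shape[0]} rows but grid has "
                f"{self.grid.n_active} active sites")

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------


def _smooth_noise(rng: np.random.Generator, shape, tau_s: float, fs: int) -> np.ndarray:
    """Stationary unit-variance AR(1) noise with correlation time tau."""
    rho = math.exp(-1.0 / (fs * tau_s))
    w = rng.standard_normal(shape)
    out = sps.lfilter([math.sqrt(1.0 - rho ** 2)], [1.0, -rho], w, axis=-1)
    # start the recursion from a stationary draw instead of zero
    out += rng.standard_normal(shape[:-1] + (1,) if len(shape) > 1 else (1,)) * rho ** np.arange(shape[-1])
    return out


def _slow_field(rng: np.random.Generator, n_rows: int, n_samples: int,
                tau_s: float, fs: int, carrier_fs: int = 100) -> np.ndarray:
    """Smooth noise field with correlation time >> 1/carrier_fs.

    Generated at a reduced rate and linearly interpolated to ``fs``;
    indistinguishable from full-rate AR(1) noise for the slow
    correlation times used here, at a fraction of the cost.
    """
    dec = max(1, fs // carrier_fs)
    n_low = n_samples // dec + 2
    low = _smooth_noise(rng, (n_rows, n_low), tau_s, fs // dec)
    pos = np.arange(n_samples) / dec
    i0 = pos.astype(int)
    frac = pos - i0
    return low[:, i0] * (1.0 - frac) + low[:, i0 + 1] * frac


def _pink_noise(rng: np.random.Generator, n_sites: int, n_samples: int,
                rms_uv: float, fs: int) -> np.ndarray:
    """Per-site independent 1/f-shaped noise, scaled to a target RMS."""
    if rms_uv == 0:
        return np.zeros((n_sites, n_samples))
    white = rng.standard_normal((n_sites, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(f, 0.5))
    shape[0] = 0.0  # no DC
    spec *= shape
    pink = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd * rms_uv


def _coupling_to_sigma(kappa: float) -> float:
    """Map coupling kappa to a wrapped-normal jitter SD (radians).

    Chosen so the mean resultant length of the jitter distribution is
    kappa: R = exp(-sigma^2 / 2)  =>  sigma = sqrt(-2 ln kappa).
    """
    kappa = max(kappa, 1e-4)
    return math.sqrt(-2.0 * math.log(kappa)) if kappa < 1.0 else 0.0


def _focus_gain(positions_mm: np.ndarray, foci) -> np.ndarray:
    """Normalized activation map in [0, 1]: max over Gaussian foci."""
    g = np.zeros(positions_mm.shape[0])
    for (cx, cy, w) in foci:
        d2 = (positions_mm[:, 0] - cx) ** 2 + (positions_mm[:, 1] - cy) ** 2
        g = np.maximum(g, np.exp(-d2 / (2.0 * w ** 2)))
    return g


def _plant_bursts(rng: np.random.Generator, n_samples: int, params: GeneratorParams,
                  fs: int, win_ms: int = 100) -> tuple[np.ndarray, list]:
    """Draw global burst events on the 100-ms analysis lattice.

    Onsets are Poisson in time (snapped to the lattice) and durations
    uniform over the lattice multiples inside the configured range; the
    lattice matches the resolution at which burst screening operates.
    Returns (waveform to add to every site, list of (start_ms, end_ms)).
    """
    wave = np.zeros(n_samples)
    events: list[tuple[float, float]] = []
    if params.burst_rate_per_min <= 0:
        return wave, events
    win = int(win_ms * fs / 1000)
    n_slots = n_samples // win
    duration_min = n_samples / fs / 60.0
    n_events = rng.poisson(params.burst_rate_per_min * duration_min)
    lo, hi = params.burst_duration_ms
    k_lo = max(2, math.ceil(lo / win_ms))  # >=2 windows so the 150-ms rule can fire
    k_hi = max(k_lo, math.floor(hi / win_ms))
    occupied = np.zeros(n_slots, dtype=bool)
    amp = params.burst_amplitude_mult * params.background_sd_uv
    for _ in range(n_events):
        k = int(rng.integers(k_lo, k_hi + 1))
        for _attempt in range(50):
            s = int(rng.integers(0, max(1, n_slots - k)))
            if not occupied[max(0, s - 1): s + k + 1].any():
                break
        else:
            continue  # no room left; drop the event
        occupied[s: s + k] = True
        a, b = s * win, (s + k) * win
        t = np.arange(b - a) / fs
        env = np.ones(b - a)
        ramp = int(0.02 * fs)
        if ramp > 0 and b - a > 2 * ramp:
            up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            env[:ramp] = up
            env[-ramp:] = up[::-1]
        phase = rng.uniform(0, 2 * np.pi)
        # low-frequency transient plus a broadband component, so every
        # 100-ms window inside the event is high-SD even at carrier
        # zero crossings
        rough = _smooth_noise(rng, (b - a,), 0.01, fs)
        wave[a:b] += amp * env * (0.8 * np.cos(2 * np.pi * 3.0 * t + phase)
                                  + 0.4 * rough)
        events.append((a * 1000.0 / fs, b * 1000.0 / fs))
    events.sort()
    return wave, events


# ---------------------------------------------------------------------------
# session and cohort simulation
# ---------------------------------------------------------------------------


def simulate_session(grid: SiteGrid, schedule: TrialSchedule,
                     params: GeneratorParams, seed, *,
                     session_id: str = "sim", fs: int = FS) -> RecordingSession:
    """Generate one seeded session; identical inputs give identical output.

    See the module docstring for the generative model.  The returned
    session carries a ``ground_truth`` dict with the planted burst
    intervals and the exact parameters used.
    """
    params.validate_against(grid, schedule)
    rng = np.random.default_rng(seed)
    n_samples = int(round(schedule.total_duration_s * fs))
    n_sites = grid.n_active
    pos = grid.positions_mm
    sig = np.zeros((n_sites, n_samples))

    # per-trial sample segments: (start, stop, tone_hz) for tones
    tone_segments = []
    for tone_hz, onset_s, dur_s in schedule.trials:
        a = int(round(onset_s * fs))
        b = int(round((onset_s + dur_s) * fs))
        tone_segments.append((a, b, tone_hz))

    for name, bp in params.bands.items():
        if bp.amplitude_uv == 0:
            continue
        f_mid = _BAND_CENTER[name]
        # latent phase: slowly wandering instantaneous frequency
        wander = 0.05 * f_mid * _slow_field(rng, 1, n_samples, 0.2, fs)[0]
        inst_f = f_mid + wander
        phi = 2 * np.pi * np.cumsum(inst_f) / fs
        # per-site smooth phase jitter (wrapped normal, resultant = kappa)
        sigma = _coupling_to_sigma(bp.coupling)
        if sigma > 0:
            eps = sigma * _slow_field(rng, n_sites, n_samples, 0.15, fs)
        else:
            eps = np.zeros((n_sites, n_samples))
        carrier = np.cos(phi[None, :] + eps)
        # tone-independent baseline gain 1 everywhere (gaps)
        band_sig = carrier.copy()
        if bp.contrast > 0:
            for (a, b, tone_hz) in tone_segments:
                bump = _focus_gain(pos, params.focus_layouts[tone_hz])
                gain = 1.0 + bp.contrast * (bump - bump.mean())
                gain = np.maximum(gain, 0.05)
                band_sig[:, a:b] = gain[:, None] * carrier[:, a:b]
        sig += bp.amplitude_uv * band_sig

    sig += _pink_noise(rng, n_sites, n_samples, params.noise_rms_uv, fs)

    burst_wave, burst_events = _plant_bursts(rng, n_samples, params, fs)
    if burst_events:
        site_scale = 1.0 + 0.05 * rng.standard_normal(n_sites)
        sig += site_scale[:, None] * burst_wave[None, :]

    return RecordingSession(
        session_id=session_id,
        lfp=sig.astype(np.float32),
        fs=fs,
        grid=grid,
        schedule=schedule,
        ground_truth={"bursts": burst_events, "params": params},
    )


def _jitter_params(params: GeneratorParams, rng: np.random.Generator,
                   sd: float = 0.1) -> GeneratorParams:
    """Between-animal lognormal (~+/-10%) jitter on amplitudes and contrasts."""
    new_bands = {}
    for name, bp in params.bands.items():
        new_bands[name] = BandParams(
            amplitude_uv=bp.amplitude_uv * rng.lognormal(0.0, sd),
            contrast=bp.contrast * rng.lognormal(0.0, sd),
            coupling=bp.coupling,
        )
    return replace(params, bands=new_bands)


def simulate_cohort(n_animals: int, layer: str, base: GeneratorParams,
                    effect: VnsEffect, seed, *,
                    grid: SiteGrid | None = None,
                    schedule_kwargs: dict | None = None,
                    fs: int = FS) -> list[tuple[RecordingSession, RecordingSession]]:
    """Simulate ``n_animals`` pre/post session pairs for one cortical layer.

    Each animal gets its own jittered copy of ``base`` (pre) and the
    VNS-perturbed copy (post); all per-animal randomness is derived from
    the master seed by seed-sequence spawning, so adding animals never
    shifts existing streams and identical seeds give identical cohorts.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    grid = grid or make_grid()
    schedule_kwargs = dict(schedule_kwargs or {})
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(n_animals)
    cohort = []
    for i, child in enumerate(children):
        a_rng = np.random.default_rng(child)
        animal_params = replace(_jitter_params(base, a_rng), layer=layer)
        post_params = apply_vns_effect(animal_params, effect)
        sched_seeds = a_rng.integers(0, 2 ** 31, size=2)
        sess_seeds = a_rng.integers(0, 2 ** 31, size=2)
        pair = []
        for tag, p, ss, ds in (("pre", animal_params, sess_seeds[0], sched_seeds[0]),
                               ("post", post_params, sess_seeds[1], sched_seeds[1])):
            schedule = TrialSchedule.make(seed=int(ds), **schedule_kwargs)
            pair.append(simulate_session(
                grid, schedule, p, int(ss), fs=fs,
                session_id=f"{layer.replace('/', '')}-a{i:02d}-{tag}"))
        cohort.append(tuple(pair))
    return cohort
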