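"""Pipeline configuration: validated, serializable, with two built-in profiles.

``PipelineConfig.default()`` describes a full-scale study: 10x10 grid
(96 active sites), 29-s tones x 7 repetitions of the five canonical
frequencies, 70 analysis windows per label, 7-fold periodic
cross-validation.  ``PipelineConfig.desk_scale()`` is the package's
reduced profile for simulation studies on a single CPU: a 5x5 grid
(21 active sites), 11-s tones x 3 repetitions, 21 windows per label —
same structure, smaller numbers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import BANDS
from .simulate import CANONICAL_FREQS


@dataclass
class PipelineConfig:
    # grid
    grid_rows: int = 10
    grid_cols: int = 10
    offline_corners: bool = True
    # schedule
    tone_frequencies: tuple = CANONICAL_FREQS
    repetitions: int = 7
    tone_duration_s: float = 29.0
    gap_duration_s: float = 29.0
    # burst screening
    sd_multiplier: float = 3.0
    site_count_threshold: int | None = None  # None -> round(0.25 * n_active)
    min_burst_duration_ms: float = 150.0
    # analysis windows
    window_ms: float = 1000.0
    onset_exclusion_s: float = 1.0
    n_per_label: int = 70
    # features
    bands: tuple = ("theta", "alpha", "beta", "low-gamma", "high-gamma")
    kinds: tuple = ("power", "plv")
    # decoding
    cv_scheme: str = "periodic"
    k_folds: int = 7
    n_rolling: int = 3
    run_two_choice: bool = False
    decoder: dict = field(default_factory=dict)
    # cohort
    layers: dict = field(default_factory=lambda: {"L2/3": 7, "L4": 7, "L5/6": 8})
    # vns effect: band -> multiplier
    contrast_mult: dict = field(default_factory=dict)
    coupling_mult: dict = field(default_factory=dict)
    # master seed
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        nyq = 500.0
        for name in self.bands:
            if name not in BANDS:
                raise ValueError(f"unknown band {name!r}")
            if BANDS[name].high >= nyq:
                raise ValueError(f"band {name} edge at/above Nyquist {nyq} Hz")
        for kind in self.kinds:
            if kind not in ("power", "plv"):
                raise ValueError(f"unknown feature kind {kind!r}")
        if self.cv_scheme not in ("periodic", "rolling"):
            raise ValueError(f"unknown CV scheme {self.cv_scheme!r}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_per_label < self.k_folds and self.cv_scheme == "periodic":
            raise ValueError("n_per_label must be >= k_folds")
        if self.window_ms <= 0 or self.onset_exclusion_s < 0:
            raise ValueError("window parameters must be positive")
        usable = self.tone_duration_s - self.onset_exclusion_s
        if usable < self.window_ms / 1000.0:
            raise ValueError("tone too short for even one analysis window")
        if self.sd_multiplier <= 0 or self.min_burst_duration_ms <= 0:
            raise ValueError("burst thresholds must be positive")

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls()

    @classmethod
    def desk_scale(cls, **overrides) -> "PipelineConfig":
        """Reduced profile for single-CPU simulation studies."""
        base = dict(
            grid_rows=5, grid_cols=5,
            repetitions=3, tone_duration_s=11.0, gap_duration_s=2.0,
            n_per_label=21,
            bands=("theta", "high-gamma"),
            layers={"L5/6": 8},
        )
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["tone_frequencies"] = list(self.tone_frequencies)
        d["bands"] = list(self.bands)
        d["kinds"] = list(self.kinds)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            text = Path(source).read_text()
        else:
            text = str(source)
        d = yaml.safe_load(text)
        for key in ("tone_frequencies", "bands", "kinds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
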