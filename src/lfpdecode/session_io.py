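"""HDF5 and plain-text readers/writers for sessions, masks and features.

The primary container is HDF5: ``/lfp`` (sites x samples, float32, µV),
``/schedule`` (trial order and timing), ``/grid`` (geometry and offline
sites) and ``/ground_truth`` (planted burst intervals and generator
parameters, when the session is synthetic).  Burst masks export as
BED-like three-column interval text and window manifests / feature
tables as TSV, so every artifact can be inspected with standard tools.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .bursts import AnalysisWindow, BurstMask
from .features import FeatureTable
from .simulate import (BandParams, GeneratorParams, RecordingSession,
                       SiteGrid, TrialSchedule)


def config_hash(obj) -> str:
    """Stable short hash of any YAML-serializable configuration object."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    return hashlib.sha256(
        yaml.safe_dump(obj, sort_keys=True).encode()).hexdigest()[:16]


def _params_to_dict(p: GeneratorParams) -> dict:
    d = dataclasses.asdict(p)
    d["focus_layouts"] = {str(k): [list(f) for f in v]
                          for k, v in p.focus_layouts.items()}
    return d


def _params_from_dict(d: dict) -> GeneratorParams:
    bands = {k: BandParams(**v) for k, v in d["bands"].items()}
    layouts = {int(k): [tuple(f) for f in v] for k, v in d["focus_layouts"].items()}
    return GeneratorParams(bands=bands, focus_layouts=layouts,
                           noise_rms_uv=d["noise_rms_uv"],
                           burst_rate_per_min=d["burst_rate_per_min"],
                           burst_duration_ms=tuple(d["burst_duration_ms"]),
                           burst_amplitude_mult=d["burst_amplitude_mult"],
                           layer=d["layer"])


def write_session(session: RecordingSession, path, *, extra_hash: str | None = None) -> None:
    """Persist a session to an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("lfp", data=session.lfp.astype(np.float32))
        d.attrs["units"] = "uV"
        f.attrs["session_id"] = session.session_id
        f.attrs["fs"] = session.fs
        if extra_hash:
            f.attrs["config_hash"] = extra_hash
        g = f.create_group("grid")
        g.attrs["rows"] = session.grid.rows
        g.attrs["cols"] = session.grid.cols
        g.attrs["extent_mm"] = session.grid.extent_mm
        g.create_dataset("offline_sites",
                         data=np.asarray(session.grid.offline_sites,
                                         dtype=int).reshape(-1, 2))
        s = f.create_group("schedule")
        s.attrs["tone_duration_s"] = session.schedule.tone_duration_s
        s.attrs["gap_duration_s"] = session.schedule.gap_duration_s
        s.attrs["repetitions"] = session.schedule.repetitions
        s.create_dataset("tone_frequencies",
                         data=np.asarray(session.schedule.tone_frequencies, dtype=int))
        s.create_dataset("order", data=np.asarray(session.schedule.order, dtype=int))
        if session.ground_truth is not None:
            gt = f.create_group("ground_truth")
            gt.create_dataset("bursts",
                              data=np.asarray(session.ground_truth.get("bursts", []),
                                              dtype=float).reshape(-1, 2))
            params = session.ground_truth.get("params")
            if params is not None:
                gt.attrs["params_yaml"] = yaml.safe_dump(_params_to_dict(params))


def read_session(path) -> RecordingSession:
    """Load a session container, validating the schema field by field."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for key in ("lfp", "grid", "schedule"):
            if key not in f:
                raise ValueError(f"{path.name}: missing required group/dataset '/{key}'")
        for attr in ("session_id", "fs"):
            if attr not in f.attrs:
                raise ValueError(f"{path.name}: missing root attribute {attr!r}")
        g = f["grid"]
        grid = SiteGrid(rows=int(g.attrs["rows"]), cols=int(g.attrs["cols"]),
                        offline_sites=tuple(map(tuple, g["offline_sites"][()].tolist())),
                        extent_mm=float(g.attrs["extent_mm"]))
        s = f["schedule"]
        schedule = TrialSchedule(
            tone_frequencies=tuple(int(x) for x in s["tone_frequencies"][()]),
            repetitions=int(s.attrs["repetitions"]),
            tone_duration_s=float(s.attrs["tone_duration_s"]),
            gap_duration_s=float(s.attrs["gap_duration_s"]),
            order=tuple(int(x) for x in s["order"][()]))
        lfp = f["lfp"][()]
        ground_truth = None
        if "ground_truth" in f:
            gt = f["ground_truth"]
            ground_truth = {"bursts": [tuple(r) for r in gt["bursts"][()]]}
            if "params_yaml" in gt.attrs:
                ground_truth["params"] = _params_from_dict(
                    yaml.safe_load(gt.attrs["params_yaml"]))
        return RecordingSession(session_id=str(f.attrs["session_id"]), lfp=lfp,
                                fs=int(f.attrs["fs"]), grid=grid,
                                schedule=schedule, ground_truth=ground_truth)


def write_mask_bed(mask: BurstMask, session_id: str, path) -> None:
    """Burst intervals as BED-like text: session id, start ms, end ms."""
    with open(path, "w") as fh:
        for a, b in mask.intervals:
            fh.write(f"{session_id}\t{int(a)}\t{int(b)}\n")


def write_windows_manifest(windows: list[AnalysisWindow], path) -> None:
    with open(path, "w") as fh:
        fh.write("session_id\ttrial\tlabel_hz\tstart_ms\n")
        for w in windows:
            fh.write(f"{w.session_id}\t{w.trial_index}\t{w.label_hz}\t{int(w.start_ms)}\n")


def write_feature_table(table: FeatureTable, path) -> None:
    """Feature table as HDF5 (dense matrix + labels) or TSV by suffix."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=table.X)
            f.create_dataset("labels_hz", data=table.labels_hz)
            f.create_dataset("starts_ms", data=table.starts_ms)
            f.attrs["band"] = table.band
            f.attrs["kind"] = table.kind
            f.attrs["session_id"] = table.session_id
    else:
        table.to_frame().to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> FeatureTable:
    with h5py.File(path, "r") as f:
        return FeatureTable(X=f["X"][()], labels_hz=f["labels_hz"][()],
                            band=str(f.attrs["band"]), kind=str(f.attrs["kind"]),
                            session_id=str(f.attrs["session_id"]),
                            starts_ms=f["starts_ms"][()])


def write_results_json(obj, path, *, extra: dict | None = None) -> None:
    payload = dict(extra or {})
    payload["results"] = obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"cannot serialize {type(o)}")
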