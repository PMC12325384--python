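"""End-to-end driver: simulate -> screen -> features -> decode -> compare.

Every stage is deterministic under the master seed.  Per-layer cohort
seeds are derived by seed-sequence spawning so changing one layer's
cohort size never shifts another layer's random streams.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import session_io
from .bursts import extract_analysis_windows, screen_session
from .compare import summarize
from .config import PipelineConfig
from .decoder import five_choice_task, run_task, two_choice_tasks
from .features import BANDS, build_feature_table
from .simulate import (GeneratorParams, RecordingSession, TrialSchedule,
                       VnsEffect, make_grid, simulate_cohort)

logger = logging.getLogger(__name__)


def decode_session(session: RecordingSession, cfg: PipelineConfig) -> pd.DataFrame:
    """Burst-screen, extract windows, and decode every configured cell.

    Returns a tidy frame with one row per (band, kind, task) and the
    cross-validated mean accuracy in percent.
    """
    mask = screen_session(session, site_count_threshold=cfg.site_count_threshold,
                          min_duration_ms=cfg.min_burst_duration_ms,
                          sd_multiplier=cfg.sd_multiplier)
    windows = extract_analysis_windows(
        session, mask, onset_exclusion_s=cfg.onset_exclusion_s,
        window_ms=cfg.window_ms, n_per_label=cfg.n_per_label, seed=cfg.seed)

    tasks = [five_choice_task(session.schedule.tone_frequencies)]
    if cfg.run_two_choice:
        tasks.extend(two_choice_tasks(session.schedule.tone_frequencies))

    rows = []
    for band_name in cfg.bands:
        band = BANDS[band_name]
        for kind in cfg.kinds:
            table = build_feature_table(session, windows, band, kind)
            for task in tasks:
                res = run_task(table, task, scheme=cfg.cv_scheme, k=cfg.k_folds,
                               n_rolling=cfg.n_rolling, fit_kwargs=cfg.decoder)
                task_name = (task.kind if task.kind == "five_choice"
                             else f"two_choice_r{task.ratio_class}")
                rows.append({"session_id": session.session_id,
                             "band": band_name, "kind": kind, "task": task_name,
                             "labels": task.labels,
                             "accuracy": res.mean_accuracy})
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None,
                 *, save_sessions: bool = False) -> pd.DataFrame:
    """Simulate all configured cohorts and return the comparison grid.

    Two-choice task rows are aggregated per ratio class (mean accuracy
    over the pairs in the class) before the per-animal delta is formed.
    Intermediates are persisted to ``out_dir`` when given.
    """
    chash = session_io.config_hash(cfg)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")

    grid = make_grid(cfg.grid_rows, cfg.grid_cols, cfg.offline_corners)
    effect = VnsEffect(contrast_mult=dict(cfg.contrast_mult),
                       coupling_mult=dict(cfg.coupling_mult))
    schedule_kwargs = dict(tone_frequencies=cfg.tone_frequencies,
                           repetitions=cfg.repetitions,
                           tone_duration_s=cfg.tone_duration_s,
                           gap_duration_s=cfg.gap_duration_s)
    layer_seeds = np.random.SeedSequence(cfg.seed).spawn(len(cfg.layers))

    records = []
    for (layer, n_animals), lseed in zip(sorted(cfg.layers.items()), layer_seeds):
        t0 = time.time()
        cohort = simulate_cohort(n_animals, layer, GeneratorParams(), effect,
                                 lseed, grid=grid, schedule_kwargs=schedule_kwargs)
        for animal, (pre, post) in enumerate(cohort):
            for phase, sess in (("pre", pre), ("post", post)):
                acc = decode_session(sess, cfg)
                acc["layer"] = layer
                acc["animal"] = animal
                acc["phase"] = phase
                records.append(acc)
                if out is not None and save_sessions:
                    session_io.write_session(sess, out / f"{sess.session_id}.h5",
                                             extra_hash=chash)
        logger.info("layer %s (%d animals): %.1f s", layer, n_animals,
                    time.time() - t0)

    tidy = pd.concat(records, ignore_index=True)
    wide = tidy.pivot_table(index=["layer", "band", "kind", "task", "animal"],
                            columns="phase", values="accuracy").reset_index()
    grid_df = summarize(wide.rename(columns={"pre": "pre", "post": "post"}))
    if out is not None:
        tidy.drop(columns=["labels"]).to_csv(out / "accuracies.tsv", sep="\t", index=False)
        grid_df.to_csv(out / "comparison.tsv", sep="\t", index=False)
        session_io.write_results_json(
            grid_df.to_dict(orient="records"), out / "comparison.json",
            extra={"config_hash": chash})
    return grid_df
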