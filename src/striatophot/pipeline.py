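"""End-to-end orchestration: simulate → normalize → bouts → peri-event → report.

`run_locomotion_pipeline` chains the full treadmill analysis on a synthetic
session and writes every product as deterministic text files (CSV/JSON), so
repeated runs with the same seed are byte-identical. It is what the CLI
``pipeline`` command and the reproducibility checks call.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .behavior import bout_summaries, segment_treadmill
from .config import PipelineConfig
from .io import write_session, write_velocity
from .perievent import align_array, max_timing, offset_slope
from .photometry import decimate_trace, normalize_gcamp
from .synthetic import SimParams, simulate_locomotion, simulate_photometry

_FLOAT_FMT = "%.17g"


def default_locomotion_params(profile: str = "patch_like",
                              duration_s: float = 240.0,
                              sampling_rate: float = 100.0) -> SimParams:
    """Study-structured treadmill session parameters at a desk-scale grid."""
    return SimParams(duration_s=duration_s, sampling_rate=sampling_rate,
                     coupling_profile=profile)


def run_locomotion_pipeline(seed: int, outdir, params: Optional[SimParams] = None,
                            config: Optional[PipelineConfig] = None) -> dict:
    """Run the whole treadmill chain and write its products under ``outdir``.

    Writes session/velocity/events CSVs, the normalized trace, the bout
    table, peri-event matrices (long format) and a stats JSON. Returns the
    stats dict (also written to ``stats.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or default_locomotion_params()
    cfg = config or PipelineConfig()

    velocity, loco_truth = simulate_locomotion(params, seed=seed)
    session, truth = simulate_photometry(params, velocity=velocity, seed=seed,
                                         true_bouts=loco_truth.true_bouts)
    write_session(session, outdir / "session.csv")
    write_velocity(velocity, outdir / "velocity.csv")

    norm = normalize_gcamp(session, cfg)
    pd.DataFrame({
        "time_s": norm.time, "dff": norm.dff, "zscore": norm.zscore,
        "transformed_reference": norm.transformed_reference,
        "f0_signal": norm.f0_signal, "f0_reference": norm.f0_reference,
    }).to_csv(outdir / "norm.csv", index=False, float_format=_FLOAT_FMT)

    bouts = segment_treadmill(velocity, cfg.bouts)
    pd.DataFrame([{
        "kind": b.kind, "onset_s": b.onset_s, "offset_s": b.offset_s,
        "duration_s": b.duration_s, "mean_velocity_cm_s": b.mean_velocity,
        "excluded_flag": b.excluded,
    } for b in bouts.bouts]).to_csv(outdir / "bouts.csv", index=False,
                                    float_format=_FLOAT_FMT)

    z_dec, fs_dec = decimate_trace(norm.zscore, norm.sampling_rate,
                                   cfg.perievent.rel_fs_hz)
    onsets = bouts.onsets("movement")
    offsets = bouts.offsets("movement")
    mats = {}
    for kind, evts in (("locomotion_onset", onsets), ("locomotion_offset", offsets)):
        mat = align_array(z_dec, fs_dec, evts, window=cfg.perievent.locomotion_window_s,
                          event_kind=kind)
        mats[kind] = mat
        long = pd.DataFrame({
            "trial": np.repeat(mat.trial_ids, mat.rel_time.size),
            "rel_time_s": np.tile(mat.rel_time, mat.values.shape[0]),
            "value": mat.values.ravel(),
        })
        long.to_csv(outdir / f"peri_{kind}.csv", index=False, float_format=_FLOAT_FMT)

    stats: dict = {
        "seed": int(seed),
        "qc": {"max_dff_percent": norm.qc.max_dff_percent,
               "signal_reference_correlation": norm.qc.signal_reference_correlation,
               "passed": bool(norm.qc.passed)},
        "bout_summary": bout_summaries(bouts, "movement"),
        "n_movement_bouts": int(len(bouts.of_kind("movement"))),
    }
    mat_on, mat_off = mats["locomotion_onset"], mats["locomotion_offset"]
    if not mat_on.empty:
        stats["t_max_onset_s"] = max_timing(mat_on, cfg.perievent.max_search_s)[0]
    if not mat_off.empty:
        stats["t_max_offset_s"] = max_timing(mat_off, cfg.perievent.max_search_s)[0]
        stats["offset_slope_z_per_s"] = offset_slope(mat_off,
                                                     cfg.perievent.slope_window_s)
    with open(outdir / "stats.json", "w", encoding="utf-8") as fh:
        json.dump(stats, fh, sort_keys=True, indent=1, default=float)
        fh.write("\n")
    return stats
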