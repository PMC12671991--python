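"""End-to-end orchestration: simulate -> segment -> detect -> metrics ->
stats -> theta, with provenance accounting and reproducible outputs.

One root seed fans out to per-stage child seeds through
``numpy.random.SeedSequence([seed, participant, task_index, stage_index])``,
so each stage of each participant-task session is individually reproducible.
Every output file is re-derivable from (config, seed); a manifest of SHA-256
content hashes is emitted and stable across reruns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import DriveGazeError, InsufficientDataError
from .events import detect_gaze_events
from .io import write_table
from .metrics import apply_exclusion, compute_metrics_table
from .segmentation import build_all_windows
from .simulate import (TaskKind, generate_gaze, generate_neural,
                       generate_task_schedule, generate_telemetry)
from .stats import comparison_table
from .theta import validate_fmt

_STAGES = {"schedule": 0, "telemetry": 1, "gaze": 2, "neural": 3}

COMPARISON_FILE_COLUMNS = ["metric", "unit", "lo_mean", "lo_sd", "hi_mean",
                           "hi_sd", "p_value", "cohens_d"]


def child_seed(seed: int, participant: int, task_index: int, stage: str) -> int:
    """Deterministic per-stage seed, kept below 2**31."""
    ss = np.random.SeedSequence(
        [int(seed), int(participant), int(task_index), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunResult:
    windows: pd.DataFrame
    metrics: pd.DataFrame
    excluded: pd.DataFrame
    comparisons: dict[str, pd.DataFrame]
    fmt_report: pd.DataFrame
    provenance: dict
    manifest: dict[str, str] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def _run_session(cfg: RunConfig, task: TaskKind, task_index: int,
                 participant: int, seed: int):
    """Simulate and analyse one participant-task session."""
    n_trials = cfg.trials_per_task.get(task.value)
    schedule = generate_task_schedule(
        task, n_trials, child_seed(seed, participant, task_index, "schedule"),
        cfg.timing)
    telemetry = generate_telemetry(
        schedule, cfg.telemetry,
        child_seed(seed, participant, task_index, "telemetry"))
    seg = build_all_windows(schedule, telemetry, cfg.rules)

    gp = cfg.gaze_params_for(task)
    if cfg.missing_fraction is not None:
        from dataclasses import replace
        gp = {k: replace(v, missing_fraction=cfg.missing_fraction)
              for k, v in gp.items()}
    label_params = {"Lo": gp["Lo"], "Hi": gp["Hi"], "Baseline": gp["Lo"]}
    win_params = [((r.t_start, r.t_end), label_params[r.label])
                  for r in seg.windows.itertuples()]
    gaze, gt = generate_gaze(
        schedule, win_params, cfg.screen,
        child_seed(seed, participant, task_index, "gaze"),
        default_params=gp["Lo"])
    det = cfg.detector
    events = detect_gaze_events(
        gaze, cfg.screen, blink_pad=det.blink_pad,
        velocity_threshold=det.velocity_threshold,
        accel_threshold=det.accel_threshold,
        min_saccade=det.min_saccade, min_fixation=det.min_fixation)
    metrics = compute_metrics_table(events, gaze, seg.windows)

    fmt = None
    if cfg.include_neural:
        hi = [(r.t_start, r.t_end) for r in
              seg.windows[seg.windows["label"] == "Hi"].itertuples()]
        neural = generate_neural(
            schedule, hi, cfg.theta_boost,
            child_seed(seed, participant, task_index, "neural"),
            band=cfg.theta_band)
        try:
            fmt = validate_fmt(neural, seg.windows, band=cfg.theta_band,
                               threshold=cfg.theta_threshold)
        except InsufficientDataError:
            fmt = None
    return schedule, seg, metrics, fmt


def run_all(cfg: RunConfig, seed: int = 0,
            out_dir: str | Path | None = None) -> RunResult:
    """Run the full pipeline for every configured participant and task.

    The provenance log records counts at every stage: trials generated (and
    hence available), windows built and flagged, windows excluded by the
    missing-data rule, and trial pairs entering the statistics.
    """
    all_windows, all_metrics, fmt_rows, log = [], [], [], []
    comparisons: dict[str, pd.DataFrame] = {}
    provenance: dict = {"seed": int(seed),
                        "n_participants": cfg.n_participants, "tasks": {}}

    for task_index, task in enumerate(cfg.task_kinds()):
        task_windows, task_metrics = [], []
        n_flagged = 0
        trials_generated = 0
        for p in range(cfg.n_participants):
            try:
                schedule, seg, metrics, fmt = _run_session(
                    cfg, task, task_index, p, seed)
            except DriveGazeError as e:
                raise DriveGazeError(
                    f"stage failure in task={task.value} participant={p}: {e}"
                ) from e
            trials_generated += len(schedule)
            n_flagged += len(seg.flags)
            # globally unique trial ids across participants
            offset = (p + 1) * 1000
            w = seg.windows.copy()
            w["trial_id"] += offset
            w.insert(0, "participant", p)
            w.insert(0, "task", task.value)
            m = metrics.copy()
            m["trial_id"] += offset
            m.insert(0, "participant", p)
            m.insert(0, "task", task.value)
            task_windows.append(w)
            task_metrics.append(m)
            if fmt is not None:
                fmt = fmt.copy()
                fmt.insert(0, "participant", p)
                fmt.insert(0, "task", task.value)
                fmt_rows.append(fmt)

        windows = pd.concat(task_windows, ignore_index=True)
        metrics = pd.concat(task_metrics, ignore_index=True)
        retained, excluded = apply_exclusion(metrics, cfg.max_missing)
        lo = retained[retained["label"] == "Lo"]
        hi = retained[retained["label"] == "Hi"]
        comp = comparison_table(lo, hi)
        comparisons[task.value] = comp

        provenance["tasks"][task.value] = {
            "participants": cfg.n_participants,
            "trials_generated": trials_generated,
            "available_trials": trials_generated,
            "windows_built": int(len(windows)),
            "windows_flagged": int(n_flagged),
            "lo_windows": int((metrics["label"] == "Lo").sum()),
            "hi_windows": int((metrics["label"] == "Hi").sum()),
            "lo_excluded": int((excluded["label"] == "Lo").sum()),
            "hi_excluded": int((excluded["label"] == "Hi").sum()),
            "lo_retained": int(len(lo)),
            "hi_retained": int(len(hi)),
            "pairs_tested": int(comp["n_pairs"].max()) if len(comp) else 0,
        }
        log.append(f"task={task.value}: {trials_generated} trials, "
                   f"{len(windows)} windows, "
                   f"{len(excluded)} excluded, "
                   f"{provenance['tasks'][task.value]['pairs_tested']} pairs")

        all_windows.append(windows)
        all_metrics.append(metrics)

    result = RunResult(
        windows=pd.concat(all_windows, ignore_index=True),
        metrics=pd.concat(all_metrics, ignore_index=True),
        excluded=pd.concat(
            [apply_exclusion(m, cfg.max_missing)[1] for m in all_metrics],
            ignore_index=True),
        comparisons=comparisons,
        fmt_report=(pd.concat(fmt_rows, ignore_index=True) if fmt_rows
                    else pd.DataFrame(columns=["task", "participant", "label",
                                               "pseudo_t", "n_trials",
                                               "elevated"])),
        provenance=provenance,
        log=log,
    )

    if out_dir is not None:
        result.manifest = _write_outputs(result, cfg, Path(out_dir))
    return result


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_outputs(result: RunResult, cfg: RunConfig, out: Path
                   ) -> dict[str, str]:
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(name, fn):
        p = out / name
        fn(p)
        written.append(p)

    _w("windows.csv", lambda p: write_table(result.windows, p))
    _w("metrics.csv", lambda p: write_table(result.metrics, p))
    for task, comp in result.comparisons.items():
        _w(f"comparison_{task}.csv",
           lambda p, c=comp: write_table(c, p, COMPARISON_FILE_COLUMNS))
    _w("fmt_report.csv", lambda p: write_table(result.fmt_report, p))
    _w("provenance.json", lambda p: p.write_text(
        json.dumps(result.provenance, indent=1, sort_keys=True)))
    _w("config.json", lambda p: cfg.to_json(p))
    _w("run.log", lambda p: p.write_text("\n".join(result.log) + "\n"))

    manifest = {p.name: _sha256(p) for p in sorted(written)}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
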