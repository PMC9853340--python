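"""CSV dialects, run configuration and the end-to-end pipeline.

All timestamps are naive local time (ISO-8601); mixing timezone-aware rows is
an error.  Dexcom-style exports encode out-of-range readings as "Low"/"High"
strings; these map to missing by default, or clamp to 40/400 with
``clamp_out_of_range=True``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .capture import EmaSession, filter_participants, summarize_capture
from .compare import schedule_table
from .events import (
    GlucoseTrace,
    apply_exclusions,
    assess_eligibility,
    detect_events,
    events_to_frame,
    restrict_daytime,
)
from .reliability import reliability_by_schedule
from .scoring import half_score_table, score_sessions
from .synthetic import SimulationParams, simulate_cohort, write_cohort_csvs

logger = logging.getLogger(__name__)

CGM_COLUMNS = ["participant_id", "timestamp", "glucose_mg_dl"]


def read_cgm_csv(
    path: str | Path, clamp_out_of_range: bool = False
) -> dict[str, GlucoseTrace]:
    """Read a CGM CSV into one GlucoseTrace per participant.

    Rows with non-numeric glucose ("Low"/"High" or otherwise) are mapped to
    missing (or clamped to 40/400 for Low/High) and reported via logging;
    duplicate timestamps within a participant are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty CGM file")
    missing = [c for c in CGM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    raw = df["glucose_mg_dl"]
    glucose = pd.to_numeric(raw, errors="coerce")
    if clamp_out_of_range:
        glucose = glucose.mask(raw.astype(str).str.strip().str.lower() == "low", 40.0)
        glucose = glucose.mask(raw.astype(str).str.strip().str.lower() == "high", 400.0)
    n_bad = int(glucose.isna().sum())
    if n_bad:
        logger.warning("%s: skipped %d non-numeric glucose row(s)", path, n_bad)
    df = df.assign(glucose_mg_dl=glucose).dropna(subset=["glucose_mg_dl"])
    ts = pd.to_datetime(df["timestamp"])
    if getattr(ts.dt, "tz", None) is not None:
        raise ValueError(f"{path}: timezone-aware timestamps are not supported")
    df = df.assign(timestamp=ts)

    traces: dict[str, GlucoseTrace] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp")
        if grp["timestamp"].duplicated().any():
            raise ValueError(f"{path}: duplicate timestamps for participant {pid}")
        traces[str(pid)] = GlucoseTrace(
            participant=str(pid),
            times=grp["timestamp"].to_numpy(),
            values=grp["glucose_mg_dl"].to_numpy(dtype=float),
        )
    return traces


def read_ema_csv(path: str | Path) -> dict[str, list[EmaSession]]:
    """Read an EMA session log CSV into per-participant session lists."""
    df = pd.read_csv(path, dtype={"start_time": str, "end_time": str}, keep_default_na=False)
    out: dict[str, list[EmaSession]] = {}
    for _, r in df.iterrows():
        nt = datetime.fromisoformat(r["notify_time"])
        completed = bool(int(r["completed"]))
        sess = EmaSession(
            participant=str(r["participant_id"]),
            schedule=r["schedule"],
            day=nt.date(),
            window_index=int(r["window_index"]),
            notify_time=nt,
            start_time=datetime.fromisoformat(r["start_time"]) if completed else None,
            end_time=datetime.fromisoformat(r["end_time"]) if completed else None,
            completed=completed,
            administrations=tuple(r["tests"].split("|")) if r.get("tests") else (),
            session_id=str(r.get("session_id", "")),
        )
        out.setdefault(sess.participant, []).append(sess)
    return out


@dataclass
class RunConfig:
    """Top-level pipeline configuration."""

    outdir: str = "glucema_out"
    cgm_path: str | None = None  # None => simulate
    ema_path: str | None = None
    simulate: bool = True
    seed: int = 0
    n_participants: int = 20
    threshold: float = 70.0
    max_jump: float = 40.0
    max_gap_min: float = 20.0
    day_start: str = "08:00"
    day_end: str = "22:00"
    n_boot: int = 1000
    min_completion: float = 50.0
    min_cgm_hours: float = 72.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in payload.items() if k in cls.__dataclass_fields__}
        unknown = set(payload) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def _manifest(config: RunConfig, outputs: dict[str, Path]) -> dict:
    params = asdict(config)
    digest = hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return {
        "package": "glucema",
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": digest,
        "parameters": params,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute simulate (optional) -> detect -> capture -> score -> reliability
    -> compare, writing every stage's output plus a manifest.

    Deterministic given the configuration (including seed); a stage failure
    raises with the stage name attached.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "simulate"
        if config.simulate:
            params = SimulationParams(
                n_participants=config.n_participants, seed=config.seed
            )
            cohort = simulate_cohort(params)
            paths = write_cohort_csvs(cohort, out / "synthetic")
            traces = cohort.traces
            sessions = cohort.sessions
            trials = cohort.trials
            outputs.update(paths)
        else:
            if not config.cgm_path or not config.ema_path:
                raise ValueError("non-simulate mode requires cgm_path and ema_path")
            traces = read_cgm_csv(config.cgm_path)
            sessions = read_ema_csv(config.ema_path)
            trials_path = Path(config.cgm_path).with_name("trials.csv")
            trials = pd.read_csv(trials_path) if trials_path.exists() else pd.DataFrame()

        stage = "detect"
        day_start = time.fromisoformat(config.day_start)
        day_end = time.fromisoformat(config.day_end)
        events_by_pid = {}
        eligibility = {}
        for pid, trace in traces.items():
            evs = detect_events(trace, threshold=config.threshold)
            evs = apply_exclusions(evs, trace, config.max_jump, config.max_gap_min)
            kept = [e for e in evs if not e.excluded]
            events_by_pid[pid] = restrict_daytime(kept, day_start, day_end) + [
                e for e in evs if e.excluded
            ]
            eligibility[pid] = assess_eligibility(trace, config.min_cgm_hours)
        all_events = [e for evs in events_by_pid.values() for e in evs]
        outputs["events"] = out / "events.csv"
        events_to_frame(all_events).to_csv(outputs["events"], index=False)

        stage = "capture"
        summary = summarize_capture(events_by_pid, sessions)
        retained, exclusions = filter_participants(
            summary, eligibility, config.min_completion, config.min_cgm_hours
        )
        outputs["capture"] = out / "capture_summary.csv"
        summary.to_csv(outputs["capture"], index=False)
        outputs["exclusions"] = out / "excluded_participants.csv"
        exclusions.to_csv(outputs["exclusions"], index=False)
        summary = summary[summary["participant_id"].isin(retained)]

        stage = "score"
        trials = trials[trials["participant_id"].isin(retained)]
        scores = score_sessions(trials)
        sched_of = {
            s.session_id: s.schedule for ss in sessions.values() for s in ss
        }
        scores["schedule"] = scores["session_id"].map(sched_of)
        outputs["scores"] = out / "scores.csv"
        scores.to_csv(outputs["scores"], index=False)

        stage = "reliability"
        halves = half_score_table(scores)
        rel = reliability_by_schedule(halves, n_boot=config.n_boot, seed=config.seed)
        outputs["reliability"] = out / "reliability.csv"
        rel.to_csv(outputs["reliability"], index=False)

        stage = "compare"
        table = schedule_table(scores, summary, rel)
        outputs["comparison"] = out / "schedule_comparison.csv"
        table.to_csv(outputs["comparison"], index=False)

        stage = "manifest"
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(_manifest(config, outputs), indent=2, default=str))
        outputs["manifest"] = manifest_path
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outputs
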