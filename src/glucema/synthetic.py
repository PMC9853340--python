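"""Synthetic coupled CGM / EMA / trial-level cohorts with known ground truth.

The generator produces everything the analysis pipeline consumes — glucose
traces, scheduled EMA sessions with completion, and per-trial cognitive
records — together with a truth registry (injected hypoglycemic episodes and
the generative score-model parameters), so every downstream stage can be
tested without participant data.

Glucose background is a discretized mean-reverting (AR(1)) process around a
baseline; hypoglycemic excursions are injected explicitly as V-shaped dips to
a drawn nadir and recorded in the truth registry on the sample grid.  The
background variability is kept moderate by default so that essentially all
sub-threshold excursions are injected ones: the registry, not physiological
realism, is what downstream tests measure against.  Sensor imperfections are
modeled as sample dropouts and single-sample jump artifacts; values clamp to
the 40-400 mg/dL reporting range.

Cognitive scores follow a three-component variance model per test: half-score
= grand mean + person effect + session effect + residual, with SDs chosen so
the defaults reproduce the pilot's score scales.  For reaction-time tests the
trials are realized so the median of each half equals the latent half score
exactly (symmetric jitter with median zero), making the generated variance
decomposition analytically exact; accuracy and CPT tests realize trials
binomially, which adds trial-sampling variance on top of the residual.

One cohort seed expands into per-participant substreams by hashing the
participant index into the seed, so any participant can be regenerated alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

from .capture import EmaSession
from .events import GLUCOSE_MAX, GLUCOSE_MIN, GlucoseTrace
from .scheduling import (
    DEFAULT_BATTERY,
    CrossoverPlan,
    assign_battery,
    build_crossover,
    draw_notification_times,
)
from .scoring import OUTCOME_BY_TEST


@dataclass(frozen=True)
class ScoreModel:
    """Generative parameters for one test's half scores."""

    mean: float
    sd_bp: float  # between-person
    sd_session: float  # between-session within person
    sd_resid: float  # residual between halves
    trials_per_admin: int = 20

    def __post_init__(self) -> None:
        if min(self.sd_bp, self.sd_session, self.sd_resid) < 0:
            raise ValueError("score-model SDs must be non-negative")
        if self.trials_per_admin < 2 or self.trials_per_admin % 2:
            raise ValueError("trials_per_admin must be an even count >= 2")


#: Default score models; means and between-person SDs follow the pilot score
#: scales, within-person SDs chosen for the high test-retest stability the
#: brief tests exhibit.
DEFAULT_SCORE_MODELS: dict[str, ScoreModel] = {
    "choice_rt": ScoreModel(731, 114, 40, 30),
    "dsm": ScoreModel(839, 135, 45, 35),
    "flicker": ScoreModel(3768, 1771, 300, 300),
    "gradcpt": ScoreModel(3.06, 0.36, 0.15, 0.10),
    "mot": ScoreModel(71.7, 7.1, 4.0, 5.0),
    "psat": ScoreModel(83.4, 18.0, 5.0, 6.0),
}

DEFAULT_COMPLETION = {"three_per_day": 0.857, "six_per_day": 0.817}


@dataclass(frozen=True)
class SimulationParams:
    """Cohort-level simulation configuration (defaults emulate the pilot)."""

    n_participants: int = 20
    days: int = 15
    cadence_min: int = 5
    start_date: date = date(2020, 3, 3)
    baseline_mean: float = 150.0
    baseline_sd: float = 25.0
    mean_reversion_rate: float = 0.05  # per-step pull toward baseline, in (0, 1]
    hypo_rate: float = 0.51  # events/day
    hypo_duration_mean: float = 40.0  # minutes
    hypo_nadir_range: tuple[float, float] = (54.0, 66.0)
    dropout_prob: float = 0.01
    artifact_prob: float = 0.002
    completion_prob: dict[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_COMPLETION)
    )
    score_models: dict[str, ScoreModel] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_MODELS)
    )
    night_hypo: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if 1440 % self.cadence_min:
            raise ValueError("cadence must divide 1440 minutes")
        if not 0 < self.mean_reversion_rate <= 1:
            raise ValueError("mean_reversion_rate must lie in (0, 1]")
        for p in (self.dropout_prob, self.artifact_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.hypo_nadir_range
        if not (0 < lo <= hi < 70):
            raise ValueError("hypo_nadir_range must lie within (0, 70)")
        if self.hypo_rate < 0:
            raise ValueError("hypo_rate must be >= 0")

    def completion_for(self, schedule: str) -> float:
        if isinstance(self.completion_prob, dict):
            return self.completion_prob[schedule]
        return float(self.completion_prob)


def participant_seed(seed: int, index: int, stream: int = 0) -> int:
    """Deterministic per-participant (and per-stream) substream seed < 2^31."""
    x = (seed * 1_000_003 + index * 7919 + stream * 104_729 + 12_345) & 0xFFFFFFFF
    x ^= x >> 16
    x = (x * 0x45D9F3B) & 0xFFFFFFFF
    x ^= x >> 16
    return int(x % (2**31))


# ---------------------------------------------------------------------------
# glucose


def simulate_glucose_trace(
    params: SimulationParams, participant_index: int
) -> tuple[GlucoseTrace, pd.DataFrame]:
    """One participant's CGM trace plus the injected-event truth registry.

    Returns ``(trace, truth)`` where truth has columns participant_id /
    start / end / nadir, with start/end aligned to the sample grid.
    """
    pid = f"P{participant_index:03d}"
    rng = np.random.default_rng(participant_seed(params.seed, participant_index, 1))
    step = params.cadence_min
    n = params.days * 1440 // step
    t0 = datetime.combine(params.start_date, time(0, 0))
    times = np.array(
        [np.datetime64(t0) + np.timedelta64(i * step, "m") for i in range(n)],
        dtype="datetime64[ns]",
    )

    # AR(1) background around baseline: x[k] = (1-theta) x[k-1] + eps
    theta = params.mean_reversion_rate
    phi = 1.0 - theta
    sd_step = params.baseline_sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    eps = rng.normal(0.0, sd_step, size=n)
    x0 = rng.normal(0.0, params.baseline_sd)
    dev = signal.lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))[0]
    values = params.baseline_mean + dev

    # injected hypoglycemic excursions (Poisson, daytime unless night_hypo)
    k = rng.poisson(params.hypo_rate * params.days)
    day_lo, day_hi = (0.0, 24.0) if params.night_hypo else (8.0, 22.0)
    accepted: list[tuple[float, float, float]] = []  # (start_min, dur, nadir)
    for _ in range(k):
        for _attempt in range(200):
            dur = float(max(20.0, rng.normal(params.hypo_duration_mean, params.hypo_duration_mean / 4)))
            day = int(rng.integers(0, params.days))
            lo = day * 1440 + day_lo * 60
            hi = day * 1440 + day_hi * 60 - dur
            if hi <= lo:
                continue
            start = float(rng.uniform(lo, hi))
            if all(
                start > s + d + 30.0 or start + dur < s - 30.0
                for s, d, _ in accepted
            ):
                nadir = float(rng.uniform(*params.hypo_nadir_range))
                accepted.append((start, dur, nadir))
                break
    accepted.sort()

    grid_min = np.arange(n, dtype=float) * step
    truth_rows = []
    for start, dur, nadir in accepted:
        inside = np.flatnonzero((grid_min >= start) & (grid_min <= start + dur))
        if len(inside) < 2:
            continue
        mid = start + dur / 2.0
        frac = np.abs(grid_min[inside] - mid) / (dur / 2.0)
        values[inside] = nadir + (68.0 - nadir) * frac  # V-shaped dip, <70 throughout
        truth_rows.append(
            {
                "participant_id": pid,
                "start": pd.Timestamp(times[inside[0]]),
                "end": pd.Timestamp(times[inside[-1]]),
                "nadir": nadir,
            }
        )

    # single-sample jump artifacts, then dropouts, then clamp
    art = rng.random(n) < params.artifact_prob
    values[art] += rng.choice([-1.0, 1.0], size=art.sum()) * rng.uniform(45.0, 90.0, size=art.sum())
    keep = rng.random(n) >= params.dropout_prob
    values = np.clip(values, GLUCOSE_MIN, GLUCOSE_MAX)
    trace = GlucoseTrace(
        participant=pid,
        times=times[keep],
        values=values[keep],
        cadence_min=step,
    )
    truth = pd.DataFrame(truth_rows, columns=["participant_id", "start", "end", "nadir"])
    return trace, truth


# ---------------------------------------------------------------------------
# sessions


def simulate_sessions(
    plan: CrossoverPlan, params: SimulationParams, participant_index: int
) -> list[EmaSession]:
    """Scheduled EMA occasions with stochastic completion and timing.

    Every occasion of the plan appears; completed occasions (independent
    Bernoulli per the schedule's completion probability) get a start time
    uniform in (notification, notification + 30 min] and an end ~5 minutes
    later.  Test triples follow the counterbalancing contract.
    """
    pid = f"P{participant_index:03d}"
    rng = np.random.default_rng(participant_seed(params.seed, participant_index, 2))
    occasions = plan.occasions()
    triples = assign_battery(
        occasions, DEFAULT_BATTERY, seed=participant_seed(params.seed, participant_index, 3)
    )
    notify: dict[tuple[date, int], datetime] = {}
    day0 = plan.start_date
    for phase_idx, cfg in enumerate(plan.phases):
        times_ = draw_notification_times(
            cfg,
            seed=participant_seed(params.seed, participant_index, 4 + phase_idx),
            start_date=day0,
        )
        for d in range(cfg.days):
            for w in range(cfg.per_day):
                notify[(day0 + timedelta(days=d), w)] = times_[d * cfg.per_day + w]
        day0 += timedelta(days=cfg.days)

    sessions: list[EmaSession] = []
    for occ, triple in zip(occasions, triples):
        nt = notify[(occ.day, occ.window_index)]
        done = rng.random() < params.completion_for(occ.schedule)
        start = end = None
        if done:
            delay_min = 30.0 * (1.0 - rng.random())  # uniform in (0, 30]
            start = nt + timedelta(minutes=delay_min)
            end = start + timedelta(minutes=float(rng.uniform(4.0, 6.0)))
        sessions.append(
            EmaSession(
                participant=pid,
                schedule=occ.schedule,
                day=occ.day,
                window_index=occ.window_index,
                notify_time=nt,
                start_time=start,
                end_time=end,
                completed=done,
                administrations=triple,
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# trials


def _rt_trials(latent: float, n_half: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """RTs whose median equals ``latent`` exactly; all trials correct."""
    spread = max(0.12 * latent, 1.0)
    offsets = np.linspace(-spread, spread, n_half)
    rng.shuffle(offsets)
    return latent + offsets, np.ones(n_half, dtype=bool)


def simulate_trials(
    session: EmaSession,
    params: SimulationParams,
    person_effects: dict[str, float],
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Trial records for one completed session (all its administrations).

    ``person_effects`` maps test id -> the participant's stable effect draw.
    Raises on incomplete sessions (there is nothing to administer).
    """
    if not session.completed:
        raise ValueError("cannot simulate trials for an incomplete session")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for test in session.administrations:
        model = params.score_models[test]
        outcome = OUTCOME_BY_TEST[test]
        n_trials = model.trials_per_admin
        n_half = n_trials // 2
        admin_latent = model.mean + person_effects[test] + rng.normal(0.0, model.sd_session)
        odd_idx = np.arange(1, n_trials + 1, 2)
        even_idx = np.arange(2, n_trials + 1, 2)
        for half_idx in (even_idx, odd_idx):
            latent = admin_latent + rng.normal(0.0, model.sd_resid)
            if outcome == "medianRTc":
                latent = max(latent, 100.0)
                rts, correct = _rt_trials(latent, n_half, rng)
                stim = np.full(n_half, "n/a")
            elif outcome == "accuracy":
                p = float(np.clip(latent, 0.0, 100.0)) / 100.0
                k = int(round(p * n_half))
                correct = np.zeros(n_half, dtype=bool)
                correct[rng.permutation(n_half)[:k]] = True
                rts = rng.normal(1500.0, 200.0, size=n_half)
                stim = np.full(n_half, "n/a")
            else:  # d-prime (CPT): ~80% targets, balanced criterion
                d = float(np.clip(latent, 0.0, 6.0))
                n_t = max(int(round(0.8 * n_half)), 1)
                n_nt = max(n_half - n_t, 1)
                n_t = n_half - n_nt
                hit_p = stats.norm.cdf(d / 2.0)
                fa_p = stats.norm.cdf(-d / 2.0)
                stim = np.array(["target"] * n_t + ["nontarget"] * n_nt)
                rng.shuffle(stim)
                correct = np.empty(n_half, dtype=bool)
                tgt = stim == "target"
                correct[tgt] = rng.random(tgt.sum()) < hit_p
                correct[~tgt] = rng.random((~tgt).sum()) >= fa_p
                rts = rng.normal(800.0, 150.0, size=n_half)
            for j, idx in enumerate(half_idx):
                rows.append(
                    {
                        "participant_id": session.participant,
                        "session_id": session.session_id,
                        "test": test,
                        "trial_index": int(idx),
                        "stim_class": stim[j],
                        "correct": bool(correct[j]),
                        "rt_ms": float(rts[j]),
                    }
                )
    df = pd.DataFrame(rows)
    return df.sort_values(["test", "trial_index"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class CohortDataset:
    """A complete simulated cohort plus its generating truth."""

    params: SimulationParams
    plans: dict[str, CrossoverPlan]
    traces: dict[str, GlucoseTrace]
    sessions: dict[str, list[EmaSession]]
    trials: pd.DataFrame
    truth_events: pd.DataFrame


def simulate_cohort(
    params: SimulationParams, with_glucose: bool = True, with_trials: bool = True
) -> CohortDataset:
    """Simulate a full cohort: alternate A/B group assignment, all streams.

    ``with_glucose`` / ``with_trials`` switch off streams not needed by a
    given analysis (they dominate the run time).
    """
    plans: dict[str, CrossoverPlan] = {}
    traces: dict[str, GlucoseTrace] = {}
    sessions: dict[str, list[EmaSession]] = {}
    all_trials: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    for i in range(params.n_participants):
        pid = f"P{i:03d}"
        plan = build_crossover("A" if i % 2 == 0 else "B", start_date=params.start_date)
        if plan.total_days != params.days:
            scale = {p.label: p.days for p in plan.phases}
            raise ValueError(
                f"params.days={params.days} does not match the crossover plan "
                f"({scale}); adjust one of them"
            )
        plans[pid] = plan
        if with_glucose:
            trace, truth = simulate_glucose_trace(params, i)
            traces[pid] = trace
            truth_frames.append(truth)
        sess = simulate_sessions(plan, params, i)
        sessions[pid] = sess
        if with_trials:
            rng_p = np.random.default_rng(participant_seed(params.seed, i, 6))
            effects = {
                t: rng_p.normal(0.0, m.sd_bp) for t, m in params.score_models.items()
            }
            rng_t = np.random.default_rng(participant_seed(params.seed, i, 7))
            for s in sess:
                if s.completed:
                    all_trials.append(simulate_trials(s, params, effects, rng_t))
    trials = (
        pd.concat(all_trials, ignore_index=True)
        if all_trials
        else pd.DataFrame(
            columns=[
                "participant_id", "session_id", "test", "trial_index",
                "stim_class", "correct", "rt_ms",
            ]
        )
    )
    truth = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames
        else pd.DataFrame(columns=["participant_id", "start", "end", "nadir"])
    )
    return CohortDataset(
        params=params, plans=plans, traces=traces, sessions=sessions,
        trials=trials, truth_events=truth,
    )


def simulate_half_scores(
    n_participants: int,
    n_sessions: int,
    mean: float = 0.0,
    sd_bp: float = 1.0,
    sd_session: float = 0.5,
    sd_resid: float = 0.5,
    seed: int = 0,
    test: str = "synthetic",
) -> pd.DataFrame:
    """Half scores drawn directly from the three-component variance model.

    A balanced table (two halves per session) in the long layout consumed by
    :mod:`glucema.reliability`; used for parameter-recovery and coverage
    studies where the trial-realization layer is irrelevant.
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sd_bp, size=n_participants)
    u = rng.normal(0.0, sd_session, size=(n_participants, n_sessions))
    e = rng.normal(0.0, sd_resid, size=(n_participants, n_sessions, 2))
    y = mean + b[:, None, None] + u[:, :, None] + e
    p_idx, s_idx, h_idx = np.meshgrid(
        np.arange(n_participants), np.arange(n_sessions), np.arange(2), indexing="ij"
    )
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in p_idx.ravel()],
            "session_id": [f"S{j:02d}" for j in s_idx.ravel()],
            "test": test,
            "half": np.where(h_idx.ravel() == 0, "even", "odd"),
            "score": y.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# CSV export


def write_cohort_csvs(dataset: CohortDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort's CGM, EMA-log and trial CSVs (package dialects)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    cgm = pd.concat([t.to_frame() for t in dataset.traces.values()], ignore_index=True) \
        if dataset.traces else pd.DataFrame(columns=["participant_id", "timestamp", "glucose_mg_dl"])
    paths["cgm"] = outdir / "cgm.csv"
    cgm.to_csv(paths["cgm"], index=False)

    ema_rows = []
    for pid, sess in dataset.sessions.items():
        for s in sess:
            ema_rows.append(
                {
                    "participant_id": pid,
                    "schedule": s.schedule,
                    "window_index": s.window_index,
                    "notify_time": s.notify_time.isoformat(),
                    "start_time": s.start_time.isoformat() if s.start_time else "",
                    "end_time": s.end_time.isoformat() if s.end_time else "",
                    "completed": int(s.completed),
                    "session_id": s.session_id,
                    "tests": "|".join(s.administrations),
                }
            )
    paths["ema"] = outdir / "ema_sessions.csv"
    pd.DataFrame(ema_rows).to_csv(paths["ema"], index=False)

    paths["trials"] = outdir / "trials.csv"
    dataset.trials.to_csv(paths["trials"], index=False)
    paths["truth"] = outdir / "truth_events.csv"
    dataset.truth_events.to_csv(paths["truth"], index=False)
    return paths
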