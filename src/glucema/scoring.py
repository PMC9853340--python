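"""Per-administration cognitive outcome scoring, with even/odd split halves.

Outcomes follow the brief mobile test battery: median reaction time on correct
trials (medianRTc, ms) for Choice RT / Digit Symbol Matching / Flicker, percent
accuracy for MOT / PSAT, and signal-detection d-prime for the gradual-onset CPT.
d-prime always applies the log-linear correction (0.5 added to hit and
false-alarm counts, 1 to their denominators), which keeps it finite at perfect
or empty rates and avoids a discontinuity between extreme and interior rates.

Split halves partition trials by the parity of their 1-based presentation
index: "odd" contains trials 1, 3, 5, ... and "even" trials 2, 4, 6, ....
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

#: outcome computed for each test in the battery
OUTCOME_BY_TEST = {
    "choice_rt": "medianRTc",
    "dsm": "medianRTc",
    "flicker": "medianRTc",
    "gradcpt": "d_prime",
    "mot": "accuracy",
    "psat": "accuracy",
}

TRIAL_COLUMNS = [
    "participant_id",
    "session_id",
    "test",
    "trial_index",
    "stim_class",
    "correct",
    "rt_ms",
]


class InsufficientTrialsError(ValueError):
    """Raised when a trial set cannot produce the requested score."""


def score_median_rtc(trials: pd.DataFrame) -> float:
    """Median reaction time (ms) over correct trials with a recorded RT."""
    ok = trials[(trials["correct"].astype(bool)) & trials["rt_ms"].notna()]
    if ok.empty:
        raise InsufficientTrialsError("no correct trials with reaction times")
    return float(np.median(ok["rt_ms"].to_numpy(dtype=float)))


def score_accuracy(trials: pd.DataFrame) -> float:
    """Percent correct over all trials (omissions count as incorrect)."""
    if trials.empty:
        raise InsufficientTrialsError("no trials")
    return 100.0 * float(trials["correct"].astype(bool).mean())


def score_dprime(trials: pd.DataFrame) -> float:
    """Log-linear-corrected d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate).

    Omitted responses on target trials are misses (``correct`` False).  Requires
    both stimulus classes to be present.
    """
    targets = trials[trials["stim_class"] == "target"]
    lures = trials[trials["stim_class"] == "nontarget"]
    if targets.empty or lures.empty:
        raise InsufficientTrialsError("d' requires both target and nontarget trials")
    hits = int(targets["correct"].astype(bool).sum())
    fas = int((~lures["correct"].astype(bool)).sum())
    hr = (hits + 0.5) / (len(targets) + 1.0)
    far = (fas + 0.5) / (len(lures) + 1.0)
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))


def split_half(
    trials: pd.DataFrame, scorer: Callable[[pd.DataFrame], float]
) -> tuple[float, float]:
    """Apply ``scorer`` separately to even- and odd-indexed trials.

    Returns (even_score, odd_score); a half whose trials cannot be scored
    yields NaN for that half.  Requires at least two trials.
    """
    if len(trials) < 2:
        raise InsufficientTrialsError("split-half scoring requires >= 2 trials")
    parity = trials["trial_index"].astype(int) % 2
    halves = []
    for want in (0, 1):  # even indices, then odd
        sub = trials[parity == want]
        try:
            halves.append(scorer(sub))
        except InsufficientTrialsError:
            halves.append(float("nan"))
    return halves[0], halves[1]


_SCORERS: dict[str, Callable[[pd.DataFrame], float]] = {
    "medianRTc": score_median_rtc,
    "accuracy": score_accuracy,
    "d_prime": score_dprime,
}


def scorer_for_test(test: str) -> Callable[[pd.DataFrame], float]:
    return _SCORERS[OUTCOME_BY_TEST[test]]


_KEYS = ["participant_id", "session_id", "test"]


def _vector_scores(trials: pd.DataFrame) -> pd.Series:
    """Outcome score per (participant, session, test) group, vectorized.

    Equivalent to applying the per-outcome scorer group by group (the property
    is asserted in the test suite); groups that cannot be scored are NaN.
    """
    test_outcome = trials["test"].map(OUTCOME_BY_TEST)
    correct = trials["correct"].astype(bool)
    pieces = []

    rt_rows = trials[(test_outcome == "medianRTc") & correct & trials["rt_ms"].notna()]
    if len(rt_rows):
        pieces.append(rt_rows.groupby(_KEYS, sort=False, observed=True)["rt_ms"].median())

    acc_rows = trials[test_outcome == "accuracy"]
    if len(acc_rows):
        pieces.append(
            100.0 * acc_rows.groupby(_KEYS, sort=False, observed=True)["correct"]
            .apply(lambda s: s.astype(bool).mean())
        )

    cpt = trials[test_outcome == "d_prime"]
    if len(cpt):
        tmp = pd.DataFrame(
            {
                "n_t": (cpt["stim_class"] == "target").astype(int),
                "n_nt": (cpt["stim_class"] == "nontarget").astype(int),
                "hit": ((cpt["stim_class"] == "target") & correct.loc[cpt.index]).astype(int),
                "fa": ((cpt["stim_class"] == "nontarget") & ~correct.loc[cpt.index]).astype(int),
            },
            index=cpt.index,
        )
        for k in _KEYS:
            tmp[k] = cpt[k]
        agg = tmp.groupby(_KEYS, sort=False, observed=True).sum()
        valid = (agg["n_t"] > 0) & (agg["n_nt"] > 0)
        hr = (agg["hit"] + 0.5) / (agg["n_t"] + 1.0)
        far = (agg["fa"] + 0.5) / (agg["n_nt"] + 1.0)
        dp = pd.Series(stats.norm.ppf(hr) - stats.norm.ppf(far), index=agg.index)
        pieces.append(dp.where(valid))

    if not pieces:
        return pd.Series(dtype=float)
    return pd.concat(pieces)


def score_sessions(trials: pd.DataFrame) -> pd.DataFrame:
    """Score every (participant, session, test) administration in a trial table.

    Input columns follow ``TRIAL_COLUMNS``.  Output: one row per administration
    with full/even/odd scores; administrations that cannot be scored appear
    with NaN scores and a reason.  Vectorized over administrations so cohort
    tables with tens of thousands of administrations score in seconds.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    groups = trials.groupby(_KEYS, sort=False, observed=True).size().rename("n_trials")
    out = groups.reset_index()
    out["outcome"] = out["test"].map(OUTCOME_BY_TEST)

    full = _vector_scores(trials)
    parity = trials["trial_index"].astype(int) % 2
    even = _vector_scores(trials[parity == 0])
    odd = _vector_scores(trials[parity == 1])
    idx = pd.MultiIndex.from_frame(out[_KEYS])
    out["full"] = full.reindex(idx).to_numpy()
    out["even"] = even.reindex(idx).to_numpy()
    out["odd"] = odd.reindex(idx).to_numpy()
    # split halves are undefined for single-trial administrations
    out.loc[out["n_trials"] < 2, ["even", "odd"]] = np.nan
    out["reason"] = np.where(out["full"].isna(), "unscoreable trials", "")
    return out.drop(columns="n_trials")


def half_score_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Reshape a scores table to long half-score form for reliability analysis.

    Keeps any ``schedule`` column so per-schedule reliability can subset rows.
    """
    keep = [c for c in ("participant_id", "session_id", "test", "schedule") if c in scores]
    long = scores.melt(
        id_vars=keep, value_vars=["even", "odd"], var_name="half", value_name="score"
    )
    return long.dropna(subset=["score"]).reset_index(drop=True)
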