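"""Between-person reliability from repeated split-half scores.

The reliability of a test under an intensive repeated-measurement design is

    reliability = Var(BP) / (Var(BP) + Var(WP) / n)

where Var(BP) is the between-participant variance of the latent trait,
Var(WP) the within-participant variance (between-session variance plus
residual half-score variance), and n the number of half-score measurements
per participant (maximum 60 in this design: two halves of each of 30
administrations).  At n = 2 on single-session data the formula reduces to the
Spearman-Brown corrected split-half correlation, 2r / (1 + r).

Variance components come from an intercept-only two-level nested decomposition
(sessions within participants, halves as replicates).  The default estimator
is a method-of-moments nested ANOVA (Searle's expected-mean-squares solution,
valid for unbalanced data); restricted maximum likelihood via statsmodels
MixedLM is available as a cross-check (``method="reml"``).  For balanced
designs with non-negative estimates the two coincide.  The ANOVA estimator is
computed from per-participant sufficient statistics, which makes the
participant-level bootstrap (resampling participants with replacement and
re-estimating per resample) cheap even at 10,000 resamples.

Confidence intervals are percentile bootstrap (2.5 / 97.5), resampled at the
participant level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VarianceComponents:
    """Two-level nested variance decomposition of half scores."""

    var_bp: float  # between-participant
    var_session: float  # between-session, within participant
    var_resid: float  # residual (between halves within session)
    n_eff: float  # mean half-score count per participant

    @property
    def var_wp(self) -> float:
        return self.var_session + self.var_resid


@dataclass(frozen=True)
class ReliabilityEstimate:
    test: str
    value: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    components: VarianceComponents
    n_redraws: int = 0


# ---------------------------------------------------------------------------
# sufficient statistics & method-of-moments estimator


@dataclass(frozen=True)
class _SuffStats:
    """Per-participant sufficient statistics for the nested ANOVA."""

    n_obs: np.ndarray  # N_p: half-scores per participant
    n_sess: np.ndarray  # B_p: sessions per participant
    sum_y: np.ndarray  # sum of scores
    mean: np.ndarray  # participant mean
    q: np.ndarray  # sum over sessions of n_ps^2
    ss_within: np.ndarray  # residual SS within sessions
    t_sess: np.ndarray  # sum over sessions of n_ps * ybar_ps^2


def _suff_stats(df: pd.DataFrame) -> _SuffStats:
    g_sess = df.groupby(["participant_id", "session_id"], sort=False, observed=True)["score"]
    sess = g_sess.agg(n="size", mean="mean", ss=lambda x: ((x - x.mean()) ** 2).sum())
    sess = sess.reset_index()
    g_p = sess.groupby("participant_id", sort=False)
    n_obs = g_p["n"].sum().to_numpy(dtype=float)
    n_sess = g_p["n"].size().to_numpy(dtype=float)
    sum_y = (sess["n"] * sess["mean"]).groupby(sess["participant_id"], sort=False).sum()
    q = (sess["n"] ** 2).groupby(sess["participant_id"], sort=False).sum()
    ss_within = g_p["ss"].sum().to_numpy(dtype=float)
    t_sess = (
        (sess["n"] * sess["mean"] ** 2)
        .groupby(sess["participant_id"], sort=False)
        .sum()
        .to_numpy(dtype=float)
    )
    sum_y = sum_y.to_numpy(dtype=float)
    return _SuffStats(
        n_obs=n_obs,
        n_sess=n_sess,
        sum_y=sum_y,
        mean=sum_y / n_obs,
        q=q.to_numpy(dtype=float),
        ss_within=ss_within,
        t_sess=t_sess,
    )


def _mom_from_stats(st: _SuffStats, idx: np.ndarray | None = None) -> tuple[float, float, float]:
    """Searle EMS solution for (var_bp, var_session, var_resid).

    ``idx``: participant indices of a (bootstrap) resample; duplicated indices
    are treated as distinct participants.  Negative solutions truncate at 0.
    """
    if idx is None:
        idx = np.arange(len(st.n_obs))
    n_obs = st.n_obs[idx]
    n_sess = st.n_sess[idx]
    sum_y = st.sum_y[idx]
    mean = st.mean[idx]
    q = st.q[idx]
    a = len(idx)
    N = n_obs.sum()
    B = n_sess.sum()
    grand = sum_y.sum() / N

    ss_e = st.ss_within[idx].sum()
    df_e = N - B
    ss_s = (st.t_sess[idx] - n_obs * mean**2).sum()
    df_s = B - a
    ss_p = float((n_obs * mean**2).sum() - N * grand**2)
    df_p = a - 1
    if df_p <= 0:
        raise ValueError("variance partitioning requires >= 2 participants")

    # residual
    var_e = ss_e / df_e if df_e > 0 else 0.0
    # between-session
    if df_s > 0:
        k1 = float((n_obs - q / n_obs).sum()) / df_s
        var_u = (ss_s / df_s - var_e) / k1 if k1 > 0 else 0.0
    else:
        var_u = 0.0
    # between-participant
    k2 = float((q / n_obs).sum() - q.sum() / N) / df_p
    k3 = float(N - (n_obs**2).sum() / N) / df_p
    var_b = (ss_p / df_p - var_e - k2 * var_u) / k3
    return max(var_b, 0.0), max(var_u, 0.0), max(var_e, 0.0)


def _split_half_moments(df: pd.DataFrame) -> tuple[float, float] | None:
    """Pearson-moment components for single-session data with both halves.

    var_bp is the sample covariance of even and odd half scores; the total
    variance is the geometric mean of the two half variances, so that the n=2
    reliability formula coincides exactly with Spearman-Brown 2r/(1+r).
    Returns None when the layout is not one complete session per participant.
    """
    if df.groupby("participant_id", observed=True)["session_id"].nunique().max() != 1:
        return None
    wide = df.pivot_table(
        index="participant_id", columns="half", values="score", observed=True
    )
    if not {"even", "odd"}.issubset(wide.columns) or wide.isna().any().any():
        return None
    e = wide["even"].to_numpy(dtype=float)
    o = wide["odd"].to_numpy(dtype=float)
    if len(e) < 2:
        raise ValueError("variance partitioning requires >= 2 participants")
    cov = float(np.cov(e, o, ddof=1)[0, 1])
    total = float(np.sqrt(np.var(e, ddof=1) * np.var(o, ddof=1)))
    var_bp = max(cov, 0.0)
    var_wp = max(total - var_bp, 0.0)
    return var_bp, var_wp


def partition_variance(
    table: pd.DataFrame,
    test: str | None = None,
    method: str = "mom",
) -> VarianceComponents:
    """Estimate the nested variance components of a half-score table.

    ``table`` columns: participant_id, session_id, half, score (plus test when
    ``test`` is given).  ``method``: "mom" (default, expected-mean-squares
    ANOVA) or "reml" (statsmodels MixedLM cross-check).  Single-session tables
    use the split-half moment estimator (see module docstring); negative
    component estimates truncate at zero.
    """
    df = table if test is None else table[table["test"] == test]
    df = df.dropna(subset=["score"])
    if df.empty:
        raise ValueError(f"no scores for test {test!r}")
    n_participants = df["participant_id"].nunique()
    if n_participants < 2:
        raise ValueError("variance partitioning requires >= 2 participants")
    n_eff = len(df) / n_participants

    single = _split_half_moments(df)
    if single is not None:
        var_bp, var_wp = single
        return VarianceComponents(var_bp, 0.0, var_wp, n_eff)

    if method == "mom":
        st = _suff_stats(df)
        var_b, var_u, var_e = _mom_from_stats(st)
    elif method == "reml":
        var_b, var_u, var_e = _reml_components(df)
    else:
        raise ValueError(f"unknown method {method!r}")
    return VarianceComponents(var_b, var_u, var_e, n_eff)


def _reml_components(df: pd.DataFrame) -> tuple[float, float, float]:
    """REML fit of the nested model via statsmodels MixedLM."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    d = df.copy()
    d["participant_id"] = d["participant_id"].astype(str)
    d["sess"] = d["participant_id"] + "/" + d["session_id"].astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            "score ~ 1",
            groups="participant_id",
            re_formula="1",
            vc_formula={"sess": "0 + C(sess)"},
            data=d,
        )
        fit = model.fit(reml=True)
    var_b = float(np.asarray(fit.cov_re)[0, 0])
    var_u = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
    var_e = float(fit.scale)
    return max(var_b, 0.0), max(var_u, 0.0), max(var_e, 0.0)


# ---------------------------------------------------------------------------
# reliability & bootstrap


def compute_reliability(vc: VarianceComponents | tuple[float, float], n: float) -> float:
    """reliability = var_bp / (var_bp + var_wp / n); NaN when both are zero."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(vc, VarianceComponents):
        var_bp, var_wp = vc.var_bp, vc.var_wp
    else:
        var_bp, var_wp = vc
    denom = var_bp + var_wp / n
    if denom == 0.0:
        logger.warning("reliability undefined: var_bp = var_wp = 0")
        return float("nan")
    return float(np.clip(var_bp / denom, 0.0, 1.0))


def bootstrap_ci(
    table: pd.DataFrame,
    test: str | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    method: str = "mom",
) -> ReliabilityEstimate:
    """Percentile bootstrap CI for between-person reliability.

    Participants are resampled with replacement; each resample re-runs the
    variance partitioning and the reliability formula with its own n_eff.
    Resamples with an undefined reliability (all scores identical) are redrawn;
    the redraw count is recorded on the estimate.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = table if test is None else table[table["test"] == test]
    df = df.dropna(subset=["score"])
    vc = partition_variance(df, method=method)
    point = compute_reliability(vc, vc.n_eff)

    rng = np.random.default_rng(seed)
    participants = df["participant_id"].unique()
    a = len(participants)
    single = _split_half_moments(df)

    def batch(idx_matrix: np.ndarray) -> np.ndarray:
        out = np.empty(len(idx_matrix))
        if single is not None:
            wide = df.pivot_table(
                index="participant_id", columns="half", values="score", observed=True
            ).loc[participants]
            e_all = wide["even"].to_numpy(dtype=float)
            o_all = wide["odd"].to_numpy(dtype=float)
            for i, idx in enumerate(idx_matrix):
                e, o = e_all[idx], o_all[idx]
                cov = float(np.cov(e, o, ddof=1)[0, 1])
                total = float(np.sqrt(np.var(e, ddof=1) * np.var(o, ddof=1)))
                var_bp = max(cov, 0.0)
                var_wp = max(total - var_bp, 0.0)
                denom = var_bp + var_wp / 2.0
                out[i] = var_bp / denom if denom > 0 else np.nan
        else:
            st = _suff_stats(df)
            for i, idx in enumerate(idx_matrix):
                var_b, var_u, var_e = _mom_from_stats(st, idx)
                n_eff = st.n_obs[idx].sum() / len(idx)
                denom = var_b + (var_u + var_e) / n_eff
                out[i] = var_b / denom if denom > 0 else np.nan
        return out

    draws = batch(rng.integers(0, a, size=(n_boot, a)))
    n_redraws = 0
    while np.isnan(draws).any():
        bad = np.flatnonzero(np.isnan(draws))
        n_redraws += len(bad)
        if n_redraws > 100 * n_boot:
            raise RuntimeError("bootstrap cannot find resamples with defined reliability")
        draws[bad] = batch(rng.integers(0, a, size=(len(bad), a)))
    if n_redraws:
        logger.info("bootstrap redrew %d degenerate resample(s)", n_redraws)

    lo, hi = np.percentile(draws, [2.5, 97.5])
    return ReliabilityEstimate(
        test=test or "",
        value=point,
        ci_low=float(np.clip(lo, 0.0, 1.0)),
        ci_high=float(np.clip(hi, 0.0, 1.0)),
        n_boot=n_boot,
        seed=seed,
        components=vc,
        n_redraws=n_redraws,
    )


def reliability_by_schedule(
    table: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    method: str = "mom",
) -> pd.DataFrame:
    """Reliability per test for each schedule subset and pooled.

    ``table`` must carry a ``schedule`` column.  Subsets that cannot be
    estimated (e.g. a single participant) yield a missing cell with a warning.
    """
    if "schedule" not in table.columns:
        raise ValueError("table must carry a 'schedule' column (join sessions first)")
    rows = []
    tests = sorted(table["test"].unique())
    subsets = [(lab, table[table["schedule"] == lab]) for lab in sorted(table["schedule"].unique())]
    subsets.append(("pooled", table))
    for i, test in enumerate(tests):
        for j, (lab, sub) in enumerate(subsets):
            row = {
                "test": test,
                "schedule": lab,
                "reliability": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "var_bp": np.nan,
                "var_wp": np.nan,
                "n_eff": np.nan,
                "n_boot": n_boot,
                "seed": seed,
            }
            try:
                est = bootstrap_ci(
                    sub, test, n_boot=n_boot, seed=seed + 1000 * i + j, method=method
                )
                row.update(
                    reliability=est.value,
                    ci_low=est.ci_low,
                    ci_high=est.ci_high,
                    var_bp=est.components.var_bp,
                    var_wp=est.components.var_wp,
                    n_eff=est.components.n_eff,
                )
            except ValueError as exc:
                logger.warning("reliability for %s / %s unavailable: %s", test, lab, exc)
            rows.append(row)
    return pd.DataFrame(rows)
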