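"""Variance partitioning, the reliability formula, and the bootstrap."""

import numpy as np
import pandas as pd
import pytest

from glucema.reliability import (
    VarianceComponents,
    bootstrap_ci,
    compute_reliability,
    partition_variance,
    reliability_by_schedule,
)
from glucema.synthetic import simulate_half_scores


def hand_table(rows):
    return pd.DataFrame(rows, columns=["participant_id", "session_id", "half", "score"])


class TestPartitionVariance:
    def test_constant_per_participant(self):
        rows = []
        for pid, score in [("a", 1.0), ("b", 3.0), ("c", 8.0)]:
            for sid in ("s1", "s2"):
                for h in ("even", "odd"):
                    rows.append((pid, sid, h, score))
        vc = partition_variance(hand_table(rows))
        assert vc.var_wp == 0.0
        assert vc.var_bp == pytest.approx(np.var([1.0, 3.0, 8.0], ddof=1))

    def test_all_identical_degenerate(self):
        rows = [(p, s, h, 5.0) for p in "ab" for s in ("s1", "s2") for h in ("even", "odd")]
        vc = partition_variance(hand_table(rows))
        assert vc.var_bp == vc.var_wp == 0.0

    def test_single_participant_errors(self):
        rows = [("a", "s1", "even", 1.0), ("a", "s1", "odd", 2.0)]
        with pytest.raises(ValueError, match="2 participants"):
            partition_variance(hand_table(rows))

    def test_two_participants_single_session_hand_computed(self):
        vc = partition_variance(
            hand_table(
                [("a", "s", "even", 10.0), ("a", "s", "odd", 10.0),
                 ("b", "s", "even", 20.0), ("b", "s", "odd", 20.0)]
            )
        )
        # method-of-moments between-person estimate by hand: cov of the two
        # halves across participants = 50; zero within
        assert vc.var_wp == 0.0
        assert vc.var_bp == pytest.approx(50.0)

    def test_n_eff_is_mean_half_count(self):
        df = simulate_half_scores(10, 3, seed=0)
        assert partition_variance(df).n_eff == 6.0
        # unbalanced: drop one row
        vc = partition_variance(df.iloc[:-1])
        assert vc.n_eff == pytest.approx(59 / 10)

    def test_recovery_monte_carlo(self):
        """ANOVA estimates are unbiased: the Monte-Carlo mean over cohorts
        recovers (var_bp, var_wp) = (1.0, 0.5) within 15% relative error."""
        bps, wps = [], []
        for rep in range(10):
            df = simulate_half_scores(
                100, 15, sd_bp=1.0, sd_session=0.5, sd_resid=0.5, seed=300 + rep
            )
            vc = partition_variance(df)
            bps.append(vc.var_bp)
            wps.append(vc.var_wp)
        assert np.mean(bps) == pytest.approx(1.0, rel=0.15)
        assert np.mean(wps) == pytest.approx(0.5, rel=0.15)

    def test_mom_agrees_with_reml_on_balanced_data(self):
        df = simulate_half_scores(40, 5, sd_bp=1.0, sd_session=0.4, sd_resid=0.6, seed=9)
        mom = partition_variance(df, method="mom")
        reml = partition_variance(df, method="reml")
        assert mom.var_bp == pytest.approx(reml.var_bp, rel=1e-2)
        assert mom.var_session == pytest.approx(reml.var_session, rel=1e-2, abs=1e-3)
        assert mom.var_resid == pytest.approx(reml.var_resid, rel=1e-2)

    def test_negative_components_truncated(self):
        rng = np.random.default_rng(2)
        # pure noise => between-person estimate frequently negative pre-truncation
        smallest = 1.0
        for rep in range(20):
            df = simulate_half_scores(5, 3, sd_bp=0.0, sd_session=0.0, sd_resid=1.0,
                                      seed=500 + rep)
            vc = partition_variance(df)
            smallest = min(smallest, vc.var_bp, vc.var_session)
            assert vc.var_bp >= 0 and vc.var_session >= 0
        assert smallest == 0.0  # truncation actually engaged


class TestComputeReliability:
    def test_zero_within_gives_one(self):
        assert compute_reliability((2.0, 0.0), 5) == 1.0

    def test_equal_components_half_at_n1(self):
        assert compute_reliability((1.0, 1.0), 1) == 0.5

    def test_n60_closed_form(self):
        assert compute_reliability((1.0, 1.0), 60) == pytest.approx(60 / 61)

    def test_undefined_when_no_variance(self):
        assert np.isnan(compute_reliability((0.0, 0.0), 10))

    def test_strictly_increasing_in_n(self):
        vals = [compute_reliability((1.0, 2.0), n) for n in range(1, 61)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            bp, wp = rng.uniform(0, 10, 2)
            n = rng.integers(1, 61)
            assert 0.0 <= compute_reliability((bp, wp), int(n)) <= 1.0


class TestSpearmanBrown:
    """At n=2 on single-session data the variance-component reliability must
    equal the Spearman-Brown corrected split-half correlation exactly."""

    @pytest.mark.parametrize("seed", range(10))
    def test_equivalence(self, seed):
        df = simulate_half_scores(30, 1, mean=50, sd_bp=10, sd_session=0.0,
                                  sd_resid=5, seed=seed)
        vc = partition_variance(df)
        rel = compute_reliability(vc, 2)
        wide = df.pivot_table(index="participant_id", columns="half", values="score")
        r = np.corrcoef(wide["even"], wide["odd"])[0, 1]
        assert rel == pytest.approx(2 * r / (1 + r), abs=1e-8)


class TestBootstrap:
    def test_zero_within_ci_degenerate(self):
        rows = []
        for pid, score in [("a", 1.0), ("b", 3.0), ("c", 8.0), ("d", 2.0)]:
            for sid in ("s1", "s2"):
                for h in ("even", "odd"):
                    rows.append((pid, sid, h, score))
        est = bootstrap_ci(hand_table(rows), n_boot=200, seed=0)
        assert est.ci_low == est.ci_high == 1.0

    def test_n_boot_zero_errors(self):
        df = simulate_half_scores(10, 2, seed=0)
        with pytest.raises(ValueError):
            bootstrap_ci(df, n_boot=0, seed=0)

    def test_reproducible_from_seed(self):
        df = simulate_half_scores(20, 3, seed=4)
        a = bootstrap_ci(df, n_boot=300, seed=7)
        b = bootstrap_ci(df, n_boot=300, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        c = bootstrap_ci(df, n_boot=300, seed=8)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_ci_brackets_point_estimate_typically(self):
        df = simulate_half_scores(50, 5, sd_bp=1.0, seed=12)
        est = bootstrap_ci(df, n_boot=500, seed=0)
        assert est.ci_low <= est.value <= est.ci_high

    def test_coverage_smoke(self):
        """95% percentile CI covers the truth in most replications (a full
        200-replication calibration runs in the acceptance suite)."""
        true = 0.9
        cover = 0
        for rep in range(20):
            df = simulate_half_scores(
                100, 5, sd_bp=np.sqrt(0.9), sd_session=np.sqrt(0.5),
                sd_resid=np.sqrt(0.5), seed=7000 + rep,
            )
            est = bootstrap_ci(df, n_boot=300, seed=rep)
            cover += est.ci_low <= true <= est.ci_high
        assert cover >= 15


class TestBySchedule:
    def _table(self):
        frames = []
        for lab, n_sess in (("three_per_day", 4), ("six_per_day", 4)):
            df = simulate_half_scores(12, n_sess, mean=700, sd_bp=80,
                                      sd_session=30, sd_resid=20,
                                      seed=hash(lab) % 1000, test="choice_rt")
            df["schedule"] = lab
            df["session_id"] = lab + "_" + df["session_id"]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_three_cells_per_test(self):
        out = reliability_by_schedule(self._table(), n_boot=100, seed=0)
        assert set(out["schedule"]) == {"three_per_day", "six_per_day", "pooled"}
        assert out["reliability"].notna().all()

    def test_pooled_n_eff_is_sum_of_phases(self):
        out = reliability_by_schedule(self._table(), n_boot=50, seed=0)
        by = out.set_index("schedule")["n_eff"]
        assert by["pooled"] == pytest.approx(
            by["three_per_day"] + by["six_per_day"]
        )

    def test_design_maximum_sixty_halves(self):
        # complete crossover: 30 administrations x 2 halves = 60 per test,
        # 15 x 2 = 30 within each phase
        frames = []
        for lab in ("three_per_day", "six_per_day"):
            df = simulate_half_scores(5, 15, mean=700, sd_bp=80, seed=1,
                                      test="choice_rt")
            df["schedule"] = lab
            df["session_id"] = lab + "_" + df["session_id"]
            frames.append(df)
        out = reliability_by_schedule(pd.concat(frames, ignore_index=True),
                                      n_boot=50, seed=0).set_index("schedule")
        assert out.loc["three_per_day", "n_eff"] == 30.0
        assert out.loc["pooled", "n_eff"] == 60.0

    def test_single_participant_subset_missing_with_warning(self, caplog):
        table = self._table()
        table = table[
            (table["schedule"] == "three_per_day") | (table["participant_id"] == "P000")
        ]
        with caplog.at_level("WARNING"):
            out = reliability_by_schedule(table, n_boot=50, seed=0)
        cell = out[(out["schedule"] == "six_per_day")]
        assert cell["reliability"].isna().all()
        assert "unavailable" in caplog.text

    def test_ema_design_effect(self):
        """Repeated measurement (30 sessions) must yield higher estimated
        reliability than a single session (n=2) from the same parameters."""
        burst = simulate_half_scores(30, 30, sd_bp=1.0, sd_session=0.7,
                                     sd_resid=0.7, seed=21)
        single = simulate_half_scores(30, 1, sd_bp=1.0, sd_session=0.7,
                                      sd_resid=0.7, seed=21)
        vc_b = partition_variance(burst)
        vc_s = partition_variance(single)
        rel_burst = compute_reliability(vc_b, vc_b.n_eff)
        rel_single = compute_reliability(vc_s, 2)
        assert rel_burst > rel_single
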