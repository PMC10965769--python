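"""Capacity estimation, discriminability, exclusions, and set-size contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acuitywm import change_detection as cd
from acuitywm.observers import ChangeObserver, make_change_schedule, simulate_change_responses


def trials_from_counts(n_change, n_hits, n_nochange, n_fas, subject="s", set_size=5):
    rows = []
    for i in range(n_change):
        rows.append((subject, set_size, True, "different" if i < n_hits else "same"))
    for i in range(n_nochange):
        rows.append((subject, set_size, True if False else False, "different" if i < n_fas else "same"))
    df = pd.DataFrame(rows, columns=["subject", "set_size", "is_change", "response"])
    df["correct"] = (df["response"] == "different") == df["is_change"]
    return df


class TestTallyRates:
    def test_hand_ratio(self):
        df = trials_from_counts(135, 120, 135, 10)
        t = cd.tally_rates(df, "s", 5)
        assert t.hit_rate == pytest.approx(120 / 135)
        assert t.hit_rate == pytest.approx(0.8889, abs=5e-5)
        assert t.fa_rate == pytest.approx(10 / 135)

    def test_all_same_responses(self):
        df = trials_from_counts(10, 0, 10, 0)
        t = cd.tally_rates(df)
        assert t.hit_rate == 0.0 and t.fa_rate == 0.0

    def test_accuracy_brute_force(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "subject": "s",
                "set_size": 3,
                "is_change": rng.random(500) < 0.5,
                "response": rng.choice(["same", "different"], 500),
            }
        )
        t = cd.tally_rates(df)
        # exhaustive count, independent of the implementation's vector path
        n_correct = sum(
            (r.response == "different") == r.is_change for r in df.itertuples()
        )
        assert t.accuracy == pytest.approx(n_correct / 500)
        assert t.n_change + t.n_nochange == 500

    def test_empty_cell_rejected(self):
        df = trials_from_counts(10, 5, 0, 0)
        with pytest.raises(ValueError):
            cd.tally_rates(df)


class TestPashlerK:
    def test_perfect_memory(self):
        assert cd.pashler_k(5, 1.0, 0.0) == 5.0

    def test_no_signal(self):
        assert cd.pashler_k(3, 0.7, 0.7) == 0.0

    def test_hand_arithmetic(self):
        assert cd.pashler_k(5, 0.9, 0.1) == pytest.approx(5 * 0.8 / 0.9)
        assert cd.pashler_k(5, 0.9, 0.1) == pytest.approx(4.4444, abs=5e-5)

    def test_undefined_at_unit_false_alarms(self):
        assert np.isnan(cd.pashler_k(5, 1.0, 1.0))

    def test_clamping_keeps_raw_available(self):
        assert cd.pashler_k(2, 0.5, 0.9) == 0.0
        assert cd.pashler_k(2, 0.5, 0.9, clamp=False) < 0.0

    @given(
        h=st.floats(0.01, 0.99), f=st.floats(0.0, 0.98), dh=st.floats(0.001, 0.01)
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_monotone_in_rates(self, h, f, dh):
        if not f < h < 0.99 - dh:
            return
        n = 5
        assert cd.pashler_k(n, h + dh, f, clamp=False) >= cd.pashler_k(n, h, f, clamp=False)
        if f + dh < h:
            assert cd.pashler_k(n, h, f + dh, clamp=False) <= cd.pashler_k(n, h, f, clamp=False)


class TestDprime:
    def test_inverse_normal_oracle(self):
        assert cd.dprime(0.9, 0.1, 100, 100) == pytest.approx(2.5631031310892007)

    def test_zero_at_equal_rates(self):
        assert cd.dprime(0.5, 0.5, 50, 50) == 0.0

    def test_antisymmetry(self):
        assert cd.dprime(0.8, 0.2, 60, 60) == pytest.approx(-cd.dprime(0.2, 0.8, 60, 60))

    def test_extreme_rate_correction(self):
        # h = 1 becomes 1 - 1/(2n); the result must stay finite
        v = cd.dprime(1.0, 0.0, 135, 135)
        assert np.isfinite(v) and v > 0

    def test_exhaustive_small_cells_match_brute_force(self):
        # independent oracle: statistics.NormalDist (not scipy) over every
        # possible (hits, fas) cell at n=4
        from statistics import NormalDist

        inv = NormalDist().inv_cdf
        n = 4
        for hits in range(n + 1):
            for fas in range(n + 1):
                h, f = hits / n, fas / n
                hc = min(max(h, 1 / (2 * n)), 1 - 1 / (2 * n))
                fc = min(max(f, 1 / (2 * n)), 1 - 1 / (2 * n))
                expected = inv(hc) - inv(fc)
                assert cd.dprime(h, f, n, n) == pytest.approx(expected, rel=1e-9)

    def test_dprime_decreases_with_set_size_for_fixed_capacity(self):
        # sub-capacity observer (k < smallest set-size would be at ceiling
        # everywhere; k = 1.8 keeps hit rates off the ceiling at every N)
        obs = ChangeObserver("s", k_true=1.8, guess_rate=0.3)
        sched = make_change_schedule(27, 30, (2, 3, 5), seed=21)
        trials = simulate_change_responses(obs, sched, seed=22)
        est = cd.estimate_capacity(trials).sort_values("set_size")
        d = est["dprime"].to_numpy()
        assert d[0] > d[1] > d[2]


class TestMaxK:
    @staticmethod
    def _estimates(ks, subject="s"):
        return pd.DataFrame(
            {"subject": subject, "set_size": [2, 3, 5], "k": list(ks)}
        )

    def test_monotone_profile(self):
        out = cd.max_k(self._estimates([1.9, 2.8, 4.4]))
        assert out.loc[0, "k_max"] == 4.4
        assert out.loc[0, "set_size_at_max"] == 5
        assert not out.loc[0, "peaked_before_largest"]

    def test_early_peak_flagged(self):
        out = cd.max_k(self._estimates([2.0, 3.0, 2.5]))
        assert out.loc[0, "k_max"] == 2.5
        assert out.loc[0, "peaked_before_largest"]

    def test_sort_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ks = rng.uniform(0, 5, 3)
            out = cd.max_k(self._estimates(ks))
            assert bool(out.loc[0, "peaked_before_largest"]) == (sorted(ks)[-1] > ks[-1])

    def test_single_set_size_rejected(self):
        df = pd.DataFrame({"subject": "s", "set_size": [5], "k": [3.0]})
        with pytest.raises(ValueError):
            cd.max_k(df)


class TestExclusions:
    @staticmethod
    def _accuracy_trials(subject, n_correct, n_total=100):
        return pd.DataFrame(
            {
                "subject": subject,
                "correct": [True] * n_correct + [False] * (n_total - n_correct),
            }
        )

    def test_strict_threshold_boundary(self):
        df = pd.concat(
            [self._accuracy_trials("low", 59), self._accuracy_trials("edge", 60),
             self._accuracy_trials("high", 90)]
        )
        retained, log = cd.exclude_low_accuracy(df)
        assert retained == ["edge", "high"]
        assert list(log["subject"]) == ["low"]

    def test_zero_capacity_observer_excluded(self):
        obs = ChangeObserver("guesser", k_true=0.0, guess_rate=0.5)
        sched = make_change_schedule(seed=31)
        trials = simulate_change_responses(obs, sched, seed=32)
        retained, log = cd.exclude_low_accuracy(trials)
        assert retained == [] and list(log["subject"]) == ["guesser"]


class TestValidityMatrix:
    @staticmethod
    def _estimates(cols):
        frames = []
        for ss, vals in cols.items():
            frames.append(pd.DataFrame({
                "subject": [f"s{i}" for i in range(len(vals))],
                "set_size": ss, "k": vals,
            }))
        return pd.concat(frames, ignore_index=True)

    def test_identical_columns(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        m = cd.validity_matrix(self._estimates({2: vals, 3: vals, 5: vals}))
        assert np.allclose(m.to_numpy(), 1.0)

    def test_anticorrelated_columns(self):
        m = cd.validity_matrix(self._estimates({2: [1, 2, 3], 5: [3, 2, 1]}))
        assert m.loc[2, 5] == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(8)
        m = cd.validity_matrix(
            self._estimates({2: rng.normal(size=10_000), 5: rng.normal(size=10_000)})
        )
        assert abs(m.loc[2, 5]) < 0.03

    def test_symmetry_and_unit_diagonal(self, small_cohort_trials):
        est = cd.estimate_capacity(small_cohort_trials["change"])
        m = cd.validity_matrix(est)
        assert np.allclose(m.to_numpy(), m.to_numpy().T)
        assert np.allclose(np.diag(m.to_numpy()), 1.0)


class TestSetsizeContrasts:
    @staticmethod
    def _estimates(cols, n=12, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        base = rng.normal(0, 1, n)
        for ss, shift in cols.items():
            frames.append(pd.DataFrame({
                "subject": [f"s{i}" for i in range(n)],
                "set_size": ss,
                "accuracy": base + shift + rng.normal(0, 0.3, n),
            }))
        return pd.concat(frames, ignore_index=True)

    def test_identical_columns_give_zero_f(self):
        df = self._estimates({2: 0.0, 3: 0.0, 5: 0.0}, seed=1)
        wide = df.pivot(index="subject", columns="set_size", values="accuracy")
        df = pd.concat(
            [wide[2].rename("accuracy").reset_index().assign(set_size=s) for s in (2, 3, 5)],
            ignore_index=True,
        )
        out = cd.setsize_contrasts(df, "accuracy")
        assert out["anova"]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_two_conditions_f_equals_t_squared(self):
        from scipy import stats

        df = self._estimates({2: 0.0, 5: 0.6}, seed=2)
        out = cd.setsize_contrasts(df, "accuracy")
        wide = df.pivot(index="subject", columns="set_size", values="accuracy")
        t, p = stats.ttest_rel(wide[2], wide[5])
        assert out["anova"]["F"] == pytest.approx(t**2)
        assert out["anova"]["p"] == pytest.approx(p)

    def test_matches_pingouin_rm_anova(self):
        import pingouin as pg

        df = self._estimates({2: 0.0, 3: 0.3, 5: 0.8}, seed=3)
        out = cd.setsize_contrasts(df, "accuracy")
        ref = pg.rm_anova(
            data=df, dv="accuracy", within="set_size", subject="subject", effsize="np2"
        )
        assert out["anova"]["F"] == pytest.approx(float(ref["F"][0]))
        assert out["anova"]["p"] == pytest.approx(float(ref["p_unc"][0]))
        assert out["anova"]["partial_eta_sq"] == pytest.approx(float(ref["np2"][0]))
        assert out["anova"]["df1"] == int(ref["ddof1"][0])
        assert out["anova"]["df2"] == int(ref["ddof2"][0])

    def test_bh_adjustment_matches_step_up_oracle(self):
        from statsmodels.stats.multitest import multipletests

        def bh_oracle(pvals):
            m = len(pvals)
            order = np.argsort(pvals)
            adj = np.empty(m)
            prev = 1.0
            for rank_from_top, idx in enumerate(order[::-1]):
                rank = m - rank_from_top
                prev = min(prev, pvals[idx] * m / rank)
                adj[idx] = prev
            return adj

        cases = [
            np.array([0.01, 0.02, 0.04]),
            np.array([0.001, 0.5, 0.04]),
            np.array([0.9, 0.8, 0.7]),
            np.array([0.03, 0.03, 0.03]),
        ]
        for p in cases:
            np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1], bh_oracle(p))
        # the canonical worked example
        np.testing.assert_allclose(bh_oracle(np.array([0.01, 0.02, 0.04])), [0.03, 0.03, 0.04])

    def test_incomplete_design_rejected(self):
        df = self._estimates({2: 0.0, 5: 0.5}, seed=4).iloc[:-1]
        with pytest.raises(ValueError):
            cd.setsize_contrasts(df, "accuracy")


class TestParameterRecoverySmall:
    def test_k_recovery_single_observer(self):
        obs = ChangeObserver("s", k_true=3.2, guess_rate=0.5)
        sched = make_change_schedule(seed=41)
        trials = simulate_change_responses(obs, sched, seed=42)
        est = cd.estimate_capacity(trials)
        k5 = float(est.loc[est["set_size"] == 5, "k"].iloc[0])
        assert k5 == pytest.approx(3.2, abs=1.0)
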