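"""Within-subject inference: permutation t-test, BH-FDR, Cohen's d, JZS BF."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from leida import (
    analyze_cohort,
    bh_fdr,
    cohens_d_paired,
    jzs_bayes_factor_from_t,
    jzs_bayes_factor_paired,
    paired_permutation_ttest,
)


def exhaustive_signflip_p(diffs):
    """Full 2^n sign-flip enumeration oracle for the two-sided paired t."""
    n = diffs.size
    t_obs = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(n))
    stats = []
    for signs in itertools.product((-1.0, 1.0), repeat=n):
        d = np.array(signs) * diffs
        sd = d.std(ddof=1)
        stats.append(np.inf if sd == 0 else d.mean() / (sd / np.sqrt(n)))
    stats = np.abs(stats)
    return t_obs, float(np.mean(stats >= abs(t_obs) - 1e-12))


class TestPairedPermutation:
    def test_identical_sessions_give_p_one(self):
        x = np.arange(8.0)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            t, p = paired_permutation_ttest(x, x, n_perm=100, seed=0)
        assert np.isnan(t)
        assert p == 1.0

    def test_matches_exhaustive_enumeration_at_n10(self, rng):
        for trial in range(3):
            diffs = rng.normal(0.3, 1.0, 10)
            t_ref, p_exact = exhaustive_signflip_p(diffs)
            t, p = paired_permutation_ttest(
                np.zeros(10), diffs, n_perm=5000, seed=100 + trial
            )
            assert t == pytest.approx(t_ref)
            se = np.sqrt(p_exact * (1 - p_exact) / 5000)
            assert abs(p - p_exact) <= 3 * se + 1e-4

    def test_agrees_with_parametric_t_for_gaussian_differences(self, rng):
        for trial in range(5):
            base = rng.normal(0, 1, 30)
            follow = base + rng.normal(0.3, 1, 30)
            _, p_perm = paired_permutation_ttest(base, follow, n_perm=5000, seed=trial)
            p_param = sp_stats.ttest_rel(follow, base).pvalue
            assert abs(p_perm - p_param) < 0.02

    def test_p_never_zero(self, rng):
        base = np.zeros(6)
        follow = np.arange(1.0, 7.0)  # overwhelming effect
        _, p = paired_permutation_ttest(base, follow, n_perm=200, seed=0)
        assert 0 < p <= 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_permutation_ttest(np.zeros(5), np.zeros(6))


class TestBhFdr:
    def test_hand_computed_step_up(self):
        adjusted = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.2])) == pytest.approx([0.2])

    def test_all_ones_stay_one(self):
        assert bh_fdr(np.ones(5)) == pytest.approx(np.ones(5))

    def test_adjusted_not_below_raw(self, rng):
        p = rng.uniform(0.001, 1.0, 40)
        assert np.all(bh_fdr(p) >= p - 1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan, 0.2]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(np.array(bad))


class TestCohensD:
    def test_hand_computed_example(self):
        # diffs (2, 4, 6): mean 4, sd 2 -> d = 2
        assert cohens_d_paired(np.zeros(3), np.array([2.0, 4.0, 6.0])) == pytest.approx(2.0)

    def test_zero_mean_difference_gives_zero(self):
        d = cohens_d_paired(np.zeros(4), np.array([1.0, -1.0, 1.0, -1.0]))
        assert d == pytest.approx(0.0)

    def test_zero_variance_flagged(self):
        with pytest.warns(RuntimeWarning):
            d = cohens_d_paired(np.zeros(4), np.ones(4))
        assert np.isnan(d)


class TestJzsBayesFactor:
    def dense_quadrature_oracle(self, t, n, direction="two_sided", r=1 / np.sqrt(2)):
        """Independent trapezoid quadrature via the Cauchy substitution
        delta = r tan(u), so the improper integral becomes a proper one."""
        df = n - 1
        u = np.linspace(-np.pi / 2 + 1e-9, np.pi / 2 - 1e-9, 200_001)
        if direction == "greater":
            u = u[u >= 0]
        elif direction == "less":
            u = u[u <= 0]
        delta = r * np.tan(u)
        # nct.pdf overflows to nan at extreme noncentrality, where the true
        # integrand is 0
        integrand = np.nan_to_num(sp_stats.nct.pdf(t, df, delta * np.sqrt(n))) / np.pi
        numerator = np.trapezoid(integrand, u)
        if direction != "two_sided":
            numerator *= 2
        return numerator / sp_stats.t.pdf(t, df)

    def test_matches_quadrature_oracle_at_t_zero(self):
        bf = jzs_bayes_factor_from_t(0.0, 20)
        assert bf < 1
        assert bf == pytest.approx(self.dense_quadrature_oracle(0.0, 20), abs=1e-6)

    @pytest.mark.parametrize("t,n", [(2.91, 11), (-1.4, 17), (3.5, 25)])
    def test_matches_quadrature_oracle(self, t, n):
        bf = jzs_bayes_factor_from_t(t, n)
        assert bf == pytest.approx(self.dense_quadrature_oracle(t, n), rel=1e-5)

    @pytest.mark.parametrize("direction", ["greater", "less"])
    def test_one_sided_matches_oracle(self, direction):
        bf = jzs_bayes_factor_from_t(1.8, 14, direction)
        assert bf == pytest.approx(
            self.dense_quadrature_oracle(1.8, 14, direction), rel=1e-5
        )

    def test_matches_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n in [(2.44, 11), (0.96, 17), (3.14, 11)]:
            ref = float(pingouin.bayesfactor_ttest(t, nx=n, paired=True, r=1 / np.sqrt(2)))
            assert jzs_bayes_factor_from_t(t, n) == pytest.approx(ref, rel=1e-8)

    def test_null_data_favour_the_null(self, rng):
        base = rng.normal(0, 1, 20)
        follow = base + rng.normal(0, 0.01, 20)
        assert jzs_bayes_factor_paired(base, follow) < 1

    def test_aligned_one_sided_beats_two_sided(self):
        assert jzs_bayes_factor_from_t(2.0, 12, "greater") > jzs_bayes_factor_from_t(
            2.0, 12, "two_sided"
        )

    def test_direction_concordance(self, rng):
        """The one-sided BF matching the sign of t always dominates, and the
        aligned BF grows monotonically with the evidence."""
        for _ in range(50):
            t = rng.uniform(-4, 4)
            n = int(rng.integers(5, 30))
            greater = jzs_bayes_factor_from_t(t, n, "greater")
            less = jzs_bayes_factor_from_t(t, n, "less")
            if t > 0:
                assert greater > less
            elif t < 0:
                assert less > greater
        bfs = [jzs_bayes_factor_from_t(t, 15, "greater") for t in (0.5, 1.5, 2.5, 3.5)]
        assert np.all(np.diff(bfs) > 0)


def _metrics_frame(rng, n_subjects=8, k=3, effect_state=None, effect=0.0):
    rows = []
    for i in range(n_subjects):
        for session in ("baseline", "follow_up"):
            occ = rng.dirichlet(np.ones(k) * 5)
            for s in range(1, k + 1):
                value = occ[s - 1]
                if session == "follow_up" and s == effect_state:
                    value += effect
                rows.append(
                    {
                        "subject_id": f"s{i}",
                        "session": session,
                        "k": k,
                        "state": s,
                        "fractional_occupancy": value,
                        "lifetime": rng.gamma(4, 2),
                        "decoupling": rng.uniform(20, 120),
                    }
                )
    return pd.DataFrame(rows)


class TestAnalyzeCohort:
    def test_result_contract(self, rng):
        table = analyze_cohort(
            _metrics_frame(rng), n_perm=500, seed=1, bayes=True
        )
        assert len(table) == 9  # 3 states x 3 metrics
        assert np.all(table["p_fdr"] >= table["p_perm"] - 1e-12)
        assert np.all(table["df"] == table["n_pairs"] - 1)
        assert np.all((table["p_perm"] > 0) & (table["p_perm"] <= 1))

    def test_planted_effect_found(self, rng):
        frame = _metrics_frame(rng, n_subjects=12, effect_state=2, effect=0.15)
        table = analyze_cohort(frame, n_perm=1000, seed=2, bayes=False)
        occ = table[table.metric == "fractional_occupancy"].set_index("state")
        assert occ.loc[2, "p_perm"] == occ["p_perm"].min()
        assert occ.loc[2, "cohens_d"] > 0

    def test_unpaired_subject_named_in_error(self, rng):
        frame = _metrics_frame(rng)
        frame = frame[
            ~((frame.subject_id == "s3") & (frame.session == "follow_up"))
        ]
        with pytest.raises(ValueError, match="s3"):
            analyze_cohort(frame, n_perm=100, seed=0, bayes=False)

    def test_label_permutation_invariance(self, rng):
        """Relabelling states consistently permutes rows but not numbers."""
        frame = _metrics_frame(rng, effect_state=1, effect=0.1)
        table = analyze_cohort(frame, n_perm=500, seed=3, bayes=False)
        perm = {1: 3, 2: 1, 3: 2}
        shuffled = frame.assign(state=frame.state.map(perm))
        table_perm = analyze_cohort(shuffled, n_perm=500, seed=3, bayes=False)
        for metric in ("fractional_occupancy", "lifetime"):
            a = table[table.metric == metric].set_index("state")["t_obs"]
            b = table_perm[table_perm.metric == metric].set_index("state")["t_obs"]
            for old, new in perm.items():
                assert a.loc[old] == pytest.approx(b.loc[new])

    def test_nan_metric_states_excluded(self, rng):
        frame = _metrics_frame(rng)
        frame.loc[frame.state == 1, "decoupling"] = np.nan
        table = analyze_cohort(frame, n_perm=200, seed=4, bayes=False)
        dec = table[table.metric == "decoupling"]
        assert set(dec["state"]) == {2, 3}
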