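"""Rhythm calling: ANOVA oracle checks and JTK_CYCLE vs exhaustive enumeration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circaprot import rhythm as R
from circaprot.simulate import make_design, simulate_abundance
from conftest import matrix_from_raw


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_S(x, ranks):
    s = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        if ranks[i] == ranks[j]:
            continue
        s += int(np.sign(x[j] - x[i]) * np.sign(ranks[j] - ranks[i]))
    return s


def brute_null_pmf(tie_sizes):
    """Exhaustive-permutation pmf of S for one reference tie structure."""
    n = sum(tie_sizes)
    ranks = np.repeat(np.arange(len(tie_sizes)), tie_sizes)
    perms = np.array(list(itertools.permutations(range(1, n + 1))))
    pairs = [(i, j) for i, j in itertools.combinations(range(n), 2)
             if ranks[i] != ranks[j]]
    S = np.zeros(len(perms), dtype=int)
    for i, j in pairs:
        S += np.sign(perms[:, j] - perms[:, i]) * int(np.sign(ranks[j] - ranks[i]))
    vals, counts = np.unique(S, return_counts=True)
    return dict(zip(vals.tolist(), (counts / len(perms)).tolist()))


def brute_jtk_p(x, timepoints, period=24.0, lag_step=2.0):
    """min-over-lags exhaustive-tail p with the same Bonferroni factor."""
    lags = np.arange(0, period, lag_step)
    keys = set()
    best = np.inf
    pmf_cache = {}
    for lag in lags:
        ranks = R.jtk_reference(timepoints, lag, period)
        rev = tuple(int(ranks.max()) + 1 - ranks)
        keys.add(min(tuple(int(v) for v in ranks), rev))
        _, counts = np.unique(ranks, return_counts=True)
        tie = tuple(sorted(counts))
        if tie not in pmf_cache:
            pmf_cache[tie] = brute_null_pmf(tie)
        pmf = pmf_cache[tie]
        s = brute_S(x, ranks)
        p = sum(pr for v, pr in pmf.items() if abs(v) >= abs(s)) if s != 0 else 1.0
        best = min(best, p)
    return min(1.0, best * len(keys))


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

class TestAnova:
    def _matrix(self, X, meta):
        raw = pd.DataFrame(np.sinh(X), index=[f"P{i}" for i in range(len(X))],
                           columns=meta.index)
        return matrix_from_raw(raw, meta)

    def test_identical_constants_excluded_as_degenerate(self, default_meta):
        X = np.full((1, len(default_meta)), 3.0)
        m = self._matrix(X, default_meta)
        res = R.anova_by_zt(m.values, m.detected, m.zt)
        assert np.isnan(res["anova_p"].iloc[0])
        assert "degenerate" in res["anova_reason"].iloc[0]

    def test_planted_groups_match_scipy_f_oneway(self, default_meta):
        rng = np.random.default_rng(3)
        zt = default_meta["zt"].to_numpy()
        X = rng.normal(8, 1, (20, len(default_meta)))
        X[:10] += 2.0 * np.cos(2 * np.pi * zt / 24)[None, :]
        m = self._matrix(X, default_meta)
        res = R.anova_by_zt(m.values, m.detected, m.zt)
        bins = sorted(default_meta["zt"].unique())
        for i in range(20):
            groups = [m.values.iloc[i][default_meta["zt"] == b].to_numpy() for b in bins]
            _, p_ref = stats.f_oneway(*groups)
            assert res["anova_p"].iloc[i] == pytest.approx(p_ref, rel=1e-9)
        assert (res["anova_p"].iloc[:10] < 0.1).all()

    def test_zero_within_variance_significant(self, default_meta):
        zt = default_meta["zt"].to_numpy()
        X = 5.0 + np.cos(2 * np.pi * zt / 24)[None, :]  # replicates identical per bin
        m = self._matrix(X, default_meta)
        res = R.anova_by_zt(m.values, m.detected, m.zt)
        assert res["anova_p"].iloc[0] == 0.0

    def test_missing_bin_makes_protein_ineligible(self, default_meta):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 1, (1, len(default_meta)))
        m = self._matrix(X, default_meta)
        cols = default_meta.index[default_meta["zt"] == 8]
        m.detected.loc[:, cols] = False
        res = R.anova_by_zt(m.values, m.detected, m.zt)
        assert np.isnan(res["anova_p"].iloc[0])
        assert "replicates per bin" in res["anova_reason"].iloc[0]


# ---------------------------------------------------------------------------
# JTK reference and statistic
# ---------------------------------------------------------------------------

class TestReference:
    def test_lag_timepoint_holds_top_rank(self):
        t = [0, 4, 8, 12, 16, 20]
        ranks = R.jtk_reference(t, 8.0)
        assert ranks[2] == ranks.max()

    def test_periodicity(self):
        t = np.arange(0, 24, 2)
        np.testing.assert_array_equal(R.jtk_reference(t, 6.0),
                                      R.jtk_reference(t, 30.0))

    def test_replicate_tie_multiplicities(self):
        t = np.repeat([0, 4, 8, 12, 16, 20], 5)
        ranks = R.jtk_reference(t, 2.0)
        _, counts = np.unique(ranks, return_counts=True)
        assert (counts % 5 == 0).all() and counts.sum() == 30


class TestStatistic:
    def test_series_equal_reference_is_maximal(self):
        ranks = R.jtk_reference([0, 4, 8, 12, 16, 20], 0.0)
        s = R.jtk_statistic(ranks.astype(float), ranks)
        n_untied = sum(1 for i, j in itertools.combinations(range(len(ranks)), 2)
                       if ranks[i] != ranks[j])
        assert s == n_untied

    def test_reversal_antisymmetry(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=8)
        ranks = R.jtk_reference(np.arange(8) * 3.0, 6.0)
        assert R.jtk_statistic(x, ranks) == -R.jtk_statistic(-x, ranks)

    def test_matches_brute_force_pair_count(self):
        rng = np.random.default_rng(9)
        ranks = np.array([1, 1, 2, 2, 3, 3, 4, 4])
        for _ in range(20):
            x = rng.normal(size=8)
            assert R.jtk_statistic(x, ranks) == brute_S(x, ranks)


# ---------------------------------------------------------------------------
# exact null
# ---------------------------------------------------------------------------

class TestNull:
    def test_n3_exact_enumeration(self):
        null = R.jtk_null((1, 1, 1))
        np.testing.assert_allclose(null.pmf, [1 / 6, 2 / 6, 2 / 6, 1 / 6])
        np.testing.assert_array_equal(null.s_values, [-3, -1, 1, 3])

    @pytest.mark.parametrize("ties", [(2, 2, 2, 2), (3, 2, 1), (1, 1, 2, 2), (4, 4)])
    def test_matches_exhaustive_permutations(self, ties):
        null = R.jtk_null(ties)
        brute = brute_null_pmf(ties)
        for s, p in zip(null.s_values, null.pmf):
            assert p == pytest.approx(brute.get(int(s), 0.0), abs=1e-12)

    @pytest.mark.parametrize("ties", [(5, 5, 5), (1, 2, 3, 4), (2, 2, 2, 2, 2)])
    def test_symmetry_and_unit_mass(self, ties):
        null = R.jtk_null(ties)
        assert null.pmf.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(null.pmf, null.pmf[::-1])

    def test_normal_approximation_beyond_limit(self):
        exact = R.jtk_null((4, 4, 4), exact_limit=60)
        approx = R.jtk_null((4, 4, 4), exact_limit=10)
        assert not approx.exact
        for s in [10, 20, 30, 40]:
            assert approx.sf_abs(s) == pytest.approx(exact.sf_abs(s), abs=0.02)


# ---------------------------------------------------------------------------
# jtk_cycle
# ---------------------------------------------------------------------------

class TestJtkCycle:
    def test_noise_free_cosine_recovers_phase_18(self, default_meta):
        t = default_meta["zt"].to_numpy()
        x = 100 * (1 + 0.5 * np.cos(2 * np.pi * (t - 18) / 24))
        res = R.jtk_cycle(x, t)
        assert res.phase_zt == 18.0
        assert res.jtk_p < 0.1
        assert res.tau == 1.0

    def test_constant_series(self, default_meta):
        t = default_meta["zt"].to_numpy()
        res = R.jtk_cycle(np.ones(len(t)), t)
        assert res.jtk_p == 1.0
        assert np.isnan(res.phase_zt)

    def test_matches_exhaustive_oracle_small_series(self):
        """Eight observations, four timepoints: package p equals the
        exhaustive-permutation min-over-lags-with-Bonferroni oracle."""
        t = np.repeat([0.0, 6.0, 12.0, 18.0], 2)
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=8)
            got = R.jtk_cycle(x, t).jtk_p
            assert got == pytest.approx(brute_jtk_p(x, t), abs=1e-10)

    def test_monotone_transform_invariance(self, default_meta):
        t = default_meta["zt"].to_numpy()
        rng = np.random.default_rng(8)
        x = np.exp(rng.normal(3, 1, len(t)))
        a = R.jtk_cycle(x, t)
        b = R.jtk_cycle(np.log(x), t)
        c = R.jtk_cycle(x ** 3, t)
        assert a.jtk_p == b.jtk_p == c.jtk_p
        assert (a.phase_zt == b.phase_zt == c.phase_zt) or all(
            np.isnan(v.phase_zt) for v in (a, b, c))

    def test_nan_measurements_dropped(self, default_meta):
        t = default_meta["zt"].to_numpy()
        x = 100 * (1 + 0.5 * np.cos(2 * np.pi * (t - 6) / 24))
        x_nan = x.copy()
        x_nan[::7] = np.nan
        res = R.jtk_cycle(x_nan, t)
        ref = R.jtk_cycle(x[np.isfinite(x_nan)], t[np.isfinite(x_nan)])
        assert res.jtk_p == ref.jtk_p and res.phase_zt == ref.phase_zt


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

class TestCalling:
    def test_alpha_threshold(self):
        df = pd.DataFrame({"jtk_p": [0.01, 0.05, 0.2]}, index=["a", "b", "c"])
        out = R.call_rhythmic(df, alpha_jtk=0.1)
        assert out["rhythmic"].sum() == 2

    def test_bh_step_up_hand_computed(self):
        df = pd.DataFrame({"jtk_p": [0.01, 0.02, 0.03, 0.9]})
        out = R.call_rhythmic(df)
        np.testing.assert_allclose(out["q_value"], [0.04, 0.04, 0.04, 0.9])

    def test_empty_input(self):
        out = R.call_rhythmic(pd.DataFrame({"jtk_p": []}))
        assert out.empty

    def test_realized_fdr_within_bh_level(self, default_design):
        """Planted 20% rhythmic at high amplitude: calling at q < 0.2 keeps
        the realized false discovery proportion near or below the level."""
        raw, truth = simulate_abundance(default_design, n_proteins=400,
                                        frac_rhythmic=0.2, noise_sd=0.25,
                                        dropout_params=None,
                                        amplitude_range=(0.4, 0.8), seed=23)
        m = matrix_from_raw(raw, default_design.sample_meta())
        res, _ = R.rhythm_analysis(m, min_peptides_per_sample=None)
        called = res.index[res["q_value"] < 0.2]
        planted = truth.index[truth["is_rhythmic"]]
        assert len(called) > 20
        fdp = len(set(called) - set(planted)) / len(called)
        assert fdp <= 0.25
        sens = len(set(called) & set(planted)) / truth["is_rhythmic"].sum()
        assert sens > 0.5
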