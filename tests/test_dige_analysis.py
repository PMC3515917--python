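"""DIGE normalization, Welch tests, Westfall-Young maxT, headline filter."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from naevus_omics import (
    SpotTable,
    analyze_spots,
    normalize_across_gels,
    normalize_within_gel,
    presence_filter,
    select_top_proteins,
    spot_log_ratios,
    welch_ttest,
    westfall_young_stepdown,
)
from naevus_omics.synthetic_data import gen_spot_table


def make_table(volumes, present=None, dye_swap=None) -> SpotTable:
    volumes = np.asarray(volumes, dtype=float)
    S, G, _ = volumes.shape
    if present is None:
        present = np.ones((S, G), dtype=bool)
    volumes = volumes.copy()
    volumes[~np.repeat(np.asarray(present)[:, :, None], 2, axis=2)] = np.nan
    if dye_swap is None:
        dye_swap = np.zeros(G, dtype=bool)
    return SpotTable(
        spot_ids=[f"s{i}" for i in range(S)],
        gel_set_ids=[f"g{j}" for j in range(G)],
        volumes=volumes,
        present=present,
        dye_swap=dye_swap,
    )


class TestNormalizeWithinGel:
    def test_worked_example(self):
        vols = np.array([[[1.0, 1.0]], [[2.0, 2.0]], [[3.0, 3.0]], [[4.0, 4.0]]])
        out = normalize_within_gel(make_table(vols))
        np.testing.assert_allclose(out.volumes[:, 0, 0], [0.1, 0.2, 0.3, 0.4])
        np.testing.assert_allclose(out.volumes[:, 0, 1], [0.1, 0.2, 0.3, 0.4])

    def test_single_present_spot(self):
        vols = np.array([[[5.0, 2.0]]])
        out = normalize_within_gel(make_table(vols))
        np.testing.assert_allclose(out.volumes[0, 0], [1.0, 1.0])

    def test_channels_sum_to_one(self):
        table, _ = gen_spot_table(n_spots=40, n_gel_sets=6, missing_rate=0.2, seed=40)
        out = normalize_within_gel(table)
        for j in range(out.n_gel_sets):
            for c in range(2):
                vals = out.volumes[:, j, c][out.present[:, j]]
                assert vals.sum() == pytest.approx(1.0)


class TestNormalizeAcrossGels:
    def test_scale_invariance(self):
        rng = np.random.default_rng(41)
        base = rng.lognormal(0, 1, size=(20, 1, 2))
        doubled = np.concatenate([base, 2 * base], axis=1)
        out = normalize_across_gels(make_table(doubled))
        np.testing.assert_allclose(out.volumes[:, 0, :], out.volumes[:, 1, :],
                                   rtol=1e-12)

    def test_aligned_gels_unchanged(self):
        rng = np.random.default_rng(42)
        base = rng.lognormal(0, 1, size=(20, 1, 2))
        same = np.concatenate([base, base], axis=1)
        table = make_table(same)
        out = normalize_across_gels(table)
        np.testing.assert_allclose(out.volumes, table.volumes, rtol=1e-12)

    def test_within_gel_ratios_preserved(self):
        table, _ = gen_spot_table(n_spots=30, n_gel_sets=5, missing_rate=0.1, seed=43)
        before = spot_log_ratios(table)
        out = normalize_across_gels(normalize_within_gel(table))
        # within-gel normalization changes ratios by the per-channel totals;
        # the across-gel step must not change them further
        mid = normalize_within_gel(table)
        after_mid = spot_log_ratios(mid)
        after = spot_log_ratios(out)
        np.testing.assert_allclose(
            after[np.isfinite(after)], after_mid[np.isfinite(after_mid)], rtol=1e-10
        )


class TestPresenceFilter:
    @pytest.mark.parametrize("n_present,kept", [(14, False), (15, True)])
    def test_boundary(self, n_present, kept):
        present = np.zeros((1, 18), dtype=bool)
        present[0, :n_present] = True
        vols = np.ones((1, 18, 2))
        table = make_table(vols, present=present)
        out = presence_filter(table, min_sets=15)
        assert (out.n_spots == 1) is kept

    def test_all_present_unchanged(self):
        table, _ = gen_spot_table(n_spots=10, n_gel_sets=18, missing_rate=0.0, seed=44)
        out = presence_filter(table, min_sets=15)
        assert out.n_spots == 10

    def test_survivor_count_matches_hand_count(self):
        rng = np.random.default_rng(45)
        present = rng.random((25, 18)) > 0.15
        vols = np.ones((25, 18, 2))
        table = make_table(vols, present=present)
        out = presence_filter(table, min_sets=15)
        assert out.n_spots == int((present.sum(axis=1) >= 15).sum())

    def test_min_sets_exceeding_gels_rejected(self):
        table, _ = gen_spot_table(n_spots=3, n_gel_sets=4, seed=46)
        with pytest.raises(ValueError):
            presence_filter(table, min_sets=5)


class TestWelchTTest:
    def test_identical_groups(self):
        t, df, p = welch_ttest([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_worked_example(self):
        t, df, p = welch_ttest([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.6742, abs=2e-4)
        assert df == pytest.approx(4.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(47)
        for _ in range(200):
            x = rng.normal(size=rng.integers(3, 20))
            y = rng.normal(size=rng.integers(3, 20)) + rng.normal()
            t, df, p = welch_ttest(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0], [1.0, 2.0])


def brute_force_maxt(L: np.ndarray) -> np.ndarray:
    """Independent double-loop step-down maxT over all sign flips."""
    S, G = L.shape

    def tstat(row):
        return row.mean() / (row.std(ddof=1) / np.sqrt(len(row)))

    t_obs = np.array([abs(tstat(L[i])) for i in range(S)])
    order = np.argsort(-t_obs, kind="stable")
    flips = list(itertools.product((1.0, -1.0), repeat=G))
    counts = np.zeros(S)
    for signs in flips:
        M = L * np.array(signs)
        t_perm = np.array([abs(tstat(M[i])) for i in range(S)])
        # successive maxima over the tail of the observed ranking
        tail_max = -np.inf
        maxima = np.empty(S)
        for pos in range(S - 1, -1, -1):
            tail_max = max(tail_max, t_perm[order[pos]])
            maxima[pos] = tail_max
        counts += maxima >= t_obs[order] - 1e-12
    p = counts / len(flips)
    p = np.maximum.accumulate(p)
    out = np.empty(S)
    out[order] = p
    return out


class TestWestfallYoung:
    def test_single_spot_equals_raw_permutation_p(self):
        rng = np.random.default_rng(48)
        L = rng.normal(0.5, 1.0, size=(1, 4))
        p_adj = westfall_young_stepdown(L, n_perm=100, seed=0)
        # raw exhaustive sign-flip p for the single spot
        t_obs = abs(L[0].mean() / (L[0].std(ddof=1) / 2))
        count = 0
        for signs in itertools.product((1, -1), repeat=4):
            row = L[0] * np.array(signs)
            count += abs(row.mean() / (row.std(ddof=1) / 2)) >= t_obs - 1e-12
        assert p_adj[0] == pytest.approx(count / 16)

    def test_adjusted_dominates_raw(self):
        rng = np.random.default_rng(49)
        L = rng.normal(size=(10, 6))
        p_adj = westfall_young_stepdown(L, n_perm=200, seed=1)
        for i in range(10):
            t_obs = abs(L[i].mean() / (L[i].std(ddof=1) / np.sqrt(6)))
            count = 0
            for signs in itertools.product((1, -1), repeat=6):
                row = L[i] * np.array(signs)
                count += abs(row.mean() / (row.std(ddof=1) / np.sqrt(6))) >= t_obs - 1e-12
            assert p_adj[i] >= count / 64 - 1e-12

    def test_matches_brute_force_exhaustive(self):
        rng = np.random.default_rng(50)
        for trial in range(5):
            L = rng.normal(0.3, 1.0, size=(4, 4))
            got = westfall_young_stepdown(L, n_perm=100, seed=trial)
            expected = brute_force_maxt(L)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_monotone_in_ranking(self):
        rng = np.random.default_rng(51)
        L = rng.normal(size=(20, 8))
        p_adj = westfall_young_stepdown(L, n_perm=500, seed=2)
        t_obs = np.abs(L.mean(axis=1) / (L.std(axis=1, ddof=1) / np.sqrt(8)))
        order = np.argsort(-t_obs)
        assert (np.diff(p_adj[order]) >= -1e-12).all()

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning, match="n_perm"):
            westfall_young_stepdown(np.random.default_rng(0).normal(size=(2, 3)),
                                    n_perm=50, seed=0)


class TestSelectTopProteins:
    def _results(self):
        return pd.DataFrame(
            {
                "spot_id": ["a", "b", "c", "d"],
                "n_present": [18, 18, 18, 14],
                "ratio": [2.0, 1.9, 0.5, 3.0],
                "t_welch": [3.0, 4.0, -3.0, 3.0],
                "df": [30.0] * 4,
                "p_raw": [0.02, 0.001, 0.02, 0.001],
                "p_adj": [0.1, 0.05, 0.1, 0.05],
            }
        )

    def test_filter_definition(self):
        out = select_top_proteins(self._results())
        # a: ratio 2.0, p .02, 18 sets -> kept; b: ratio 1.9 -> dropped;
        # c: ratio 0.5 (2-fold down) -> kept; d: only 14 sets -> dropped
        assert set(out["spot_id"]) == {"a", "c"}

    def test_fold_cut_validation(self):
        with pytest.raises(ValueError):
            select_top_proteins(self._results(), fold_cut=1.0)

    def test_planted_survivors_recovered_exactly(self):
        # a constructed table with exactly 16 spots engineered to pass
        rng = np.random.default_rng(52)
        n_spots, G = 40, 18
        L = rng.normal(0.0, 0.05, size=(n_spots, G))
        L[:16] += np.log(2.5)  # strong planted up-shifts
        volumes = np.empty((n_spots, G, 2))
        base = rng.lognormal(2, 0.1, size=(n_spots, G))
        volumes[:, :, 0] = base
        volumes[:, :, 1] = base * np.exp(L)
        table = make_table(volumes)
        results = analyze_spots(table, n_perm=200, seed=3, normalize=False)
        assert int(results["passes_filter"].sum()) == 16
        out = select_top_proteins(results)
        assert len(out) == 16


class TestDyeSwapInvariance:
    def test_results_identical_with_zero_dye_bias(self):
        table_a, _ = gen_spot_table(n_spots=30, n_gel_sets=16, de_spots=5,
                                    n_dye_swap=0, dye_bias=0.0, seed=53)
        table_b, _ = gen_spot_table(n_spots=30, n_gel_sets=16, de_spots=5,
                                    n_dye_swap=8, dye_bias=0.0, seed=53)
        ra = analyze_spots(table_a, n_perm=300, seed=4, min_sets=12)
        rb = analyze_spots(table_b, n_perm=300, seed=4, min_sets=12)
        pd.testing.assert_frame_equal(ra, rb)
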