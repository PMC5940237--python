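import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.integrate import quad

import skbio

from percnorm import (
    FeatureTable,
    FeatureTestResult,
    TableError,
    abundance_filter,
    bh_fdr,
    bray_curtis,
    fisher_combine,
    opposing_direction_screen,
    permanova,
    rank_sum_table,
    stouffer_combine,
    wilcoxon_ranksum,
)
from conftest import random_table


class TestAbundanceFilter:
    def _table(self, rows, samples):
        return FeatureTable(
            pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))], columns=samples),
            state="unknown",
        )

    def test_boundary_kept_at_one_third(self):
        # nonzero in 2/6 cases, 0/12 controls -> kept (2/6 >= 1/3)
        cases = [f"k{i}" for i in range(6)]
        controls = [f"c{i}" for i in range(12)]
        row = [1.0, 1.0] + [0.0] * 4 + [0.0] * 12
        table = self._table([row], cases + controls)
        assert abundance_filter(table, cases, controls) == ["f0"]

    def test_below_threshold_dropped(self):
        cases = [f"k{i}" for i in range(6)]
        controls = [f"c{i}" for i in range(12)]
        row = [1.0] + [0.0] * 5 + [1.0] * 3 + [0.0] * 9
        table = self._table([row], cases + controls)
        assert abundance_filter(table, cases, controls) == []

    def test_empty_group_rejected(self):
        table = self._table([[1.0]], ["s"])
        with pytest.raises(TableError, match="non-empty"):
            abundance_filter(table, [], ["s"])

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_brute_force_rule(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng, n_features=12, n_samples=9, sparsity=0.6)
        a, b = table.sample_ids[:4], table.sample_ids[4:]
        kept = set(abundance_filter(table, a, b))
        expected = set()
        for fid in table.feature_ids:
            row = table.data.loc[fid]
            if (row[a] > 0).sum() / len(a) >= 1 / 3 or (row[b] > 0).sum() / len(b) >= 1 / 3:
                expected.add(fid)
        assert kept == expected


def ranksum_oracle(x, y):
    """Rank-sum z from first principles: midranks by sorting, normal tail."""
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n_x, n_y = len(x), len(y)
    N = n_x + n_y
    rx = ranks[:n_x].sum()
    z = (rx - n_x * (N + 1) / 2) / np.sqrt(n_x * n_y * (N + 1) / 12)
    return z, 2 * sps.norm.sf(abs(z))


class TestWilcoxonRankSum:
    def test_hand_computed_example(self):
        z, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert z == pytest.approx(-1.9640, abs=1e-4)
        assert p == pytest.approx(0.0495, abs=1e-4)

    def test_symmetric_ranks_give_zero(self):
        z, p = wilcoxon_ranksum([1, 4], [2, 3])
        assert z == 0 and p == 1

    def test_empty_sample_rejected(self):
        with pytest.raises(TableError, match="non-empty"):
            wilcoxon_ranksum([], [1.0])

    @settings(deadline=None, max_examples=60)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_rank_oracle_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=rng.integers(1, 9)).astype(float)
        y = rng.integers(0, 6, size=rng.integers(1, 9)).astype(float)
        z, p = wilcoxon_ranksum(x, y)
        z0, p0 = ranksum_oracle(x, y)
        assert z == pytest.approx(z0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_rank_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(size=7)
        z1, p1 = wilcoxon_ranksum(x, y)
        z2, p2 = wilcoxon_ranksum(np.exp(2 * x), np.exp(2 * y))
        assert z1 == pytest.approx(z2) and p1 == pytest.approx(p2)


class TestVectorizedRankSum:
    def test_matches_scalar_path_and_handles_missing(self, rng):
        values = np.abs(rng.normal(size=(5, 10))) * 30 % 100
        values[2, 0] = np.nan  # feature absent from one study's samples
        frame = pd.DataFrame(
            values, index=[f"f{i}" for i in range(5)], columns=[f"s{j}" for j in range(10)]
        )
        table = FeatureTable(frame, state="percentile", meta={})
        case, ctrl = table.sample_ids[:4], table.sample_ids[4:]
        results = rank_sum_table(table, case, ctrl)
        for r in results:
            row = table.data.loc[r.feature_id]
            x = row[case].dropna().to_numpy()
            y = row[ctrl].dropna().to_numpy()
            z0, p0 = ranksum_oracle(x, y)
            assert r.z == pytest.approx(z0, abs=1e-12)
            assert r.p == pytest.approx(p0, abs=1e-12)
        assert results[2].n_case == 3  # NaN sample dropped pairwise


class TestBHFDR:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(TableError, match="0, 1"):
            bh_fdr([0.0, 0.5])

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_brute_force_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(size=rng.integers(1, 20))
        q = bh_fdr(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order, start=1):
            candidates = [
                m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)
            ]
            expected[idx] = min(1.0, min(candidates))
        np.testing.assert_allclose(q, expected, atol=1e-12)
        assert (q >= p - 1e-15).all()


def fisher_oracle(p1, p2):
    """Survival of -2(ln p1 + ln p2) under chi-square(4) by quadrature."""
    x = -2 * (np.log(p1) + np.log(p2))
    val, _ = quad(sps.chi2(4).pdf, x, np.inf)
    return val


def stouffer_oracle(p1, p2):
    z = (sps.norm.isf(p1) + sps.norm.isf(p2)) / np.sqrt(2)
    return sps.norm.sf(z)


class TestCombiners:
    def test_fisher_known_values(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(0.01748, abs=1e-4)
        assert fisher_combine([0.3]) == pytest.approx(0.3, abs=1e-12)

    def test_fisher_zero_rejected(self):
        with pytest.raises(TableError, match="floor"):
            fisher_combine([0.0, 0.5])

    def test_stouffer_known_values(self):
        assert stouffer_combine([0.5, 0.5], [1, 1]) == pytest.approx(0.5)
        assert stouffer_combine([0.05, 0.05], [1, 1]) == pytest.approx(0.0100, abs=1e-4)
        assert stouffer_combine([0.123], [7.0]) == pytest.approx(0.123, abs=1e-12)

    def test_stouffer_boundary_rejected(self):
        with pytest.raises(TableError, match="strictly"):
            stouffer_combine([1.0, 0.5], [1, 1])

    def test_agreement_with_integration_oracle_on_grid(self):
        grid = [0.001, 0.01, 0.05, 0.2, 0.5, 0.8, 0.99]
        for p1 in grid:
            for p2 in grid:
                assert fisher_combine([p1, p2]) == pytest.approx(
                    fisher_oracle(p1, p2), abs=1e-8
                )
                assert stouffer_combine([p1, p2], [1, 1]) == pytest.approx(
                    stouffer_oracle(p1, p2), abs=1e-8
                )


def _result(fid, z, q):
    return FeatureTestResult(
        feature_id=fid, n_case=10, n_control=10, z=z, p=min(1.0, q), q=q,
        direction=FeatureTestResult.direction_of(z),
    )


class TestOpposingDirectionScreen:
    def test_significant_opposite_directions_excluded(self):
        per_study = {
            "s1": [_result("f", 2.5, 0.01)],
            "s2": [_result("f", -2.2, 0.02)],
        }
        assert opposing_direction_screen(per_study) == {"f"}

    def test_single_study_significance_retained(self):
        per_study = {"s1": [_result("f", 2.5, 0.01)], "s2": [_result("f", -1.0, 0.4)]}
        assert opposing_direction_screen(per_study) == set()

    def test_non_significant_conflict_retained_by_default(self):
        per_study = {"s1": [_result("f", 1.0, 0.3)], "s2": [_result("f", -1.0, 0.4)]}
        assert opposing_direction_screen(per_study) == set()
        # but excluded under the any-sign-conflict rule
        assert opposing_direction_screen(per_study, use="none") == {"f"}


class TestBrayCurtis:
    def test_identical_columns_zero(self, toy_table):
        dm = bray_curtis(toy_table)
        assert dm["s1", "s1"] == 0.0

    def test_disjoint_supports_one(self):
        frame = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 1.0]}, index=["a", "b"])
        dm = bray_curtis(FeatureTable(frame, state="unknown"))
        assert dm["s1", "s2"] == pytest.approx(1.0)

    def test_known_half_distance(self):
        frame = pd.DataFrame({"u": [0.5, 0.5], "v": [1.0, 0.0]}, index=["a", "b"])
        dm = bray_curtis(FeatureTable(frame, state="unknown"))
        assert dm["u", "v"] == pytest.approx(0.5)

    def test_all_zero_sample_rejected(self):
        frame = pd.DataFrame({"ok": [1.0], "bad": [0.0]}, index=["a"])
        with pytest.raises(TableError, match="bad"):
            bray_curtis(FeatureTable(frame, state="unknown"))


def permanova_oracle_F(dm, labels):
    """pseudo-F from the squared-distance sums directly."""
    d2 = dm.data**2
    N = len(labels)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    ss_total = d2[np.triu_indices(N, 1)].sum() / N
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    a = len(groups)
    return (ss_among / (a - 1)) / (ss_within / (N - a)), ss_among / ss_total


class TestPermanova:
    def _random_dm(self, rng, n=14):
        pts = rng.normal(size=(n, 4))
        from scipy.spatial.distance import pdist, squareform

        return skbio.DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(n)])

    def test_statistic_matches_sums_of_squares_oracle(self, rng):
        dm = self._random_dm(rng)
        labels = ["a"] * 7 + ["b"] * 7
        res = permanova(dm, labels, n_permutations=99, seed=1)
        f0, r20 = permanova_oracle_F(dm, labels)
        assert res.pseudo_F == pytest.approx(f0, rel=1e-10)
        assert res.r2 == pytest.approx(r20, rel=1e-10)
        assert 0 <= res.r2 <= 1

    def test_maximal_separation_gives_smallest_p(self, rng):
        from scipy.spatial.distance import pdist, squareform

        pts = np.vstack([rng.normal(0, 0.01, (6, 3)), rng.normal(50, 0.01, (6, 3))])
        dm = skbio.DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(12)])
        res = permanova(dm, ["a"] * 6 + ["b"] * 6, n_permutations=199, seed=2)
        assert res.p == pytest.approx(1 / 200)

    def test_single_group_rejected(self, rng):
        dm = self._random_dm(rng, n=6)
        with pytest.raises(TableError, match="two groups"):
            permanova(dm, ["a"] * 6, seed=0)

    def test_small_group_rejected(self, rng):
        dm = self._random_dm(rng, n=6)
        with pytest.raises(TableError, match="fewer than two"):
            permanova(dm, ["a"] * 5 + ["b"], seed=0)

    def test_deterministic_under_seed(self, rng):
        dm = self._random_dm(rng)
        labels = ["a"] * 7 + ["b"] * 7
        p1 = permanova(dm, labels, n_permutations=99, seed=42).p
        p2 = permanova(dm, labels, n_permutations=99, seed=42).p
        assert p1 == p2


class TestGlobalNullFDR:
    def test_bh_discovery_fraction_controlled(self):
        """Under a global null the expected share of q<=0.05 features stays
        at or below 0.05 (averaged over 50 replicates)."""
        rng = np.random.default_rng(123)
        fracs = []
        for _ in range(50):
            values = rng.normal(size=(100, 24))
            frame = pd.DataFrame(
                values, index=[f"f{i}" for i in range(100)],
                columns=[f"s{j}" for j in range(24)],
            )
            table = FeatureTable(frame, state="log")
            res = rank_sum_table(table, table.sample_ids[:12], table.sample_ids[12:])
            fracs.append(np.mean([r.q <= 0.05 for r in res]))
        assert np.mean(fracs) <= 0.05 + 0.01
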