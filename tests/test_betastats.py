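"""Bray-Curtis, ANOSIM, PERMANOVA, nMDS, Venn sets and indicator values."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import rankdata

import phylosym as ps
from phylosym.betastats import DistanceMatrix, _anosim_r


def table_from(rows, samples=None, otus=None):
    rows = np.atleast_2d(rows)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    otus = otus or [f"o{j}" for j in range(rows.shape[1])]
    return ps.CountTable(pd.DataFrame(rows, index=samples, columns=otus))


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        dm = ps.bray_curtis(table_from([[3, 5], [3, 5]]))
        assert dm.d[0, 1] == 0

    def test_disjoint_rows_one(self):
        dm = ps.bray_curtis(table_from([[10, 0], [0, 10]]))
        assert dm.d[0, 1] == 1

    def test_hand_arithmetic(self):
        dm = ps.bray_curtis(table_from([[6, 4], [2, 8]]))
        assert dm.d[0, 1] == pytest.approx(0.4)

    def test_joint_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 30, size=(4, 12))
        a = ps.bray_curtis(table_from(x))
        b = ps.bray_curtis(table_from(x * 7))
        assert np.allclose(a.d, b.d)

    def test_matches_skbio(self):
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(1)
        x = rng.integers(0, 50, size=(6, 20)) + 1
        mine = ps.bray_curtis(table_from(x))
        theirs = beta_diversity("braycurtis", x)
        assert np.allclose(mine.d, theirs.data)


def exhaustive_anosim(dm, groups):
    """Oracle: R and p over all distinct label permutations (small n)."""
    groups = np.asarray(groups)
    ranks = rankdata(dm.condensed())
    i_idx, j_idx = np.triu_indices(dm.n, k=1)

    def r_of(g):
        return _anosim_r(ranks, g[i_idx] == g[j_idx])

    r_obs = r_of(groups)
    values = []
    n = len(groups)
    from itertools import permutations

    seen = set()
    for perm in permutations(range(n)):
        key = tuple(groups[list(perm)])
        if key in seen:
            continue
        seen.add(key)
        values.append(r_of(np.asarray(key)))
    values = np.asarray(values)
    return r_obs, (values >= r_obs - 1e-12).mean()


class TestAnosim:
    @staticmethod
    def separated_dm():
        # two groups of 3; all between distances exceed all within distances
        d = np.full((6, 6), 0.9)
        np.fill_diagonal(d, 0)
        for block in ([0, 1, 2], [3, 4, 5]):
            for i, j in combinations(block, 2):
                d[i, j] = d[j, i] = 0.1
        return DistanceMatrix([f"s{i}" for i in range(6)], d)

    def test_perfect_separation_r_one(self):
        res = ps.anosim(self.separated_dm(), list("aaabbb"), n_permutations=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_all_ties_r_zero(self):
        d = np.full((6, 6), 0.5)
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
        res = ps.anosim(dm, list("aaabbb"), n_permutations=99, seed=0)
        assert res.R == pytest.approx(0.0)

    def test_r_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.random((6, 4))
        dm = ps.bray_curtis(table_from(x * 100))
        groups = list("aaabbb")
        r_oracle, p_oracle = exhaustive_anosim(dm, groups)
        res = ps.anosim(dm, groups, n_permutations=4999, seed=1)
        assert res.R == pytest.approx(r_oracle)
        # Monte-Carlo p within binomial error of the exhaustive p
        se = np.sqrt(p_oracle * (1 - p_oracle) / 4999)
        assert abs(res.p_value - p_oracle) < 4 * se + 1 / 4999

    def test_matches_skbio_r(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(3)
        x = rng.integers(1, 40, size=(9, 15))
        dm = ps.bray_curtis(table_from(x))
        groups = list("aaabbbccc")
        res = ps.anosim(dm, groups, n_permutations=99, seed=0, pairwise=False)
        theirs = skbio_anosim(SkbioDM(dm.d, ids=dm.labels), grouping=groups,
                              permutations=99)
        assert res.R == pytest.approx(theirs["test statistic"])

    def test_singleton_group_excluded_from_pairwise(self):
        d = self.separated_dm()
        with pytest.warns(UserWarning, match="size 1"):
            res = ps.anosim(d, list("aaabbc"), n_permutations=99, seed=0)
        assert all("c" not in pair[:2] for pair in res.pairwise)


def oracle_one_way_ss(dm, groups):
    """Direct within-group sums formula SS_W = sum_g sum_{i<j in g} d2/n_g."""
    groups = np.asarray(groups)
    n = dm.n
    ss_total = (dm.condensed() ** 2).sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        sub = dm.d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), k=1)] ** 2).sum() / len(idx)
    return ss_total, ss_within


class TestPermanova:
    def test_one_way_matches_direct_sums_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            sizes = rng.integers(3, 6, size=3)
            groups = np.repeat(list("abc"), sizes)
            x = rng.random((len(groups), 8)) * 50
            dm = ps.bray_curtis(table_from(x))
            design = pd.DataFrame({"group": groups}, index=dm.labels)
            res = ps.permanova(dm, design, ["group"], n_permutations=99, seed=0)
            ss_total, ss_within = oracle_one_way_ss(dm, groups)
            tab = res.table
            assert tab.loc["group", "SumOfSqs"] == pytest.approx(ss_total - ss_within)
            assert tab.loc["Residuals", "SumOfSqs"] == pytest.approx(ss_within)

    def test_one_way_matches_skbio_pseudo_f(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(5)
        groups = list("aaaabbbbcccc")
        x = rng.integers(1, 60, size=(12, 10))
        dm = ps.bray_curtis(table_from(x))
        design = pd.DataFrame({"group": groups}, index=dm.labels)
        res = ps.permanova(dm, design, ["group"], n_permutations=99, seed=0)
        theirs = skbio_permanova(SkbioDM(dm.d, ids=dm.labels), grouping=groups,
                                 permutations=99)
        assert res.table.loc["group", "F_model"] == pytest.approx(
            theirs["test statistic"])

    def test_degenerate_full_separation(self):
        coords = np.array([0, 0, 0, 10, 10, 10.0])
        d = np.abs(coords[:, None] - coords[None, :])
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
        design = pd.DataFrame({"g": list("aaabbb")}, index=dm.labels)
        res = ps.permanova(dm, design, ["g"], n_permutations=99, seed=0)
        assert res.table.loc["g", "R2"] == pytest.approx(1.0)
        assert res.table.loc["Residuals", "SumOfSqs"] == pytest.approx(0.0, abs=1e-9)

    def test_null_r2_matches_expectation(self):
        # with random labels, E[R2] ~ df_term / (n - 1)
        rng = np.random.default_rng(9)
        n = 12
        r2 = []
        for _ in range(200):
            x = rng.random((n, 6))
            dm = ps.bray_curtis(table_from(x * 30 + 1))
            design = pd.DataFrame({"g": rng.permutation(list("aabb" * 3))},
                                  index=dm.labels)
            res = ps.permanova(dm, design, ["g"], n_permutations=1, seed=0)
            r2.append(res.table.loc["g", "R2"])
        assert np.mean(r2) == pytest.approx(1 / (n - 1), abs=0.02)

    def test_r2_partition_and_df_sum(self, rarefied_dataset):
        table, info, _ = rarefied_dataset
        sub = ps.CountTable(table.data.iloc[:30])
        dm = ps.bray_curtis(sub)
        design = info.data.loc[sub.sample_ids].copy()
        design["individual"] = pd.factorize(design["individual"])[0].astype(float)
        terms = ["species", "section", "individual", "species:section"]
        res = ps.permanova(dm, design, terms, n_permutations=49, seed=0)
        tab = res.table
        term_rows = tab.drop(index=["Residuals", "Total"])
        assert term_rows["R2"].sum() + tab.loc["Residuals", "R2"] == pytest.approx(1.0)
        assert term_rows["df"].sum() + tab.loc["Residuals", "df"] == dm.n - 1
        assert tab.loc["individual", "df"] == 1  # numeric covariate coding

    def test_permutation_invariance_to_sample_order(self):
        rng = np.random.default_rng(13)
        x = rng.integers(1, 30, size=(8, 6))
        groups = list("aabbaabb")
        dm = ps.bray_curtis(table_from(x))
        design = pd.DataFrame({"g": groups}, index=dm.labels)
        f1 = ps.permanova(dm, design, ["g"], n_permutations=0).table.loc["g", "F_model"]
        order = rng.permutation(dm.n)
        dm2 = DistanceMatrix([dm.labels[i] for i in order], dm.d[np.ix_(order, order)])
        f2 = ps.permanova(dm2, design, ["g"], n_permutations=0).table.loc["g", "F_model"]
        assert f1 == pytest.approx(f2)


class TestNmds:
    def test_planar_configuration_embeds_with_low_stress(self):
        rng = np.random.default_rng(2)
        pts = rng.random((10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        dm = DistanceMatrix([f"s{i}" for i in range(10)], d)
        res = ps.nmds(dm, k=2, n_starts=8, seed=0)
        assert res.stress < 0.01

    def test_four_equidistant_points_not_embeddable(self):
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(list("abcd"), d)
        res = ps.nmds(dm, k=2, n_starts=10, seed=1)
        assert res.stress > 0
        assert res.coordinates.shape == (4, 2)


class TestSharedOtuSets:
    def test_disjoint_groups(self):
        table = table_from([[5, 0], [0, 5]])
        out = ps.shared_otu_sets(table, {"a": ["s0"], "b": ["s1"]})
        assert out.loc["a+b", "n_otus"] == 0
        assert out.loc["a", "n_otus"] == 1

    def test_identical_groups_full_intersection(self):
        table = table_from([[5, 2], [5, 2]])
        out = ps.shared_otu_sets(table, {"a": ["s0"], "b": ["s1"]})
        assert out.loc["a+b", "n_otus"] == 2
        assert out.loc["a", "n_otus"] == 0

    def test_hand_computed_region_shares(self):
        # o1 only in a, o2 shared, o3 only in b
        table = table_from([[4, 6, 0], [0, 3, 7]])
        out = ps.shared_otu_sets(table, {"a": ["s0"], "b": ["s1"]})
        assert out.loc["a+b", "n_otus"] == 1
        assert out.loc["a+b", "share_a"] == pytest.approx(0.6)
        assert out.loc["a+b", "share_b"] == pytest.approx(0.3)
        assert out.loc["a+b", "share_pooled"] == pytest.approx(9 / 20)

    def test_too_many_groups_rejected(self):
        table = table_from(np.eye(5, dtype=int) * 3)
        with pytest.raises(ValueError):
            ps.shared_otu_sets(table, {g: [f"s{i}"] for i, g in enumerate("abcde")})


class TestIndicatorValues:
    def test_perfect_indicator(self):
        x = np.zeros((8, 1), dtype=int)
        x[:4] = 5
        res = ps.indicator_values(table_from(x), list("aaaabbbb"),
                                  n_permutations=99, seed=0)
        assert res.table["indval"].iloc[0] == pytest.approx(100.0)

    def test_uniform_taxon_indval_100_over_g(self):
        x = np.full((9, 1), 4)
        res = ps.indicator_values(table_from(x), list("aaabbbccc"),
                                  n_permutations=99, seed=0)
        assert res.table["indval"].iloc[0] == pytest.approx(100 / 3)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        # perfect indicator, groups 4+4: only C(8,4) label assignments;
        # exactly 2 of 70 reach indval = 100 (the assignment and its swap),
        # but every assignment placing all mass in one group's samples is
        # just those 2; Monte-Carlo p should approach (1 + #) / (1 + B)
        x = np.zeros((8, 1), dtype=int)
        x[:4] = 7
        n_exhaustive = comb(8, 4, exact=True)
        p_true = 2 / n_exhaustive
        res = ps.indicator_values(table_from(x), list("aaaabbbb"),
                                  n_permutations=4999, seed=2)
        p_mc = res.table["p"].iloc[0]
        se = np.sqrt(p_true * (1 - p_true) / 4999)
        assert abs(p_mc - p_true) < 4 * se + 2 / 4999

    def test_absent_taxon_skipped(self):
        x = np.array([[3, 0], [4, 0], [5, 0], [1, 0]])
        res = ps.indicator_values(table_from(x), list("aabb"), n_permutations=9, seed=0)
        assert list(res.table.index) == ["o0"]
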