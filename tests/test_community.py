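import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sps

from pmena import community
from pmena.containers import CountTable, TaxonomyMap


def _table(values, group=None, samples=None, features=None):
    values = np.asarray(values)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    features = features or [f"f{i}" for i in range(values.shape[1])]
    g = pd.Series(group, index=samples) if group is not None else None
    return CountTable(pd.DataFrame(values, index=samples, columns=features), group=g)


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

class TestRarefy:
    def test_depth_equal_to_total_is_identity(self):
        t = _table([[3, 5, 2], [1, 0, 9]])
        out = community.rarefy(t, 10, seed=0)
        assert out.counts.equals(t.counts.astype(out.counts.to_numpy().dtype))

    def test_zero_feature_stays_zero_and_total_exact(self):
        t = _table([[10, 0, 10]])
        out = community.rarefy(t, 10, seed=1)
        assert out.counts.iloc[0, 1] == 0
        assert out.sample_sums().iloc[0] == 10

    def test_insufficient_sample_named_in_error(self):
        t = _table([[4, 1]], samples=["shallow"])
        with pytest.raises(ValueError, match="shallow"):
            community.rarefy(t, 10)

    def test_expected_richness_matches_hypergeometric_formula(self):
        counts = np.array([40, 25, 10, 5, 3, 1, 1])
        total, depth = counts.sum(), 20
        expected = sum(
            1 - comb(total - c, depth) / comb(total, depth) for c in counts
        )
        t = _table([counts])
        rng_draws = [
            (community.rarefy(t, depth, seed=s).counts.to_numpy() > 0).sum()
            for s in range(2000)
        ]
        assert np.mean(rng_draws) == pytest.approx(expected, abs=0.05)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_total_conserved_at_depth(self, seed):
        t = _table([[7, 3, 12, 0, 8], [2, 2, 2, 2, 22]])
        out = community.rarefy(t, 15, seed=seed)
        assert (out.sample_sums() == 15).all()
        assert (out.counts.to_numpy() <= t.counts.to_numpy()).all()


class TestRarefactionCurve:
    def test_richness_one_at_depth_one(self):
        t = _table([[5, 5, 5]])
        curve = community.rarefaction_curve(t, [1], reps=5, seed=0)
        assert (curve.iloc[:, 0] == 1).all()

    def test_monotone_and_saturating(self):
        t = _table([[30, 20, 10, 5], [50, 1, 1, 1]])
        curve = community.rarefaction_curve(t, [1, 5, 20, 53], reps=20, seed=0)
        arr = curve.to_numpy()
        assert (np.diff(arr, axis=1) >= -1e-12).all()
        # at full depth the curve equals observed richness
        assert curve.iloc[0, -1] == (t.counts.iloc[0] > 0).sum()

    def test_excess_depth_truncated_with_warning(self):
        t = _table([[5, 5]])
        with pytest.warns(UserWarning, match="truncated"):
            curve = community.rarefaction_curve(t, [5, 100], reps=3, seed=0)
        assert np.isnan(curve.iloc[0, 1])


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

class TestShannonPielou:
    @pytest.mark.parametrize(
        "row, h_expected, j_expected",
        [
            ([1, 1, 1, 1], np.log(4), 1.0),
            ([10, 0, 0], 0.0, 1.0),
            ([2, 1, 1], 1.0397207708399179, None),  # -sum p ln p at (.5,.25,.25)
        ],
    )
    def test_hand_computed_values(self, row, h_expected, j_expected):
        res = community.shannon_pielou(_table([row]))
        assert res["shannon"].iloc[0] == pytest.approx(h_expected, abs=1e-12)
        if j_expected is not None:
            assert res["pielou"].iloc[0] == pytest.approx(j_expected, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            community.shannon_pielou(_table([[0, 0]]))

    @given(st.lists(st.integers(min_value=1, max_value=100), min_size=2, max_size=12))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_uniform_maximizes_shannon_and_pielou_bounded(self, counts):
        s = len(counts)
        res = community.shannon_pielou(_table([counts]))
        uniform = community.shannon_pielou(_table([[1] * s]))
        assert res["shannon"].iloc[0] <= uniform["shannon"].iloc[0] + 1e-12
        assert 0.0 <= res["pielou"].iloc[0] <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# distances & dissimilarity tests
# ---------------------------------------------------------------------------

class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        d = community.bray_curtis(_table([[1, 2, 0], [1, 2, 0], [0, 0, 5]]))
        assert d.iloc[0, 1] == pytest.approx(0.0)
        assert d.iloc[0, 2] == pytest.approx(1.0)

    def test_hand_evaluated_formula_on_raw_counts(self):
        d = community.bray_curtis(_table([[1, 1], [1, 3]]), relative=False)
        assert d.iloc[0, 1] == pytest.approx(2 / 6)

    def test_symmetric_zero_diagonal_bounded(self, small_table):
        d = community.bray_curtis(small_table).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()


class TestDissimilarityTests:
    def test_perfect_separation_gives_minimal_p(self):
        n = 12
        d = np.full((n, n), 0.9)
        d[:6, :6] = 0.1
        d[6:, 6:] = 0.1
        np.fill_diagonal(d, 0)
        dm = pd.DataFrame(d, index=[f"s{i}" for i in range(n)], columns=[f"s{i}" for i in range(n)])
        group = pd.Series(["A"] * 6 + ["B"] * 6, index=dm.index)
        res = community.dissimilarity_tests(dm, group, n_perm=199, seed=0)
        assert res["p"].tolist() == pytest.approx([1 / 200] * 3)

    def test_equal_distances_give_anosim_r_zero(self):
        n = 8
        d = np.ones((n, n)) - np.eye(n)
        dm = pd.DataFrame(d, index=[f"s{i}" for i in range(n)], columns=[f"s{i}" for i in range(n)])
        group = pd.Series(["A"] * 4 + ["B"] * 4, index=dm.index)
        res = community.dissimilarity_tests(dm, group, n_perm=99, seed=0)
        assert res.loc["ANOSIM", "statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_statistics_match_skbio(self, small_table):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix

        d = community.bray_curtis(small_table)
        res = community.dissimilarity_tests(d, small_table.group, n_perm=99, seed=0)
        dm = DistanceMatrix(d.to_numpy(), ids=list(d.index))
        grouping = list(small_table.group)
        r_skbio = skbio_stats.anosim(dm, grouping, permutations=0)["test statistic"]
        f_skbio = skbio_stats.permanova(dm, grouping, permutations=0)["test statistic"]
        assert res.loc["ANOSIM", "statistic"] == pytest.approx(r_skbio, abs=1e-12)
        assert res.loc["PERMANOVA", "statistic"] == pytest.approx(f_skbio, rel=1e-10)

    def test_p_respects_permutation_floor(self, small_table):
        d = community.bray_curtis(small_table)
        res = community.dissimilarity_tests(d, small_table.group, n_perm=99, seed=3)
        assert (res["p"] >= 1 / 100).all()
        assert (res["p"] <= 1).all()


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def _ca_axis1_svd_oracle(y):
    """Plain CA axis-1 sample scores from the SVD of the chi-square
    standardized matrix (independent of the reciprocal-averaging path)."""
    y = np.asarray(y, dtype=float)
    p = y / y.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    return u[:, 0] / np.sqrt(r)


class TestDCA:
    def test_disjoint_blocks_separate_on_axis_one(self):
        y = np.zeros((6, 8))
        y[:3, :4] = np.random.default_rng(0).integers(5, 20, (3, 4))
        y[3:, 4:] = np.random.default_rng(1).integers(5, 20, (3, 4))
        scores = community.dca(_table(y), n_axes=1)
        axis1 = scores["DCA1"].round(6)
        assert axis1.nunique() == 2
        assert set(axis1.iloc[:3]) != set(axis1.iloc[3:])

    def test_independent_margins_have_no_axes(self):
        rows = np.array([1.0, 2.0, 3.0])
        cols = np.array([4.0, 1.0, 2.0, 3.0])
        y = np.outer(rows, cols)
        with pytest.raises(ValueError, match="inertia"):
            community.dca(_table(y))

    def test_axis_one_matches_svd_oracle(self, small_table):
        scores = community.dca(small_table, n_axes=1)
        oracle = _ca_axis1_svd_oracle(small_table.counts.to_numpy())
        a = scores["DCA1"].to_numpy()
        a = a / np.linalg.norm(a)
        b = oracle / np.linalg.norm(oracle)
        assert min(np.linalg.norm(a - b), np.linalg.norm(a + b)) < 1e-4


# ---------------------------------------------------------------------------
# response ratios
# ---------------------------------------------------------------------------

@pytest.fixture
def flat_taxonomy():
    return TaxonomyMap(
        pd.DataFrame({"phylum": ["P1", "P1", "P2"]}, index=["f0", "f1", "f2"])
    )


class TestResponseRatio:
    def test_equal_means_are_ns(self, flat_taxonomy):
        values = np.tile([10.0, 10.0, 30.0], (8, 1))
        t = _table(values, group=["H"] * 4 + ["L"] * 4)
        # perturb within groups symmetrically so variances are nonzero
        t.counts.iloc[0, 0] += 1
        t.counts.iloc[4, 0] += 1
        res = community.response_ratio(t, flat_taxonomy, rank="phylum")
        assert res.ratios.loc["P2", "RR"] == pytest.approx(0.0, abs=1e-9)
        assert res.ratios.loc["P2", "call"] == "ns"

    def test_twofold_change_zero_variance(self):
        taxonomy = TaxonomyMap(pd.DataFrame({"phylum": ["A", "B"]}, index=["f0", "f1"]))
        values = np.array([[2.0, 1.0]] * 4 + [[1.0, 2.0]] * 4)
        t = _table(values, group=["H"] * 4 + ["L"] * 4)
        res = community.response_ratio(t, taxonomy, rank="phylum")
        row = res.ratios.loc["A"]
        assert row["RR"] == pytest.approx(np.log(2), abs=1e-12)
        assert row["ci_low"] == row["ci_high"] == row["RR"]
        assert row["call"] == "enriched_H"

    def test_zero_group_mean_reported_separately(self, flat_taxonomy):
        values = np.array([[5.0, 5.0, 0.0]] * 4 + [[5.0, 5.0, 3.0]] * 4)
        t = _table(values, group=["H"] * 4 + ["L"] * 4)
        res = community.response_ratio(t, flat_taxonomy, rank="phylum")
        assert "P2" not in res.ratios.index
        assert res.one_group_only.loc["P2", "present_in"] == "L"

    def test_unknown_rank_rejected(self, small_table, flat_taxonomy):
        with pytest.raises(KeyError):
            community.response_ratio(small_table, flat_taxonomy, rank="species")

    def test_ci_invariant_means_bracket(self):
        # ci_low <= RR <= ci_high on noisy data
        rng = np.random.default_rng(11)
        taxonomy = TaxonomyMap(
            pd.DataFrame({"phylum": [f"P{i}" for i in range(6)]},
                         index=[f"f{i}" for i in range(6)])
        )
        t = _table(rng.uniform(1, 50, (16, 6)), group=["H"] * 8 + ["L"] * 8)
        res = community.response_ratio(t, taxonomy, rank="phylum")
        assert (res.ratios["ci_low"] <= res.ratios["RR"] + 1e-12).all()
        assert (res.ratios["RR"] <= res.ratios["ci_high"] + 1e-12).all()


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

class TestMantel:
    def test_self_comparison_gives_r_one_minimal_p(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 3))
        d = squareform(pdist(x))
        r, p = community.mantel(d, d, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_r_equals_brute_force_pair_loop(self):
        rng = np.random.default_rng(5)
        d1 = squareform(pdist(rng.standard_normal((9, 2))))
        d2 = squareform(pdist(rng.standard_normal((9, 2))))
        r, _p = community.mantel(d1, d2, n_perm=9, seed=0)
        xs, ys = [], []
        for i in range(9):
            for j in range(i + 1, 9):
                xs.append(d1[i, j])
                ys.append(d2[i, j])
        assert r == pytest.approx(np.corrcoef(xs, ys)[0, 1], abs=1e-12)

    def test_constant_matrix_rejected(self):
        d = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError):
            community.mantel(d, d, n_perm=9)


# ---------------------------------------------------------------------------
# group difference tests
# ---------------------------------------------------------------------------

class TestGroupDifference:
    def test_identical_groups_not_significant(self):
        mat = pd.DataFrame(
            np.tile([[1.0, 5.0]], (8, 1)),
            index=[f"s{i}" for i in range(8)],
        )
        group = pd.Series(["A", "B"] * 4, index=mat.index)
        res = community.group_difference_test(mat, group)
        assert (res["p"] == 1.0).all()

    def test_t_squared_equals_anova_f(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.standard_normal((12, 5)),
                           index=[f"s{i}" for i in range(12)])
        group = pd.Series(["A"] * 6 + ["B"] * 6, index=mat.index)
        res = community.group_difference_test(mat, group, equal_var=True)
        for j in range(5):
            f = sps.f_oneway(mat.iloc[:6, j], mat.iloc[6:, j]).statistic
            assert res["t"].iloc[j] ** 2 == pytest.approx(f, rel=1e-10)

    def test_null_flag_rate_near_alpha(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.standard_normal((16, 200)),
                           index=[f"s{i}" for i in range(16)])
        group = pd.Series(["A"] * 8 + ["B"] * 8, index=mat.index)
        res = community.group_difference_test(mat, group, alpha=0.1)
        lo, hi = sps.binom.ppf([0.025, 0.975], 200, 0.1)
        assert lo <= res["significant"].sum() <= hi


# ---------------------------------------------------------------------------
# normalization & aggregation
# ---------------------------------------------------------------------------

class TestNormalizeIntensity:
    def test_equal_totals_unchanged(self):
        t = _table([[1.0, 3.0], [2.0, 2.0]])
        out = community.normalize_intensity(t)
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_totals_equalized(self):
        t = _table([[1.0, 3.0], [10.0, 30.0], [2.0, 2.0]])
        out = community.normalize_intensity(t)
        totals = out.counts.sum(axis=1)
        assert np.allclose(totals, totals.iloc[0], rtol=1e-9)

    def test_scale_invariance_of_one_sample(self):
        base = np.array([[1.0, 3.0], [4.0, 4.0]])
        doubled = base.copy()
        doubled[0] *= 2
        a = community.normalize_intensity(_table(base)).counts
        b = community.normalize_intensity(_table(doubled)).counts
        # doubling one input sample leaves its normalized profile unchanged
        np.testing.assert_allclose(
            (a.iloc[0] / a.iloc[0].sum()).to_numpy(),
            (b.iloc[0] / b.iloc[0].sum()).to_numpy(),
        )

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            community.normalize_intensity(_table([[0.0, 0.0], [1.0, 2.0]]))


class TestAggregateByMap:
    def test_single_category_collects_all(self):
        mat = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["s1", "s2"], columns=["a", "b"])
        agg, unmapped = community.aggregate_by_map(mat, {"a": "C", "b": "C"})
        assert unmapped == []
        np.testing.assert_allclose(agg.loc["C"].to_numpy(), [3.0, 7.0])

    def test_hand_built_tally_and_conservation(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]],
            index=["s1", "s2"], columns=["a", "b", "c", "d"],
        )
        mapping = {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        agg, _ = community.aggregate_by_map(mat, mapping)
        assert agg.loc["X", "s1"] == 3.0 and agg.loc["Y", "s2"] == 15.0
        assert agg.to_numpy().sum() == mat.to_numpy().sum()

    def test_unmapped_reported_and_empty_map_rejected(self):
        mat = pd.DataFrame([[1.0, 2.0]], index=["s"], columns=["a", "b"])
        _agg, unmapped = community.aggregate_by_map(mat, {"a": "X"})
        assert unmapped == ["b"]
        with pytest.raises(ValueError):
            community.aggregate_by_map(mat, {})
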