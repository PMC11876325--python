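"""Rate covariation: RER model, Winsorization, Fisher-scaled ERC, permutation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ratecov import erc, io, simulate
from ratecov.io import BranchLengthMatrix, ComplexSet

from conftest import make_erc_matrix


# ---------------------------------------------------------------------------
# RER model fitting
# ---------------------------------------------------------------------------

class TestFitRerModel:
    def test_scale_separability(self):
        # every row is c_g x fixed vector v -> m ∝ v, s ∝ c (common constant)
        v = np.array([1.0, 2.0, 0.5, 4.0])
        c = np.array([1.0, 3.0, 0.25])
        df = pd.DataFrame(np.outer(c, v), index=list("xyz"),
                          columns=["A", "B", "C", "D"])
        model = erc.fit_rer_model(BranchLengthMatrix(df), trim_frac=0.0)
        m = model.master_lengths.to_numpy()
        s = model.gene_scales.to_numpy()
        np.testing.assert_allclose(m / m[0], v / v[0])
        np.testing.assert_allclose(s / s[0], c / c[0])
        # and the product reproduces each cell exactly
        np.testing.assert_allclose(np.outer(s, m), df.to_numpy())

    def test_single_gene(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                          columns=["A", "B", "C"])
        model = erc.fit_rer_model(BranchLengthMatrix(df),
                                  min_genes_per_branch=1, trim_frac=0.0)
        assert model.gene_scales["g"] == pytest.approx(1.0)
        np.testing.assert_allclose(model.master_lengths.to_numpy(),
                                   [1.0, 2.0, 3.0])

    def test_trimmed_mean_against_sort_and_average(self):
        # 3 genes, one outlier column value, trim_frac=0.34:
        # floor(3 * 0.34) = 1 trimmed per tail -> the median survives
        col = np.array([1.0, 2.0, 100.0])
        df = pd.DataFrame({"A": col, "B": [1.0, 1.0, 1.0]},
                          index=["g1", "g2", "g3"])
        model = erc.fit_rer_model(BranchLengthMatrix(df), trim_frac=0.34)
        expected = np.sort(col)[1:-1].mean()  # independent sort-and-average
        assert model.master_lengths["A"] == pytest.approx(expected)
        assert expected == 2.0

    def test_sparse_branch_dropped(self):
        df = pd.DataFrame(
            [[1.0, np.nan], [2.0, np.nan], [3.0, 5.0]],
            index=["g1", "g2", "g3"], columns=["A", "B"])
        model = erc.fit_rer_model(BranchLengthMatrix(df),
                                  min_genes_per_branch=2)
        assert list(model.master_lengths.index) == ["A"]


class TestComputeRer:
    def test_exact_product_gives_zero(self):
        v = np.array([1.0, 2.0, 0.5, 4.0])
        c = np.array([1.0, 3.0, 0.25])
        df = pd.DataFrame(np.outer(c, v), index=list("xyz"),
                          columns=["A", "B", "C", "D"])
        blm = BranchLengthMatrix(df)
        model = erc.fit_rer_model(blm, trim_frac=0.0, epsilon=0.0)
        rer = erc.compute_rer(blm, model)
        np.testing.assert_allclose(rer.df.to_numpy(), 0.0, atol=1e-12)

    def test_uniform_doubling_gives_log2(self):
        # one gene uniformly 2x the reference with s_g forced to 1
        m = pd.Series([1.0, 2.0, 3.0], index=["A", "B", "C"])
        model = erc.RERModel(master_lengths=m,
                             gene_scales=pd.Series({"g": 1.0}), epsilon=0.0)
        df = pd.DataFrame([2.0 * m.to_numpy()], index=["g"], columns=m.index)
        rer = erc.compute_rer(BranchLengthMatrix(df), model)
        np.testing.assert_allclose(rer.df.to_numpy(), math.log(2.0))

    def test_hand_evaluated_log_ratio_table(self):
        # 2 genes x 3 branches, fixed model; expectations done by hand
        m = pd.Series({"A": 1.0, "B": 2.0, "C": 4.0})
        s = pd.Series({"g1": 1.0, "g2": 2.0})
        model = erc.RERModel(master_lengths=m, gene_scales=s, epsilon=0.0)
        df = pd.DataFrame([[2.0, 2.0, 4.0],
                           [1.0, 8.0, np.nan]],
                          index=["g1", "g2"], columns=["A", "B", "C"])
        rer = erc.compute_rer(BranchLengthMatrix(df), model)
        expected = np.array([
            [math.log(2.0), math.log(1.0), math.log(1.0)],
            [math.log(0.5), math.log(2.0), np.nan],
        ])
        np.testing.assert_allclose(rer.df.to_numpy(), expected)

    def test_missing_propagates(self, toy_blm):
        model = erc.fit_rer_model(toy_blm, min_genes_per_branch=2)
        rer = erc.compute_rer(toy_blm, model)
        assert np.isnan(rer.df.at["g3", "B"])
        assert rer.df.notna().drop(columns="B").all().all()

    def test_global_rescale_leaves_rer_unchanged(self, toy_blm):
        """Multiplying every branch length by one constant is absorbed."""
        model = erc.fit_rer_model(toy_blm, epsilon=0.0,
                                  min_genes_per_branch=2)
        rer = erc.compute_rer(toy_blm, model)
        scaled = BranchLengthMatrix(toy_blm.df * 7.0)
        model2 = erc.fit_rer_model(scaled, epsilon=0.0,
                                   min_genes_per_branch=2)
        rer2 = erc.compute_rer(scaled, model2)
        pd.testing.assert_frame_equal(rer.df, rer2.df)

    def test_single_gene_rescale_with_fixed_reference(self, toy_blm):
        """Scaling one gene's row cancels through its refit scale when the
        reference lengths are held fixed."""
        model = erc.fit_rer_model(toy_blm, epsilon=0.0,
                                  min_genes_per_branch=2)
        rer = erc.compute_rer(toy_blm, model)
        scaled_df = toy_blm.df.copy()
        scaled_df.loc["g2"] *= 13.0
        scaled = BranchLengthMatrix(scaled_df)
        m = model.master_lengths
        present = scaled.df[m.index].notna()
        s_new = scaled.df[m.index].sum(axis=1) / present.mul(m, axis=1).sum(axis=1)
        model2 = erc.RERModel(master_lengths=m, gene_scales=s_new, epsilon=0.0)
        rer2 = erc.compute_rer(scaled, model2)
        pd.testing.assert_frame_equal(rer.df, rer2.df)


# ---------------------------------------------------------------------------
# Winsorization
# ---------------------------------------------------------------------------

class TestWinsorize:
    @pytest.mark.parametrize("v,k,expected", [
        ([1, 2, 3, 4, 5, 6, 7], 3, [4] * 7),
        ([0, 1, 2, 3, 4, 5, 6, 7, 8, 100], 3, [3, 3, 3, 3, 4, 5, 6, 6, 6, 6]),
        ([5, 5, 5, 5], 2, [5, 5, 5, 5]),
        ([3, 1, 2], 0, [3, 1, 2]),
    ])
    def test_examples(self, v, k, expected):
        np.testing.assert_array_equal(erc.winsorize(np.array(v, float), k),
                                      expected)

    def test_negative_k_is_error(self):
        with pytest.raises(ValueError):
            erc.winsorize(np.array([1.0, 2.0]), -1)

    def test_order_preserved(self):
        v = np.array([9.0, 1.0, 5.0, 7.0, 3.0, 8.0, 2.0, 6.0, 4.0, 0.0])
        w = erc.winsorize(v, 2)
        assert np.argsort(w, kind="stable").tolist() == \
            np.argsort(np.clip(v, 2, 7), kind="stable").tolist()

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40),
           st.integers(0, 6))
    def test_idempotent(self, v, k):
        v = np.array(v)
        once = erc.winsorize(v, k)
        np.testing.assert_array_equal(erc.winsorize(once, k), once)


# ---------------------------------------------------------------------------
# pairwise ERC
# ---------------------------------------------------------------------------

def _rer_from_rows(rows: dict[str, list[float]]) -> erc.RERMatrix:
    return erc.RERMatrix(pd.DataFrame.from_dict(rows, orient="index").astype(float))


class TestErcPair:
    def test_identical_vectors_hit_the_clamp(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20).tolist()
        rer = _rer_from_rows({"a": v, "b": v})
        res = erc.erc_pair(rer, "a", "b", k=0, r_clamp=1e-6)
        assert res.n == 20
        assert res.r == pytest.approx(1 - 1e-6)
        assert res.erc == pytest.approx(math.atanh(1 - 1e-6) * math.sqrt(17))

    def test_orthogonal_vectors_give_zero(self):
        # exactly uncorrelated toy vectors -> erc == 0
        a = [1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0]
        b = [1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0, 1.0, 1.0]
        assert np.dot(a, b) == 0 and sum(a) == 0
        rer = _rer_from_rows({"a": a, "b": b})
        res = erc.erc_pair(rer, "a", "b", k=0, min_branches=10)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.erc == pytest.approx(0.0, abs=1e-12)

    def test_textbook_pearson_fisher_oracle(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        b = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0]
        rer = _rer_from_rows({"a": a, "b": b})
        res = erc.erc_pair(rer, "a", "b", k=0, min_branches=5)
        r_ref = stats.pearsonr(a, b).statistic  # independent implementation
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.erc == pytest.approx(math.atanh(r_ref) * math.sqrt(8 - 3),
                                        abs=1e-9)

    def test_shared_branch_restriction(self):
        rer = _rer_from_rows({
            "a": [1, 2, 3, 4, np.nan, 6],
            "b": [2, 4, 6, np.nan, 10, 12]})
        res = erc.erc_pair(rer, "a", "b", k=0, min_branches=4)
        assert res.n == 4
        assert res.valid

    def test_too_few_branches_invalid(self):
        rer = _rer_from_rows({"a": [1, 2, 3], "b": [1, 2, 3]})
        res = erc.erc_pair(rer, "a", "b", k=0, min_branches=10)
        assert not res.valid and math.isnan(res.erc)

    def test_constant_vector_invalid(self):
        rer = _rer_from_rows({"a": [1.0] * 12, "b": list(range(12))})
        res = erc.erc_pair(rer, "a", "b", k=0)
        assert not res.valid and math.isnan(res.erc)

    def test_missing_gene_is_error(self):
        rer = _rer_from_rows({"a": [1, 2, 3]})
        with pytest.raises(KeyError):
            erc.erc_pair(rer, "a", "zzz")

    def test_antisymmetric_under_negation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        rer = _rer_from_rows({"a": a, "b": b, "nb": (-b).tolist()})
        plus = erc.erc_pair(rer, "a", "b", k=0)
        minus = erc.erc_pair(rer, "a", "nb", k=0)
        assert minus.erc == pytest.approx(-plus.erc, abs=1e-9)


class TestErcMatrix:
    def _random_rer(self, seed, genes=10, branches=30, missing=0.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(genes, branches))
        if missing:
            X[rng.random(X.shape) < missing] = np.nan
        names = [f"g{i}" for i in range(genes)]
        return erc.RERMatrix(pd.DataFrame(X, index=names))

    def test_matches_looped_erc_pair(self):
        rer = self._random_rer(1, missing=0.15)
        m = erc.erc_matrix(rer, k=2, min_branches=8)
        for a, b in itertools.combinations(rer.genes, 2):
            ref = erc.erc_pair(rer, a, b, k=2, min_branches=8)
            got = m.values.at[a, b]
            if math.isnan(ref.erc):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(ref.erc, abs=1e-12)
            assert m.n_branches.at[a, b] == ref.n

    def test_fast_path_equals_loop_path(self):
        """With no missing data the vectorized pass must agree with the
        per-pair loop (forced by adding then removing a NaN-free mask)."""
        rer = self._random_rer(2, missing=0.0)
        fast = erc.erc_matrix(rer, k=3, min_branches=8)
        for a, b in itertools.combinations(rer.genes, 2):
            ref = erc.erc_pair(rer, a, b, k=3, min_branches=8)
            assert fast.values.at[a, b] == pytest.approx(ref.erc, abs=1e-10)

    def test_symmetry_and_diagonal(self):
        rer = self._random_rer(3, missing=0.1)
        m = erc.erc_matrix(rer, min_branches=8)
        V = m.values.to_numpy()
        assert np.array_equal(V, V.T, equal_nan=True)
        assert np.isnan(np.diag(V)).all()

    def test_gene_subset(self):
        rer = self._random_rer(4)
        m = erc.erc_matrix(rer, genes=["g1", "g5", "g7"], min_branches=8)
        assert m.genes == ["g1", "g5", "g7"]
        assert np.isfinite(m.values.to_numpy()).sum() == 6  # 3 pairs x 2


# ---------------------------------------------------------------------------
# between-set values and the permutation test
# ---------------------------------------------------------------------------

class TestBetweenSetValues:
    def test_disjoint_pair_counts_match_complex_sizes(self):
        genes = [f"s{i}" for i in range(4)] + [f"c{i}" for i in range(11)]
        vals = {(a, b): 1.0 for a, b in itertools.combinations(genes, 2)}
        m = make_erc_matrix(genes, vals)
        shu = ComplexSet("shu", tuple(genes[:4]))
        cmg = ComplexSet("cmg", tuple(genes[4:]))
        assert len(erc.between_set_values(m, shu, cmg)) == 44

    def test_within_set_counts_pairs_once(self):
        genes = ["a", "b", "c"]
        vals = {(x, y): 1.0 for x, y in itertools.combinations(genes, 2)}
        m = make_erc_matrix(genes, vals)
        s = ComplexSet("s", ("a", "b", "c"))
        assert len(erc.between_set_values(m, s, s)) == 3  # C(3,2)

    def test_absent_members_dropped_with_warning(self):
        genes = ["a", "b", "c"]
        vals = {(x, y): 1.0 for x, y in itertools.combinations(genes, 2)}
        m = make_erc_matrix(genes, vals)
        with pytest.warns(UserWarning, match="absent"):
            out = erc.between_set_values(
                m, ComplexSet("s", ("a", "ghost")), ComplexSet("t", ("b", "c")))
        assert len(out) == 2

    def test_no_pairs_is_error(self):
        m = make_erc_matrix(["a", "b"], {("a", "b"): 1.0})
        with pytest.raises(ValueError, match="no pairs"):
            erc.between_set_values(m, ComplexSet("s", ("zz",)),
                                   ComplexSet("t", ("qq",)))


class TestComplexPermutationTest:
    def _toy_matrix(self):
        """6 genes; every a-b value exceeds every a-other value."""
        genes = ["a1", "a2", "b1", "b2", "u1", "u2"]
        vals = {}
        for x, y in itertools.combinations(genes, 2):
            in_a = {x, y} <= {"a1", "a2"}
            a_to_b = ({x, y} & {"a1", "a2"}) and ({x, y} & {"b1", "b2"})
            vals[(x, y)] = 5.0 if (a_to_b and not in_a) else 0.5
        return make_erc_matrix(genes, vals)

    def test_exhaustive_enumeration_oracle(self):
        m = self._toy_matrix()
        a = ComplexSet("a", ("a1", "a2"))
        b = ComplexSet("b", ("b1", "b2"))
        res = erc.complex_permutation_test(m, a, b, exhaustive=True)
        # universe = {b1, b2, u1, u2}; C(4, 2) = 6 subsets; only the true b
        # attains the observed mean, and ties count -> p = 2/7
        assert res.n_permutations == 6
        assert res.p_empirical == pytest.approx(2 / 7)
        assert res.observed_stat == pytest.approx(5.0)

    def test_plus_one_correction_floor(self):
        m = self._toy_matrix()
        a = ComplexSet("a", ("a1", "a2"))
        b = ComplexSet("b", ("b1", "b2"))
        res = erc.complex_permutation_test(m, a, b, n_perm=1000, seed=0,
                                           universe=["u1", "u2", "b1"])
        # every size-2 draw from {u1, u2, b1} has mean < 5.0, so the
        # +1 correction pins p at its floor
        assert res.p_empirical == pytest.approx(1 / 1001)

    def test_sampled_converges_to_exhaustive(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(10)]
        vals = {p: float(rng.normal()) for p in itertools.combinations(genes, 2)}
        m = make_erc_matrix(genes, vals)
        a = ComplexSet("a", tuple(genes[:3]))
        b = ComplexSet("b", tuple(genes[3:5]))
        ex = erc.complex_permutation_test(m, a, b, exhaustive=True)
        n_perm = 4000
        sam = erc.complex_permutation_test(m, a, b, n_perm=n_perm, seed=5)
        assert abs(sam.p_empirical - ex.p_empirical) <= 2 / math.sqrt(n_perm)

    def test_universe_too_small_is_error(self):
        m = self._toy_matrix()
        a = ComplexSet("a", ("a1", "a2"))
        b = ComplexSet("b", ("b1", "b2"))
        with pytest.raises(ValueError, match="universe"):
            erc.complex_permutation_test(m, a, b, universe=["u1"])

    def test_seed_reproducibility(self):
        m = self._toy_matrix()
        a = ComplexSet("a", ("a1", "a2"))
        b = ComplexSet("b", ("b1", "b2"))
        r1 = erc.complex_permutation_test(m, a, b, n_perm=200, seed=42)
        r2 = erc.complex_permutation_test(m, a, b, n_perm=200, seed=42)
        assert r1 == r2
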