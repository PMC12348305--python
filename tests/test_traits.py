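import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexistkit import (
    SyntheticTraitSpec,
    TraitRecord,
    aggregate_traits,
    anova_pc_scores,
    gen_traits,
    impute_iterative_pca,
    pca_traits,
    permanova,
)
from coexistkit.traits import (
    DegenerateDistanceError,
    TraitDataError,
    read_trait_records,
)


def _rank_k_table(n, p, k, rng, scale=1.0):
    U = rng.normal(size=(n, k))
    V = rng.normal(size=(k, p))
    return pd.DataFrame(U @ V * scale + 10.0, columns=[f"T{i}" for i in range(p)])


class TestAggregateTraits:
    def test_mean_within_species_source_group(self):
        recs = [
            TraitRecord("A", "X", "H", 10.0),
            TraitRecord("A", "X", "H", 20.0),
        ]
        with pytest.warns(UserWarning, match="all-missing"):
            table = aggregate_traits(recs)
        assert table.loc[("A", "X"), "H"] == 15.0

    def test_absent_trait_is_missing(self):
        with pytest.warns(UserWarning, match="all-missing"):
            table = aggregate_traits(
                [TraitRecord("A", "X", "H", 10.0), TraitRecord("B", "Y", "SM", 3.0)]
            )
        assert np.isnan(table.loc[("A", "X"), "SM"])

    def test_single_record_identity(self):
        with pytest.warns(UserWarning, match="all-missing"):
            table = aggregate_traits([TraitRecord("A", "X", "SLA", 12.5)])
        assert table.loc[("A", "X"), "SLA"] == 12.5

    def test_unknown_trait_rejected(self):
        with pytest.raises(TraitDataError):
            TraitRecord("A", "X", "bogus", 1.0)

    def test_read_trait_records_round_trip(self, tmp_path):
        path = tmp_path / "tr.csv"
        path.write_text("species,source,trait,value\nA,X,H,10\nA,X,N,2.1\n")
        recs = read_trait_records(path)
        assert len(recs) == 2 and recs[1].trait == "N"


class TestImputation:
    def test_complete_table_passes_through_unchanged(self):
        rng = np.random.default_rng(0)
        table = _rank_k_table(10, 6, 3, rng)
        out = impute_iterative_pca(table, ncomp=3)
        pd.testing.assert_frame_equal(out, table)

    def test_rank1_deleted_cell_recovered(self):
        rng = np.random.default_rng(1)
        table = _rank_k_table(8, 6, 1, rng)
        holed = table.copy()
        holed.iloc[2, 3] = np.nan
        out = impute_iterative_pca(holed, ncomp=1, regularized=False, tol=1e-14,
                                   max_iter=10_000)
        assert abs(out.iloc[2, 3] - table.iloc[2, 3]) < 1e-6

    def test_observed_cells_bit_identical(self):
        rng = np.random.default_rng(2)
        table = _rank_k_table(12, 6, 3, rng)
        mask = rng.random(table.shape) < 0.2
        holed = table.mask(mask)
        out = impute_iterative_pca(holed, ncomp=3)
        obs = ~holed.isna()
        assert (out.to_numpy()[obs.to_numpy()] == table.to_numpy()[obs.to_numpy()]).all()

    def test_error_shrinks_with_less_missingness(self):
        """Mean completion error is non-increasing as gaps get rarer."""
        fractions = (0.4, 0.25, 0.1)
        mean_err = []
        for frac in fractions:
            errs = []
            for ss in np.random.SeedSequence(5).spawn(50):
                rng = np.random.default_rng(ss)
                table = _rank_k_table(15, 6, 3, rng)
                mask = rng.random(table.shape) < frac
                mask[mask.all(axis=1)] = False
                holed = table.mask(mask)
                if holed.isna().all(axis=0).any():
                    continue
                out = impute_iterative_pca(holed, ncomp=3)
                errs.append(np.abs(out.to_numpy() - table.to_numpy())[mask].mean())
            mean_err.append(np.mean(errs))
        assert mean_err[0] >= mean_err[1] >= mean_err[2]

    def test_empty_column_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(TraitDataError):
            impute_iterative_pca(table, ncomp=1)


class TestPCA:
    def test_collinear_points_load_on_single_axis(self):
        t = np.linspace(-2, 2, 20)
        table = pd.DataFrame({"x": t, "y": t})
        res = pca_traits(table)
        assert res.var_explained[0] == pytest.approx(1.0)
        assert res.loadings["PC1"].to_numpy() == pytest.approx(
            np.array([1, 1]) / np.sqrt(2)
        )

    def test_variance_fractions_conserved(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("ABCDEF"))
        res = pca_traits(table)
        assert res.var_explained.sum() == pytest.approx(1.0)
        assert (np.diff(res.var_explained) <= 1e-12).all()

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.normal(size=(25, 5)))
        L = pca_traits(table).loadings.to_numpy()
        assert L.T @ L == pytest.approx(np.eye(L.shape[1]), abs=1e-10)

    def test_isotropic_cloud_splits_variance_evenly(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.normal(size=(4000, 4)))
        res = pca_traits(table)
        assert res.var_explained == pytest.approx(np.full(4, 0.25), abs=0.03)

    def test_scores_invariant_to_row_order_up_to_sign(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(rng.normal(size=(15, 4)))
        perm = rng.permutation(15)
        a = pca_traits(table).scores.to_numpy()
        b = pca_traits(table.iloc[perm]).scores.to_numpy()
        assert np.abs(a[perm]) == pytest.approx(np.abs(b), abs=1e-9)

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10),
                              "c": rng.normal(size=10)})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_traits(table)
        assert list(res.loadings.index) == ["a", "c"]


class TestAnovaPCScores:
    def test_equal_groups_give_near_zero_f(self):
        scores = pd.DataFrame({"PC1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        res = anova_pc_scores(scores, ["a"] * 3 + ["b"] * 3)
        assert res["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_oracle_value(self):
        # brute-force sums of squares give F = 150 for {1,2,3} vs {11,12,13}
        scores = pd.DataFrame({"PC1": [1.0, 2.0, 3.0, 11.0, 12.0, 13.0]})
        res = anova_pc_scores(scores, ["a"] * 3 + ["b"] * 3)
        assert res["F"].iloc[0] == pytest.approx(150.0)
        assert res["p"].iloc[0] < 0.01

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=24)
        labels = np.repeat(list("abc"), 8)
        res = anova_pc_scores(pd.DataFrame({"PC1": x}), labels)
        grand = x.mean()
        ssb = sum(8 * (x[labels == g].mean() - grand) ** 2 for g in "abc")
        ssw = sum(((x[labels == g] - x[labels == g].mean()) ** 2).sum() for g in "abc")
        f_oracle = (ssb / 2) / (ssw / 21)
        assert res["F"].iloc[0] == pytest.approx(f_oracle, abs=1e-10)

    def test_tiny_group_rejected(self):
        scores = pd.DataFrame({"PC1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            anova_pc_scores(scores, ["a", "a", "b"])


class TestPermanova:
    def test_univariate_equals_anova_f(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=18)
        g = np.repeat(list("abc"), 6)
        res = permanova(pd.DataFrame({"t": x}), g, n_perm=99, seed=0,
                        standardize=False)
        f, _ = stats.f_oneway(*[x[g == k] for k in "abc"])
        assert res.pseudo_F == pytest.approx(f, abs=1e-9)

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(10)
        X = rng.normal(size=(15, 4))
        g = np.repeat(list("abc"), 5)
        d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        ref = skbio_permanova(DistanceMatrix(d), g, permutations=0)
        res = permanova(pd.DataFrame(X), g, n_perm=99, seed=0, standardize=False)
        assert res.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_separated_clusters_reach_minimum_p(self):
        # group sizes large enough that a random relabeling essentially never
        # reproduces the true partition (2/C(20,10) per shuffle)
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(30, 0.1, (10, 3))])
        res = permanova(pd.DataFrame(X), ["a"] * 10 + ["b"] * 10, n_perm=199, seed=1)
        assert res.p_perm == pytest.approx(1 / 200)

    def test_p_bounded_below_by_add_one(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(12, 3))
        res = permanova(pd.DataFrame(X), ["a"] * 6 + ["b"] * 6, n_perm=99, seed=2)
        assert res.p_perm >= 1 / 100

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(12, 3))
        g = ["a"] * 6 + ["b"] * 6
        a = permanova(pd.DataFrame(X), g, n_perm=199, seed=42)
        b = permanova(pd.DataFrame(X), g, n_perm=199, seed=42)
        assert a.p_perm == b.p_perm

    def test_identical_points_rejected(self):
        X = np.ones((6, 3))
        with pytest.raises(DegenerateDistanceError):
            permanova(pd.DataFrame(X), ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)

    def test_null_pvalues_approximately_uniform(self):
        """Labels independent of data: permutation p should be ~Uniform."""
        ps = []
        for ss in np.random.SeedSequence(14).spawn(200):
            rng = np.random.default_rng(ss)
            X = rng.normal(size=(12, 3))
            g = rng.permutation(["a"] * 6 + ["b"] * 6)
            s = int(ss.generate_state(1, dtype=np.uint32)[0] % 2**31)
            ps.append(permanova(pd.DataFrame(X), g, n_perm=99, seed=s).p_perm)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSyntheticTraitWorkflow:
    def test_large_offsets_perfectly_separated(self):
        spec = SyntheticTraitSpec(
            species_offsets={"Pserotina": 50.0, "Qrubra": -50.0, "Cdentata": 0.0},
            within_sd=0.01,
            missing_fraction=0.0,
            seed=15,
        )
        table = aggregate_traits(gen_traits(spec))
        species = [i[0] for i in table.index]
        res = permanova(table, species, n_perm=199, seed=3)
        assert res.p_perm == pytest.approx(1 / 200)
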