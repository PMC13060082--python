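import numpy as np
import pandas as pd
import pytest
from scipy import stats

from risefall.vulnerability import (VulnerabilityAxis, benjamini_hochberg,
                                    categorize_pathways, category_enrichment,
                                    compare_axes, extract_axis,
                                    gene_regressions, gsea_preranked,
                                    select_regions, standardize)


class TestStandardize:
    def test_hand_value(self):
        assert np.allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_idempotent(self, rng):
        z = standardize(rng.normal(3, 2, 50))
        assert np.abs(standardize(z) - z).max() < 1e-12

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])


class TestSelectRegions:
    def test_all_negative_beta_errors(self):
        with pytest.raises(ValueError):
            select_regions([-1.0, -0.5], [True, True], [True, True])

    def test_positive_and_updated_only(self):
        mask = select_regions([0.5, -0.1, 0.3], [True, True, False],
                              [True, True, True])
        assert mask.tolist() == [True, False, False]


class TestGeneRegressions:
    def _zs(self, rng, n=50):
        return standardize(rng.normal(size=n)), standardize(rng.normal(size=n))

    def test_pure_beta_gene(self, rng):
        zb, zg = self._zs(rng)
        expr = pd.DataFrame({"g1": zb})
        out = gene_regressions(expr, zb, zg)
        assert out.loc["g1", "a"] == pytest.approx(1.0, abs=1e-10)
        assert out.loc["g1", "b"] == pytest.approx(0.0, abs=1e-10)
        assert out.loc["g1", "intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_affine_gamma_gene(self, rng):
        zb, zg = self._zs(rng)
        expr = pd.DataFrame({"g1": 2 * zg + 5})
        out = gene_regressions(expr, zb, zg)
        assert out.loc["g1", "a"] == pytest.approx(0.0, abs=1e-10)
        assert out.loc["g1", "b"] == pytest.approx(2.0, abs=1e-10)
        assert out.loc["g1", "intercept"] == pytest.approx(5.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        zb, zg = self._zs(rng)
        expr = pd.DataFrame(rng.normal(size=(50, 8)),
                            columns=[f"g{i}" for i in range(8)])
        out = gene_regressions(expr, zb, zg)
        X = np.column_stack([np.ones(50), zb, zg])
        coef = np.linalg.solve(X.T @ X, X.T @ expr.values)
        assert np.abs(out["intercept"].values - coef[0]).max() < 1e-8
        assert np.abs(out["a"].values - coef[1]).max() < 1e-8
        assert np.abs(out["b"].values - coef[2]).max() < 1e-8

    def test_collinear_predictors_rejected(self, rng):
        zb = standardize(rng.normal(size=30))
        expr = pd.DataFrame({"g1": zb})
        with pytest.raises(ValueError, match="collinear"):
            gene_regressions(expr, zb, zb * (1 + 1e-12))


class TestExtractAxis:
    def test_collinear_cloud(self, rng):
        a = rng.normal(size=200)
        coeffs = pd.DataFrame({"a": a, "b": 2 * a})
        ax = extract_axis(coeffs)
        expected = np.array([1.0, 2.0]) / np.sqrt(5)
        assert np.allclose(ax.loadings, expected, atol=1e-10)
        assert ax.variance_explained_pc1 == pytest.approx(1.0)

    def test_isotropic_cloud_splits_variance(self):
        rng = np.random.default_rng(7)
        coeffs = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        ax = extract_axis(coeffs)
        assert 0.48 < ax.variance_explained_pc1 < 0.52

    def test_planted_anisotropic_axis_recovered(self):
        rng = np.random.default_rng(3)
        v = np.array([-0.37, 0.93])
        v = v / np.linalg.norm(v)
        w = np.array([-v[1], v[0]])
        pts = (np.outer(rng.normal(0, 1, 5000), v)
               + np.outer(rng.normal(0, 0.1, 5000), w))
        ax = extract_axis(pd.DataFrame(pts, columns=["a", "b"]))
        assert abs(ax.loadings @ v) > 0.99
        assert ax.c2 >= 0

    def test_eta_invariant_to_affine_rescaling_of_raw_parameters(self, rng):
        beta = rng.normal(1, 0.5, 40)
        gamma = rng.normal(0.5, 0.2, 40)
        coeffs = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        ax1 = extract_axis(coeffs, standardize(beta), standardize(gamma))
        ax2 = extract_axis(coeffs, standardize(3 * beta + 1),
                           standardize(0.5 * gamma - 2))
        assert np.allclose(ax1.eta, ax2.eta, atol=1e-10)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            extract_axis(pd.DataFrame({"a": [1, 2], "b": [1, 2]}))


def _es_loop_oracle(scores, members, p=1.0):
    """Exhaustive running-sum evaluation on a small ranked list."""
    order = np.argsort(-scores.values, kind="stable")
    genes = scores.index.to_numpy()[order]
    vals = scores.values[order]
    hits = np.isin(genes, list(members))
    nr = np.sum(np.abs(vals[hits]) ** p)
    nh = hits.sum()
    run, best = 0.0, 0.0
    for i in range(genes.size):
        if hits[i]:
            run += np.abs(vals[i]) ** p / nr
        else:
            run -= 1.0 / (genes.size - nh)
        if abs(run) > abs(best) or (abs(run) == abs(best) and run > best):
            best = run
    return best


class TestGseaPreranked:
    def test_hand_evaluated_top_two_set(self):
        scores = pd.Series([0.9, 0.5, -0.2, -0.8], index=list("abcd"))
        out = gsea_preranked(scores, {"top": ["a", "b"]}, min_size=2,
                             n_perm=50, rng_seed=0)
        assert out.loc["top", "es"] == pytest.approx(1.0)

    def test_weight_zero_reduces_to_classic_ks(self, rng):
        n = 40
        scores = pd.Series(rng.normal(size=n),
                           index=[f"g{i}" for i in range(n)])
        members = list(scores.nlargest(8).index)
        out = gsea_preranked(scores, {"s": members}, weight_p=0.0, min_size=2,
                             n_perm=10, rng_seed=0)
        # unweighted: hit steps are 1/Nh, so ES is the max D over positions
        order = np.argsort(-scores.values, kind="stable")
        hits = np.isin(scores.index.to_numpy()[order], members)
        run = np.cumsum(np.where(hits, 1 / 8, -1 / (n - 8)))
        expected = run[np.argmax(np.abs(run))]
        assert out.loc["s", "es"] == pytest.approx(expected, abs=1e-12)

    def test_matches_loop_oracle_on_8_gene_toys(self, rng):
        for trial in range(10):
            scores = pd.Series(rng.normal(size=8),
                               index=[f"g{i}" for i in range(8)])
            members = rng.choice(scores.index, size=3, replace=False)
            out = gsea_preranked(scores, {"s": list(members)}, min_size=2,
                                 n_perm=10, rng_seed=trial)
            assert out.loc["s", "es"] == pytest.approx(
                _es_loop_oracle(scores, members), abs=1e-12)

    def test_null_pvalues_are_uniform(self):
        # random scores, random sets: the permutation p-values should be
        # uniform on (0, 1]
        rng = np.random.default_rng(42)
        n = 300
        scores = pd.Series(rng.normal(size=n),
                           index=[f"g{i}" for i in range(n)])
        sets = {
            f"s{k}": list(rng.choice(scores.index, size=15, replace=False))
            for k in range(200)
        }
        out = gsea_preranked(scores, sets, n_perm=1000, min_size=10,
                             rng_seed=9)
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.05

    def test_set_covering_all_genes_rejected(self):
        scores = pd.Series([1.0, 0.5, -1.0], index=list("abc"))
        with pytest.raises(ValueError):
            gsea_preranked(scores, {"all": list("abc")}, min_size=1)

    def test_enrichment_scores_match_gseapy(self, rng):
        # independent cross-check of the weighted running-sum ES against
        # the reference pre-ranked implementation
        import gseapy

        genes = [f"G{i}" for i in range(80)]
        scores = pd.Series(rng.normal(size=80), index=genes)
        sets = {"S1": genes[:15], "S2": genes[30:55], "S3": genes[60:75]}
        mine = gsea_preranked(scores, sets, weight_p=1.0, n_perm=10,
                              min_size=5, rng_seed=0)
        rnk = scores.sort_values(ascending=False).reset_index()
        rnk.columns = ["gene", "score"]
        ref = gseapy.prerank(rnk=rnk, gene_sets=sets, permutation_num=5,
                             min_size=5, max_size=60, seed=1, outdir=None,
                             threads=1, no_plot=True).res2d.set_index("Term")
        for name in sets:
            assert mine.loc[name, "es"] == pytest.approx(
                float(ref.loc[name, "ES"]), abs=1e-6)


class TestCategoryEnrichment:
    def test_balanced_extreme_table(self):
        cats = pd.Series(["m"] * 3 + ["o"] * 3, index=[f"p{i}" for i in range(6)])
        sig = pd.Series([True] * 3 + [False] * 3, index=cats.index)
        out = category_enrichment(cats, sig)
        # 2x2 table [[3,0],[0,3]]: two-sided hypergeometric p = 2/20
        assert out.loc["m", "p"] == pytest.approx(0.1, abs=1e-10)
        assert out.loc["m", "log2_odds_ratio"] > 0

    def test_concentrated_category_has_smallest_p(self, rng):
        cats = pd.Series(rng.choice(["m", "s", "o"], size=60),
                         index=[f"p{i}" for i in range(60)])
        sig = pd.Series(cats == "m", index=cats.index)
        out = category_enrichment(cats, sig)
        assert out["p"].idxmin() == "m"

    def test_independent_flags_control_type_i(self):
        # q > 0.05 in most seeded repeats when flags ignore category
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            cats = pd.Series(rng.choice(["m", "h", "s", "n", "o"], size=80),
                             index=[f"p{i}" for i in range(80)])
            sig = pd.Series(rng.random(80) < 0.2, index=cats.index)
            out = category_enrichment(cats, sig)
            if (out["q"] < 0.05).any():
                hits += 1
        assert hits <= 3  # 94%+ of repeats stay null

    def test_keyword_mapping_defaults(self):
        cats = categorize_pathways([
            "Oxidative phosphorylation", "Proteasome", "Synaptic vesicle cycle",
            "Parkinson disease", "Ribosome biogenesis",
        ])
        assert cats.tolist() == [
            "metabolism", "protein homeostasis", "synaptic function",
            "neurodegenerative disease", "other",
        ]


class TestCompareAxes:
    def _axis(self, c1, c2, corr=None):
        ax = VulnerabilityAxis(c1=c1, c2=c2, variance_explained_pc1=0.9)
        if corr is not None:
            ax.gene_axis_corr = corr
        return ax

    def test_identical_axes_fixed_point(self, rng):
        corr = pd.Series(rng.uniform(-1, 1, 30),
                         index=[f"g{i}" for i in range(30)])
        a = self._axis(-0.37, 0.93, corr)
        out = compare_axes(a, a)
        assert out["cosine"] == pytest.approx(1.0)
        assert out["angle_deg"] == pytest.approx(0.0, abs=1e-6)
        assert out["ols_slope"] == pytest.approx(1.0)
        assert out["sign_agreement"] == pytest.approx(1.0)

    def test_printed_loading_vectors(self):
        # the two reported PC1 loading pairs agree to ~0.984 / 10.2 degrees
        # at 2-decimal precision
        out = compare_axes(self._axis(-0.37, 0.93), self._axis(-0.20, 0.98))
        assert out["cosine"] == pytest.approx(0.984, abs=0.001)
        assert out["angle_deg"] == pytest.approx(10.2, abs=0.1)

    def test_orthogonal_axes(self):
        out = compare_axes(self._axis(1.0, 0.0), self._axis(0.0, 1.0))
        assert out["cosine"] == pytest.approx(0.0, abs=1e-12)
        assert out["angle_deg"] == pytest.approx(90.0)

    def test_disjoint_gene_sets_rejected(self):
        a = self._axis(0.0, 1.0, pd.Series([0.5], index=["g1"]))
        b = self._axis(0.0, 1.0, pd.Series([0.5], index=["g2"]))
        with pytest.raises(ValueError):
            compare_axes(a, b)


class TestBenjaminiHochberg:
    def test_step_up_hand_values(self):
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.04]),
                           [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        assert np.all(benjamini_hochberg([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_monotone_in_sorted_order(self, rng):
        q = benjamini_hochberg(rng.random(100))
        p = rng.random(100)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
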