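import numpy as np
import pandas as pd
import pytest
from scipy import stats

from risefall.celltype import (CellCluster, clr_transform,
                               composition_from_counts,
                               estimate_regional_counts, monoaminergic_score,
                               paired_hemisphere_permutation, spearman)
from risefall.synthetic import gen_celltypes


class TestEstimateRegionalCounts:
    def test_proportional_split(self):
        clusters = [CellCluster("c1", 100, "gabaergic", {"A": 0.7, "B": 0.3})]
        out = estimate_regional_counts(clusters, {}, ["A", "B"])
        assert out.loc["A", "gabaergic"] == pytest.approx(70.0)
        assert out.loc["B", "gabaergic"] == pytest.approx(30.0)

    def test_one_step_ontology_propagation(self):
        clusters = [CellCluster("c1", 50, "dopaminergic", {"C": 1.0})]
        out = estimate_regional_counts(clusters, {"C": "A"}, ["A"])
        assert out.loc["A", "dopaminergic"] == pytest.approx(50.0)

    def test_three_level_ontology_conserves_totals(self, rng):
        # per-cell loop oracle over a mixed three-level toy ontology
        ontology = {"leaf1": "mid", "leaf2": "mid", "mid": "A", "other": "B"}
        targets = ["A", "B"]
        clusters = [
            CellCluster(f"c{k}", float(rng.integers(10, 200)),
                        rng.choice(["glutamatergic", "gabaergic"]),
                        {s: f for s, f in zip(
                            ["leaf1", "leaf2", "A", "other"],
                            rng.dirichlet(np.ones(4)) * 0.9)})
            for k in range(6)
        ]
        out = estimate_regional_counts(clusters, ontology, targets)
        # loop oracle
        expected = {t: {} for t in targets}
        for cl in clusters:
            for s, f in cl.frequencies.items():
                node = s
                while node not in targets:
                    node = ontology[node]
                d = expected[node]
                d[cl.neurotransmitter_class] = d.get(
                    cl.neurotransmitter_class, 0.0) + cl.size * f
        for t in targets:
            for c, v in expected[t].items():
                assert out.loc[t, c] == pytest.approx(v, abs=1e-10)
        allocated = sum(cl.size * f for cl in clusters
                        for f in cl.frequencies.values())
        assert out.values.sum() == pytest.approx(allocated, abs=1e-8)

    def test_unreachable_structure_dropped_with_warning(self, caplog):
        clusters = [CellCluster("c1", 10, "gabaergic", {"X": 1.0})]
        out = estimate_regional_counts(clusters, {}, ["A"])
        assert out.values.sum() == 0.0

    def test_cyclic_ontology_rejected(self):
        clusters = [CellCluster("c1", 10, "gabaergic", {"X": 1.0})]
        with pytest.raises(ValueError, match="cycle"):
            estimate_regional_counts(clusters, {"X": "Y", "Y": "X"}, ["A"])

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError):
            CellCluster("c1", -1, "gabaergic", {"A": 1.0})


class TestClr:
    def test_uniform_composition_maps_to_zero(self):
        out = clr_transform(np.array([0.25, 0.25, 0.25, 0.25]))
        assert np.allclose(out, 0.0)

    def test_hand_value(self):
        out = clr_transform(np.array([0.5, 0.25, 0.25]))
        assert np.allclose(out, [0.4621, -0.2310, -0.2310], atol=1e-4)

    def test_rows_sum_to_zero(self, rng):
        X = rng.dirichlet(np.ones(5), size=20)
        out = clr_transform(X)
        assert np.abs(out.sum(axis=1)).max() < 1e-10

    def test_zero_entries_replaced(self):
        out = clr_transform(np.array([[0.6, 0.4, 0.0]]))
        assert np.all(np.isfinite(out))
        assert abs(out.sum()) < 1e-10

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            clr_transform(np.array([[0.0, 0.0]]))


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman([1, 2, 3, 4], [10, 20, 25, 100]) == pytest.approx(1.0)

    def test_hand_value(self):
        assert spearman([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        x = rng.integers(0, 4, size=30).astype(float)
        y = rng.integers(0, 4, size=30).astype(float)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestPairedPermutation:
    def _setup(self, rng, n_regions=20, coupled=False):
        bases = [f"r{i}" for i in range(n_regions)]
        pred = pd.DataFrame({"x": rng.normal(size=n_regions)}, index=bases)
        eta_base = (pred["x"].values + rng.normal(0, 0.5, n_regions)
                    if coupled else rng.normal(size=n_regions))
        eta = np.repeat(eta_base, 2)
        base = np.repeat(bases, 2)
        return eta, base, pred

    def test_perfect_association_hits_add_one_floor(self, rng):
        bases = [f"r{i}" for i in range(20)]
        pred = pd.DataFrame({"x": np.arange(20.0)}, index=bases)
        eta = np.repeat(np.arange(20.0), 2)
        out = paired_hemisphere_permutation(eta, np.repeat(bases, 2), pred,
                                            n_perm=199, rng_seed=0)
        assert out.loc["x", "rho"] == pytest.approx(1.0)
        assert out.loc["x", "p"] == pytest.approx(1 / 200)

    def test_type_i_error_calibrated(self):
        # independent eta and predictor: p < 0.05 in about 5% of repeats
        hits = 0
        n_rep = 400
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            eta, base, pred = self._setup(rng)
            out = paired_hemisphere_permutation(eta, base, pred, n_perm=99,
                                                rng_seed=seed + 1)
            if out.loc["x", "p"] < 0.05:
                hits += 1
        assert 0.02 <= hits / n_rep <= 0.08

    def test_missing_predictor_region_rejected(self, rng):
        eta, base, pred = self._setup(rng)
        with pytest.raises(ValueError):
            paired_hemisphere_permutation(eta, base, pred.iloc[:-1],
                                          n_perm=10, rng_seed=0)


class TestMonoaminergicScore:
    def test_equal_components_give_that_value(self):
        df = pd.DataFrame(
            {c: [0.3, -0.1] for c in
             ("dopaminergic", "noradrenergic", "serotonergic", "histaminergic")}
        )
        df["gabaergic"] = [5.0, 5.0]
        out = monoaminergic_score(df)
        assert np.allclose(out.values, [0.3, -0.1])

    def test_order_invariant(self, rng):
        cols = ["dopaminergic", "noradrenergic", "serotonergic",
                "histaminergic", "other"]
        df = pd.DataFrame(rng.normal(size=(5, 5)), columns=cols)
        a = monoaminergic_score(df)
        b = monoaminergic_score(df[cols[::-1]])
        assert np.allclose(a.values, b.values)

    def test_missing_class_listed_in_error(self):
        df = pd.DataFrame({"dopaminergic": [0.1]})
        with pytest.raises(ValueError, match="noradrenergic"):
            monoaminergic_score(df)


class TestGenCelltypes:
    def test_rows_on_simplex(self, rng):
        eta = rng.normal(size=12)
        comp = gen_celltypes(eta, [f"r{i}" for i in range(12)], rng_seed=3)
        assert np.allclose(comp.sum(axis=1), 1.0)
        assert (comp.values >= 0).all()

    def test_zero_coupling_is_null(self):
        # Spearman(monoaminergic score, eta) stays near zero without coupling
        inside = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            eta = rng.normal(size=30)
            comp = gen_celltypes(eta, [f"r{i}" for i in range(30)],
                                 coupling_strength=0.0, rng_seed=seed)
            rho = spearman(monoaminergic_score(clr_transform(comp)).values, eta)
            if abs(rho) < 0.35:
                inside += 1
        assert inside >= 36  # ~95% of seeds

    def test_strong_coupling_detectable(self):
        strong = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            eta = rng.normal(size=30)
            comp = gen_celltypes(eta, [f"r{i}" for i in range(30)],
                                 coupling_strength=3.0, rng_seed=seed)
            rho = spearman(monoaminergic_score(clr_transform(comp)).values, eta)
            if rho > 0.5:
                strong += 1
        assert strong >= 18  # >= 90% of seeds
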