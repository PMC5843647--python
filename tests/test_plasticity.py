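import numpy as np
import pandas as pd
import pytest
import skbio

from plastigene import (
    compare_slope_intercept,
    cross_env_correlation,
    euclidean_distances,
    nj_tree,
    pc_anova,
    pca,
    reaction_norms,
)
from plastigene.plasticity import ReactionNormTable
from tests.conftest import make_expression


def _three_family_design(reps=1):
    rows = []
    for fam in ("F1", "F2", "F3"):
        for season in ("dry", "wet"):
            for food in ("control", "stress"):
                for r in range(reps):
                    rows.append((f"{fam}_{season}_{food}_{r}", fam, season, food))
    return pd.DataFrame(
        rows, columns=["sample", "family", "season", "food"]
    ).set_index("sample")


class TestReactionNorms:
    def test_two_point_ols(self):
        design = _three_family_design()
        expr = make_expression(
            design, lambda fam, season, food: [2.0 if season == "wet" else 1.0]
        )
        rn = reaction_norms(expr, design)
        assert np.allclose(rn.intercept, 1.0)
        assert np.allclose(rn.slope, 1.0)
        assert np.allclose(rn.summary["sd_slope"], 0.0)
        assert np.allclose(rn.summary["sd_intercept"], 0.0)

    def test_hand_computed_slope_spread(self):
        design = _three_family_design()
        slopes = {"F1": 1.0, "F2": 1.5, "F3": 2.0}
        expr = make_expression(
            design,
            lambda fam, season, food: [slopes[fam] if season == "wet" else 0.0],
        )
        rn = reaction_norms(expr, design)
        assert rn.summary["sd_slope"].iloc[0] == pytest.approx(0.5)
        assert rn.summary["cv_slope"].iloc[0] == pytest.approx(1 / 3)

    def test_slope_equals_wet_minus_dry_mean(self, small_experiment):
        _, design, counts, _ = small_experiment
        expr = np.log2(counts + 1)
        rn = reaction_norms(expr, design)
        fam = design["family"].to_numpy()
        season = design["season"].to_numpy()
        for f in rn.families[:3]:
            wet = expr.loc[:, (fam == f) & (season == "wet")].mean(axis=1)
            dry = expr.loc[:, (fam == f) & (season == "dry")].mean(axis=1)
            assert np.allclose(rn.slope[f], wet - dry, atol=1e-12)
            assert np.allclose(rn.intercept[f], dry, atol=1e-12)

    def test_family_missing_a_season_dropped(self):
        design = _three_family_design()
        design = design[~((design["family"] == "F3") & (design["season"] == "wet"))]
        expr = make_expression(design, lambda fam, season, food: [1.0, 2.0])
        with pytest.warns(UserWarning, match="F3"):
            rn = reaction_norms(expr, design)
        assert rn.families == ["F1", "F2"]
        assert rn.dropped_families == ["F3"]


def _rn_from_sds(sd_slope, sd_intercept):
    n = len(sd_slope)
    summary = pd.DataFrame(
        {
            "mean_intercept": np.ones(n),
            "sd_intercept": sd_intercept,
            "cv_intercept": sd_intercept,
            "mean_slope": np.ones(n),
            "sd_slope": sd_slope,
            "cv_slope": sd_slope,
        },
        index=[f"g{i}" for i in range(n)],
    )
    empty = pd.DataFrame()
    return ReactionNormTable(empty, empty, summary, families=["F1", "F2"])


class TestSlopeVsIntercept:
    def test_equal_variability_is_null(self):
        v = np.linspace(0.5, 2.0, 10)
        res = compare_slope_intercept(_rn_from_sds(v, v))
        assert res.p == 1.0
        assert res.median_pct_difference == 0.0

    def test_halved_slope_variability(self):
        rng = np.random.default_rng(4)
        vi = rng.uniform(1, 3, 8)
        res = compare_slope_intercept(_rn_from_sds(0.5 * vi, vi))
        assert res.median_pct_difference == pytest.approx(-50.0)
        assert res.p < 0.05

    def test_requires_enough_genes(self):
        v = np.ones(3)
        with pytest.raises(ValueError, match=">= 6"):
            compare_slope_intercept(_rn_from_sds(v, v))


class TestCrossEnvCorrelation:
    def test_additive_family_effects_give_unit_correlation(self):
        design = _three_family_design()
        offsets = {"F1": 0.0, "F2": 1.0, "F3": 2.5}
        expr = make_expression(
            design,
            lambda fam, season, food: [
                offsets[fam] + (1.0 if season == "wet" else 0.0)
            ],
        )
        corr = cross_env_correlation(expr, design, "pearson")
        assert np.allclose(corr.rho, 1.0)

    def test_reversed_ranking_gives_minus_one_spearman(self):
        design = _three_family_design()
        dry_vals = {"F1": 1.0, "F2": 2.0, "F3": 3.0}
        wet_vals = {"F1": 3.0, "F2": 2.0, "F3": 1.0}
        expr = make_expression(
            design,
            lambda fam, season, food: [
                wet_vals[fam] if season == "wet" else dry_vals[fam]
            ],
        )
        corr = cross_env_correlation(expr, design, "spearman")
        assert corr.rho.iloc[0] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        design = _three_family_design()
        dry_vals = {"F1": 2.0, "F2": 4.0, "F3": 6.0}
        wet_vals = {"F1": 1.0, "F2": 2.0, "F3": 3.0}
        expr = make_expression(
            design,
            lambda fam, season, food: [
                wet_vals[fam] if season == "wet" else dry_vals[fam]
            ],
        )
        corr = cross_env_correlation(expr, design, "pearson")
        assert corr.rho.iloc[0] == pytest.approx(1.0)

    def test_constant_family_means_flagged(self):
        design = _three_family_design()
        expr = make_expression(
            design, lambda fam, season, food: [1.0 if season == "wet" else 0.0]
        )
        corr = cross_env_correlation(expr, design)
        assert corr.rho.isna().all()


class TestPCA:
    def test_variance_fractions_sum_to_one(self, small_experiment):
        _, _, counts, _ = small_experiment
        pcs = pca(np.log10(counts + 1))
        assert pcs.variance_fraction.sum() == pytest.approx(1.0)
        # score columns mutually orthogonal
        s = pcs.scores.to_numpy()
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6

    def test_rank_one_season_pattern_dominates_pc1(self, toy_design):
        rng = np.random.default_rng(5)
        wet = (toy_design["season"] == "wet").to_numpy().astype(float)
        signal = np.outer(rng.normal(size=30), wet - wet.mean())
        expr = pd.DataFrame(
            5 + 10 * signal + 1e-4 * rng.normal(size=signal.shape),
            columns=toy_design.index,
        )
        pcs = pca(expr)
        assert pcs.variance_fraction[0] > 0.99
        pc1 = pcs.scores["PC1"]
        assert set(np.sign(pc1[wet == 1])) != set(np.sign(pc1[wet == 0]))

    def test_duplicating_samples_preserves_components(self, toy_design):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(
            rng.normal(size=(20, len(toy_design))), columns=toy_design.index
        )
        dup = pd.concat(
            [expr, expr.rename(columns=lambda c: c + "_dup")], axis=1
        )
        p1, p2 = pca(expr), pca(dup)
        k = min(3, p1.loadings.shape[1])
        assert np.allclose(
            p1.loadings.iloc[:, :k], p2.loadings.iloc[:, :k], atol=1e-6
        )
        assert np.allclose(
            p2.scores.iloc[: len(toy_design), :k].to_numpy(),
            p2.scores.iloc[len(toy_design) :, :k].to_numpy(),
            atol=1e-6,
        )


class TestPCAnova:
    def test_pure_season_score(self, toy_design):
        rng = np.random.default_rng(7)
        wet = (toy_design["season"] == "wet").to_numpy().astype(float)
        expr = pd.DataFrame(
            np.outer(np.ones(10), wet) + 1e-3 * rng.normal(size=(10, len(toy_design))),
            columns=toy_design.index,
        )
        pcs = pca(expr)
        assoc = pc_anova(pcs, toy_design, n_pcs=1)
        season_p = assoc.loc[assoc["term"] == "season", "p"].iloc[0]
        inter_p = assoc.loc[assoc["term"] == "season:family", "p"].iloc[0]
        assert season_p < 1e-10
        assert inter_p > 0.05

    def test_null_scores_no_discoveries(self, toy_design):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(
            rng.normal(size=(40, len(toy_design))), columns=toy_design.index
        )
        assoc = pc_anova(pca(expr), toy_design, n_pcs=5)
        assert (assoc["q"] > 0.05).mean() > 0.8


class TestDistances:
    def test_hand_computed_three_samples(self):
        expr = pd.DataFrame({"s1": [0.0, 0.0], "s2": [3.0, 4.0], "s3": [0.0, 1.0]})
        d = euclidean_distances(expr)
        assert d.loc["s1", "s2"] == pytest.approx(5.0)
        assert d.loc["s1", "s3"] == pytest.approx(1.0)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(15, 6)))
        d = euclidean_distances(expr).to_numpy()
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def _random_additive_tree(rng, n):
    """Random binary tree with positive branch lengths; returns a skbio
    TreeNode and its tip-to-tip distance matrix."""
    tips = [skbio.TreeNode(name=f"t{i}", length=rng.uniform(0.1, 2.0)) for i in range(n)]
    nodes = list(tips)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = skbio.TreeNode(length=rng.uniform(0.1, 2.0), children=[a, b])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = skbio.TreeNode(children=nodes)
    dm = root.tip_tip_distances()
    labels = list(dm.ids)
    return root, pd.DataFrame(dm.data, index=labels, columns=labels)


class TestNeighbourJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        tree = skbio.TreeNode.read([nj_tree(d)])
        # x = (3+4-5)/2 = 1, y = (3+5-4)/2 = 2, z = (4+5-3)/2 = 3
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_four_taxon_additive_example(self):
        labels = list("ABCD")
        d = pd.DataFrame(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            index=labels,
            columns=labels,
            dtype=float,
        )
        tree = skbio.TreeNode.read([nj_tree(d)])
        dm = tree.tip_tip_distances()
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert dm[a, b] == pytest.approx(d.loc[a, b], abs=1e-9)
        # AB|CD split with internal branch length 1
        internal = [
            n.length
            for n in tree.non_tips(include_self=False)
            if n.length is not None
        ]
        assert any(np.isclose(l, 1.0) for l in internal)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_recovers_random_additive_trees_exactly(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            _, d = _random_additive_tree(rng, n)
            tree = skbio.TreeNode.read([nj_tree(d)])
            dm = tree.tip_tip_distances()
            recovered = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
            recovered = recovered.loc[d.index, d.columns]
            assert np.allclose(recovered.to_numpy(), d.to_numpy(), atol=1e-9)

    def test_taxon_order_permutation_invariant_topology(self):
        rng = np.random.default_rng(11)
        _, d = _random_additive_tree(rng, 7)
        perm = list(rng.permutation(d.index))
        t1 = skbio.TreeNode.read([nj_tree(d)])
        t2 = skbio.TreeNode.read([nj_tree(d.loc[perm, perm])])
        assert t1.compare_rfd(t2) == 0

    def test_matches_skbio_nj_topology_on_noisy_distances(self):
        rng = np.random.default_rng(12)
        _, d = _random_additive_tree(rng, 8)
        noisy = d + rng.uniform(0, 0.05, size=d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy.values, 0.0)
        mine = skbio.TreeNode.read([nj_tree(noisy)])
        dm = skbio.DistanceMatrix(noisy.to_numpy(), ids=list(noisy.index))
        theirs = skbio.tree.nj(dm)
        assert mine.compare_rfd(theirs) == 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(np.array([[0, 1, 2], [3, 0, 1], [2, 1, 0.0]]))
        with pytest.raises(ValueError, match=">= 3"):
            nj_tree(np.array([[0.0, 1.0], [1.0, 0.0]]))
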