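"""Tree I/O, phylogenetic VCV, Pagel's λ, PGLS, and the Bayesian model."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from flocknet import (
    Phylogeny,
    bayes_phylo_lm,
    fit_all_models,
    pagel_lambda_ml,
    pgls_fit,
    phylo_vcv,
    read_newick,
    read_newick_trees,
    simulate_tree,
)
from flocknet.phylo_models import PhylogenyError, lambda_transform


def _bm_draw(tree, lam, rng, sigma=1.0):
    _, C = tree.vcv()
    n = C.shape[0]
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    d = np.sqrt(np.diagonal(C))
    y = np.sqrt(lam) * (L @ rng.standard_normal(n)) + np.sqrt(1 - lam) * d * rng.standard_normal(n)
    return pd.Series(sigma * y, index=tree.species)


class TestTreeIO:
    def test_parse_and_depths(self, tree3):
        assert sorted(tree3.species) == ["A", "B", "C"]
        sp, C = tree3.vcv()
        assert np.diagonal(C) == pytest.approx([2.0, 2.0, 2.0])

    def test_malformed_string(self):
        with pytest.raises(PhylogenyError):
            Phylogeny.from_newick("((A:1,B:1;")

    def test_missing_branch_lengths(self):
        with pytest.raises(PhylogenyError, match="branch length"):
            Phylogeny.from_newick("((A,B),C);")

    def test_duplicate_tips(self):
        with pytest.raises(PhylogenyError, match="duplicate"):
            Phylogeny.from_newick("((A:1,A:1):1,C:2);")

    def test_multi_tree_file(self, tmp_path):
        p = tmp_path / "trees.nwk"
        p.write_text("((A:1,B:1):1,C:2);\n" * 50)
        trees = read_newick_trees(p)
        assert len(trees) == 50
        assert all(t.n_tips == 3 for t in trees)
        single = tmp_path / "one.nwk"
        single.write_text("((A:1,B:1):1,C:2);\n")
        assert isinstance(read_newick(single), Phylogeny)

    def test_newick_round_trip(self, tree3, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text(tree3.to_newick() + "\n")
        back = read_newick(p)
        _, C1 = tree3.vcv(sorted(tree3.species))
        _, C2 = back.vcv(sorted(back.species))
        assert np.allclose(C1, C2)


class TestVCV:
    def test_hand_example(self, tree3):
        sp, C = tree3.vcv(["A", "B", "C"])
        assert np.allclose(C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])
        assert phylo_vcv(tree3)[1].shape == (3, 3)

    def test_star_tree_diagonal(self, star_tree):
        _, C = star_tree.vcv()
        assert np.allclose(C, np.eye(star_tree.n_tips))

    def test_lambda_transform_endpoints(self, tree3):
        _, C = tree3.vcv()
        assert np.allclose(lambda_transform(C, 0.0), np.diag(np.diagonal(C)))
        assert np.allclose(lambda_transform(C, 1.0), C)

    def test_subset_ordering(self, small_study):
        tree = small_study.tree
        subset = list(reversed(tree.species[:10]))
        sp, C = tree.vcv(subset)
        assert sp == subset
        full_sp, full_C = tree.vcv()
        idx = [full_sp.index(s) for s in subset]
        assert np.allclose(C, full_C[np.ix_(idx, idx)])


class TestPagelLambda:
    def test_bm_traits_recover_high_lambda(self):
        rng = np.random.default_rng(0)
        ests = []
        for k in range(8):
            tree = simulate_tree(150, seed=k)
            ests.append(pagel_lambda_ml(_bm_draw(tree, 1.0, rng), tree).lam)
        assert np.mean(ests) > 0.9

    def test_iid_noise_recovers_zero(self):
        rng = np.random.default_rng(1)
        tree = simulate_tree(200, seed=5)
        ests = [
            pagel_lambda_ml(
                pd.Series(rng.standard_normal(200), index=tree.species), tree
            ).lam
            for _ in range(8)
        ]
        assert np.mean(ests) < 0.05

    def test_ml_beats_endpoints(self, small_study):
        rng = np.random.default_rng(2)
        y = _bm_draw(small_study.tree, 0.5, rng)
        res = pagel_lambda_ml(y, small_study.tree)
        from flocknet.phylo_models import _ProfileGLS

        yv = y.loc[small_study.tree.species].to_numpy()
        prof = _ProfileGLS(yv, np.ones((len(yv), 1)), small_study.tree.vcv()[1])
        assert res.loglik >= prof.loglik(0.0) - 1e-9
        assert res.loglik >= prof.loglik(1.0) - 1e-9

    def test_branch_rescaling_invariance(self, small_study):
        rng = np.random.default_rng(3)
        y = _bm_draw(small_study.tree, 0.6, rng)
        base = pagel_lambda_ml(y, small_study.tree)
        scaled = Phylogeny.from_newick(small_study.tree.to_newick())
        for edge in scaled.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * 7.3
        res = pagel_lambda_ml(y, scaled)
        assert res.lam == pytest.approx(base.lam, abs=1e-4)

    def test_requires_four_species(self, tree3):
        y = pd.Series([1.0, 2.0, 3.0], index=tree3.species)
        with pytest.raises(ValueError, match="at least 4"):
            pagel_lambda_ml(y, tree3)

    def test_matches_phytools_phylosig(self, tmp_path):
        """Independent oracle: R phytools' lambda ML on the same data."""
        tree = simulate_tree(60, seed=9)
        rng = np.random.default_rng(4)
        y = _bm_draw(tree, 0.7, rng)
        res = pagel_lambda_ml(y, tree)
        (tmp_path / "tree.nwk").write_text(tree.to_newick() + "\n")
        y.to_frame("y").to_csv(tmp_path / "trait.csv")
        script = tmp_path / "lam.R"
        script.write_text(
            'suppressMessages(library(phytools))\n'
            'tr <- read.tree("tree.nwk")\n'
            'd <- read.csv("trait.csv", row.names=1)\n'
            'fit <- phylosig(tr, setNames(d$y, rownames(d)), method="lambda")\n'
            'cat(fit$lambda, fit$logL, "\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", "lam.R"], cwd=tmp_path, capture_output=True, text=True,
            timeout=300,
        )
        assert out.returncode == 0, out.stderr
        r_lam, r_ll = map(float, out.stdout.split())
        assert res.lam == pytest.approx(r_lam, abs=1e-4)
        assert res.loglik == pytest.approx(r_ll, abs=1e-3)


class TestPGLS:
    def test_star_tree_equals_ols(self, star_tree):
        rng = np.random.default_rng(0)
        n = star_tree.n_tips
        X = pd.DataFrame(
            rng.standard_normal((n, 2)), index=star_tree.species, columns=["a", "b"]
        )
        y = pd.Series(
            1.0 + X["a"] * 0.5 - X["b"] * 0.2 + rng.standard_normal(n) * 0.3,
            index=star_tree.species,
        )
        fit = pgls_fit(y, X, star_tree)
        Xm = np.column_stack([np.ones(n), X.loc[star_tree.species].to_numpy()])
        ols = np.linalg.lstsq(Xm, y.loc[star_tree.species].to_numpy(), rcond=None)[0]
        assert np.allclose(fit.params["estimate"].to_numpy(), ols, atol=1e-8)

    def test_exact_fit(self, small_study):
        tree = small_study.tree
        x = pd.Series(np.linspace(0, 1, tree.n_tips), index=tree.species)
        y = 2.0 + 3.0 * x
        fit = pgls_fit(y, x.to_frame("x"), tree)
        assert fit.params.loc["Intercept", "estimate"] == pytest.approx(2.0, abs=1e-8)
        assert fit.params.loc["x", "estimate"] == pytest.approx(3.0, abs=1e-8)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_direct_gls_oracle(self, seed):
        """Explicit (X'C(λ)^-1 X)^-1 X'C(λ)^-1 y with plain inversions."""
        rng = np.random.default_rng(seed)
        tree = simulate_tree(50, seed=100 + seed)
        sp = tree.species
        _, C = tree.vcv(sp)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(50))
        X = pd.DataFrame(
            rng.standard_normal((50, 2)), index=sp, columns=["a", "b"]
        )
        y = pd.Series(
            0.5 * X["a"].to_numpy() + L @ rng.standard_normal(50), index=sp
        )
        fit = pgls_fit(y, X, tree)
        Cl = lambda_transform(C, fit.lam)
        Ci = np.linalg.inv(Cl)
        Xm = np.column_stack([np.ones(50), X.to_numpy()])
        beta = np.linalg.inv(Xm.T @ Ci @ Xm) @ Xm.T @ Ci @ y.to_numpy()
        assert np.allclose(fit.params["estimate"].to_numpy(), beta, atol=1e-8)
        resid = y.to_numpy() - Xm @ beta
        sigma2 = float(resid @ Ci @ resid) / (50 - 3)
        se = np.sqrt(np.diagonal(sigma2 * np.linalg.inv(Xm.T @ Ci @ Xm)))
        assert np.allclose(fit.params["se"].to_numpy(), se, atol=1e-8)

    def test_rank_deficient_names_column(self, star_tree):
        n = star_tree.n_tips
        rng = np.random.default_rng(1)
        a = rng.standard_normal(n)
        X = pd.DataFrame({"a": a, "dup": a}, index=star_tree.species)
        y = pd.Series(rng.standard_normal(n), index=star_tree.species)
        with pytest.raises(ValueError, match="aliased"):
            pgls_fit(y, X, star_tree)

    def test_branch_rescaling_leaves_beta_unchanged(self, small_study):
        rng = np.random.default_rng(2)
        tree = small_study.tree
        X = pd.DataFrame(
            rng.standard_normal((tree.n_tips, 1)), index=tree.species, columns=["x"]
        )
        y = _bm_draw(tree, 0.8, rng) + 0.4 * X["x"]
        f1 = pgls_fit(y, X, tree)
        scaled = Phylogeny.from_newick(tree.to_newick())
        for edge in scaled.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * 0.01
        f2 = pgls_fit(y, X, scaled)
        assert f2.params["estimate"].to_numpy() == pytest.approx(
            f1.params["estimate"].to_numpy(), abs=1e-5
        )
        assert f2.lam == pytest.approx(f1.lam, abs=1e-3)


class TestBayesPhyloLM:
    def test_star_tree_agrees_with_ols(self):
        """With no phylogenetic structure the posterior centres on OLS."""
        rng = np.random.default_rng(0)
        n = 120
        tips = ",".join(f"t{i}:1" for i in range(n))
        star = Phylogeny.from_newick(f"({tips});")
        X = pd.DataFrame(
            rng.standard_normal((n, 2)), index=star.species, columns=["a", "b"]
        )
        y = pd.Series(
            0.5 * X["a"] - 0.3 * X["b"] + 0.4 * rng.standard_normal(n),
            index=star.species,
        )
        fit = bayes_phylo_lm(y, X, star, n_iter=1500, burn=500, seed=1)
        Xm = np.column_stack([np.ones(n), X.to_numpy()])
        ols, *_ = np.linalg.lstsq(Xm, y.to_numpy(), rcond=None)
        resid = y.to_numpy() - Xm @ ols
        s2 = resid @ resid / (n - 3)
        ses = np.sqrt(np.diagonal(s2 * np.linalg.inv(Xm.T @ Xm)))
        for name, b, se in zip(["Intercept", "a", "b"], ols, ses):
            assert abs(fit.summary.loc[name, "mean"] - b) < 0.15 * se

    def test_pooling_duplicate_trees_is_invariant(self, small_study):
        rng = np.random.default_rng(1)
        tree = small_study.tree
        X = pd.DataFrame(
            rng.standard_normal((tree.n_tips, 1)), index=tree.species, columns=["x"]
        )
        y = 0.4 * X["x"] + _bm_draw(tree, 0.5, rng, sigma=0.5)
        one = bayes_phylo_lm(y, X, [tree], n_iter=2000, burn=500, seed=2)
        ten = bayes_phylo_lm(y, X, [tree] * 10, n_iter=2000, burn=500, seed=3)
        sd = one.summary.loc["x", "sd"]
        assert abs(one.summary.loc["x", "mean"] - ten.summary.loc["x", "mean"]) < 0.1 * sd
        assert one.summary.loc["x", "lower95"] == pytest.approx(
            ten.summary.loc["x", "lower95"], abs=0.15 * sd
        )

    def test_deterministic_given_seed(self, small_study):
        rng = np.random.default_rng(4)
        tree = small_study.tree
        X = pd.DataFrame(
            rng.standard_normal((tree.n_tips, 1)), index=tree.species, columns=["x"]
        )
        y = _bm_draw(tree, 0.5, rng)
        a = bayes_phylo_lm(y, X, tree, n_iter=400, burn=200, seed=9)
        b = bayes_phylo_lm(y, X, tree, n_iter=400, burn=200, seed=9)
        assert np.array_equal(a.draws["x"], b.draws["x"])

    def test_iter_burn_validation(self, small_study):
        y = pd.Series(np.arange(60, dtype=float), index=small_study.tree.species)
        X = y.to_frame("x")
        with pytest.raises(ValueError, match="burn"):
            bayes_phylo_lm(y, X, small_study.tree, n_iter=100, burn=100)


class TestFitAllModels:
    def test_one_fit_per_response(self, small_study):
        rng = np.random.default_rng(0)
        tree = small_study.tree
        X = pd.DataFrame(
            rng.standard_normal((tree.n_tips, 2)),
            index=tree.species,
            columns=["a", "b"],
        )
        responses = {
            f"resp{k}": pd.Series(rng.standard_normal(tree.n_tips), index=tree.species)
            for k in range(3)
        }
        out = fit_all_models(
            responses, X, tree, method="bayes", seed=0, n_iter=400, burn=200
        )
        assert set(out["response"]) == set(responses)
        per = out.groupby("response")["parameter"].count()
        assert (per == 5).all()  # intercept + 2 betas + 2 variance components
        assert (out["lower95"] <= out["mean"]).all()
        assert (out["mean"] <= out["upper95"]).all()

    def test_identical_response_identical_fit(self, small_study):
        rng = np.random.default_rng(1)
        tree = small_study.tree
        X = pd.DataFrame(
            rng.standard_normal((tree.n_tips, 1)), index=tree.species, columns=["a"]
        )
        y = pd.Series(rng.standard_normal(tree.n_tips), index=tree.species)
        o1 = fit_all_models({"y": y}, X, tree, seed=5, n_iter=400, burn=200)
        o2 = fit_all_models({"y": y}, X, tree, seed=5, n_iter=400, burn=200)
        pd.testing.assert_frame_equal(o1, o2)

    def test_pgls_method(self, small_study):
        rng = np.random.default_rng(2)
        tree = small_study.tree
        X = pd.DataFrame(
            rng.standard_normal((tree.n_tips, 1)), index=tree.species, columns=["a"]
        )
        y = pd.Series(rng.standard_normal(tree.n_tips), index=tree.species)
        out = fit_all_models({"y": y}, X, tree, method="pgls")
        assert {"Intercept", "a"} <= set(out["parameter"])
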