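import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from phyloniche import charmap as cm
from phyloniche import envspace as es
from phyloniche import evomodels as em
from phyloniche import synthetic as syn
from phyloniche.trees import Phylogeny, SimmapTree

from oracles import bm_moments_bruteforce, ou_moments_bruteforce, \
    ou_moments_euler


def _painted3():
    """Hand-painted 3-tip tree with three regimes."""
    t = Phylogeny.from_newick("((A:0.5,B:0.5):0.5,C:1.0);")
    sm = SimmapTree.single_regime(t, "r0")
    segs = [list(s) for s in sm.segments]
    states = list(sm.node_states)
    tip = {t.labels[i]: i for i in t.tip_indices}
    segs[tip["A"]] = [("r0", 0.2), ("r1", 0.3)]
    states[tip["A"]] = "r1"
    segs[tip["C"]] = [("r0", 0.4), ("r2", 0.6)]
    states[tip["C"]] = "r2"
    return SimmapTree(t, segs, states)


class TestMoments:
    def test_bm_two_tips_no_shared_path(self):
        t = Phylogeny.from_newick("(A:0.8,B:0.8);")
        sm = SimmapTree.single_regime(t, "all")
        spec = em.ModelSpec("BM", "none", ("x",))
        mean, cov, order = em.model_moments(
            sm, spec, {"sigma2": 1.7, "root_state": 0.3})
        assert np.allclose(mean, 0.3)
        assert np.allclose(cov, 1.7 * 0.8 * np.eye(2))

    def test_ou_alpha_to_zero_recovers_bm(self, balanced4):
        sm = SimmapTree.single_regime(balanced4, "all")
        bm_spec = em.ModelSpec("BM", "none", ("x",))
        ou_spec = em.ModelSpec("OU", "none", ("x",))
        _, bm_cov, _ = em.model_moments(sm, bm_spec,
                                        {"sigma2": 1.0, "root_state": 0.4})
        ou_mean, ou_cov, _ = em.model_moments(
            sm, ou_spec, {"alpha": 1e-8, "sigma2": 1.0, "theta": [0.4]})
        assert np.max(np.abs(ou_cov - bm_cov)) < 1e-6
        assert np.allclose(ou_mean, 0.4, atol=1e-6)

    def test_multi_regime_bm_matches_path_enumeration(self):
        sm = _painted3()
        spec = em.ModelSpec("BM", "pollination", ("x",), ("r0", "r1", "r2"))
        sig = {"r0": 1.0, "r1": 2.5, "r2": 0.4}
        mean, cov, order = em.model_moments(
            sm, spec, {"sigma2": [sig["r0"], sig["r1"], sig["r2"]],
                       "root_state": 0.1})
        bmean, bcov = bm_moments_bruteforce(sm, order, sig, 0.1)
        assert np.max(np.abs(cov - bcov)) < 1e-12
        assert np.allclose(mean, bmean)

    def test_multi_regime_ou_matches_path_enumeration(self):
        sm = _painted3()
        spec = em.ModelSpec("OU", "pollination", ("x",), ("r0", "r1", "r2"))
        theta = {"r0": 0.0, "r1": 2.0, "r2": -1.0}
        mean, cov, order = em.model_moments(
            sm, spec, {"alpha": 1.3, "sigma2": 0.8,
                       "theta": [theta["r0"], theta["r1"], theta["r2"]]})
        bmean, bcov = ou_moments_bruteforce(sm, order, 1.3, 0.8, theta)
        assert np.max(np.abs(cov - bcov)) < 1e-10
        assert np.max(np.abs(mean - bmean)) < 1e-10

    def test_ou_three_regimes_match_euler_integration(self):
        sm = _painted3()
        spec = em.ModelSpec("OU", "pollination", ("x",), ("r0", "r1", "r2"))
        theta = {"r0": 0.0, "r1": 2.0, "r2": -1.0}
        alpha, sigma2 = 1.3, 0.8
        mean, cov, order = em.model_moments(
            sm, spec, {"alpha": alpha, "sigma2": sigma2,
                       "theta": [0.0, 2.0, -1.0]})
        emean, ecov = ou_moments_euler(sm, order, alpha, sigma2, theta,
                                       root_state=theta["r0"], dt=1e-5)
        assert np.max(np.abs(mean - emean)) < 1e-4
        assert np.max(np.abs(cov - ecov)) < 1e-4

    def test_bivariate_bm_is_kron_structured(self, balanced4):
        sm = SimmapTree.single_regime(balanced4, "all")
        spec = em.ModelSpec("BM", "none", ("x", "y"))
        R = np.array([[1.0, 0.3], [0.3, 0.5]])
        _, cov, order = em.model_moments(
            sm, spec, {"sigma2": R, "root_state": [0.0, 1.0]})
        C = balanced4.mrca_depths(order)
        assert np.allclose(cov, np.kron(R, C))

    def test_negative_alpha_rejected(self, balanced4):
        sm = SimmapTree.single_regime(balanced4, "all")
        spec = em.ModelSpec("OU", "none", ("x",))
        with pytest.raises(ValueError):
            em.model_moments(sm, spec, {"alpha": -0.5, "sigma2": 1.0,
                                        "theta": [0.0]})

    def test_unpainted_regime_rejected(self):
        sm = _painted3()
        spec = em.ModelSpec("OU", "pollination", ("x",), ("r0", "r1"))
        with pytest.raises(ValueError, match="not covered"):
            em.model_moments(sm, spec, {"alpha": 1.0, "sigma2": 1.0,
                                        "theta": [0.0, 1.0]})


class TestLoglik:
    def test_bm_star_tree_factorizes(self):
        star = Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1);")
        sm = SimmapTree.single_regime(star, "all")
        spec = em.ModelSpec("BM", "none", ("x",))
        y = pd.DataFrame({"x": [0.1, -0.4, 1.2, 0.0, -0.7]},
                         index=["A", "B", "C", "D", "E"])
        got = em.loglik(sm, spec, {"sigma2": 0.9, "root_state": 0.2}, y)
        expect = norm.logpdf(y["x"], loc=0.2, scale=np.sqrt(0.9)).sum()
        assert abs(got - expect) < 1e-10

    def test_strong_selection_approaches_iid_stationary(self):
        star = Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1,F:1);")
        sm = SimmapTree.single_regime(star, "all")
        spec = em.ModelSpec("OU", "none", ("x",))
        alpha, sigma2, theta = 30.0, 2.0, 0.7
        rng = np.random.default_rng(0)
        y = pd.DataFrame({"x": rng.normal(theta, 0.2, 6)},
                         index=sorted(star.tip_labels))
        got = em.loglik(sm, spec, {"alpha": alpha, "sigma2": sigma2,
                                   "theta": [theta]}, y)
        expect = norm.logpdf(y["x"], loc=theta,
                             scale=np.sqrt(sigma2 / (2 * alpha))).sum()
        assert abs(got - expect) < 1e-8

    def test_invariant_to_joint_permutation(self, tree10):
        sm = SimmapTree.single_regime(tree10, "all")
        spec = em.ModelSpec("OU", "none", ("x",))
        params = {"alpha": 1.0, "sigma2": 1.0, "theta": [0.0]}
        rng = np.random.default_rng(1)
        labels = sorted(tree10.tip_labels)
        y = pd.DataFrame({"x": rng.normal(size=10)}, index=labels)
        shuffled = y.sample(frac=1.0, random_state=3)
        assert np.isclose(em.loglik(sm, spec, params, y),
                          em.loglik(sm, spec, params, shuffled))


class TestInformationCriteria:
    def test_small_sample_correction_arithmetic(self):
        # logL=-50, k=2, n=35: AIC=104, AICc=104 + 12/32
        assert em.aicc(-50.0, 2, 35) == pytest.approx(104.0 + 12.0 / 32.0)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            em.aicc(-10.0, 5, 6)

    def test_equal_scores_share_weight(self):
        w = em.akaike_weights([12.0, 12.0, 12.0, 12.0])
        assert np.allclose(w, 0.25)

    def test_two_unit_delta(self):
        w = em.akaike_weights([100.0, 102.0])
        assert np.allclose(w, [0.7311, 0.2689], atol=1e-4)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=6))
    def test_weights_form_a_simplex(self, vals):
        w = em.akaike_weights(vals)
        assert np.isclose(w.sum(), 1.0, atol=1e-12)
        assert (w >= 0).all()

    def test_aicc_exceeds_aic(self, tree10):
        sm = SimmapTree.single_regime(tree10, "all")
        spec = em.ModelSpec("BM", "none", ("x",))
        rng = np.random.default_rng(2)
        y = pd.DataFrame({"x": rng.normal(size=10)},
                         index=sorted(tree10.tip_labels))
        fit = em.fit_model(sm, spec, y, restarts=1)
        assert fit.aicc >= fit.aic


class TestFitting:
    def test_bm1_rate_recovery(self):
        cfg = syn.SyntheticConfig(seed=41, n_taxa=50, n_trees=1)
        tree = syn.generate_tree(cfg)
        sm = SimmapTree.single_regime(tree, "all")
        spec = em.ModelSpec("BM", "none", ("x",))
        rng = np.random.default_rng(5)
        errs = []
        for _ in range(10):
            y = syn.simulate_traits(sm, spec, {"sigma2": 1.0,
                                               "root_state": 0.0}, rng)
            fit = em.fit_model(sm, spec, y, restarts=1)
            errs.append(abs(fit.estimates["sigma2"][0] - 1.0))
        assert np.median(errs) < 0.25

    def test_mle_dominates_constrained_rate(self, tree10):
        sm = SimmapTree.single_regime(tree10, "all")
        spec = em.ModelSpec("BM", "none", ("x",))
        y = syn.simulate_traits(sm, spec, {"sigma2": 1.0, "root_state": 0.0},
                                7)
        fit = em.fit_model(sm, spec, y, restarts=1)
        half = dict(fit.estimates)
        half["sigma2"] = fit.estimates["sigma2"] / 2.0
        assert fit.log_likelihood >= em.loglik(sm, spec, half, y)

    def test_ou_at_lower_alpha_bound_matches_bm_loglik(self, tree10):
        sm = SimmapTree.single_regime(tree10, "all")
        y = syn.simulate_traits(sm, em.ModelSpec("BM", "none", ("x",)),
                                {"sigma2": 1.0, "root_state": 0.0}, 11)
        bm = em.fit_model(sm, em.ModelSpec("BM", "none", ("x",)), y,
                          restarts=1)
        ou_params = {"alpha": 1e-9, "sigma2": bm.estimates["sigma2"][0],
                     "theta": [bm.estimates["root_state"]]}
        l_ou = em.loglik(sm, em.ModelSpec("OU", "none", ("x",)), ou_params, y)
        assert abs(l_ou - bm.log_likelihood) < 1e-4

    def test_model_set_weights_normalize(self, dataset18):
        ds = dataset18
        occ = es.dedupe_per_pixel(
            es.apply_filters(ds.plant_occurrences, ds.raster)[0])
        niches = es.species_niche(occ, ds.space, ds.raster)
        traits = es.niches_to_frame(niches).set_index("species")
        species = list(traits.index)
        tree = ds.tree.prune_to(species)
        rng = np.random.default_rng(0)
        meta = occ.subset_metadata()
        isl = cm.delta_priors(cm.assign_single_island(meta, rng),
                              cm.ISLAND_STATES)
        im = cm.fit_mk(tree, isl, "SYM", cm.ISLAND_STATES, restarts=1)
        imap = cm.sample_stochastic_map(tree, im, isl, rng)
        pol = cm.build_tip_priors(meta)
        pm = cm.fit_mk(tree, pol, "ARD", cm.POLLINATION_STATES, restarts=1)
        pmap = cm.sample_stochastic_map(tree, pm, pol, rng)
        fits = em.fit_model_set(
            {"none": SimmapTree.single_regime(tree, "all"),
             "pollination": pmap, "island": imap},
            traits, ("identity_pc1", "identity_pc2"), restarts=1)
        assert np.isclose(sum(f.akaike_weight for f in fits), 1.0,
                          atol=1e-12)
        names = [f.name for f in fits]
        assert names == ["BM1", "BM3", "BM4", "OU1", "OU3", "OU4"]
        for f in fits:
            assert f.aicc >= f.aic
            assert f.n == 2 * len(species)


class TestRunReplicates:
    def test_deterministic_given_seed(self, dataset18):
        ds = dataset18
        occ = es.dedupe_per_pixel(
            es.apply_filters(ds.plant_occurrences, ds.raster)[0])
        cfg = em.ReplicateConfig(n_iterations=2, seed=3, restarts=1,
                                 mk_restarts=1,
                                 trait_sets=(("identity_pc1",),
                                             ("breadth_pc1", "breadth_pc2")))
        kw = dict(trees=ds.trees, occurrences=occ,
                  metadata=occ.subset_metadata(), space=ds.space, config=cfg,
                  raster=ds.raster)
        r1 = em.run_replicates(**kw)
        r2 = em.run_replicates(**kw)
        pd.testing.assert_frame_equal(r1.iterations, r2.iterations)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)
        assert not r1.failures

    def test_per_iteration_weights_sum_to_one(self, dataset18):
        ds = dataset18
        occ = es.dedupe_per_pixel(
            es.apply_filters(ds.plant_occurrences, ds.raster)[0])
        cfg = em.ReplicateConfig(n_iterations=2, seed=9, restarts=1,
                                 mk_restarts=1,
                                 trait_sets=(("identity_pc2",),))
        res = em.run_replicates(ds.trees, occ, occ.subset_metadata(),
                                ds.space, cfg, raster=ds.raster)
        sums = res.iterations.groupby(["iteration", "trait_set"])["weight"] \
            .sum()
        assert np.allclose(sums, 1.0, atol=1e-9)
        ci_ok = res.summary[["ci_low", "ci_high"]].to_numpy()
        assert ((ci_ok >= -1e-12) & (ci_ok <= 1 + 1e-12)).all()
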