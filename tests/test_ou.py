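"""OU/BM likelihood machinery: closed forms, limits, simulation oracles,
information criteria and derived quantities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import copetrend as ct
from copetrend.errors import ValidationError
from conftest import cherry_tree


class TestBmLoglik:
    def test_cherry_matches_bivariate_normal_closed_form(self):
        # shared time 5 at the root, tip depths 15 and 12
        root = ct.Node()
        mid = root.add_child(ct.Node(length=5.0))
        mid.add_child(ct.Node(label="A", length=10.0))
        mid.add_child(ct.Node(label="B", length=7.0))
        root.add_child(ct.Node(label="C", length=20.0))
        tree = ct.CalibratedTree(root, root_age=30.0)
        tree = tree.prune_to(["A", "B"])  # cherry with shared root path
        beta, z0 = 0.004, 0.1
        y = {"A": 0.35, "B": -0.05}
        traits = ct.TraitVector(values=y, se={"A": 0.0, "B": 0.0}, provenance={})
        got = ct.bm_loglik(tree, traits, beta, z0, mserr=True)
        S = tree.shared_times(["A", "B"])
        V = beta * S
        r = np.array([y["A"] - z0, y["B"] - z0])
        expected = (
            -0.5 * (2 * math.log(2 * math.pi) + math.log(np.linalg.det(V))
                    + float(r @ np.linalg.solve(V, r)))
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_time_rate_rescaling_invariance(self, small_tree):
        y = {t: v for t, v in zip(small_tree.tip_labels(), [0.1, 0.3, -0.2, 0.0, 0.5])}
        traits = ct.TraitVector(values=y, se={t: 0.0 for t in y}, provenance={})
        base = ct.bm_loglik(small_tree, traits, 0.002, 0.1)
        scaled = small_tree.copy()
        for n in scaled.preorder():
            if n.length is not None:
                n.length *= 4.0
        scaled = ct.CalibratedTree(scaled.root, root_age=small_tree.root_age * 4)
        assert ct.bm_loglik(scaled, traits, 0.002 / 4.0, 0.1) == pytest.approx(base, rel=1e-12)

    def test_five_tip_brute_force_covariance_assembly(self, small_tree):
        # independent construction: V_ij = beta * (shared path time), via
        # explicit root-path intersection per tip pair
        labels = small_tree.tip_labels()
        y = dict(zip(labels, [0.2, -0.1, 0.05, 0.4, -0.3]))
        se = dict(zip(labels, [0.05, 0.0, 0.02, 0.0, 0.01]))
        traits = ct.TraitVector(values=y, se=se, provenance={})
        beta, z0 = 0.0031, -0.05

        paths = {}
        depths = small_tree.depths()
        for tip in small_tree.tips():
            path, node = [], tip
            while node is not None:
                path.append(node.id)
                node = node.parent
            paths[tip.label] = set(path)
        n = len(labels)
        V = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                shared = paths[a] & paths[b]
                V[i, j] = beta * max(depths[k] for k in shared)
        V += np.diag([se[t] ** 2 for t in labels])
        r = np.array([y[t] - z0 for t in labels])
        expected = -0.5 * (
            n * math.log(2 * math.pi)
            + math.log(np.linalg.det(V))
            + float(r @ np.linalg.solve(V, r))
        )
        got = ct.bm_loglik(small_tree, traits, beta, z0, mserr=True)
        assert got == pytest.approx(expected, rel=1e-10)


class TestMeanWeights:
    def test_single_regime_theta_weight_telescopes(self, fossil_tree):
        rm = ct.single_regime_map(fossil_tree)
        alpha = 0.03
        order, cols, W = ct.ou_mean_weights(fossil_tree, rm, alpha)
        depths = fossil_tree.tip_depths()
        for i, lab in enumerate(order):
            assert W[i, 0] == pytest.approx(math.exp(-alpha * depths[lab]), rel=1e-10)
            assert W[i, 1] == pytest.approx(1 - math.exp(-alpha * depths[lab]), rel=1e-10)

    def test_alpha_to_zero_limit_gives_root_weight_one(self, fossil_tree, era_map):
        order, cols, W = ct.ou_mean_weights(fossil_tree, era_map, 1e-12)
        assert np.allclose(W[:, 0], 1.0, atol=1e-9)
        assert np.all(W[:, 1:] < 1e-9)

    def test_two_era_two_tip_hand_computation(self):
        # tree: root -> A (duration 30), root -> B (duration 20);
        # era boundary at depth 10 (age 40 on a 50 Ma root)
        tree = cherry_tree(t_a=30.0, t_b=20.0, root_age=50.0)
        rm = ct.paint_eras(tree, [40.0], labels=["old", "young"])
        a_old, a_yng = 0.05, 0.02
        order, cols, W = ct.ou_mean_weights(
            tree, rm, {"old": a_old, "young": a_yng}
        )
        assert cols == ["Z0", "old", "young"]
        i = order.index("A")
        # A: 10 Ma in 'old' then 20 Ma in 'young'
        z0_w = math.exp(-(a_old * 10 + a_yng * 20))
        old_w = (1 - math.exp(-a_old * 10)) * math.exp(-a_yng * 20)
        young_w = 1 - math.exp(-a_yng * 20)
        assert W[i, 0] == pytest.approx(z0_w, rel=1e-10)
        assert W[i, 1] == pytest.approx(old_w, rel=1e-10)
        assert W[i, 2] == pytest.approx(young_w, rel=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        a1=st.floats(1e-6, 1.0),
        a2=st.floats(1e-6, 1.0),
    )
    def test_rows_sum_to_one_property(self, a1, a2, fossil_tree, era_map):
        order, cols, W = ct.ou_mean_weights(
            fossil_tree, era_map, {"basal": a1, "derived": a2}
        )
        assert np.abs(W.sum(axis=1) - 1.0).max() < 1e-12


class TestCovariance:
    def test_single_tip_variance_closed_form(self):
        tree = cherry_tree(t_a=25.0, t_b=25.0)
        rm = ct.single_regime_map(tree)
        alpha, beta = 0.04, 0.002
        order, V = ct.ou_covariance(tree, rm, alpha, beta)
        expected = beta / (2 * alpha) * (1 - math.exp(-2 * alpha * 25.0))
        assert V[0, 0] == pytest.approx(expected, rel=1e-10)
        assert V[0, 1] == pytest.approx(0.0, abs=1e-15)  # no shared path

    def test_bm_limit(self, fossil_tree, era_map):
        order, V = ct.ou_covariance(fossil_tree, era_map, 1e-10, 0.002)
        S = 0.002 * fossil_tree.shared_times(order)
        assert np.abs(V - S).max() / S.max() < 1e-6

    def test_positive_definite_over_parameter_draws(self, fossil_tree, era_map):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = {r: float(rng.uniform(1e-4, 0.5)) for r in era_map.regimes}
            b = {r: float(rng.uniform(1e-5, 0.05)) for r in era_map.regimes}
            order, V = ct.ou_covariance(fossil_tree, era_map, a, b)
            assert np.allclose(V, V.T)
            assert np.linalg.eigvalsh(V).min() > 0

    def test_matches_monte_carlo_multi_regime(self):
        # analytic covariance vs exact-transition simulation (oracle coupling)
        tree = ct.simulate_tree(6, 100.0, seed=13, root_age=120.0)
        rm = ct.paint_eras(tree, [60.0], labels=["old", "young"])
        alpha = {"old": 0.03, "young": 0.012}
        beta = {"old": 0.002, "young": 0.006}
        params = {k: ct.OUParams(alpha[k], beta[k], th)
                  for k, th in [("old", 0.0), ("young", 0.8)]}
        n_rep = 100000
        X = ct.simulate_trait_replicates(tree, rm, params, z0=0.1, n_rep=n_rep, seed=14)
        emp = np.cov(X.T)
        order, V = ct.ou_covariance(tree, rm, alpha, beta)
        se = np.sqrt((np.outer(np.diag(V), np.diag(V)) + V**2) / n_rep)
        assert np.all(np.abs(V - emp) < 3.5 * se)

    def test_nonpositive_alpha_rejected(self, fossil_tree, era_map):
        with pytest.raises(ValidationError):
            ct.ou_covariance(fossil_tree, era_map, {"basal": 0.0, "derived": 0.01}, 0.001)


class TestFitModel:
    def test_ou1_nests_bm(self, fossil_tree):
        rm = ct.single_regime_map(fossil_tree)
        tv = ct.simulate_trait(
            fossil_tree, rm, {"all": ct.OUParams(0.0, 0.001, 0.0)}, z0=0.0, seed=20
        )
        bm = ct.fit_model(ct.ModelSpec("BM1"), fossil_tree, tv, seed=1)
        ou = ct.fit_model(ct.ModelSpec("OU1"), fossil_tree, tv, seed=1)
        assert ou.lnL >= bm.lnL - 1e-4
        assert ou.alpha["all"] < 5e-3  # alpha near its lower bound on BM data

    def test_taxon_permutation_invariance(self, fossil_tree, era_map):
        params = {"basal": ct.OUParams(0.02, 0.001, 0.0),
                  "derived": ct.OUParams(0.02, 0.001, 0.6)}
        tv = ct.simulate_trait(fossil_tree, era_map, params, z0=0.0, seed=21)
        fit = ct.fit_model(ct.ModelSpec("OUM", regime_map=era_map), fossil_tree, tv, seed=2)
        shuffled = ct.TraitVector(
            values=dict(reversed(list(tv.values.items()))),
            se=dict(reversed(list(tv.se.items()))),
            provenance={},
        )
        fit2 = ct.fit_model(ct.ModelSpec("OUM", regime_map=era_map), fossil_tree,
                            shuffled, seed=2)
        assert fit2.lnL == pytest.approx(fit.lnL, abs=1e-8)

    def test_separate_root_adds_one_parameter(self, fossil_tree, era_map):
        params = {"basal": ct.OUParams(0.02, 0.001, 0.0),
                  "derived": ct.OUParams(0.02, 0.001, 0.6)}
        tv = ct.simulate_trait(fossil_tree, era_map, params, z0=0.0, seed=22)
        base = ct.fit_model(ct.ModelSpec("OUM", regime_map=era_map), fossil_tree, tv, seed=3)
        root = ct.fit_model(
            ct.ModelSpec("OUM", regime_map=era_map, root_mode="separate_Z0"),
            fossil_tree, tv, seed=3,
        )
        assert root.k == base.k + 1
        assert root.lnL >= base.lnL - 1e-4  # nesting
        assert root.z0 is not None and root.z0_se is not None

    def test_family_parameter_counts(self, fossil_tree, era_map):
        params = {"basal": ct.OUParams(0.02, 0.001, 0.0),
                  "derived": ct.OUParams(0.02, 0.001, 0.6)}
        tv = ct.simulate_trait(fossil_tree, era_map, params, z0=0.0, seed=23)
        ks = {}
        for fam in ("OUM", "OUMV", "OUMA", "OUMVA"):
            fit = ct.fit_model(ct.ModelSpec(fam, regime_map=era_map), fossil_tree,
                               tv, seed=4, n_starts=4)
            ks[fam] = fit.k
        # shared-root mode, r = 2: variance params + 2 optima
        assert ks == {"OUM": 4, "OUMV": 5, "OUMA": 5, "OUMVA": 6}

    def test_mserr_changes_likelihood(self, fossil_tree):
        rm = ct.single_regime_map(fossil_tree)
        tv = ct.simulate_trait(fossil_tree, rm, {"all": ct.OUParams(0.01, 0.001, 0.3)},
                               z0=0.0, seed=24, se_scale=0.08)
        with_err = ct.fit_model(ct.ModelSpec("OU1", mserr=True), fossil_tree, tv, seed=5)
        without = ct.fit_model(ct.ModelSpec("OU1", mserr=False), fossil_tree, tv, seed=5)
        assert with_err.lnL != pytest.approx(without.lnL, abs=1e-3)

    def test_multiregime_family_requires_regimes(self):
        with pytest.raises(ValidationError):
            ct.ModelSpec("OUM")


class TestInformationCriteria:
    def test_aicc_closed_form(self):
        assert ct.aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)

    def test_aicc_needs_enough_observations(self):
        with pytest.raises(ValidationError):
            ct.aicc(0.0, 9, 10)

    def test_equal_scores_give_equal_weights(self):
        w = ct.akaike_weights([12.0, 12.0, 12.0])
        assert np.allclose(w, 1 / 3)
        assert w.sum() == pytest.approx(1.0)

    def test_delta_two_gives_weight_ratio_e(self):
        w = ct.akaike_weights([10.0, 12.0])
        assert w[0] / w[1] == pytest.approx(math.e)


class TestDerivedQuantities:
    def test_half_life_of_ln2_is_one(self):
        assert ct.half_life(math.log(2)) == pytest.approx(1.0)

    def test_zero_alpha_half_life_infinite(self):
        assert math.isinf(ct.half_life(0.0))

    def test_mu_bounds(self):
        mu, lo, hi = ct.trend_coefficient(0.0056, 1.350, 0.221)
        assert mu == pytest.approx(0.0056 * 1.350)
        assert hi == pytest.approx(0.0056 * (1.350 + 0.442))
        assert lo == pytest.approx(0.0056 * (1.350 - 0.442))

    def test_derived_quantities_recomputable_from_fit(self, fossil_tree, era_map):
        params = {"basal": ct.OUParams(0.02, 0.001, 0.0),
                  "derived": ct.OUParams(0.02, 0.001, 0.6)}
        tv = ct.simulate_trait(fossil_tree, era_map, params, z0=0.0, seed=25)
        fit = ct.fit_model(ct.ModelSpec("OUM", regime_map=era_map), fossil_tree, tv,
                           seed=6, n_starts=4)
        d = ct.derived_quantities(fit)
        for lab in fit.regimes:
            assert d["half_life"][lab] == pytest.approx(math.log(2) / fit.alpha[lab])
            assert d["mu"][lab] == pytest.approx(fit.alpha[lab] * fit.theta[lab])
            assert d["theta_m"][lab] == pytest.approx(10 ** fit.theta[lab])
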