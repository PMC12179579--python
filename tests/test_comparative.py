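"""Pagel's lambda, PGLS, phylo-ANOVA, contrasts, ancestral states, changes.

The frozen expected values for lambda, PGLS and PIC on the 12-tip fixture
were computed once with an independent reference implementation (R: ape /
phytools / nlme gls with a Pagel correlation structure) and are asserted
at 1e-6 unless noted.
"""

import numpy as np
import pytest

from pleurokit import comparative as comp
from pleurokit import trees as T
from pleurokit.simulate import simulate_bm_traits
from conftest import ultrametric_tree

FIXTURE_NEWICK = (
    "((((t1:1,t2:1):1,(t3:1,t4:1):1):1,((t5:1,t6:1):1,(t7:1,t8:1):1):1):1,"
    "((t9:2,(t10:1,t11:1):1):1,t12:3):1);"
)
FIXTURE_X = {
    "t1": -1.5803049999, "t2": -3.876785268, "t3": -0.5394025714,
    "t4": 0.0597429361, "t5": -1.1302540928, "t6": -0.4854158088,
    "t7": 2.1735362422, "t8": 2.5069337896, "t9": 1.4152780416,
    "t10": 1.8988559046, "t11": 0.3869228211, "t12": 2.2826209587,
}
FIXTURE_Y = {
    "t1": -1.7447281016, "t2": -3.9143141893, "t3": 0.7203590577,
    "t4": 0.6426327743, "t5": -1.8424214, "t6": -0.1539416951,
    "t7": 3.5354833445, "t8": 4.8124579314, "t9": 0.180684203,
    "t10": 3.7070099614, "t11": 2.0459138657, "t12": 1.9816316041,
}


@pytest.fixture
def fixture_tree():
    return T.parse_newick(FIXTURE_NEWICK)


class TestCovariance:
    def test_diagonal_is_root_to_tip_distance(self, fixture_tree):
        cov = comp.phylo_covariance(fixture_tree)
        assert np.allclose(np.diag(cov.matrix), 4.0)  # ultrametric depth 4

    def test_lambda_transform_scales_offdiagonals(self, fixture_tree):
        cov = comp.phylo_covariance(fixture_tree)
        half = cov.lambda_transform(0.5)
        off = ~np.eye(len(cov.taxa), dtype=bool)
        assert np.allclose(half[off], 0.5 * cov.matrix[off])
        assert np.allclose(np.diag(half), np.diag(cov.matrix))

    def test_loglik_matches_reference_gls(self, fixture_tree):
        # frozen from nlme::gls(x ~ 1, corPagel(lam, fixed=TRUE), method="ML")
        cov = comp.phylo_covariance(fixture_tree)
        y = np.array([FIXTURE_X[t] for t in cov.taxa])
        ones = np.ones((len(y), 1))
        expected = {0.0: -24.32641371, 0.5: -23.44419315, 1.0: -22.73584430}
        for lam, ll_ref in expected.items():
            ll, _, _ = comp._gls_loglik(y, ones, cov.lambda_transform(lam))
            assert ll == pytest.approx(ll_ref, abs=1e-6)


class TestPagelLambda:
    def test_bm_fixture_estimate_at_boundary(self, fixture_tree):
        res = comp.pagel_lambda_ml(fixture_tree, FIXTURE_X)
        assert res.lambda_hat == 1.0
        assert res.ci_high is None  # boundary not excluded -> NA
        assert res.loglik == pytest.approx(-22.73584430, abs=1e-6)

    def test_optimum_beats_probe_points(self, fixture_tree):
        res = comp.pagel_lambda_ml(fixture_tree, FIXTURE_Y)
        cov = comp.phylo_covariance(fixture_tree)
        y = np.array([FIXTURE_Y[t] for t in cov.taxa])
        ones = np.ones((len(y), 1))
        for lam in (0.0, 0.5, 1.0):
            ll, _, _ = comp._gls_loglik(y, ones, cov.lambda_transform(lam))
            assert res.loglik >= ll - 1e-9

    def test_recovery_bm_vs_white_noise(self, rng):
        tree = ultrametric_tree(rng, 120)
        hits_bm = hits_white = 0
        n = 30
        for seed in range(n):
            bm = simulate_bm_traits(tree, sigma2=1.0, lam=1.0, seed=seed)
            white = simulate_bm_traits(tree, sigma2=1.0, lam=0.0, seed=1000 + seed)
            hits_bm += comp.pagel_lambda_ml(tree, bm).lambda_hat >= 0.9
            hits_white += comp.pagel_lambda_ml(tree, white).lambda_hat <= 0.1
        assert hits_bm >= 0.9 * n
        assert hits_white >= 0.9 * n

    def test_star_phylogeny_flat_likelihood(self):
        star = T.parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        trait = {"A": 0.3, "B": -1.2, "C": 0.7, "D": 0.1, "E": -0.5}
        res = comp.pagel_lambda_ml(star, trait)
        assert res.ci_low == 0.0 and res.ci_high is None

    def test_zero_variance_errors(self, fixture_tree):
        with pytest.raises(ValueError):
            comp.pagel_lambda_ml(fixture_tree, {t: 1.0 for t in FIXTURE_X})


class TestPgls:
    def test_matches_reference_implementation(self, fixture_tree):
        # frozen from nlme::gls(y ~ x, corPagel(1, fixed=TRUE), method="ML")
        res = comp.pgls(fixture_tree, FIXTURE_Y, FIXTURE_X, lam=1.0)
        assert res.slope == pytest.approx(1.23457522, abs=1e-6)
        assert res.slope_se == pytest.approx(0.20201721, abs=1e-6)
        assert res.intercept == pytest.approx(0.27246587, abs=1e-6)
        assert res.p_value == pytest.approx(0.00011399108, rel=1e-4)

    def test_lambda_zero_reduces_to_ols(self, fixture_tree):
        res = comp.pgls(fixture_tree, FIXTURE_Y, FIXTURE_X, lam=0.0)
        taxa = sorted(FIXTURE_X)
        x = np.array([FIXTURE_X[t] for t in taxa])
        y = np.array([FIXTURE_Y[t] for t in taxa])
        slope = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        assert res.slope == pytest.approx(slope, abs=1e-10)

    def test_star_tree_equals_ols_for_any_lambda(self):
        star = T.parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        x = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "E": 5.0}
        y = {"A": 1.1, "B": 1.9, "C": 3.2, "D": 3.8, "E": 5.1}
        slopes = {comp.pgls(star, y, x, lam=l).slope for l in (0.0, 0.5, 1.0)}
        assert max(slopes) - min(slopes) < 1e-10

    def test_slope_recovery_under_bm(self, rng):
        tree = ultrametric_tree(rng, 80)
        hits = 0
        n = 25
        for seed in range(n):
            x = simulate_bm_traits(tree, sigma2=1.0, lam=1.0, seed=seed)
            noise = simulate_bm_traits(tree, sigma2=0.01, lam=1.0, seed=5000 + seed)
            y = {t: 2.0 * x[t] + noise[t] for t in x}
            r = comp.pgls(tree, y, x, lam=1.0)
            hits += 1.9 <= r.slope <= 2.1
        assert hits >= 0.9 * n

    def test_ml_lambda_mode_runs(self, fixture_tree):
        res = comp.pgls(fixture_tree, FIXTURE_Y, FIXTURE_X, lam="ML")
        assert 0.0 <= res.lam <= 1.0
        assert 0.0 <= res.explained_variance_pct <= 100.0

    def test_singular_design_errors(self, fixture_tree):
        with pytest.raises(ValueError):
            comp.pgls(fixture_tree, FIXTURE_Y, {t: 3.0 for t in FIXTURE_X})


class TestPglsUncertainty:
    def test_zero_width_bounds_reduce_to_plain_pgls(self, fixture_tree):
        bounds = {t: (v, v) for t, v in FIXTURE_X.items()}
        res = comp.pgls_with_uncertainty(fixture_tree, FIXTURE_Y, bounds,
                                         n_intra=20, seed=1)
        plain = comp.pgls(fixture_tree, FIXTURE_Y, FIXTURE_X, lam=1.0)
        assert np.allclose(res.p_values, plain.p_value)
        assert res.p_min == res.p_max == pytest.approx(plain.p_value)

    def test_wider_bounds_never_tighten_envelope(self, fixture_tree):
        narrow = {t: (v - 0.1, v + 0.1) for t, v in FIXTURE_X.items()}
        wide = {t: (v - 0.2, v + 0.2) for t, v in FIXTURE_X.items()}
        rn = comp.pgls_with_uncertainty(fixture_tree, FIXTURE_Y, narrow,
                                        n_intra=100, seed=7)
        rw = comp.pgls_with_uncertainty(fixture_tree, FIXTURE_Y, wide,
                                        n_intra=100, seed=7)
        assert rw.p_min <= rn.p_min + 1e-12
        assert rw.p_max >= rn.p_max - 1e-12

    def test_deterministic_under_seed(self, fixture_tree):
        bounds = {t: (v - 0.3, v + 0.3) for t, v in FIXTURE_X.items()}
        r1 = comp.pgls_with_uncertainty(fixture_tree, FIXTURE_Y, bounds,
                                        n_intra=50, seed=3)
        r2 = comp.pgls_with_uncertainty(fixture_tree, FIXTURE_Y, bounds,
                                        n_intra=50, seed=3)
        assert np.array_equal(r1.p_values, r2.p_values)
        assert "(" in r1.summary() and "-" in r1.summary()


class TestPhyloAnova:
    def test_separated_groups_on_star_tree(self):
        star = T.parse_newick("(A:1,B:1,C:1,D:1,E:1,F:1);")
        trait = {"A": 0.0, "B": 0.01, "C": -0.01, "D": 10.0, "E": 10.01, "F": 9.99}
        groups = {t: ("g1" if trait[t] < 5 else "g2") for t in trait}
        f, p_std, p_phylo = comp.phylo_anova(star, trait, groups, n_sim=200, seed=0)
        assert f > 100
        assert p_std < 1e-6
        assert p_phylo == pytest.approx(1.0 / 201.0)  # smoothing floor

    def test_degenerate_groups_error(self, fixture_tree):
        groups = {t: "g1" for t in FIXTURE_X}
        groups["t1"] = "g2"
        with pytest.raises(ValueError):
            comp.phylo_anova(fixture_tree, FIXTURE_X, groups)

    def test_null_p_values_roughly_uniform(self, rng):
        tree = ultrametric_tree(rng, 24)
        taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        ps = []
        for seed in range(120):
            trait = simulate_bm_traits(tree, sigma2=1.0, lam=1.0, seed=seed)
            labels = np.array(["g1"] * 12 + ["g2"] * 12)
            rng.shuffle(labels)
            groups = dict(zip(taxa, labels))
            ps.append(comp.phylo_anova(tree, trait, groups, n_sim=199,
                                       seed=10_000 + seed)[2])
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPicAndAncestral:
    def test_pic_matches_reference(self, fixture_tree):
        # ape::pic contrasts (absolute values, sorted) and the
        # through-origin correlation, frozen from R
        u = np.sort(np.abs(comp.pic(fixture_tree, FIXTURE_X)))
        expected = np.array([
            0.14559787, 0.23574767, 0.42365985, 0.45596952, 0.46417578,
            1.00212344, 1.06909814, 1.20288272, 1.43686046, 1.62385677,
            1.81753904,
        ])
        assert np.allclose(u, expected, atol=1e-6)
        r, p = comp.pic_correlation(fixture_tree, FIXTURE_X, FIXTURE_Y)
        assert r == pytest.approx(0.88814098, abs=1e-6)
        assert 0 < p < 0.01

    def test_contrast_count_law(self, rng):
        tree = ultrametric_tree(rng, 37)
        trait = simulate_bm_traits(tree, seed=1)
        assert len(comp.pic(tree, trait)) == 36

    def test_identical_traits_correlate_perfectly(self, fixture_tree):
        r, _ = comp.pic_correlation(fixture_tree, FIXTURE_X, FIXTURE_X)
        assert r == pytest.approx(1.0)

    def test_independent_bm_traits_uncorrelated(self, rng):
        tree = ultrametric_tree(rng, 200)
        x = simulate_bm_traits(tree, seed=11)
        y = simulate_bm_traits(tree, seed=12)
        r, _ = comp.pic_correlation(tree, x, y)
        assert abs(r) < 3.0 / np.sqrt(199)

    def test_ancestral_constant_and_symmetric(self):
        t = T.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        anc = comp.ancestral_states_bm(t, {k: 3.0 for k in "ABCD"})
        assert all(v == pytest.approx(3.0) for v in anc.node_states.values())
        two = T.parse_newick("(A:1,B:1);")
        assert comp.ancestral_states_bm(two, {"A": 0.0, "B": 10.0}).root_state == pytest.approx(5.0)

    def test_ancestral_root_equals_gls_phylogenetic_mean(self, fixture_tree):
        anc = comp.ancestral_states_bm(fixture_tree, FIXTURE_X)
        cov = comp.phylo_covariance(fixture_tree)
        y = np.array([FIXTURE_X[t] for t in cov.taxa])
        vi = np.linalg.inv(cov.matrix)
        ones = np.ones(len(y))
        mu = float(ones @ vi @ y) / float(ones @ vi @ ones)
        assert anc.root_state == pytest.approx(mu, abs=1e-8)

    def test_ancestral_matches_dense_gls_solve(self, rng):
        # brute-force oracle: maximize the BM joint density over internal
        # states by solving the full quadratic system symbolically via lstsq
        tree = T.parse_newick("(((A:1,B:2):1,C:3):1,((D:1,E:1):2,F:2):1);")
        trait = dict(zip("ABCDEF", [1.0, 2.0, 0.5, 3.0, 3.5, 2.5]))
        anc = comp.ancestral_states_bm(tree, trait)
        # oracle: direct normal equations over internal nodes, built edge
        # by edge from scratch
        nodes = list(anc.tree.preorder_internal_node_iter())
        idx = {id(n): i for i, n in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        b = np.zeros(len(nodes))
        for nd in anc.tree.preorder_node_iter():
            if nd is anc.tree.seed_node:
                continue
            w = 1.0 / nd.edge.length
            pi = idx[id(nd.parent_node)]
            A[pi, pi] += w
            if nd.is_leaf():
                b[pi] += w * trait[nd.taxon.label]
            else:
                ci = idx[id(nd)]
                A[ci, ci] += w
                A[pi, ci] -= w
                A[ci, pi] -= w
        states = np.linalg.solve(A, b)
        for nd in nodes:
            assert anc.node_states[id(nd)] == pytest.approx(states[idx[id(nd)]], abs=1e-8)


class TestSignificantChanges:
    def test_constant_trait_flags_nothing(self, fixture_tree):
        assert comp.significant_changes(fixture_tree, {t: 5.0 for t in FIXTURE_X}) == []

    def test_injected_jump_detected(self, rng):
        tree = ultrametric_tree(rng, 60)
        hits = 0
        n = 30
        for seed in range(n):
            trait = simulate_bm_traits(tree, sigma2=1.0, lam=1.0, seed=seed)
            # +10 sigma jump on one deep clade
            clade = next(
                nd for nd in tree.preorder_internal_node_iter(exclude_seed_node=True)
                if 5 <= sum(1 for _ in nd.leaf_iter()) <= 20
            )
            members = {lf.taxon.label for lf in clade.leaf_iter()}
            jumped = {t: v + (10.0 if t in members else 0.0) for t, v in trait.items()}
            flags = comp.significant_changes(tree, jumped, alpha=0.05)
            hits += any(clade_set == members for clade_set, _, _ in flags)
        assert hits >= 0.9 * n

    def test_false_positive_rate_bounded(self, rng):
        tree = ultrametric_tree(rng, 40)
        n_branches = sum(1 for nd in tree.preorder_node_iter()
                         if nd is not tree.seed_node)
        flagged = total = 0
        for seed in range(100):
            trait = simulate_bm_traits(tree, sigma2=1.0, lam=1.0, seed=seed)
            flagged += len(comp.significant_changes(tree, trait, alpha=0.05))
            total += n_branches
        assert flagged / total <= 0.05 + 0.02
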