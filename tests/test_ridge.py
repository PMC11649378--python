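"""Rate-heterogeneous ridge model and Brownian-motion baseline."""

import numpy as np
import pytest
from scipy.linalg import solve

import genarch as ga
from genarch.ridge import _gls_mean, phylo_covariance_matrix


def test_path_matrix_two_tips():
    t = ga.read_newick("(A:1,B:1);")
    X, branches = ga.build_path_matrix(t)
    assert X.shape == (2, 2)
    assert sorted(map(tuple, X.tolist())) == [(0.0, 1.0), (1.0, 0.0)]


def test_path_matrix_three_tips(three_tip_tree):
    t = three_tip_tree
    X, branches = ga.build_path_matrix(t)
    keys = [t.clade_key(b) for b in branches]
    rowA = X[t.tip_names().index("A")]
    as_map = dict(zip(keys, rowA))
    assert as_map == {"A|B": 1.0, "A": 1.0, "B": 0.0, "C": 0.0}


def test_path_matrix_row_sums_are_depths(yule_tree):
    X, _ = ga.build_path_matrix(yule_tree)
    depths = yule_tree.depths()
    expected = np.array([depths[t] for t in yule_tree.tips()])
    assert np.allclose(X.sum(axis=1), expected)


def test_ridge_constant_trait(three_tip_tree):
    fit = ga.RidgeRateModel(three_tip_tree, {"A": 3.0, "B": 3.0, "C": 3.0}).fit()
    assert fit.root_state == pytest.approx(3.0)
    assert np.allclose(fit.beta, 0.0, atol=1e-10)
    assert all(v == pytest.approx(3.0) for v in fit.ancestral_states().values())


def test_ridge_small_lambda_matches_normal_equations(five_tip_tree):
    """λ→0 fit equals the dense ridge normal-equation solve."""
    t = five_tip_tree
    rng = np.random.default_rng(0)
    y = {n: v for n, v in zip(t.tip_names(), rng.normal(0, 1, 5))}
    lam = 1e-8
    fit = ga.RidgeRateModel(t, y).fit(lam=lam)
    X, _ = ga.build_path_matrix(t)
    yv = np.array([y[n] for n in t.tip_names()])
    root = _gls_mean(phylo_covariance_matrix(t), yv)
    beta_dense = solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ (yv - root))
    assert np.allclose(fit.beta, beta_dense, atol=1e-8)
    # near-interpolation of tips
    assert np.allclose(fit.fitted_tips.loc[t.tip_names()].values, yv, atol=1e-6)


def test_ridge_shrinkage_is_monotone(five_tip_tree):
    rng = np.random.default_rng(1)
    y = dict(zip(five_tip_tree.tip_names(), rng.normal(0, 1, 5)))
    norms = []
    for lam in (1e-4, 1e-2, 1.0, 100.0):
        fit = ga.RidgeRateModel(five_tip_tree, y).fit(lam=lam)
        norms.append(float(np.sum(fit.beta**2)))
    assert all(a > b for a, b in zip(norms, norms[1:]))


def test_ridge_requires_three_tips():
    t = ga.read_newick("(A:1,B:1);")
    with pytest.raises(ValueError):
        ga.RidgeRateModel(t, {"A": 0.0, "B": 1.0})


def test_ancestral_states_telescoping(yule_tree, rng):
    tips, _ = ga.simulate_bm(yule_tree, ga.TraitSimSpec(sigma2=0.01), rng=rng)
    fit = ga.RidgeRateModel(yule_tree, tips).fit()
    states = fit.node_states()
    beta = dict(zip(fit.model.branch_nodes, fit.beta))
    for node in yule_tree.branches():
        inc = states[node] - states[node.parent]
        assert inc == pytest.approx(beta[node] * node.length, abs=1e-10)


def test_ancestral_states_interpolate_tips_at_small_lambda(three_tip_tree):
    fit = ga.RidgeRateModel(three_tip_tree, {"A": 0.0, "B": 0.0, "C": 5.0}).fit(
        lam=1e-10
    )
    states = fit.ancestral_states()
    assert states["C"] == pytest.approx(5.0, abs=1e-6)
    assert states["A"] == pytest.approx(0.0, abs=1e-6)


def test_loocv_matches_brute_force(yule_tree, rng):
    """The SVD leave-one-out shortcut equals explicit refits."""
    tips, _ = ga.simulate_bm(yule_tree, ga.TraitSimSpec(sigma2=0.01), rng=rng)
    model = ga.RidgeRateModel(yule_tree, tips)
    root = _gls_mean(phylo_covariance_matrix(yule_tree), model.y)
    r = model.y - root
    X = model.X
    n, p = X.shape
    for lam in (1e-4, 1.0, 100.0):
        fit = model.fit(lam=lam)
        brute = []
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            beta = solve(X[mask].T @ X[mask] + lam * np.eye(p),
                         X[mask].T @ r[mask])
            brute.append((r[i] - X[i] @ beta) ** 2)
        assert fit.cv_error == pytest.approx(np.mean(brute), rel=1e-6)


def test_rescale_identity_for_equal_rates(three_tip_tree):
    fit = ga.RidgeRateModel(three_tip_tree, {"A": 1.0, "B": 1.0, "C": 1.0}).fit()
    fit.beta = np.full_like(fit.beta, 0.7)  # uniform |rate| → identity rescale
    out = ga.rescale_tree(three_tip_tree, fit)
    orig = {three_tip_tree.clade_key(b): b.length
            for b in three_tip_tree.branches()}
    for branch in out.branches():
        assert branch.length == pytest.approx(orig[out.clade_key(branch)])


def test_rescale_all_zero_rates_is_degenerate(three_tip_tree):
    fit = ga.RidgeRateModel(three_tip_tree, {"A": 1.0, "B": 1.0, "C": 1.0}).fit()
    with pytest.raises(ValueError):
        ga.rescale_tree(three_tip_tree, fit)


def test_rescale_two_branch_arithmetic():
    """|β| = (1, 3) on unit branches gives lengths (0.5, 1.5)."""
    t = ga.read_newick("((A:1,B:1):1,C:2);")
    fit = ga.RidgeRateModel(t, {"A": 0.0, "B": 0.0, "C": 0.0}).fit()
    fit.beta = np.zeros_like(fit.beta)
    keys = [t.clade_key(b) for b in fit.model.branch_nodes]
    lengths = np.array([b.length for b in fit.model.branch_nodes])
    # craft rates so |β|·ℓ = 1 on branch A and 3 on branch B, 0 elsewhere
    fit.beta[keys.index("A")] = 1.0
    fit.beta[keys.index("B")] = 3.0
    out = ga.rescale_tree(t, fit)
    by = {out.clade_key(b): b.length for b in out.branches()}
    total = sum(lengths)
    assert by["A"] == pytest.approx(total * 1 / 4)
    assert by["B"] == pytest.approx(total * 3 / 4)
    assert by["C"] == 0.0


def test_rescale_conserves_total_length(yule_tree, rng):
    tips, _ = ga.simulate_bm(yule_tree, ga.TraitSimSpec(sigma2=0.02), rng=rng)
    fit = ga.RidgeRateModel(yule_tree, tips).fit()
    out = fit.rescaled_tree()
    assert out.total_length() == pytest.approx(
        yule_tree.total_length(), rel=1e-9
    )


def test_rate_shift_inflates_clade_rates():
    """A 5× σ² clade shows larger mean |rate| than the background."""
    rng = np.random.default_rng(99)
    wins = 0
    diffs = []
    reps = 0
    while reps < 25:
        tree = ga.simulate_tree(24, 400.0, rng=rng)
        left = tree._tipset(tree.root.children[0])
        if not (3 <= len(left) <= 21):
            continue
        reps += 1
        cm = {n: ("A" if n in left else "B") for n in tree.tip_names()}
        tips, _ = ga.simulate_bm(
            tree, ga.TraitSimSpec(sigma2=1e-3, clade_rate_multipliers={"A": 5.0}),
            rng=rng, clade_map=cm,
        )
        fit = ga.RidgeRateModel(tree, tips).fit()
        labels = ga.assign_branches(tree, cm)
        lab_by_key = {tree.clade_key(b): l for b, l in labels.items()}
        rates = fit.rates
        inside = np.mean([abs(v) for k, v in rates.items() if lab_by_key[k] == "A"])
        outside = np.mean([abs(v) for k, v in rates.items() if lab_by_key[k] == "B"])
        diffs.append(inside - outside)
        wins += inside > outside
    # one-sided sign test at alpha=0.05: >=18/25 successes rejects p=0.5
    assert wins >= 18, f"rate contrast in only {wins}/25 replicates"


# ------------------------------------------------------------ BM baseline


def test_bm_star_symmetry():
    t = ga.read_newick("(A:1,B:1,C:1,D:1);")
    fit = ga.BrownianMotionModel(t, {"A": 0.0, "B": 4.0, "C": 0.0, "D": 4.0}).fit()
    assert fit.root_state == pytest.approx(2.0)


def test_bm_ancestral_matches_dense_gls_oracle(five_tip_tree, rng):
    """Conditional-mean reconstruction equals a full joint-covariance solve."""
    t = five_tip_tree
    tips, _ = ga.simulate_bm(t, ga.TraitSimSpec(sigma2=0.5, root=1.0), rng=rng)
    fit = ga.BrownianMotionModel(t, tips).fit()
    states = fit.node_states()

    # oracle: joint normal over (internal nodes, tips) with covariance =
    # depth of the shared ancestor; condition internal nodes on tips
    nodes = t.nodes()
    depth = t.depths()
    tipsets = {n: t._tipset(n) for n in nodes}

    def shared_depth(a, b):
        chain = []
        node = a
        while node is not None:
            chain.append(node)
            node = node.parent
        node = b
        while node not in chain:
            node = node.parent
        return depth[node]

    tip_nodes = t.tips()
    internal = [n for n in nodes if not n.is_leaf()]
    y = np.array([tips[n.name] for n in tip_nodes])
    Cyy = np.array([[shared_depth(a, b) for b in tip_nodes] for a in tip_nodes])
    Czy = np.array([[shared_depth(z, b) for b in tip_nodes] for z in internal])
    mu = fit.root_state
    cond = mu + Czy @ np.linalg.solve(Cyy + 1e-12 * np.eye(len(y)), y - mu)
    for node, expect in zip(internal, cond):
        assert states[node] == pytest.approx(expect, abs=1e-7)


def test_bm_sigma2_recovery_within_3se():
    """ML σ² over replicated 200-tip BM simulations recovers the truth."""
    rng = np.random.default_rng(5)
    true = 0.04
    tree = ga.simulate_tree(200, 300.0, rng=rng)
    estimates = []
    for _ in range(30):
        tips, _ = ga.simulate_bm(tree, ga.TraitSimSpec(sigma2=true), rng=rng)
        estimates.append(ga.BrownianMotionModel(tree, tips).fit().sigma2)
    mean = np.mean(estimates)
    se_mean = true * np.sqrt(2 / 200) / np.sqrt(30)
    assert abs(mean - true) < 3 * se_mean + true / 200  # ML bias ~ σ²/n


def test_bm_loglik_is_finite_and_aic_consistent(yule_tree, rng):
    tips, _ = ga.simulate_bm(yule_tree, ga.TraitSimSpec(sigma2=0.01), rng=rng)
    fit = ga.BrownianMotionModel(yule_tree, tips).fit()
    assert np.isfinite(fit.loglik)
    assert fit.aic == pytest.approx(4 - 2 * fit.loglik)
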