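"""Weighted GP-IRL: EBF features, kernel, weighted likelihood, reward field,
and the reward-to-modulation mapping."""

import numpy as np
import pytest

from errpirl.ds import ModulationParams, integrate_trajectory, min_clearance
from errpirl.irl import (
    Demonstration,
    EBFBasis,
    GPRewardIRL,
    GPRewardModel,
    cross_kernel,
    default_basis,
    ebf_features,
    finite_difference_gradient,
    gp_kernel,
    optimize_modulation,
    resample_arclength,
    reward_at,
    trajectory_reward,
    weighted_log_likelihood,
)


@pytest.fixture(scope="module")
def basis(scene):
    return default_basis(scene)


def _demo(rollout, scene, rho, eta, w):
    return Demonstration(path=rollout(rho, eta), weight=w, scene=scene)


# -- EBF features ------------------------------------------------------------

def test_ebf_at_center_is_one_and_decays(basis, scene):
    f = ebf_features(scene.obstacle_arr, basis)
    assert np.allclose(f, 1.0)
    far = ebf_features(scene.obstacle_arr + np.array([50.0, 0.0]), basis)
    assert np.all(far < 1e-12)


def test_ebf_matches_quadratic_form_oracle(basis):
    rng = np.random.default_rng(0)
    for _ in range(30):
        xi = rng.uniform(-0.5, 0.5, size=2)
        f = ebf_features(xi, basis)
        for k in range(basis.n_features):
            d = xi - basis.center
            q = d @ basis.lambdas[k] @ d
            assert f[k] == pytest.approx(np.exp(-0.5 * basis.zetas[k] * q))
        assert np.all((f > 0) & (f <= 1))


def test_ebf_basis_validation():
    with pytest.raises(ValueError):
        EBFBasis(center=np.zeros(2), zetas=np.array([1.0, 2.0, 3.0]),
                 lambdas=np.stack([np.eye(2), -np.eye(2), np.eye(2)]))
    with pytest.raises(ValueError):
        EBFBasis(center=np.zeros(2), zetas=np.array([1.0, 1.0, 3.0]),
                 lambdas=np.stack([np.eye(2)] * 3))
    with pytest.raises(ValueError):
        ebf_features(np.array([np.inf, 0.0]),
                     EBFBasis(center=np.zeros(2), zetas=np.array([1.0, 2.0, 3.0]),
                              lambdas=np.stack([np.eye(2)] * 3)))


# -- GP kernel ----------------------------------------------------------------

def test_kernel_diagonal_equals_beta():
    rng = np.random.default_rng(1)
    F = rng.uniform(0, 1, size=(7, 3))
    K = gp_kernel(F, np.array([0.5, 1.0, 2.0]), beta=1.7, sigma2=0.05)
    assert np.allclose(np.diag(K), 1.7)
    assert np.allclose(K, K.T)


def test_kernel_lambda_zero_all_entries_beta():
    rng = np.random.default_rng(2)
    F = rng.uniform(0, 1, size=(5, 3))
    K = gp_kernel(F, np.zeros(3), beta=2.5, sigma2=0.3)
    assert np.allclose(K, 2.5)


def test_kernel_matches_nested_loop_oracle():
    rng = np.random.default_rng(3)
    F = rng.uniform(0, 1, size=(5, 3))
    lam = np.array([0.8, 1.5, 0.1])
    beta, sigma2 = 1.3, 0.07
    K = gp_kernel(F, lam, beta, sigma2)
    for i in range(5):
        for j in range(5):
            s = 0.0
            for k in range(3):
                s += lam[k] * ((F[i, k] - F[j, k]) ** 2 + (sigma2 if i != j else 0.0))
            assert K[i, j] == pytest.approx(beta * np.exp(-0.5 * s))


# -- weighted likelihood -----------------------------------------------------

def _loglik_oracle(y, K, lam):
    """Independent dense-linear-algebra evaluation of one demo's term."""
    Kj = K + 1e-8 * K[0, 0] * np.eye(len(y))
    Kinv = np.linalg.inv(Kj)
    _, logdet = np.linalg.slogdet(Kj)
    prior = -0.5 * np.trace(Kinv @ Kinv) - np.sum(np.log(lam + 1.0))
    return -0.5 * y @ Kinv @ y - 0.5 * logdet + prior


def test_weighted_likelihood_linearity_and_zero_weight(rollout, scene, basis):
    d1 = _demo(rollout, scene, 1.5, 1.2, 1.0)
    model = GPRewardIRL([d1], seed=0).fit().model

    # single demo with w = 1 equals the unweighted value (oracle)
    pts = resample_arclength(d1.path)
    rel = ebf_features(pts, basis).max(axis=1) >= 0.05
    F1 = ebf_features(pts[rel], basis)
    K1 = gp_kernel(F1, model.lam, model.beta, model.sigma2)
    oracle = _loglik_oracle(model.y, K1, model.lam)
    assert weighted_log_likelihood([d1], model) == pytest.approx(oracle, rel=1e-9)

    # two identical demos with weights 0.3 / 0.7 sum to the single-demo value
    d03 = Demonstration(path=d1.path, weight=0.3, scene=scene)
    d07 = Demonstration(path=d1.path, weight=0.7, scene=scene)
    model2 = GPRewardModel(F=model.F, y=np.concatenate([model.y, model.y]),
                           lam=model.lam, beta=model.beta, sigma2=model.sigma2,
                           basis=model.basis)
    both = weighted_log_likelihood([d03, d07], model2)
    assert both == pytest.approx(oracle, rel=1e-9)

    # w = 0 demo contributes exactly nothing
    d0 = Demonstration(path=rollout(2.0, 1.8), weight=0.0, scene=scene)
    assert weighted_log_likelihood([d1, d0], model) == pytest.approx(oracle, rel=1e-9)


def test_fit_determinism_and_random_draw_sanity(rollout, scene):
    demos = [_demo(rollout, scene, 1.5, 1.1, 0.9),
             _demo(rollout, scene, 1.5, 1.8, 0.2)]
    m1 = GPRewardIRL(demos, seed=3).fit().model
    m2 = GPRewardIRL(demos, seed=3).fit().model
    assert np.array_equal(m1.lam, m2.lam)
    assert m1.beta == m2.beta
    assert np.array_equal(m1.y, m2.y)

    irl = GPRewardIRL(demos, seed=3)
    best = irl.objective(m1.y, m1.lam, m1.beta)
    rng = np.random.default_rng(4)
    for _ in range(100):
        y = rng.normal(0.5, 0.5, size=m1.y.size)
        lam = rng.uniform(5.0, 150.0, size=3)
        beta = rng.uniform(0.5, 2.0)
        assert irl.objective(y, lam, beta) <= best + 1e-6


def test_fit_requires_positive_weight(scene, rollout):
    d0 = Demonstration(path=rollout(1.5, 1.2), weight=0.0, scene=scene)
    with pytest.raises(ValueError):
        GPRewardIRL([d0], seed=0)


def test_identical_demos_reward_peaks_near_their_path(rollout, scene):
    demos = [_demo(rollout, scene, 1.5, 1.4, 1.0) for _ in range(3)]
    res = GPRewardIRL(demos, seed=0).fit()
    path = demos[0].path
    d = np.linalg.norm(path.states - scene.obstacle_arr, axis=1)
    closest = path.states[int(np.argmin(d))]
    r_demo = res.reward_at(closest)
    n_hat = (closest - scene.obstacle_arr) / np.linalg.norm(closest - scene.obstacle_arr)
    far = scene.obstacle_arr + n_hat * (np.min(d) + 2 * 1.4 * scene.obstacle_radius)
    assert r_demo > res.reward_at(far)


# -- reward field ------------------------------------------------------------

def _toy_model(basis, y, lam=None, beta=1.0, sigma2=1e-4):
    rng = np.random.default_rng(5)
    pts = rng.uniform(-0.3, 0.3, size=(len(y), 2))
    F = ebf_features(pts, basis)
    return GPRewardModel(F=F, y=np.asarray(y, float),
                         lam=lam if lam is not None else np.ones(3) * 10.0,
                         beta=beta, sigma2=sigma2, basis=basis)


def test_reward_zero_outputs_give_zero_field(basis, scene):
    m = _toy_model(basis, np.zeros(6))
    rng = np.random.default_rng(6)
    for _ in range(10):
        assert reward_at(m, rng.uniform(-0.5, 0.5, size=2)) == 0.0
    assert trajectory_reward(ModulationParams(1.2, 1.3), m, scene) == 0.0


def test_reward_matches_dense_linear_algebra_oracle(basis):
    rng = np.random.default_rng(7)
    m = _toy_model(basis, rng.normal(size=8))
    for _ in range(10):
        xi = rng.uniform(-0.5, 0.5, size=2)
        f = ebf_features(xi, basis)
        K = gp_kernel(m.F, m.lam, m.beta, m.sigma2) + 1e-8 * m.beta * np.eye(8)
        k_star = cross_kernel(f, m.F, m.lam, m.beta, m.sigma2).ravel()
        oracle = k_star @ np.linalg.solve(K, m.y)
        assert reward_at(m, xi) == pytest.approx(oracle, rel=1e-8)


def test_gp_interpolation_in_noiseless_limit(basis):
    # well-separated inducing features: reward at an inducing point -> y_j
    pts = np.array([[0.0, 0.07], [0.0, 0.2], [0.3, 0.0]]) + basis.center
    F = ebf_features(pts, basis)
    y = np.array([0.9, 0.2, -0.4])
    m = GPRewardModel(F=F, y=y, lam=np.array([200.0, 200.0, 200.0]), beta=1.0,
                      sigma2=0.0, basis=basis)
    for j, p in enumerate(pts):
        assert reward_at(m, p) == pytest.approx(y[j], abs=1e-4)


def test_doubling_outputs_doubles_trajectory_reward(basis, scene):
    rng = np.random.default_rng(8)
    y = rng.normal(size=8)
    m1 = _toy_model(basis, y)
    m2 = _toy_model(basis, 2 * y)
    params = ModulationParams(1.4, 1.5)
    assert trajectory_reward(params, m2, scene) == pytest.approx(
        2 * trajectory_reward(params, m1, scene), rel=1e-9)


def _ring_model(scene, clearance, width=0.02):
    """Planted preference: reward peaked on the ring at the given clearance."""
    basis = default_basis(scene)
    radius = scene.obstacle_radius + clearance
    angles = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    ring = scene.obstacle_arr + radius * np.column_stack([np.cos(angles), np.sin(angles)])
    inner = scene.obstacle_arr + (radius - width) * np.column_stack(
        [np.cos(angles), np.sin(angles)])
    outer = scene.obstacle_arr + (radius + width) * np.column_stack(
        [np.cos(angles), np.sin(angles)])
    pts = np.vstack([ring, inner, outer])
    y = np.concatenate([np.full(24, 1.0), np.full(24, -0.5), np.full(24, -0.5)])
    F = ebf_features(pts, basis)
    return GPRewardModel(F=F, y=y, lam=np.full(3, 400.0), beta=1.0, sigma2=1e-3,
                         basis=basis)


def test_planted_ring_grid_search_oracle(scene, start):
    # R is maximized near the (rho, eta) whose rollout clearance matches the ring
    target = 0.035
    m = _ring_model(scene, target)
    best, best_clear = -np.inf, None
    for rho in np.linspace(0.8, 3.0, 5):
        for eta in np.linspace(0.8, 2.4, 12):
            params = ModulationParams(rho, eta)
            R = trajectory_reward(params, m, scene)
            if R > best:
                path = integrate_trajectory(start, scene, params)
                best, best_clear = R, min_clearance(path, scene)
    assert best_clear == pytest.approx(target, abs=0.01)


def test_optimizer_recovers_planted_clearance(scene, start):
    target = 0.035
    m = _ring_model(scene, target)
    opt = optimize_modulation(m, scene, ModulationParams(1.0, 1.2), seed=0)
    path = integrate_trajectory(start, scene, opt)
    assert min_clearance(path, scene) == pytest.approx(target, rel=0.10)


def test_optimizer_returns_init_for_constant_reward(basis, scene):
    m = _toy_model(basis, np.zeros(6))
    init = ModulationParams(1.3, 1.7)
    opt = optimize_modulation(m, scene, init, seed=0)
    assert (opt.rho, opt.eta) == (init.rho, init.eta)


def test_finite_difference_gradient_matches_central_oracle(scene):
    m = _ring_model(scene, 0.03)
    params = ModulationParams(1.6, 1.4)
    eps = 1e-3
    g = finite_difference_gradient(params, m, scene, epsilon=eps)

    def R(rho, eta):
        return trajectory_reward(ModulationParams(rho, eta), m, scene)

    central_rho = -(R(params.rho + eps, params.eta) - R(params.rho - eps, params.eta)) / (2 * eps)
    central_eta = -(R(params.rho, params.eta + eps) - R(params.rho, params.eta - eps)) / (2 * eps)
    # forward difference agrees with the central oracle to O(eps) curvature
    assert g[0] == pytest.approx(central_rho, abs=50 * eps + 0.05 * abs(central_rho))
    assert g[1] == pytest.approx(central_eta, abs=50 * eps + 0.05 * abs(central_eta))


def test_model_json_roundtrip(basis):
    rng = np.random.default_rng(9)
    m = _toy_model(basis, rng.normal(size=5))
    back = GPRewardModel.from_json(m.to_json())
    assert np.allclose(back.F, m.F)
    assert np.allclose(back.y, m.y)
    xi = np.array([0.05, 0.02])
    assert reward_at(back, xi) == pytest.approx(reward_at(m, xi), rel=1e-12)


def test_demonstration_weight_bounds(scene, rollout):
    with pytest.raises(ValueError):
        Demonstration(path=rollout(1.2, 1.2), weight=1.5, scene=scene)
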