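import numpy as np
import pytest

from dapnet import covpool as cp
from dapnet.exceptions import DegenerateInput, NotConvergedWarning
from dapnet.nn.tensor import Tensor

from conftest import random_psd


# ---------------------------------------------------------------------------
# flatten_spatial
# ---------------------------------------------------------------------------

def test_flatten_single_location():
    x = cp.FeatureMap(np.array([[[3.0]], [[5.0]]]))
    f = cp.flatten_spatial(x)
    assert f.matrix.shape == (2, 1)
    np.testing.assert_array_equal(f.matrix, [[3.0], [5.0]])
    assert f.n_locations == 1


def test_flatten_row_major():
    x = cp.FeatureMap(np.array([[[1.0, 2.0], [3.0, 4.0]]]))
    f = cp.flatten_spatial(x)
    np.testing.assert_array_equal(f.matrix, [[1.0, 2.0, 3.0, 4.0]])


def test_flatten_round_trip(rng):
    vals = rng.normal(size=(5, 3, 4))
    f = cp.flatten_spatial(cp.FeatureMap(vals))
    np.testing.assert_array_equal(f.matrix.reshape(5, 3, 4), vals)


# ---------------------------------------------------------------------------
# compute_covariance
# ---------------------------------------------------------------------------

def test_covariance_constant_columns():
    f = cp.FlattenedFeatures(np.tile([[2.0], [7.0]], (1, 6)))
    c = cp.compute_covariance(f)
    np.testing.assert_allclose(c.matrix, 0.0, atol=1e-14)
    assert c.trace_pre_norm == pytest.approx(0.0, abs=1e-14)


def test_covariance_hand_case():
    # columns (1,0) and (-1,0): mean (0,0); C = [[1,0],[0,0]]
    f = cp.FlattenedFeatures(np.array([[1.0, -1.0], [0.0, 0.0]]))
    c = cp.compute_covariance(f)
    np.testing.assert_allclose(c.matrix, [[1.0, 0.0], [0.0, 0.0]], atol=1e-14)


def test_covariance_matches_centering_matrix_form(rng):
    m = rng.normal(size=(4, 20))
    c = cp.compute_covariance(cp.FlattenedFeatures(m))
    explicit = m @ cp.centering_matrix(20) @ m.T
    np.testing.assert_allclose(c.matrix, explicit, atol=1e-10)


def test_loop_vs_matrix_form_equivalence(rng):
    """Definition-by-sum and centering-matrix forms agree on 200 random inputs."""
    for _ in range(200):
        d = int(rng.integers(1, 17))
        n = int(rng.integers(1, 65))
        m = rng.normal(size=(d, n)) * rng.uniform(0.1, 10.0)
        mu = m.mean(axis=1, keepdims=True)
        loop = sum(np.outer(m[:, j] - mu[:, 0], m[:, j] - mu[:, 0]) for j in range(n)) / n
        matrix = m @ cp.centering_matrix(n) @ m.T
        np.testing.assert_allclose(loop, matrix, atol=1e-10)
        np.testing.assert_allclose(
            cp.compute_covariance(cp.FlattenedFeatures(m)).matrix, loop, atol=1e-10)


# ---------------------------------------------------------------------------
# trace_normalize
# ---------------------------------------------------------------------------

def test_trace_normalize_identity():
    c = cp.trace_normalize(cp.CovarianceDescriptor(np.eye(4), 0.0))
    np.testing.assert_allclose(c.matrix, np.eye(4) / 4.0)
    assert c.trace_pre_norm == pytest.approx(4.0)


def test_trace_normalize_diag():
    c = cp.trace_normalize(cp.CovarianceDescriptor(np.diag([3.0, 1.0]), 0.0))
    np.testing.assert_allclose(c.matrix, np.diag([0.75, 0.25]))
    assert c.trace_pre_norm == pytest.approx(4.0)


def test_trace_normalize_zero_matrix_raises():
    with pytest.raises(DegenerateInput):
        cp.trace_normalize(cp.CovarianceDescriptor(np.zeros((3, 3)), 0.0))


# ---------------------------------------------------------------------------
# newton_schulz_sqrt
# ---------------------------------------------------------------------------

def _scalar_ns(a: float, n: int) -> float:
    y, m = a, 1.0
    for _ in range(n):
        t = 0.5 * (3.0 - m * y)
        y, m = y * t, t * m
    return y


@pytest.mark.parametrize("d", [2, 4, 16, 64])
def test_ns_identity_over_d_matches_scalar_recursion(d):
    desc = cp.CovarianceDescriptor(np.eye(d) / d, 1.0)
    it = cp.newton_schulz_sqrt(desc, 5, residual_tol=np.inf)
    expected = _scalar_ns(1.0 / d, 5)
    np.testing.assert_allclose(it.Y, expected * np.eye(d), atol=1e-12)
    # iterates head toward sqrt(1/d) * I
    assert abs(expected - np.sqrt(1.0 / d)) < abs(1.0 / d - np.sqrt(1.0 / d))


def test_ns_matches_eig_oracle_small_diag():
    desc = cp.CovarianceDescriptor(np.diag([0.75, 0.25]), 1.0)
    it = cp.newton_schulz_sqrt(desc, 5)
    oracle = np.diag([np.sqrt(0.75), np.sqrt(0.25)])
    assert np.linalg.norm(it.Y - oracle) / np.linalg.norm(oracle) < 1e-3


def test_ns_zero_iterations_returns_input():
    c = np.diag([0.6, 0.4])
    it = cp.newton_schulz_sqrt(cp.CovarianceDescriptor(c, 1.0), 0)
    np.testing.assert_array_equal(it.Y, c)
    assert it.n_iter == 0


def test_ns_warns_when_not_converged():
    d = 64
    desc = cp.CovarianceDescriptor(np.eye(d) / d, 1.0)
    with pytest.warns(NotConvergedWarning):
        cp.newton_schulz_sqrt(desc, 1)


def test_ns_symmetry_of_iterates(rng):
    c = random_psd(rng, 12)
    it = cp.newton_schulz_sqrt(cp.CovarianceDescriptor(c, 1.0), 5,
                               residual_tol=np.inf)
    assert np.abs(it.Y - it.Y.T).max() < 1e-9
    assert np.abs(it.M_aux - it.M_aux.T).max() < 1e-9


def test_ns_monotone_refinement(rng):
    """Oracle residual is non-increasing over iterations 1..5."""
    for _ in range(20):
        d = int(rng.integers(2, 33))
        c = random_psd(rng, d, cond=1e3)
        desc = cp.CovarianceDescriptor(c, 1.0)
        oracle = cp.matrix_power_eig(desc, 0.5)
        prev = np.inf
        for n in range(1, 6):
            it = cp.newton_schulz_sqrt(desc, n, residual_tol=np.inf)
            err = np.linalg.norm(it.Y - oracle) / np.linalg.norm(oracle)
            assert err <= prev + 1e-9
            prev = err


# ---------------------------------------------------------------------------
# post_compensate / matrix_power_eig
# ---------------------------------------------------------------------------

def test_post_compensate_trace_one_is_identity_op(rng):
    y = cp.SqrtIterates(rng.normal(size=(3, 3)), np.eye(3), 5)
    np.testing.assert_array_equal(cp.post_compensate(y, 1.0), y.Y)


def test_post_compensate_identity_closed_form():
    # C = I_2 (trace 2): C_hat = I/2, sqrt = sqrt(1/2) I, M = sqrt(2)*sqrt(1/2)*I = I
    desc = cp.trace_normalize(cp.CovarianceDescriptor(np.eye(2), 0.0))
    it = cp.newton_schulz_sqrt(desc, 20, residual_tol=np.inf)
    m = cp.post_compensate(it, desc.trace_pre_norm)
    np.testing.assert_allclose(m, np.eye(2), atol=1e-6)


def test_post_compensate_zero_trace():
    y = cp.SqrtIterates(np.ones((2, 2)), np.eye(2), 5)
    np.testing.assert_array_equal(cp.post_compensate(y, 0.0), np.zeros((2, 2)))


def test_power_eig_diag():
    out = cp.matrix_power_eig(cp.CovarianceDescriptor(np.diag([4.0, 1.0]), 0.0), 0.5)
    np.testing.assert_allclose(out, np.diag([2.0, 1.0]), atol=1e-12)


def test_power_eig_exponent_one(rng):
    c = random_psd(rng, 6, trace_one=False)
    out = cp.matrix_power_eig(cp.CovarianceDescriptor(c, 0.0), 1.0)
    np.testing.assert_allclose(out, c, atol=1e-10)


def test_power_eig_sqrt_defining_property(rng):
    c = random_psd(rng, 6, trace_one=False)
    root = cp.matrix_power_eig(cp.CovarianceDescriptor(c, 0.0), 0.5)
    np.testing.assert_allclose(root @ root, c, atol=1e-8)


# ---------------------------------------------------------------------------
# second_order_pool / sop_vectorize
# ---------------------------------------------------------------------------

def test_pool_constant_map_is_zero():
    out = cp.second_order_pool(cp.FeatureMap(np.full((3, 4, 4), 2.5)))
    np.testing.assert_array_equal(out, np.zeros((3, 3)))


def test_pool_identity_covariance():
    # rows are orthogonal sign patterns with zero mean and unit variance
    f = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]]).reshape(2, 2, 2)
    out = cp.second_order_pool(cp.FeatureMap(f), n_iter=5)
    np.testing.assert_allclose(out, np.eye(2), atol=1e-3)


def test_pool_agrees_with_eig_oracle(rng):
    x = cp.FeatureMap(rng.normal(size=(8, 7, 7)))
    pooled = cp.second_order_pool(x)
    cov = cp.compute_covariance(cp.flatten_spatial(x))
    oracle = cp.matrix_power_eig(cov, 0.5)
    rel = np.linalg.norm(pooled - oracle) / np.linalg.norm(oracle)
    assert rel < 1e-2


def test_pool_scale_consistency(rng):
    x = rng.normal(size=(4, 5, 5))
    base_cov = cp.compute_covariance(cp.flatten_spatial(cp.FeatureMap(x))).matrix
    base = cp.second_order_pool(cp.FeatureMap(x))
    for k in (0.5, 2.0):
        cov_k = cp.compute_covariance(cp.flatten_spatial(cp.FeatureMap(k * x))).matrix
        np.testing.assert_allclose(cov_k, k ** 2 * base_cov, atol=1e-9)
        np.testing.assert_allclose(cp.second_order_pool(cp.FeatureMap(k * x)),
                                   abs(k) * base, rtol=5e-3, atol=1e-6)


def test_pool_output_symmetric_psd(rng):
    out = cp.second_order_pool(cp.FeatureMap(rng.normal(size=(6, 4, 4))))
    assert np.abs(out - out.T).max() < 1e-5
    assert np.linalg.eigvalsh((out + out.T) / 2).min() > -1e-5


def test_vectorize_full_and_upper():
    np.testing.assert_array_equal(cp.sop_vectorize(np.eye(2), "full"), [1, 0, 0, 1])
    np.testing.assert_array_equal(cp.sop_vectorize(np.eye(2), "upper"), [1, 0, 1])


def test_vectorize_round_trip(rng):
    a = rng.normal(size=(5, 5))
    sym = (a + a.T) / 2
    np.testing.assert_array_equal(cp.sop_vectorize(sym, "full").reshape(5, 5), sym)


# ---------------------------------------------------------------------------
# differentiable batched pipeline
# ---------------------------------------------------------------------------

def test_sop_tensor_matches_reference(rng):
    x = rng.normal(size=(2, 6, 5, 5))
    out = cp.sop_tensor(Tensor(x))
    for b in range(2):
        ref = cp.second_order_pool(cp.FeatureMap(x[b]))
        np.testing.assert_allclose(out.data[b], ref, atol=1e-8)


def test_sop_tensor_gradient_finite_difference(rng):
    x = rng.normal(size=(1, 3, 2, 2))
    xt = Tensor(x.copy(), requires_grad=True)
    w = rng.normal(size=(1, 3, 3))
    (cp.sop_tensor(xt) * Tensor(w)).sum().backward()
    eps = 1e-6
    for idx in [(0, 0, 0, 0), (0, 1, 1, 0), (0, 2, 0, 1)]:
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        fp = float((cp.sop_tensor(Tensor(xp)).data * w).sum())
        fm = float((cp.sop_tensor(Tensor(xm)).data * w).sum())
        num = (fp - fm) / (2 * eps)
        assert xt.grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-6)
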