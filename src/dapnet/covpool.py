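"""Second-order (covariance) pooling with Newton-Schulz matrix square root.

The functional API here works on plain NumPy arrays in float64 and is the
reference implementation: spatial flattening, covariance with trace
pre-normalization, the coupled Newton-Schulz iteration, post-compensation,
and an eigendecomposition oracle for the matrix power.  A differentiable
batched version of the same pipeline (used inside the network) lives in
:func:`sop_tensor`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInput, NotConvergedWarning, ShapeMismatch
from .nn.tensor import Tensor

logger = logging.getLogger(__name__)

DEFAULT_N_ITER = 5          # "specifically five in this case"
DEFAULT_POWER_EXPONENT = 0.5
TRACE_EPS = 1e-12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureMap:
    """Activation block of shape [C, H, W]."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ShapeMismatch(f"feature map must be [C,H,W], got shape {self.values.shape}")
        if min(self.values.shape) < 1:
            raise ShapeMismatch("all dimensions must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature map contains non-finite entries")

    @property
    def channels(self) -> int:
        return self.values.shape[0]


@dataclass
class FlattenedFeatures:
    """Channel-by-location matrix [d, N], N = H*W."""

    matrix: np.ndarray
    spatial_shape: tuple[int, int] | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ShapeMismatch("flattened features must be 2-D [d, N]")

    @property
    def n_locations(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CovarianceDescriptor:
    """Symmetric PSD matrix [d, d] plus the trace it had before normalization."""

    matrix: np.ndarray
    trace_pre_norm: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ShapeMismatch("covariance must be square")
        asym = np.abs(self.matrix - self.matrix.T).max() if self.matrix.size else 0.0
        if asym > 1e-6:
            raise ValueError(f"covariance asymmetry {asym:.2e} exceeds 1e-6")


@dataclass
class SqrtIterates:
    """State of the coupled Newton-Schulz iteration."""

    Y: np.ndarray
    M_aux: np.ndarray
    n_iter: int
    residual: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def flatten_spatial(x: FeatureMap) -> FlattenedFeatures:
    """Reshape [C, H, W] into [d=C, N=H*W] with row-major spatial order."""
    c, h, w = x.values.shape
    return FlattenedFeatures(x.values.reshape(c, h * w), spatial_shape=(h, w))


def centering_matrix(n: int) -> np.ndarray:
    """Ī = (1/N)(I − (1/N) J Jᵀ), J the length-N all-ones vector."""
    j = np.ones((n, 1))
    return (np.eye(n) - (j @ j.T) / n) / n


def compute_covariance(f: FlattenedFeatures) -> CovarianceDescriptor:
    """C = (1/N) Σ_j (f_j − μ)(f_j − μ)ᵀ  (equals F Ī Fᵀ)."""
    m = f.matrix
    n = m.shape[1]
    centered = m - m.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / n
    cov = (cov + cov.T) / 2.0
    return CovarianceDescriptor(cov, float(np.trace(cov)))


def trace_normalize(c: CovarianceDescriptor, eps: float = TRACE_EPS) -> CovarianceDescriptor:
    """Ĉ = C / tr(C); raises :class:`DegenerateInput` when the trace vanishes."""
    tr = float(np.trace(c.matrix))
    if tr <= eps:
        raise DegenerateInput(f"covariance trace {tr:.3e} <= {eps:.0e}")
    return CovarianceDescriptor(c.matrix / tr, trace_pre_norm=tr)


def newton_schulz_sqrt(c_hat: CovarianceDescriptor, n_iter: int = DEFAULT_N_ITER,
                       residual_tol: float = 0.05) -> SqrtIterates:
    """Coupled iteration Y_n = ½ Y_{n−1}(3I − M_{n−1} Y_{n−1}),
    M_n = ½ (3I − M_{n−1} Y_{n−1}) M_{n−1}, from Y_0 = Ĉ, M_0 = I.

    Expects a trace-normalized input (tr ≈ 1) for convergence.  Emits a
    :class:`NotConvergedWarning` when the relative residual of Y·Y vs Ĉ
    exceeds ``residual_tol`` after ``n_iter`` steps.
    """
    a = c_hat.matrix
    d = a.shape[0]
    eye = np.eye(d)
    y = a.copy()
    m = eye.copy()
    for _ in range(n_iter):
        t = 0.5 * (3.0 * eye - m @ y)
        y = y @ t
        m = t @ m
        y = (y + y.T) / 2.0
        m = (m + m.T) / 2.0
    denom = np.linalg.norm(a)
    residual = np.linalg.norm(y @ y - a) / denom if denom > 0 else 0.0
    if n_iter > 0 and residual > residual_tol:
        warnings.warn(
            f"Newton-Schulz residual {residual:.3g} > {residual_tol} after {n_iter} iterations",
            NotConvergedWarning, stacklevel=2)
    return SqrtIterates(Y=y, M_aux=m, n_iter=n_iter, residual=float(residual))


def post_compensate(y: SqrtIterates, trace_pre_norm: float) -> np.ndarray:
    """M = sqrt(tr C) · Y_N — restores the scale of the un-normalized covariance."""
    if trace_pre_norm < 0:
        raise ValueError("trace must be nonnegative")
    return np.sqrt(trace_pre_norm) * y.Y


def matrix_power_eig(c: CovarianceDescriptor, exponent: float = DEFAULT_POWER_EXPONENT) -> np.ndarray:
    """Oracle: C^α via eigendecomposition, eigenvalues clamped at 0 before powering."""
    lam, u = np.linalg.eigh((c.matrix + c.matrix.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    return (u * lam ** exponent) @ u.T


def second_order_pool(x: FeatureMap, n_iter: int = DEFAULT_N_ITER) -> np.ndarray:
    """End-to-end: flatten → covariance → trace-normalize → NS sqrt → post-compensate.

    A zero-variance (constant) map yields the zero matrix rather than an error.
    """
    cov = compute_covariance(flatten_spatial(x))
    try:
        c_hat = trace_normalize(cov)
    except DegenerateInput:
        logger.warning("second_order_pool: degenerate (zero-trace) covariance; returning zeros")
        return np.zeros_like(cov.matrix)
    it = newton_schulz_sqrt(c_hat, n_iter=n_iter)
    return post_compensate(it, c_hat.trace_pre_norm)


def sop_vectorize(m: np.ndarray, mode: str = "full") -> np.ndarray:
    """Flatten a symmetric matrix: ``full`` → row-major C², ``upper`` → C(C+1)/2."""
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ShapeMismatch("expected a square matrix")
    if np.abs(m - m.T).max(initial=0.0) > 1e-5:
        raise ValueError("matrix is not symmetric within tolerance")
    if mode == "full":
        return m.reshape(-1).copy()
    if mode == "upper":
        return m[np.triu_indices(m.shape[0])].copy()
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Differentiable batched pipeline (autograd Tensors)
# ---------------------------------------------------------------------------

def batched_covariance(x: Tensor) -> tuple[Tensor, Tensor]:
    """[B,C,H,W] → (covariance [B,C,C], trace [B,1,1]); differentiable."""
    b, c, h, w = x.shape
    f = x.reshape(b, c, h * w)
    mu = f.mean(axis=2, keepdims=True)
    centered = f - mu
    cov = centered @ centered.transpose_last() * (1.0 / (h * w))
    tr = cov.diagonal_last().sum(axis=-1).reshape(b, 1, 1)
    return cov, tr


def sop_tensor(x: Tensor, n_iter: int = DEFAULT_N_ITER, eps: float = 1e-8) -> Tensor:
    """Differentiable second-order pooling: [B,C,H,W] → [B,C,C].

    Same math as :func:`second_order_pool`; the trace is floored at ``eps``
    so zero-variance samples flow through as (near-)zero matrices instead of
    raising mid-batch.
    """
    b, c, _, _ = x.shape
    cov, tr = batched_covariance(x)
    tr_safe = tr + eps
    c_hat = cov * tr_safe ** -1.0
    eye = Tensor(np.broadcast_to(np.eye(c, dtype=x.dtype), (b, c, c)).copy())
    y, m = c_hat, eye
    for _ in range(n_iter):
        t = (eye * 3.0 - m @ y) * 0.5
        y = y @ t
        m = t @ m
    return y * tr_safe ** 0.5
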