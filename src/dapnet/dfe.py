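"""Dynamic feature-enhancement gate.

A learned scalar gate ``alpha`` (sigmoid of the mean of a linear map of the
channel descriptor) selects or blends the second-order-pooling branch and the
squeeze-excitation branch, and emits the balance regularizer (alpha - 0.5)^2,
which is applied as an *additive* loss penalty.

Functional single-sample reference API plus the batched network modules
(:class:`DFEIntermediate`, shape-preserving, and :class:`DFEHead`, vector
fusion before the classifier).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attention import ChannelDescriptor, SEBlock
from .covpool import sop_tensor
from .exceptions import MissingBranchInput, ShapeMismatch
from .nn.tensor import Tensor, _sigmoid

DEFAULT_TAU = 0.5
DEFAULT_REG_WEIGHT = 0.01


@dataclass
class GateParams:
    """Learnable gate parameters W_d [C, C], b_d [C] and gate configuration."""

    W_d: np.ndarray
    b_d: np.ndarray
    tau: float = DEFAULT_TAU
    mode: str = "hard"
    reg_weight: float = DEFAULT_REG_WEIGHT

    def __post_init__(self):
        self.W_d = np.asarray(self.W_d, dtype=np.float64)
        self.b_d = np.asarray(self.b_d, dtype=np.float64).reshape(-1)
        if self.W_d.ndim != 2 or self.W_d.shape[0] != self.W_d.shape[1]:
            raise ShapeMismatch("W_d must be square [C, C]")
        if self.b_d.shape[0] != self.W_d.shape[0]:
            raise ShapeMismatch("b_d length must equal C")
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie strictly inside (0, 1)")
        if self.mode not in ("hard", "soft"):
            raise ValueError("mode must be 'hard' or 'soft'")
        if self.reg_weight < 0:
            raise ValueError("reg_weight must be nonnegative")


@dataclass
class GateDecision:
    """Gate value, selected branch, and the balance regularizer (alpha-0.5)^2."""

    alpha: float
    branch: str
    regularizer: float = field(init=False)

    def __post_init__(self):
        self.regularizer = (self.alpha - 0.5) ** 2


def gate(s_c: ChannelDescriptor, p: GateParams) -> GateDecision:
    """z = W_d s_c + b_d; alpha = sigmoid(mean(z)); branch 'sop' iff alpha > tau."""
    if s_c.z.shape[0] != p.W_d.shape[1]:
        raise ShapeMismatch(
            f"descriptor length {s_c.z.shape[0]} != gate width {p.W_d.shape[1]}")
    z_vec = p.W_d @ s_c.z + p.b_d
    alpha = float(_sigmoid(np.asarray(z_vec.mean())))
    branch = "sop" if alpha > p.tau else "senet"
    return GateDecision(alpha=alpha, branch=branch)


def dfe_apply_soft(s_sqrt_vec: np.ndarray, h_prime_vec: np.ndarray,
                   alpha: float) -> np.ndarray:
    """Elementwise convex combination alpha*a + (1-alpha)*b."""
    a = np.asarray(s_sqrt_vec, dtype=np.float64)
    b = np.asarray(h_prime_vec, dtype=np.float64)
    if a.shape != b.shape:
        raise ShapeMismatch(f"branch shapes differ: {a.shape} vs {b.shape}")
    return alpha * a + (1.0 - alpha) * b


def dfe_apply_hard(h, d: GateDecision, sop_out: np.ndarray | None = None,
                   senet_out: np.ndarray | None = None):
    """Hard-branch application (single sample, reference semantics).

    SOP branch (alpha > tau): F = alpha * sop_out + (1 - alpha) * h_lift where
    ``h_lift`` is the mean activation of ``h`` broadcast to the SOP vector's
    width (the unlearned stand-in for the head's linear lift).  SENet branch:
    F = (1 - alpha) * senet_out + alpha * h, shape-preserving.
    """
    hv = h.values if hasattr(h, "values") else np.asarray(h, dtype=np.float64)
    if d.branch == "sop":
        if sop_out is None:
            raise MissingBranchInput("gate selected SOP but sop_out was not computed")
        sop_out = np.asarray(sop_out, dtype=np.float64).reshape(-1)
        h_lift = np.full_like(sop_out, hv.mean())
        return d.alpha * sop_out + (1.0 - d.alpha) * h_lift
    if senet_out is None:
        raise MissingBranchInput("gate selected SENet but senet_out was not computed")
    senet_out = np.asarray(senet_out, dtype=np.float64)
    if senet_out.shape != hv.shape:
        raise ShapeMismatch("senet_out must match the input map's shape")
    return (1.0 - d.alpha) * senet_out + d.alpha * hv


def dfe_regularization_loss(decisions, reg_weight: float = DEFAULT_REG_WEIGHT) -> float:
    """lambda * mean of (alpha - 0.5)^2 over the collected gate decisions."""
    decisions = list(decisions)
    if not decisions or reg_weight == 0:
        return 0.0
    return reg_weight * float(np.mean([d.regularizer for d in decisions]))


# ---------------------------------------------------------------------------
# Batched network modules
# ---------------------------------------------------------------------------

class _GateMixin:
    def _gate_alpha(self, s_c: Tensor) -> Tensor:
        """[B, C] descriptor -> per-sample scalar gate in (0, 1), shape [B]."""
        z = self.gate_fc(s_c)
        return z.mean(axis=1).sigmoid()

    def _record(self, alpha: Tensor):
        # kept on the graph so the penalty trains the gate
        self.last_reg = ((alpha - 0.5) ** 2.0).mean()
        self.last_alpha = alpha.data.copy()


class DFEIntermediate(nn.Module, _GateMixin):
    """Shape-preserving gate between two stages, [B,C,H,W] -> [B,C,H,W].

    SOP branch: alpha * (scales ⊙ H) + (1 - alpha) * H, where ``scales`` is
    the diagonal of S^{1/2} (per-channel second-order energy).  When C exceeds
    ``sop_dim`` the covariance is taken on a 1x1-conv-reduced map and its
    diagonal is lifted back to C channels by a learned linear map (full CxC
    Newton-Schulz at C >= 512 is computationally infeasible).
    SENet branch: (1 - alpha) * SE(H) + alpha * H.
    """

    def __init__(self, channels: int, tau: float = DEFAULT_TAU, mode: str = "hard",
                 se_reduction: int = 16, ns_iterations: int = 5,
                 sop_dim: int | None = None, *, rng: np.random.Generator):
        super().__init__()
        if mode not in ("hard", "soft"):
            raise ValueError("mode must be 'hard' or 'soft'")
        self.tau, self.mode, self.ns_iterations = tau, mode, ns_iterations
        self.gate_fc = nn.Linear(channels, channels, bias=True, rng=rng)
        self.se = SEBlock(channels, se_reduction, rng=rng)
        if sop_dim is not None and channels > sop_dim:
            self.reduce = nn.Conv2d(channels, sop_dim, 1, bias=False, rng=rng)
            self.diag_lift = nn.Linear(sop_dim, channels, rng=rng)
        else:
            self.reduce = None
            self.diag_lift = None
        self.last_alpha = np.zeros(0)
        self.last_reg: Tensor | None = None

    def _sop_scales(self, x: Tensor) -> Tensor:
        xr = self.reduce(x) if self.reduce is not None else x
        s_sqrt = sop_tensor(xr, n_iter=self.ns_iterations)
        diag = s_sqrt.diagonal_last()            # [B, d]
        if self.diag_lift is not None:
            diag = self.diag_lift(diag)          # [B, C]
        return diag

    def forward(self, x: Tensor) -> Tensor:
        b, c, _, _ = x.shape
        alpha = self._gate_alpha(x.mean(axis=(2, 3)))
        self._record(alpha)
        a4 = alpha.reshape(b, 1, 1, 1)
        scales = self._sop_scales(x).reshape(b, c, 1, 1)
        sop_form = a4 * (scales * x) + (1.0 - a4) * x
        h_prime = self.se(x)
        if self.mode == "soft":
            return a4 * (scales * x) + (1.0 - a4) * h_prime
        senet_form = (1.0 - a4) * h_prime + a4 * x
        mask = Tensor((self.last_alpha > self.tau).astype(x.dtype).reshape(b, 1, 1, 1))
        return mask * sop_form + (1.0 - mask) * senet_form


class DFEHead(nn.Module, _GateMixin):
    """Head-placement gate fusing the flattened SOP matrix with lifted descriptors.

    Inputs: the channel-reduced map feeding the head SOP block and the refined
    (H'_L) and unrefined (H_L) global descriptors.  Both descriptors pass
    through one learned linear lift to the SOP vector's width so the convex
    combinations are well-typed.  SOP branch: alpha*flatten(S^{1/2}) +
    (1-alpha)*lift(H_L); SENet branch: (1-alpha)*lift(H'_L) + alpha*lift(H_L).
    """

    def __init__(self, channels: int, sop_dim: int, tau: float = DEFAULT_TAU,
                 mode: str = "hard", ns_iterations: int = 5,
                 *, rng: np.random.Generator):
        super().__init__()
        if mode not in ("hard", "soft"):
            raise ValueError("mode must be 'hard' or 'soft'")
        self.tau, self.mode, self.ns_iterations = tau, mode, ns_iterations
        self.sop_dim = sop_dim
        self.out_width = sop_dim * sop_dim
        self.gate_fc = nn.Linear(channels, channels, bias=True, rng=rng)
        self.lift = nn.Linear(channels, self.out_width, rng=rng)
        self.last_alpha = np.zeros(0)
        self.last_reg: Tensor | None = None

    def forward(self, x_reduced: Tensor, desc_refined: Tensor,
                desc_plain: Tensor) -> Tensor:
        b = x_reduced.shape[0]
        alpha = self._gate_alpha(desc_refined)
        self._record(alpha)
        a2 = alpha.reshape(b, 1)
        sop_vec = sop_tensor(x_reduced, n_iter=self.ns_iterations).reshape(b, self.out_width)
        h_prime_vec = self.lift(desc_refined)
        h_vec = self.lift(desc_plain)
        if self.mode == "soft":
            return a2 * sop_vec + (1.0 - a2) * h_prime_vec
        sop_form = a2 * sop_vec + (1.0 - a2) * h_vec
        senet_form = (1.0 - a2) * h_prime_vec + a2 * h_vec
        mask = Tensor((self.last_alpha > self.tau).astype(sop_vec.dtype).reshape(b, 1))
        return mask * sop_form + (1.0 - mask) * senet_form
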