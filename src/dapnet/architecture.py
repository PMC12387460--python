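"""Classifier assembly on a ResNet50 backbone, baseline builders, parameter counting.

The flagship model ("LungSESOP") is: 7x7 stem conv + max pool, a first
shape-preserving gate, the bottleneck stages, a second gate, a
squeeze-excitation block, then a head that fuses the global-average-pooled
descriptor with the flattened second-order (covariance square-root) features
before the softmax classifier.  Ablation flags produce the ResNet50-only,
+SE, +SOP, +SE+SOP and full variants from the same builder.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from . import nn
from .attention import SEBlock
from .covpool import sop_tensor
from .dfe import DEFAULT_REG_WEIGHT, DEFAULT_TAU, DFEHead, DFEIntermediate
from .exceptions import ConfigError, ShapeMismatch
from .nn import functional as F
from .nn.tensor import Tensor, no_grad

CHECKPOINT_VERSION = 1


@dataclass
class DFEConfig:
    tau: float = DEFAULT_TAU
    mode: str = "hard"            # "hard" (branching) or "soft" (blend)
    reg_weight: float = DEFAULT_REG_WEIGHT


@dataclass
class ModelConfig:
    n_classes: int = 3
    input_size: int = 224
    se_reduction: int = 16
    ns_iterations: int = 5
    cov_power_exponent: float = 0.5
    dfe: DFEConfig = field(default_factory=DFEConfig)
    width_multiplier: float = 1.0
    pretrained_backbone: bool = False
    three_stage: bool = False      # literal "3, 4, 6" reading; default keeps canonical 3-4-6-3
    sop_dim: int | None = None     # channel width of the covariance head; None -> 64 * width
    use_se: bool = True
    use_sop: bool = True
    use_dfe: bool = True

    def __post_init__(self):
        if self.n_classes < 1:
            raise ConfigError("n_classes must be positive")
        if self.input_size < 32:
            raise ConfigError("input_size must be >= 32")
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ConfigError("width_multiplier must be in (0, 1]")
        if self.ns_iterations < 0:
            raise ConfigError("ns_iterations must be nonnegative")
        if isinstance(self.dfe, dict):
            self.dfe = DFEConfig(**self.dfe)

    def scaled(self, channels: int) -> int:
        return max(int(round(channels * self.width_multiplier)), 8)

    def head_sop_dim(self) -> int:
        return self.sop_dim if self.sop_dim is not None else max(int(round(64 * self.width_multiplier)), 8)


# ---------------------------------------------------------------------------
# Residual bottleneck
# ---------------------------------------------------------------------------

class Bottleneck(nn.Module):
    """Standard 1x1-3x3-1x1 bottleneck, expansion 4, projection shortcut on
    stride or width change."""

    expansion = 4

    def __init__(self, in_ch: int, planes: int, stride: int = 1,
                 *, rng: np.random.Generator):
        super().__init__()
        out_ch = planes * self.expansion
        self.conv1 = nn.Conv2d(in_ch, planes, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(planes)
        self.conv2 = nn.Conv2d(planes, planes, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(planes)
        self.conv3 = nn.Conv2d(planes, out_ch, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        sc = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + sc).relu()


def residual_block(x: np.ndarray, block: Bottleneck) -> np.ndarray:
    """Apply one bottleneck (eval mode) to a single [C, H, W] map."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise ShapeMismatch("expected a [C, H, W] map")
    was_training = block.training
    block.eval()
    with no_grad():
        out = block(Tensor(x[None]))
    block.train(was_training)
    return out.data[0]


def _make_stage(in_ch: int, planes: int, blocks: int, stride: int,
                rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    layers = [Bottleneck(in_ch, planes, stride, rng=rng)]
    out_ch = planes * Bottleneck.expansion
    for _ in range(blocks - 1):
        layers.append(Bottleneck(out_ch, planes, 1, rng=rng))
    return nn.Sequential(*layers), out_ch


# ---------------------------------------------------------------------------
# Flagship model
# ---------------------------------------------------------------------------

class LungSESOP(nn.Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg.scaled
        stem_ch = c(64)
        self.stem_conv = nn.Conv2d(3, stem_ch, 7, stride=2, padding=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem_ch)
        self.pool = nn.MaxPool2d(3, 2, 1)

        sop_dim = cfg.head_sop_dim()
        if cfg.use_dfe:
            self.dfe1 = DFEIntermediate(stem_ch, cfg.dfe.tau, cfg.dfe.mode,
                                        cfg.se_reduction, cfg.ns_iterations,
                                        sop_dim=sop_dim, rng=rng)
        else:
            self.dfe1 = None

        stage_defs = [(64, 3, 1), (128, 4, 2), (256, 6, 2)]
        if not cfg.three_stage:
            stage_defs.append((512, 3, 2))
        stages = []
        in_ch = stem_ch
        for planes, blocks, stride in stage_defs:
            stage, in_ch = _make_stage(in_ch, c(planes), blocks, stride, rng)
            stages.append(stage)
        self.stages = nn.Sequential(*stages)
        self.feat_ch = in_ch

        if cfg.use_dfe:
            self.dfe2 = DFEIntermediate(in_ch, cfg.dfe.tau, cfg.dfe.mode,
                                        cfg.se_reduction, cfg.ns_iterations,
                                        sop_dim=sop_dim, rng=rng)
        else:
            self.dfe2 = None
        self.se = SEBlock(in_ch, cfg.se_reduction, rng=rng) if cfg.use_se else None

        if cfg.use_sop:
            self.sop_reduce = nn.Conv2d(in_ch, sop_dim, 1, bias=False, rng=rng)
            self.sop_bn = nn.BatchNorm2d(sop_dim)
            head_width = sop_dim * sop_dim
            if cfg.use_dfe:
                self.dfe_head = DFEHead(in_ch, sop_dim, cfg.dfe.tau, cfg.dfe.mode,
                                        cfg.ns_iterations, rng=rng)
            else:
                self.dfe_head = None
        else:
            self.sop_reduce = None
            self.dfe_head = None
            head_width = in_ch
        self.fc = nn.Linear(head_width, cfg.n_classes, rng=rng)

    # -- plumbing ------------------------------------------------------------
    def dfe_modules(self):
        return [m for m in (self.dfe1, self.dfe2, self.dfe_head) if m is not None]

    def regularization(self) -> Tensor | float:
        """Sum of the (alpha-0.5)^2 penalties recorded on the last forward."""
        terms = [m.last_reg for m in self.dfe_modules() if m.last_reg is not None]
        if not terms:
            return 0.0
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        return total

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ShapeMismatch(f"expected [B,3,H,W] input, got {x.shape}")
        h = self.stem_bn(self.stem_conv(x)).relu()
        h = self.pool(h)
        if self.dfe1 is not None:
            h = self.dfe1(h)
        h = self.stages(h)
        if self.dfe2 is not None:
            h = self.dfe2(h)
        h_se = self.se(h) if self.se is not None else h
        desc_refined = h_se.mean(axis=(2, 3))
        if self.sop_reduce is None:
            return self.fc(desc_refined)
        xr = self.sop_bn(self.sop_reduce(h_se)).relu()
        if self.dfe_head is not None:
            feats = self.dfe_head(xr, desc_refined, h.mean(axis=(2, 3)))
        else:
            b = xr.shape[0]
            feats = sop_tensor(xr, n_iter=self.cfg.ns_iterations).reshape(
                b, self.cfg.head_sop_dim() ** 2)
        return self.fc(feats)


def build_lung_se_sop(cfg: ModelConfig | None = None, seed: int = 0) -> LungSESOP:
    return LungSESOP(cfg or ModelConfig(), seed=seed)


def classify(model: nn.Module, x: np.ndarray) -> np.ndarray:
    """Softmax class probabilities in eval mode; accepts [3,H,W] or [B,3,H,W]."""
    x = np.asarray(x, dtype=np.float32)
    single = x.ndim == 3
    if single:
        x = x[None]
    was_training = model.training
    model.eval()
    with no_grad():
        probs = F.softmax(model(Tensor(x)), axis=1).data
    model.train(was_training)
    return probs[0] if single else probs


# ---------------------------------------------------------------------------
# Reference builders (parameter-count anchors)
# ---------------------------------------------------------------------------

class ResNet50(nn.Module):
    """Canonical ResNet50: stem + bottleneck stages 3-4-6-3 + GAP + fc."""

    def __init__(self, n_classes: int = 1000, width_multiplier: float = 1.0,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        scale = lambda ch: max(int(round(ch * width_multiplier)), 8)
        stem_ch = scale(64)
        self.stem_conv = nn.Conv2d(3, stem_ch, 7, stride=2, padding=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem_ch)
        self.pool = nn.MaxPool2d(3, 2, 1)
        stages = []
        in_ch = stem_ch
        for planes, blocks, stride in [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)]:
            stage, in_ch = _make_stage(in_ch, scale(planes), blocks, stride, rng)
            stages.append(stage)
        self.stages = nn.Sequential(*stages)
        self.gap = nn.GlobalAvgPool2d()
        self.fc = nn.Linear(in_ch, n_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.stem_bn(self.stem_conv(x)).relu()
        h = self.pool(h)
        h = self.stages(h)
        return self.fc(self.gap(h))


def build_resnet50_baseline(n_classes: int = 1000, pretrained_flag: bool = False,
                            width_multiplier: float = 1.0, seed: int = 0) -> ResNet50:
    """Canonical ResNet50 head-swapped to ``n_classes``.

    ``pretrained_flag`` only marks that externally supplied weights may be
    loaded via :func:`load_checkpoint`; nothing is downloaded.
    """
    return ResNet50(n_classes=n_classes, width_multiplier=width_multiplier, seed=seed)


_VGG16_CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512, "M"]


class VGG16(nn.Module):
    """Canonical VGG configuration D: 13 convs (with biases) + 4096/4096/K head."""

    def __init__(self, n_classes: int = 1000, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        layers: list[nn.Module] = []
        in_ch = 3
        for item in _VGG16_CFG:
            if item == "M":
                layers.append(nn.MaxPool2d(2, 2))
            else:
                layers.append(nn.Conv2d(in_ch, item, 3, padding=1, bias=True, rng=rng))
                layers.append(nn.ReLU())
                in_ch = item
        self.features = nn.Sequential(*layers)
        self.fc1 = nn.Linear(512 * 7 * 7, 4096, rng=rng)
        self.fc2 = nn.Linear(4096, 4096, rng=rng)
        self.fc3 = nn.Linear(4096, n_classes, rng=rng)

    @property
    def n_conv_layers(self) -> int:
        return sum(1 for m in self.features.layers if isinstance(m, nn.Conv2d))

    def forward(self, x: Tensor) -> Tensor:
        h = self.features(x)
        h = h.reshape(h.shape[0], -1)
        h = self.fc1(h).relu()
        h = self.fc2(h).relu()
        return self.fc3(h)


def build_vgg16_reference(n_classes: int = 1000, seed: int = 0) -> VGG16:
    return VGG16(n_classes=n_classes, seed=seed)


def count_parameters(model: nn.Module) -> tuple[int, float]:
    """(exact trainable-parameter count, millions rounded half-up to 1 d.p.)."""
    exact = sum(int(p.size) for p in model.parameters() if p.requires_grad)
    millions = float(Decimal(exact) / Decimal(10 ** 6))
    rounded = float(Decimal(str(millions)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return exact, rounded


def parameter_checksum(model: nn.Module) -> float:
    """Deterministic scalar fingerprint of all parameters."""
    return float(sum(np.abs(p.data).sum() for p in model.parameters()))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: LungSESOP, path: str, extra: dict | None = None):
    cfg_json = json.dumps({"version": CHECKPOINT_VERSION,
                           "config": asdict(model.cfg),
                           "extra": extra or {}})
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **{k: v for k, v in state.items()})


def load_checkpoint(path: str) -> tuple[LungSESOP, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ConfigError(f"unsupported checkpoint version {meta.get('version')}")
        cfg = ModelConfig(**meta["config"])
        model = LungSESOP(cfg, seed=0)
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta.get("extra", {})
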