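"""Training loop, evaluation, and the augmented-train / raw-test protocol."""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import metrics as M
from . import nn
from .architecture import LungSESOP, ModelConfig, build_lung_se_sop
from .data import AugmentPlan, LabeledImage, SplitSpec, balance_classes, \
    stratified_split, to_model_input
from .exceptions import DegenerateVariance, EmptyDataset, NonFiniteLoss
from .nn import functional as F
from .nn.tensor import Tensor, no_grad

logger = logging.getLogger(__name__)

CLASS_NAMES = ("benign", "malignant", "normal")


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    lr_initial: float = 0.001
    lr_decay_factor: float = 0.1
    lr_decay_every_epochs: int = 20
    epochs: int = 50
    batch_size: int = 32
    weight_decay: float = 1e-4     # prose value; the summary table prints 1e-3
    loss: str = "cross_entropy"
    dfe_reg_weight: float = 0.01
    seed: int = 0

    def lr_at_epoch(self, epoch: int) -> float:
        """Closed form: lr_initial * factor^floor(epoch / every)."""
        return nn.step_lr(self.lr_initial, epoch, self.lr_decay_factor,
                          self.lr_decay_every_epochs)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    mean_gate_alpha: list[dict[str, float]] = field(default_factory=list)
    ce_loss: list[float] = field(default_factory=list)
    reg_loss: list[float] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _as_batch(items: list[LabeledImage]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([to_model_input(it) for it in items])
    y = np.array([CLASS_NAMES.index(it.label) for it in items], dtype=np.int64)
    return x, y


def _alpha_stats(model: LungSESOP) -> dict[str, float]:
    names = ["dfe1", "dfe2", "dfe_head"]
    out = {}
    for name in names:
        mod = getattr(model, name, None)
        if mod is not None and getattr(mod, "last_alpha", np.zeros(0)).size:
            out[name] = float(mod.last_alpha.mean())
    return out


def _forward_loss(model: LungSESOP, x: np.ndarray, y: np.ndarray,
                  reg_weight: float) -> tuple[Tensor, float, float, int]:
    logits = model(Tensor(x))
    ce = F.cross_entropy(logits, y)
    reg = model.regularization() if reg_weight else 0.0
    loss = ce + reg * reg_weight if reg_weight and not isinstance(reg, float) else ce
    correct = int((logits.data.argmax(axis=1) == y).sum())
    reg_val = float(reg.data) if isinstance(reg, Tensor) else float(reg)
    return loss, float(ce.data), reg_val, correct


def train(model: LungSESOP, train_set: list[LabeledImage],
          val_set: list[LabeledImage], cfg: TrainConfig,
          verbose: bool = False) -> tuple[LungSESOP, TrainHistory]:
    """Adam + step-decayed LR; loss = cross-entropy + lambda * gate penalty.

    Deterministic given the seed (seeded shuffling, single-threaded).  The
    parameters achieving the best validation accuracy are restored at the end.
    """
    if not train_set or not val_set:
        raise EmptyDataset("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr_initial,
                  weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_val = -1.0
    best_state = None
    n = len(train_set)
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at_epoch(epoch)
        opt.lr = lr
        model.train()
        order = rng.permutation(n)
        ep_loss = ep_ce = ep_reg = 0.0
        ep_correct = 0
        alpha_accum: dict[str, list[float]] = {}
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x, y = _as_batch([train_set[i] for i in idx])
            loss, ce_val, reg_val, correct = _forward_loss(
                model, x, y, cfg.dfe_reg_weight)
            if not np.isfinite(loss.data):
                raise NonFiniteLoss(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            w = len(idx)
            ep_loss += float(loss.data) * w
            ep_ce += ce_val * w
            ep_reg += reg_val * w
            ep_correct += correct
            for k, v in _alpha_stats(model).items():
                alpha_accum.setdefault(k, []).append(v)
        val_loss, val_acc = _eval_loss(model, val_set, cfg)
        history.train_loss.append(ep_loss / n)
        history.ce_loss.append(ep_ce / n)
        history.reg_loss.append(ep_reg / n)
        history.train_accuracy.append(ep_correct / n)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.learning_rate.append(lr)
        history.mean_gate_alpha.append(
            {k: float(np.mean(v)) for k, v in alpha_accum.items()})
        if val_acc > best_val:
            best_val = val_acc
            best_state = copy.deepcopy(model.state_dict())
        if verbose:
            logger.info(json.dumps({"epoch": epoch, "lr": lr,
                                    "train_loss": history.train_loss[-1],
                                    "val_acc": val_acc}))
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def _eval_loss(model: LungSESOP, items: list[LabeledImage],
               cfg: TrainConfig) -> tuple[float, float]:
    model.eval()
    total_loss = 0.0
    correct = 0
    with no_grad():
        for start in range(0, len(items), cfg.batch_size):
            x, y = _as_batch(items[start:start + cfg.batch_size])
            logits = model(Tensor(x))
            ce = F.cross_entropy(logits, y)
            total_loss += float(ce.data) * len(y)
            correct += int((logits.data.argmax(axis=1) == y).sum())
    return total_loss / len(items), correct / len(items)


def predict(model: LungSESOP, items: list[LabeledImage],
            batch_size: int = 32) -> tuple[list[str], np.ndarray]:
    """Deterministic eval-mode predictions and softmax scores."""
    if not items:
        raise EmptyDataset("nothing to predict on")
    model.eval()
    scores = []
    with no_grad():
        for start in range(0, len(items), batch_size):
            x, _ = _as_batch(items[start:start + batch_size])
            logits = model(Tensor(x))
            scores.append(F.softmax(logits, axis=1).data)
    scores = np.concatenate(scores)
    preds = [CLASS_NAMES[i] for i in scores.argmax(axis=1)]
    return preds, scores


def evaluate(model: LungSESOP, test_set: list[LabeledImage],
             n_boot: int = 200, seed: int = 0,
             with_cis: bool = True) -> M.EvalReport:
    preds, scores = predict(model, test_set)
    y_true = [it.label for it in test_set]
    report = M.build_report(y_true, preds, scores, list(CLASS_NAMES),
                            n_boot=n_boot, seed=seed, with_cis=with_cis)
    model.eval()
    with no_grad():
        x, _ = _as_batch(test_set[:min(len(test_set), 64)])
        model(Tensor(x))
    report.extra["mean_gate_alpha"] = _alpha_stats(model)
    return report


def generalization_protocol(model_cfg: ModelConfig, train_cfg: TrainConfig,
                            raw_set: list[LabeledImage], aug_plan: AugmentPlan | None,
                            split_spec: SplitSpec | None = None,
                            n_boot: int = 200):
    """Split raw slices, augment the train partition, evaluate on augmented
    and raw test sets, and run the paired t-test over matched per-class TPRs.

    Returns (model, report_augmented_test, report_raw_test, ttest_or_None).
    """
    split_spec = split_spec or SplitSpec(seed=train_cfg.seed)
    tr, va, te = stratified_split(raw_set, split_spec)
    if aug_plan is not None:
        counts = {}
        for it in tr:
            counts[it.label] = counts.get(it.label, 0) + 1
        plan = AugmentPlan(ops=aug_plan.ops, ranges=aug_plan.ranges,
                           target_counts={k: max(v, counts.get(k, 0))
                                          for k, v in aug_plan.target_counts.items()},
                           seed=aug_plan.seed)
        tr_aug = balance_classes(tr, plan)
        te_plan = AugmentPlan(ops=aug_plan.ops, ranges=aug_plan.ranges,
                              target_counts={k: 2 * sum(1 for it in te if it.label == k)
                                             for k in plan.target_counts},
                              seed=aug_plan.seed + 1)
        te_aug = balance_classes(te, te_plan)
    else:
        tr_aug, te_aug = tr, te
    # leakage guard: no augmented descendant of a test image in the train split
    test_ids = {it.id for it in te}
    for it in tr_aug:
        if it.parent_id in test_ids:
            raise AssertionError("leakage: augmented descendant of a test image in train")
    model = build_lung_se_sop(model_cfg, seed=train_cfg.seed)
    model, _ = train(model, tr_aug, va, train_cfg)
    report_aug = evaluate(model, te_aug, n_boot=n_boot, seed=train_cfg.seed)
    report_raw = evaluate(model, te, n_boot=n_boot, seed=train_cfg.seed)
    tpr_aug = [report_aug.per_class[c].recall for c in CLASS_NAMES]
    tpr_raw = [report_raw.per_class[c].recall for c in CLASS_NAMES]
    try:
        ttest = M.paired_ttest(tpr_aug, tpr_raw)
    except DegenerateVariance:
        ttest = None
    return model, report_aug, report_raw, ttest
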