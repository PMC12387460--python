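"""Evaluation battery: confusion matrix, one-vs-rest metrics, ROC/AUC,
stratified percentile bootstrap CIs, paired two-tailed t-test."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DegenerateVariance, ShapeMismatch, SingleClassInput, UnknownLabel

DEFAULT_N_BOOT = 2000
DEFAULT_LEVEL = 0.95


@dataclass
class ConfusionMatrix:
    counts: np.ndarray               # [K, K]; rows true, columns predicted
    class_names: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ShapeMismatch("confusion matrix must be [K, K]")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def micro_accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total if self.total else 0.0


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    accuracy: float                  # one-vs-rest accuracy (Eq-20 reduction)
    support: int
    zero_division_flags: list[str] = field(default_factory=list)


def confusion(y_true, y_pred, class_names) -> ConfusionMatrix:
    """counts[i][j] = number of samples with true class i predicted as j."""
    index = {c: i for i, c in enumerate(class_names)}
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ShapeMismatch("y_true and y_pred lengths differ")
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise UnknownLabel(f"label {t!r}/{p!r} not in {class_names}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(class_names))


def per_class_metrics(cm: ConfusionMatrix) -> dict[str, ClassMetrics]:
    """One-vs-rest reduction per class.

    TP = cm[c][c]; FN = row c − TP; FP = column c − TP; TN = remainder.
    Zero-denominator metrics are 0 and flagged.
    """
    out: dict[str, ClassMetrics] = {}
    total = cm.total
    for i, name in enumerate(cm.class_names):
        tp = int(cm.counts[i, i])
        fn = int(cm.counts[i].sum() - tp)
        fp = int(cm.counts[:, i].sum() - tp)
        tn = total - tp - fn - fp
        flags = []

        def safe(num, den, flag):
            if den == 0:
                flags.append(flag)
                return 0.0
            return num / den

        recall = safe(tp, tp + fn, "recall")
        precision = safe(tp, tp + fp, "precision")
        f1 = safe(2.0 * precision * recall, precision + recall, "f1")
        accuracy = safe(tp + tn, total, "accuracy")
        out[name] = ClassMetrics(precision=precision, recall=recall, f1=f1,
                                 accuracy=accuracy, support=tp + fn,
                                 zero_division_flags=flags)
    return out


def roc_one_vs_rest(scores: np.ndarray, y_true, class_names, cls) -> tuple[list, float]:
    """Threshold sweep over the class's probability column.

    Returns points sorted by (FPR, TPR) including the (0,0) and (1,1)
    endpoints, and the trapezoid AUC.
    """
    scores = np.asarray(scores, dtype=np.float64)
    idx = list(class_names).index(cls)
    y = np.asarray([1 if t == cls else 0 for t in y_true])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassInput(f"class {cls!r}: positives={n_pos}, negatives={n_neg}")
    s = scores[:, idx]
    order = np.argsort(-s, kind="stable")
    tps = np.cumsum(y[order])
    fps = np.cumsum(1 - y[order])
    # collapse ties on the score value
    distinct = np.r_[np.nonzero(np.diff(s[order]))[0], len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:
        fpr = np.r_[fpr, 1.0]
        tpr = np.r_[tpr, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def bootstrap_ci(metric_fn, y_true, y_pred_or_scores, n_boot: int = DEFAULT_N_BOOT,
                 level: float = DEFAULT_LEVEL, seed: int = 0) -> tuple[float, float]:
    """Stratified case resampling with replacement; percentile interval."""
    y_true = list(y_true)
    vals = np.asarray(y_pred_or_scores, dtype=object) \
        if not isinstance(y_pred_or_scores, np.ndarray) else y_pred_or_scores
    n = len(y_true)
    if n < 10:
        raise ValueError("need at least 10 samples for a bootstrap CI")
    rng = np.random.default_rng(seed)
    labels = sorted(set(y_true))
    strata = {lab: np.flatnonzero([t == lab for t in y_true]) for lab in labels}
    estimates = np.empty(n_boot)
    y_arr = np.asarray(y_true, dtype=object)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(s, size=len(s), replace=True)
                              for s in strata.values()])
        estimates[b] = metric_fn(list(y_arr[idx]), vals[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def paired_ttest(values_a, values_b):
    """Classical paired two-tailed t-test on the differences.

    Returns (t statistic, two-tailed p, mean difference, 95 % CI of the
    difference).  Raises :class:`DegenerateVariance` when the differences
    have zero variance.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ShapeMismatch("need two equal-length vectors with n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateVariance("differences have zero variance")
    mean_diff = float(d.mean())
    se = sd / np.sqrt(n)
    t_stat = mean_diff / se
    p = 2.0 * stats.t.sf(abs(t_stat), df=n - 1)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)
    return float(t_stat), float(p), mean_diff, (float(ci[0]), float(ci[1]))


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    cm: ConfusionMatrix
    per_class: dict[str, ClassMetrics]
    roc: dict[str, dict]
    cis: dict[str, tuple[float, float, float]]
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_names": self.cm.class_names,
            "confusion": self.cm.counts.tolist(),
            "micro_accuracy": self.cm.micro_accuracy(),
            "per_class": {
                c: {"precision": m.precision, "recall": m.recall, "f1": m.f1,
                    "accuracy": m.accuracy, "support": m.support,
                    "zero_division_flags": m.zero_division_flags}
                for c, m in self.per_class.items()},
            "roc": self.roc,
            "cis": {k: list(v) for k, v in self.cis.items()},
            "extra": self.extra,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def write_csv(self, prefix):
        with open(f"{prefix}_confusion.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["true\\pred"] + self.cm.class_names)
            for name, row in zip(self.cm.class_names, self.cm.counts):
                w.writerow([name] + row.tolist())
        with open(f"{prefix}_per_class.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["class", "precision", "recall", "f1", "ovr_accuracy", "support"])
            for c, m in self.per_class.items():
                w.writerow([c, m.precision, m.recall, m.f1, m.accuracy, m.support])

    @staticmethod
    def from_dict(d: dict) -> "EvalReport":
        cm = ConfusionMatrix(np.asarray(d["confusion"]), list(d["class_names"]))
        per_class = {c: ClassMetrics(m["precision"], m["recall"], m["f1"],
                                     m["accuracy"], m["support"],
                                     list(m.get("zero_division_flags", [])))
                     for c, m in d["per_class"].items()}
        cis = {k: tuple(v) for k, v in d["cis"].items()}
        return EvalReport(cm, per_class, d["roc"], cis, d.get("extra", {}))


def build_report(y_true, y_pred, scores, class_names, n_boot: int = 200,
                 level: float = DEFAULT_LEVEL, seed: int = 0,
                 with_cis: bool = True) -> EvalReport:
    """Assemble the full evaluation report from predictions and scores."""
    cm = confusion(y_true, y_pred, class_names)
    per_class = per_class_metrics(cm)
    roc: dict[str, dict] = {}
    scores = np.asarray(scores, dtype=np.float64)
    for cls in class_names:
        try:
            points, auc = roc_one_vs_rest(scores, y_true, class_names, cls)
            roc[cls] = {"points": points, "auc": auc}
        except SingleClassInput:
            roc[cls] = {"points": [], "auc": float("nan")}
    # binary benign-vs-malignant restriction when both classes are present
    if "benign" in class_names and "malignant" in class_names:
        keep = [i for i, t in enumerate(y_true) if t in ("benign", "malignant")]
        if keep:
            sub_true = [y_true[i] for i in keep]
            bi, mi = class_names.index("benign"), class_names.index("malignant")
            pair = scores[keep][:, [bi, mi]]
            norm = pair.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            try:
                points, auc = roc_one_vs_rest(pair / norm, sub_true,
                                              ["benign", "malignant"], "malignant")
                roc["benign_vs_malignant"] = {"points": points, "auc": auc}
            except SingleClassInput:
                pass
    cis: dict[str, tuple[float, float, float]] = {}
    if with_cis and len(y_true) >= 10:
        y_pred_arr = np.asarray(y_pred, dtype=object)

        def acc(yt, yp):
            return float(np.mean([a == b for a, b in zip(yt, yp)]))

        lo, hi = bootstrap_ci(acc, y_true, y_pred_arr, n_boot=n_boot,
                              level=level, seed=seed)
        cis["overall,accuracy"] = (lo, hi, level)
        for cls in class_names:
            def rec(yt, yp, _c=cls):
                mask = [t == _c for t in yt]
                if not any(mask):
                    return 0.0
                return float(np.mean([p == _c for t, p in zip(yt, yp) if t == _c]))

            lo, hi = bootstrap_ci(rec, y_true, y_pred_arr, n_boot=n_boot,
                                  level=level, seed=seed + 1)
            cis[f"{cls},recall"] = (lo, hi, level)
    return EvalReport(cm, per_class, roc, cis)
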