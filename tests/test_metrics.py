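import numpy as np
import pytest
from scipy.stats import rankdata

from dapnet import metrics as M
from dapnet.exceptions import (DegenerateVariance, ShapeMismatch,
                               SingleClassInput, UnknownLabel)


# ---------------------------------------------------------------------------
# confusion
# ---------------------------------------------------------------------------

def test_confusion_perfect_predictions():
    y = ["b"] * 3 + ["m"] * 2
    cm = M.confusion(y, y, ["b", "m"])
    np.testing.assert_array_equal(cm.counts, [[3, 0], [0, 2]])
    np.testing.assert_array_equal(cm.supports, [3, 2])
    assert cm.micro_accuracy() == 1.0


def test_confusion_hand_count():
    cm = M.confusion(["b", "b", "m"], ["b", "m", "m"], ["b", "m"])
    np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])


def test_confusion_order_invariant(rng):
    y_true = list(rng.choice(["a", "b", "c"], size=50))
    y_pred = list(rng.choice(["a", "b", "c"], size=50))
    cm1 = M.confusion(y_true, y_pred, ["a", "b", "c"])
    perm = rng.permutation(50)
    cm2 = M.confusion([y_true[i] for i in perm], [y_pred[i] for i in perm],
                      ["a", "b", "c"])
    np.testing.assert_array_equal(cm1.counts, cm2.counts)


def test_confusion_unknown_label():
    with pytest.raises(UnknownLabel):
        M.confusion(["x"], ["b"], ["b", "m"])


def test_confusion_length_mismatch():
    with pytest.raises(ShapeMismatch):
        M.confusion(["b"], ["b", "m"], ["b", "m"])


# ---------------------------------------------------------------------------
# per-class metrics (printed worked examples)
# ---------------------------------------------------------------------------

def paper_confusion():
    """Published augmented-data confusion counts with stated supports
    1344/1344/1328.  The benign and malignant rows as printed (1325+9+9,
    1327+8+8) each fall one short of their stated support; the leftover error
    is assigned to the class-confusion the source text highlights
    (benign<->normal) so that row sums equal the stated supports and the
    recalls reproduce the printed percentages."""
    counts = np.array([
        [1325, 9, 10],
        [8, 1327, 9],
        [1, 0, 1327],
    ])
    return M.ConfusionMatrix(counts, ["benign", "malignant", "normal"])


def test_paper_benign_recall_rounds_to_98_6():
    pc = M.per_class_metrics(paper_confusion())
    assert pc["benign"].recall == pytest.approx(1325 / 1344)
    assert round(100 * pc["benign"].recall, 1) == 98.6


def test_paper_malignant_recall_rounds_to_98_7():
    pc = M.per_class_metrics(paper_confusion())
    assert pc["malignant"].recall == pytest.approx(1327 / 1344)
    assert round(100 * pc["malignant"].recall, 1) == 98.7


def test_paper_normal_recall_rounds_to_99_9():
    pc = M.per_class_metrics(paper_confusion())
    assert round(100 * pc["normal"].recall, 1) == 99.9
    assert pc["normal"].recall == pytest.approx(1327 / 1328)


def test_per_class_f1_identity_and_perfect_case():
    cm = M.ConfusionMatrix(np.array([[5, 0], [0, 7]]), ["a", "b"])
    pc = M.per_class_metrics(cm)
    for m in pc.values():
        assert m.precision == m.recall == m.f1 == 1.0


def test_per_class_one_vs_rest_reduction(rng):
    y_true = list(rng.choice(["a", "b", "c"], size=200))
    y_pred = list(rng.choice(["a", "b", "c"], size=200))
    cm = M.confusion(y_true, y_pred, ["a", "b", "c"])
    pc = M.per_class_metrics(cm)
    for m in pc.values():
        if m.precision + m.recall > 0:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall))
    assert cm.micro_accuracy() == pytest.approx(np.trace(cm.counts) / 200)


def test_per_class_zero_denominator_flagged():
    cm = M.ConfusionMatrix(np.array([[0, 0], [3, 4]]), ["a", "b"])
    pc = M.per_class_metrics(cm)
    assert pc["a"].recall == 0.0
    assert "recall" in pc["a"].zero_division_flags


def test_ovr_accuracy_vs_recall(rng):
    """One-vs-rest accuracy >= recall when TN > 0 (verified numerically)."""
    for _ in range(20):
        y_true = list(rng.choice(["a", "b", "c"], size=60))
        y_pred = list(rng.choice(["a", "b", "c"], size=60))
        cm = M.confusion(y_true, y_pred, ["a", "b", "c"])
        pc = M.per_class_metrics(cm)
        for i, (cls, m) in enumerate(pc.items()):
            tp = cm.counts[i, i]
            tn = cm.total - cm.counts[i].sum() - cm.counts[:, i].sum() + tp
            if tn > 0 and m.support < cm.total:
                assert m.accuracy >= m.recall - 1e-12


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def _scores_for(y, good):
    s = np.zeros((len(y), 2))
    for i, t in enumerate(y):
        p = 0.9 if (t == "pos") == good else 0.1
        s[i] = [1 - p, p]
    return s


def test_roc_perfect_separation():
    y = ["neg"] * 5 + ["pos"] * 5
    _, auc = M.roc_one_vs_rest(_scores_for(y, True), y, ["neg", "pos"], "pos")
    assert auc == pytest.approx(1.0)


def test_roc_uninformative_scores():
    y = ["neg"] * 5 + ["pos"] * 5
    s = np.full((10, 2), 0.5)
    _, auc = M.roc_one_vs_rest(s, y, ["neg", "pos"], "pos")
    assert auc == pytest.approx(0.5)


def test_roc_endpoints_and_monotonicity(rng):
    y = list(rng.choice(["neg", "pos"], size=50))
    if "pos" not in y:
        y[0] = "pos"
    if "neg" not in y:
        y[1] = "neg"
    s = rng.random((50, 2))
    s = s / s.sum(axis=1, keepdims=True)
    points, _ = M.roc_one_vs_rest(s, y, ["neg", "pos"], "pos")
    assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)
    fprs = [p[0] for p in points]
    tprs = [p[1] for p in points]
    assert all(b >= a - 1e-12 for a, b in zip(fprs, fprs[1:]))
    assert all(b >= a - 1e-12 for a, b in zip(tprs, tprs[1:]))


def test_roc_auc_equals_mann_whitney(rng):
    """Trapezoid AUC == rank-statistic (Mann-Whitney U / n1 n0) oracle."""
    for trial in range(5):
        y = list(rng.choice(["neg", "pos"], size=50, p=[0.6, 0.4]))
        if "pos" not in y:
            y[0] = "pos"
        if "neg" not in y:
            y[1] = "neg"
        p_pos = rng.random(50)
        scores = np.c_[1 - p_pos, p_pos]
        _, auc = M.roc_one_vs_rest(scores, y, ["neg", "pos"], "pos")
        pos = np.array([t == "pos" for t in y])
        ranks = rankdata(p_pos)
        n1, n0 = pos.sum(), (~pos).sum()
        u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
        assert auc == pytest.approx(u / (n1 * n0), abs=1e-10)


def test_roc_single_class_raises():
    y = ["pos"] * 5
    with pytest.raises(SingleClassInput):
        M.roc_one_vs_rest(np.random.rand(5, 2), y, ["neg", "pos"], "pos")


# ---------------------------------------------------------------------------
# bootstrap CI
# ---------------------------------------------------------------------------

def _acc(yt, yp):
    return float(np.mean([a == b for a, b in zip(yt, yp)]))


def test_bootstrap_degenerate_interval():
    y = ["a"] * 10 + ["b"] * 10
    lo, hi = M.bootstrap_ci(_acc, y, np.asarray(y, dtype=object), n_boot=100, seed=0)
    assert (lo, hi) == (1.0, 1.0)


def test_bootstrap_contains_point_estimate(rng):
    """Percentile interval contains the point estimate across 50 seeded runs."""
    y_true = list(rng.choice(["a", "b"], size=80))
    y_pred = [t if rng.random() < 0.8 else ("a" if t == "b" else "b")
              for t in y_true]
    point = _acc(y_true, y_pred)
    for seed in range(50):
        lo, hi = M.bootstrap_ci(_acc, y_true, np.asarray(y_pred, dtype=object),
                                n_boot=1000, seed=seed)
        assert lo - 1e-12 <= point <= hi + 1e-12


def test_bootstrap_level_nesting(rng):
    y_true = list(rng.choice(["a", "b"], size=60))
    y_pred = [t if rng.random() < 0.7 else ("a" if t == "b" else "b")
              for t in y_true]
    preds = np.asarray(y_pred, dtype=object)
    lo90, hi90 = M.bootstrap_ci(_acc, y_true, preds, n_boot=2000, level=0.90, seed=3)
    lo99, hi99 = M.bootstrap_ci(_acc, y_true, preds, n_boot=2000, level=0.99, seed=3)
    assert lo99 <= lo90 and hi90 <= hi99


def test_bootstrap_deterministic():
    y = ["a"] * 20 + ["b"] * 20
    p = np.asarray(["a"] * 15 + ["b"] * 25, dtype=object)
    assert M.bootstrap_ci(_acc, y, p, n_boot=200, seed=9) == \
        M.bootstrap_ci(_acc, y, p, n_boot=200, seed=9)


# ---------------------------------------------------------------------------
# paired t-test
# ---------------------------------------------------------------------------

def test_ttest_identical_vectors_degenerate():
    with pytest.raises(DegenerateVariance):
        M.paired_ttest([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


def test_ttest_p_shrinks_with_jitter():
    rng = np.random.default_rng(0)
    base = np.arange(10.0)
    p_prev = 1.0
    for jitter in (1e-1, 1e-3, 1e-5):
        b = base - 1.0 + rng.normal(0, jitter, size=10)
        _, p, _, _ = M.paired_ttest(base, b)
        assert p < p_prev
        p_prev = p
    assert p_prev < 1e-10


def test_ttest_textbook_case():
    """a=[1,2,3], b=[0,1.1,1.9]: d=[1,.9,1.1], mean 1, sd 0.1.

    Frozen oracle: t = 1/(0.1/sqrt(3)) = 10*sqrt(3); for df=2 the exact
    two-tailed p is 2*(0.5 - t/(2*sqrt(2+t^2))).
    """
    t, p, mean_diff, ci = M.paired_ttest([1, 2, 3], [0, 1.1, 1.9])
    t_exact = 10.0 * np.sqrt(3.0)
    p_exact = 2.0 * (0.5 - t_exact / (2.0 * np.sqrt(2.0 + t_exact ** 2)))
    assert t == pytest.approx(t_exact, rel=1e-12)
    assert p == pytest.approx(p_exact, rel=1e-9)
    assert mean_diff == pytest.approx(1.0)
    assert ci[0] < 1.0 < ci[1]


# ---------------------------------------------------------------------------
# report round trip
# ---------------------------------------------------------------------------

def test_report_json_round_trip(rng, tmp_path):
    y_true = list(rng.choice(["benign", "malignant", "normal"], size=40))
    for c in ("benign", "malignant", "normal"):
        if c not in y_true:
            y_true[0] = c
    scores = rng.random((40, 3))
    scores /= scores.sum(axis=1, keepdims=True)
    y_pred = [["benign", "malignant", "normal"][i] for i in scores.argmax(axis=1)]
    rep = M.build_report(y_true, y_pred, scores, ["benign", "malignant", "normal"],
                         n_boot=50, seed=0)
    path = tmp_path / "rep.json"
    rep.to_json(path)
    import json
    loaded = M.EvalReport.from_dict(json.loads(path.read_text()))
    np.testing.assert_array_equal(loaded.cm.counts, rep.cm.counts)
    assert loaded.per_class["benign"].f1 == rep.per_class["benign"].f1
    for key, (lo, hi, level) in rep.cis.items():
        assert lo <= hi
    rep.write_csv(str(tmp_path / "out"))
    assert (tmp_path / "out_confusion.csv").exists()
    assert (tmp_path / "out_per_class.csv").exists()
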