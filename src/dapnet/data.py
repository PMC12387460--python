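"""Image ingestion, preprocessing, stratified splitting, augmentation, balancing.

Pipeline convention: split the raw slices first, then augment/balance the
training partition only.  Balancing the full set before splitting (the
literal published protocol, which leaks augmented near-duplicates across
partitions) is available behind an explicit ``paper_protocol`` flag.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .exceptions import (EmptyClass, InsufficientClass, TargetBelowCurrent,
                         UnknownLabel)

logger = logging.getLogger(__name__)

CLASS_NAMES = ("benign", "malignant", "normal")
DEFAULT_TARGET_COUNTS = {"benign": 1344, "malignant": 1344, "normal": 1328}
DEFAULT_IMAGE_SIZE = 224

#: default parameter ranges for each augmentation op (all configurable)
DEFAULT_RANGES = {
    "rotation": {"degrees": 15.0},
    "brightness": {"delta": 0.2},
    "zoom": {"low": 0.9, "high": 1.1},
    "width_shift": {"fraction": 0.1},
    "height_shift": {"fraction": 0.1},
    "horizontal_flip": {"p": 0.5},
    "gaussian_noise": {"sigma": 0.01},
    "salt_pepper_noise": {"density": 0.002},
    "shear": {"degrees": 10.0},
    "crop": {"fraction": 0.9},
}

#: the six published techniques plus the two noise resampling transforms
DEFAULT_OPS = ("rotation", "brightness", "zoom", "width_shift", "height_shift",
               "horizontal_flip", "gaussian_noise", "salt_pepper_noise")


@dataclass
class LabeledImage:
    pixels: np.ndarray          # [H, W] or [3, H, W], values in [0, 1]
    label: str
    id: str
    provenance: str = "raw"    # "raw" | "augmented"
    group: str | None = None   # optional leakage-group key (e.g. patient)
    parent_id: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.min(initial=0.0) < -1e-9 or self.pixels.max(initial=0.0) > 1 + 1e-9:
            raise ValueError("pixels must lie in [0, 1] after normalization")


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    level: str = "slice"        # "slice" | "group"

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class AugmentPlan:
    ops: tuple[str, ...] = DEFAULT_OPS
    ranges: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RANGES.items()})
    target_counts: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_COUNTS))
    seed: int = 0

    def __post_init__(self):
        for op in self.ops:
            if op not in self.ranges:
                raise ValueError(f"op {op!r} has no parameter range")


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_class_folder_dataset(root_path, size: int = DEFAULT_IMAGE_SIZE,
                              class_names=None) -> list[LabeledImage]:
    """Load a one-folder-per-class tree of raster images.

    Images are resized to ``size`` x ``size`` (bilinear), converted to
    grayscale [H, W] in [0, 1], and returned in deterministic lexicographic
    order.  Unreadable files are skipped with a logged count; an empty class
    folder raises :class:`EmptyClass`.
    """
    root = Path(root_path)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if class_names is not None:
        class_dirs = [p for p in class_dirs if p.name in set(class_names)]
    items: list[LabeledImage] = []
    for cdir in class_dirs:
        files = sorted(p for p in cdir.iterdir() if p.is_file())
        loaded = 0
        skipped = 0
        for f in files:
            try:
                with Image.open(f) as im:
                    im = im.convert("L").resize((size, size), Image.BILINEAR)
                    pixels = np.asarray(im, dtype=np.float64) / 255.0
            except Exception:
                skipped += 1
                continue
            items.append(LabeledImage(pixels, label=cdir.name,
                                      id=f"{cdir.name}/{f.name}"))
            loaded += 1
        if skipped:
            logger.warning("skipped %d unreadable files in %s", skipped, cdir)
        if loaded == 0:
            raise EmptyClass(f"class folder {cdir} has no readable images")
    return items


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, fractions) -> list[int]:
    """Apportion n items to the fractions, assigning leftovers by largest remainder."""
    raw = [n * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def stratified_split(items, spec: SplitSpec):
    """Partition into (train, val, test) preserving per-class proportions.

    Deterministic for a given seed; with ``level='group'`` all items sharing
    a group key stay in one partition (group counts are apportioned instead).
    """
    rng = np.random.default_rng(spec.seed)
    by_class: dict[str, list] = {}
    for it in items:
        by_class.setdefault(it.label, []).append(it)
    parts: tuple[list, list, list] = ([], [], [])
    for label in sorted(by_class):
        members = sorted(by_class[label], key=lambda it: it.id)
        if spec.level == "group":
            groups: dict[str, list] = {}
            for it in members:
                groups.setdefault(it.group if it.group is not None else it.id, []).append(it)
            units = [groups[k] for k in sorted(groups)]
        else:
            units = [[it] for it in members]
        if len(units) < 3:
            raise InsufficientClass(f"class {label!r} has {len(units)} units; need >= 3")
        perm = rng.permutation(len(units))
        counts = _largest_remainder(len(units), spec.fractions)
        offset = 0
        for part, cnt in zip(parts, counts):
            for idx in perm[offset:offset + cnt]:
                part.extend(units[idx])
            offset += cnt
    return parts


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _geom(img: np.ndarray, fn):
    """Apply fn to [H,W] or each channel of [3,H,W]."""
    if img.ndim == 2:
        return fn(img)
    return np.stack([fn(ch) for ch in img])


def augment_one(img: LabeledImage, op: str, params: dict,
                rng: np.random.Generator) -> LabeledImage:
    """Apply one transform with parameters sampled from the given ranges."""
    px = img.pixels
    desc = op
    if op == "horizontal_flip":
        out = np.flip(px, axis=-1).copy()
    elif op == "rotation":
        angle = float(rng.uniform(-params["degrees"], params["degrees"])) \
            if "angle" not in params else float(params["angle"])
        desc = f"rotation{angle:+.2f}"
        out = px if angle == 0.0 else _geom(px, lambda a: ndimage.rotate(
            a, angle, reshape=False, order=1, mode="reflect"))
    elif op == "brightness":
        delta = float(rng.uniform(-params["delta"], params["delta"])) \
            if "factor" not in params else float(params["factor"]) - 1.0
        desc = f"brightness{delta:+.3f}"
        out = px * (1.0 + delta)
    elif op == "zoom":
        factor = float(rng.uniform(params["low"], params["high"])) \
            if "factor" not in params else float(params["factor"])
        desc = f"zoom{factor:.3f}"
        out = px if factor == 1.0 else _geom(px, lambda a: _zoom_about_center(a, factor))
    elif op in ("width_shift", "height_shift"):
        axis = -1 if op == "width_shift" else -2
        frac = float(rng.uniform(-params["fraction"], params["fraction"])) \
            if "shift" not in params else float(params["shift"])
        desc = f"{op}{frac:+.3f}"
        px_len = px.shape[axis]
        shift_px = frac * px_len
        if shift_px == 0.0:
            out = px
        else:
            vec = [0.0] * px.ndim
            vec[axis] = shift_px
            out = ndimage.shift(px, vec, order=1, mode="reflect")
    elif op == "gaussian_noise":
        sigma = float(params.get("sigma", 0.01))
        desc = f"gauss{sigma:.4f}"
        out = px if sigma == 0.0 else px + rng.normal(0.0, sigma, size=px.shape)
    elif op == "salt_pepper_noise":
        density = float(params.get("density", 0.002))
        desc = f"saltpepper{density:.4f}"
        out = px.copy()
        if density > 0:
            mask = rng.random(px.shape) < density
            out[mask] = rng.integers(0, 2, size=int(mask.sum())).astype(np.float64)
    elif op == "shear":
        angle = float(rng.uniform(-params["degrees"], params["degrees"]))
        desc = f"shear{angle:+.2f}"
        m = np.tan(np.radians(angle))
        out = _geom(px, lambda a: ndimage.affine_transform(
            a, [[1.0, m], [0.0, 1.0]], offset=[-m * a.shape[1] / 2.0, 0.0],
            order=1, mode="reflect"))
    elif op == "crop":
        frac = float(params.get("fraction", 0.9))
        desc = f"crop{frac:.2f}"
        out = _geom(px, lambda a: _crop_and_resize(a, frac))
    else:
        raise ValueError(f"unknown augmentation op {op!r}")
    out = np.clip(out, 0.0, 1.0)
    return LabeledImage(out, label=img.label, id=f"{img.id}|{desc}",
                        provenance="augmented", group=img.group, parent_id=img.id)


def _zoom_about_center(a: np.ndarray, factor: float) -> np.ndarray:
    h, w = a.shape
    zoomed = ndimage.zoom(a, factor, order=1, mode="reflect")
    zh, zw = zoomed.shape
    if factor >= 1.0:
        top, left = (zh - h) // 2, (zw - w) // 2
        return zoomed[top:top + h, left:left + w]
    out = np.zeros_like(a)
    top, left = (h - zh) // 2, (w - zw) // 2
    out[top:top + zh, left:left + zw] = zoomed
    return out


def _crop_and_resize(a: np.ndarray, frac: float) -> np.ndarray:
    h, w = a.shape
    ch, cw = max(int(h * frac), 1), max(int(w * frac), 1)
    top, left = (h - ch) // 2, (w - cw) // 2
    return _zoom_to_shape(a[top:top + ch, left:left + cw], (h, w))


def _zoom_to_shape(a: np.ndarray, shape) -> np.ndarray:
    fy, fx = shape[0] / a.shape[0], shape[1] / a.shape[1]
    out = ndimage.zoom(a, (fy, fx), order=1, mode="reflect")
    return out[:shape[0], :shape[1]]


def balance_classes(items, plan: AugmentPlan) -> list[LabeledImage]:
    """Augment each class up to exactly its target count.

    Source images are cycled in deterministic order; ops and parameters are
    sampled from the seeded rng.  Raw images are always retained.
    """
    rng = np.random.default_rng(plan.seed)
    by_class: dict[str, list] = {}
    for it in items:
        by_class.setdefault(it.label, []).append(it)
    out: list[LabeledImage] = list(items)
    for label in sorted(by_class):
        members = sorted(by_class[label], key=lambda it: it.id)
        target = plan.target_counts.get(label, len(members))
        if target < len(members):
            raise TargetBelowCurrent(
                f"class {label!r}: target {target} < current {len(members)}")
        need = target - len(members)
        for k in range(need):
            src = members[k % len(members)]
            op = plan.ops[rng.integers(0, len(plan.ops))]
            aug = augment_one(src, op, plan.ranges[op], rng)
            aug = LabeledImage(aug.pixels, label=aug.label, id=f"{aug.id}#{k}",
                               provenance="augmented", group=aug.group,
                               parent_id=src.id)
            out.append(aug)
    return out


def prepare_dataset(items, plan: AugmentPlan | None, spec: SplitSpec,
                    paper_protocol: bool = False):
    """Split and balance: returns (train, val, test).

    Default order is split-then-augment (only the training partition is
    balanced), which keeps augmented descendants out of val/test.  With
    ``paper_protocol=True`` the *full* set is balanced to the plan's target
    counts before splitting — this reproduces the published totals but leaks
    augmented near-duplicates across partitions, so it is opt-in only.
    """
    if plan is not None and paper_protocol:
        balanced = balance_classes(items, plan)
        return stratified_split(balanced, spec)
    tr, va, te = stratified_split(items, spec)
    if plan is not None:
        counts: dict[str, int] = {}
        for it in tr:
            counts[it.label] = counts.get(it.label, 0) + 1
        train_plan = AugmentPlan(
            ops=plan.ops, ranges=plan.ranges, seed=plan.seed,
            target_counts={k: max(v, counts.get(k, 0))
                           for k, v in plan.target_counts.items()})
        tr = balance_classes(tr, train_plan)
    return tr, va, te


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def write_manifest(path, items, splits: dict[str, set] | None = None):
    """CSV manifest: id, label, split, provenance, parent_id."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label", "split", "provenance", "parent_id"])
        for it in items:
            split = ""
            if splits:
                for name, ids in splits.items():
                    if it.id in ids:
                        split = name
                        break
            writer.writerow([it.id, it.label, split, it.provenance, it.parent_id or ""])


def check_labels(items, class_names=CLASS_NAMES):
    for it in items:
        if it.label not in class_names:
            raise UnknownLabel(f"label {it.label!r} not in {class_names}")


def to_model_input(img: LabeledImage) -> np.ndarray:
    """[H,W] or [3,H,W] pixels -> float32 [3,H,W] (grayscale replicated)."""
    px = img.pixels.astype(np.float32)
    if px.ndim == 2:
        px = np.repeat(px[None], 3, axis=0)
    return px
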