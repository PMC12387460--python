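"""Seeded generator of three-class CT-like phantom slices.

Classes are separable by construction: ``normal`` slices contain bare lung
fields, ``benign`` a single smooth bright disc, ``malignant`` an irregular
star-convex blob with high-frequency internal texture and a brighter base.
All randomness flows from the spec seed, and every random quantity is drawn
in the same order regardless of class so that same-seed phantoms of
different classes differ only inside the nodule support.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .data import LabeledImage, write_manifest

CLASS_NAMES = ("benign", "malignant", "normal")

LUNG_INTENSITY = 0.35
BACKGROUND_INTENSITY = 0.05
BENIGN_BUMP = 0.30
MALIGNANT_BUMP = 0.40
NODULE_THRESHOLD = 0.5   # bright-component threshold used by the geometry oracle


@dataclass
class PhantomSpec:
    size: int = 224
    class_label: str = "normal"
    nodule_radius_px: float | None = None   # None -> 10 % of the image side
    irregularity: float = 0.6
    texture_contrast: float = 0.5
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if not 0.0 <= self.irregularity <= 1.0:
            raise ValueError("irregularity must be in [0, 1]")
        if self.texture_contrast < 0 or self.noise_sigma < 0:
            raise ValueError("contrast and noise must be nonnegative")

    @property
    def radius(self) -> float:
        return self.nodule_radius_px if self.nodule_radius_px is not None else 0.10 * self.size


def _rng_for(spec: PhantomSpec) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec.seed, 0xDA9)))


def _lung_mask(size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = 0.52 * size
    ay, ax = 0.30 * size, 0.16 * size
    left = ((yy - cy) / ay) ** 2 + ((xx - 0.30 * size) / ax) ** 2 <= 1.0
    right = ((yy - cy) / ay) ** 2 + ((xx - 0.70 * size) / ax) ** 2 <= 1.0
    return left | right


def phantom_geometry(spec: PhantomSpec) -> dict:
    """Deterministic geometry oracle: lung mask and per-class nodule masks.

    Returns the masks a phantom with this spec is built from, including the
    nodule supports that *would* be used for the benign (disc) and malignant
    (star-convex) variants of the same seed.
    """
    size = spec.size
    rng = _rng_for(spec)
    lungs = _lung_mask(size)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)

    # draws below happen for every class so rng streams stay aligned
    lung_jitter = rng.uniform(-0.02, 0.02)
    side = rng.integers(0, 2)                      # which lung hosts the nodule
    cx = (0.30 if side == 0 else 0.70) * size + rng.uniform(-0.04, 0.04) * size
    cy = 0.52 * size + rng.uniform(-0.12, 0.12) * size
    radius = spec.radius * rng.uniform(0.85, 1.15)
    harmonics = rng.uniform(-1.0, 1.0, size=6)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=6)
    texture_field = rng.normal(0.0, 1.0, size=(size, size))
    noise_field = rng.normal(0.0, 1.0, size=(size, size))

    r = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)
    disc_mask = r <= radius

    irr = max(spec.irregularity, 0.5)
    wobble = np.zeros_like(theta)
    for k, (h, ph) in enumerate(zip(harmonics, phases), start=2):
        wobble += h * np.cos(k * theta + ph)
    wobble /= max(np.abs(wobble).max(), 1e-12)
    star_mask = r <= radius * (1.0 + 0.6 * irr * wobble)

    return {
        "lung_mask": lungs,
        "disc_mask": disc_mask,
        "star_mask": star_mask,
        "nodule_center": (cy, cx),
        "nodule_radius": radius,
        "lung_jitter": lung_jitter,
        "texture_field": texture_field,
        "noise_field": noise_field,
    }


def generate_phantom(spec: PhantomSpec) -> LabeledImage:
    """Render one phantom slice; bit-identical for identical specs."""
    geo = phantom_geometry(spec)
    size = spec.size
    img = np.full((size, size), BACKGROUND_INTENSITY)
    img[geo["lung_mask"]] = LUNG_INTENSITY + geo["lung_jitter"]

    if spec.class_label == "benign":
        img[geo["disc_mask"]] += BENIGN_BUMP
    elif spec.class_label == "malignant":
        mask = geo["star_mask"]
        img[mask] += MALIGNANT_BUMP
        if spec.texture_contrast > 0:
            tex = ndimage.gaussian_filter(geo["texture_field"], sigma=1.0)
            tex = np.abs(tex) / max(np.abs(tex).max(), 1e-12)
            img[mask] += spec.texture_contrast * 0.5 * tex[mask]

    if spec.noise_sigma > 0:
        img = img + spec.noise_sigma * geo["noise_field"]
    img = np.clip(img, 0.0, 1.0)
    return LabeledImage(img, label=spec.class_label,
                        id=f"{spec.class_label}/phantom_{spec.seed:010d}",
                        provenance="raw")


def child_seed(master_seed: int, class_index: int, index: int) -> int:
    """Documented counter scheme: SeedSequence((master, class, index))."""
    ss = np.random.SeedSequence((master_seed, class_index, index))
    return int(ss.generate_state(1)[0])


def generate_dataset(n_per_class: dict, seed: int = 0, size: int = 224,
                     irregularity: float = 0.6, texture_contrast: float = 0.5,
                     noise_sigma: float = 0.01) -> list[LabeledImage]:
    """Generate phantoms per class with independent per-image child seeds."""
    items: list[LabeledImage] = []
    for ci, label in enumerate(CLASS_NAMES):
        n = int(n_per_class.get(label, 0))
        if n < 0:
            raise ValueError("counts must be nonnegative")
        for i in range(n):
            spec = PhantomSpec(size=size, class_label=label,
                               irregularity=irregularity,
                               texture_contrast=texture_contrast,
                               noise_sigma=noise_sigma,
                               seed=child_seed(seed, ci, i))
            img = generate_phantom(spec)
            img.id = f"{label}/phantom_{i:05d}_{spec.seed:010d}"
            items.append(img)
    return items


def write_dataset_png(items, out_dir) -> Path:
    """Write phantoms as PNGs in the class-folder layout plus a manifest CSV."""
    out = Path(out_dir)
    for it in items:
        cdir = out / it.label
        cdir.mkdir(parents=True, exist_ok=True)
        arr = (np.clip(it.pixels, 0, 1) * 255).round().astype(np.uint8)
        name = it.id.split("/")[-1] + ".png"
        Image.fromarray(arr, mode="L").save(cdir / name)
    write_manifest(out / "manifest.csv", items)
    return out
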