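"""Synthetic H&E-like image generator and class-per-folder dataset I/O.

The generator emulates the coarse statistics of hematoxylin-and-eosin
stained tissue: a class-specific base color in the pink/purple palette, a
Poisson-scattered field of dark elliptical "nuclei", a low-frequency
sinusoidal texture and Gaussian pixel noise. A single ``difficulty`` knob
interpolates every class's parameters toward their common mean, so class
separability degrades continuously from trivially separable (0) to
indistinguishable (1).

Datasets round-trip to the conventional layout of public histopathology
collections: one subdirectory per class holding JPEG or PNG files, plus a
manifest CSV.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "ClassParams",
    "SyntheticSpec",
    "LabeledImageSet",
    "DEFAULT_CLASS_NAMES",
    "default_class_params",
    "render_class_image",
    "generate_class_image",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "split_dataset",
    "centroid_baseline_accuracy",
]

# lung/colon histology class tags: adenocarcinoma / benign per organ plus
# lung squamous-cell carcinoma
DEFAULT_CLASS_NAMES = ("Col-Ad", "Col-Be", "Lun-Ad", "Lun-Be", "Lun-SC")


@dataclass(frozen=True)
class ClassParams:
    """Generative parameters of one tissue class.

    ``base_color`` is the RGB stain tone; ``blob_density`` the expected
    nucleus count per pixel; ``blob_eccentricity`` in [0, 1) elongates the
    ellipses; ``texture_freq`` the sinusoid's cycles per image (0 disables
    the texture); ``noise_sd`` the Gaussian pixel-noise standard deviation.
    """

    base_color: tuple[float, float, float]
    blob_density: float = 0.003
    blob_eccentricity: float = 0.3
    texture_freq: float = 3.0
    noise_sd: float = 8.0
    blob_color: tuple[float, float, float] = (90.0, 60.0, 130.0)


def default_class_params() -> list[ClassParams]:
    """Five distinct H&E-palette classes (pinks/purples, varied nuclei)."""
    return [
        ClassParams((196, 130, 170), 0.004, 0.40, 3.0),
        ClassParams((225, 170, 195), 0.002, 0.20, 5.0),
        ClassParams((180, 140, 200), 0.005, 0.50, 2.0),
        ClassParams((235, 200, 215), 0.0015, 0.10, 6.0),
        ClassParams((160, 110, 150), 0.006, 0.60, 4.0),
    ]


@dataclass(frozen=True)
class SyntheticSpec:
    n_classes: int = 5
    images_per_class: int = 100
    image_size: int = 64
    difficulty: float = 0.0
    seed: int = 0
    class_params: tuple[ClassParams, ...] | None = None
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError("difficulty must lie in [0, 1]")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")

    def resolved_params(self) -> list[ClassParams]:
        """Class parameters after the difficulty interpolation."""
        base = list(self.class_params) if self.class_params else default_class_params()
        if len(base) < self.n_classes:
            raise ValueError("not enough class parameter sets for n_classes")
        base = base[: self.n_classes]
        if self.difficulty == 0.0:
            return base
        a = self.difficulty
        mean_color = np.mean([p.base_color for p in base], axis=0)
        mean_dens = float(np.mean([p.blob_density for p in base]))
        mean_ecc = float(np.mean([p.blob_eccentricity for p in base]))
        mean_freq = float(np.mean([p.texture_freq for p in base]))
        return [
            replace(
                p,
                base_color=tuple((1 - a) * np.asarray(p.base_color) + a * mean_color),
                blob_density=(1 - a) * p.blob_density + a * mean_dens,
                blob_eccentricity=(1 - a) * p.blob_eccentricity + a * mean_ecc,
                texture_freq=(1 - a) * p.texture_freq + a * mean_freq,
            )
            for p in base
        ]

    def resolved_names(self) -> list[str]:
        if self.class_names:
            if len(self.class_names) != self.n_classes:
                raise ValueError("class_names length must equal n_classes")
            return list(self.class_names)
        if self.n_classes <= len(DEFAULT_CLASS_NAMES):
            return list(DEFAULT_CLASS_NAMES[: self.n_classes])
        return [f"class-{i}" for i in range(self.n_classes)]


@dataclass
class LabeledImageSet:
    """Images with integer labels and an ordered class-name table."""

    images: np.ndarray  # (N, H, W, 3) uint8
    labels: np.ndarray  # (N,) int
    class_names: list[str]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(self.images[idx], self.labels[idx], list(self.class_names))


def render_class_image(
    params: ClassParams, size: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Render one image; returns (uint8 HxWx3 image, nucleus count drawn)."""
    img = np.ones((size, size, 3), dtype=float) * np.asarray(params.base_color)

    if params.texture_freq > 0:
        yy, xx = np.mgrid[0:size, 0:size] / size
        phase_x, phase_y = 2 * np.pi * rng.random(2)
        tex = np.sin(2 * np.pi * params.texture_freq * xx + phase_x) * np.sin(
            2 * np.pi * params.texture_freq * yy + phase_y
        )
        img += 12.0 * tex[:, :, None]

    n_blobs = int(rng.poisson(params.blob_density * size * size))
    for _ in range(n_blobs):
        cx, cy = rng.random(2) * size
        theta = rng.random() * np.pi
        r0 = 2.0 + 2.0 * rng.random()
        a = r0 * (1.0 + params.blob_eccentricity)
        b = max(r0 * (1.0 - params.blob_eccentricity), 0.5)
        _stamp_ellipse(img, cx, cy, a, b, theta, np.asarray(params.blob_color))

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), n_blobs


def _stamp_ellipse(img, cx, cy, a, b, theta, color, alpha: float = 0.85) -> None:
    size = img.shape[0]
    r = int(np.ceil(max(a, b))) + 1
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, size)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, size)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    mask = u * u + v * v <= 1.0
    patch = img[y0:y1, x0:x1]
    patch[mask] = (1 - alpha) * patch[mask] + alpha * color


def generate_class_image(params: ClassParams, size: int, rng: np.random.Generator) -> np.ndarray:
    """Render one image (see :func:`render_class_image`)."""
    return render_class_image(params, size, rng)[0]


def generate_dataset(spec: SyntheticSpec) -> LabeledImageSet:
    """Generate a balanced, seeded dataset of ``n_classes * images_per_class``."""
    rng = np.random.default_rng(spec.seed)
    params = spec.resolved_params()
    images, labels = [], []
    for cls in range(spec.n_classes):
        for _ in range(spec.images_per_class):
            images.append(generate_class_image(params[cls], spec.image_size, rng))
            labels.append(cls)
    return LabeledImageSet(np.stack(images), np.asarray(labels), spec.resolved_names())


def write_dataset(dataset: LabeledImageSet, root, fmt: str = "png") -> None:
    """Write ``<root>/<class_name>/<id>.<fmt>`` plus a manifest CSV."""
    if fmt not in ("png", "jpeg"):
        raise ValueError("fmt must be 'png' or 'jpeg'")
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    counters = [0] * dataset.n_classes
    for img, label in zip(dataset.images, dataset.labels):
        name = dataset.class_names[label]
        (root / name).mkdir(exist_ok=True)
        rel = f"{name}/{counters[label]:05d}.{fmt}"
        Image.fromarray(img).save(root / rel, quality=95)
        counters[label] += 1
        rows.append((rel, int(label)))
    with open(root / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label"])
        writer.writerows(rows)


def read_dataset(root) -> LabeledImageSet:
    """Read a class-per-folder directory back into memory.

    Class names are the sorted subdirectory names; non-image entries inside
    a class folder trigger a warning and are skipped.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"dataset root {root} contains no class subdirectories")
    images, labels, names = [], [], []
    for label, cdir in enumerate(class_dirs):
        names.append(cdir.name)
        for f in sorted(cdir.iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                warnings.warn(f"skipping non-image file {f}", stacklevel=2)
                continue
            images.append(np.asarray(Image.open(f).convert("RGB")))
            labels.append(label)
    if not images:
        raise ValueError(f"no images found under {root}")
    return LabeledImageSet(np.stack(images), np.asarray(labels), names)


def split_dataset(
    dataset: LabeledImageSet, train_fraction: float, seed: int = 0
) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Stratified train/test split; disjoint, union equals the input."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in range(dataset.n_classes):
        idx = np.flatnonzero(dataset.labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {dataset.class_names[cls]} has < 2 images")
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return (
        dataset.subset(np.concatenate(train_idx)),
        dataset.subset(np.concatenate(test_idx)),
    )


def centroid_baseline_accuracy(
    train: LabeledImageSet, test: LabeledImageSet
) -> float:
    """Accuracy (percent) of a nearest-mean-color classifier.

    A deliberately weak baseline: each class is summarized by its mean RGB
    vector; test images go to the nearest centroid. Used to calibrate the
    difficulty scale.
    """
    feats_train = train.images.reshape(len(train), -1, 3).mean(axis=1)
    feats_test = test.images.reshape(len(test), -1, 3).mean(axis=1)
    centroids = np.stack([
        feats_train[train.labels == c].mean(axis=0) for c in range(train.n_classes)
    ])
    d = ((feats_test[:, None, :] - centroids[None]) ** 2).sum(axis=2)
    pred = d.argmin(axis=1)
    return float(100.0 * np.mean(pred == test.labels))
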