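"""Synthetic brain-MRI phantoms with ground-truth tumor masks.

A phantom is a 2-D 8-bit grayscale image containing an elliptical "brain"
on a dark background, optionally with a bright circular "tumor" blob,
corrupted by additive Gaussian noise followed by salt-and-pepper impulses.
The template is piecewise constant (at most three intensities), which is
exactly the regime the downstream pipeline assumes: the median filter
targets the impulse noise and fuzzy c-means targets the intensity clusters.

Images are plain ``numpy`` ``uint8`` arrays (scikit-image convention:
arrays in, arrays out).  Datasets mirror the two-folder layout common to
public brain-MRI collections: ``root/yes/`` holds tumor images (label 1),
``root/no/`` holds tumor-free images (label 0), ``root/masks/`` holds the
ground-truth masks for the tumor images, and ``manifest.csv`` records
filename, label, split and per-image seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "GRAY_LEVELS",
    "PhantomSpec",
    "LabeledDataset",
    "generate_phantom",
    "generate_dataset",
    "read_image_folder",
    "validate_gray_image",
]

#: Number of gray levels of the canonical 8-bit image.
GRAY_LEVELS = 256

#: Luminance weights used to collapse color inputs to grayscale (ITU-R BT.601,
#: the same convention as Pillow's "L" mode).
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)


def validate_gray_image(img: np.ndarray, levels: int = GRAY_LEVELS) -> np.ndarray:
    """Check that *img* is a 2-D integer intensity grid in ``[0, levels-1]``.

    Returns the array unchanged so the call can be used inline.
    """
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a nonempty 2-D image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"expected an integer dtype, got {arr.dtype}")
    if arr.min() < 0 or arr.max() > levels - 1:
        raise ValueError(f"intensities outside [0, {levels - 1}]")
    return arr


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic phantom.

    All intensities are gray levels in ``[0, 255]``; all geometry is in
    pixels.  The tumor is a circle that must lie fully inside the brain
    ellipse.  ``noise_sigma`` is the standard deviation of the additive
    Gaussian noise; ``salt_pepper`` is the fraction of pixels replaced by
    0/255 impulses (half each).
    """

    size: tuple[int, int] = (64, 64)  # (height, width)
    brain_axes: tuple[float, float] = (26.0, 22.0)  # semi-axes (row, col)
    brain_center: tuple[float, float] | None = None  # defaults to image center
    brain_intensity: int = 120
    background_intensity: int = 20
    tumor: bool = False
    tumor_center: tuple[float, float] = (32.0, 32.0)
    tumor_radius: float = 7.0
    tumor_intensity: int = 220
    noise_sigma: float = 0.0
    salt_pepper: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 1 or w < 1:
            raise ValueError("image size must be at least 1x1")
        for name in ("brain_intensity", "background_intensity", "tumor_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= GRAY_LEVELS - 1:
                raise ValueError(f"{name}={v} outside [0, {GRAY_LEVELS - 1}]")
        if not 0.0 <= self.salt_pepper <= 0.5:
            raise ValueError("salt_pepper fraction must lie in [0, 0.5]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.tumor:
            self._check_tumor_inside_brain()

    @property
    def center(self) -> tuple[float, float]:
        if self.brain_center is not None:
            return self.brain_center
        h, w = self.size
        return ((h - 1) / 2.0, (w - 1) / 2.0)

    def _check_tumor_inside_brain(self) -> None:
        # Conservative containment test: the tumor center must lie inside the
        # brain ellipse with both semi-axes shrunk by the tumor radius.
        a, b = self.brain_axes
        r = self.tumor_radius
        if r <= 0:
            raise ValueError("tumor_radius must be positive")
        if r >= a or r >= b:
            raise ValueError("tumor does not fit inside the brain ellipse")
        cy, cx = self.center
        ty, tx = self.tumor_center
        if ((ty - cy) / (a - r)) ** 2 + ((tx - cx) / (b - r)) ** 2 > 1.0:
            raise ValueError("tumor ellipse extends outside the brain ellipse")


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    a, b = axes
    return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0


def render_template(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the noiseless piecewise-constant template and its tumor mask."""
    img = np.full(spec.size, spec.background_intensity, dtype=np.uint8)
    brain = _ellipse_mask(spec.size, spec.center, spec.brain_axes)
    img[brain] = spec.brain_intensity
    mask = np.zeros(spec.size, dtype=bool)
    if spec.tumor:
        mask = _ellipse_mask(
            spec.size, spec.tumor_center, (spec.tumor_radius, spec.tumor_radius)
        )
        img[mask] = spec.tumor_intensity
    return img, mask


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, int]:
    """Generate one phantom: ``(image, tumor_mask, label)``.

    The template is rendered first; Gaussian noise is added, the result is
    rounded and clipped to ``[0, 255]``; finally a ``salt_pepper`` fraction
    of pixels is replaced by 0 or 255 impulses.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    template, mask = render_template(spec)
    img = template.astype(np.float64)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, GRAY_LEVELS - 1).astype(np.uint8)
    if spec.salt_pepper > 0:
        n_pix = img.size
        n_imp = int(round(spec.salt_pepper * n_pix))
        flat_idx = rng.choice(n_pix, size=n_imp, replace=False)
        values = rng.choice([0, GRAY_LEVELS - 1], size=n_imp).astype(np.uint8)
        img.flat[flat_idx] = values
    label = 1 if spec.tumor else 0
    return img, mask, label


@dataclass
class LabeledDataset:
    """Images with binary tumor labels, optional truth masks and a split tag."""

    images: list[np.ndarray]
    labels: np.ndarray  # int, 0 = no tumor, 1 = tumor
    masks: list[np.ndarray] | None = None
    split: np.ndarray | None = None  # "train" / "test" per image
    seeds: np.ndarray | None = None
    filenames: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels differ in length")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be 0 or 1")
        if self.masks is not None:
            for m, lab in zip(self.masks, self.labels):
                if bool(m.any()) != bool(lab == 1):
                    raise ValueError("mask must be nonempty iff label is 1")

    def __len__(self) -> int:
        return len(self.images)

    def indices(self, split: str) -> np.ndarray:
        if self.split is None:
            raise ValueError("dataset has no split assignment")
        return np.flatnonzero(self.split == split)

    def save(self, root: str | os.PathLike) -> None:
        """Export in the two-folder layout with masks and a manifest CSV."""
        root = Path(root)
        for sub in ("yes", "no", "masks"):
            (root / sub).mkdir(parents=True, exist_ok=True)
        rows = []
        for i, (img, lab) in enumerate(zip(self.images, self.labels)):
            name = self.filenames[i] if self.filenames else f"img_{i:04d}.png"
            folder = "yes" if lab == 1 else "no"
            Image.fromarray(img, mode="L").save(root / folder / name)
            if self.masks is not None and lab == 1:
                mask_img = (self.masks[i].astype(np.uint8)) * 255
                Image.fromarray(mask_img, mode="L").save(root / "masks" / name)
            rows.append(
                {
                    "filename": name,
                    "label": int(lab),
                    "split": self.split[i] if self.split is not None else "",
                    "seed": int(self.seeds[i]) if self.seeds is not None else -1,
                }
            )
        pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)


def assign_split(
    labels: np.ndarray, test_fraction: float, seed: int
) -> np.ndarray:
    """Stratified train/test assignment (per-class rounding, seeded shuffle)."""
    labels = np.asarray(labels)
    out = np.full(len(labels), "train", dtype=object)
    rng = np.random.default_rng(seed)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_test = int(round(test_fraction * len(idx)))
        out[idx[:n_test]] = "test"
    return out.astype(str)


def generate_dataset(
    n_images: int,
    class_balance: float = 0.6,
    template: PhantomSpec | None = None,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> LabeledDataset:
    """Generate *n_images* phantoms, a ``class_balance`` fraction with tumors.

    Per-image geometry (brain axes, tumor center and radius) is jittered
    deterministically from *seed*; every image gets its own child seed so the
    whole dataset is reproducible bit for bit.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images")
    if not 0.0 < class_balance < 1.0:
        raise ValueError("class_balance must be strictly between 0 and 1")
    base = template if template is not None else PhantomSpec()
    n_tumor = int(round(class_balance * n_images))
    n_tumor = min(max(n_tumor, 1), n_images - 1)

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_images + 1)]
    jitter_rng = np.random.default_rng(child_seeds[-1])

    h, w = base.size
    images, masks, labels, seeds = [], [], [], []
    for i in range(n_images):
        has_tumor = i < n_tumor
        a = base.brain_axes[0] * jitter_rng.uniform(0.92, 1.0)
        b = base.brain_axes[1] * jitter_rng.uniform(0.92, 1.0)
        radius = base.tumor_radius * jitter_rng.uniform(0.8, 1.2)
        # place the tumor center inside the shrunken brain ellipse
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        while True:
            ty = cy + jitter_rng.uniform(-0.5, 0.5) * (a - radius)
            tx = cx + jitter_rng.uniform(-0.5, 0.5) * (b - radius)
            if ((ty - cy) / (a - radius)) ** 2 + ((tx - cx) / (b - radius)) ** 2 <= 0.9:
                break
        spec = replace(
            base,
            brain_axes=(a, b),
            brain_center=None,
            tumor=has_tumor,
            tumor_center=(ty, tx),
            tumor_radius=radius,
            seed=child_seeds[i],
        )
        img, mask, label = generate_phantom(spec)
        images.append(img)
        masks.append(mask)
        labels.append(label)
        seeds.append(child_seeds[i])

    labels = np.array(labels)
    split = assign_split(labels, test_fraction, child_seeds[-1])
    filenames = [f"img_{i:04d}.png" for i in range(n_images)]
    return LabeledDataset(
        images=images,
        labels=labels,
        masks=masks,
        split=split,
        seeds=np.array(seeds),
        filenames=filenames,
    )


def _load_grayscale(path: Path) -> np.ndarray:
    """Read one image file as 8-bit grayscale.

    Color inputs are collapsed with the BT.601 luminance weights; 16-bit
    inputs are rescaled by the fixed linear map ``v * 255 / 65535`` (so the
    format maximum maps to 255).
    """
    try:
        with Image.open(path) as im:
            if im.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(im, dtype=np.float64)
                arr = np.rint(arr * (255.0 / 65535.0))
                return np.clip(arr, 0, 255).astype(np.uint8)
            if im.mode == "L":
                return np.asarray(im, dtype=np.uint8)
            r, g, b = LUMINANCE_WEIGHTS
            rgb = np.asarray(im.convert("RGB"), dtype=np.float64)
            lum = rgb[..., 0] * r + rgb[..., 1] * g + rgb[..., 2] * b
            return np.clip(np.rint(lum), 0, 255).astype(np.uint8)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc


_IMAGE_EXTS = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def read_image_folder(root: str | os.PathLike) -> LabeledDataset:
    """Read a two-folder (``yes``/``no``) dataset from disk.

    Labels are inferred from the folder name; masks are picked up from a
    sibling ``masks/`` directory when present (matched by filename).  Files
    are read in sorted order, ``yes`` first, so the result is reproducible.
    """
    root = Path(root)
    entries: list[tuple[Path, int]] = []
    for folder, label in (("yes", 1), ("no", 0)):
        d = root / folder
        if d.is_dir():
            for p in sorted(d.iterdir()):
                if p.suffix.lower() in _IMAGE_EXTS:
                    entries.append((p, label))
    if not entries:
        raise FileNotFoundError(f"no images found under {root} (yes/ and no/)")

    manifest = None
    if (root / "manifest.csv").is_file():
        manifest = pd.read_csv(root / "manifest.csv").set_index("filename")

    images, labels, masks, split, filenames = [], [], [], [], []
    for path, label in entries:
        images.append(_load_grayscale(path))
        labels.append(label)
        filenames.append(path.name)
        mask_path = root / "masks" / path.name
        if label == 1 and mask_path.is_file():
            masks.append(_load_grayscale(mask_path) > 127)
        else:
            masks.append(np.zeros(images[-1].shape, dtype=bool))
        if manifest is not None and path.name in manifest.index:
            split.append(str(manifest.loc[path.name, "split"]))
        else:
            split.append("train")
    have_masks = any(m.any() for m in masks)
    return LabeledDataset(
        images=images,
        labels=np.array(labels),
        masks=masks if have_masks else None,
        split=np.array(split),
        filenames=filenames,
    )
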