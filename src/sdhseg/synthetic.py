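"""Synthetic MRI-like tumor phantoms for hermetic training and testing.

Each phantom is a 2-D grayscale image in [0,1]: a dark exterior, an
elliptical "skull" region filled with smooth low-frequency tissue texture,
and — for tumor-positive samples — one or two irregular bright lesions
(randomly deformed ellipses with softened interior edges) whose exact
pixel support is the ground-truth mask. Lesions cover 1-10% of the frame,
mirroring the strong class imbalance of clinical low-grade glioma data
(34.9% of samples tumor-positive; 70/20/10 train/test/validation split).

Everything is a pure function of the seed: identical (n, prevalence, seed)
yield bit-identical images, masks and manifests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import InvalidSplit

__all__ = [
    "PhantomSample",
    "PhantomSet",
    "DatasetSplits",
    "generate_phantom",
    "generate_dataset",
    "load_image_mask_directory",
]

PARTITIONS = ("train", "test", "val")
DEFAULT_PREVALENCE = 0.349
DEFAULT_SPLIT = (0.70, 0.20, 0.10)


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray
    mask: np.ndarray
    meta: dict

    def __post_init__(self):
        assert bool(self.meta["has_tumor"]) == bool(self.mask.any())
        assert self.meta["tumor_area_px"] == int(self.mask.sum())


@dataclass(frozen=True)
class PhantomSet:
    """A partition: images (n,H,W) float32 in [0,1], masks (n,H,W) uint8."""

    images: np.ndarray
    masks: np.ndarray
    meta: pd.DataFrame

    def __len__(self) -> int:
        return len(self.images)


@dataclass(frozen=True)
class DatasetSplits:
    train: PhantomSet
    test: PhantomSet
    val: PhantomSet
    manifest: pd.DataFrame

    def __getitem__(self, name: str) -> PhantomSet:
        return {"train": self.train, "test": self.test, "val": self.val}[name]


def _lowfreq_noise(rng: np.random.Generator, shape: tuple[int, int], cells: int = 7) -> np.ndarray:
    """Smooth noise in [0,1]: coarse grid upsampled with cubic splines."""
    coarse = rng.random((cells, cells))
    zoomed = ndimage.zoom(coarse, (shape[0] / cells, shape[1] / cells), order=3, mode="nearest")
    zoomed = zoomed[: shape[0], : shape[1]]
    lo, hi = zoomed.min(), zoomed.max()
    return (zoomed - lo) / (hi - lo + 1e-12)


def _skull_ellipse(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = h / 2 + rng.normal(0, 0.01 * h), w / 2 + rng.normal(0, 0.01 * w)
    ry = (0.40 + 0.04 * rng.random()) * h
    rx = (0.40 + 0.04 * rng.random()) * w
    return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


def _deformed_blob(rng: np.random.Generator, shape: tuple[int, int],
                   area_px: float, skull: np.ndarray) -> np.ndarray:
    """Support mask of one randomly deformed ellipse of roughly ``area_px``."""
    h, w = shape
    mean_r = np.sqrt(area_px / np.pi)
    aspect = 0.6 + 0.8 * rng.random()
    ry, rx = mean_r / np.sqrt(aspect), mean_r * np.sqrt(aspect)
    inside = np.argwhere(ndimage.binary_erosion(skull, iterations=max(2, int(mean_r))))
    if len(inside) == 0:
        inside = np.argwhere(skull)
    cy, cx = inside[rng.integers(len(inside))]
    theta0 = rng.uniform(0, np.pi)
    # radial deformation: low-order harmonics keep the contour irregular but closed
    ks = np.array([2, 3, 4])
    amps = rng.uniform(0.0, 0.15, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    rr, cc = np.mgrid[0:h, 0:w]
    dy, dx = rr - cy, cc - cx
    y_r = dy * np.cos(theta0) - dx * np.sin(theta0)
    x_r = dy * np.sin(theta0) + dx * np.cos(theta0)
    rho = np.sqrt((y_r / ry) ** 2 + (x_r / rx) ** 2)
    ang = np.arctan2(y_r, x_r)
    r_bound = 1.0 + sum(a * np.cos(k * ang + p) for k, a, p in zip(ks, amps, phases))
    return rho <= r_bound


def generate_phantom(rng, size: tuple[int, int] = (64, 64), with_tumor: bool = True,
                     seed: int | None = None) -> PhantomSample:
    """One phantom image/mask pair, fully determined by the generator state.

    ``rng`` may be an integer seed or a ``numpy.random.Generator``. Lesion
    support totals 1-10% of the frame (resampled until satisfied, which is
    itself deterministic under the rng stream).
    """
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    h, w = size
    if h < 16 or w < 16:
        raise ValueError("phantom size must be at least 16x16")

    skull = _skull_ellipse(rng, size)
    tissue = 0.30 + 0.30 * _lowfreq_noise(rng, size)
    image = np.where(skull, tissue, 0.02 + 0.02 * _lowfreq_noise(rng, size))

    mask = np.zeros(size, dtype=np.uint8)
    if with_tumor:
        lo, hi = 0.01 * h * w, 0.10 * h * w
        for _ in range(50):  # resample until the stated area constraint holds
            n_blobs = 1 if rng.random() < 0.6 else 2
            frac = rng.uniform(0.015, 0.08)
            support = np.zeros(size, dtype=bool)
            for _ in range(n_blobs):
                support |= _deformed_blob(rng, size, frac * h * w / n_blobs, skull)
            area = int(support.sum())
            if lo <= area <= hi:
                break
        else:
            raise RuntimeError("could not draw a lesion satisfying the area constraint")
        mask = support.astype(np.uint8)
        # bright lesion with genuinely blurred margins: the brightness bump
        # ramps from ~0 at the support edge to its maximum over a few px and
        # is lightly smoothed, so edge pixels are ambiguous in intensity
        # while the mask remains the exact support
        dist_in = ndimage.distance_transform_edt(support)
        bump = 0.45 * np.clip(dist_in / 4.0, 0.0, 1.0)
        bump = ndimage.gaussian_filter(bump, sigma=0.8)
        image = np.where(skull, image + bump, image)

    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    meta = {"has_tumor": bool(mask.any()), "tumor_area_px": int(mask.sum()),
            "seed": -1 if seed is None else int(seed)}
    return PhantomSample(image=image, mask=mask, meta=meta)


def _largest_remainder(total: int, fractions) -> list[int]:
    """Integer apportionment of ``total`` by ``fractions`` (sums exactly)."""
    raw = [total * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    rem = total - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainders first
    for i in range(rem):
        base[order[i]] += 1
    return base


def generate_dataset(n: int, prevalence: float = DEFAULT_PREVALENCE,
                     split: tuple[float, float, float] = DEFAULT_SPLIT,
                     seed: int = 0, size: tuple[int, int] = (64, 64),
                     out_dir=None) -> DatasetSplits:
    """A stratified phantom dataset with train/test/val manifests.

    Exactly ``round(n * prevalence)`` samples are tumor-positive, and the
    positives are apportioned so every partition's prevalence matches the
    global one to within one sample. With ``out_dir`` set, images and masks
    are written as 8-bit PNGs along with a ``manifest.csv``.
    """
    if n < 10:
        raise ValueError("n must be at least 10")
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    if abs(sum(split) - 1.0) > 1e-9:
        raise InvalidSplit(f"split {split} does not sum to 1")

    n_pos = int(round(n * prevalence))
    pos_per_part = _largest_remainder(n_pos, split)
    tot_per_part = _largest_remainder(n, split)
    neg_per_part = [t - p for t, p in zip(tot_per_part, pos_per_part)]
    if min(neg_per_part) < 0:
        raise InvalidSplit("split incompatible with the requested prevalence")

    labels: list[tuple[bool, str]] = []
    for part, np_, nn_ in zip(PARTITIONS, pos_per_part, neg_per_part):
        labels += [(True, part)] * np_ + [(False, part)] * nn_

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    sample_seeds = np.random.SeedSequence(seed).generate_state(n).astype(np.int64) % (2**31)

    records = []
    samples: list[PhantomSample] = []
    for idx, (has_tumor, part) in enumerate(labels):
        s = generate_phantom(int(sample_seeds[idx]), size=size, with_tumor=has_tumor)
        samples.append(s)
        records.append({"sample_id": idx, "image_path": f"images/sample_{idx:05d}.png",
                        "mask_path": f"masks/sample_{idx:05d}.png",
                        "has_tumor": s.meta["has_tumor"],
                        "tumor_area_px": s.meta["tumor_area_px"],
                        "seed": s.meta["seed"], "partition": part})
    manifest = pd.DataFrame(records)

    if out_dir is not None:
        from .io import write_image, write_mask

        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for rec, s in zip(records, samples):
            write_image(out / rec["image_path"], s.image)
            write_mask(out / rec["mask_path"], s.mask)
        manifest.to_csv(out / "manifest.csv", index=False)

    def collect(part: str) -> PhantomSet:
        idxs = [i for i, (_, p) in enumerate(labels) if p == part]
        images = np.stack([samples[i].image for i in idxs]) if idxs else np.zeros((0, *size), np.float32)
        masks = np.stack([samples[i].mask for i in idxs]) if idxs else np.zeros((0, *size), np.uint8)
        return PhantomSet(images=images, masks=masks,
                          meta=manifest.iloc[idxs].reset_index(drop=True))

    return DatasetSplits(train=collect("train"), test=collect("test"),
                         val=collect("val"), manifest=manifest)


def load_image_mask_directory(root, mask_suffix: str = "_mask") -> tuple[np.ndarray, np.ndarray]:
    """Adapter for on-disk image/mask pair layouts (e.g. TIFF pairs where the
    mask file shares the image stem plus a suffix). Never required by tests.
    """
    from .io import read_image, read_mask

    root = Path(root)
    images, masks = [], []
    exts = (".png", ".tif", ".tiff")
    for img_path in sorted(p for p in root.rglob("*") if p.suffix.lower() in exts
                           and mask_suffix not in p.stem):
        mask_path = img_path.with_name(img_path.stem + mask_suffix + img_path.suffix)
        if mask_path.exists():
            images.append(read_image(img_path))
            masks.append(read_mask(mask_path))
    if not images:
        raise FileNotFoundError(f"no image/mask pairs under {root}")
    return np.stack(images), np.stack(masks)
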