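"""Tissue masking, patch grids, the white-patch rule, splits and flips.

A whole-slide raster is first reduced to a tissue mask (Otsu threshold on
the channel-mean intensity, tissue on the dark side, then a morphological
closing-and-opening clean-up), and a non-overlapping window grid is laid
over it; only windows that touch tissue are worth classifying.  Patch
datasets for classifier training are split per class with fixed fractions
and augmented with horizontal/vertical flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.morphology import closing as _closing, disk, opening as _opening

__all__ = [
    "TissueMask",
    "PatchGrid",
    "SplitAllocation",
    "otsu_threshold",
    "tissue_mask",
    "tile_grid",
    "is_white_patch",
    "scale_patches",
    "stratified_split",
    "split_assign",
    "write_patch_dataset",
    "augment_flips",
]


@dataclass
class TissueMask:
    """Binary tissue raster plus the parameters that produced it."""

    mask: np.ndarray
    threshold: float | None
    morph_radius: int

    @property
    def shape(self):
        return self.mask.shape


def otsu_threshold(gray: np.ndarray) -> int | None:
    """Otsu's threshold over the 256 integer candidates 0..255.

    Returns the t maximizing the between-class variance of the split
    ``gray <= t`` vs ``gray > t`` (ties broken toward the lowest t), or
    ``None`` when the image is constant and no split exists.
    """
    gray = np.clip(np.asarray(gray, dtype=float), 0, 255)
    hist = np.bincount(np.round(gray).astype(np.int64).ravel(), minlength=256)
    hist = hist[:256].astype(float)
    total = hist.sum()
    if (hist > 0).sum() < 2:
        return None
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * levels)
    mu_total = m0[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    var_b = np.zeros(256)
    var_b[valid] = (
        (mu_total * w0[valid] - m0[valid] * total) ** 2
        / (w0[valid] * w1[valid])
    )
    return int(np.argmax(var_b))  # argmax takes the first (lowest) maximizer


def tissue_mask(image: np.ndarray, morph_radius: int = 1) -> TissueMask:
    """Tissue mask of an RGB (or grayscale) raster.

    Grayscale is the per-pixel mean over channels; tissue pixels are those
    at or below the Otsu threshold (stained tissue is darker than glass
    background); a binary closing then opening with a disk of
    ``morph_radius`` removes pinholes and specks.  A constant image yields
    an empty mask and a warning.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image is empty")
    gray = image.mean(axis=2) if image.ndim == 3 else image.astype(float)
    t = otsu_threshold(gray)
    if t is None:
        warnings.warn("constant image: returning empty tissue mask",
                      stacklevel=2)
        return TissueMask(np.zeros(gray.shape, dtype=bool), None, morph_radius)
    mask = gray <= t
    if morph_radius > 0:
        footprint = disk(morph_radius)
        mask = _opening(_closing(mask, footprint), footprint).astype(bool)
    return TissueMask(mask, float(t), morph_radius)


@dataclass
class PatchGrid:
    """Non-overlapping window grid over an image.

    Cell (i, j) covers pixel rows ``[i*s, (i+1)*s)`` and columns
    ``[j*s, (j+1)*s)``; remainders at the right/bottom edges are dropped.
    ``tissue`` flags the cells worth classifying.
    """

    patch_size: int
    n_rows: int
    n_cols: int
    tissue: np.ndarray  # (n_rows, n_cols) bool

    @property
    def shape(self):
        return self.n_rows, self.n_cols

    def window(self, i: int, j: int):
        s = self.patch_size
        return slice(i * s, (i + 1) * s), slice(j * s, (j + 1) * s)

    def iter_tissue(self):
        """Yield (i, j) of tissue cells in row-major order."""
        for i, j in np.argwhere(self.tissue):
            yield int(i), int(j)


def tile_grid(image_shape, patch_size: int, mask: TissueMask | np.ndarray | None = None,
              tissue_fraction: float = 0.0) -> PatchGrid:
    """Lay a non-overlapping patch grid over an image.

    A cell is flagged tissue iff strictly more than ``tissue_fraction`` of
    its pixels are tissue (default 0: any tissue pixel counts).  With no
    mask, all cells are tissue.  A patch size exceeding either image
    dimension yields an empty grid with a warning.
    """
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    h, w = int(image_shape[0]), int(image_shape[1])
    n_rows, n_cols = h // patch_size, w // patch_size
    if n_rows == 0 or n_cols == 0:
        warnings.warn("patch_size exceeds image dimensions: empty grid",
                      stacklevel=2)
        return PatchGrid(patch_size, n_rows, n_cols,
                         np.zeros((n_rows, n_cols), dtype=bool))
    if mask is None:
        flags = np.ones((n_rows, n_cols), dtype=bool)
    else:
        m = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask)
        m = m[: n_rows * patch_size, : n_cols * patch_size].astype(float)
        frac = m.reshape(n_rows, patch_size, n_cols, patch_size).mean(axis=(1, 3))
        flags = frac > tissue_fraction
    return PatchGrid(patch_size, n_rows, n_cols, flags)


def is_white_patch(patch: np.ndarray, threshold: float = 200.0) -> bool:
    """True iff the mean over all pixels and channels strictly exceeds the
    white threshold (0-255 scale)."""
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("patch is empty")
    return float(patch.mean()) > threshold


def scale_patches(patches: np.ndarray) -> np.ndarray:
    """Rescale 0-255 intensities to [0, 1] by dividing by 255."""
    return np.asarray(patches, dtype=np.float64) / 255.0


@dataclass
class SplitAllocation:
    """Per-class (n_train, n_val, n_test) allocation; counts are conserved."""

    per_class: dict

    def totals(self):
        t = np.sum([v for v in self.per_class.values()], axis=0)
        return int(t[0]), int(t[1]), int(t[2])


def stratified_split(class_counts: dict, fractions=(0.72, 0.08, 0.20)) -> SplitAllocation:
    """Allocate each class's patches to train/val/test.

    Per class of size n: ``n_train = round-half-up(f_train * n)``,
    ``n_test = floor(f_test * n)``, and validation takes the remainder, so
    counts are conserved exactly.
    """
    f_train, f_val, f_test = fractions
    if not np.isclose(f_train + f_val + f_test, 1.0):
        raise ValueError("fractions must sum to 1")
    alloc = {}
    for cls, n in class_counts.items():
        n = int(n)
        if n < 0:
            raise ValueError("class counts must be >= 0")
        n_train = int(np.floor(f_train * n + 0.5))
        n_test = int(np.floor(f_test * n))
        n_val = n - n_train - n_test
        if n_val < 0:
            raise ValueError(f"negative validation count for class {cls!r}")
        alloc[cls] = (n_train, n_val, n_test)
    return SplitAllocation(alloc)


def split_assign(labels, fractions=(0.72, 0.08, 0.20), seed: int = 0):
    """Assign each labeled item to 'train'/'val'/'test' by seeded shuffle,
    honoring the per-class allocation of :func:`stratified_split`."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    alloc = stratified_split(dict(zip(classes.tolist(), counts.tolist())),
                             fractions)
    rng = np.random.default_rng(seed)
    out = np.empty(labels.shape, dtype=object)
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_train, n_val, _ = alloc.per_class[cls]
        out[idx[:n_train]] = "train"
        out[idx[n_train:n_train + n_val]] = "val"
        out[idx[n_train + n_val:]] = "test"
    return out, alloc


def write_patch_dataset(directory, patches, labels, splits=None,
                        class_names=("tumor", "non_malignant", "white"),
                        source_info=None):
    """Write a labeled patch dataset as PNG files plus a manifest CSV.

    The manifest holds one row per patch: patch_id, source_image, row, col,
    class_label, split.  ``source_info`` may supply (source_image, row, col)
    triples; absent entries are blank.
    """
    import pandas as pd
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (patch, label) in enumerate(zip(patches, labels)):
        pid = f"patch_{k:05d}"
        Image.fromarray(np.asarray(patch, dtype=np.uint8)).save(
            directory / f"{pid}.png")
        src, row, col = (source_info[k] if source_info is not None
                         else ("", "", ""))
        rows.append({
            "patch_id": pid,
            "source_image": src,
            "row": row,
            "col": col,
            "class_label": class_names[int(label)],
            "split": splits[k] if splits is not None else "",
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def augment_flips(patch: np.ndarray):
    """The four flip variants of a patch: identity, horizontal flip,
    vertical flip, and both (a 180-degree rotation)."""
    patch = np.asarray(patch)
    return [
        patch.copy(),
        patch[:, ::-1].copy(),
        patch[::-1, :].copy(),
        patch[::-1, ::-1].copy(),
    ]
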