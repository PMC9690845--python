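"""Dataset loading, tumor-size measurement, size groups, resizing, folds.

Tumor size is the length in pixels of the longest axis of the tumor region
in the original-resolution mask, i.e. the maximum Euclidean distance
between any two foreground pixel centres (Feret diameter). Tumors with a
longest axis of at most 120 px count as small; the four reporting groups
tile (0, inf) as (0,100], (100,120], (120,160], (160,inf).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage.transform import resize as _sk_resize

log = logging.getLogger(__name__)

SMALL_TUMOR_THRESHOLD_PX = 120.0
GROUP_EDGES = (0.0, 100.0, 120.0, 160.0)
GROUP_LABELS = ("G1", "G2", "G3", "G4")


@dataclass
class ImageSample:
    """One grayscale image with its binary tumor mask at original resolution."""

    id: str
    image: np.ndarray          # float in [0, 1]
    mask: np.ndarray           # uint8 in {0, 1}, same shape as image
    axis_px: float             # longest-axis length on the original mask; 0 if empty

    @property
    def empty_mask(self) -> bool:
        return not self.mask.any()


@dataclass(frozen=True)
class SizeGroup:
    label: str
    is_small: bool


@dataclass
class FoldPlan:
    k: int
    assignment: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignment.items() if f == fold]

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        """(train_ids, test_ids) for one fold."""
        test = self.fold_ids(fold)
        train = [i for i, f in self.assignment.items() if f != fold]
        return train, test


def tumor_longest_axis(mask: np.ndarray) -> float:
    """Feret diameter of the foreground: max pairwise pixel-centre distance.

    Computed on the convex hull vertices (the diameter of a point set is
    attained by hull vertices), with a dense fallback for degenerate hulls.
    A single foreground pixel has diameter 0.
    """
    pts = np.argwhere(np.asarray(mask) != 0).astype(float)
    if pts.shape[0] == 0:
        raise ValueError("empty mask: longest axis undefined")
    if pts.shape[0] == 1:
        return 0.0
    if pts.shape[0] > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points: fall through to the pairwise scan
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def assign_size_group(axis_px: float) -> SizeGroup:
    """Map a longest-axis length to its reporting group (intervals open below,
    closed above); small means axis <= 120 px."""
    if axis_px <= 0:
        raise ValueError(f"axis length must be positive, got {axis_px}")
    if axis_px <= GROUP_EDGES[1]:
        label = "G1"
    elif axis_px <= GROUP_EDGES[2]:
        label = "G2"
    elif axis_px <= GROUP_EDGES[3]:
        label = "G3"
    else:
        label = "G4"
    return SizeGroup(label=label, is_small=axis_px <= SMALL_TUMOR_THRESHOLD_PX)


def _read_gray(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return np.asarray(arr)


def load_dataset(manifest: str | Path) -> list[ImageSample]:
    """Load image/mask pairs listed in a manifest CSV.

    Columns: image_path, mask_path and optionally id (default: image stem).
    Paths are resolved relative to the manifest's directory. Images are
    normalized to [0, 1] by their dtype range; masks binarize at value > 0.
    Samples whose mask is empty are loaded but flagged (axis_px = 0) and are
    skipped by metric computation downstream. Unreadable rows are reported
    and skipped.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    if len(df) == 0:
        raise ValueError(f"empty manifest: {manifest}")
    if not {"image_path", "mask_path"} <= set(df.columns):
        raise ValueError("manifest must have image_path and mask_path columns")
    root = manifest.parent
    samples = []
    for row in df.itertuples(index=True):
        img_path = root / str(row.image_path)
        mask_path = root / str(row.mask_path)
        try:
            img = _read_gray(img_path)
            mask = _read_gray(mask_path)
        except (FileNotFoundError, OSError, ValueError) as exc:
            log.warning("manifest row %d unreadable (%s): skipped", row.Index, exc)
            continue
        if img.shape != mask.shape:
            raise ValueError(
                f"manifest row {row.Index}: image {img.shape} and mask "
                f"{mask.shape} shapes differ ({img_path.name})")
        if np.issubdtype(img.dtype, np.integer):
            img = img.astype(np.float64) / np.iinfo(img.dtype).max
        else:
            img = np.clip(img.astype(np.float64), 0.0, 1.0)
        mask = (mask > 0).astype(np.uint8)
        sid = str(getattr(row, "id", img_path.stem)) if "id" in df.columns else img_path.stem
        if mask.any():
            axis = tumor_longest_axis(mask)
        else:
            axis = 0.0
            log.warning("sample %s has an empty mask; excluded from metrics", sid)
        samples.append(ImageSample(id=sid, image=img, mask=mask, axis_px=axis))
    if not samples:
        raise ValueError(f"no readable rows in manifest {manifest}")
    return samples


def resize_for_net(sample: ImageSample, side: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Resize to the network's square input: bilinear for the image,
    nearest-neighbour for the mask (so it stays binary). The sample's
    original-resolution axis_px is not touched."""
    if side < 16:
        raise ValueError(f"side {side} is below the four pooling stages' minimum of 16")
    if sample.image.shape == (side, side):
        return sample.image.copy(), sample.mask.copy()
    img = _sk_resize(sample.image, (side, side), order=1, mode="reflect",
                     anti_aliasing=True, preserve_range=True)
    mask = _sk_resize(sample.mask, (side, side), order=0, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    return np.clip(img, 0.0, 1.0), (mask > 0.5).astype(np.uint8)


def make_folds(ids: list[str], k: int = 5, seed: int = 0) -> FoldPlan:
    """Deterministic balanced k-fold partition (fold sizes differ by <= 1)."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    if len(ids) < k:
        raise ValueError(f"need at least k={k} samples, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[j]: int(pos % k) for pos, j in enumerate(order)}
    return FoldPlan(k=k, assignment=assignment, seed=seed)
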