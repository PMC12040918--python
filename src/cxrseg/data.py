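"""Loading, mask combination, preprocessing, augmentation and splitting.

The processing flow mirrors how paired chest-radiograph segmentation sets
are prepared: per-structure masks (left/right lungs, left/right clavicles,
heart) are merged into one channel per anatomical class plus a background
channel, images are resized and normalized to [0, 1], the corpus is doubled
by one small random rotation per sample, and train/test splits are seeded,
optionally stratified, and guarded against leaking an augmented copy to the
opposite side of the split from its source image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .datatypes import (
    CLASS_NAMES,
    STRUCTURE_CLASSES,
    Dataset,
    MaskStack,
    SamplePair,
)

__all__ = [
    "SplitResult",
    "load_sample",
    "combine_masks",
    "preprocess_sample",
    "augment_dataset",
    "split_dataset",
    "clavicle_fraction_strata",
    "save_dataset",
    "load_dataset",
]


def _read_gray(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale raster and rescale to [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if arr.dtype.kind == "i":
        # PIL mode I;16 TIFFs load as int32
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def load_sample(
    image_path: str | Path,
    mask_paths: Mapping[str, str | Path],
    identifier: str | None = None,
) -> SamplePair:
    """Load an image and its per-structure masks from disk.

    Image intensities are rescaled from the native bit depth to [0, 1];
    masks are binarized at half of full scale.  Mask keys may be final
    class names (``lungs``, ``heart``, ``clavicles``) or paired part names
    (``lung_left``/``lung_right``, ``clavicle_left``/``clavicle_right``),
    which are merged by :func:`combine_masks`.
    """
    image = _read_gray(image_path)
    rasters = {}
    for name, p in mask_paths.items():
        m = _read_gray(p)
        if m.shape != image.shape:
            raise ValueError(
                f"mask {name!r} shape {m.shape} does not match image {image.shape}"
            )
        rasters[name] = (m > 0.5).astype(np.uint8)
    masks = combine_masks(rasters)
    ident = identifier or Path(image_path).stem
    return SamplePair(image=image, masks=masks, identifier=ident, provenance="loaded")


_PART_ALIASES = {
    "lung": "lungs",
    "lung_left": "lungs",
    "lung_right": "lungs",
    "left_lung": "lungs",
    "right_lung": "lungs",
    "clavicle": "clavicles",
    "clavicle_left": "clavicles",
    "clavicle_right": "clavicles",
    "left_clavicle": "clavicles",
    "right_clavicle": "clavicles",
}


def combine_masks(structure_masks: Mapping[str, np.ndarray]) -> MaskStack:
    """Merge per-part masks into canonical per-class channels plus background.

    Left/right lung and clavicle rasters are merged by elementwise maximum
    into single ``lungs`` / ``clavicles`` channels; a background channel is
    appended as the complement of the union of all structures.
    """
    merged: dict[str, np.ndarray] = {}
    shapes = set()
    for name, raster in structure_masks.items():
        raster = np.asarray(raster)
        if not np.isin(raster, (0, 1)).all():
            raise ValueError(f"mask {name!r} is not binary")
        shapes.add(raster.shape)
        target = _PART_ALIASES.get(name, name)
        if target not in STRUCTURE_CLASSES:
            raise ValueError(f"unknown structure class {name!r}")
        if target in merged:
            merged[target] = np.maximum(merged[target], raster.astype(np.uint8))
        else:
            merged[target] = raster.astype(np.uint8)
    if len(shapes) > 1:
        raise ValueError(f"mask shapes disagree: {shapes}")
    return MaskStack.from_channels(merged)


def preprocess_sample(sample: SamplePair, target_size: int = 512) -> SamplePair:
    """Resize to ``target_size`` square and renormalize.

    The image is resampled bilinearly, masks with nearest-neighbor so they
    stay binary; the background channel is recomputed afterwards so the
    complement identity holds exactly at the new resolution.
    """
    if target_size <= 0:
        raise ValueError("target size must be positive")
    shape = (target_size, target_size)
    if sample.image.shape == shape:
        image = sample.image.copy()
        chans = {
            c: sample.masks[c].copy() for c in STRUCTURE_CLASSES
        }
    else:
        image = _sk_resize(
            sample.image, shape, order=1, preserve_range=True, anti_aliasing=False
        )
        chans = {
            c: _sk_resize(
                sample.masks[c], shape, order=0, preserve_range=True, anti_aliasing=False
            ).astype(np.uint8)
            for c in STRUCTURE_CLASSES
        }
    image = np.clip(image, 0.0, 1.0)
    return SamplePair(
        image=image,
        masks=MaskStack.from_channels(chans),
        identifier=sample.identifier,
        provenance=sample.provenance,
        meta=dict(sample.meta),
    )


def _rotate_sample(sample: SamplePair, angle: float) -> SamplePair:
    """Rotate image and masks about the center by ``angle`` degrees."""
    image = ndimage.rotate(
        sample.image, angle, reshape=False, order=1, mode="constant", cval=0.0
    )
    image = np.clip(image, 0.0, 1.0)
    chans = {}
    for c in STRUCTURE_CLASSES:
        chans[c] = ndimage.rotate(
            sample.masks[c], angle, reshape=False, order=0, mode="constant", cval=0
        ).astype(np.uint8)
    meta = dict(sample.meta)
    meta.update({"source_id": sample.identifier, "rotation_deg": float(angle)})
    return SamplePair(
        image=image,
        masks=MaskStack.from_channels(chans),
        identifier=f"{sample.identifier}-rot",
        provenance=sample.provenance,
        meta=meta,
    )


def augment_dataset(
    dataset: Dataset,
    angle_low: float = -5.0,
    angle_high: float = 5.0,
    seed: int = 0,
) -> Dataset:
    """Double the corpus: each sample gains one randomly rotated copy.

    The rotation angle is drawn uniformly from ``[angle_low, angle_high]``
    excluding exactly 0 (re-drawn on a zero hit); image and masks rotate by
    the same angle about the center with black fill outside the original
    support.  Copies carry a ``source_id`` so splits can keep them on the
    same side as their original.
    """
    if not (angle_low < 0 < angle_high):
        raise ValueError("angle range must straddle 0 (angle_low < 0 < angle_high)")
    rng = np.random.default_rng(seed)
    out = list(dataset)
    for sample in dataset:
        angle = 0.0
        while angle == 0.0:
            angle = rng.uniform(angle_low, angle_high)
        out.append(_rotate_sample(sample, angle))
    return Dataset(out)


@dataclass
class SplitResult:
    """A seeded train/test partition of sample identifiers."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    fraction: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train": self.train_ids,
                    "test": self.test_ids,
                    "seed": self.seed,
                    "fraction": self.fraction,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitResult":
        d = json.loads(Path(path).read_text())
        return cls(d["train"], d["test"], d["seed"], d["fraction"])


def split_dataset(
    dataset: Dataset,
    test_fraction: float = 0.2,
    seed: int = 0,
    strata: Sequence | None = None,
) -> SplitResult:
    """Seeded, optionally stratified train/test split with a leakage guard.

    Samples sharing a ``source_id`` (an original and its augmented copies)
    always land on the same side.  With strata, test slots are allocated to
    strata by largest-remainder rounding so every stratum's test share is
    within one sample of ``test_fraction`` and the total equals
    ``round(test_fraction * n)`` (up to group indivisibility).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    n = len(dataset)
    if strata is not None and len(strata) != n:
        raise ValueError("strata length must match dataset size")

    # Group samples by source id; a group's stratum is its source sample's.
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(dataset):
        groups.setdefault(s.source_id, []).append(i)
    group_ids = sorted(groups)
    group_stratum = {}
    for gid, members in groups.items():
        src = members[0]
        for m in members:
            if dataset[m].identifier == gid:
                src = m
                break
        group_stratum[gid] = strata[src] if strata is not None else 0

    # Largest-remainder allocation of test slots across strata.
    target_total = int(round(test_fraction * n))
    strata_values = sorted({group_stratum[g] for g in group_ids}, key=repr)
    sizes = {
        v: sum(len(groups[g]) for g in group_ids if group_stratum[g] == v)
        for v in strata_values
    }
    ideal = {v: test_fraction * sizes[v] for v in strata_values}
    alloc = {v: int(np.floor(ideal[v])) for v in strata_values}
    leftover = target_total - sum(alloc.values())
    by_frac = sorted(strata_values, key=lambda v: ideal[v] - alloc[v], reverse=True)
    for v in by_frac[: max(leftover, 0)]:
        alloc[v] += 1

    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for v in strata_values:
        gids = [g for g in group_ids if group_stratum[g] == v]
        order = rng.permutation(len(gids))
        count = 0
        for j in order:
            if count >= alloc[v]:
                break
            members = groups[gids[j]]
            test_idx.extend(members)
            count += len(members)
    test_set = set(test_idx)
    ids = dataset.identifiers
    train_ids = [ids[i] for i in range(n) if i not in test_set]
    test_ids = [ids[i] for i in sorted(test_set)]
    return SplitResult(train_ids, test_ids, seed=seed, fraction=test_fraction)


def clavicle_fraction_strata(dataset: Dataset, n_bins: int = 2) -> np.ndarray:
    """Quantile-bin labels of the clavicle pixel fraction per sample.

    The clavicles are the smallest class, so their per-image pixel share is
    the natural balance label for stratified splits of a segmentation set
    in which every image contains every class.
    """
    fracs = np.array(
        [s.masks["clavicles"].mean() for s in dataset], dtype=np.float64
    )
    return pd.qcut(fracs, q=n_bins, labels=False, duplicates="drop")


def save_dataset(dataset: Dataset, root: str | Path) -> Path:
    """Write ``<root>/images/<id>.png``, ``<root>/masks/<id>_<class>.png``
    and a manifest CSV; returns the manifest path."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in dataset:
        img_path = root / "images" / f"{s.identifier}.png"
        Image.fromarray(np.round(s.image * 255).astype(np.uint8), mode="L").save(
            img_path
        )
        row = {"id": s.identifier, "image_path": str(img_path)}
        for c in CLASS_NAMES:
            p = root / "masks" / f"{s.identifier}_{c}.png"
            Image.fromarray((s.masks[c] * 255).astype(np.uint8), mode="L").save(p)
            row[f"mask_{c}"] = str(p)
        rows.append(row)
    manifest = root / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest: str | Path) -> Dataset:
    """Load a dataset back from a manifest CSV written by :func:`save_dataset`."""
    df = pd.read_csv(manifest)
    samples = []
    for _, row in df.iterrows():
        mask_paths = {
            c: row[f"mask_{c}"] for c in STRUCTURE_CLASSES if f"mask_{c}" in row
        }
        samples.append(
            load_sample(row["image_path"], mask_paths, identifier=str(row["id"]))
        )
    return Dataset(samples)
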