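"""Core in-memory containers shared by every stage of the pipeline.

Images are 2-D ``float64`` arrays with intensities in ``[0, 1]``, row-major,
origin at the top-left corner.  Masks are stacks of per-class binary rasters
in a canonical channel order: the three anatomical structures first, then a
background channel defined as the complement of their union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

#: Canonical channel order for all mask stacks.
CLASS_NAMES: tuple[str, ...] = ("lungs", "heart", "clavicles", "background")

#: The anatomical classes, excluding the derived background channel.
STRUCTURE_CLASSES: tuple[str, ...] = CLASS_NAMES[:-1]


def _as_binary(arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{what} must contain only 0/1 values")
    return arr.astype(np.uint8)


@dataclass(frozen=True)
class MaskStack:
    """Per-class binary rasters aligned to one image.

    Parameters
    ----------
    channels
        Array of shape ``(n_classes, H, W)`` with values in ``{0, 1}``.
    class_names
        Channel labels in storage order; defaults to :data:`CLASS_NAMES`.
    """

    channels: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        channels = _as_binary(self.channels, "mask channels")
        if channels.ndim != 3:
            raise ValueError("channels must be a (n_classes, H, W) array")
        if channels.shape[0] != len(self.class_names):
            raise ValueError(
                f"{channels.shape[0]} channels but {len(self.class_names)} class names"
            )
        object.__setattr__(self, "channels", channels)

    @classmethod
    def from_channels(cls, named: Mapping[str, np.ndarray]) -> "MaskStack":
        """Build a stack from structure channels, appending the background.

        ``named`` must provide every class in :data:`STRUCTURE_CLASSES`; the
        background channel is computed as ``1 - max`` over the structures.
        """
        missing = set(STRUCTURE_CLASSES) - set(named)
        if missing:
            raise ValueError(f"missing structure channels: {sorted(missing)}")
        rasters = [_as_binary(named[c], c) for c in STRUCTURE_CLASSES]
        shapes = {r.shape for r in rasters}
        if len(shapes) != 1:
            raise ValueError(f"structure channels disagree on shape: {shapes}")
        union = np.maximum.reduce(rasters)
        background = (1 - union).astype(np.uint8)
        return cls(np.stack(rasters + [background]))

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (H, W) shape shared by every channel."""
        return self.channels.shape[1:]

    def __getitem__(self, class_name: str) -> np.ndarray:
        return self.channels[self.class_names.index(class_name)]

    def pixel_counts(self) -> dict[str, int]:
        return {
            name: int(self.channels[i].sum()) for i, name in enumerate(self.class_names)
        }

    def background_is_complement(self) -> bool:
        union = np.maximum.reduce(self.channels[:-1])
        return bool(np.array_equal(self.channels[-1], 1 - union))


@dataclass
class SamplePair:
    """One grayscale image together with its ground-truth mask stack."""

    image: np.ndarray
    masks: MaskStack
    identifier: str
    provenance: str = "synthetic"  # {"synthetic", "loaded"}
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise ValueError("image must be 2-D")
        if self.image.shape != self.masks.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.masks.shape}"
            )
        if self.provenance not in ("synthetic", "loaded"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def source_id(self) -> str:
        """Identifier of the un-augmented original this sample derives from."""
        return self.meta.get("source_id", self.identifier)


class Dataset:
    """An ordered collection of :class:`SamplePair` with unique identifiers."""

    def __init__(self, samples: Iterable[SamplePair]):
        self.samples: list[SamplePair] = list(samples)
        ids = [s.identifier for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample identifiers must be unique")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SamplePair]:
        return iter(self.samples)

    def __getitem__(self, key):
        if isinstance(key, str):
            for s in self.samples:
                if s.identifier == key:
                    return s
            raise KeyError(key)
        if isinstance(key, slice):
            return Dataset(self.samples[key])
        return self.samples[key]

    @property
    def identifiers(self) -> list[str]:
        return [s.identifier for s in self.samples]

    def subset(self, ids: Iterable[str]) -> "Dataset":
        wanted = list(ids)
        by_id = {s.identifier: s for s in self.samples}
        return Dataset(by_id[i] for i in wanted)

    def images(self) -> np.ndarray:
        """Stack all images into an ``(n, H, W)`` array (uniform shapes only)."""
        return np.stack([s.image for s in self.samples])

    def mask_tensor(self) -> np.ndarray:
        """Stack all masks into an ``(n, n_classes, H, W)`` array."""
        return np.stack([s.masks.channels for s in self.samples])
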