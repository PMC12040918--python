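"""Seeded synthetic chest phantoms with exact ground-truth masks.

A phantom mimics the statistical layout of a posteroanterior chest
radiograph at the level segmentation cares about: two large bright lung
fields, a medium heart shadow overlapping one lung, and two thin,
low-contrast clavicle bars crossing the upper lung region.  Pixel counts
are therefore heavily imbalanced (lungs >> heart >> clavicles), which is
the property the class-weighting and stratification stages exercise.

This is test scaffolding, not an anatomical simulation: geometry is
parametric (jittered ellipses and rotated bars) and noise is additive
Gaussian clipped to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .datatypes import Dataset, MaskStack, SamplePair

_BASE_INTENSITY = 0.30


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    Parameters
    ----------
    height, width
        Raster size in pixels; at least 32 each.
    contrast
        Structure-to-background intensity gap on the [0, 1] scale, in (0, 1].
        Lungs sit at the full gap, the heart at 0.75 of it, clavicles at half
        (the hardest, lowest-contrast class).
    noise_sd
        Standard deviation of the additive Gaussian noise; 0 disables noise.
    seed
        Seed controlling jitter and noise; identical specs are bit-identical.
    """

    height: int = 64
    width: int = 64
    contrast: float = 0.4
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom size must be at least 32x32")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _ellipse_mask(h, w, cy, cx, ry, rx, angle):
    """Binary raster of a rotated ellipse; centers/radii in pixel units."""
    yy, xx = np.mgrid[0:h, 0:w]
    c, s = np.cos(angle), np.sin(angle)
    u = (xx - cx) * c + (yy - cy) * s
    v = -(xx - cx) * s + (yy - cy) * c
    return ((u / rx) ** 2 + (v / ry) ** 2 <= 1.0).astype(np.uint8)


def _bar_mask(h, w, cy, cx, half_len, half_thick, angle):
    """Binary raster of a rotated rectangle (a 'bar')."""
    yy, xx = np.mgrid[0:h, 0:w]
    c, s = np.cos(angle), np.sin(angle)
    u = (xx - cx) * c + (yy - cy) * s
    v = -(xx - cx) * s + (yy - cy) * c
    return ((np.abs(u) <= half_len) & (np.abs(v) <= half_thick)).astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> SamplePair:
    """Render one phantom image plus exact per-structure masks.

    The image is composed on a flat background: lung fields are brighter by
    ``spec.contrast``, the heart overwrites its overlap with a lung at 0.75
    of the gap, clavicle bars add half the gap on top.  Gaussian noise is
    added and the result clipped to [0, 1].  Masks record the exact geometry
    (structures may overlap; the background channel is the complement of
    their union).
    """
    rng = np.random.default_rng(spec.seed)
    h, w, c = spec.height, spec.width, spec.contrast

    def jit(scale):
        return rng.uniform(-scale, scale)

    # Two lung fields, mirrored about the midline with mild jitter.
    lungs = np.zeros((h, w), dtype=np.uint8)
    lung_params = []
    for cx_frac in (0.30, 0.70):
        cy = (0.52 + jit(0.02)) * h
        cx = (cx_frac + jit(0.02)) * w
        ry = (0.28 * (1 + jit(0.10))) * h
        rx = (0.16 * (1 + jit(0.10))) * w
        ang = jit(np.deg2rad(5))
        lung_params.append((cy, cx))
        lungs |= _ellipse_mask(h, w, cy, cx, ry, rx, ang)

    # Heart: medium ellipse low on the midline, overlapping the right-side
    # lung field (image coordinates).
    heart = _ellipse_mask(
        h,
        w,
        (0.62 + jit(0.02)) * h,
        (0.56 + jit(0.02)) * w,
        (0.15 * (1 + jit(0.10))) * h,
        (0.16 * (1 + jit(0.10))) * w,
        jit(np.deg2rad(8)),
    )

    # Clavicles: one thin tilted bar over the apex of each lung field.
    clav = np.zeros((h, w), dtype=np.uint8)
    for (cy, cx) in lung_params:
        bar_cy = 0.22 * h + jit(0.01) * h
        ang = np.deg2rad(rng.uniform(6, 14)) * (1 if cx < w / 2 else -1)
        clav |= _bar_mask(
            h, w, bar_cy, cx, 0.15 * w, max(0.012 * h, 1.0), ang
        )

    image = np.full((h, w), _BASE_INTENSITY)
    image[lungs == 1] = _BASE_INTENSITY + c
    image[heart == 1] = _BASE_INTENSITY + 0.75 * c  # heart shadow occludes lung
    image[clav == 1] += 0.5 * c
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=(h, w))
    image = np.clip(image, 0.0, 1.0)

    masks = MaskStack.from_channels({"lungs": lungs, "heart": heart, "clavicles": clav})
    return SamplePair(
        image=image,
        masks=masks,
        identifier=f"phantom-{spec.seed:010d}",
        provenance="synthetic",
        meta={"spec": asdict(spec)},
    )


def generate_dataset(n: int, base_spec: PhantomSpec) -> Dataset:
    """Generate ``n`` phantoms with per-sample seeds derived from the base seed.

    Seeds come from a :class:`numpy.random.SeedSequence` keyed on
    ``(base_spec.seed, index)``, so the same call yields identical datasets
    and different indices yield independent jitter and noise.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    samples = []
    for i in range(n):
        child = int(
            np.random.SeedSequence([base_spec.seed, i]).generate_state(1)[0] % 2**31
        )
        spec_i = PhantomSpec(
            height=base_spec.height,
            width=base_spec.width,
            contrast=base_spec.contrast,
            noise_sd=base_spec.noise_sd,
            seed=child,
        )
        sample = generate_phantom(spec_i)
        sample.identifier = f"phantom-{base_spec.seed}-{i:04d}"
        samples.append(sample)
    return Dataset(samples)


def save_sample(sample: SamplePair, out_dir: str | Path, bitdepth: int = 8) -> dict:
    """Write a sample as PNGs plus a JSON sidecar.

    Layout: ``<id>.png`` (8-bit grayscale) or ``<id>.tif`` (16-bit), one
    ``<id>_<class>.png`` binary mask per class, and ``<id>.json`` recording
    provenance and metadata.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if bitdepth == 8:
        img_path = out_dir / f"{sample.identifier}.png"
        arr = np.round(sample.image * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(img_path)
    elif bitdepth == 16:
        img_path = out_dir / f"{sample.identifier}.tif"
        arr = np.round(sample.image * 65535).astype(np.uint16)
        Image.fromarray(arr).save(img_path)
    else:
        raise ValueError("bitdepth must be 8 or 16")

    paths = {"image": str(img_path)}
    for name in sample.masks.class_names:
        p = out_dir / f"{sample.identifier}_{name}.png"
        Image.fromarray((sample.masks[name] * 255).astype(np.uint8), mode="L").save(p)
        paths[name] = str(p)

    sidecar = out_dir / f"{sample.identifier}.json"
    sidecar.write_text(
        json.dumps(
            {
                "identifier": sample.identifier,
                "provenance": sample.provenance,
                "meta": sample.meta,
                "class_names": list(sample.masks.class_names),
                "paths": paths,
            },
            indent=2,
        )
    )
    paths["sidecar"] = str(sidecar)
    return paths
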