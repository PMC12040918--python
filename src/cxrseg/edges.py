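"""Gradient-based edge operators and artifact-mitigation filters.

The segmentation pipeline sharpens anatomical boundaries before training:
horizontal and vertical intensity gradients are estimated with a 3x3 Sobel
or Scharr kernel pair,

    g_x(i,j) = sum_{u=-1..1} sum_{v=-1..1} I(i+u, j+v) * k_x(u+1, v+1),

the per-pixel edge strength is the Euclidean norm g = sqrt(g_x^2 + g_y^2),
and the normalized edge map is blended back into the image.  Optional
contrast-limited adaptive histogram equalization (CLAHE) before edge
detection and local-mean adaptive thresholding after it suppress the noise
amplification the gradient operators introduce.

The double sums are correlations (no kernel flip).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SOBEL_X",
    "SOBEL_Y",
    "SCHARR_X",
    "SCHARR_Y",
    "GradientField",
    "EnhanceOptions",
    "convolve3x3",
    "gradient_magnitude",
    "edge_map",
    "clahe",
    "adaptive_threshold",
    "enhance_image",
    "EdgeEnhancer",
]

# Horizontal-gradient kernels respond to left-right intensity transitions;
# the vertical kernels are their transposes.
SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
SOBEL_Y = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=np.float64)
SCHARR_X = np.array([[-3, 0, 3], [-10, 0, 10], [-3, 0, 3]], dtype=np.float64)
SCHARR_Y = np.array([[-3, -10, -3], [0, 0, 0], [3, 10, 3]], dtype=np.float64)

_KERNELS = {"sobel": (SOBEL_X, SOBEL_Y), "scharr": (SCHARR_X, SCHARR_Y)}
_BORDER_MODES = {"replicate": "nearest", "reflect": "reflect", "zero": "constant"}


@dataclass(frozen=True)
class GradientField:
    """Horizontal/vertical gradient responses and their Euclidean magnitude."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray


@dataclass(frozen=True)
class EnhanceOptions:
    """Configuration of the edge-enhancement front end.

    ``blend_weight`` is the fraction of the normalized edge component mixed
    into the (optionally CLAHE-equalized) image: 0 keeps the image as is,
    1 feeds the pure edge map to the network.  CLAHE and adaptive-threshold
    parameters are plain configuration; no canonical values exist for them.
    """

    method: str = "sobel"  # {"sobel", "scharr", "none"}
    blend_weight: float = 0.5
    use_clahe: bool = False
    clahe_clip: float = 2.0
    clahe_tiles: int = 4
    use_adaptive_threshold: bool = False
    at_block: int = 11
    at_offset: float = 0.0
    border: str = "replicate"

    def __post_init__(self) -> None:
        if self.method not in ("sobel", "scharr", "none"):
            raise ValueError(f"unknown edge method {self.method!r}")
        if not 0 <= self.blend_weight <= 1:
            raise ValueError("blend_weight must lie in [0, 1]")
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be positive")
        if self.clahe_tiles < 1:
            raise ValueError("clahe_tiles must be >= 1")
        if self.at_block < 3 or self.at_block % 2 == 0:
            raise ValueError("at_block must be an odd integer >= 3")


def convolve3x3(
    image: np.ndarray, kernel: np.ndarray, border: str = "replicate"
) -> np.ndarray:
    """Correlate an image with a 3x3 kernel.

    Interior pixels are the exact double sum
    ``out(i,j) = sum_uv I(i+u, j+v) * k(u+1, v+1)``; border pixels follow
    the requested extension rule (``replicate``, ``reflect`` or ``zero``).
    """
    image = np.asarray(image, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    if kernel.shape != (3, 3):
        raise ValueError("kernel must be 3x3")
    if not np.isfinite(kernel).all():
        raise ValueError("kernel coefficients must be finite")
    if border not in _BORDER_MODES:
        raise ValueError(f"unknown border mode {border!r}")
    return ndimage.correlate(image, kernel, mode=_BORDER_MODES[border], cval=0.0)


def gradient_magnitude(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm ``sqrt(gx**2 + gy**2)``."""
    gx = np.asarray(gx, dtype=np.float64)
    gy = np.asarray(gy, dtype=np.float64)
    if gx.shape != gy.shape:
        raise ValueError(f"shape mismatch: {gx.shape} vs {gy.shape}")
    return np.hypot(gx, gy)


def edge_map(
    image: np.ndarray, method: str = "sobel", border: str = "replicate"
) -> GradientField:
    """Gradient field of an image under the Sobel or Scharr kernel pair."""
    if method not in _KERNELS:
        raise ValueError(f"unknown edge method {method!r}")
    kx, ky = _KERNELS[method]
    gx = convolve3x3(image, kx, border)
    gy = convolve3x3(image, ky, border)
    return GradientField(gx=gx, gy=gy, magnitude=gradient_magnitude(gx, gy))


def _tile_mapping(tile: np.ndarray, clip: float, nbins: int) -> np.ndarray:
    """Histogram-equalization mapping of one tile with clip/redistribute."""
    hist = np.bincount(tile.ravel(), minlength=nbins).astype(np.float64)
    limit = clip * tile.size / nbins
    excess = np.maximum(hist - limit, 0.0).sum()
    hist = np.minimum(hist, limit) + excess / nbins
    cdf = np.cumsum(hist)
    return cdf / cdf[-1]


def clahe(image: np.ndarray, clip: float = 2.0, tiles: int = 4, nbins: int = 256) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 1] image.

    The image is divided into a ``tiles x tiles`` grid; each tile's
    histogram is clipped at ``clip`` times the uniform bin height, the
    clipped excess is redistributed evenly, and the per-tile equalization
    mappings are blended bilinearly between tile centers.  With a single
    tile and a non-binding clip limit this reduces exactly to global
    histogram equalization.
    """
    image = np.asarray(image, dtype=np.float64)
    if clip <= 0:
        raise ValueError("clip must be positive")
    if tiles < 1:
        raise ValueError("tiles must be >= 1")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("intensities must lie in [0, 1]")
    h, w = image.shape
    bins = np.minimum((image * nbins).astype(np.intp), nbins - 1)

    # Tile edges by even split; mappings computed per tile.
    y_edges = np.linspace(0, h, tiles + 1).astype(int)
    x_edges = np.linspace(0, w, tiles + 1).astype(int)
    mappings = np.empty((tiles, tiles, nbins))
    for ty in range(tiles):
        for tx in range(tiles):
            tile = bins[y_edges[ty] : y_edges[ty + 1], x_edges[tx] : x_edges[tx + 1]]
            mappings[ty, tx] = _tile_mapping(tile, clip, nbins)

    if tiles == 1:
        return mappings[0, 0][bins]

    # Bilinear blend between the mappings of the four surrounding tile
    # centers, clamped at the image border.
    cy = (y_edges[:-1] + y_edges[1:]) / 2.0
    cx = (x_edges[:-1] + x_edges[1:]) / 2.0
    yy = np.arange(h)[:, None] * np.ones((1, w))
    xx = np.ones((h, 1)) * np.arange(w)[None, :]
    ty = np.clip(np.searchsorted(cy, yy.ravel()) - 1, 0, tiles - 2)
    tx = np.clip(np.searchsorted(cx, xx.ravel()) - 1, 0, tiles - 2)
    fy = np.clip((yy.ravel() - cy[ty]) / (cy[ty + 1] - cy[ty]), 0.0, 1.0)
    fx = np.clip((xx.ravel() - cx[tx]) / (cx[tx + 1] - cx[tx]), 0.0, 1.0)
    b = bins.ravel()
    out = (
        (1 - fy) * (1 - fx) * mappings[ty, tx, b]
        + (1 - fy) * fx * mappings[ty, tx + 1, b]
        + fy * (1 - fx) * mappings[ty + 1, tx, b]
        + fy * fx * mappings[ty + 1, tx + 1, b]
    )
    # guard against float accumulation a hair past 1.0 in the blend
    return np.clip(out.reshape(h, w), 0.0, 1.0)


def adaptive_threshold(
    image: np.ndarray, block: int = 11, offset: float = 0.0
) -> np.ndarray:
    """Binarize against the local mean: 1 where ``I > mean_block(I) + offset``.

    The neighborhood is a centered ``block x block`` window with replicated
    borders.  ``block`` must be odd and no larger than either image side.
    """
    image = np.asarray(image, dtype=np.float64)
    if block < 3 or block % 2 == 0:
        raise ValueError("block must be an odd integer >= 3")
    if block > min(image.shape):
        raise ValueError("block exceeds image size")
    local_mean = ndimage.uniform_filter(image, size=block, mode="nearest")
    return (image > local_mean + offset).astype(np.uint8)


def _minmax(arr: np.ndarray) -> np.ndarray:
    lo, hi = arr.min(), arr.max()
    if hi - lo == 0:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def enhance_image(image: np.ndarray, options: EnhanceOptions | None = None) -> np.ndarray:
    """Produce the network input: edge-enhanced version of a [0, 1] image.

    Pipeline: optional CLAHE -> gradient magnitude (Sobel/Scharr) ->
    per-image min-max normalization -> optional adaptive thresholding of
    the magnitude -> convex blend ``(1-w)*image + w*edge``.  With
    ``method="none"`` the (optionally equalized) image passes through.
    """
    if options is None:
        options = EnhanceOptions()
    image = np.asarray(image, dtype=np.float64)
    if image.min() < -1e-12 or image.max() > 1 + 1e-12:
        raise ValueError("intensities must lie in [0, 1]")
    base = clahe(image, options.clahe_clip, options.clahe_tiles) if options.use_clahe else image
    if options.method == "none":
        return base
    field = edge_map(base, options.method, options.border)
    edge = _minmax(field.magnitude)
    if options.use_adaptive_threshold:
        edge = adaptive_threshold(edge, options.at_block, options.at_offset).astype(
            np.float64
        )
    w = options.blend_weight
    return np.clip((1.0 - w) * base + w * edge, 0.0, 1.0)


class EdgeEnhancer(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer applying :func:`enhance_image`.

    Operates on a single 2-D image or a stack of shape ``(n, H, W)``.
    """

    def __init__(
        self,
        method: str = "sobel",
        blend_weight: float = 0.5,
        use_clahe: bool = False,
        clahe_clip: float = 2.0,
        clahe_tiles: int = 4,
        use_adaptive_threshold: bool = False,
        at_block: int = 11,
        at_offset: float = 0.0,
        border: str = "replicate",
    ):
        self.method = method
        self.blend_weight = blend_weight
        self.use_clahe = use_clahe
        self.clahe_clip = clahe_clip
        self.clahe_tiles = clahe_tiles
        self.use_adaptive_threshold = use_adaptive_threshold
        self.at_block = at_block
        self.at_offset = at_offset
        self.border = border

    def _options(self) -> EnhanceOptions:
        return EnhanceOptions(
            method=self.method,
            blend_weight=self.blend_weight,
            use_clahe=self.use_clahe,
            clahe_clip=self.clahe_clip,
            clahe_tiles=self.clahe_tiles,
            use_adaptive_threshold=self.use_adaptive_threshold,
            at_block=self.at_block,
            at_offset=self.at_offset,
            border=self.border,
        )

    def fit(self, X, y=None):
        self._options()  # validates parameters
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        opts = self._options()
        if X.ndim == 2:
            return enhance_image(X, opts)
        return np.stack([enhance_image(x, opts) for x in X])
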