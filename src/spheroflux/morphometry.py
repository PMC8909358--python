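"""Spheroid morphometry from fluorescence z-stacks.

The measurement chain mirrors a high-content imaging workflow: maximum
projection over the stack, a global Otsu threshold (single bright object on
a dark background), hole filling, and extraction of area, circularity-based
roundness and centroid from the largest connected component.

Roundness here is the circularity 4*pi*A/P^2 with the perimeter taken from
the marching-squares contour of the mask; the value is clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import NoSpheroidError, ValidationError

CHANNELS = ("tracker_fluorescence", "nuclei", "brightfield")


@dataclass(frozen=True)
class ImageStack:
    """A z-stack of same-shape 2-D intensity planes with physical pixel size."""

    planes: np.ndarray  # (z, rows, cols)
    pixel_size_um: float
    channel: str = "tracker_fluorescence"

    def __post_init__(self) -> None:
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise ValidationError("stack must hold >= 1 plane of shape (rows, cols)")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.channel!r}")

    @property
    def n_planes(self) -> int:
        return int(self.planes.shape[0])


@dataclass(frozen=True)
class MorphometryResult:
    """Area, roundness and centroid of one segmented spheroid."""

    area_um2: float
    roundness: float
    centroid_um: tuple[float, float]  # (x, y); x rightward, y downward
    mask_pixel_count: int
    pixel_size_um: float
    border_touching: bool = False


def max_projection(stack: ImageStack) -> np.ndarray:
    """Pixelwise maximum over all planes of the stack."""
    return np.max(stack.planes, axis=0)


def circularity(area: float, perimeter: float) -> float:
    """4*pi*A/P^2, the shape factor that is 1 for a perfect circle."""
    if perimeter <= 0:
        raise ValidationError("perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


#: Circular moving-average window (contour points) applied to the
#: marching-squares contour before measuring its length. The raw contour's
#: half-pixel staircase inflates a circle's perimeter by ~6%; smoothing at
#: this scale removes the rasterization bias while leaving true shape
#: features (many pixels long) intact.
CONTOUR_SMOOTHING_WINDOW = 9


def contour_perimeter(mask: np.ndarray, smoothing_window: int = CONTOUR_SMOOTHING_WINDOW) -> float:
    """Perimeter of the longest marching-squares contour of a binary mask.

    The mask is zero-padded so border-touching shapes still yield a closed
    contour, and the contour is smoothed with a circular moving average to
    suppress pixelation jitter.
    """
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValidationError("mask has no contour")
    c = max(contours, key=len)
    if np.allclose(c[0], c[-1]):
        c = c[:-1]
    n = len(c)
    w = smoothing_window
    if w > 1 and n >= w:
        kernel = np.ones(w) / w
        sm = np.empty_like(c)
        for d in range(2):
            ext = np.concatenate([c[-(w // 2):, d], c[:, d], c[: w // 2, d]])
            sm[:, d] = np.convolve(ext, kernel, mode="valid")[:n]
        c = sm
    diffs = np.diff(np.vstack([c, c[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def roundness(mask: np.ndarray) -> float:
    """Circularity of a binary mask, clipped to [0, 1].

    Rasterization can push 4*pi*A/P^2 slightly above 1 for near-circular
    masks; clipping keeps the invariant range.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty mask")
    perim = contour_perimeter(mask)
    value = circularity(float(mask.sum()), perim)
    return float(np.clip(value, 0.0, 1.0))


def segment_spheroid(image: np.ndarray, pixel_size_um: float) -> MorphometryResult:
    """Segment the single largest bright object and measure it.

    Otsu global threshold, keep the largest connected component, fill holes
    (spheroid interiors may be dimmer than rims). A component touching the
    image border is flagged as possibly truncated but still measured.
    """
    image = np.asarray(image, dtype=float)
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be positive")
    if image.size == 0:
        raise ValidationError("empty image")
    if np.ptp(image) == 0:
        raise NoSpheroidError("image is constant; no foreground")
    thresh = threshold_otsu(image)
    fg = image > thresh
    if not fg.any():
        raise NoSpheroidError("no pixels above Otsu threshold")

    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    # A genuine spheroid dominates the above-threshold foreground; pure noise
    # fragments into many small clusters none of which does.
    if sizes[biggest - 1] < 9 or sizes[biggest - 1] < 0.5 * fg.sum():
        raise NoSpheroidError("no dominant foreground object (noise-only image?)")
    mask = ndimage.binary_fill_holes(labels == biggest)

    border = bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    count = int(mask.sum())
    rows, cols = np.nonzero(mask)
    cy = float(rows.mean()) * pixel_size_um
    cx = float(cols.mean()) * pixel_size_um
    return MorphometryResult(
        area_um2=count * pixel_size_um**2,
        roundness=roundness(mask),
        centroid_um=(cx, cy),
        mask_pixel_count=count,
        pixel_size_um=pixel_size_um,
        border_touching=border,
    )


def centroid_displacement(pre: MorphometryResult, post: MorphometryResult) -> float:
    """Euclidean distance in micrometres between two centroids."""
    if not np.isclose(pre.pixel_size_um, post.pixel_size_um):
        raise ValidationError("pre/post results have different pixel sizes")
    dx = post.centroid_um[0] - pre.centroid_um[0]
    dy = post.centroid_um[1] - pre.centroid_um[1]
    return float(np.hypot(dx, dy))
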