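"""Training-set conversion and test-time region preparation.

A K-ary label map is converted into per-instance binary crops: each
instance (a connected component of one class, or an entry of an explicit
instance map) is binarized against its own label, its tight bounding box is
expanded by a random margin of 0-10 pixels per side, and the image and mask
are cropped to that box.  At test time the same cropping is followed by
region-wise intensity standardization and an isotropic resize (2D: minimum
side to a target length; 3D: maximum side), and predictions are mapped back
into source-image coordinates by inverting the resize and pasting at the
box.

Coordinates are 0-based and boxes are half-open ``[lo, hi)`` on every axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import InputError, StateError

DEFAULT_MARGIN_RANGE = (0, 10)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with 0-based half-open per-axis index ranges."""

    lo: tuple[int, ...]
    hi: tuple[int, ...]

    def __post_init__(self):
        if len(self.lo) != len(self.hi):
            raise InputError("box lo/hi dimensionality mismatch")
        if any(a >= b for a, b in zip(self.lo, self.hi)):
            raise InputError("box must satisfy lo < hi on every axis")

    @property
    def ndim(self) -> int:
        return len(self.lo)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(b - a for a, b in zip(self.lo, self.hi))

    def slices(self) -> tuple[slice, ...]:
        return tuple(slice(a, b) for a, b in zip(self.lo, self.hi))

    def contains(self, other: "BoundingBox") -> bool:
        return all(a <= oa and ob <= b
                   for a, oa, ob, b in zip(self.lo, other.lo, other.hi, self.hi))

    @staticmethod
    def of_mask(mask: np.ndarray) -> "BoundingBox":
        """Tight box of the nonzero pixels of ``mask``."""
        if not np.any(mask):
            raise InputError("cannot compute the bounding box of an empty mask")
        coords = np.nonzero(mask)
        return BoundingBox(tuple(int(c.min()) for c in coords),
                           tuple(int(c.max()) + 1 for c in coords))

    def expanded(self, margins_lo, margins_hi, image_shape) -> "BoundingBox":
        """Per-side expansion clipped to the image bounds."""
        lo = tuple(max(0, a - int(m)) for a, m in zip(self.lo, margins_lo))
        hi = tuple(min(s, b + int(m)) for b, m, s in zip(self.hi, margins_hi, image_shape))
        return BoundingBox(lo, hi)


@dataclass
class ImageRegion:
    """A cropped scalar region with its normalization and resize provenance.

    ``intensities`` is the array actually fed to the network (standardized,
    possibly resized).  ``mean``/``std`` record the standardization;
    ``original_box`` locates the crop in the source image and
    ``original_crop_shape`` is the crop shape before any resize.
    """

    intensities: np.ndarray
    mean: float | None = None
    std: float | None = None
    original_box: BoundingBox | None = None
    original_crop_shape: tuple[int, ...] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape


@dataclass
class TrainingInstance:
    """One binary training example cropped from a labeled source image."""

    region: ImageRegion
    mask: np.ndarray
    source_image_id: int | str | None = None
    source_label: int | None = None

    def __post_init__(self):
        if self.region.shape != self.mask.shape:
            raise InputError("instance region and mask shapes differ")
        if not np.any(self.mask):
            raise InputError("instance mask has no foreground")


def extract_instances(
    image: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    margin_range: tuple[int, int] = DEFAULT_MARGIN_RANGE,
    instance_map: np.ndarray | None = None,
    image_id=None,
) -> list[TrainingInstance]:
    """Crop every labeled instance with a randomly expanded bounding box.

    Instances are connected components of each class unless an explicit
    ``instance_map`` (positive integer per instance, 0 background) is given.
    Each per-side margin is drawn independently and uniformly from
    ``margin_range`` (inclusive).  An all-background label map yields an
    empty list.
    """
    image = np.asarray(image)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise InputError("image and label map shapes differ")
    lo, hi = margin_range
    out: list[TrainingInstance] = []
    if instance_map is not None:
        ids = [i for i in np.unique(instance_map) if i != 0]
        comp_iter = [(instance_map == i, int(labels[instance_map == i].flat[0])) for i in ids]
    else:
        comp_iter = []
        for cls in np.unique(labels):
            if cls == 0:
                continue
            comp, n = ndimage.label(labels == cls)
            for i in range(1, n + 1):
                comp_iter.append((comp == i, int(cls)))
    for mask, cls in comp_iter:
        tight = BoundingBox.of_mask(mask)
        m_lo = rng.integers(lo, hi + 1, size=mask.ndim)
        m_hi = rng.integers(lo, hi + 1, size=mask.ndim)
        box = tight.expanded(m_lo, m_hi, image.shape)
        region = ImageRegion(
            intensities=np.ascontiguousarray(image[box.slices()]),
            original_box=box,
            original_crop_shape=box.shape,
        )
        out.append(TrainingInstance(region, np.ascontiguousarray(mask[box.slices()]).astype(np.uint8),
                                    source_image_id=image_id, source_label=cls))
    return out


def crop_region(image: np.ndarray, box: BoundingBox) -> ImageRegion:
    """Extract the raw (unnormalized) sub-image inside a user-provided box."""
    image = np.asarray(image)
    if box.ndim != image.ndim:
        raise InputError("box dimensionality does not match the image")
    full = BoundingBox((0,) * image.ndim, image.shape)
    if not full.contains(box):
        raise InputError("box exceeds image bounds")
    return ImageRegion(np.ascontiguousarray(image[box.slices()]),
                       original_box=box, original_crop_shape=box.shape)


def normalize_region(region: ImageRegion | np.ndarray) -> ImageRegion:
    """Standardize the region by its own mean and standard deviation.

    A constant region maps to all zeros with the recorded std forced to 1,
    so downstream divisions never blow up.
    """
    if not isinstance(region, ImageRegion):
        region = ImageRegion(np.asarray(region))
    x = region.intensities.astype(np.float64)
    if x.size == 0:
        raise InputError("cannot normalize an empty region")
    mean = float(x.mean())
    std = float(x.std())
    if std <= 1e-12 * (1.0 + abs(mean)):  # constant up to float rounding
        out, std = np.zeros_like(x), 1.0
    else:
        out = (x - mean) / std
    return replace(region, intensities=out.astype(np.float32), mean=mean, std=std)


def resize_for_network(region: ImageRegion | np.ndarray, mode: str, target: int) -> ImageRegion:
    """Isotropically rescale so the min (2D) or max (3D) side hits ``target``.

    ``mode`` is ``"2d_min_side"`` or ``"3d_max_side"``.  The pre-resize crop
    shape is recorded so the output can be mapped back exactly.
    """
    if not isinstance(region, ImageRegion):
        region = ImageRegion(np.asarray(region))
    if target <= 0:
        raise InputError("resize target must be positive")
    shape = region.shape
    if mode == "2d_min_side":
        scale = target / min(shape)
    elif mode == "3d_max_side":
        scale = target / max(shape)
    else:
        raise InputError(f"unknown resize mode {mode!r}")
    new_shape = tuple(max(1, int(round(s * scale))) for s in shape)
    out = _resize_array(region.intensities, new_shape, order=1)
    return replace(region, intensities=out,
                   original_crop_shape=region.original_crop_shape or shape)


def _resize_array(arr: np.ndarray, new_shape: tuple[int, ...], order: int) -> np.ndarray:
    if tuple(arr.shape) == tuple(new_shape):
        return arr.copy()
    zoom = [n / s for n, s in zip(new_shape, arr.shape)]
    out = ndimage.zoom(arr.astype(np.float32), zoom, order=order,
                       mode="nearest", grid_mode=True)
    # grid_mode zoom yields exactly round(s * z); enforce the requested shape
    if out.shape != tuple(new_shape):
        out = out[tuple(slice(0, n) for n in new_shape)]
        pads = [(0, n - s) for n, s in zip(new_shape, out.shape)]
        if any(p[1] for p in pads):
            out = np.pad(out, pads, mode="edge")
    return out


def map_indices_to_resized(indices: np.ndarray, old_shape, new_shape) -> np.ndarray:
    """Map integer pixel indices through the crop resize (center convention)."""
    idx = np.asarray(indices, dtype=np.float64)
    scale = np.array([n / s for n, s in zip(new_shape, old_shape)])
    mapped = np.floor((idx + 0.5) * scale).astype(int)
    return np.clip(mapped, 0, np.array(new_shape) - 1)


def restore_to_source(
    array: np.ndarray,
    region: ImageRegion,
    image_shape: tuple[int, ...],
    kind: str = "mask",
) -> np.ndarray:
    """Map a mask or probability map back to full source-image coordinates.

    The array is inverse-resized to the original crop shape (nearest
    neighbor for ``kind="mask"``, linear for ``kind="probability"``) and
    pasted into a zero canvas at the recorded box.
    """
    if region.original_box is None or region.original_crop_shape is None:
        raise StateError("region lacks box/resize records; cannot restore")
    arr = np.asarray(array)
    if arr.shape != region.shape:
        raise InputError("array shape does not match the region")
    order = 0 if kind == "mask" else 1
    back = _resize_array(arr.astype(np.float32), region.original_crop_shape, order=order)
    canvas = np.zeros(image_shape, dtype=back.dtype)
    canvas[region.original_box.slices()] = back
    if kind == "mask":
        return canvas.astype(np.uint8)
    return canvas
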