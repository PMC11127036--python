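"""Channel segmentation and object extraction shared by both assays.

Conventions fixed here and used everywhere downstream:

* 8-connectivity for labeling and adjacency (diagonal touch counts as
  contact, matching the strict-contact apposition rule);
* masks are true where the (optionally smoothed) intensity is **>=** the
  threshold;
* object ids are assigned in raster order of each component's first pixel;
* an object from channel A is called B-positive when at least
  ``min_frac`` (default 0.5) of its pixels fall inside the channel-B mask.
"""

from __future__ import annotations

import numpy as np
from skimage import filters, measure

from .micrograph import BinaryMask, CellObject, Micrograph

DEFAULT_SMOOTH_SIGMA_PX = 1.0
OTSU_NBINS = 256


def segment_mask(
    micrograph: Micrograph,
    channel: str,
    method: str = "otsu",
    threshold: float | None = None,
    smooth_sigma_um: float | None = None,
) -> BinaryMask:
    """Threshold one channel into a binary mask.

    Parameters
    ----------
    method
        ``"otsu"`` (256-bin between-class-variance maximiser) or ``"fixed"``
        (requires ``threshold``).
    smooth_sigma_um
        Gaussian pre-smoothing in micrometres; ``None`` means the default of
        1 pixel.

    Raises
    ------
    ValueError
        For an unknown method, a missing/non-finite fixed threshold, or a
        constant-intensity channel under Otsu (no threshold exists).
    """
    img = micrograph.channel(channel)
    if smooth_sigma_um is None:
        sigma_px = DEFAULT_SMOOTH_SIGMA_PX
    else:
        if smooth_sigma_um < 0:
            raise ValueError("smooth_sigma_um must be >= 0")
        sigma_px = smooth_sigma_um / micrograph.pixel_size_um
    if sigma_px > 0:
        img = filters.gaussian(img, sigma=sigma_px, preserve_range=True)

    if method == "otsu":
        if np.ptp(img) == 0:
            raise ValueError(
                f"channel {channel!r} has constant intensity: Otsu defines no threshold"
            )
        t = filters.threshold_otsu(img, nbins=OTSU_NBINS)
    elif method == "fixed":
        if threshold is None or not np.isfinite(threshold):
            raise ValueError("fixed method requires a finite threshold")
        t = threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    return BinaryMask(mask=img >= t, pixel_size_um=micrograph.pixel_size_um)


def extract_objects(mask: BinaryMask, min_area_um2: float = 0.0) -> list[CellObject]:
    """8-connected components of a mask, small components removed.

    Components with physical area below ``min_area_um2`` are dropped; ids are
    assigned 1..n in raster order of each surviving component's first pixel.
    """
    if min_area_um2 < 0:
        raise ValueError("min_area_um2 must be >= 0")
    labels = measure.label(mask.mask, connectivity=2)
    objects: list[tuple[int, np.ndarray]] = []
    for region in measure.regionprops(labels):
        px = region.coords
        if px.shape[0] * mask.pixel_size_um**2 < min_area_um2:
            continue
        first = px[np.lexsort((px[:, 1], px[:, 0]))[0]]
        raster_key = int(first[0]) * mask.shape[1] + int(first[1])
        objects.append((raster_key, px))
    objects.sort(key=lambda kv: kv[0])
    return [
        CellObject(object_id=i + 1, pixels=px, pixel_size_um=mask.pixel_size_um)
        for i, (_, px) in enumerate(objects)
    ]


def region_mean_intensity(
    micrograph: Micrograph, region: BinaryMask, channel: str
) -> float:
    """Arithmetic mean of a channel over the true pixels of ``region``."""
    if region.shape != micrograph.shape:
        raise ValueError("region geometry does not match micrograph")
    if not region.mask.any():
        raise ValueError("region is empty: mean intensity undefined")
    return float(micrograph.channel(channel)[region.mask].mean())


def positivity_fraction(obj: CellObject, other: BinaryMask) -> float:
    """Fraction of an object's pixels that fall inside another channel's mask."""
    if obj.pixels[:, 0].max() >= other.shape[0] or obj.pixels[:, 1].max() >= other.shape[1]:
        raise ValueError("object pixels outside mask geometry")
    return float(other.mask[obj.pixels[:, 0], obj.pixels[:, 1]].mean())


def is_positive(obj: CellObject, other: BinaryMask, min_frac: float = 0.5) -> bool:
    """Co-positivity call: >= ``min_frac`` of the object's pixels in ``other``."""
    return positivity_fraction(obj, other) >= min_frac


def object_mask(obj: CellObject, shape: tuple[int, int]) -> np.ndarray:
    """Render an object's pixel set as a boolean grid of the given shape."""
    out = np.zeros(shape, dtype=bool)
    out[obj.pixels[:, 0], obj.pixels[:, 1]] = True
    return out
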