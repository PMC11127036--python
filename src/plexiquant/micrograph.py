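"""Core raster containers shared by the adhesion and plexitis assays.

A :class:`Micrograph` is a set of named, same-shaped 2D intensity channels
with a physical pixel size; a :class:`BinaryMask` is a segmentation of one
channel; a :class:`CellObject` is an 8-connected component extracted from a
mask, carrying its pixel set and physical area.  All coordinates are 0-based
``(row, col)``; pixel area is ``pixel_size_um ** 2``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

DEFAULT_PIXEL_SIZE_UM = 0.413
"""Default physical pixel size in micrometres (epifluorescence setup)."""


@dataclass
class Micrograph:
    """Named 2D intensity channels sharing dimensions, with pixel size in um.

    Parameters
    ----------
    channels
        Mapping channel name (e.g. ``"DAPI"``, ``"CFSE"``, ``"S100B"``) to a
        2D array of non-negative intensities.
    pixel_size_um
        Physical edge length of one pixel, micrometres.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("micrograph needs at least one channel")
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        shapes = {name: np.asarray(img).shape for name, img in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel dimensions differ: {shapes}")
        for name, img in self.channels.items():
            arr = np.asarray(img, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            )
        return self.channels[name]


@dataclass
class BinaryMask:
    """Boolean segmentation grid tied to the source micrograph geometry."""

    mask: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.ndim != 2:
            raise ValueError("mask must be 2D")
        self.mask = arr.astype(bool)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2


@dataclass
class CellObject:
    """One 8-connected object: pixel set, centroid and physical area.

    ``positivity`` records per-channel co-staining calls (e.g. a CFSE object
    that is DAPI-positive), filled in by the assay pipelines.
    """

    object_id: int
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    pixel_size_um: float
    positivity: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=int)
        if px.ndim != 2 or px.shape[1] != 2 or px.shape[0] == 0:
            raise ValueError("pixels must be a non-empty (n, 2) array")
        self.pixels = px

    @property
    def area_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2

    @property
    def centroid(self) -> tuple[float, float]:
        r, c = self.pixels.mean(axis=0)
        return float(r), float(c)


def write_micrograph(path: str | Path, micrograph: Micrograph) -> Path:
    """Write a micrograph as a single OME-TIFF with named channels."""
    path = Path(path)
    names = list(micrograph.channels)
    stack = np.stack([micrograph.channels[n] for n in names]).astype(np.float32)
    # deterministic UUID from the pixel content: identical data -> identical file
    import hashlib

    digest = hashlib.sha256(stack.tobytes() + "|".join(names).encode()).hexdigest()
    uuid = f"{digest[:8]}-{digest[8:12]}-{digest[12:16]}-{digest[16:20]}-{digest[20:32]}"
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        photometric="minisblack",
        datetime=False,  # keep identical inputs byte-identical on disk
        metadata={
            "axes": "CYX",
            "UUID": f"urn:uuid:{uuid}",
            "Channel": {"Name": names},
            "PhysicalSizeX": micrograph.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": micrograph.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
        },
    )
    return path


def read_micrograph(path: str | Path) -> Micrograph:
    """Read an OME-TIFF written by :func:`write_micrograph` (or compatible)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        ome = tf.ome_metadata or ""
    if stack.ndim == 2:
        stack = stack[None]
    names = re.findall(r'<Channel[^>]*\bName="([^"]+)"', ome)
    if len(names) != stack.shape[0]:
        names = [f"C{i}" for i in range(stack.shape[0])]
    m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', ome)
    pixel_size = float(m.group(1)) if m else DEFAULT_PIXEL_SIZE_UM
    channels = {name: stack[i].astype(float) for i, name in enumerate(names)}
    return Micrograph(channels=channels, pixel_size_um=pixel_size)
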