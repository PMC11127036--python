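"""Synthetic micrographs, cohorts and count matrices with known ground truth.

Every generator is deterministic given its parameters and seed, and records
a per-object ground truth (adherence / apposition flags, ganglion
membership) in a separate noiseless label image, so detector validation
never depends on renderer internals.

Rendering model
---------------
Objects are hard disks (T cells, nuclei) or ellipses (ganglia) of unit
amplitude on a constant background, convolved with a Gaussian point-spread
function and corrupted by additive Gaussian read noise, clipped at zero.
This is deliberately the simplest model that exercises thresholding-based
segmentation; it makes no attempt at realistic tissue texture (see the
methods note for what this does and does not validate).

Placement margins are renderer internals chosen so that segmentation-mask
growth under the PSF cannot flip a truth label: non-adherent T cells keep a
clearance of at least 3 px from the glial sheet (truth overlap exactly 0),
truth-adherent cells overlap the sheet by at least 20 % of their area
(well above the 5 % adherence rule), and non-apposed cells keep a Chebyshev
gap of at least 4 px from neural labels (the apposition rule needs 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .micrograph import DEFAULT_PIXEL_SIZE_UM, Micrograph
from .sc import SCMatrix

# -- placement margins (renderer internals, see module docstring) ------------
_TCELL_SEPARATION_PX = 4  # min background gap between any two rendered cells
_NONADHERENT_CLEARANCE_PX = 3  # min gap between a non-adherent cell and glia
_NONAPPOSED_GAP_PX = 4  # min Chebyshev gap between a non-apposed cell and neural labels
_NUCLEUS_RADIUS_FRACTION = 0.8  # nucleus radius as a fraction of the cell radius
_MIN_ADHERENT_OVERLAP = 0.2  # rendered overlap for truth-adherent cells
_MAX_PLACEMENT_ATTEMPTS = 2000

RUTGEERTS_LEVELS = ("i0", "i1", "i2", "i3", "i4")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthFieldParams:
    """Parameters of one simulated fluorescence field.

    Defaults reflect the imaging setup the assays assume: 0.413 um pixels,
    lymphocyte-sized T cells (5 um radius, ~79 um^2 area, above the 50 um^2
    detection filter), a mildly blurring PSF and noiseless read-out.
    """

    image_size_px: tuple[int, int] = (384, 384)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_tcells: int = 20
    glia_coverage: float = 0.4
    adhesion_prob: float = 0.5
    tcell_radius_um: float = 5.0
    psf_sigma_um: float = 0.5
    noise_sd: float = 0.0
    background_level: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_size_px
        if rows <= 0 or cols <= 0:
            raise ValueError("image_size_px must be positive")
        for name in (
            "pixel_size_um",
            "glia_coverage",
            "adhesion_prob",
            "tcell_radius_um",
            "psf_sigma_um",
            "noise_sd",
            "background_level",
        ):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.pixel_size_um <= 0 or self.tcell_radius_um <= 0:
            raise ValueError("pixel_size_um and tcell_radius_um must be positive")
        if not 0 <= self.glia_coverage <= 1:
            raise ValueError("glia_coverage must be in [0, 1]")
        if not 0 <= self.adhesion_prob <= 1:
            raise ValueError("adhesion_prob must be in [0, 1]")
        if self.psf_sigma_um < 0 or self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("psf_sigma_um, noise_sd, background_level must be >= 0")
        if self.n_tcells < 0:
            raise ValueError("n_tcells must be >= 0")


@dataclass
class TruthObject:
    """One simulated object with its validated labels."""

    object_id: int
    kind: str  # tcell | glia_region | ganglion | hu_cell
    centroid_px: tuple[float, float]
    area_um2: float
    adherent: bool | None = None
    apposed: bool | None = None
    ganglion_id: int | None = None
    intensity_factor: float | None = None  # ganglion marker amplitude (GFAP)


@dataclass
class GroundTruth:
    """Per-object truth plus noiseless label images keyed by object class."""

    objects: list[TruthObject]
    labels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        ids = [o.object_id for o in self.objects]
        if len(ids) != len(set(ids)):
            raise ValueError("truth object ids must be unique")
        if any(o.area_um2 <= 0 for o in self.objects):
            raise ValueError("truth areas must be positive")

    def of_kind(self, kind: str) -> list[TruthObject]:
        return [o for o in self.objects if o.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "object_id": [o.object_id for o in self.objects],
                "kind": [o.kind for o in self.objects],
                "centroid_row": [o.centroid_px[0] for o in self.objects],
                "centroid_col": [o.centroid_px[1] for o in self.objects],
                "area_um2": [o.area_um2 for o in self.objects],
                "adherent": [o.adherent for o in self.objects],
                "apposed": [o.apposed for o in self.objects],
                "ganglion_id": [o.ganglion_id for o in self.objects],
            }
        )


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: patients, ganglia per patient, count distribution."""

    name: str
    n_patients: int
    ganglia_per_patient: int = 20
    mean_tcells_per_ganglion: float = 0.36
    dispersion: float = 1.0  # NB size parameter; inf -> Poisson
    recurrent: bool | None = None  # None marks control subjects

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.ganglia_per_patient < 1:
            raise ValueError("n_patients and ganglia_per_patient must be >= 1")
        if self.mean_tcells_per_ganglion < 0:
            raise ValueError("mean_tcells_per_ganglion must be >= 0")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")


@dataclass(frozen=True)
class CohortParams:
    groups: tuple[GroupSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")


def default_cohort_params(seed: int = 0) -> CohortParams:
    """Study-sized cohort: 9 controls, 6 non-recurrent and 11 recurrent
    Crohn patients, 20 ganglia each, means 0.36 / 0.36 / 2.42 apposed T
    cells per ganglion."""
    return CohortParams(
        groups=(
            GroupSpec("Ctrl", 9, 20, 0.36, recurrent=None),
            GroupSpec("NonRecurrent", 6, 20, 0.36, recurrent=False),
            GroupSpec("Recurrent", 11, 20, 2.42, recurrent=True),
        ),
        seed=seed,
    )


@dataclass(frozen=True)
class StratumSpec:
    """One (sample, tissue, cell type, status) stratum of a count matrix."""

    sample_id: str
    tissue: str
    cell_type: str
    status: str
    n_cells: int
    expressing_fraction: float

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 <= self.expressing_fraction <= 1:
            raise ValueError("expressing_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SCSynthParams:
    strata: tuple[StratumSpec, ...]
    n_genes: int = 100
    designated_gene: str = "ICAM1"
    mean_library_size: float = 100.0
    seed: int = 0
    exact_fractions: bool = False
    """When true the designated gene expresses in exactly
    ``round(fraction * n_cells)`` cells per stratum instead of Bernoulli
    sampling (useful to pin realized fractions)."""

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("at least one stratum required")
        if self.n_genes < 1 or self.mean_library_size <= 0:
            raise ValueError("n_genes >= 1 and mean_library_size > 0 required")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _disk_offsets(radius_px: int) -> np.ndarray:
    r = radius_px
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return np.argwhere(yy**2 + xx**2 <= r**2) - r


def _chebyshev_dilated_disk_offsets(radius_px: int, gap_px: int) -> np.ndarray:
    """Offsets of a disk dilated by a Chebyshev ball (square) of ``gap_px``."""
    size = radius_px + gap_px
    yy, xx = np.mgrid[-size : size + 1, -size : size + 1]
    disk = yy**2 + xx**2 <= radius_px**2
    dilated = ndimage.binary_dilation(
        disk, structure=np.ones((2 * gap_px + 1,) * 2, dtype=bool)
    )
    return np.argwhere(dilated) - size


def _stamp(grid: np.ndarray, center: tuple[int, int], offsets: np.ndarray, value) -> None:
    coords = offsets + np.asarray(center)
    grid[coords[:, 0], coords[:, 1]] = value


def _hits(grid: np.ndarray, center: tuple[int, int], offsets: np.ndarray) -> bool:
    coords = offsets + np.asarray(center)
    return bool(grid[coords[:, 0], coords[:, 1]].any())


def _overlap_fraction_at(
    glia: np.ndarray, center: tuple[int, int], offsets: np.ndarray
) -> float:
    coords = offsets + np.asarray(center)
    return float(glia[coords[:, 0], coords[:, 1]].mean())


def _render_channel(
    amplitude_image: np.ndarray, params: SynthFieldParams, rng: np.random.Generator
) -> np.ndarray:
    img = params.background_level + amplitude_image
    sigma_px = params.psf_sigma_um / params.pixel_size_um
    if sigma_px > 0:
        img = ndimage.gaussian_filter(img, sigma=sigma_px)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    return np.clip(img, 0.0, None)


def _glial_sheet(
    shape: tuple[int, int], coverage: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random field thresholded at the coverage quantile."""
    if coverage <= 0:
        return np.zeros(shape, dtype=bool)
    if coverage >= 1:
        return np.ones(shape, dtype=bool)
    noise = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(noise, sigma=8.0)
    t = np.quantile(smooth, 1.0 - coverage)
    return smooth >= t


def _negative_binomial(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """NB(mean, size=dispersion); dispersion -> inf recovers Poisson."""
    if mean < 0:
        raise ValueError("mean must be >= 0")
    if mean == 0:
        return np.zeros(size, dtype=int)
    if not np.isfinite(dispersion) or dispersion > 1e8:
        return rng.poisson(mean, size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size)


# ---------------------------------------------------------------------------
# co-culture fields
# ---------------------------------------------------------------------------


def generate_coculture_field(params: SynthFieldParams) -> tuple[Micrograph, GroundTruth]:
    """Simulate one glia/T-cell co-culture field (DAPI, CFSE, S100B).

    Each simulated T cell draws its adherence flag from
    ``Bernoulli(adhesion_prob)``; adherent cells are rendered overlapping
    the glial sheet by >5 % of their area, non-adherent ones with zero
    overlap.  The returned truth stores the flags together with noiseless
    ``tcell`` (integer labels) and ``glia`` (0/1) label images.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.image_size_px)
    radius_px = max(1, round(params.tcell_radius_um / params.pixel_size_um))
    nucleus_px = max(1, round(_NUCLEUS_RADIUS_FRACTION * radius_px))

    glia = _glial_sheet(shape, params.glia_coverage, rng)

    disk = _disk_offsets(radius_px)
    nucleus = _disk_offsets(nucleus_px)
    sep = _chebyshev_dilated_disk_offsets(radius_px, _TCELL_SEPARATION_PX)
    clear = _chebyshev_dilated_disk_offsets(radius_px, _NONADHERENT_CLEARANCE_PX)

    margin = radius_px + _TCELL_SEPARATION_PX + 1
    if params.n_tcells > 0 and (shape[0] <= 2 * margin or shape[1] <= 2 * margin):
        raise ValueError("image too small for the requested T-cell radius")
    interior = np.zeros(shape, dtype=bool)
    interior[margin : shape[0] - margin, margin : shape[1] - margin] = True
    glia_interior_coords = np.argwhere(glia & interior)

    tcell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_mask = np.zeros(shape, dtype=bool)
    forbidden = np.zeros(shape, dtype=bool)

    objects: list[TruthObject] = []
    adherent_flags = rng.random(params.n_tcells) < params.adhesion_prob
    for i in range(params.n_tcells):
        adherent = bool(adherent_flags[i])
        if adherent and glia_interior_coords.size == 0:
            raise ValueError(
                "cannot place an adherent T cell: glial sheet empty "
                "(glia_coverage too low for adhesion_prob > 0)"
            )
        placed = False
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            if adherent:
                center = tuple(
                    glia_interior_coords[rng.integers(len(glia_interior_coords))]
                )
            else:
                center = (
                    int(rng.integers(margin, shape[0] - margin)),
                    int(rng.integers(margin, shape[1] - margin)),
                )
            if _hits(forbidden, center, disk):
                continue
            if adherent:
                if _overlap_fraction_at(glia, center, disk) < _MIN_ADHERENT_OVERLAP:
                    continue
            else:
                if _hits(glia, center, clear):
                    continue
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "could not place T cell after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts; field too crowded"
            )
        object_id = i + 1
        _stamp(tcell_labels, center, disk, object_id)
        _stamp(nucleus_mask, center, nucleus, True)
        _stamp(forbidden, center, sep, True)
        objects.append(
            TruthObject(
                object_id=object_id,
                kind="tcell",
                centroid_px=(float(center[0]), float(center[1])),
                area_um2=disk.shape[0] * params.pixel_size_um**2,
                adherent=adherent,
            )
        )

    # glia nuclei give the DAPI channel non-T-cell content
    n_glia_nuclei = int(glia.sum() // 4000)
    glia_coords = np.argwhere(glia & interior)
    small_nucleus = _disk_offsets(max(1, round(2.5 / params.pixel_size_um)))
    for _ in range(n_glia_nuclei):
        if glia_coords.size == 0:
            break
        center = tuple(glia_coords[rng.integers(len(glia_coords))])
        if _hits(tcell_labels > 0, center, small_nucleus):
            continue
        _stamp(nucleus_mask, center, small_nucleus, True)

    labeled_glia, n_regions = ndimage.label(glia, structure=np.ones((3, 3)))
    next_id = params.n_tcells + 1
    for g in range(1, n_regions + 1):
        region_px = np.argwhere(labeled_glia == g)
        objects.append(
            TruthObject(
                object_id=next_id,
                kind="glia_region",
                centroid_px=tuple(region_px.mean(axis=0)),
                area_um2=region_px.shape[0] * params.pixel_size_um**2,
            )
        )
        next_id += 1

    channels = {
        "DAPI": _render_channel(nucleus_mask.astype(float), params, rng),
        "CFSE": _render_channel((tcell_labels > 0).astype(float), params, rng),
        "S100B": _render_channel(glia.astype(float), params, rng),
    }
    micrograph = Micrograph(channels=channels, pixel_size_um=params.pixel_size_um)
    truth = GroundTruth(
        objects=objects,
        labels={"tcell": tcell_labels, "glia": glia.astype(np.int32)},
        pixel_size_um=params.pixel_size_um,
    )
    return micrograph, truth


# ---------------------------------------------------------------------------
# ganglion sections
# ---------------------------------------------------------------------------


def generate_section_image(
    params: SynthFieldParams,
    n_ganglia: int,
    tcell_rate_per_ganglion: float,
    dispersion: float = 3.0,
    include_gfap: bool = True,
    include_hu: bool = True,
) -> tuple[Micrograph, GroundTruth]:
    """Simulate a transmural section: S100B+ ganglia with apposed T cells.

    Per-ganglion apposed T-cell counts are drawn from a negative binomial
    with mean ``tcell_rate_per_ganglion`` and the given dispersion (size)
    parameter.  Apposed cells are rendered touching or overlapping the
    ganglion; ``params.n_tcells`` additional non-apposed cells are rendered
    with a Chebyshev gap of at least 2 background pixels from all neural
    staining.  Truth records per-ganglion membership and the per-ganglion
    GFAP amplitude factor.
    """
    if n_ganglia < 0:
        raise ValueError("n_ganglia must be >= 0")
    if tcell_rate_per_ganglion < 0:
        raise ValueError("tcell_rate_per_ganglion must be >= 0")
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.image_size_px)
    radius_px = max(1, round(params.tcell_radius_um / params.pixel_size_um))
    nucleus_px = max(1, round(_NUCLEUS_RADIUS_FRACTION * radius_px))

    disk = _disk_offsets(radius_px)
    nucleus = _disk_offsets(nucleus_px)
    sep = _chebyshev_dilated_disk_offsets(radius_px, _TCELL_SEPARATION_PX)
    gap = _chebyshev_dilated_disk_offsets(radius_px, _NONAPPOSED_GAP_PX)

    # --- ganglia: well separated ellipses ---------------------------------
    ganglion_labels = np.zeros(shape, dtype=np.int32)
    semi_axis_range = (40, 56)  # px
    g_margin = semi_axis_range[1] + 4
    min_center_gap = 2 * semi_axis_range[1] + 2 * radius_px + 12
    # jittered grid: adjacent chosen centers keep at least min_center_gap
    jitter = 16
    spacing = min_center_gap + jitter
    grid_rows = range(g_margin, shape[0] - g_margin - jitter + 1, spacing)
    grid_cols = range(g_margin, shape[1] - g_margin - jitter + 1, spacing)
    cells = [(r, c) for r in grid_rows for c in grid_cols]
    if n_ganglia > len(cells):
        raise RuntimeError(
            f"cannot place {n_ganglia} ganglia in a {shape} image "
            f"(capacity {len(cells)}); enlarge the image"
        )
    chosen = rng.choice(len(cells), size=n_ganglia, replace=False) if n_ganglia else []
    centers: list[tuple[int, int]] = []
    for g in range(n_ganglia):
        r0, c0 = cells[int(chosen[g])]
        center = (
            int(r0 + rng.integers(0, jitter + 1)),
            int(c0 + rng.integers(0, jitter + 1)),
        )
        a = rng.uniform(*semi_axis_range)
        b = rng.uniform(*semi_axis_range)
        theta = rng.uniform(0, math.pi)
        ext = semi_axis_range[1] + 1
        r_lo, r_hi = center[0] - ext, center[0] + ext + 1
        c_lo, c_hi = center[1] - ext, center[1] + ext + 1
        yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        dy, dx = yy - center[0], xx - center[1]
        u = dy * math.cos(theta) + dx * math.sin(theta)
        v = -dy * math.sin(theta) + dx * math.cos(theta)
        patch = ganglion_labels[r_lo:r_hi, c_lo:c_hi]
        patch[(u / a) ** 2 + (v / b) ** 2 <= 1] = g + 1
        centers.append(center)

    # relabel ganglia in raster order of their first pixel so that truth ids
    # coincide with the ids the object extractor assigns at analysis time
    if n_ganglia > 0:
        first_px = {}
        flat = ganglion_labels.ravel()
        for pos in np.flatnonzero(flat):
            label = flat[pos]
            if label not in first_px:
                first_px[label] = pos
            if len(first_px) == n_ganglia:
                break
        order = sorted(first_px, key=first_px.get)
        remap = np.zeros(n_ganglia + 1, dtype=np.int32)
        for new_id, old_id in enumerate(order, start=1):
            remap[old_id] = new_id
        ganglion_labels = remap[ganglion_labels]
    else:
        order = []

    ganglion_mask = ganglion_labels > 0
    gfap_factors_raw = rng.uniform(0.5, 1.5, size=n_ganglia)
    gfap_factors = np.array([gfap_factors_raw[old_id - 1] for old_id in order])

    # --- Hu neurons inside ganglia ----------------------------------------
    hu_labels = np.zeros(shape, dtype=np.int32)
    hu_radius = max(1, round(3.0 / params.pixel_size_um))
    hu_disk = _disk_offsets(hu_radius)
    hu_objects: list[tuple[int, tuple[int, int], int]] = []  # (hu_id, center, ganglion)
    hu_id = 0
    hu_occupied = np.zeros(shape, dtype=bool)
    if include_hu:
        eroded = ndimage.binary_erosion(
            ganglion_mask, structure=np.ones((2 * hu_radius + 3,) * 2)
        )
        for g in range(1, n_ganglia + 1):
            coords = np.argwhere(eroded & (ganglion_labels == g))
            n_hu = max(1, int((ganglion_labels == g).sum() // 2500)) if coords.size else 0
            for _ in range(n_hu):
                for _ in range(200):
                    center = tuple(coords[rng.integers(len(coords))])
                    if not _hits(hu_occupied, center, _disk_offsets(2 * hu_radius + 2)):
                        hu_id += 1
                        _stamp(hu_labels, center, hu_disk, hu_id)
                        _stamp(hu_occupied, center, hu_disk, True)
                        hu_objects.append((hu_id, center, g))
                        break

    # --- T cells -----------------------------------------------------------
    neural_mask = ganglion_mask | (hu_labels > 0)
    tcell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_mask = np.zeros(shape, dtype=bool)
    forbidden = np.zeros(shape, dtype=bool)
    margin = radius_px + _NONAPPOSED_GAP_PX + 1
    objects: list[TruthObject] = []
    tcell_id = 0

    counts = _negative_binomial(rng, tcell_rate_per_ganglion, dispersion, n_ganglia)
    for g in range(1, n_ganglia + 1):
        # work inside the ganglion's padded bounding box for speed
        rows = np.flatnonzero((ganglion_labels == g).any(axis=1))
        cols = np.flatnonzero((ganglion_labels == g).any(axis=0))
        pad = radius_px + 2
        r_lo = max(0, rows[0] - pad)
        c_lo = max(0, cols[0] - pad)
        local = ganglion_labels[r_lo : rows[-1] + pad + 1, c_lo : cols[-1] + pad + 1] == g
        offset = np.array([r_lo, c_lo])
        perimeter_coords = np.argwhere(local & ~ndimage.binary_erosion(local)) + offset
        # candidate centers: inside the ganglion or at most 1 px outside, so
        # the rendered cell is both apposed and centroid-wise "inside or at
        # the border" under the analysis rule
        band = ndimage.binary_dilation(local, structure=np.ones((3, 3)))
        band_coords = np.argwhere(band) + offset

        def _valid(center: tuple[int, int]) -> bool:
            if (
                center[0] < margin
                or center[1] < margin
                or center[0] >= shape[0] - margin
                or center[1] >= shape[1] - margin
            ):
                return False
            return not _hits(forbidden, center, disk)

        for _ in range(int(counts[g - 1])):
            placed = False
            for attempt in range(500):
                pool = perimeter_coords if attempt < 250 else band_coords
                center = tuple(pool[rng.integers(len(pool))])
                if _valid(center):
                    placed = True
                    break
            if not placed:  # exhaustive sweep up to the geometric capacity
                for idx in rng.permutation(len(band_coords)):
                    center = tuple(band_coords[idx])
                    if _valid(center):
                        placed = True
                        break
            if not placed:
                raise RuntimeError(
                    f"could not place apposed T cell in ganglion {g}; "
                    "increase image size or lower the rate"
                )
            tcell_id += 1
            _stamp(tcell_labels, center, disk, tcell_id)
            _stamp(nucleus_mask, center, nucleus, True)
            _stamp(forbidden, center, sep, True)
            objects.append(
                TruthObject(
                    object_id=tcell_id,
                    kind="tcell",
                    centroid_px=(float(center[0]), float(center[1])),
                    area_um2=disk.shape[0] * params.pixel_size_um**2,
                    apposed=True,
                    ganglion_id=g,
                )
            )

    for _ in range(params.n_tcells):  # non-apposed background T cells
        placed = False
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            center = (
                int(rng.integers(margin, shape[0] - margin)),
                int(rng.integers(margin, shape[1] - margin)),
            )
            if _hits(forbidden, center, disk):
                continue
            if _hits(neural_mask, center, gap):
                continue
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place non-apposed T cell; field too crowded")
        tcell_id += 1
        _stamp(tcell_labels, center, disk, tcell_id)
        _stamp(nucleus_mask, center, nucleus, True)
        _stamp(forbidden, center, sep, True)
        objects.append(
            TruthObject(
                object_id=tcell_id,
                kind="tcell",
                centroid_px=(float(center[0]), float(center[1])),
                area_um2=disk.shape[0] * params.pixel_size_um**2,
                apposed=False,
                ganglion_id=None,
            )
        )

    next_id = tcell_id
    for g in range(1, n_ganglia + 1):
        next_id += 1
        px = np.argwhere(ganglion_labels == g)
        objects.append(
            TruthObject(
                object_id=next_id,
                kind="ganglion",
                centroid_px=tuple(px.mean(axis=0)),
                area_um2=px.shape[0] * params.pixel_size_um**2,
                ganglion_id=g,
                intensity_factor=float(gfap_factors[g - 1]),
            )
        )
    for hid, center, g in hu_objects:
        next_id += 1
        objects.append(
            TruthObject(
                object_id=next_id,
                kind="hu_cell",
                centroid_px=(float(center[0]), float(center[1])),
                area_um2=hu_disk.shape[0] * params.pixel_size_um**2,
                ganglion_id=g,
            )
        )

    gfap_amplitude = np.zeros(shape, dtype=float)
    for g in range(1, n_ganglia + 1):
        gfap_amplitude[ganglion_labels == g] = gfap_factors[g - 1]

    channels = {
        "DAPI": _render_channel(
            (nucleus_mask | (hu_labels > 0)).astype(float), params, rng
        ),
        "CD3": _render_channel((tcell_labels > 0).astype(float), params, rng),
        "S100B": _render_channel(ganglion_mask.astype(float), params, rng),
    }
    if include_hu:
        channels["Hu"] = _render_channel((hu_labels > 0).astype(float), params, rng)
    if include_gfap:
        channels["GFAP"] = _render_channel(gfap_amplitude, params, rng)

    micrograph = Micrograph(channels=channels, pixel_size_um=params.pixel_size_um)
    truth = GroundTruth(
        objects=objects,
        labels={
            "tcell": tcell_labels,
            "ganglion": ganglion_labels,
            "hu": hu_labels,
        },
        pixel_size_um=params.pixel_size_um,
    )
    return micrograph, truth


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------


def generate_cohort_table(params: CohortParams) -> pd.DataFrame:
    """Simulate a per-ganglion cohort table (one row per patient x ganglion).

    Counts follow a negative binomial per group; GFAP/S100B intensities are
    lognormal around group baselines with a per-patient random effect.
    Rutgeerts scores and 18-month clinical recurrence are attached for
    Crohn subjects (``recurrent`` is True/False in the group spec) and left
    missing for controls.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for group in params.groups:
        # lower GFAP baseline in disease groups mirrors glial activation loss
        gfap_base = 1.0 if group.recurrent is None else 0.7
        for p in range(1, group.n_patients + 1):
            patient_id = f"{group.name}_{p:02d}"
            counts = _negative_binomial(
                rng,
                group.mean_tcells_per_ganglion,
                group.dispersion,
                group.ganglia_per_patient,
            )
            patient_gfap = gfap_base * rng.lognormal(0.0, 0.15)
            patient_s100b = rng.lognormal(0.0, 0.15)
            if group.recurrent is None:
                rutgeerts, clinical = None, None
            elif group.recurrent:
                rutgeerts = RUTGEERTS_LEVELS[rng.integers(1, 5)]
                clinical = bool(rng.random() < 0.3)
            else:
                rutgeerts = "i0"
                clinical = False
            for g in range(1, group.ganglia_per_patient + 1):
                rows.append(
                    {
                        "patient_id": patient_id,
                        "group": group.name,
                        "ganglion_id": g,
                        "n_tcells_apposed": int(counts[g - 1]),
                        "gfap_intensity": patient_gfap * rng.lognormal(0.0, 0.10),
                        "s100b_intensity": patient_s100b * rng.lognormal(0.0, 0.10),
                        "rutgeerts": rutgeerts,
                        "clinical_recurrence_18mo": clinical,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# single-cell matrices
# ---------------------------------------------------------------------------


def generate_sc_matrix(params: SCSynthParams) -> tuple[SCMatrix, pd.DataFrame]:
    """Simulate a sparse gene x cell count matrix with controlled expressing
    fractions for one designated gene.

    Returns the matrix plus a truth table with one row per stratum holding
    the realized expressing fraction (exact nonzero-cell count / cells).
    """
    from scipy import sparse

    rng = np.random.default_rng(params.seed)
    gene_names = [params.designated_gene] + [
        f"GENE{i:04d}" for i in range(1, params.n_genes)
    ]
    # skewed per-gene rates scaled to the requested mean library size
    rates = rng.lognormal(0.0, 1.5, size=params.n_genes)
    rates *= params.mean_library_size / rates.sum()

    blocks = []
    meta_rows = []
    truth_rows = []
    cell_counter = 0
    for stratum in params.strata:
        n = stratum.n_cells
        counts = rng.poisson(rates[:, None], size=(params.n_genes, n))
        counts[0, :] = 0
        if params.exact_fractions:
            n_expr = int(round(stratum.expressing_fraction * n))
            expressing = rng.permutation(n)[:n_expr]
        else:
            expressing = np.flatnonzero(rng.random(n) < stratum.expressing_fraction)
        counts[0, expressing] = 1 + rng.poisson(1.0, size=expressing.size)
        blocks.append(sparse.csr_matrix(counts))
        for _ in range(n):
            cell_counter += 1
            meta_rows.append(
                {
                    "barcode": f"CELL{cell_counter:06d}",
                    "sample_id": stratum.sample_id,
                    "tissue": stratum.tissue,
                    "cell_type": stratum.cell_type,
                    "status": stratum.status,
                }
            )
        truth_rows.append(
            {
                "sample_id": stratum.sample_id,
                "tissue": stratum.tissue,
                "cell_type": stratum.cell_type,
                "status": stratum.status,
                "n_cells": n,
                "n_expressing": int(expressing.size),
                "realized_fraction": expressing.size / n,
            }
        )

    matrix = sparse.hstack(blocks, format="csr")
    metadata = pd.DataFrame(meta_rows).set_index("barcode")
    sc = SCMatrix(matrix=matrix, gene_names=gene_names, cell_metadata=metadata)
    return sc, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# serialisation helpers
# ---------------------------------------------------------------------------


def write_truth_csv(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    truth.to_frame().to_csv(path, index=False)
    return path


def write_params_yaml(params, path: str | Path) -> Path:
    path = Path(path)
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=True)
    return path
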