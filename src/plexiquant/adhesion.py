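"""Quantification of T-cell adhesion to enteric glia in co-culture fields.

The counting rules: a T cell is a DAPI+CFSE+ object with an area of at
least 50 um^2; it is *adherent* when at least 5 % of its area overlaps the
S100B+ (glial) mask — both thresholds inclusive.  Adherent counts are
expressed per mm^2 of S100B surface, summed over all fields of a well; per
condition the median well density is used and reported as a percentage of
the control condition's median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .imageops import extract_objects, is_positive, segment_mask
from .micrograph import BinaryMask, CellObject, Micrograph

MIN_TCELL_AREA_UM2 = 50.0
MIN_ADHESION_OVERLAP = 0.05


@dataclass(frozen=True)
class AdhesionConfig:
    """Channel names and thresholds of the co-culture assay."""

    tcell_channel: str = "CFSE"
    nuclear_channel: str = "DAPI"
    glia_channel: str = "S100B"
    min_area_um2: float = MIN_TCELL_AREA_UM2
    min_overlap: float = MIN_ADHESION_OVERLAP
    copositivity_frac: float = 0.5
    smooth_sigma_um: float | None = None  # None -> 1 px default
    method: str = "otsu"
    threshold: float | None = None  # used by method="fixed"


@dataclass
class WellResult:
    """Adherent T cells per S100B surface, pooled over the fields of one well."""

    well_id: str
    n_fields: int
    n_adherent_tcells: int
    s100b_area_um2: float

    def __post_init__(self) -> None:
        if self.n_adherent_tcells < 0:
            raise ValueError("adherent count must be >= 0")
        if self.s100b_area_um2 <= 0:
            raise ValueError("S100B area must be positive")

    @property
    def density_per_mm2(self) -> float:
        return self.n_adherent_tcells / (self.s100b_area_um2 / 1e6)


@dataclass
class ConditionResult:
    """Median well density of a condition, normalised to the control median."""

    condition: str
    densities: list[float]
    median_density: float
    pct_of_control: float


@dataclass
class SizeHistogram:
    """Relative size-frequency of adherent T-cell areas (um^2)."""

    bin_edges_um2: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        if np.any(freqs < 0) or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("frequencies must be >= 0 and sum to 1")
        self.frequencies = freqs
        self.bin_edges_um2 = np.asarray(self.bin_edges_um2, dtype=float)


def overlap_fraction(tcell: CellObject, glia_mask: BinaryMask) -> float:
    """Fraction of the T-cell object's pixels inside the glial mask."""
    px = tcell.pixels
    if px.shape[0] == 0:
        raise ValueError("empty T-cell object")
    if px[:, 0].max() >= glia_mask.shape[0] or px[:, 1].max() >= glia_mask.shape[1]:
        raise ValueError("T-cell pixels outside glia mask geometry")
    return float(glia_mask.mask[px[:, 0], px[:, 1]].mean())


def classify_adherent(
    tcells: Sequence[CellObject],
    glia_mask: BinaryMask,
    min_area_um2: float = MIN_TCELL_AREA_UM2,
    min_overlap: float = MIN_ADHESION_OVERLAP,
) -> list[tuple[CellObject, bool]]:
    """Adherence calls for the size-passing T cells.

    Objects with ``area_um2 < min_area_um2`` are excluded from the output
    entirely (they do not count as T cells); the remaining objects are
    flagged adherent iff their overlap fraction is at least ``min_overlap``.
    Both thresholds are inclusive.
    """
    calls = []
    for obj in tcells:
        if obj.area_um2 < min_area_um2:
            continue
        calls.append((obj, overlap_fraction(obj, glia_mask) >= min_overlap))
    return calls


def detect_tcells(
    micrograph: Micrograph, config: AdhesionConfig = AdhesionConfig()
) -> tuple[list[CellObject], BinaryMask]:
    """DAPI+CFSE+ object detection in one field.

    Returns the CFSE objects that pass the nuclear co-positivity rule
    (before size filtering) together with the glial mask.  A CFSE or DAPI
    channel with constant intensity (no stained content) yields no objects.
    """

    def _mask_or_empty(channel: str) -> BinaryMask:
        try:
            return segment_mask(
                micrograph,
                channel,
                method=config.method,
                threshold=config.threshold,
                smooth_sigma_um=config.smooth_sigma_um,
            )
        except ValueError:
            if config.method != "otsu":
                raise
            return BinaryMask(
                np.zeros(micrograph.shape, dtype=bool), micrograph.pixel_size_um
            )

    cfse = _mask_or_empty(config.tcell_channel)
    dapi = _mask_or_empty(config.nuclear_channel)
    glia = _mask_or_empty(config.glia_channel)
    objects = [
        obj
        for obj in extract_objects(cfse)
        if is_positive(obj, dapi, config.copositivity_frac)
    ]
    return objects, glia


def quantify_field(
    micrograph: Micrograph, config: AdhesionConfig = AdhesionConfig()
) -> tuple[list[tuple[CellObject, bool]], float]:
    """Adherence calls and S100B mask area (um^2) for one field."""
    objects, glia = detect_tcells(micrograph, config)
    calls = classify_adherent(objects, glia, config.min_area_um2, config.min_overlap)
    return calls, glia.area_um2


def quantify_well(
    fields: Sequence[Micrograph],
    config: AdhesionConfig = AdhesionConfig(),
    well_id: str = "well",
) -> WellResult:
    """Sum adherent counts and S100B area over the fields of one well.

    The acquisition design images 81 fields (36 mm^2) per well; any number
    of fields is accepted and recorded.
    """
    if not fields:
        raise ValueError("at least one field required")
    pixel_sizes = {f.pixel_size_um for f in fields}
    if len(pixel_sizes) != 1:
        raise ValueError(f"inconsistent pixel sizes across fields: {pixel_sizes}")
    n_adherent = 0
    total_area = 0.0
    for field_img in fields:
        calls, area = quantify_field(field_img, config)
        n_adherent += sum(adherent for _, adherent in calls)
        total_area += area
    if total_area == 0:
        raise ValueError("no glial surface detected in any field")
    return WellResult(
        well_id=well_id,
        n_fields=len(fields),
        n_adherent_tcells=n_adherent,
        s100b_area_um2=total_area,
    )


def summarize_condition(
    wells: Sequence[WellResult],
    control_wells: Sequence[WellResult],
    condition: str = "condition",
) -> ConditionResult:
    """Median well density of a condition as a percentage of the control
    median (the comparison unit of the assay: 3 wells, median)."""
    if not wells or not control_wells:
        raise ValueError("need at least one well per condition")
    densities = [w.density_per_mm2 for w in wells]
    control_median = float(np.median([w.density_per_mm2 for w in control_wells]))
    if control_median == 0:
        raise ValueError("control median density is zero: %-of-control undefined")
    median = float(np.median(densities))
    return ConditionResult(
        condition=condition,
        densities=densities,
        median_density=median,
        pct_of_control=100.0 * median / control_median,
    )


def size_frequency(
    tcells: Sequence[CellObject] | np.ndarray, bin_edges_um2: Sequence[float]
) -> SizeHistogram:
    """Normalised histogram of adherent T-cell areas (um^2)."""
    if isinstance(tcells, np.ndarray) or (
        len(tcells) and not isinstance(tcells[0], CellObject)
    ):
        areas = np.asarray(tcells, dtype=float)
    else:
        areas = np.asarray([obj.area_um2 for obj in tcells], dtype=float)
    if areas.size == 0:
        raise ValueError("size_frequency needs at least one object")
    counts, edges = np.histogram(areas, bins=np.asarray(bin_edges_um2, dtype=float))
    total = counts.sum()
    if total == 0:
        raise ValueError("no areas fall inside the requested bins")
    return SizeHistogram(bin_edges_um2=edges, frequencies=counts / total)
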