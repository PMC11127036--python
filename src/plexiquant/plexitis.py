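"""Counting T cells apposed to neural staining in myenteric ganglia.

Apposition is overlap or strict contact between T-cell and neural staining:
no background pixel between the two (8-adjacency, i.e. a Chebyshev pixel
distance of at most 1).  On sections, T cells are counted per ganglion when
their centroid lies inside the ganglion or at its border (1-px dilation)
and they are apposed to that ganglion's mask.  On whole-mounts, 12 randomly
selected ganglia per animal are averaged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imageops import extract_objects, is_positive, object_mask, segment_mask
from .micrograph import BinaryMask, CellObject, Micrograph

logger = logging.getLogger(__name__)

DEFAULT_GANGLION_MIN_AREA_UM2 = 200.0
DEFAULT_WHOLEMOUNT_SAMPLE = 12


@dataclass(frozen=True)
class SectionConfig:
    """Channel names and thresholds of the section/whole-mount assay."""

    tcell_channel: str = "CD3"
    nuclear_channel: str = "DAPI"
    glia_channel: str = "S100B"
    hu_channel: str = "Hu"
    gfap_channel: str = "GFAP"
    ganglion_min_area_um2: float = DEFAULT_GANGLION_MIN_AREA_UM2
    tcell_min_area_um2: float = 10.0  # suppresses sub-cellular speckle
    hu_min_area_um2: float = 10.0
    copositivity_frac: float = 0.5
    smooth_sigma_um: float | None = None


@dataclass
class GanglionRecord:
    """Per-ganglion apposed T-cell count, marker intensities, neuron count."""

    ganglion_id: int
    area_um2: float
    n_tcells_apposed: int
    mean_intensity: dict[str, float]
    n_hu_cells: int | None = None
    n_tcells_apposed_hu: int | None = None

    def __post_init__(self) -> None:
        if self.n_tcells_apposed < 0:
            raise ValueError("counts must be >= 0")
        for marker, value in self.mean_intensity.items():
            if value < 0:
                raise ValueError(f"negative intensity for {marker}")


@dataclass
class PatientSummary:
    patient_id: str
    group: str
    n_ganglia: int
    mean_tcells_per_ganglion: float
    pct_ganglia_positive: float
    tcells_per_hu_cell: float | None = None


@dataclass
class AnimalSummary:
    animal_id: str
    group: str
    n_ganglia_analyzed: int
    mean_tcells_per_ganglion: float


def is_apposed(tcell: CellObject, neural_mask: BinaryMask) -> bool:
    """True iff the T cell overlaps the neural mask or touches it with no
    background pixel in between (8-adjacency, Chebyshev distance <= 1)."""
    px = tcell.pixels
    if px.shape[0] == 0:
        raise ValueError("empty T-cell object")
    dilated = ndimage.binary_dilation(neural_mask.mask, structure=np.ones((3, 3)))
    rows = np.clip(px[:, 0], 0, neural_mask.shape[0] - 1)
    cols = np.clip(px[:, 1], 0, neural_mask.shape[1] - 1)
    return bool(dilated[rows, cols].any())


def _mask_or_empty(
    micrograph: Micrograph, channel: str, smooth_sigma_um: float | None
) -> BinaryMask:
    try:
        return segment_mask(
            micrograph, channel, method="otsu", smooth_sigma_um=smooth_sigma_um
        )
    except ValueError:
        return BinaryMask(np.zeros(micrograph.shape, dtype=bool), micrograph.pixel_size_um)


def quantify_section(
    micrograph: Micrograph, config: SectionConfig = SectionConfig()
) -> list[GanglionRecord]:
    """Quantify one section: ganglia, apposed T cells, marker intensities.

    Ganglia are the S100B+ components above ``ganglion_min_area_um2``; a
    CD3+DAPI+ T cell is assigned to a ganglion iff its centroid lies inside
    the ganglion dilated by 1 px (inside or at the border) and it is
    apposed to that ganglion's mask.  A cell straddling several candidate
    ganglia goes to the one with the larger pixel overlap, ties to the
    lower ganglion id.  Marker intensities are background-subtracted means
    (background = median intensity outside all ganglia).  Returns an empty
    list (logged) when no ganglia are found.
    """
    px_size = micrograph.pixel_size_um
    glia = _mask_or_empty(micrograph, config.glia_channel, config.smooth_sigma_um)
    ganglia = extract_objects(glia, min_area_um2=config.ganglion_min_area_um2)
    if not ganglia:
        logger.info("no ganglia above %.0f um^2 found", config.ganglion_min_area_um2)
        return []

    shape = micrograph.shape
    ganglion_masks = {g.object_id: object_mask(g, shape) for g in ganglia}
    dilated_masks = {
        gid: ndimage.binary_dilation(m, structure=np.ones((3, 3)))
        for gid, m in ganglion_masks.items()
    }
    all_ganglia = np.zeros(shape, dtype=bool)
    for m in ganglion_masks.values():
        all_ganglia |= m

    dapi = _mask_or_empty(micrograph, config.nuclear_channel, config.smooth_sigma_um)
    cd3 = _mask_or_empty(micrograph, config.tcell_channel, config.smooth_sigma_um)
    tcells = [
        obj
        for obj in extract_objects(cd3, min_area_um2=config.tcell_min_area_um2)
        if is_positive(obj, dapi, config.copositivity_frac)
    ]

    counts = {g.object_id: 0 for g in ganglia}
    assigned: dict[int, int] = {}
    for tcell in tcells:
        r, c = tcell.centroid
        ri, ci = int(round(r)), int(round(c))
        candidates = []
        for g in ganglia:
            gid = g.object_id
            if not dilated_masks[gid][ri, ci]:
                continue
            gm = BinaryMask(ganglion_masks[gid], px_size)
            if not is_apposed(tcell, gm):
                continue
            overlap_px = int(
                ganglion_masks[gid][tcell.pixels[:, 0], tcell.pixels[:, 1]].sum()
            )
            candidates.append((gid, overlap_px))
        if not candidates:
            continue
        best = max(candidates, key=lambda kv: (kv[1], -kv[0]))
        counts[best[0]] += 1
        assigned[tcell.object_id] = best[0]

    # Hu neurons and T cells apposed to Hu (when the channel is present)
    hu_objects: list[CellObject] = []
    hu_counts: dict[int, int] = {}
    hu_tcell_counts: dict[int, int] = {}
    has_hu = config.hu_channel in micrograph.channels
    if has_hu:
        hu = _mask_or_empty(micrograph, config.hu_channel, config.smooth_sigma_um)
        hu_objects = extract_objects(hu, min_area_um2=config.hu_min_area_um2)
        hu_counts = {g.object_id: 0 for g in ganglia}
        for obj in hu_objects:
            r, c = obj.centroid
            ri, ci = int(round(r)), int(round(c))
            for g in ganglia:
                if dilated_masks[g.object_id][ri, ci]:
                    hu_counts[g.object_id] += 1
                    break
        hu_tcell_counts = {g.object_id: 0 for g in ganglia}
        hu_full = BinaryMask(hu.mask, px_size)
        for tcell in tcells:
            gid = assigned.get(tcell.object_id)
            if gid is not None and is_apposed(tcell, hu_full):
                hu_tcell_counts[gid] += 1

    # background-subtracted marker intensities
    outside = ~all_ganglia
    records = []
    for g in ganglia:
        gid = g.object_id
        intensities: dict[str, float] = {}
        for channel in (config.glia_channel, config.gfap_channel):
            if channel not in micrograph.channels:
                continue
            img = micrograph.channel(channel)
            background = float(np.median(img[outside])) if outside.any() else 0.0
            mean = float(img[ganglion_masks[gid]].mean())
            intensities[channel] = max(0.0, mean - background)
        records.append(
            GanglionRecord(
                ganglion_id=gid,
                area_um2=g.area_um2,
                n_tcells_apposed=counts[gid],
                mean_intensity=intensities,
                n_hu_cells=hu_counts.get(gid) if has_hu else None,
                n_tcells_apposed_hu=hu_tcell_counts.get(gid) if has_hu else None,
            )
        )
    return records


def patient_summary(
    records: Sequence[GanglionRecord], patient_id: str, group: str = ""
) -> PatientSummary:
    """Per-patient plexitis summary over all analysed ganglia.

    ``tcells_per_hu_cell`` is reported only when Hu data are present and at
    least one Hu+ cell was counted.
    """
    if not records:
        raise ValueError("patient summary needs at least one ganglion")
    counts = np.array([r.n_tcells_apposed for r in records])
    summary = PatientSummary(
        patient_id=patient_id,
        group=group,
        n_ganglia=len(records),
        mean_tcells_per_ganglion=float(counts.mean()),
        pct_ganglia_positive=100.0 * float((counts >= 1).mean()),
    )
    hu_totals = [r.n_hu_cells for r in records if r.n_hu_cells is not None]
    hu_tcells = [r.n_tcells_apposed_hu for r in records if r.n_tcells_apposed_hu is not None]
    if hu_totals and sum(hu_totals) > 0:
        summary.tcells_per_hu_cell = float(sum(hu_tcells)) / float(sum(hu_totals))
    return summary


def wholemount_summary(
    records: Sequence[GanglionRecord],
    animal_id: str,
    group: str = "",
    n_sample: int = DEFAULT_WHOLEMOUNT_SAMPLE,
    seed: int = 0,
) -> AnimalSummary:
    """Average apposed T cells over ``n_sample`` randomly selected ganglia.

    Samples uniformly without replacement (seeded); when fewer ganglia are
    available, all are used and a warning is emitted.
    """
    if not records:
        raise ValueError("whole-mount summary needs at least one ganglion")
    rng = np.random.default_rng(seed)
    if len(records) < n_sample:
        warnings.warn(
            f"only {len(records)} ganglia available for {animal_id} "
            f"(target {n_sample}); using all",
            stacklevel=2,
        )
        chosen = list(records)
    else:
        idx = rng.choice(len(records), size=n_sample, replace=False)
        chosen = [records[i] for i in idx]
    mean = float(np.mean([r.n_tcells_apposed for r in chosen]))
    return AnimalSummary(
        animal_id=animal_id,
        group=group,
        n_ganglia_analyzed=len(chosen),
        mean_tcells_per_ganglion=mean,
    )
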