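"""Cell classification, densities, background-normalized intensities,
Cavalieri volumes and round-to-round antigenicity correlations.

Density follows the stereological convention count / (region area [mm²] ×
section thickness [0.04 mm]).  Fluorescence is measured in the z-position
where the cell is brightest and normalized to the mean of five
signal-free background ROIs *of that same slice*, which cancels the
z-axis antibody-penetrance gradient.  Volumes follow Cavalieri's
principle: positive area per slice summed and multiplied by the z-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from skimage.draw import polygon2mask

from .geometry import Geometry
from .io_alignment import ImageStack
from .segmentation import BinaryMask

__all__ = [
    "CellRecord",
    "NormalizedIntensity",
    "CELL_TYPES",
    "classify_cell",
    "cell_density",
    "background_reference",
    "cell_intensity",
    "cavalieri_volume",
    "vascular_density",
    "antigenicity_correlation",
]

CELL_TYPES = (
    "R-cell",
    "NR-proliferating",
    "immature-neuron",
    "astrocyte",
    "microglia",
    "OPC",
    "unclassified",
)

#: marker flags every classification needs
REQUIRED_FLAGS = (
    "HOPX", "SOX2", "GFAP_process", "S100B", "KI67", "DCX_ring",
    "IBA1", "NG2", "location",
)


@dataclass
class CellRecord:
    """One counted cell: a 2D soma outline applied across its z-extent."""

    id: int
    soma_polygon: np.ndarray  # (n, 2) of (y, x)
    region: str = ""  # GCL blade / ML / hilus / SGZ
    marker_flags: dict = field(default_factory=dict)
    cell_type: str = ""

    def __post_init__(self) -> None:
        self.soma_polygon = np.asarray(self.soma_polygon, dtype=float)
        if self.soma_polygon.ndim != 2 or self.soma_polygon.shape[0] < 3:
            raise ValueError("soma polygon needs >= 3 vertices")


@dataclass(frozen=True)
class NormalizedIntensity:
    """Background-normalized soma intensity at the brightest slice."""

    marker: str
    raw_mean: float
    background_mean: float
    value: float
    z_index: int


def classify_cell(marker_flags: Mapping[str, object]) -> str:
    """Apply the phenotyping rule table in fixed precedence.

    1. R cell: HOPX+ and SOX2+ soma with a GFAP+ radial process, S100β−
       (S100β marks mature astrocytes and excludes R identity).
    2. Proliferating non-radial progenitor: KI67+ in the SGZ without a
       radial process.
    3. Immature neuron: DCX ring.
    4. Astrocyte: S100β+.  5. Microglia: IBA1+.  6. OPC: NG2+.
    Otherwise "unclassified".
    """
    missing = [k for k in REQUIRED_FLAGS if k not in marker_flags]
    if missing:
        raise ValueError(f"missing required marker flags: {missing}")
    f = marker_flags
    if f["HOPX"] and f["SOX2"] and f["GFAP_process"] and not f["S100B"]:
        return "R-cell"
    if f["KI67"] and f["location"] == "SGZ" and not f["GFAP_process"]:
        return "NR-proliferating"
    if f["DCX_ring"]:
        return "immature-neuron"
    if f["S100B"]:
        return "astrocyte"
    if f["IBA1"]:
        return "microglia"
    if f["NG2"]:
        return "OPC"
    return "unclassified"


def cell_density(
    count: int, region_area_mm2: float, thickness_mm: float = 0.04
) -> float:
    """Cells per mm³: count / (area [mm²] × section thickness [mm])."""
    if region_area_mm2 <= 0:
        raise ValueError("region area must be positive")
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / (region_area_mm2 * thickness_mm)


def _roi_footprint(
    shape2d: tuple[int, int], roi: object
) -> np.ndarray:
    """ROI as boolean footprint; accepts (y0, y1, x0, x1) boxes or (n, 2)
    polygons of (y, x) vertices."""
    if isinstance(roi, tuple) and len(roi) == 4:
        y0, y1, x0, x1 = roi
        fp = np.zeros(shape2d, dtype=bool)
        fp[y0:y1, x0:x1] = True
        return fp
    return polygon2mask(shape2d, np.asarray(roi, dtype=float))


def background_reference(
    stack: ImageStack,
    background_rois: Sequence[object],
    expected_rois: int = 5,
) -> np.ndarray:
    """Per-slice background mean, averaged over the per-ROI means.

    ``background_rois`` are signal-free 2D patches (boxes or polygons)
    applied to every slice; the default convention uses five.
    """
    if len(background_rois) == 0:
        raise ValueError("at least one background ROI is required")
    if len(background_rois) != expected_rois:
        import logging

        logging.getLogger(__name__).warning(
            "using %d background ROIs (convention is %d)",
            len(background_rois), expected_rois,
        )
    shape2d = stack.shape[1:]
    fps = [_roi_footprint(shape2d, r) for r in background_rois]
    if any(fp.sum() == 0 for fp in fps):
        raise ValueError("background ROI has no pixels inside the canvas")
    means = np.stack(
        [stack.voxels[:, fp].mean(axis=1) for fp in fps], axis=1
    )  # (z, n_rois)
    return means.mean(axis=1)


def cell_intensity(
    stack: ImageStack,
    cell: CellRecord,
    background: np.ndarray,
    marker: str = "",
    mode: str = "ratio",
) -> NormalizedIntensity:
    """Soma intensity at the brightest slice, normalized to that slice's
    background (ratio by default; ``mode="subtract"`` available)."""
    if mode not in ("ratio", "subtract"):
        raise ValueError("mode must be 'ratio' or 'subtract'")
    fp = polygon2mask(stack.shape[1:], cell.soma_polygon)
    if not fp.any():
        raise ValueError(f"soma polygon of cell {cell.id} lies outside the stack")
    slice_means = stack.voxels[:, fp].mean(axis=1)
    z = int(np.argmax(slice_means))
    bg = float(background[z])
    if bg <= 0:
        raise ValueError("background mean must be positive")
    raw = float(slice_means[z])
    value = raw / bg if mode == "ratio" else raw - bg
    return NormalizedIntensity(
        marker=marker or stack.marker,
        raw_mean=raw,
        background_mean=bg,
        value=value,
        z_index=z,
    )


def cavalieri_volume(mask: BinaryMask) -> tuple[float, int]:
    """Volume by Cavalieri's principle: Σ slices (positive area) × z-step.

    Returns ``(volume_um3, voxel_count)``.
    """
    count = mask.count()
    return count * mask.geometry.voxel_volume_um3, count


def vascular_density(
    vessel_mask: BinaryMask,
    region_polygons: Sequence[np.ndarray],
    geometry: Optional[Geometry] = None,
) -> float:
    """Vessel volume / region tissue volume, in percent."""
    from .segmentation import clip_to_roi

    geometry = geometry or vessel_mask.geometry
    clipped = clip_to_roi(vessel_mask, region_polygons)
    footprint = np.zeros(vessel_mask.shape[1:], dtype=bool)
    for poly in region_polygons:
        footprint |= polygon2mask(vessel_mask.shape[1:], np.asarray(poly, dtype=float))
    region_voxels = int(footprint.sum()) * vessel_mask.shape[0]
    if region_voxels == 0:
        raise ValueError("region polygons cover no pixels")
    vol, _ = cavalieri_volume(clipped)
    region_vol = region_voxels * geometry.voxel_volume_um3
    return 100.0 * vol / region_vol


def antigenicity_correlation(
    values_round_a: Sequence[float], values_round_b: Sequence[float]
) -> tuple[float, float, int]:
    """Pearson correlation of paired normalized intensities across two
    staining rounds: ``(r, p, n)``."""
    a = np.asarray(values_round_a, dtype=float)
    b = np.asarray(values_round_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors of equal length required")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), len(a)
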