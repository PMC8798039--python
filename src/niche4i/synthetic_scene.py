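"""Synthetic dentate-gyrus phantoms with exact ground truth.

The generator builds a 3D scene with the statistical structure the analysis
assumes — a granule-cell-layer (GCL) band flanked by molecular layer above
and hilus below, straight tubular vessels spanning the canvas with partial
pericyte (CD13) and astrocytic (GFAP) surface coverage, and typed cells with
combinatorial marker expression:

* R cells (radial glia-like stem cells): HOPX+/SOX2+ nuclei on the GCL's
  hilar border with a GFAP+/Nestin+ radial process crossing the GCL,
  S100β−.
* proliferating non-radial progenitors: KI67+/SOX2+ in the subgranular
  zone, no radial process.
* immature neurons: DCX as a cytoplasmic ring (shell excluding the
  nucleus).
* astrocytes (S100β+), microglia (IBA1+), OPCs (NG2+/OLIG2+),
  PV interneurons and ARC+ granule neurons.

Channels are rendered per marker per staining round with the acquisition
artifacts the pipeline must undo: a z-axis intensity gradient (antibody
penetrance), integer rigid shifts between rounds, per-round intensity
decay, and Gaussian read noise with optional Poisson shot noise.  Every
stage downstream is validated against the scene's ground truth, so no
external image download is needed.

Voxels are anisotropic (see :mod:`niche4i.geometry`); all object sizes are
specified in µm and rasterized through the shared geometry helper.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .geometry import DEFAULT_LATERAL_SCALE, DEFAULT_Z_STEP, Geometry
from .io_alignment import ImageStack, LandmarkPair

__all__ = [
    "MarkerSpec",
    "SceneConfig",
    "GroundTruthObject",
    "SyntheticScene",
    "CanvasOverflowError",
    "DEFAULT_MARKER_RULES",
    "generate_scene",
    "render_channel",
    "ground_truth_mask",
    "write_ground_truth",
]


class CanvasOverflowError(RuntimeError):
    """Raised when requested objects cannot be placed on the canvas."""


@dataclass(frozen=True)
class MarkerSpec:
    """How one cell type expresses one marker.

    ``pattern`` is one of ``nuclear`` (nucleus sphere), ``soma`` (full
    soma sphere), ``ring`` (cytoplasmic shell excluding the nucleus),
    ``process`` (radial process tube), ``tube`` (full vessel lumen+wall)
    or ``surface_patch`` (contiguous angular patch on the vessel surface).
    ``mean`` is the rendered mean intensity on the 16-bit scale.
    """

    pattern: str
    mean: float

    _PATTERNS = ("nuclear", "soma", "ring", "process", "tube", "surface_patch")

    def __post_init__(self) -> None:
        if self.pattern not in self._PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not 0 < self.mean <= 65535:
            raise ValueError("mean intensity must be in (0, 65535]")


def _default_marker_rules() -> dict[str, dict[str, MarkerSpec]]:
    """Packaged expression table.

    Mean intensities default to twice each marker's packaged binarization
    threshold for volumetric (nuclear / soma / tube) stains and three to
    four times for thin high-contrast structures (filaments, rings,
    vessel-surface patches), whose blurred cross-sections would otherwise
    fall below the detection limit.  They are free parameters of the
    phantom, not claims about any real acquisition.
    """
    n = MarkerSpec  # brevity
    return {
        "R": {
            "DAPI": n("nuclear", 8000),
            "HOPX": n("nuclear", 4400),
            "SOX2": n("nuclear", 3200),
            "GFAP": n("process", 15750),
            "Nestin": n("process", 8000),
        },
        "NR": {
            "DAPI": n("nuclear", 8000),
            "KI67": n("nuclear", 4000),
            "SOX2": n("nuclear", 3200),
        },
        "immature_neuron": {
            "DAPI": n("nuclear", 8000),
            "DCX": n("ring", 10000),
        },
        "astrocyte": {
            "DAPI": n("nuclear", 8000),
            "S100B": n("soma", 3000),
        },
        "microglia": {
            "DAPI": n("nuclear", 8000),
            "IBA1": n("soma", 4000),
        },
        "OPC": {
            "DAPI": n("nuclear", 8000),
            "NG2": n("soma", 11000),
            "OLIG2": n("nuclear", 3000),
        },
        "PV_interneuron": {
            "DAPI": n("nuclear", 8000),
            "PV": n("soma", 8600),
        },
        "arc_neuron": {
            "DAPI": n("nuclear", 8000),
            "ARC": n("soma", 5000),
        },
        "vessel": {
            "CollagenIV": n("tube", 3000),
            "CD13": n("surface_patch", 5400),
            "GFAP": n("surface_patch", 15750),
        },
    }


DEFAULT_MARKER_RULES = _default_marker_rules()

#: Default soma radii per cell type (µm); fallback 4.0.
DEFAULT_SOMA_RADIUS_UM = {
    "R": 4.0,
    "NR": 4.0,
    "immature_neuron": 3.5,
    "astrocyte": 4.0,
    "microglia": 4.0,
    "OPC": 3.5,
    "PV_interneuron": 5.0,
    "arc_neuron": 4.0,
}

_CELL_REGION = {
    # which anatomical compartment each type is seeded in
    "R": "gcl_border",
    "NR": "sgz",
    "immature_neuron": "gcl",
    "arc_neuron": "gcl",
    "astrocyte": "any",
    "microglia": "any",
    "OPC": "any",
    "PV_interneuron": "any",
}


def _default_cell_counts() -> dict[str, int]:
    return {
        "R": 8,
        "NR": 5,
        "immature_neuron": 12,
        "astrocyte": 14,
        "microglia": 10,
        "OPC": 8,
        "PV_interneuron": 3,
        "arc_neuron": 10,
    }


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene (all sizes µm unless noted)."""

    canvas_size: tuple[int, int, int] = (40, 512, 512)  # (z, y, x)
    lateral_scale: float = DEFAULT_LATERAL_SCALE
    z_step: float = DEFAULT_Z_STEP
    cell_counts: dict[str, int] = field(default_factory=_default_cell_counts)
    vessel_count: int = 4
    vessel_radius_um: tuple[float, float] = (2.5, 4.0)
    pericyte_coverage_fraction: float = 0.6
    astro_coverage_fraction: float = 0.25
    marker_rules: dict[str, dict[str, MarkerSpec]] = field(
        default_factory=_default_marker_rules
    )
    soma_radius_um: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SOMA_RADIUS_UM)
    )
    nucleus_fraction: float = 0.7  # nucleus radius / soma radius
    process_length_um: float = 25.0
    process_radius_um: float = 1.0
    vessel_wall_um: float = 1.5  # surface-shell thickness for coverage
    background_level: float = 0.0  # autofluorescence floor (16-bit units)
    z_gradient_slope: float = 0.0  # fractional intensity loss per frame, compounded
    noise_sd: float = 0.0  # Gaussian read noise
    poisson_noise: bool = False
    round_shifts: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(0, 0, 0)]
    )  # (dx, dy, dz) per round
    round_decay: float = 1.0  # intensity factor per round index
    intensity_cv: float = 0.0  # per-cell lognormal brightness variability
    seed: int = 0

    def __post_init__(self) -> None:
        z, h, w = self.canvas_size
        if min(z, h, w) < 1:
            raise ValueError("canvas dimensions must be positive")
        for kind, count in self.cell_counts.items():
            if count < 0:
                raise ValueError(f"negative count for {kind}")
            if count > 0 and kind not in self.marker_rules:
                raise ValueError(f"no marker rules for cell type {kind!r}")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be >= 0")
        for frac in (self.pericyte_coverage_fraction, self.astro_coverage_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("coverage fractions must lie in [0, 1]")
        if not 0.0 <= self.z_gradient_slope < 1.0:
            raise ValueError("z_gradient_slope must lie in [0, 1)")
        if self.round_decay <= 0:
            raise ValueError("round_decay must be positive")
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be >= 0")
        for s in self.round_shifts:
            if len(s) != 3 or any(int(v) != v for v in s):
                raise ValueError("round_shifts entries must be integer (dx, dy, dz)")
        # canvas must be able to host the largest requested object
        max_r = 0.0
        for kind, count in self.cell_counts.items():
            if count > 0:
                max_r = max(max_r, self.soma_radius_um.get(kind, 4.0))
        if self.vessel_count > 0:
            max_r = max(max_r, self.vessel_radius_um[1] + self.vessel_wall_um)
        if max_r > 0:
            if 2 * max_r * self.lateral_scale > min(h, w):
                raise CanvasOverflowError(
                    "canvas too small for the largest requested object"
                )

    @property
    def geometry(self) -> Geometry:
        return Geometry(lateral_scale=self.lateral_scale, z_step=self.z_step)

    @property
    def known_markers(self) -> set[str]:
        out: set[str] = set()
        for rules in self.marker_rules.values():
            out.update(rules)
        return out


@dataclass
class GroundTruthObject:
    """One planted object: a typed cell or a vessel segment."""

    id: int
    kind: str
    centroid: tuple[float, float, float]  # (z, y, x) voxel coordinates
    expressed_markers: frozenset[str]
    true_volume_um3: float
    brightness: float = 1.0  # per-cell expression-level factor
    soma_radius_um: Optional[float] = None
    nucleus_radius_um: Optional[float] = None
    # radial process: (end point in voxel coords, radius µm)
    process_end: Optional[tuple[float, float, float]] = None
    process_radius_um: Optional[float] = None
    # vessel: endpoints in voxel coords, radius µm, and precomputed voxels
    vessel_p0: Optional[tuple[float, float, float]] = None
    vessel_p1: Optional[tuple[float, float, float]] = None
    vessel_radius_um: Optional[float] = None
    _tube_idx: Optional[tuple[np.ndarray, ...]] = None
    _shell_idx: Optional[tuple[np.ndarray, ...]] = None
    _coverage_idx: dict = field(default_factory=dict)  # marker -> index tuple
    coverage_fraction_true: dict = field(default_factory=dict)  # marker -> exact

    def __post_init__(self) -> None:
        if self.true_volume_um3 <= 0:
            raise ValueError("true_volume must be positive")


@dataclass
class SyntheticScene:
    """Ground-truth object list plus region annotations for one section."""

    config: SceneConfig
    objects: list[GroundTruthObject]
    region_polygons: dict[str, np.ndarray]  # name -> (n, 2) array of (y, x)
    background_rois: list[tuple[int, int, int, int]]  # (y0, y1, x0, x1)

    @property
    def geometry(self) -> Geometry:
        return self.config.geometry

    @property
    def canvas_size(self) -> tuple[int, int, int]:
        return self.config.canvas_size

    def objects_of_kind(self, kind: str) -> list[GroundTruthObject]:
        return [o for o in self.objects if o.kind == kind]

    def dapi_landmarks(
        self,
        round_index: int,
        n: int = 5,
        jitter_px: int = 0,
        rng: Optional[np.random.Generator] = None,
    ) -> list[LandmarkPair]:
        """Landmark pairs from nucleus centroids, as a user would click them.

        The reference point is the round-0 (scene-frame) integer centroid;
        the moving point is the same punctum in round ``round_index``,
        displaced by that round's planted shift, optionally with ±jitter
        emulating click imprecision.
        """
        cells = [o for o in self.objects if o.kind != "vessel"]
        if len(cells) < n:
            raise ValueError(f"scene has only {len(cells)} cells, need {n}")
        dx, dy, dz = self.config.round_shifts[round_index]
        rng = rng or np.random.default_rng(self.config.seed + 7)
        pairs = []
        for obj in cells[:n]:
            ref = tuple(int(round(c)) for c in obj.centroid)
            jit = (
                rng.integers(-jitter_px, jitter_px + 1, size=3)
                if jitter_px
                else np.zeros(3, dtype=int)
            )
            mov = (ref[0] + dz + jit[0], ref[1] + dy + jit[1], ref[2] + dx + jit[2])
            pairs.append(LandmarkPair(reference_point=ref, moving_point=tuple(int(v) for v in mov)))
        return pairs


# ---------------------------------------------------------------------------
# rasterization primitives (voxel-space, µm distances)
# ---------------------------------------------------------------------------

def _ball_indices(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radius_um: float,
    geom: Geometry,
    inner_um: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxels whose µm distance to ``center`` lies in (inner, radius]."""
    cz, cy, cx = center
    rz = radius_um / geom.z_step
    rxy = radius_um * geom.lateral_scale
    z0, z1 = max(0, int(np.floor(cz - rz))), min(shape[0] - 1, int(np.ceil(cz + rz)))
    y0, y1 = max(0, int(np.floor(cy - rxy))), min(shape[1] - 1, int(np.ceil(cy + rxy)))
    x0, x1 = max(0, int(np.floor(cx - rxy))), min(shape[2] - 1, int(np.ceil(cx + rxy)))
    if z1 < z0 or y1 < y0 or x1 < x0:
        empty = np.array([], dtype=np.intp)
        return empty, empty, empty
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1 + 1), np.arange(y0, y1 + 1), np.arange(x0, x1 + 1),
        indexing="ij",
    )
    d2 = (
        ((zz - cz) * geom.z_step) ** 2
        + ((yy - cy) / geom.lateral_scale) ** 2
        + ((xx - cx) / geom.lateral_scale) ** 2
    )
    sel = (d2 <= radius_um**2) & (d2 > inner_um**2)
    return zz[sel], yy[sel], xx[sel]


def _segment_distance_um(
    shape: tuple[int, int, int],
    p0: np.ndarray,
    p1: np.ndarray,
    geom: Geometry,
    max_radius_um: float,
) -> tuple[tuple[np.ndarray, ...], np.ndarray, np.ndarray]:
    """Distances (µm) from voxels near a segment to the segment.

    Returns (indices, distance, axial parameter t in [0, 1]) for voxels
    within ``max_radius_um`` of the segment, computed slice-by-slice to
    bound memory.  Endpoints in voxel coordinates.
    """
    # µm coordinates of endpoints
    scale = np.array([geom.z_step, 1.0 / geom.lateral_scale, 1.0 / geom.lateral_scale])
    a = np.asarray(p0, dtype=float) * scale
    b = np.asarray(p1, dtype=float) * scale
    ab = b - a
    ab2 = float(ab @ ab)
    pad_z = int(np.ceil(max_radius_um / geom.z_step)) + 1
    z0 = max(0, int(np.floor(min(p0[0], p1[0]))) - pad_z)
    z1 = min(shape[0] - 1, int(np.ceil(max(p0[0], p1[0]))) + pad_z)
    zs, ys, xs, ds, ts = [], [], [], [], []
    yy, xx = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    for z in range(z0, z1 + 1):
        pts = np.stack(
            [
                np.full(yy.shape, z * geom.z_step),
                yy / geom.lateral_scale,
                xx / geom.lateral_scale,
            ],
            axis=-1,
        )
        rel = pts - a
        t = np.clip((rel @ ab) / ab2, 0.0, 1.0) if ab2 > 0 else np.zeros(yy.shape)
        closest = a + t[..., None] * ab
        d = np.linalg.norm(pts - closest, axis=-1)
        sel = d <= max_radius_um
        if sel.any():
            zs.append(np.full(sel.sum(), z, dtype=np.intp))
            ys.append(yy[sel].astype(np.intp))
            xs.append(xx[sel].astype(np.intp))
            ds.append(d[sel])
            ts.append(t[sel])
    if not zs:
        empty = np.array([], dtype=np.intp)
        return (empty, empty, empty), np.array([]), np.array([])
    return (
        (np.concatenate(zs), np.concatenate(ys), np.concatenate(xs)),
        np.concatenate(ds),
        np.concatenate(ts),
    )


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _region_polygons(config: SceneConfig) -> dict[str, np.ndarray]:
    """Rectangular-band anatomy: ML on top, GCL band, hilus below.

    The subgranular zone (SGZ) is the GCL's hilar border extended 20 µm
    into the hilus.
    """
    _, h, w = config.canvas_size
    top = int(0.35 * h)
    bottom = int(0.55 * h)
    sgz_depth = int(round(config.geometry.um_to_px(20.0)))
    rect = lambda y0, y1: np.array(
        [[y0, 0], [y0, w - 1], [y1, w - 1], [y1, 0]], dtype=float
    )
    return {
        "ML": rect(0, top),
        "GCL": rect(top, bottom),
        "hilus": rect(bottom, h - 1),
        "SGZ": rect(bottom - int(config.geometry.um_to_px(5.0)),
                    min(h - 1, bottom + sgz_depth)),
    }


def _place_cells(
    config: SceneConfig,
    regions: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> list[GroundTruthObject]:
    z_n, h, w = config.canvas_size
    geom = config.geometry
    placed: list[GroundTruthObject] = []
    next_id = 1
    gcl_top = regions["GCL"][0, 0]
    gcl_bottom = regions["GCL"][2, 0]
    sgz_bottom = regions["SGZ"][2, 0]

    def y_range(kind: str, r_px: float) -> tuple[float, float]:
        where = _CELL_REGION.get(kind, "any")
        if where == "gcl":
            return gcl_top + r_px, gcl_bottom - r_px
        if where == "sgz":
            return gcl_bottom - r_px, sgz_bottom - r_px
        if where == "gcl_border":
            return gcl_bottom, gcl_bottom  # exactly on the hilar border
        return r_px, h - 1 - r_px

    # most constrained placements first (border line, then bands)
    order = {"gcl_border": 0, "sgz": 1, "gcl": 2, "any": 3}
    kinds = sorted(
        config.cell_counts,
        key=lambda k: (order[_CELL_REGION.get(k, "any")], k),
    )
    for kind in kinds:
        count = config.cell_counts[kind]
        r_um = config.soma_radius_um.get(kind, 4.0)
        r_px = r_um * geom.lateral_scale
        r_fr = r_um / geom.z_step
        for _ in range(count):
            for attempt in range(500):
                y_lo, y_hi = y_range(kind, r_px)
                y = y_lo if y_lo >= y_hi else rng.uniform(y_lo, y_hi)
                x = rng.uniform(r_px, w - 1 - r_px)
                z_lo, z_hi = r_fr, z_n - 1 - r_fr
                if z_hi <= z_lo:
                    z = (z_n - 1) / 2.0
                else:
                    z = rng.uniform(z_lo, z_hi)
                ok = True
                for other in placed:
                    if other.kind == "vessel":
                        continue
                    dz = (z - other.centroid[0]) * geom.z_step
                    dy = (y - other.centroid[1]) / geom.lateral_scale
                    dx = (x - other.centroid[2]) / geom.lateral_scale
                    min_sep = r_um + (other.soma_radius_um or 4.0)
                    if dz * dz + dy * dy + dx * dx < min_sep**2:
                        ok = False
                        break
                if ok:
                    break
            else:
                raise CanvasOverflowError(
                    f"could not place {kind} cell after 500 attempts"
                )
            markers = frozenset(config.marker_rules[kind])
            has_process = any(
                spec.pattern == "process" for spec in config.marker_rules[kind].values()
            )
            process_end = None
            if has_process:
                # vertical process crossing the GCL (toward the ML), small tilt
                length_px = config.process_length_um * geom.lateral_scale
                tilt = rng.uniform(-0.2, 0.2)
                # guarantee the process crosses the GCL's upper border
                end_y = max(1.0, min(y - length_px, gcl_top - 2))
                end_x = float(np.clip(x + tilt * length_px, 1, w - 2))
                process_end = (z, end_y, end_x)
            if config.intensity_cv > 0:
                sigma = np.sqrt(np.log(1 + config.intensity_cv**2))
                brightness = float(rng.lognormal(-(sigma**2) / 2, sigma))
            else:
                brightness = 1.0
            placed.append(
                GroundTruthObject(
                    id=next_id,
                    kind=kind,
                    centroid=(z, y, x),
                    expressed_markers=markers,
                    brightness=brightness,
                    true_volume_um3=4.0 / 3.0 * np.pi * r_um**3,
                    soma_radius_um=r_um,
                    nucleus_radius_um=config.nucleus_fraction * r_um,
                    process_end=process_end,
                    process_radius_um=(
                        config.process_radius_um if has_process else None
                    ),
                )
            )
            next_id += 1
    return placed


def _contiguous_angular_patch(
    angles: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean selection of a contiguous angular window covering an exact
    count of ``round(fraction * n)`` voxels."""
    n = len(angles)
    k = int(round(fraction * n))
    if k <= 0:
        return np.zeros(n, dtype=bool)
    start = rng.uniform(0, 2 * np.pi)
    order = np.argsort((angles - start) % (2 * np.pi))
    sel = np.zeros(n, dtype=bool)
    sel[order[:k]] = True
    return sel


def _place_vessels(
    config: SceneConfig,
    rng: np.random.Generator,
    start_id: int,
) -> list[GroundTruthObject]:
    z_n, h, w = config.canvas_size
    geom = config.geometry
    vessels = []
    for i in range(config.vessel_count):
        r_um = rng.uniform(*config.vessel_radius_um)
        margin = (r_um + config.vessel_wall_um) * geom.lateral_scale + 2
        z_margin = (r_um + config.vessel_wall_um) / geom.z_step
        # straight tube spanning the canvas in x; mild slope in y and z
        y0 = rng.uniform(margin, h - 1 - margin)
        y1 = float(np.clip(y0 + rng.uniform(-0.15, 0.15) * w, margin, h - 1 - margin))
        if z_n - 1 - 2 * z_margin > 0:
            z0 = rng.uniform(z_margin, z_n - 1 - z_margin)
            z1 = float(
                np.clip(z0 + rng.uniform(-0.2, 0.2) * z_n, z_margin, z_n - 1 - z_margin)
            )
        else:
            z0 = z1 = (z_n - 1) / 2.0
        p0 = np.array([z0, y0, 0.0])
        p1 = np.array([z1, y1, float(w - 1)])
        outer = r_um + config.vessel_wall_um
        idx, dist, _ = _segment_distance_um(config.canvas_size, p0, p1, geom, outer)
        tube_sel = dist <= r_um
        shell_sel = (dist > r_um) & (dist <= outer)
        tube_idx = tuple(a[tube_sel] for a in idx)
        shell_idx = tuple(a[shell_sel] for a in idx)
        # angular position of shell voxels around the centerline (µm space)
        scale = np.array([geom.z_step, 1 / geom.lateral_scale, 1 / geom.lateral_scale])
        a_um, b_um = p0 * scale, p1 * scale
        u = b_um - a_um
        u /= np.linalg.norm(u)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(u @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
        wvec = np.cross(u, v)
        pts = np.stack(
            [shell_idx[0] * scale[0], shell_idx[1] * scale[1], shell_idx[2] * scale[2]],
            axis=-1,
        )
        rel = pts - a_um
        rel -= np.outer(rel @ u, u)
        angles = np.arctan2(rel @ wvec, rel @ v)
        coverage_idx = {}
        coverage_true = {}
        rules = config.marker_rules.get("vessel", {})
        frac_by_marker = {
            "CD13": config.pericyte_coverage_fraction,
            "GFAP": config.astro_coverage_fraction,
        }
        for marker, spec in rules.items():
            if spec.pattern != "surface_patch":
                continue
            frac = frac_by_marker.get(marker, 0.0)
            sel = _contiguous_angular_patch(angles, frac, rng)
            coverage_idx[marker] = tuple(a[sel] for a in shell_idx)
            coverage_true[marker] = (
                float(sel.sum()) / len(sel) if len(sel) else 0.0
            )
        length_um = float(np.linalg.norm(b_um - a_um))
        vessels.append(
            GroundTruthObject(
                id=start_id + i,
                kind="vessel",
                centroid=tuple((p0 + p1) / 2.0),
                expressed_markers=frozenset(rules),
                true_volume_um3=np.pi * r_um**2 * length_um,
                vessel_p0=tuple(p0),
                vessel_p1=tuple(p1),
                vessel_radius_um=r_um,
                _tube_idx=tube_idx,
                _shell_idx=shell_idx,
                _coverage_idx=coverage_idx,
                coverage_fraction_true=coverage_true,
            )
        )
    return vessels


def _background_patches(
    config: SceneConfig,
    objects: list[GroundTruthObject],
    rng: np.random.Generator,
    n_patches: int = 5,
    patch_px: int = 10,
) -> list[tuple[int, int, int, int]]:
    """Five 2D patches guaranteed free of any rendered object footprint."""
    _, h, w = config.canvas_size
    geom = config.geometry
    # conservative 2D keep-out boxes (object footprint + blur spill margin)
    margin = 8
    boxes = []
    for obj in objects:
        if obj.kind == "vessel":
            ys = [obj.vessel_p0[1], obj.vessel_p1[1]]
            r_px = (obj.vessel_radius_um + config.vessel_wall_um) * geom.lateral_scale
            boxes.append((min(ys) - r_px - margin, max(ys) + r_px + margin, -1e9, 1e9))
        else:
            r_px = obj.soma_radius_um * geom.lateral_scale
            y0 = obj.centroid[1] - r_px
            y1 = obj.centroid[1] + r_px
            x0 = obj.centroid[2] - r_px
            x1 = obj.centroid[2] + r_px
            if obj.process_end is not None:
                y0 = min(y0, obj.process_end[1] - margin)
                x0 = min(x0, obj.process_end[2] - margin)
                x1 = max(x1, obj.process_end[2] + margin)
            boxes.append((y0 - margin, y1 + margin, x0 - margin, x1 + margin))
    patches = []
    for _ in range(n_patches):
        for attempt in range(2000):
            y = rng.integers(0, h - patch_px)
            x = rng.integers(0, w - patch_px)
            clear = all(
                not (y < b[1] and y + patch_px > b[0] and x < b[3] and x + patch_px > b[2])
                for b in boxes
            )
            if clear:
                patches.append((int(y), int(y + patch_px), int(x), int(x + patch_px)))
                break
        else:
            raise CanvasOverflowError(
                "could not place marker-free background patches; canvas too crowded"
            )
    return patches


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Build a scene deterministically from ``config`` (fixed seed).

    Raises :class:`CanvasOverflowError` when the requested objects cannot
    be placed after a bounded number of attempts.
    """
    rng = np.random.default_rng(config.seed)
    regions = _region_polygons(config)
    cells = _place_cells(config, regions, rng)
    vessels = _place_vessels(config, rng, start_id=len(cells) + 1)
    objects = cells + vessels
    patches = _background_patches(config, objects, rng)
    return SyntheticScene(
        config=config,
        objects=objects,
        region_polygons=regions,
        background_rois=patches,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _object_marker_indices(
    scene: SyntheticScene, obj: GroundTruthObject, spec: MarkerSpec, marker: str
) -> tuple[np.ndarray, ...]:
    geom = scene.geometry
    shape = scene.canvas_size
    if spec.pattern == "nuclear":
        return _ball_indices(shape, obj.centroid, obj.nucleus_radius_um, geom)
    if spec.pattern == "soma":
        return _ball_indices(shape, obj.centroid, obj.soma_radius_um, geom)
    if spec.pattern == "ring":
        return _ball_indices(
            shape, obj.centroid, obj.soma_radius_um, geom,
            inner_um=obj.nucleus_radius_um,
        )
    if spec.pattern == "process":
        idx, dist, _ = _segment_distance_um(
            shape,
            np.asarray(obj.centroid),
            np.asarray(obj.process_end),
            geom,
            obj.process_radius_um,
        )
        return idx
    if spec.pattern == "tube":
        return obj._tube_idx
    if spec.pattern == "surface_patch":
        return obj._coverage_idx.get(marker, (np.array([], dtype=np.intp),) * 3)
    raise AssertionError(spec.pattern)


def ground_truth_mask(
    scene: SyntheticScene,
    marker: str,
    kinds: Optional[Iterable[str]] = None,
) -> np.ndarray:
    """Exact boolean voxel mask of everything expressing ``marker``
    (scene frame: no shift, gradient or noise).  ``kinds`` restricts the
    contributing object types."""
    config = scene.config
    if marker not in config.known_markers:
        raise KeyError(f"unknown marker {marker!r}")
    mask = np.zeros(scene.canvas_size, dtype=bool)
    kinds = set(kinds) if kinds is not None else None
    for obj in scene.objects:
        if marker not in obj.expressed_markers:
            continue
        if kinds is not None and obj.kind not in kinds:
            continue
        spec = config.marker_rules[obj.kind][marker]
        idx = _object_marker_indices(scene, obj, spec, marker)
        mask[idx] = True
    return mask


def _shift_canvas(arr: np.ndarray, shift_zyx: tuple[int, int, int]) -> np.ndarray:
    """Rigidly translate content within the same canvas, zero-filling."""
    out = np.zeros_like(arr)
    src = []
    dst = []
    for ax, s in enumerate(shift_zyx):
        n = arr.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def render_channel(
    scene: SyntheticScene,
    marker: str,
    round_index: int = 0,
    config: Optional[SceneConfig] = None,
) -> ImageStack:
    """Render one marker channel for one staining round.

    The noiseless signal is ``mean × (1 - z_gradient)^z × decay^round`` on
    object voxels over the (equally attenuated) background floor; the
    whole frame is then rigidly shifted by the round's planted shift and
    noise is added.  Deterministic per (seed, marker, round).
    """
    config = config or scene.config
    if marker not in config.known_markers:
        raise KeyError(
            f"unknown marker {marker!r}; known: {sorted(config.known_markers)}"
        )
    if not 0 <= round_index < len(config.round_shifts):
        raise IndexError(f"round_index {round_index} outside configured rounds")
    canvas = np.full(scene.canvas_size, float(config.background_level))
    for obj in scene.objects:
        if marker not in obj.expressed_markers:
            continue
        spec = config.marker_rules[obj.kind][marker]
        idx = _object_marker_indices(scene, obj, spec, marker)
        if len(idx[0]):
            canvas[idx] = np.maximum(canvas[idx], spec.mean * obj.brightness)
    # antibody-penetrance gradient along tissue depth (scene frame),
    # compounded per frame: frame z keeps (1 - slope)^z of the intensity
    z = np.arange(scene.canvas_size[0], dtype=float)
    atten = (1.0 - config.z_gradient_slope) ** z
    canvas *= atten[:, None, None]
    dx, dy, dz = config.round_shifts[round_index]
    canvas = _shift_canvas(canvas, (int(dz), int(dy), int(dx)))
    canvas *= config.round_decay**round_index
    rng = np.random.default_rng(
        [config.seed, round_index, zlib.crc32(marker.encode())]
    )
    if config.poisson_noise:
        canvas = rng.poisson(np.clip(canvas, 0, None)).astype(float)
    if config.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, config.noise_sd, size=canvas.shape)
    voxels = np.clip(np.rint(canvas), 0, 65535).astype(np.uint16)
    return ImageStack(
        voxels=voxels,
        marker=marker,
        round_index=round_index,
        geometry=config.geometry,
    )


# ---------------------------------------------------------------------------
# ground-truth export
# ---------------------------------------------------------------------------

def write_ground_truth(scene: SyntheticScene, out_dir: str | Path) -> dict[str, Path]:
    """Write the object table (CSV), region polygons (GeoJSON + ImageJ
    XY-coordinate text files) and the config-derived geometry.

    Returns the paths written, keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geom = scene.geometry
    rows = []
    for obj in scene.objects:
        z, y, x = obj.centroid
        rows.append(
            {
                "id": obj.id,
                "kind": obj.kind,
                "centroid_z_um": z * geom.z_step,
                "centroid_y_um": y / geom.lateral_scale,
                "centroid_x_um": x / geom.lateral_scale,
                "true_volume_um3": obj.true_volume_um3,
                "markers": ";".join(sorted(obj.expressed_markers)),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "id", "kind", "centroid_z_um", "centroid_y_um", "centroid_x_um",
            "true_volume_um3", "markers",
        ],
    )
    csv_path = out_dir / "ground_truth_objects.csv"
    table.to_csv(csv_path, index=False)
    paths = {"objects": csv_path}

    features = []
    for name, poly in scene.region_polygons.items():
        # GeoJSON rings are (x, y); polygons are stored (y, x)
        ring = [[float(x), float(y)] for y, x in poly] + [
            [float(poly[0][1]), float(poly[0][0])]
        ]
        features.append(
            {
                "type": "Feature",
                "properties": {"name": name},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
        xy_path = out_dir / f"roi_{name}.txt"
        # ImageJ "XY Coordinates" import format: one "x<TAB>y" pair per line
        with open(xy_path, "w") as fh:
            for y, x in poly:
                fh.write(f"{x:.1f}\t{y:.1f}\n")
        paths[f"roi_{name}"] = xy_path
    geojson_path = out_dir / "regions.geojson"
    with open(geojson_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
    paths["regions"] = geojson_path
    return paths
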