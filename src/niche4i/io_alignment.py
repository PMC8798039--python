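"""Stack I/O and round-to-round registration.

Iterative immunofluorescence acquires one stack per marker per staining
round; rounds drift by a few pixels/frames relative to each other.  The
procedure mirrored here is landmark-based rigid alignment: corresponding
DAPI puncta are identified across rounds, the integer translation is the
component-wise median of the landmark differences, and the moving stack is
placed on an enlarged canvas so no data is cropped (z handled by
prepending/removing blank frames).

Translations are integer-only; deformable registration, rotation and
sub-pixel shifts are out of scope (sections are rigidly mounted).
"""

from __future__ import annotations

import csv
import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile

from .geometry import Geometry

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "LandmarkPair",
    "RegistrationTransform",
    "read_stack",
    "write_stack",
    "read_landmarks",
    "estimate_translation",
    "apply_transform",
    "reference_window",
]


@dataclass
class ImageStack:
    """A single-marker 3D acquisition plus its physical calibration.

    ``voxels`` is a ``(z, y, x)`` uint16 array.  ``origin`` records where
    voxel (0, 0, 0) sits in the reference round's coordinate frame; it is
    (0, 0, 0) for freshly read stacks and becomes nonzero only when
    :func:`apply_transform` has to grow the canvas in the negative
    direction.
    """

    voxels: np.ndarray
    marker: str = ""
    round_index: int = 0
    geometry: Geometry = field(default_factory=Geometry)
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.voxels.ndim}")
        if self.voxels.dtype != np.uint16:
            raise ValueError(
                f"expected 16-bit (uint16) voxels, got {self.voxels.dtype}; "
                "8-bit or float stacks are not supported"
            )

    @property
    def lateral_scale(self) -> float:
        return self.geometry.lateral_scale

    @property
    def z_step(self) -> float:
        return self.geometry.z_step

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class LandmarkPair:
    """One DAPI punctum identified in both the reference and a moving round."""

    reference_point: tuple[int, int, int]  # (z, y, x)
    moving_point: tuple[int, int, int]


@dataclass(frozen=True)
class RegistrationTransform:
    """Integer translation mapping a moving stack onto the reference round.

    ``reference = moving + (dz, dy, dx)`` for corresponding content.
    """

    dx: int
    dy: int
    dz: int

    def __post_init__(self) -> None:
        for v in (self.dx, self.dy, self.dz):
            if int(v) != v:
                raise ValueError("translations must be integral (pixels / frames)")

    @property
    def zyx(self) -> tuple[int, int, int]:
        return (int(self.dz), int(self.dy), int(self.dx))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF, embedding voxel size and channel name."""
    path = Path(path)
    px = stack.geometry.pixel_size_um
    tifffile.imwrite(
        path,
        stack.voxels,
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": px,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": px,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.geometry.z_step,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": [stack.marker or "unknown"]},
        },
    )
    return path


def _geometry_from_ome(xml_text: str) -> tuple[Optional[Geometry], Optional[str]]:
    """Pull (geometry, channel name) out of OME-XML; namespace-agnostic."""
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return None, None
    geometry = None
    channel = None
    for el in root.iter():
        tag = el.tag.rsplit("}", 1)[-1]
        if tag == "Pixels":
            sx = el.get("PhysicalSizeX")
            sz = el.get("PhysicalSizeZ")
            if sx is not None:
                geometry = Geometry(
                    lateral_scale=1.0 / float(sx),
                    z_step=float(sz) if sz is not None else 1.0,
                )
        elif tag == "Channel" and channel is None:
            channel = el.get("Name")
    return geometry, channel


def read_stack(
    path: str | Path,
    marker: str = "",
    round_index: int = 0,
    fallback_geometry: Optional[Geometry] = None,
) -> ImageStack:
    """Read a 3D single-channel TIFF / OME-TIFF.

    Geometry is taken from OME metadata when present; otherwise
    ``fallback_geometry`` is used with a logged warning.  Non-16-bit input
    is rejected.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.series[0].asarray()
        geometry = None
        channel = None
        if tf.ome_metadata:
            geometry, channel = _geometry_from_ome(tf.ome_metadata)
    data = np.atleast_3d(np.asarray(data))
    if data.ndim != 3:
        data = data.reshape(data.shape[-3:])
    if data.dtype != np.uint16:
        raise ValueError(
            f"{path.name}: expected 16-bit (uint16) pixel depth, got {data.dtype}"
        )
    if geometry is None:
        if fallback_geometry is None:
            raise ValueError(
                f"{path.name}: no geometry metadata and no fallback supplied"
            )
        logger.warning(
            "%s: missing physical-size metadata; using supplied geometry %s",
            path.name,
            fallback_geometry,
        )
        geometry = fallback_geometry
    return ImageStack(
        voxels=data,
        marker=marker or (channel or ""),
        round_index=round_index,
        geometry=geometry,
    )


def read_landmarks(path: str | Path) -> list[LandmarkPair]:
    """Read landmark pairs from a CSV with columns
    ``ref_z,ref_y,ref_x,mov_z,mov_y,mov_x``."""
    pairs = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            pairs.append(
                LandmarkPair(
                    reference_point=(int(row["ref_z"]), int(row["ref_y"]), int(row["ref_x"])),
                    moving_point=(int(row["mov_z"]), int(row["mov_y"]), int(row["mov_x"])),
                )
            )
    return pairs


def write_landmarks(pairs: Sequence[LandmarkPair], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ref_z", "ref_y", "ref_x", "mov_z", "mov_y", "mov_x"])
        for p in pairs:
            writer.writerow([*p.reference_point, *p.moving_point])
    return path


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def estimate_translation(
    pairs: Sequence[LandmarkPair],
    residual_tolerance_px: float = 2.0,
) -> RegistrationTransform:
    """Estimate the integer translation from landmark correspondences.

    The translation is the component-wise rounded median of
    ``reference - moving``; the median makes the estimate robust to a
    minority of mis-clicked landmarks.  A warning is raised when any
    per-pair residual after the transform exceeds ``residual_tolerance_px``.
    """
    if len(pairs) == 0:
        raise ValueError("at least one landmark pair is required")
    ref = np.array([p.reference_point for p in pairs], dtype=float)
    mov = np.array([p.moving_point for p in pairs], dtype=float)
    diffs = ref - mov  # (n, 3) in (z, y, x)
    med = np.rint(np.median(diffs, axis=0)).astype(int)
    residuals = np.abs(diffs - med)
    worst = residuals.max() if len(pairs) else 0.0
    if worst > residual_tolerance_px:
        warnings.warn(
            f"inconsistent landmarks: max residual {worst:.1f} px after the "
            f"median translation exceeds {residual_tolerance_px} px",
            UserWarning,
            stacklevel=2,
        )
    return RegistrationTransform(dx=int(med[2]), dy=int(med[1]), dz=int(med[0]))


def apply_transform(
    stack: ImageStack,
    transform: RegistrationTransform,
    reference_shape: Optional[tuple[int, int, int]] = None,
) -> ImageStack:
    """Translate a moving stack into the reference frame without cropping.

    The output canvas is the bounding union of the reference canvas and the
    shifted moving canvas; vacated voxels are zero-filled.  Positive ``dz``
    prepends blank frames (the moving content sits deeper in the reference
    stack); negative ``dz`` drops the leading frames that fall before the
    reference z-range origin while keeping the canvas union, so no signal
    that overlaps the union is lost.

    The returned stack's ``origin`` gives the reference-frame coordinate of
    its voxel (0, 0, 0) (non-positive components; zero unless the union had
    to grow in the negative direction).
    """
    shift = np.array(transform.zyx)  # (dz, dy, dx)
    mshape = np.array(stack.shape)
    if abs(transform.dz) >= stack.shape[0]:
        raise ValueError(
            f"dz={transform.dz} exceeds stack depth {stack.shape[0]}"
        )
    rshape = np.array(reference_shape if reference_shape is not None else stack.shape)
    origin = np.minimum(0, shift)  # reference coordinate of output voxel 0
    extent = np.maximum(rshape, mshape + shift) - origin
    out = np.zeros(tuple(extent), dtype=stack.voxels.dtype)
    offset = shift - origin  # where moving voxel 0 lands in the output
    out[
        offset[0] : offset[0] + mshape[0],
        offset[1] : offset[1] + mshape[1],
        offset[2] : offset[2] + mshape[2],
    ] = stack.voxels
    return ImageStack(
        voxels=out,
        marker=stack.marker,
        round_index=stack.round_index,
        geometry=stack.geometry,
        origin=tuple(int(v) for v in origin),
    )


def reference_window(stack: ImageStack, reference_shape: tuple[int, int, int]) -> np.ndarray:
    """Crop an aligned stack back to the reference round's canvas.

    :func:`apply_transform` grows the canvas so nothing is lost; for
    voxel-wise comparison with the reference round this extracts the
    window of the output that covers exactly the reference canvas (always
    fully contained in the union canvas).
    """
    z0, y0, x0 = (max(0, -o) for o in stack.origin)
    return stack.voxels[
        z0 : z0 + reference_shape[0],
        y0 : y0 + reference_shape[1],
        x0 : x0 + reference_shape[2],
    ]
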