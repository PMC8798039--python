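"""Voxel geometry shared by every stage of the pipeline.

Stacks are indexed ``(z, y, x)``, 0-based, with y increasing downward
(image convention).  Voxels are anisotropic: the confocal acquisitions the
pipeline targets have ~0.312 µm lateral pixels (3.2055 px/µm) and a 1 µm
z-step, so every µm <-> pixel conversion goes through this one helper.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Lateral sampling of the 20x acquisitions (pixels per µm).
DEFAULT_LATERAL_SCALE = 3.2055
#: Axial frame spacing (µm).
DEFAULT_Z_STEP = 1.0


@dataclass(frozen=True)
class Geometry:
    """Physical calibration of a z-stack.

    Parameters
    ----------
    lateral_scale:
        Pixels per µm in x and y (isotropic in-plane).
    z_step:
        µm between consecutive frames.
    """

    lateral_scale: float = DEFAULT_LATERAL_SCALE
    z_step: float = DEFAULT_Z_STEP

    def __post_init__(self) -> None:
        if self.lateral_scale <= 0 or self.z_step <= 0:
            raise ValueError("lateral_scale and z_step must be positive")

    # -- conversions -------------------------------------------------
    def um_to_px(self, um: float) -> float:
        return um * self.lateral_scale

    def px_to_um(self, px: float) -> float:
        return px / self.lateral_scale

    def um_to_frames(self, um: float) -> float:
        return um / self.z_step

    @property
    def pixel_size_um(self) -> float:
        return 1.0 / self.lateral_scale

    @property
    def pixel_area_um2(self) -> float:
        """In-plane area of one pixel (µm²)."""
        return self.pixel_size_um ** 2

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel (µm³)."""
        return self.pixel_area_um2 * self.z_step
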