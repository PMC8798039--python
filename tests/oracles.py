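"""Independent brute-force oracles for distance-map sampling.

These deliberately avoid the production code path: distances are computed
per pixel as the exact Euclidean distance to the nearest origin pixel
(pairwise, via ``scipy.spatial.distance.cdist``), then quantized with the
same declared rule (round, cap) before counting.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def brute_force_quantized_distance(origin2d: np.ndarray, cap: int = 255) -> np.ndarray:
    """Exact per-pixel distance to the nearest origin pixel, rounded and
    capped — computed by exhaustive pairwise distances."""
    origin2d = np.asarray(origin2d, dtype=bool)
    h, w = origin2d.shape
    pts = np.argwhere(~np.zeros_like(origin2d))  # all pixels
    src = np.argwhere(origin2d)
    d = cdist(pts, src).min(axis=1)
    grid = d.reshape(h, w)
    return np.minimum(np.rint(grid), cap).astype(np.uint16)


def brute_force_microniche_count(
    origin2d: np.ndarray, mask3d: np.ndarray, radius_px: int, cap: int = 255
) -> tuple[int, int]:
    """(marker voxels, total voxels) within ``radius_px`` of the origin."""
    d = brute_force_quantized_distance(origin2d, cap)
    region = d <= radius_px
    total = int(region.sum()) * mask3d.shape[0]
    count = int(np.asarray(mask3d, dtype=bool)[:, region].sum())
    return count, total


def brute_force_radial_bins(
    origin2d: np.ndarray,
    mask3d: np.ndarray,
    edges_px: np.ndarray,
    cap: int = 255,
) -> list[tuple[int, int]]:
    """Per-annulus (marker voxels, shell voxels); first bin [0, e1],
    others (e_k, e_{k+1}]."""
    d = brute_force_quantized_distance(origin2d, cap)
    mask3d = np.asarray(mask3d, dtype=bool)
    out = []
    for b in range(len(edges_px) - 1):
        if b == 0:
            shell = d <= edges_px[1]
        else:
            shell = (d > edges_px[b]) & (d <= edges_px[b + 1])
        shell_vox = int(shell.sum()) * mask3d.shape[0]
        count = int(mask3d[:, shell].sum())
        out.append((count, shell_vox))
    return out
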