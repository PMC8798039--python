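"""Phantom generator: determinism, ground-truth consistency, rendering
artifacts (gradient, decay, shifts, noise) and exports."""

import numpy as np
import pandas as pd
import pytest
from skimage.registration import phase_cross_correlation

from niche4i.synthetic_scene import (
    CanvasOverflowError,
    MarkerSpec,
    SceneConfig,
    generate_scene,
    ground_truth_mask,
    render_channel,
    write_ground_truth,
)


def single_object_config(pattern="soma", mean=5000.0, radius=3.0, **kwargs):
    rules = {"cell": {"X": MarkerSpec(pattern, mean)}}
    defaults = dict(
        canvas_size=(20, 128, 128),
        cell_counts={"cell": 1},
        vessel_count=0,
        marker_rules=rules,
        soma_radius_um={"cell": radius},
        seed=0,
    )
    defaults.update(kwargs)
    return SceneConfig(**defaults)


def test_empty_config_yields_empty_scene():
    cfg = SceneConfig(
        canvas_size=(8, 64, 64), cell_counts={}, vessel_count=0, seed=0
    )
    scene = generate_scene(cfg)
    assert scene.objects == []
    assert set(scene.region_polygons) >= {"GCL", "ML", "hilus"}
    assert len(scene.background_rois) == 5


def test_same_seed_reproduces_scene_and_render_bit_identically():
    cfg = SceneConfig(canvas_size=(10, 256, 256), seed=11,
                      cell_counts={"R": 3, "microglia": 4}, vessel_count=2,
                      noise_sd=50.0)
    a, b = generate_scene(cfg), generate_scene(cfg)
    assert [o.centroid for o in a.objects] == [o.centroid for o in b.objects]
    ra = render_channel(a, "IBA1")
    rb = render_channel(b, "IBA1")
    assert np.array_equal(ra.voxels, rb.voxels)


def test_requested_counts_and_combinatorial_marker_rules():
    cfg = SceneConfig(
        canvas_size=(20, 448, 448),
        cell_counts={"R": 10},
        vessel_count=5,
        seed=1,
    )
    scene = generate_scene(cfg)
    r_cells = scene.objects_of_kind("R")
    vessels = scene.objects_of_kind("vessel")
    assert len(r_cells) == 10 and len(vessels) == 5
    for cell in r_cells:
        assert {"HOPX", "SOX2", "GFAP", "Nestin"} <= cell.expressed_markers
        assert "S100B" not in cell.expressed_markers
    # R somas sit on the GCL's hilar (lower) border
    gcl_bottom = scene.region_polygons["GCL"][2, 0]
    for cell in r_cells:
        assert cell.centroid[1] == pytest.approx(gcl_bottom)


def test_r_cell_processes_cross_the_gcl():
    cfg = SceneConfig(canvas_size=(16, 320, 320), cell_counts={"R": 4},
                      vessel_count=0, seed=3)
    scene = generate_scene(cfg)
    gcl_top = scene.region_polygons["GCL"][0, 0]
    for cell in scene.objects_of_kind("R"):
        assert cell.process_end is not None
        assert cell.process_end[1] < gcl_top  # reaches past the upper border


def test_noiseless_render_values_and_background():
    cfg = single_object_config()
    scene = generate_scene(cfg)
    stack = render_channel(scene, "X")
    truth = ground_truth_mask(scene, "X")
    assert stack.voxels.dtype == np.uint16
    assert np.all(stack.voxels[truth] == 5000)
    assert np.all(stack.voxels[~truth] == 0)


def test_unknown_marker_is_rejected():
    scene = generate_scene(single_object_config())
    with pytest.raises(KeyError, match="unknown marker"):
        render_channel(scene, "NOPE")


def test_round_decay_scales_in_object_mean():
    cfg = single_object_config(
        round_shifts=[(0, 0, 0), (0, 0, 0), (0, 0, 0)], round_decay=0.9,
        poisson_noise=True,
    )
    scene = generate_scene(cfg)
    truth = ground_truth_mask(scene, "X")
    stack = render_channel(scene, "X", round_index=2)
    mean = stack.voxels[truth].mean()
    assert mean == pytest.approx(5000 * 0.81, rel=0.05)


def test_rendered_voxel_count_matches_analytic_volume(geom):
    radius = 4.0
    cfg = single_object_config(radius=radius)
    scene = generate_scene(cfg)
    truth = ground_truth_mask(scene, "X")
    volume = truth.sum() * geom.voxel_volume_um3
    analytic = 4.0 / 3.0 * np.pi * radius**3
    shell_bound = 4.0 * np.pi * radius**2 * geom.z_step  # ±1 voxel shell
    assert abs(volume - analytic) <= shell_bound
    assert scene.objects[0].true_volume_um3 == pytest.approx(analytic)


def test_background_patches_are_signal_free_at_zero_noise():
    cfg = SceneConfig(canvas_size=(10, 320, 320), seed=4,
                      cell_counts={"R": 3, "astrocyte": 4}, vessel_count=2)
    scene = generate_scene(cfg)
    for marker in ("GFAP", "S100B", "CollagenIV", "DAPI"):
        stack = render_channel(scene, marker)
        for (y0, y1, x0, x1) in scene.background_rois:
            assert stack.voxels[:, y0:y1, x0:x1].sum() == 0


def test_round_shift_recoverable_by_cross_correlation():
    shift = (6, -4, 1)  # (dx, dy, dz)
    cfg = single_object_config(round_shifts=[(0, 0, 0), shift])
    scene = generate_scene(cfg)
    r0 = render_channel(scene, "X", 0)
    r1 = render_channel(scene, "X", 1)
    est, _, _ = phase_cross_correlation(
        r1.voxels.astype(float), r0.voxels.astype(float)
    )
    assert tuple(int(v) for v in est) == (shift[2], shift[1], shift[0])


def test_z_gradient_attenuates_per_frame_compounded():
    cfg = single_object_config(z_gradient_slope=0.02, background_level=1000.0)
    scene = generate_scene(cfg)
    stack = render_channel(scene, "X")
    truth = ground_truth_mask(scene, "X")
    bg = np.where(~truth.any(axis=0))
    for z in (0, 5, 15):
        expected = 1000.0 * 0.98**z
        assert stack.voxels[z][bg].mean() == pytest.approx(expected, abs=1.0)


def test_canvas_overflow_raises():
    with pytest.raises(CanvasOverflowError):
        SceneConfig(canvas_size=(4, 16, 16), cell_counts={"R": 5}, seed=0)


@pytest.mark.parametrize(
    "bad",
    [
        dict(cell_counts={"R": -1}),
        dict(pericyte_coverage_fraction=1.5),
        dict(z_gradient_slope=1.0),
        dict(round_shifts=[(0.5, 0, 0)]),
        dict(cell_counts={"unknown_kind": 2}),
    ],
)
def test_invalid_configs_rejected(bad):
    with pytest.raises((ValueError, CanvasOverflowError)):
        SceneConfig(canvas_size=(8, 128, 128), vessel_count=0, seed=0, **bad)


def test_vessel_coverage_fraction_exact_by_construction():
    cfg = SceneConfig(
        canvas_size=(24, 256, 256), cell_counts={}, vessel_count=2,
        pericyte_coverage_fraction=0.5, astro_coverage_fraction=0.2, seed=9,
    )
    scene = generate_scene(cfg)
    for vessel in scene.objects_of_kind("vessel"):
        shell = len(vessel._shell_idx[0])
        covered = len(vessel._coverage_idx["CD13"][0])
        assert covered == round(0.5 * shell)
        assert vessel.coverage_fraction_true["CD13"] == pytest.approx(
            covered / shell
        )


def test_ground_truth_export(tmp_path):
    empty = generate_scene(
        SceneConfig(canvas_size=(8, 64, 64), cell_counts={}, vessel_count=0, seed=0)
    )
    paths = write_ground_truth(empty, tmp_path / "empty")
    table = pd.read_csv(paths["objects"])
    assert len(table) == 0 and "true_volume_um3" in table.columns

    cfg = single_object_config(radius=3.0)
    scene = generate_scene(cfg)
    paths = write_ground_truth(scene, tmp_path / "one")
    table = pd.read_csv(paths["objects"])
    assert table["id"].is_unique
    assert table["true_volume_um3"].iloc[0] == pytest.approx(
        4.0 / 3.0 * np.pi * 27.0, rel=1e-6
    )
    assert paths["regions"].exists() and paths["roi_GCL"].exists()
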