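"""Cell phenotyping rules, stereological density, background-normalized
intensity, Cavalieri volumes and antigenicity correlation."""

import numpy as np
import pytest

from conftest import make_mask
from niche4i.geometry import Geometry
from niche4i.io_alignment import ImageStack
from niche4i.quantification import (
    CellRecord,
    antigenicity_correlation,
    background_reference,
    cavalieri_volume,
    cell_density,
    cell_intensity,
    classify_cell,
    vascular_density,
)
from niche4i.synthetic_scene import MarkerSpec, SceneConfig, generate_scene, render_channel


def flags(**overrides):
    base = dict(
        HOPX=False, SOX2=False, GFAP_process=False, S100B=False, KI67=False,
        DCX_ring=False, IBA1=False, NG2=False, location="GCL",
    )
    base.update(overrides)
    return base


@pytest.mark.parametrize(
    "marker_flags, expected",
    [
        (flags(HOPX=True, SOX2=True, GFAP_process=True), "R-cell"),
        (flags(HOPX=True, SOX2=True, GFAP_process=True, S100B=True), "astrocyte"),
        (flags(S100B=True, HOPX=True), "astrocyte"),
        (flags(KI67=True, location="SGZ"), "NR-proliferating"),
        (flags(KI67=True, location="SGZ", GFAP_process=True), "unclassified"),
        (flags(KI67=True, location="ML"), "unclassified"),
        (flags(DCX_ring=True), "immature-neuron"),
        (flags(IBA1=True), "microglia"),
        (flags(NG2=True), "OPC"),
        (flags(IBA1=True, NG2=True), "microglia"),
        (flags(), "unclassified"),
    ],
)
def test_phenotyping_rule_table(marker_flags, expected):
    assert classify_cell(marker_flags) == expected


def test_missing_flag_is_an_error():
    with pytest.raises(ValueError, match="missing"):
        classify_cell({"HOPX": True})


@pytest.mark.parametrize(
    "count, area, expected",
    [(0, 0.5, 0.0), (30, 0.5, 1500.0), (1, 1.0, 25.0)],
)
def test_density_formula(count, area, expected):
    assert cell_density(count, area) == pytest.approx(expected)


def test_density_is_linear_in_count_and_inverse_in_area():
    assert cell_density(60, 0.5) == 2 * cell_density(30, 0.5)
    assert cell_density(30, 1.0) == cell_density(30, 0.5) / 2


def test_density_rejects_bad_area():
    with pytest.raises(ValueError):
        cell_density(10, 0.0)


# ---------------------------------------------------------------------------
# background & intensity
# ---------------------------------------------------------------------------

BG_ROIS = [(0, 4, 0, 4), (0, 4, 8, 12), (8, 12, 0, 4), (8, 12, 8, 12), (4, 8, 4, 8)]


def test_background_reference_uniform_and_errors():
    stack = ImageStack(voxels=np.full((6, 16, 16), 1000, dtype=np.uint16))
    bg = background_reference(stack, BG_ROIS)
    assert np.allclose(bg, 1000.0)
    with pytest.raises(ValueError):
        background_reference(stack, [])


def test_background_reference_tracks_z_gradient():
    g = 0.02
    z = np.arange(8)
    vals = np.rint(1000.0 * (1 - g) ** z).astype(np.uint16)
    stack = ImageStack(voxels=np.broadcast_to(vals[:, None, None], (8, 16, 16)).copy())
    bg = background_reference(stack, BG_ROIS)
    assert np.allclose(bg, 1000.0 * (1 - g) ** z, atol=0.5)


def square_polygon(cy, cx, half):
    return np.array(
        [[cy - half, cx - half], [cy - half, cx + half],
         [cy + half, cx + half], [cy + half, cx - half]], float
    )


def test_cell_intensity_is_ratio_at_brightest_slice():
    voxels = np.full((5, 32, 32), 1000, dtype=np.uint16)
    voxels[2, 18:28, 18:28] = 3000  # brightest slice
    voxels[3, 18:28, 18:28] = 2000
    stack = ImageStack(voxels=voxels)
    cell = CellRecord(id=1, soma_polygon=square_polygon(22.5, 22.5, 3))
    bg = background_reference(stack, BG_ROIS)
    res = cell_intensity(stack, cell, bg)
    assert res.z_index == 2
    assert res.value == pytest.approx(3.0, rel=1e-3)
    sub = cell_intensity(stack, cell, bg, mode="subtract")
    assert sub.value == pytest.approx(2000.0, rel=1e-3)


def test_normalization_cancels_z_gradient_for_phantom_cells():
    """A cell at fold 3 over background reads ~3.0 wherever it sits in z."""
    fold, bg_level = 3.0, 200.0
    values = []
    for seed in range(4):  # cells land at different z positions
        cfg = SceneConfig(
            canvas_size=(20, 128, 128),
            cell_counts={"cell": 1},
            vessel_count=0,
            marker_rules={"cell": {"X": MarkerSpec("soma", fold * bg_level)}},
            soma_radius_um={"cell": 4.0},
            background_level=bg_level,
            z_gradient_slope=0.01,
            seed=seed,
        )
        scene = generate_scene(cfg)
        stack = render_channel(scene, "X")
        obj = scene.objects[0]
        bg = background_reference(
            stack, [tuple(r) for r in scene.background_rois]
        )
        poly = square_polygon(obj.centroid[1], obj.centroid[2],
                              0.5 * 4.0 * scene.geometry.lateral_scale)
        cell = CellRecord(id=obj.id, soma_polygon=poly)
        res = cell_intensity(stack, cell, bg)
        values.append(res.value)
    zs = [s for s in values]
    assert all(abs(v - fold) / fold < 0.05 for v in zs), zs


def test_absent_marker_normalizes_to_one():
    cfg = SceneConfig(
        canvas_size=(12, 96, 96),
        cell_counts={"cell": 1},
        vessel_count=0,
        marker_rules={"cell": {"X": MarkerSpec("soma", 600.0),
                               "Y": MarkerSpec("nuclear", 600.0)}},
        soma_radius_um={"cell": 4.0},
        background_level=200.0,
        seed=1,
    )
    scene = generate_scene(cfg)
    # render a marker the cell does express, then one it does not
    obj = scene.objects[0]
    poly = square_polygon(obj.centroid[1], obj.centroid[2], 4)
    cell = CellRecord(id=1, soma_polygon=poly)
    blank_cfg_marker = "X"
    stack = render_channel(scene, blank_cfg_marker)
    # measuring far away from the soma: build a polygon in a background patch
    y0, y1, x0, x1 = scene.background_rois[0]
    far_cell = CellRecord(id=2, soma_polygon=square_polygon((y0 + y1) / 2, (x0 + x1) / 2, 3))
    bg = background_reference(stack, [tuple(r) for r in scene.background_rois])
    res = cell_intensity(stack, far_cell, bg)
    assert res.value == pytest.approx(1.0, abs=0.01)


def test_soma_outside_stack_rejected():
    stack = ImageStack(voxels=np.zeros((2, 16, 16), dtype=np.uint16))
    cell = CellRecord(id=1, soma_polygon=square_polygon(100, 100, 3))
    with pytest.raises(ValueError, match="outside"):
        cell_intensity(stack, cell, np.ones(2))


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def test_cavalieri_empty_mask_is_zero():
    vol, n = cavalieri_volume(make_mask(np.zeros((3, 8, 8))))
    assert vol == 0.0 and n == 0


def test_cavalieri_single_slice_arithmetic(geom):
    voxels = np.zeros((4, 32, 32), dtype=bool)
    voxels[1].flat[:100] = True
    vol, n = cavalieri_volume(make_mask(voxels, geometry=geom))
    assert n == 100
    assert vol == pytest.approx(100 / 3.2055**2, rel=1e-6)


def test_cavalieri_additive_and_z_order_invariant():
    rng = np.random.default_rng(5)
    a = rng.random((4, 16, 16)) < 0.2
    b = (rng.random((4, 16, 16)) < 0.2) & ~a
    va, _ = cavalieri_volume(make_mask(a))
    vb, _ = cavalieri_volume(make_mask(b))
    vab, _ = cavalieri_volume(make_mask(a | b))
    assert vab == pytest.approx(va + vb)
    shuffled, _ = cavalieri_volume(make_mask(a[::-1]))
    assert shuffled == pytest.approx(va)


def test_vascular_density_full_and_empty():
    region = [np.array([[-1, -1], [-1, 17], [17, 17], [17, -1]], float)]
    full = make_mask(np.ones((3, 16, 16)))
    assert vascular_density(full, region) == pytest.approx(100.0)
    empty = make_mask(np.zeros((3, 16, 16)))
    assert vascular_density(empty, region) == 0.0


def test_vascular_density_planted_fraction():
    voxels = np.zeros((10, 20, 20), dtype=bool)
    voxels[:, :3, :] = True  # 3/20 of the region volume
    region = [np.array([[-1, -1], [-1, 21], [21, 21], [21, -1]], float)]
    assert vascular_density(make_mask(voxels), region) == pytest.approx(15.0)


# ---------------------------------------------------------------------------
# antigenicity
# ---------------------------------------------------------------------------

def test_antigenicity_perfect_and_inverted_correlation():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    r, p, n = antigenicity_correlation(a, 2 * a + 1)
    assert r == pytest.approx(1.0)
    r, _, _ = antigenicity_correlation(a, -a)
    assert r == pytest.approx(-1.0)


def test_antigenicity_input_validation():
    with pytest.raises(ValueError):
        antigenicity_correlation([1, 2], [1, 2])
    with pytest.raises(ValueError):
        antigenicity_correlation([1, 1, 1], [1, 2, 3])
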