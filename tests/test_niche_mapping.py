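"""Coverage, sampling bars, distance maps (vs brute-force oracle), spot
clustering/splitting and radial profiles."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import make_mask
from niche4i.geometry import Geometry
from niche4i.niche_mapping import (
    SpotSample,
    bar_distance_map,
    cluster_spots,
    coverage_fraction,
    generate_sampling_bars,
    radial_profile,
    sample_microniche,
    split_spots_by_marker,
)
from oracles import (
    brute_force_microniche_count,
    brute_force_quantized_distance,
    brute_force_radial_bins,
)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def test_coverage_superset_disjoint_and_self():
    base = np.zeros((2, 10, 10), dtype=bool)
    base[0, :5, :5] = True
    superset = np.ones_like(base)
    assert coverage_fraction(make_mask(base), make_mask(superset)) == 100.0
    assert coverage_fraction(make_mask(base), make_mask(~base)) == 0.0
    assert coverage_fraction(make_mask(base), make_mask(base)) == 100.0


def test_coverage_planted_overlap_is_exact():
    base = np.zeros((1, 40, 40), dtype=bool)
    base.flat[:1000] = True
    marker = np.zeros_like(base)
    marker.flat[:250] = True
    assert coverage_fraction(make_mask(base), make_mask(marker)) == 25.0


def test_coverage_monotone_in_marker_mask():
    rng = np.random.default_rng(0)
    base = rng.random((3, 16, 16)) < 0.5
    small = rng.random((3, 16, 16)) < 0.2
    big = small | (rng.random((3, 16, 16)) < 0.2)
    assert coverage_fraction(make_mask(base), make_mask(big)) >= coverage_fraction(
        make_mask(base), make_mask(small)
    )


def test_coverage_empty_base_rejected():
    with pytest.raises(ValueError, match="empty"):
        coverage_fraction(make_mask(np.zeros((1, 4, 4))), make_mask(np.ones((1, 4, 4))))


# ---------------------------------------------------------------------------
# sampling bars & distance maps
# ---------------------------------------------------------------------------

def gcl_rect(x_max=800, y0=10, y1=60):
    return np.array([[y0, 0], [y0, x_max - 1], [y1, x_max - 1], [y1, 0]], float)


def test_bar_count_over_gcl_span():
    bars = generate_sampling_bars(gcl_rect(800), (100, 800), spacing_px=160)
    assert len(bars) == 5  # ceil(800 / 160)
    for bar in bars:
        xs = np.unique(np.argwhere(bar)[:, 1])
        assert len(xs) == 1  # 1 px wide


def test_narrow_polygon_yields_at_most_one_bar():
    poly = np.array([[10, 0], [10, 99], [60, 99], [60, 0]], float)
    bars = generate_sampling_bars(poly, (100, 800), spacing_px=160)
    assert len(bars) <= 1


def test_bar_spacing_matches_fifty_micrometers(geom):
    assert geom.px_to_um(160) == pytest.approx(50.0, abs=0.1)


def test_bad_spacing_rejected():
    with pytest.raises(ValueError):
        generate_sampling_bars(gcl_rect(), (100, 800), spacing_px=0)


def test_distance_map_neighbors_and_axis_distance():
    bar = np.zeros((30, 400), dtype=bool)
    bar[5:25, 100] = True
    dmap = bar_distance_map(bar)
    assert dmap.values[10, 100] == 0
    assert dmap.values[10, 101] == 1  # 4-neighbor
    assert dmap.values[4, 101] == 1  # diagonal: round(sqrt(2)) = 1
    assert dmap.values[10, 260] == 160  # axis-aligned
    assert dmap.values.max() <= 255


def test_distance_map_empty_bar_rejected():
    with pytest.raises(ValueError, match="empty"):
        bar_distance_map(np.zeros((10, 10), dtype=bool))


def test_distance_map_cap_saturates():
    bar = np.zeros((10, 400), dtype=bool)
    bar[:, 0] = True
    dmap = bar_distance_map(bar)
    assert dmap.values[0, 399] == 255


# ---------------------------------------------------------------------------
# microniche sampling
# ---------------------------------------------------------------------------

def test_microniche_full_and_empty_marker():
    bar = np.zeros((40, 40), dtype=bool)
    bar[:, 20] = True
    dmap = bar_distance_map(bar)
    full = np.ones((3, 40, 40), dtype=bool)
    spot = sample_microniche(dmap, {"A": full, "B": ~full}, radius_px=10)
    assert spot.volume_fraction["A"] == 100.0
    assert spot.volume_fraction["B"] == 0.0
    assert spot.sampled_volume_um3 > 0


def test_microniche_radius_beyond_cap_rejected():
    bar = np.zeros((10, 10), dtype=bool)
    bar[0, 0] = True
    dmap = bar_distance_map(bar)
    with pytest.raises(ValueError, match="cap"):
        sample_microniche(dmap, {"A": np.ones((2, 10, 10), dtype=bool)}, radius_px=300)


@pytest.mark.parametrize("seed", range(12))
def test_microniche_matches_bruteforce_oracle(seed):
    """Distance-transform sampling equals exhaustive per-voxel Euclidean
    distances on random small instances."""
    rng = np.random.default_rng(seed)
    h, w, nz = rng.integers(24, 65), rng.integers(24, 65), rng.integers(2, 5)
    bar = np.zeros((h, w), dtype=bool)
    x = rng.integers(0, w)
    y0 = rng.integers(0, h - 4)
    bar[y0 : y0 + rng.integers(2, h - y0), x] = True
    mask = rng.random((nz, h, w)) < 0.3
    radius = int(rng.integers(5, 40))
    dmap = bar_distance_map(bar)
    assert np.array_equal(dmap.values, brute_force_quantized_distance(bar))
    spot = sample_microniche(dmap, {"A": mask}, radius_px=radius)
    count, total = brute_force_microniche_count(bar, mask, radius)
    assert spot.volume_fraction["A"] == pytest.approx(100.0 * count / total)


def test_histogram_conservation_within_reach():
    """Summing a marker's per-distance histogram over all d <= cap equals
    its voxel count within the map's reach."""
    rng = np.random.default_rng(42)
    bar = np.zeros((50, 50), dtype=bool)
    bar[10:40, 25] = True
    mask = rng.random((4, 50, 50)) < 0.4
    dmap = bar_distance_map(bar)
    within = dmap.values <= dmap.cap
    per_distance = [
        int(mask[:, dmap.values == d].sum()) for d in range(dmap.values.max() + 1)
    ]
    assert sum(per_distance) == int(mask[:, within].sum()) == int(mask.sum())


# ---------------------------------------------------------------------------
# clustering & splitting
# ---------------------------------------------------------------------------

MARKERS = ["Nestin", "SOX2", "DCX", "CollagenIV", "IBA1"]


def make_spots(rng, n, means, spread=0.05, tag="s"):
    spots = []
    for i in range(n):
        vf = {m: float(max(0.0, rng.normal(mu, spread))) for m, mu in means.items()}
        spots.append(SpotSample(spot_id=f"{tag}{i}", volume_fraction=vf))
    return spots


def test_well_separated_populations_recovered_perfectly():
    rng = np.random.default_rng(0)
    young = make_spots(rng, 30, {m: 2.0 for m in MARKERS}, tag="y")
    old = make_spots(rng, 30, {m: 0.5 for m in MARKERS}, tag="o")
    spots = young + old
    planted = ["young"] * 30 + ["old"] * 30
    res = cluster_spots(spots, MARKERS, seed=0)
    assert adjusted_rand_score(planted, res.class_labels) == 1.0
    # naming rule: the neurogenic-richer population is called young
    young_ids = {s.spot_id for s, c in zip(spots, res.class_labels) if c == "young"}
    assert young_ids == {s.spot_id for s in young}


def test_clustering_invariant_to_spot_ordering():
    rng = np.random.default_rng(1)
    spots = make_spots(rng, 20, {m: 2.0 for m in MARKERS}) + make_spots(
        rng, 20, {m: 0.5 for m in MARKERS}, tag="t"
    )
    res = cluster_spots(spots, MARKERS, seed=3)
    shuffled = list(spots)
    rng.shuffle(shuffled)
    res2 = cluster_spots(shuffled, MARKERS, seed=3)
    by_id = dict(zip([s.spot_id for s in shuffled], res2.class_labels))
    assert [by_id[s.spot_id] for s in spots] == res.class_labels


def test_identical_spots_are_degenerate():
    spots = [
        SpotSample(spot_id=f"s{i}", volume_fraction={m: 1.0 for m in MARKERS})
        for i in range(10)
    ]
    with pytest.raises(ValueError, match="degenerate"):
        with pytest.warns(UserWarning, match="zero-variance"):
            cluster_spots(spots, MARKERS, seed=0)


def test_too_few_spots_rejected():
    spots = [SpotSample(spot_id="a", volume_fraction={m: 1.0 for m in MARKERS})]
    with pytest.raises(ValueError):
        cluster_spots(spots, MARKERS, k=2)


def test_quartile_split_threshold_and_labels():
    def spot(i, v):
        return SpotSample(spot_id=str(i), volume_fraction={"Nestin": v})

    # all reference fractions equal
    ref = [spot(i, 0.5) for i in range(8)]
    labels, thr = split_spots_by_marker([spot("a", 0.5), spot("b", 0.4)], ref)
    assert thr == 0.5 and labels == ["high", "low"]
    # uniform reference 0.1..1.0 %: linear-interpolation 25th percentile
    ref = [spot(i, v) for i, v in enumerate(np.arange(0.1, 1.01, 0.1))]
    labels, thr = split_spots_by_marker(
        [spot("a", 0.33), spot("b", 0.32), spot("c", 0.0)], ref
    )
    assert thr == pytest.approx(0.325)
    assert labels == ["high", "low", "low"]
    # zero-fraction reference spots are ignored
    with pytest.raises(ValueError, match="positive"):
        split_spots_by_marker([spot("a", 1.0)], [spot(i, 0.0) for i in range(3)])


# ---------------------------------------------------------------------------
# radial profiles
# ---------------------------------------------------------------------------

def test_radial_profile_uniform_density_recovers_rate():
    rng = np.random.default_rng(2)
    origin = np.zeros((60, 60), dtype=bool)
    origin[28:32, 28:32] = True
    p = 0.3
    mask = rng.random((6, 60, 60)) < p
    prof = radial_profile(origin, {"A": mask}, geometry=Geometry(1.0, 1.0),
                          bin_um=5.0, max_radius_um=25.0)
    filled = prof.bins.dropna(subset=["A"])
    for _, row in filled.iterrows():
        n = row["shell_volume_um3"]  # voxel count at unit geometry
        tol = 4 * np.sqrt(p * (1 - p) / n) * 100
        assert abs(row["A"] - 100 * p) < tol


def test_radial_profile_signal_only_in_first_shell():
    origin = np.zeros((40, 40), dtype=bool)
    origin[20, 20] = True
    mask = np.zeros((2, 40, 40), dtype=bool)
    mask[:, 19:22, 19:22] = True  # within ~1.4 px of the origin
    prof = radial_profile(origin, {"A": mask}, geometry=Geometry(1.0, 1.0),
                          bin_um=5.0, max_radius_um=20.0)
    vals = prof.bins["A"].to_numpy()
    assert vals[0] > 0
    assert np.nansum(vals[1:]) == 0


def test_radial_profile_bins_are_contiguous_from_zero():
    origin = np.zeros((30, 30), dtype=bool)
    origin[15, 15] = True
    prof = radial_profile(origin, {"A": np.zeros((1, 30, 30), dtype=bool)},
                          geometry=Geometry(2.0, 1.0), bin_um=5.0, max_radius_um=50.0)
    assert prof.bins["inner_um"].iloc[0] == 0.0
    assert np.allclose(prof.bins["outer_um"] - prof.bins["inner_um"], 5.0)
    assert len(prof.bins) == 10


@pytest.mark.parametrize("seed", range(8))
def test_radial_profile_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    h = w = int(rng.integers(32, 80))
    nz = int(rng.integers(2, 5))
    origin = np.zeros((h, w), dtype=bool)
    oy, ox = rng.integers(4, h - 8), rng.integers(4, w - 8)
    origin[oy : oy + 4, ox : ox + 2] = True
    mask = rng.random((nz, h, w)) < 0.25
    geom = Geometry(lateral_scale=float(rng.uniform(1.0, 4.0)), z_step=1.0)
    prof = radial_profile(origin, {"A": mask}, geometry=geom,
                          bin_um=5.0, max_radius_um=25.0)
    edges_px = np.arange(6) * 5.0 * geom.lateral_scale
    oracle = brute_force_radial_bins(origin, mask, edges_px)
    for (count, shell_vox), (_, row) in zip(oracle, prof.bins.iterrows()):
        assert row["shell_volume_um3"] == pytest.approx(
            shell_vox * geom.voxel_volume_um3
        )
        if shell_vox:
            assert row["A"] == pytest.approx(100.0 * count / shell_vox)


def test_radial_profile_input_validation():
    with pytest.raises(ValueError, match="empty origin"):
        radial_profile(np.zeros((10, 10), dtype=bool),
                       {"A": np.zeros((1, 10, 10), dtype=bool)})
    origin = np.zeros((10, 10), dtype=bool)
    origin[5, 5] = True
    with pytest.raises(ValueError, match="bin_um"):
        radial_profile(origin, {"A": np.zeros((1, 10, 10), dtype=bool)}, bin_um=0)
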