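"""Study conditions for the synthetic aging experiment.

This module pins the phantom configurations the analysis drivers and the
acceptance script share: three age groups (2, 6, 12 months) with the
age effects the real dentate gyrus shows — fewer stem cells, progenitors
and immature neurons, ~30% lower vascular and Nestin volume fractions,
reduced pericyte coverage and more microglia — plus a fast spot-composition
simulator for the microniche classification analyses.

Canvas sizes are deliberately smaller than a full tiled acquisition
(hundreds of µm) so a complete synthetic study runs on a laptop; the
per-voxel geometry (3.2055 px/µm, 1 µm z-step, 16-bit) matches the
acquisitions the pipeline targets.
"""

from __future__ import annotations


from typing import Optional, Sequence

import numpy as np

from .niche_mapping import SpotSample
from .synthetic_scene import (
    DEFAULT_MARKER_RULES,
    MarkerSpec,
    SceneConfig,
    SyntheticScene,
    generate_scene,
)

__all__ = [
    "AGE_GROUPS",
    "MICRONICHE_MARKERS",
    "YOUNG_SPOT_MEANS",
    "OLD_SPOT_MULTIPLIERS",
    "scene_config_for_age",
    "aging_scene",
    "simulate_spot_population",
    "fidelity_config",
]

AGE_GROUPS = (2, 6, 12)

#: the eleven markers whose volumes characterize a microniche
MICRONICHE_MARKERS = (
    "CollagenIV", "CD13", "GFAP", "Nestin", "SOX2", "HOPX",
    "DCX", "KI67", "IBA1", "NG2", "PV",
)

#: mean volume fractions (percent of sampled volume) of young microniches
YOUNG_SPOT_MEANS = {
    "CollagenIV": 3.0,
    "CD13": 1.2,
    "GFAP": 2.5,
    "Nestin": 0.8,
    "SOX2": 1.5,
    "HOPX": 1.2,
    "DCX": 1.0,
    "KI67": 0.15,
    "IBA1": 1.0,
    "NG2": 1.2,
    "PV": 0.4,
}

#: multiplicative age effects of old microniches (30% lower vessel and
#: Nestin content; neurogenic markers down, microglia up)
OLD_SPOT_MULTIPLIERS = {
    "CollagenIV": 0.7,
    "CD13": 0.7,
    "GFAP": 1.0,
    "Nestin": 0.7,
    "SOX2": 0.75,
    "HOPX": 1.0,
    "DCX": 0.5,
    "KI67": 0.5,
    "IBA1": 1.3,
    "NG2": 1.0,
    "PV": 0.8,
}

_AGE_CELL_COUNTS = {
    2: {"R": 8, "NR": 6, "immature_neuron": 10, "astrocyte": 10,
        "microglia": 7, "OPC": 6, "PV_interneuron": 2, "arc_neuron": 7},
    6: {"R": 5, "NR": 3, "immature_neuron": 5, "astrocyte": 10,
        "microglia": 9, "OPC": 7, "PV_interneuron": 2, "arc_neuron": 6},
    12: {"R": 3, "NR": 2, "immature_neuron": 2, "astrocyte": 8,
         "microglia": 11, "OPC": 6, "PV_interneuron": 2, "arc_neuron": 5},
}
_AGE_VESSELS = {2: 5, 6: 4, 12: 3}
_AGE_PERICYTE = {2: 0.60, 6: 0.45, 12: 0.42}

#: rigid drift between staining rounds (dx, dy, dz), round 0 = reference
DEFAULT_ROUND_SHIFTS = [(0, 0, 0), (5, -3, 1), (-4, 6, 0), (7, 2, -1)]

#: which markers are stained and imaged in which round (DAPI counterstain
#: is imaged every round and anchors the registration landmarks)
ROUND_PANEL = {
    0: ("HOPX", "SOX2", "KI67"),
    1: ("GFAP", "Nestin", "DCX", "S100B"),
    2: ("CollagenIV", "CD13", "IBA1", "NG2"),
    3: ("PV", "ARC", "OLIG2"),
}


def scene_config_for_age(
    age_months: int,
    seed: int,
    canvas_size: tuple[int, int, int] = (16, 448, 448),
    noise_sd: float = 80.0,
) -> SceneConfig:
    """Phantom configuration for one section of one age group."""
    if age_months not in _AGE_CELL_COUNTS:
        raise ValueError(f"age must be one of {sorted(_AGE_CELL_COUNTS)}")
    return SceneConfig(
        canvas_size=canvas_size,
        cell_counts=dict(_AGE_CELL_COUNTS[age_months]),
        vessel_count=_AGE_VESSELS[age_months],
        pericyte_coverage_fraction=_AGE_PERICYTE[age_months],
        astro_coverage_fraction=0.25,
        background_level=200.0,
        z_gradient_slope=0.01,
        noise_sd=noise_sd,
        round_shifts=list(DEFAULT_ROUND_SHIFTS),
        round_decay=0.95,
        intensity_cv=0.3,
        seed=seed,
    )


def aging_scene(age_months: int, seed: int, **kwargs) -> SyntheticScene:
    return generate_scene(scene_config_for_age(age_months, seed, **kwargs))


def simulate_spot_population(
    n_young: int,
    n_old: int,
    seed: int,
    markers: Sequence[str] = MICRONICHE_MARKERS,
    cv: float = 0.2,
    old_multipliers: Optional[dict] = None,
) -> tuple[list[SpotSample], list[str]]:
    """Draw microniche compositions for a young and an old population.

    Per-marker fractions are lognormal around the young means (coefficient
    of variation ``cv``), with the old population's means scaled by the
    planted age effects.  Returns ``(spots, planted_labels)``; spot order
    is shuffled so clustering cannot exploit ordering.
    """
    rng = np.random.default_rng(seed)
    mult = old_multipliers or OLD_SPOT_MULTIPLIERS
    sigma = np.sqrt(np.log(1 + cv**2))
    spots: list[SpotSample] = []
    planted: list[str] = []
    for pop, n in (("young", n_young), ("old", n_old)):
        for i in range(n):
            vf = {}
            for m in markers:
                mean = YOUNG_SPOT_MEANS[m] * (mult.get(m, 1.0) if pop == "old" else 1.0)
                mu = np.log(mean) - sigma**2 / 2
                vf[m] = float(np.clip(rng.lognormal(mu, sigma), 0.0, 100.0))
            spots.append(
                SpotSample(
                    spot_id=f"{pop}_{i}",
                    labels={"population": pop},
                    volume_fraction=vf,
                    sampled_volume_um3=1.0,
                )
            )
            planted.append(pop)
    order = rng.permutation(len(spots))
    return [spots[i] for i in order], [planted[i] for i in order]


def fidelity_config(seed: int = 0) -> SceneConfig:
    """Phantom for mask-recipe fidelity checks.

    One generously sized object per recipe marker, rendered noiseless at
    twice its packaged threshold: a r=7 µm tube for CollagenIV (so the
    two-erosion shell stays small relative to the vessel) and r=5 µm
    spheres for the others, plus bright sub-floor specks for ARC and KI67
    so the particle-area floors are exercised.
    """
    from .segmentation import load_default_recipes

    recipes = load_default_recipes()
    rules: dict[str, dict[str, MarkerSpec]] = {}
    counts: dict[str, int] = {}
    radii: dict[str, float] = {}
    for marker, recipe in recipes.items():
        if marker == "CollagenIV":
            continue  # carried by the vessel
        kind = f"blob_{marker}"
        rules[kind] = {marker: MarkerSpec("soma", 2.0 * recipe.threshold)}
        counts[kind] = 3
        radii[kind] = 5.0
    rules["vessel"] = {"CollagenIV": MarkerSpec("tube", 2.0 * recipes["CollagenIV"].threshold)}
    for marker in ("ARC", "KI67"):
        kind = f"speck_{marker}"
        # bright enough to survive blur+threshold; removed by the area floor
        rules[kind] = {marker: MarkerSpec("soma", 6.0 * recipes[marker].threshold)}
        counts[kind] = 4
        radii[kind] = 0.9
    return SceneConfig(
        canvas_size=(24, 320, 320),
        cell_counts=counts,
        vessel_count=1,
        vessel_radius_um=(7.0, 7.0),
        pericyte_coverage_fraction=0.0,
        astro_coverage_fraction=0.0,
        marker_rules=rules,
        soma_radius_um=radii,
        background_level=0.0,
        z_gradient_slope=0.0,
        noise_sd=0.0,
        seed=seed,
    )
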