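import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles

from niche4i.geometry import Geometry
from niche4i.segmentation import (
    BinaryMask,
    dice_coefficient,
    filter_particles,
    load_default_recipes,
    make_binary,
)
from niche4i.study import fidelity_config
from niche4i.synthetic_scene import generate_scene, ground_truth_mask, render_channel


@pytest.fixture(scope="session")
def geom() -> Geometry:
    return Geometry()


@pytest.fixture(scope="session")
def fidelity_scene():
    """Noiseless phantom with one generously sized structure per recipe
    marker, rendered at twice each packaged threshold."""
    return generate_scene(fidelity_config(seed=0))


@pytest.fixture(scope="session")
def fidelity_dice(fidelity_scene):
    """Per-marker Dice of the default-recipe mask against ground truth."""
    recipes = load_default_recipes()
    out = {}
    for marker, recipe in recipes.items():
        stack = render_channel(fidelity_scene, marker)
        mask = make_binary(stack, recipe)
        if recipe.particle_min_area_um2 is not None:
            mask = filter_particles(
                mask, recipe.particle_min_area_um2, recipe.particle_projection
            )
        kinds = {"vessel"} if marker == "CollagenIV" else {f"blob_{marker}"}
        truth = ground_truth_mask(fidelity_scene, marker, kinds=kinds)
        out[marker] = dice_coefficient(mask.voxels, truth)
    return out


def make_mask(voxels, marker="test", geometry=None) -> BinaryMask:
    return BinaryMask(
        voxels=np.asarray(voxels, dtype=bool),
        marker=marker,
        geometry=geometry or Geometry(),
    )
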