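#!/usr/bin/env python
"""Binarize every recipe marker of every aligned section with the packaged
default recipes and score the masks against the phantom ground truth.

In this phantom Nestin is expressed only on R-cell radial processes, so
the manual "isolate processes into an ROI" step of the bench workflow is
an identity here.  Dice values are descriptive: the aging sections carry
noise, a penetrance gradient and per-round intensity decay, so they sit
below the noiseless-phantom fidelity bound by design.

Reads scratch/aligned/, writes scratch/masks/ and results/mask_dice.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import common
import pandas as pd

from niche4i.io_alignment import read_stack
from niche4i.segmentation import (
    dice_coefficient,
    filter_particles,
    load_default_recipes,
    make_binary,
    write_mask,
)
from niche4i.synthetic_scene import ground_truth_mask


def main() -> None:
    manifest = common.read_manifest("study_manifest.json")
    recipes = load_default_recipes()
    rows = []
    for entry in manifest["sections"]:
        age, sec, name = entry["age"], entry["section"], entry["name"]
        scene = common.section_scene(age, sec)
        for marker, recipe in recipes.items():
            stack = read_stack(common.aligned_path(age, sec, marker), marker=marker)
            mask = make_binary(stack, recipe)
            if recipe.particle_min_area_um2 is not None:
                mask = filter_particles(
                    mask, recipe.particle_min_area_um2, recipe.particle_projection
                )
            out = common.mask_path(age, sec, marker)
            out.parent.mkdir(parents=True, exist_ok=True)
            write_mask(mask, out)
            truth = ground_truth_mask(scene, marker)
            rows.append(
                {
                    "section": name,
                    "age": age,
                    "marker": marker,
                    "mask_voxels": mask.count(),
                    "truth_voxels": int(truth.sum()),
                    "dice": dice_coefficient(mask.voxels, truth),
                }
            )
        done = [r for r in rows if r["section"] == name]
        print(f"{name}: mean Dice {pd.DataFrame(done)['dice'].mean():.3f} "
              f"over {len(done)} markers")
    table = pd.DataFrame(rows)
    table.to_csv(common.RESULTS / "mask_dice.csv", index=False)
    print(f"overall mean Dice {table['dice'].mean():.3f}; "
          "masks -> scratch/masks, table -> results/mask_dice.csv")


if __name__ == "__main__":
    main()
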