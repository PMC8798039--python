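#!/usr/bin/env python
"""Generate the synthetic aging study: phantom sections for 2-, 6- and
12-month groups, rendered per marker per staining round with realistic
acquisition artifacts (z-gradient, round drift and decay, noise).

Writes OME-TIFF stacks and DAPI landmark CSVs under scratch/stacks/,
ground-truth tables and region ROIs under results/phantoms/, and a
manifest (results/study_manifest.json) the later drivers consume.
"""

import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import common
from niche4i.io_alignment import write_landmarks, write_stack
from niche4i.study import ROUND_PANEL
from niche4i.synthetic_scene import render_channel, write_ground_truth


def main() -> None:
    t0 = time.time()
    manifest = {"sections": [], "round_panel": {str(k): list(v) for k, v in ROUND_PANEL.items()}}
    for age, sec in common.section_ids():
        name = common.section_name(age, sec)
        scene = common.section_scene(age, sec)
        gt_dir = common.RESULTS / "phantoms" / name
        write_ground_truth(scene, gt_dir)
        n_stacks = 0
        for round_index, markers in ROUND_PANEL.items():
            for marker in markers + ("DAPI",):
                if marker == "DAPI" and round_index == 0:
                    pass  # reference round DAPI is rendered too
                stack = render_channel(scene, marker, round_index)
                path = common.stack_path(age, sec, marker, round_index)
                path.parent.mkdir(parents=True, exist_ok=True)
                write_stack(stack, path)
                n_stacks += 1
            if round_index > 0:
                # landmark clicks: DAPI puncta matched to the reference round
                pairs = scene.dapi_landmarks(round_index, n=5)
                write_landmarks(pairs, common.landmarks_path(age, sec, round_index))
        manifest["sections"].append(
            {
                "age": age,
                "section": sec,
                "name": name,
                "seed": common.section_seed(age, sec),
                "n_objects": len(scene.objects),
                "n_vessels": len(scene.objects_of_kind("vessel")),
                "round_shifts": [list(s) for s in scene.config.round_shifts],
            }
        )
        print(
            f"{name}: {len(scene.objects)} objects "
            f"({len(scene.objects_of_kind('vessel'))} vessels), {n_stacks} stacks"
        )
    common.write_manifest(manifest, "study_manifest.json")
    print(f"done in {time.time() - t0:.0f} s -> scratch/stacks, results/phantoms")


if __name__ == "__main__":
    main()
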