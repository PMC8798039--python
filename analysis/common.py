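"""Shared plumbing for the numbered analysis drivers.

The synthetic aging study: three age groups (2, 6, 12 months), two
sections per group, one deterministic phantom per section.  Rendered
stacks and masks (binary/bulky) live under ``scratch/``; every table a
reader would inspect goes to ``results/``.
"""

from __future__ import annotations

import json
from pathlib import Path

from niche4i.study import AGE_GROUPS, scene_config_for_age
from niche4i.synthetic_scene import SyntheticScene, generate_scene

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

#: (z, y, x) canvas of one synthetic section (~120 x 120 µm, 10 frames)
CANVAS = (10, 384, 384)
SECTIONS_PER_AGE = 2
NOISE_SD = 80.0

#: microniche bars: paper spacing, phased so bars sit inside the canvas
BAR_SPACING_PX = 160
BAR_PHASE_PX = 80


def section_ids() -> list[tuple[int, int]]:
    return [(age, sec) for age in AGE_GROUPS for sec in range(SECTIONS_PER_AGE)]


def section_seed(age: int, sec: int) -> int:
    return 1000 * age + sec


def section_name(age: int, sec: int) -> str:
    return f"age{age:02d}_sec{sec}"


def section_scene(age: int, sec: int) -> SyntheticScene:
    """Regenerate a section's phantom (deterministic in its seed)."""
    cfg = scene_config_for_age(
        age, seed=section_seed(age, sec), canvas_size=CANVAS, noise_sd=NOISE_SD
    )
    return generate_scene(cfg)


def stack_path(age: int, sec: int, marker: str, round_index: int) -> Path:
    d = SCRATCH / "stacks" / section_name(age, sec)
    return d / f"{marker}_r{round_index}.ome.tif"


def aligned_path(age: int, sec: int, marker: str) -> Path:
    return SCRATCH / "aligned" / section_name(age, sec) / f"{marker}.ome.tif"


def mask_path(age: int, sec: int, marker: str) -> Path:
    return SCRATCH / "masks" / section_name(age, sec) / f"{marker}.tif"


def landmarks_path(age: int, sec: int, round_index: int) -> Path:
    return SCRATCH / "stacks" / section_name(age, sec) / f"landmarks_r{round_index}.csv"


def write_manifest(payload: dict, name: str) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def read_manifest(name: str) -> dict:
    with open(RESULTS / name) as fh:
        return json.load(fh)
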