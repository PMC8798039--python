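# niche4i

Quantitative analysis of **iterative indirect immunofluorescence imaging
(4i) on tissue sections**: the same section is stained, imaged as a 16-bit
confocal z-stack, eluted and restained over several cycles, multiplexing
~18 antibodies onto one sample.  `niche4i` provides the downstream image
analysis for such experiments — built for quantifying the aging
neurogenic niche of the dentate gyrus (radial glia-like stem cells,
progenitors, immature neurons, glia and vasculature), and applicable to
any cyclic-IF stack collection.

The pipeline covers:

* **Round registration** — integer rigid translation from DAPI landmark
  pairs (component-wise median of `reference − moving`), canvas grown so
  no data is cropped, blank z-frames prepended as needed.
* **Recipe-based 3D binarization** — per-marker prefilter → lower
  intensity limit (`>=`) → erosions → particle-area floor on the max
  projection; the packaged recipe table covers 12 markers (e.g.
  CollagenIV: 3D Gaussian σ = (2, 2, 1.5) px, threshold 1500, two
  erosions; KI67: threshold 2000 with a 15 µm² particle floor).
* **Quantification** — rule-based cell phenotyping; densities as
  count / (area[mm²] × 0.04 mm); per-cell intensities measured at the
  brightest slice and divided by that slice's background (five
  signal-free ROIs per slice), which cancels the z-axis
  antibody-penetrance gradient; Cavalieri volumes
  `V = Σ_slices A_slice · Δz`; vessel coverage
  `100·|base ∧ marker|/|base|`; round-to-round antigenicity via Pearson
  correlation.
* **Niche mapping** — randomized microniches: 1-px sampling bars every
  160 px (50 µm) across the GCL, 8-bit Euclidean distance maps (0 on the
  bar, +1 per pixel, capped at 255), per-spot marker volume fractions
  within a 50 µm radius; k-means (k = 2) on standardized fractions into
  "young"/"old" spots with PCA for display; Nestin high/low split at the
  25th percentile of the young reference; targeted 5 µm-binned radial
  profiles around Nestin⁺ process sets and Ki67⁺ cells.
* **Statistics** — a thin layer delegating to scipy / statsmodels /
  pingouin, with an automatic Brown–Forsythe gate that substitutes Welch
  variants and flags the substitution.

Everything is validated on a **synthetic dentate-gyrus phantom
generator** (`niche4i.synthetic_scene`) that renders typed cells,
tubular vessels with exact planted pericyte coverage, penetrance
gradients, round drifts/decay and noise — with exact ground truth, so
the whole pipeline is testable without any image download.  See
`docs/methods.md` for models, parameters and limitations.

## Worked example

The `analysis/` drivers run a complete synthetic aging study (three age
groups, two sections each, four staining rounds with planted drifts):

```bash
python analysis/01_simulate_phantoms.py   # phantoms + OME-TIFFs + landmarks
python analysis/02_align_rounds.py        # landmark registration
python analysis/03_segment_markers.py     # default-recipe masks + Dice
python analysis/04_quantify_cells.py      # phenotypes, densities, intensities
python analysis/05_microniche.py          # bars, spots, young/old k-means
python analysis/06_radial_profiles.py     # 5 µm radial niche profiles
python analysis/07_stats_report.py        # comparison report
```

Driver 02 prints `recovered 24/24 round shifts exactly` — every planted
inter-round drift is recovered from five landmark clicks.  Driver 04
prints

```
R cells counted per age: {2: 16, 6: 10, 12: 6}
antigenicity (HOPX, round 0 vs restain): r=0.998 (n=8)
```

i.e. rule-based phenotyping recovers the planted age-dependent stem-cell
decline (8/5/3 R cells per section were planted) and per-cell HOPX
intensities correlate almost perfectly across an elution/restain cycle.
Driver 05 prints

```
young/old mix per age (image-derived spots):
age  spot_class
2    young         100.0
6    old           100.0
12   old           100.0
population-scale clustering ARI vs planted labels: 1.000
Nestin high/low threshold (25th pct of young reference): 0.692% volume
```

— 2-month microniches classify as young and 6/12-month ones as old, and
at population scale the k-means classification reproduces the planted
labels exactly.  Tables land in `results/` (spot compositions, PCA
loadings, radial profiles, densities, the Markdown statistics report);
bulky stacks and masks go to `scratch/`.

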