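# Methods

`niche4i` implements the image-analysis workflow of iterative indirect
immunofluorescence imaging (4i) on tissue sections: the same section is
stained, imaged as a 3D confocal z-stack, eluted and restained over
several rounds, multiplexing ~18 antibodies onto one sample.  The
pipeline turns the per-marker, per-round stacks into registered volumes,
binary masks, stereological quantities and spatial "niche" statistics.
Every stage is validated against synthetic phantoms with exact ground
truth, so the package is fully testable offline.

## Geometry and conventions

Stacks are `(z, y, x)`, 0-based, y down.  Voxels are anisotropic: the
targeted acquisitions have 3.2055 px/µm laterally (0.312 µm pixels) and a
1 µm z-step, so one voxel is ≈ 0.097 µm³.  All µm↔pixel conversions go
through `Geometry`; every size parameter in the API is in µm.

## Round registration (`io_alignment`)

Rounds drift by a few pixels because the plate is re-mounted each cycle.
Registration is deliberately integer-only rigid translation, mirroring
the manual bench procedure: DAPI puncta recognizable across cycles are
recorded as landmark pairs; the transform is the component-wise rounded
median of `reference − moving` (the median absorbs a minority of
mis-clicked landmarks; a residual above 2 px triggers a warning).
Applying the transform grows the canvas to the bounding union of the
reference and the shifted moving stack — nothing is ever cropped, the
total signal is conserved, and z is handled by prepending blank frames.
Sub-pixel, rotational or deformable registration is out of scope:
sections are rigidly mounted and the downstream measures are volume
fractions, which are insensitive to sub-pixel phase.

## Binarization recipes (`segmentation`)

Volumetric analyses run on binary masks produced by per-marker recipes
(packaged in `recipes.yaml`): optional prefilter, a 16-bit lower
intensity limit (`>=` keeps, ImageJ "lower limit" semantics), optional
binary erosions, and an optional particle-area floor applied to the
maximum z-projection (components with projected area `>=` the floor are
kept and their footprints select the retained 3D voxels).  The packaged
thresholds are: CollagenIV 1500 (3D Gaussian blur, sigmas 2, 2, 1.5 px
in x, y, z; two erosions), CD13 1800, GFAP 5250, Nestin 2000, DCX 2500,
HOPX 2200, SOX2 1600, PV 4300, ARC 2500 (25 µm² floor), KI67 2000
(15 µm² floor), and NG2 5500 / IBA1 2000 behind a slice-wise 2D median
filter of radius 2 px.  S100β deliberately has no recipe — its
background level precludes a faithful binary — and requesting one is an
error.

Numerical choices: the Gaussian "radii" are interpreted as per-axis
sigmas in pixels (configurable); erosion defaults to an in-plane
4-connected cross applied slice-wise, because with 1 µm frames a 3D
erosion removes a 2 µm axial shell per pass and visibly corrodes
vessel-scale tubes — a 3D 6-connected cross is available via
`erosion_mode="3d"`.  Labeling is 8-connected on 2D projections.  Object
isolation follows the projection rule: one object per connected
component of the max projection, so two objects overlapping only in
projection merge (documented consequence).

## Quantification

* **Phenotyping** applies a fixed-precedence rule table to marker flags:
  R cell = HOPX⁺∧SOX2⁺∧GFAP-process∧S100β⁻ (S100β marks mature
  astrocytes and vetoes R identity); proliferating non-radial progenitor
  = KI67⁺ in the SGZ without a radial process; immature neuron = DCX
  ring; then astrocyte (S100β⁺), microglia (IBA1⁺), OPC (NG2⁺);
  otherwise unclassified.  The SGZ is operationalized as the GCL's hilar
  border band extended 20 µm into the hilus.  Flags are inputs; the
  analysis drivers derive them from normalized soma intensities
  (≥ 2× background by default, configurable) — on real data this
  threshold stands in for the annotator's eye.
* **Density** = count / (region area [mm²] × section thickness
  [0.04 mm]), i.e. cells/mm³.
* **Normalized intensity**: each cell is measured in the z-slice where
  its soma is brightest and divided by that same slice's background mean
  (five signal-free ROIs per slice).  Because the antibody-penetrance
  gradient attenuates signal and background by the same per-slice
  factor, the ratio is invariant to the cell's depth.  Ratio
  normalization is the default; subtraction is available behind a flag.
* **Cavalieri volume** = Σ over slices of (positive area) × z-step;
  vascular density is the CollagenIV mask volume over the region volume,
  in percent.
* **Antigenicity** across staining rounds is the Pearson correlation of
  paired per-cell normalized intensities (n ≥ 3, non-degenerate).

## Niche mapping

* **Coverage** of a base structure (vessels, radial processes) by
  another marker is `100·|base ∧ marker| / |base|`; at this optical
  resolution colocalization reads as proximity within ~1 µm, not
  physical contact.
* **Randomized microniches**: 1-px-wide vertical bars spaced 160 px
  (50 µm) are clipped to the GCL polygon; each surviving bar seeds a
  spot.  The bar's 2D Euclidean distance transform is integer-rounded
  and capped at 255 (the 8-bit ImageJ distance map; a city-block
  chamfer variant sits behind a flag), then applied identically to every
  z-slice.  A marker's spot fraction is 100 × its voxels with
  d ≤ 160 px over all voxels with d ≤ 160 px — equivalent by
  construction to multiplying the binaries into the map and summing the
  histogram.  Distances are strictly 2D (bars and footprints are 2D);
  anisotropic 3D distances are a non-goal.  Neighboring spots overlap
  (spacing = radius); this contiguous sampling is kept, with no
  de-overlap correction.
* **Spot classification**: k-means (k = 2, fixed seed, 10 restarts) on
  z-standardized volume fractions; PCA is computed separately for
  display coordinates and loadings only — clustering on standardized
  fractions rather than PCA scores is this package's resolution of an
  ambiguity in the source procedure.  The cluster with the higher mean
  Nestin+SOX2+DCX content is named "young".  The Nestin high/low split
  thresholds at the 25th percentile (linear interpolation — stated and
  fixed) of marker-positive young-reference spots, so "high" spans the
  young population's top three quartiles; a fallback threshold of 0.4%
  volume applies only when no reference population exists.
* **Targeted radial profiles**: a distance map is built on the origin's
  2D max-projection footprint (Nestin⁺ process sets measured whole per
  section; Ki67⁺ cells isolated by projection particle analysis —
  projection chosen for consistency with the bar procedure) and binned
  into 5 µm annuli, half-open `(inner, outer]` except the first
  `[0, outer]`; each annulus reports marker voxels / annulus voxels.

The distance-map path is proven equal to an exhaustive per-voxel
Euclidean oracle on randomized instances (tests and acceptance script).

## Statistics (`reporting_stats`)

A thin delegation layer: pooled/Welch t (scipy), one-way ANOVA + Tukey
HSD (statsmodels), Welch ANOVA + Games–Howell (pingouin), multiple t
tests with Holm–Šidák correction (statsmodels), and a random-intercept
mixed model per animal (statsmodels MixedLM) with Tukey-style
studentized-range contrasts at residual df — the random-intercept
structure and the df are stated approximations.  When an equal-variance
test is planned and the groups fail Brown–Forsythe (Levene with median
centering) at 0.05, the Welch variant is substituted automatically and
flagged in the report.  The Welch-ANOVA post hoc is Games–Howell, the
installed studentized-range unequal-variance method; Dunnett T3 (which
uses the studentized maximum modulus) has no installed implementation
and Games–Howell is its close large-sample analog, not an exact
equivalent.  α = 0.05 throughout.

## The phantom generator (`synthetic_scene`)

The generator emulates exactly the features the analysis relies on — and
no more.  A rectangular-band anatomy (ML / GCL / hilus, SGZ = hilar
border + 20 µm) hosts straight tubular vessels spanning the canvas and
typed cells with the combinatorial marker rules above.  R-cell somas sit
on the GCL's hilar border with a radial process guaranteed to cross the
GCL.  Pericyte (CD13) and astrocytic (GFAP) vessel coverage is rendered
as contiguous angular patches on a 1.5 µm surface shell whose voxel
count is exact by construction, so planted coverage is a usable ground
truth.  Acquisition artifacts are layered in this order: per-cell
lognormal brightness (default CV 0 in the API, 0.3 in the study
configs), penetrance gradient `(1−g)^z` applied in the tissue frame,
rigid per-round shift, per-round decay `decay^round`, Poisson shot noise
(optional) and Gaussian read noise, clipped to uint16.  Rendering is
bit-deterministic per (seed, marker, round).

Default intensities are free parameters, not claims about real data:
volumetric stains render at 2× their binarization threshold, and thin
high-contrast structures (processes, DCX rings, vessel-surface patches)
at 3–4×, since a 1–2-voxel-thick structure loses half or more of its
peak under the recipe's anisotropic blur.  That loss is a real
limitation worth stating: with a 1 µm z-step, structures ≲ 2 µm thick in
z are at the edge of detectability under the packaged recipes, and the
phantom's GFAP vessel shells segment poorly by design rather than by
bug.

What the phantom does **not** emulate: PSF shape, spectral
bleed-through, tile-stitching seams, curved anatomy, touching cells
(placement enforces near-disjoint somas), or per-marker intensity
distributions of any real acquisition.  Passing tests therefore
demonstrate the correctness of the computational pipeline under known
ground truth, not segmentation performance on real tissue.

## Study conditions and problem sizes

The synthetic aging study (`study.py`, drivers in `analysis/`) uses
three age groups (2, 6, 12 months) with planted effects in the direction
the dentate gyrus ages: fewer R/NR cells and immature neurons, vessel
count 5→4→3, pericyte coverage 0.60→0.45→0.42, more microglia, plus a
1%/frame gradient, 4 staining rounds with drifts up to 7 px, decay 0.95
per round and read noise σ = 80.  Sections are 10 × 384 × 384 voxels
(~120 × 120 × 10 µm) with two sections per group — canvas and replication
chosen so the full study and its acceptance checks run on a single CPU in
minutes; a full tiled acquisition would simply scale the same code.  The
microniche classification analyses additionally use a population-scale
composition simulator (young means with old-age multipliers, e.g. 0.7 on
CollagenIV/CD13/Nestin, 1.3 on IBA1, lognormal CV 0.2, 100 spots per
population), matching the planted 30% vessel/Nestin reduction.

## Known limitations

* Integer-only registration cannot express rotation or shear; gross
  landmark disagreement only warns.
* Projection-based object isolation merges cells that overlap in z.
* The mixed-model Tukey contrasts use a residual-df studentized-range
  approximation rather than Kenward–Roger/Satterthwaite df.
* The quartile-split threshold depends on the chosen percentile
  convention (linear interpolation); other conventions shift it by up to
  one reference-spot gap.
* Statistical power at the desk-scale study (n = 2 sections per age) is
  minimal; the drivers demonstrate the machinery, not inference.
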