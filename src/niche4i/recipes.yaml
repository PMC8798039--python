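# Packaged binarization recipes, one per marker.
#
# threshold:  16-bit lower intensity limit (kept if filtered value >= threshold)
# prefilter:  gaussian sigmas are per-axis pixels (x, y, z); median radius is
#             an in-plane (2D) disk radius in pixels applied slice-wise
# erosions:   number of binary erosions applied after thresholding
# particle_min_area_um2 / particle_projection: connected components of the
#             max z-projection smaller than the floor are removed (>= keeps)
#
# S100B is deliberately absent: its background level precludes a faithful
# binary and it is excluded from all contact and volumetric analyses.
CollagenIV:
  prefilter: {kind: gaussian, sigma_xyz: [2.0, 2.0, 1.5]}
  threshold: 1500
  erosions: 2
CD13:
  prefilter: {kind: gaussian, sigma_xyz: [2.0, 2.0, 1.5]}
  threshold: 1800
GFAP:
  prefilter: {kind: gaussian, sigma_xyz: [2.0, 2.0, 1.5]}
  threshold: 5250
Nestin:
  prefilter: {kind: gaussian, sigma_xyz: [2.0, 2.0, 1.5]}
  threshold: 2000
NG2:
  prefilter: {kind: median, radius: 2}
  threshold: 5500
IBA1:
  prefilter: {kind: median, radius: 2}
  threshold: 2000
DCX:
  prefilter: {kind: gaussian, sigma_xyz: [2.0, 2.0, 1.5]}
  threshold: 2500
HOPX:
  prefilter: {kind: gaussian, sigma_xyz: [2.0, 2.0, 1.5]}
  threshold: 2200
SOX2:
  prefilter: {kind: gaussian, sigma_xyz: [2.0, 2.0, 1.5]}
  threshold: 1600
PV:
  prefilter: {kind: gaussian, sigma_xyz: [2.0, 2.0, 1.5]}
  threshold: 4300
ARC:
  prefilter: {kind: gaussian, sigma_xyz: [2.0, 2.0, 1.5]}
  threshold: 2500
  particle_min_area_um2: 25.0
  particle_projection: true
KI67:
  prefilter: {kind: gaussian, sigma_xyz: [2.0, 2.0, 1.5]}
  threshold: 2000
  particle_min_area_um2: 15.0
  particle_projection: true
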