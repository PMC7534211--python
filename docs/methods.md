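# Methods

## Scope and model

`osteoflow` is the computational counterpart of a low-shear perfusion
experiment on human mesenchymal stem cells (hMSC): cells cultured on the
inner wall of a 560 µm borosilicate capillary (a biomimetic stand-in
for a trabecular-bone pore) or in a conventional parallel-plate flow
chamber (PPFC), exposed to ~10 mPa wall shear or kept static, then
imaged by confocal microscopy (DAPI / phalloidin / Runx-2) and scored
per cell for nuclear Runx-2 intensity and for the spatial organisation
of the actin cytoskeleton via grey-level co-occurrence (Haralick)
texture. The package covers four stages: shear design, synthetic image
generation, per-cell quantification, and group statistics.

## Shear design

Fully developed laminar flow is assumed in both devices.

* Capillary (Hagen–Poiseuille wall shear): τ = 32 Q µ / (π d³).
* PPFC (plane-Poiseuille wall shear between wide plates):
  τ = 6 Q µ / (w h²), valid for h ≪ w; a warning is raised when
  h/w > 0.2.

At the experiment's operating conditions (µ = 1.0 mPa·s) the capillary
at 10 µl/min gives τ = 9.67 mPa and the 5 mm × 200 µm chamber at
20 µl/min gives τ = 10.0 mPa — both 10 mPa to the nearest mPa, and
both deeply laminar (Re < 1). `flow_rate_for_fss` is the exact
algebraic inverse; round trips recover the target shear to 1e-12
relative tolerance.

The medium's dynamic viscosity is not a measured quantity here; the
default 1.0 mPa·s (≈ water / culture medium at 37 °C) and density
1000 kg/m³ are configurable. Entrance-length effects and
non-Newtonian rheology are out of scope.

## Synthetic scenes

No raw images from this kind of experiment are publicly available, so
every downstream stage is validated on generated scenes with exact
ground truth. A scene is a three-channel z-stack (defaults: 1024 ×
1024 px, 20 planes at 5 µm spacing, ~1.14 µm/px as for a 10×
objective; tests and the bundled demo configs use smaller fields purely
for speed). Cells are placed by rejection sampling with a minimum
centre separation and bounded retries (deterministic given the seed;
infeasible requests raise a placement error naming the constraint).
Each cell has a circular cytoplasm, an elliptical nucleus, an integer
nuclear Runx-2 level drawn per group, and one of two actin phenotypes:

* **homogeneous_filaments** — many thin, aligned filaments spread over
  the whole cytoplasm. At 10× these structures are at or below the
  resolution limit, so the renderer uses a high filament density
  (150 chords, 1 px) with a 1.6 px Gaussian blur: they blend into a
  nearly smooth texture, as in the pre-osteogenic state.
* **peripheral_stress_fibres** — a few (4) thick (4 px), bright arcs
  confined to the outer quarter of the cell radius, over a dimmer
  interior with sparse thin filament remnants. These stay resolved and
  produce strong local intensity variation, as in the osteogenic state.

Both phenotypes are rescaled to the same whole-cell mean intensity
(matched to < 2 %), so texture differences downstream reflect spatial
organisation rather than brightness. The quantitative renderer
parameters (counts, thicknesses, relative intensities) are modelling
choices — no counterpart numbers exist for the real cells — and are
all exposed on `PhenotypeSpec`.

Axially, each cell's signal follows a Gaussian profile (sd 1.5 planes)
normalised to peak weight exactly 1, so a maximum-intensity projection
of a noiseless stack recovers the ideal 2-D image exactly; this is what
makes intensity ground truth exactly recoverable. Noise is scaled
Poisson shot noise plus additive Gaussian read noise (sd 8) plus a
flat background (100), applied per plane; output is clipped 16-bit
unsigned. What the generator does *not* model: optical PSF blur,
spectral bleed-through, photobleaching, autofluorescence gradients,
3-D filament geometry. Tests passing on these scenes therefore show
the pipeline's correctness under idealised confocal statistics, not
robustness to every real-world artefact.

## Projection and segmentation

Maximum-intensity projection per channel, then: Gaussian smoothing
(σ = 1 px) → global Otsu (or fixed) threshold on DAPI → connected
components → watershed declumping on the distance transform (markers
from `peak_local_max`, ties broken by scan order) → speck removal.
Candidates are then filtered by four explicit rules replacing manual
curation: border contact; area outside [50, 2500] px; solidity < 0.85;
and mutual proximity (masks dilated by 3 px intersecting another
object — both partners removed). Every decision is recorded with a
reason in a QC report. Surviving labels are renumbered contiguously in
centroid (row, col) order, which makes the whole chain deterministic.

Cytoplasm is assigned by seeded propagation: phalloidin foreground is
thresholded and each foreground pixel is claimed by the nucleus
reachable at lowest cost over a surface mixing geometric distance and
inverse actin intensity (weight λ = 0.05 on the geometric term),
implemented as a marker-controlled watershed. Cytoplasm label k always
contains nucleus k; disconnected foreground stays unassigned. One
non-obvious choice: the foreground threshold is the *lowest* cut of a
three-class Otsu rather than the classic two-class one. With bright
stress fibres present the phalloidin histogram is trimodal
(background / diffuse cytoplasm / fibres) and a bimodal Otsu lands
between cytoplasm and fibres, discarding the dim interior entirely;
the three-class variant separates background from all cell signal.
`cytoplasm_threshold_classes = 2` restores the classic behaviour.

Thresholding, smoothing and declumping settings are explicit
configuration — the analysis they stand in for was semi-manual and its
settings unrecorded — so defaults are documented stand-ins, not
reconstructions.

## Texture and intensity measurement

Per cell, the phalloidin projection is quantized over the cytoplasm
mask by linear min–max rescaling onto g = 8 grey levels (constant
regions map to level 0). The GLCM counts ordered pairs (p, p+Δ) with
*both* endpoints inside the mask, symmetrised, normalised by the pair
count; a zero pair count marks the matrix degenerate and the cell is
flagged rather than scored. Features:

* contrast = Σ (i−j)² p(i,j)
* entropy = −Σ p(i,j) log₂ p(i,j) (bits; 0·log 0 ≡ 0)

computed at the four standard directions {(0,d),(d,0),(d,d),(d,−d)}
with d = 3 px and averaged; per-direction values are also emitted.
g and d are common defaults in cell-image analysis software, recorded
in output metadata, and configurable. Per-object quantization makes
both features exactly invariant to affine intensity rescaling; a
whole-image quantization mode exists for sensitivity checks. Nuclear
Runx-2 is summarised as the mean over nucleus pixels (primary) and the
integrated sum (secondary), since either convention is defensible for
semi-quantitative immunofluorescence.

## Group statistics

Four groups (capillary/PPFC × static/perfused), replication unit = the
biological sample: cells are averaged within each sample before
testing because cells sharing a device are not independent (a per-cell
mode exists but is labelled pseudo-replication in its output). Donor
is pooled, matching the n = 6 design of three samples from each of two
donors; a donor-blocked model is a known limitation, not implemented.
One-way ANOVA uses classical between/within mean squares with
(k−1, N−k) df; the all-identical degenerate case is defined as F = 0,
p = 1 (and zero within-variance with unequal means as F = ∞, p = 0).
Tukey HSD uses the studentized-range distribution with the
Tukey–Kramer standard error, so unbalanced designs are handled;
adjusted p-values match `statsmodels` to machine precision in the
cross-check tests. α = 0.05 by default. The plain-text report marks
geometry contrasts (capillary vs PPFC at matched flow) with `#` and
flow contrasts (perfused vs static within a geometry) with `*`.

## Pipeline and determinism

`run_experiment` generates n samples per group (default 6), each a
scene whose seed derives from the run seed via `SeedSequence` spawning
(stable across platforms, < 2³¹), quantifies every stack, pools the
per-cell table and runs the comparison; a manifest records a SHA-256
config hash, package version and outputs. Identical config + seed
yields bit-identical stacks and byte-identical CSVs. Group-level
defaults encode the qualitative outcome the system is designed to
detect — elevated Runx-2 and peripheral stress fibres in the perfused
capillary group, weak PPFC response — plus a between-sample sd of 100
intensity units representing biological replicate variability; these
are generative settings, not measurements.

## Validation strategy and problem sizes

All expected values in the tests come from independent oracles:
hand-enumerated GLCMs, an exhaustive check over all 512 binary 3×3
images, `skimage.feature.graycomatrix` as an independent reference
implementation, manual sums of squares for ANOVA, `statsmodels` for
Tukey, and generator ground truth for segmentation/intensity recovery.
Simulation-based checks use fixed seeds: type-I error of the all-null
design over 1000 seeds, power of the capillary-flow contrast over 200
seeds (at measurement level; image rendering for thousands of scenes
would add nothing to what the exact-recovery tests already establish),
segmentation recovery over scenes of 1–20 cells at 640² px, and texture
phenotype separation over 30 cells per phenotype. Test scenes use
256²–640² fields rather than the 1024² acquisition default; all
pipeline behaviour is resolution-independent apart from the documented
area thresholds.

## Known limitations

* Segmentation thresholds are tuned for the generator's contrast
  regime; real stacks with uneven illumination would need the fixed- or
  multi-class threshold options and possibly illumination correction
  (out of scope).
* The two phenotypes are rendered as 2-D projections; no 3-D filament
  geometry exists to project.
* The peripheral phenotype's ground-truth cytoplasm extends beyond the
  propagated mask where the interior falls below the foreground
  threshold (Jaccard ≈ 0.7 on noisy scenes vs ≈ 1.0 for the
  homogeneous phenotype); texture is measured on the recovered mask.
* Only contrast and entropy are implemented; the remaining classic
  Haralick features and filament morphometrics are deliberately
  excluded.
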