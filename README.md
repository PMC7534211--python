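# osteoflow

Shear-stress design and per-cell confocal image quantification for
low-shear perfusion experiments on human mesenchymal stem cells
(hMSC), where flow through a 560 µm glass capillary mimics the wall
shear a cell experiences inside a trabecular-bone pore.

The package is aimed at tissue-engineering and mechanobiology groups
who need to (1) pick flow rates that deliver a target wall shear
stress in a capillary tube or a parallel-plate flow chamber (PPFC),
and (2) quantify the cellular response — nuclear Runx-2 intensity and
actin network organisation — from three-channel confocal stacks
(DAPI / phalloidin / Runx-2), per cell and with defensible statistics.
Because no public datasets exist for this assay, the package includes
a synthetic scene generator with exact ground truth that exercises the
whole pipeline end to end.

## The core calculations

Wall shear stress τ under laminar flow, with Q the volumetric flow
rate, µ the dynamic viscosity:

* capillary of inner diameter d: τ = 32 Q µ / (π d³)
* PPFC of width w and height h (h ≪ w): τ = 6 Q µ / (w h²)

Actin texture uses the grey-level co-occurrence matrix p(i, j) of the
cytoplasm region (8 levels, distance 3 px, four directions averaged):

* contrast = Σ (i−j)² p(i, j) — local intensity variation; high for
  a few thick, bright stress fibres at the cell periphery
* entropy = −Σ p(i, j) log₂ p(i, j) — pair complexity in bits; low
  for a smooth, homogeneous filament meshwork

Nuclear marker intensity is the mean Runx-2 fluorescence over each
nucleus. Groups (capillary/PPFC × static/perfused) are compared by
one-way ANOVA with Tukey HSD on per-sample means (cells averaged
within each sample).

## Worked example

Design: what shear does the capillary see at 10 µl/min, and what flow
rate does the chamber need for 10 mPa?

```sh
$ osteoflow design --geometry capillary --flow-ul-min 10
quantity               value
geometry           capillary
Q (ul/min)            10.000
tau (mPa)              9.667
Re                    0.3789
laminar                 True

$ osteoflow design --geometry ppfc --target-fss-mpa 10
quantity               value
geometry                ppfc
Q (ul/min)            20.000
tau (mPa)             10.000
Re                    0.1282
laminar                 True
```

So 10 µl/min in the capillary and 20 µl/min in the chamber both
deliver 10 mPa (to the nearest mPa) at medium viscosity 1.0 mPa·s,
with Reynolds numbers far below the laminar limit.

Full in-silico experiment (simulate four groups → segment and measure
every cell → compare groups):

```sh
$ cat run.yaml
n_samples_per_group: 4
scene:
  image_size: [320, 320]
  n_cells: 5
  min_cell_separation: 90

$ osteoflow run --config run.yaml --seed 42 --out-dir demo_run
runx2_mean: F = 7.781, p = 0.003781 (alpha = 0.05, unit = sample)
  cap_static - cap_flow: diff = -392.6, p_adj = 0.01339 [significant] *
  ppfc_flow - cap_flow: diff = -411.5, p_adj = 0.009785 [significant] #
  ...
contrast: F = 122.365, p = 2.91e-09 (alpha = 0.05, unit = sample)
  cap_static - cap_flow: diff = -2.913, p_adj = 1.245e-08 [significant] *
  ...
```

Read: the perfused-capillary group has nuclear Runx-2 about 390
intensity units above its static control (`*` marks perfused-vs-static
pairs, `#` marks capillary-vs-PPFC pairs), and its actin contrast is
higher by ~2.9 — the peripheral-stress-fibre phenotype given to that
group in the default configuration is detected through the full
imaging and measurement chain. `demo_run/` holds the per-cell CSV,
ANOVA and Tukey tables, the shear-design report and a provenance
manifest.

The same stages are available individually (`simulate`, `quantify`,
`compare`) and as library functions (`osteoflow.generate_scene`,
`osteoflow.segment_projection`, `osteoflow.measure_cells`,
`osteoflow.compare_groups`).

## Layout

| module | contents |
| --- | --- |
| `osteoflow.geometry` | shear formulas, inverse solver, Reynolds checks |
| `osteoflow.synthetic` | scene generator, phenotype renderer, ground truth |
| `osteoflow.segmentation` | projection, nucleus detection, QC filter, cytoplasm propagation |
| `osteoflow.texture` | masked GLCM, Haralick contrast/entropy, per-cell measurement |
| `osteoflow.stats` | one-way ANOVA, Tukey HSD, group comparison |
| `osteoflow.pipeline` | end-to-end runs, config, manifest |
| `osteoflow.cli` | `osteoflow` command-line interface |

Modelling assumptions, parameter defaults and validation strategy are
documented in `docs/methods.md`.
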