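# mitomorph

Automated per-cell quantification of mitochondrial fragmentation in
live-cell fluorescence microscopy.

Mitochondria shift between long tubular networks (fusion-dominated) and
many small punctate organelles (fission-dominated); the balance is a
sensitive readout of cell stress, e.g. in keratinocytes exposed to UVB.
`mitomorph` turns three-channel confocal fields — a nuclear stain, a
plasma-membrane stain, and a mitochondrial stain — into per-cell shape
statistics and condition-level significance tests, for screening settings
where visual scoring is too slow and too subjective.

## What it measures

Each field is partitioned into cells by a seeded watershed: nuclei are
segmented from the nuclear channel (Gaussian smoothing → Otsu → hole
filling → distance-transform watershed at h-maxima) and used as seeds on
the membrane channel, whose bright ridges form the basin boundaries.
Alternatively, a user-drawn cell-label mask can be supplied ("semi-manual"
mode). Within each cell the mitochondrial channel is background-subtracted
(white top-hat), binarized with a per-cell Otsu threshold, and split into
connected components ("particles"). Each particle *P* gets two descriptors:

- **circularity** `C = 4π·A(P) / P(P)²`, with the perimeter estimated by the
  4-direction Crofton formula and C clamped at 1 — equal to 1 for a circle
  and approaching 0 for elongated or branched shapes;
- **aspect ratio** `AR = a/b ≥ 1`, the axis ratio of the moment-equivalent
  ellipse (the ellipse with the same second central moments as the particle,
  each pixel modeled as a unit square so that single pixels stay finite).

Fragmentation raises circularity and lowers aspect ratio. The unit of
analysis is the cell: particle descriptors are averaged per cell, cells are
summarized per condition as mean ± SD, and conditions are compared with
two-sided Welch t-tests (stars at p < 0.05 / 0.01 / 0.001).

Because real annotated data are rarely available, the package ships a
synthetic-field generator with full ground truth: disjoint polygonal cells
with nuclei, per-cell mitochondrial skeletons spanning a hyperfused-to-
punctate axis via a single fragmentation parameter `f ∈ [0, 1]`, and an
imaging model (Gaussian PSF, Poisson shot noise, Gaussian read noise,
camera offset). Every pipeline stage is validated end-to-end against it.

## Worked example

Simulate a control-like and a fragmented condition (three single-cell
fields each), then analyze them in automatic mode:

```sh
mitomorph simulate --out control --n-fields 3 --n-cells 1 \
    --fragmentation 0.15 --condition control --seed 1
mitomorph simulate --out uvb --n-fields 3 --n-cells 1 \
    --fragmentation 0.75 --condition uvb --seed 31
# merge the two per-condition manifests into manifest.csv, then:
mitomorph analyze manifest.csv --out results
```

The run log reports per-image bookkeeping, e.g.
`uvb/field_000.tif [uvb]: 1 cells, 31 particles`, and `results/` receives
four CSVs. `conditions.csv`:

```
condition,n_cells,circularity_mean,circularity_sd,aspect_ratio_mean,aspect_ratio_sd
control,3,0.417849,0.00957689,4.86635,0.199174
uvb,3,0.751664,0.0102722,2.12363,0.0500698
```

and `comparisons.csv`:

```
descriptor,group_a,group_b,n_a,n_b,t_stat,p_value,stars
mean_circularity,control,uvb,3,3,-41.1693,2.19017e-06,***
mean_aspect_ratio,control,uvb,3,3,23.1314,0.00100518,**
```

The fragmented condition's cells have mean circularity 0.75 versus 0.42 in
the control and mean aspect ratio 2.12 versus 4.87 — the punctate phenotype
— and both shifts are significant even at three cells per condition.
`particles.csv` and `cells.csv` carry the per-particle and per-cell detail;
`run_manifest.json` snapshots config, inputs and versions so the run can be
reproduced exactly.

The same experiment is available programmatically:

```python
from mitomorph.experiments import two_condition_experiment, descriptor_significance

control, fragmented = two_condition_experiment(cells_per_condition=30)
print(descriptor_significance(control, fragmented)["mean_circularity"])
```

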