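# organoquant

Semi-automated quantification of fluorescence microscopy for kidney-organoid
and endothelial-monolayer experiments: organoid-body immunofluorescence
intensity (APOL1, GSDMD, …), CD31⁺ vessel-network density with exclusion of
spurious small components, stromal-vessel intensity, longitudinal
per-organoid PODXL-GFP tracking, nuclear density and per-cell intensity in
monolayers — together with a ground-truthed synthetic-microscopy generator
and the normalization + ANOVA/Tukey statistics layer that turns pixel
measurements into condition comparisons.

It is written for bench scientists and image analysts who quantify
interferon-driven phenotypes (APOL1 induction, endothelial network
degradation, podocyte reporter loss) from confocal z-stacks and widefield
planes, and who need those measurements reproducible, scripted and tested
rather than buried in one-off ImageJ macros.

## The measurement model

Every assay follows the same chain. A multi-channel z-stack *I(c, z, y, x)*
is collapsed to its maximum intensity projection

> P(y, x) = max₂ I(c, z, y, x),

the per-staining-set background *b* is the mean over the set's images of
each image's minimum pixel intensity, and quantification happens on
max(P − b, 0) within a region: a manually traced organoid-body polygon
(pixel-center rasterization), or a thresholded binary (pixel ≥ t; t from
config or Otsu, always logged). Connected components use 8-connectivity;
for stromal vessel measurements, network components with area < 2,000 μm²
are removed as spurious noise, and an organoid whose retained stromal
network does not exceed 2,000 μm² is excluded rather than measured.
Per-condition values are normalized to the control-condition mean (so the
control group averages exactly 1); time-course metrics are normalized to
each organoid's own day-0 value. Groups are compared with two-tailed Welch
t tests or one-way ANOVA with Tukey HSD (studentized-range) post hoc
families, reported as mean ± SD and median/quartiles with the
`*/**/***/****` significance convention.

Because raw microscopy of this kind is rarely deposited, the package ships
a generator that renders the whole scene — elliptical organoid body with
LTL⁺ tubules and PODXL⁺ tufts, a branching CD31⁺ network grown to a target
coverage split between interior and stroma, DAPI nuclei, per-condition
channel multipliers (the interferon preset raises the target channel 1.5×),
additive background and Poisson + Gaussian camera noise — and exports every
ground-truth mask, so each assay is validated by parameter recovery rather
than by eye.

## Worked example

The numbered scripts under `analysis/` run the full study on a rendered
two-arm dataset (control vs interferon-stimulated, with the stimulated arm
losing vessels, GFP signal and endothelial nuclei):

```sh
python analysis/01_generate_fixtures.py --seed 1 --n-per-condition 4
python analysis/02_quantify_assays.py
python analysis/03_group_statistics.py
python analysis/04_recovery_benchmarks.py --seed 1 --n-per-arm 10
```

Step 02 prints the per-set backgrounds it estimated and writes the tidy
record table (`results/records.csv`, one row per image × metric):

```
quantified 40 images -> 120 records
  background[set1/APOL1] = 17.913623
  background[set_tc/GFP] = 17.821597
  background[set_mono/APOL1] = 4.65045
```

Step 03 runs one Tukey family per metric (per day for time-course metrics)
on the normalized values. In this dataset the interferon arm shows the
expected phenotype — higher APOL1 everywhere, lower network density, faster
GFP loss (`estimate` is the control-minus-treated difference of normalized
means):

```
  per_cell_APOL1: IFNg vs control diff=-0.434 p_adj=0.00e+00 ****
  network_density_total: IFNg vs control diff=+0.350 p_adj=0.00e+00 ****
  stromal_vessel_APOL1: IFNg vs control diff=-0.476 p_adj=0.00e+00 ****
  mean_APOL1: IFNg vs control diff=-0.474 p_adj=0.00e+00 ****
  integrated_GFP: IFNg vs control diff=+0.521 p_adj=1.71e-08 ****
```

Step 04 benchmarks the pipeline against the generator's ground truth:
configured target-channel multipliers of 1.25/1.5/2.0 are recovered as
treated/control intensity ratios 1.236/1.474/1.947 over 10 organoids per
arm at default noise; rendered vessel coverages of 5/12/25 % come back
within 10⁻⁴ absolute; nuclear particle counts match truth exactly at 50–300
nuclei per field; and a configured 0.7-per-session GFP decay is recovered
as 1.00 / 0.72 / 0.53 against the ideal 1.00 / 0.70 / 0.49.

The same pipeline is scriptable through a CLI
(`organoquant generate|quantify|stats|run-all --seed … --out …`), whose
seeded runs are byte-identical end to end.

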