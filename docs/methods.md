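# Methods

## Measurement procedures

**Projection and background.** All quantification happens on maximum
intensity projections of the acquired z-stacks; projection always precedes
background subtraction. The background of a staining set — the batch of
images stained and imaged together, identified by the manifest's `set_id`
column — is the arithmetic mean over the set's images of each image's
minimum pixel intensity, computed per channel. Subtraction clips at zero,
so intensities stay non-negative. Whether the original macro-based
workflows shared one background across channels is not knowable from the
outside; per-(set, channel) is this package's convention.

**Regions.** Manual traces are simple closed polygons (ImageJ `.roi`/`.zip`
or GeoJSON, pixel coordinates, 0-based, (x, y) vertex order). A pixel
belongs to a polygon mask when its center lies inside or on the boundary.
A trace that misses the image entirely produces an empty mask and a logged
warning rather than an error, so one mis-registered ROI cannot abort a
batch; assays that then receive an empty mask fail per image. Thresholding
uses `pixel ≥ t` (ties foreground). Where an operator would have chosen a
threshold by eye per replicate, the pipeline takes an explicit value from
configuration or, failing that, Otsu's threshold on the projected plane;
either way the value used is recorded in the run's provenance header —
reproducibility is preferred over fidelity to an unrecorded human choice.

**Components and the spurious-area rule.** Connected components use
8-connectivity (the particle-analysis convention for contiguous
structures). The stromal-vessel intensity measurement removes network
components with area strictly below 2,000 μm²; a component of exactly
2,000 μm² survives, because only areas *less than* the cutoff are spurious.
The total network density is measured on the unfiltered binary; the filter
applies only where small stromal fragments would contaminate an intensity
average. An organoid whose retained stromal network area does not exceed
2,000 μm² is flagged excluded instead of contributing a value.

**Densities.** "Network density" is an area fraction: CD31⁺ mask area over
the area of the acquired region of interest (which contains a single
organoid), and, for the stromal compartment, stromal CD31⁺ area over the
field-minus-organoid area. Fractions are comparable across fields of
different sizes; the absolute areas are also emitted (`network_area_*_um2`)
for workflows that want them.

**Monolayers.** Nuclei are DAPI connected components with areas inside
[20, 500] μm² (defaults; configurable) counted per mm² — touching nuclei
stay merged, as no declumping is performed. The cell body is approximated
by dilating each retained nuclear mask by 5 μm (default; configurable and
logged), and per-cell target intensity is the mean background-subtracted
signal inside the dilated union. Junctional CD31 is the area fraction above
one uniform global threshold set high enough to exclude the dimmer
intracellular staining; that threshold is a config value, not Otsu, because
the bimodality is between two positive stain compartments.

**Normalization and summaries.** Non-timecourse metrics divide by the mean
raw value of the control condition within a normalization group — default
(assay, metric, replicate), mirroring per-replicate staining sets — which
makes every control group's normalized mean exactly 1. Time-course metrics
divide by the same organoid's day-0 value instead, which makes them
invariant to any global intensity rescaling. Well-level reporting averages
the (typically 4) fields of a culture well. Comparisons use a hand-computed
one-way fixed-effects ANOVA with Tukey–Kramer adjusted pairwise p-values
from the studentized-range distribution, a Welch two-tailed t test for
two-group designs (unequal variances are the norm between treatment arms),
and a type-II two-way ANOVA (via statsmodels) for factorial layouts, with
star tiers at p < 0.05/0.01/0.001/0.0001. No correction is applied across
metrics; the family is the set of pairwise comparisons within one metric.

## The synthetic scene

The generator emulates the statistical structure the assays rely on, not
optics. One field is a 384 × 384 px scene at 1.0 μm/px (a desk-scale choice;
objective pixel sizes vary by instrument and are configurable) with 10
z-slices at 10 μm — the geometry of a 100 μm stack. Fluorescent signal
follows a peaked depth profile whose maximum slice weight is exactly 1, so
the noiseless projection returns the 2-D scene; background (default 20
intensity units) is uniform across depth.

The scene contains: an elliptical organoid body (default semi-axes
90 × 70 μm) holding random-walk LTL⁺ tubule tubes and four 15 μm PODXL⁺
tufts; a CD31⁺ network of branching random-walk tubes (6 μm wide) grown
until a target coverage fraction of the field (default 0.12) is met, seeded
inside the body with probability 0.35 and in the stroma otherwise; and DAPI
nuclei (4 μm radius, ≥ 12 μm separation). The target channel (APOL1 by
default) renders at base × condition-multiplier inside the cellular masks;
the interferon preset multiplier is 1.5, i.e. a 50 % induction, with the
multiplier table fully configurable per condition. Noise is Poisson shot
noise at a 0.5 gain plus Gaussian read noise (σ = 2), applied per slice —
the standard fluorescence-camera model; the real acquisition's noise
parameters are unknown, and the assays only need to be robust to a
plausible one.

Channel bases sit near 100–150 intensity units except the live PODXL-GFP
reporter, which renders at 800: an integrated-intensity time course is only
meaningful when in-trace signal dominates the residual projected
background (maximum-projection of noisy background slices sits a few units
above the estimated set background), and a live GFP reporter is in reality
far brighter than immunostains. Time-course rendering scales the GFP
channel by decayᵏ at the k-th imaging session, optionally shrinks the body
ellipse (area factor per session) and applies a vessel retention factor;
the per-day trace polygon is exported with each stack. Monolayer fields
render nuclei as disks, a cytoplasmic target-channel halo (dilated nuclei),
and CD31 as bright watershed-cell boundaries (200) over a dim intracellular
fill (40), so a global threshold of 100 isolates the junctional
compartment exactly.

All randomness flows from one seed through named, order-stable Philox
substreams (body, tubules, tufts, vessels, nuclei, noise); identical
(config, seed, condition) is bit-identical. Ground truth accompanies every
field: object masks, vessel component areas and compartments, nuclei
centers, noiseless channel fields and the realized multipliers.

### What the generator does not emulate

No point-spread function, spectral bleed-through, flat-field error,
stage drift between sessions, nuclear declumping challenges (nuclei are
placed with a minimum separation) or photobleaching beyond the configured
per-session decay. Passing recovery tests therefore demonstrates that the
measurement chain is correct and calibrated on images with known answers —
not that it is robust to every artifact of real acquisitions.

## Problem sizes and numerical choices

Recovery benchmarks use 20 organoids per arm for effect-ratio recovery
(multipliers 1.25/1.5/2.0), 3 fields per arm for vessel-coverage
(0.05/0.12/0.25) and retention (1.0/0.7/0.4) arms, monolayers of 50–300
nuclei, 3 time-course series, and 5,000 replicates for the ANOVA type-I
calibration — sizes at which every recovered quantity is comfortably
resolved on a single CPU in about a minute. Primitive-level fidelity is
established separately: each pixel statistic agrees with naive loop oracles
to 10⁻⁹ relative on random 64 × 64 instances, so the simulation sizes only
need to resolve statistical, not numerical, error.

Degenerate inputs are contracts, not surprises: empty masks make mean
intensity an error and integrated intensity 0; Otsu on a constant plane is
an error; a missing time point drops the series with a warning rather than
interpolating; a normalization group that lost every control record to the
stromal exclusion is left unnormalized with a warning in pipeline runs
(and is an error when calling the library function directly). ANOVA with
zero within-group variance is undefined and such families are skipped with
a warning by the comparison driver. Tukey p-values use the exact
studentized-range survival function; the F statistic matches reference
implementations to 10⁻¹⁰, which is also the bar the tests hold the Welch t
to.

## Design choices that were genuinely open

- Welch rather than pooled t: treatment arms routinely differ in variance.
- Density as an area fraction rather than an absolute area: comparable
  across fields; absolute areas are still emitted.
- The stromal denominator is field area minus organoid-trace area.
- Backgrounds per (set, channel); sets are declared in the manifest.
- The area-filter boundary keeps exact ties (only "less than" is excluded).
- A polygon fully outside the image warns and yields an empty mask so batch
  runs survive mis-registered traces.
- Normalization groups default to (assay, metric, replicate); `set_id` is
  carried through so users can stratify by staining batch instead.
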