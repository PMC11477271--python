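# Methods

## Synthetic scenes and what they emulate

All validation rests on generated scenes with exact ground truth
(`nquant.synthetic`). The forward model is the usual widefield/confocal
chain: binary rasterization of the geometry (no anti-aliasing, so truth
masks are exact pixel sets) → Gaussian PSF blur (`psf_sigma`, default
1 px) → Poisson shot noise at `poisson_scale` photons per intensity unit
(default 1) → additive Gaussian read noise (`read_noise_sigma`, default
2). Defaults put the foreground (`signal_level` 180 over a
`background_level` of 20) at high SNR, comparable to a well-exposed
fixed-cell acquisition. One `numpy` Generator is derived per scene from
`ImagingParams.seed`, with deterministic per-channel substreams, so
identical parameters give bit-identical scenes.

Three scene families:

- **Neuron-like cells**: a soma disk, polyline neurites of fixed width
  whose first vertex must sit on the soma boundary, and short spine
  segments anchored on a neurite. Truth per cell: the soma disk, the
  neurite compartment (cell minus soma, so soma ⊎ neurites = cell holds
  exactly), and the spine centre lines. Default study-like morphology:
  soma radius ~10 px, neurite width 3 px, spines 6–12 px.
- **PLA fields**: non-overlapping nuclei disks (radius ~16–18 px) and
  small non-overlapping punctae (radius 2 px) placed by bounded rejection
  sampling (an error is raised if the requested packing cannot be met).
- **Wound series**: a confluent monolayer of disk "cells" carrying
  spatially correlated multiplicative speckle (correlation length 1.5 px,
  just above the PSF so blurring does not flatten it), with an exact
  integer-width cell-free vertical band of width
  `max(0, initial_gap − rate·t)` per frame. Density default 0.035
  cells/px² makes the field genuinely confluent.

What the generator does *not* emulate: realistic intracellular texture,
touching/overlapping cells, 3-D stacks (2-D projections only), uneven
illumination, stage drift. Tests passing on these scenes therefore
demonstrate correctness of the measurement operators under known
geometry and a standard noise model, not robustness to every artefact of
real acquisitions.

## Segmentation and morphometry

Foreground thresholding uses the half-maximum point between a robust
background estimate (5th percentile of the smoothed image) and a robust
peak estimate (99.9th percentile), after Gaussian smoothing (sigma 1 px).
We chose half-max over histogram-shape criteria (Otsu is available via
`threshold_method="otsu"`) because sparse fields with thin neurites have
extreme class imbalance: the Otsu cut settles far below the half-max
level and inflates a halo around 3-px neurites (measured minimum Jaccard
0.74 vs truth over the noisy validation suite, against 0.98 for
half-max). Holes are filled; components below `min_cell_area` (default
200 px) are dropped; touching-cell splitting is not attempted.

The soma is recovered by a **Euclidean opening**: cell pixels whose exact
Euclidean distance to background exceeds `soma_opening_radius` form the
core; the largest connected core is dilated by the same radius (again via
EDT) and intersected with the cell. This is the disk opening computed
with exact distances; the raster-disk structuring element loses a large
boundary ring whenever the opening radius comes within ~1 px of the soma
radius, while the EDT form reconstructs a rasterized disk of radius R
exactly when the radius matches. A closing with a 2-px disk regularises
the boundary first (single-pixel noise dents otherwise truncate the
distance transform); the soma always remains a subset of the input mask,
so soma and neurites exactly partition the cell.

Choosing the opening radius: it must exceed the neurite half-width and
sit safely below the smallest expected soma radius — we use 7 px as the
package default (somas ~10 px) and 5 px in suites whose smallest somas
are 8 px. On noise-free scenes with the radius matched to the generated
soma, recovery is pixel-exact; with the default noise the neurite/cell
ratio tracks truth to within ~0.02.

Both ratio variants are computed (neurite/cell and neurite/soma) because
both conventions appear in practice; neurite/cell is the default report.
Intensity measurements report region mean and integrated intensity with a
background estimate (5th percentile of the image, or the outside-mask
mean) and floor corrected values at zero.

## Spine skeleton graphs

Neurite masks are thinned with `skimage.morphology.skeletonize`
(8-connected, unit width). Node pixels are those with one neighbour
(endpoints) or three or more (junctions); adjacent node pixels merge into
one junction cluster anchored at the pixel nearest the cluster centroid.
Edges are traced along degree-2 chains and extended through the cluster
to its anchor, so lengths measure crossing-to-crossing geodesics: 1 per
axial step, √2 per diagonal. A straight 10-pixel line is one edge of
length 9; every edge length equals the brute-force shortest-path distance
between its terminal pixels over the raw pixel graph (property-tested).

The **main axis** is the longest endpoint-to-endpoint geodesic; edges off
it are side branches. Spine-like branches are those with length in
`[min_spine_length, max_spine_length]` (defaults 2 and 30 px: shorter are
thinning spurs, longer are daughter neurites). The "relative" branch
count is branches per unit main-axis length, making arbors of different
sizes comparable before any fold-change normalisation; the denominator
choice is a convention of this package. Lengths are emitted in both px
and µm (via `pixel_size`).

## Wound detection and the closure model

The texture map is the windowed standard deviation (uniform window,
default 15 px). Pixels below the Otsu cut of the texture map are
"low texture"; the wound is the largest connected low-texture component,
dilated by the window half-width (the windowed statistic erodes the true
band by ~window/2 on each side, since pixels whose window straddles the
edge already see cell texture). A wound is only accepted when the split
is genuine: the low class's mean texture must be below 0.3× the high
class's, otherwise a confluent (unimodal-texture) field would percolate
into a spurious giant "wound". Accuracy on synthetic series: ~4–8%
relative area error for bands of 60–100 px at the default window; bands
narrower than ~2× the window approach the method's resolution limit and
may be rejected by the contrast guard — use a smaller window there.

Closure series are normalised to the first frame
(`percent(t) = 100·area(t)/area(0)`, so percent(0) = 100 exactly) and
modelled with

```
percent ~ 1 + time + group + group:time + (1 | replicate),  REML
```

via `statsmodels` MixedLM. The random effect is a per-replicate intercept
(random slopes are a flag). Group contrasts vs the reference are Wald t
tests on the interaction using within-replicate degrees of freedom
`n_obs − n_replicates − n_time_terms` (Pinheiro–Bates level-1 df; for the
balanced designs used here this equals lmerTest's Satterthwaite df, which
we verified against lme4 on a seeded dataset — estimates and SEs agree to
machine precision). Bonferroni correction is applied over the
non-reference groups. Calibration at study scale (8 replicates/group,
times 0/22/45 h, σ_u = 2, σ_ε = 3 %): 95% CI coverage of the true slope
difference ≈ 0.94 over 200 simulations; null rejection ≈ 0.05–0.06 over
1000. With zero replicate variance the fit collapses onto OLS
(coefficients agree to 1e-6).

## PLA / RDNAR

Nuclei: smoothed Otsu, hole fill, minimum-area filter (default 50 px);
an image without nuclei is an error because the ratio is undefined.
Dots: the response `−LoG(image, σ=1.5 px)` thresholded by Otsu, components
kept within [3, 60] px² (zero dots is a valid result). The per-image
readout is `dnar = dot area / nuclei area` — area, not count, though the
count is also emitted. `rdnar = dnar / mean(control dnar)`, so the
control-condition mean is exactly 1 by construction; inference then uses
the one-sample t vs 1. The detection is invariant to uniform intensity
rescaling (both thresholds are data-derived). Dots are not assigned to
individual cells and nuclear vs cytoplasmic dots are not distinguished.

## Statistical workflow

Shapiro–Wilk screens each sample at α = 0.05; a failing screen logs a
warning but does not switch test families (no automatic nonparametric
fallback). Fold changes divide by the control mean, so the control's mean
fold is exactly 1 and treated groups are tested with the one-sample t
against 1 (two-sided, df = n−1). Between-group questions use the pooled-
variance Student t for two groups (Welch is a flag, off by default) or
one-way ANOVA for more. Bonferroni uses an explicit `m` (the number of
planned comparisons); it is never inferred silently from whatever
p-values happen to be present. Outlier exclusion exists only as an
explicit call implementing a documented rule (drop points > 3 scaled
MADs from the median). All tests agree with direct-formula evaluation to
1e-10 and the F test's type-I error is calibrated at ~0.05 under the
simulated null.

## Structure profiling

`gemmi` parses PDB/mmCIF; one record per polymer residue of the first
chain, B-factor from the Cα atom. AlphaFold deposits per-residue model
confidence (pLDDT) in the B-factor field; this module reports the column
verbatim (so published B-factor summaries of AlphaFold models are
reproduced) and labels the alternative reading in output metadata rather
than resolving the semantics. Domain summaries use ANKK1's kinase
(22–289) and ankyrin-repeat (361–753) spans. The haplotype table carries
H2B/H2/H1 at positions 239/318/442/490/713 with side-chain charge classes
Arg/Lys/His → `+` (His counted positive, following the convention used in
these haplotype comparisons despite partial protonation at pH 7),
Asp/Glu → `−`, else `n`. H2B's residue at 239 is not established; the
default is Ala (as in H2) and it is configurable. A synthetic 765-residue
Cα-only model generator (clearly labelled synthetic; random sequence,
smooth bounded B-factor profile) exercises the full-length parsing path
without bundling data. The real AlphaFold file, when placed in `data/`,
is checked against its published profile; model version v4 is assumed
since per-residue values can change across releases.

## Problem sizes and numerical choices

Validation suites use 160×220 to 400×400 px scenes, 20-cell morphometry
sets, 8-replicate × 3-time-point closure experiments, and 200/1000-run
simulation batches — sizes chosen so the whole suite and the acceptance
script each complete in about a minute on one CPU while keeping Monte
Carlo error well inside the asserted bands. Ties in the main-axis search
resolve by node order (deterministic); dot/nuclei thresholds are
data-derived; degenerate inputs (constant images, empty masks, zero
initial wound area, constant samples) raise informative errors rather
than returning silent zeros, except where a zero is a meaningful result
(dot counts, fully closed wounds).

## Known limitations

- Touching cells are not split; the morphometry assumes sparse fields.
- Wound detection resolves bands only down to ~2× the texture window.
- The skeleton main axis is the longest endpoint geodesic; on arbors
  whose longest side branch rivals the trunk, the axis can run into a
  branch (junction-cluster anchoring makes near-ties deterministic but
  geometry-dependent).
- The mixed model assumes registered frames and a linear mean trajectory
  over the observed window.
- Synthetic-scene fidelity limits are listed in the first section; in
  particular the noise defaults were chosen for testability, not fitted
  to any instrument.
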