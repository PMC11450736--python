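# Methods

## Scientific setting

Single extracellular vesicle nanoscopy (SEVEN) quantifies exosomes one
vesicle at a time: raw biofluid is incubated on a coverslip functionalized
with a capture antibody (anti-mouse-CD81 for the total exosome pool,
anti-human-CD81 for the pool carrying a transgenic HsCD81 tracer), the
retained vesicles are stained with AF647-conjugated anti-tetraspanin
antibodies at ~1 dye per antibody, and dSTORM imaging yields a point cloud
of localizations per field of view (ROI). Clusters of localizations are
vesicles; their localization count, divided by the mean localizations
emitted per antibody, estimates the number of detected tetraspanins
(CD9/CD63/CD81), and their spatial second moment estimates the vesicle
diameter. Counts per ROI, normalized to the incubated volume, give EV/ROI/uL
concentrations, and the ratio of tracer-specific to total concentration is
the fraction of the biofluid's exosomes contributed by the tracer-expressing
cell type.

This package implements that analysis chain for localization tables, plus a
synthetic dSTORM generator so every stage can be verified against known
ground truth — no real microscope data is required or shipped.

## Synthetic data model

Per ROI, the number of captured vesicles is Poisson with mean
`n_ev_per_roi_mean x volume_ul`; the rate is quoted per microlitre so that
incubating more biofluid deposits proportionally more vesicles, which is
what makes the EV/ROI/uL normalization meaningful. Vesicle diameters are
lognormal (median 78 nm, log-sd 0.25, matching the ~70–80 nm exosome size
range); per-species tetraspanin copy numbers are Poisson. A Bernoulli
fraction of vesicles descends from the tracer-activated cell type and
carries HsCD81 copies; all others carry none.

Capture retains a vesicle with probability `1 − (1 − p)^k`, where `k` is
its copy number of the capture species — one engaged epitope suffices, so
vesicles with zero copies are never retained.

Rendering: each copy of each stained species becomes a bound antibody with
probability `labeling_efficiency`; the antibody sits at a uniformly random
point of the vesicle sphere, orthographically projected onto the image
plane (vesicles are intact and imaged in TIRF at the coverslip). Each
antibody emits `G ~ Geometric` localizations (support ≥ 1, mean 14) —
memoryless photoswitching is the standard first-order dSTORM approximation
and only the mean is empirically constrained. Each localization is the
projected position plus isotropic Gaussian noise of `sigma_loc_nm` per
axis. Background localizations are homogeneous Poisson per ROI. Frames are
assigned consecutively per antibody burst and carried through, but
clustering is purely spatial.

Default study conditions, chosen once as realistic for this assay and not
revisited: ROI 10 um square; localization precision 10 nm; labeling
efficiency 0.7; per-epitope capture probability 0.35; background
0.5 /um^2; mouse tetraspanin copy means 8 per species, so a three-species
stain yields ~17 detected proteins per vesicle (inside the reported 10–20
range); HsCD81 tracer mean 2.5 copies, so most tracer-positive vesicles
carry fewer than four detectable tracer molecules. Neither labeling nor
capture efficiency is identifiable from published summaries, so absolute
EV/ROI/uL values are not simulation targets — only ratios and recovery
properties are.

What the generator does not emulate: camera/PSF image formation, drift,
multichannel registration, axial structure, vesicle aggregation, and
antibody cross-reactivity. Passing tests therefore validate the analysis
chain under the stated point-process model, not the upstream image
processing of a real microscope.

## Tessellation and segmentation

The Voronoi diagram of each ROI is computed with the point set augmented by
reflections across the ROI edges. For any location inside the rectangle a
reflected site is strictly farther than its original, so the original
sites' cells in the augmented diagram are exactly the box-clipped cells:
areas are exact, sum to the ROI area, and shared-edge adjacency can be read
off the diagram's ridges. As an optimization, only sites whose raw cell is
unbounded or pokes past the box are reflected; interior cells are provably
unaffected. Duplicate coordinates are jittered deterministically (hash of
row index, ≤ 1e-6 nm) because coincident sites make the tessellation
undefined; fewer than three sites, or an all-collinear ROI, raises a
degenerate-geometry error naming the ROI (the pipeline driver treats such
ROIs as zero-vesicle observations).

A localization is *dense* when its first-rank density `1/area` exceeds
`alpha x N/ROI_area` (`alpha` = 2, configurable — the conventional Voronoi
segmentation rule for SMLM; the exact threshold used in the original
Matlab analysis is unpublished, so it is exposed as a parameter).
Edge-adjacent dense cells are merged by connected components, and
components with fewer than 40 localizations are discarded — 40 being the
published minimum cluster size, coherent with the 3-protein detection rule
(40/14 rounds to 3).

Boundary handling: a cluster is flagged (and by default excluded from
phenotyping) when its centroid lies within three rms radii of an ROI edge,
i.e. when its footprint is plausibly truncated by the field of view. An
earlier cell-based criterion — flag any cluster owning a cell that touches
the boundary — proved density-dependent: in sparse fields (tracer-specific
capture) the outer cells of a central cluster stretch to the ROI edge, so
sparse conditions lost twice as many clusters as dense ones and the
specific/total ratio was biased low. The geometric criterion excludes
edge-truncated clusters at the same ~5% rate regardless of field density.

## Phenotyping

Detected proteins per cluster: `round_half_up(n_loc / 14)`. Half-up
rounding keeps the 40-localization minimum coherent with the ≥3-protein
rule; a floor variant is provided since the original convention is
unpublished.

Diameter: antibodies uniform on a sphere of radius `R`, orthographically
projected, give `E[r^2] = (2/3) R^2` about the projection center; each
localization adds `2 sigma^2` of planar noise variance. Inverting,

    D = 2 * sqrt(1.5 * max(msr − 2 sigma^2, 1 nm^2))

with `msr` the cluster's mean squared distance from its centroid and
`sigma` the cluster-mean localization precision (falling back to the
configured value). The 1 nm^2 floor handles sub-resolution clusters. The
estimator is unbiased to within ~2% at ≥30 antibodies per vesicle; at low
antibody counts the sample-centroid bias pulls estimates down (measured:
monotone growth of bias as antibody count falls from 50 to 4), which is
documented rather than corrected — reported mean diameters on detected
vesicles therefore sit slightly below the generator's true mean when
antibody counts are modest.

Vesicle calls require ≥3 detected proteins, a non-boundary cluster, and a
diameter ≤ 400 nm (larger clusters are treated as aggregates/debris, not
exosomes).

## Quantification

Per-ROI vesicle counts divided by incubated volume give EV/ROI/uL values;
ROIs with no calls enter as explicit zeros (this matters for the SEM and CV
of weak conditions, whose published medians can be 0.0 with nonzero mean).
Mean, median, SEM (sd/sqrt(n), ddof 1) and CV (sd/mean) are reported per
condition.

The contribution fraction is the ratio of per-ROI-mean concentrations
(means, not medians, reproduce every published in-text ratio; medians
cannot for the zero-median rows). Its 95% interval is a percentile
bootstrap over ROIs (10^4 resamples, seeded; ROIs resampled jointly when
the two conditions have equal replicate counts, independently otherwise).
The background ratio from a tracer-free control is reported alongside the
fraction, never subtracted silently. Headline percentages are rounded to
the nearest integer percent; unrounded values are always emitted as well,
since published background figures show truncation-vs-rounding ambiguity
(e.g. 1.7/648 = 0.26% quoted as ~0.2%).

Group comparisons of skewed per-vesicle quantities (diameters, proteins per
vesicle) log-transform before a two-sided t-test (two groups) or one-way
ANOVA (more). Zero within-group variance is handled explicitly: identical
groups give p = 1, distinct degenerate groups give p = 0 with a warning.

## Capture-vs-stain sensitivity asymmetry

A single engaged tracer epitope can capture a vesicle, while immunostain
detection requires at least three detected tracer proteins. With a sparse
tracer (~2.5 copies/vesicle) the same simulated population therefore yields
a substantially higher capture-based than stain-based contribution
estimate (measured ~3-fold at the default efficiencies), reproducing the
direction of the published 17% (capture) vs 11% (stain) discrepancy and
the 7-fold capture-vs-stain gap of the doubly-tracer-specific condition.

## Validation study sizes

The end-to-end recovery study uses 15 expected vesicles/ROI/uL, 20 ROIs per
condition, and 100 seeded replicate experiments with a symmetric design
(tracer copy mean equal to the mouse per-species mean, identical capture
probabilities), chosen as a scaled-down but Poisson-realistic experiment;
measured CI coverage of the true labeled fraction 0.15 is ≥90/100 with a
mean recovered fraction within 1% relative of truth. The shell study uses
500 vesicles of 80 nm with 30 antibodies each. The analysis scripts run the
same studies at smaller replicate counts for narrative output.

## Known limitations

- Per-vesicle protein counts carry irreducible blink-count noise
  (~28%/sqrt(k) relative sd for k antibodies at geometric mean 14), so only
  aggregate protein-count recovery is meaningful; per-vesicle counts are
  estimates, not measurements.
- Overlapping vesicles closer than ~150 nm merge into single clusters;
  at the default densities this loses <1% of counts but it grows
  quadratically with density.
- The density threshold `alpha`, labeling efficiency, and per-epitope
  capture probability are not identifiable from published data; absolute
  concentrations are therefore reproduced in design (normalization,
  summary layout) but not in value.
- Diameter estimates on weakly-labeled vesicles are biased low (see
  Phenotyping); comparisons across conditions with similar labeling are
  unaffected.
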