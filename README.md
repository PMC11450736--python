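# sevenq — single-EV nanoscopy quantification

`sevenq` implements the quantitative single-molecule localization
microscopy (qSMLM) analysis used in single extracellular vesicle nanoscopy
(SEVEN): exosomes are immunocaptured from raw biofluid onto an
antibody-functionalized coverslip, stained with AF647-labeled
anti-tetraspanin antibodies (~1 dye/antibody), and imaged by dSTORM. The
package turns the resulting localization tables into per-vesicle
immunophenotypes, per-ROI exosome concentrations, and cell-type-specific
contribution fractions — and ships a synthetic dSTORM generator so the
whole chain is testable against known ground truth without microscope data.

It is written for researchers using tetraspanin-tracer mouse models (e.g.
the Exomap1 HsCD81mNG reporter) to ask what fraction of a biofluid's
exosomes a given cell type contributes.

## Method

1. **Segmentation.** Localizations of each ROI are tessellated (Voronoi,
   clipped exactly to the ROI). A localization is dense when its cell
   density `1/A_i` exceeds `α·N/A_ROI` (α = 2); edge-adjacent dense cells
   merge into clusters, and clusters with fewer than **40 localizations**
   are discarded.
2. **Phenotyping.** Detected tetraspanins per cluster =
   `round(n_loc / 14)` (14 localizations per fluorescent antibody);
   diameter `D = 2·√(1.5·(⟨r²⟩ − 2σ²))` from the projected spherical-shell
   geometry. A vesicle is counted only with **≥ 3 detected proteins**, an
   untruncated (non-boundary) cluster, and `D ≤ 400 nm`.
3. **Quantification.** Per-ROI counts / incubated µL give EV/ROI/µL with
   mean, median, SEM, CV; the contribution fraction is
   `specific / total` concentration (tracer-specific ÷ total capture),
   with a seeded bootstrap CI over ROIs and the tracer-free-control
   background reported alongside.
4. **Simulation.** Ground-truth vesicles (lognormal diameters ~78 nm,
   Poisson tetraspanin copies, Bernoulli tracer labeling) are captured with
   probability `1−(1−p)^k`, stained, and rendered as geometric blink
   trains (mean 14) with Gaussian localization noise plus Poisson
   background.

Details, parameter defaults and limitations: [docs/methods.md](docs/methods.md).

## Worked example

```sh
python analysis/01_published_ratios.py
```

```
hepatocyte_plasma_stain       11.39% (~11%)  background 0.14%
hepatocyte_plasma_capture     17.33% (~17%)
neuron_plasma                  1.27% (~1%)  background 0.26%
neuron_csf                     0.95% (~1%)  background 0.43%
capture vs stain sensitivity: 7.0-fold
```

These are the published plasma/CSF concentration summaries pushed through
the contribution arithmetic: hepatocytes contribute ~11–17% of plasma
exosomes (stain-based vs capture-based detection), neurons ~1% of both
plasma and CSF exosomes, each against a ≤0.4% tracer-free background. The
7-fold figure is the sensitivity gap between capturing a vesicle (one
engaged tracer epitope suffices) and calling it by immunostain (≥ 3
detected tracer proteins).

A fully simulated experiment, end to end:

```sh
python analysis/02_simulate_experiments.py
```

```
hepatocyte-tracer plasma experiment (20 ROIs, 1 uL total / 5 uL specific)
  cre_mm_capture       13.30 EV/ROI/uL (median 14.00, SEM 0.71, CV 0.24)
  cre_hs_capture        2.12 EV/ROI/uL (median 2.30, SEM 0.14, CV 0.30)
  ...
  contribution 15.94% (true 15%), CI95 [13.41, 18.69]%, background 0.00%
```

i.e. the pipeline recovers the simulated 15% hepatocyte contribution from
rendered localization tables. `analysis/03_recovery_study.py` repeats this
over seeded replicates and measures CI coverage, the capture-vs-stain
asymmetry, and diameter recovery on 80 nm shells.

The same stages are exposed as a CLI for use on external localization
tables (`roi_id,x_nm,y_nm,frame,precision_nm`, nm units, origin at the
ROI's lower-left corner):

```sh
seven simulate --config analysis/configs/hepatocyte_plasma.yaml --out out/ --seed 1
seven cluster   --in out/cre_mm_capture_localizations.csv --min-size 40 --alpha 2.0 --out clusters.csv
seven phenotype --clusters clusters.csv --loc-per-ab 14 --min-proteins 3 --out evs.csv
seven quantify  --ev-tables evs_specific.csv evs_total.csv --volumes 5 1 --n-roi 20 20 --out report.json
seven run       --config analysis/configs/hepatocyte_plasma.yaml --out out/ --seed 1
```

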