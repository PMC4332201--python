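# hepcyto

Single-hepatocyte fluorescence image analysis: nuclear segmentation from
Hoechst stain, per-cell fluorescent-bile-acid (FBA) accumulation in annular
cytosolic ROIs, quantitative outlier/viability exclusion, propidium-iodide
death calling in 30-h time-lapse movies, and tertile stratification of
cytotoxicity by FBA accumulation.

## The scientific problem

Primary hepatocytes take up organic anions — above all bile acids — through
dedicated transporters, and lose that ability as they dedifferentiate in
culture. High-content imaging with a fluorescent bile acid
(chenodeoxycholylglycylamidofluorescein, "FBA") turns transport phenotype
into a per-cell measurement: how much FBA each cell accumulates, how that
varies from cell to cell, and whether high accumulators are the cells that
die when hydrophobic bile acids or drugs are added.

`hepcyto` implements the full measurement chain for such assays:

1. **Segmentation** — nuclei are enhanced with either a sign-flipped,
   scale-normalised Laplacian-of-Gaussian ("spot-enhancing") filter or a
   smoothing convolution, thresholded automatically by the **triangle
   method** (the bin of maximal perpendicular distance from the
   histogram-peak-to-tail chord), and labelled as connected components.
   Per nucleus: area, maximum **Feret diameter** (the nuclear "diameter")
   and circularity 4πA/P².
2. **Cellular ROI** — the "cytosol" of each cell is the annulus from the
   nuclear border to 3 µm beyond it; contested pixels go to the nearest
   nucleus, so annuli of neighbouring cells are disjoint.
3. **Measurement and correction** — mean/SD/integrated intensity per
   channel per ROI. Anion intensities are corrected by the vehicle-control
   (no-anion) mean; Hoechst, Lysotracker and propidium iodide by the
   image mode. Cell fluorescence can be expressed as a ratio to Hoechst.
4. **Exclusion rules** — three declarative rulesets remove damaged cells
   and debris by outlier status, e.g. for the accumulation assay: pixel-SD
   outside mean ×15/÷15 (anion), ×10/÷5 (Lysotracker), ×2.5/÷5 (Hoechst),
   nuclear Lysotracker > mean ×1.5, nuclear area outside 47–360 µm², or
   circularity < 0.6. Viable cells are nuclei of 36–468 µm² with nuclear
   propidium iodide < 200, Hoechst SD within ×2/÷2 and regular shape.
5. **Death calling** — ROIs are frozen at frame 1; a cell is dead from the
   first frame whose background-subtracted PI cell fluorescence exceeds
   100 a.u.
6. **Statistics** — cells sorted by initial FBA are split into three
   equal-size groups (low/mid/high accumulators); the package reports
   death percentage per group, the FBA fold-difference between dying and
   surviving cells, cell-to-cell CV (100·SD/mean), per-cell Pearson
   correlations, experiment-level time-course means ± SEM with Student's
   t-tests, and power-law trend fits *y = a·x^b*.

Because the original rat-hepatocyte images are not public, the package
ships a **synthetic-field generator** with a per-cell ground-truth table:
lognormal FBA heterogeneity, soft-edged nuclei at 1200 cells/mm², dead
cells and debris that trip each exclusion rule, and a time-lapse mode whose
per-frame death hazard increases with log FBA. Every analysis stage is
validated against that ground truth and against independent brute-force
oracles.

## Worked example

```bash
python examples/05_tertile_stratification.py
```

simulates 1500 cells under a bile-acid-like death hazard (40% marginal
death over 30 h, log-odds slope 3 per unit log FBA) and prints:

```
 group     n  death %  mean FBA   CV %
   low   500     26.0       420    7.9
   mid   500     36.8       495    3.5
  high   500     53.2       580    8.4
 whole  1500     38.7       498   14.9

high-tertile excess death: +14.5 percentage points (1.38-fold relative)
dying cells had 1.08-fold higher initial FBA than survivors
```

Reading: the highest FBA accumulators die at 53% versus 39% for the whole
population — the per-cell signature of accumulation-coupled toxicity —
while the low tertile is relatively protected. The other examples cover
field simulation (`01`), segmentation and ROI measurement (`02`), the
exclusion rules (`03`), time-lapse death calling (`04`) and the population
statistics (`06`).

The same workflows run from the shell:

```bash
hepcyto run --assay timelapse --seed 7 --outdir runs/demo
hepcyto simulate --outdir runs/sim --seed 1
hepcyto segment --hoechst runs/sim/sim_000_hoechst_0001.tif --pixel-size 0.65 --outdir runs/seg
```

Each run directory is self-describing: resolved `config.yaml`, `cells.csv`
(one row per cell with every ROI statistic), `report.json`, label-map
TIFFs and an `exclusions.log` naming each excluded cell and the rules it
tripped. Re-running with the same seed reproduces every file byte for
byte.

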