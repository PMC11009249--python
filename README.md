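# dropflux

Quantification pipeline for single-cell secretion and metabolic-flux assays
in droplet microfluidics. Individual B cells are encapsulated in ~50 pL
water-in-oil droplets together with fluorogenic reporter assays and imaged
repeatedly (six frames at 10-minute intervals); `dropflux` turns the
resulting per-droplet fluorescence time series into calibrated secretion
rates, antibody affinity slopes, and cell-state classes, and aggregates
transcriptomic pathway activity downstream of a differential-expression
analysis.

## What it computes

**Calibration.** The lactate channel follows a four-parameter logistic
curve, y = bottom + (top − bottom)/(1 + (EC50/x)^h), fitted to a standard
ladder (2–200,000 amol/nL). Its working limits are

- LoD = median(low) + 1.646·(SD_low + SD_low+1), using the two lowest
  nonzero standards (2 and 20 amol/nL), and
- cutoff = plateau − 2·SD with SD = √N·(CI₉₅ width of the plateau)/3.92.

Antibody relocation (the ratio of nanoparticle to whole-droplet
fluorescence in a sandwich immunoassay) follows a saturating exponential
y = y_plateau − (y_plateau − y_blank)·e^(−K·x), fitted to a blank plus
100 nM and eight twofold dilutions, with the upper cutoff at the plateau
minus the half-width of a 90% prediction interval.

**Detection and rates.** Blank noise is estimated robustly from droplets
without a cell: σ̂ = 1.4826·MAD. A droplet secretes its analyte when its
relocation series (I) reaches median + 1.645·2·σ̂ at least once, (II)
increases over time, and (III) spans more than 1.645·2·σ̂. Rates are
interval averages of calibrated concentration (lactate, amol/s after
multiplying by droplet volume) or molecule counts (antibodies,
molecules/s). Cells at ≥ 3 IgG/s (≥ 7 IgM/s) are IgG-SCs (IgM-SCs);
lactate rates are flagged against the 0.10–0.80 amol/s quantitative range.

**Phenotype.** Affinity is the regression slope of antigen relocation on
antibody relocation inside [LoD, cutoff]. ROS, intracellular pH, and
caspase-3/7 states are threshold classifiers built from reference
distributions (mean + 2 SD of reference-day signal increases; pH-5.5
calibration mean + SEM on cohort-median-normalized signals; median + 3 SD
of empty-droplet SD_WDF).

**Cohort statistics & pathways.** Poisson encapsulation λ (mean cells per
droplet) by maximum likelihood, single-pass Grubbs outlier screening,
KS / Wilcoxon / Kruskal–Wallis + Dunn comparisons, and pathway activity as
the mean log2 fold change of significant DEGs per gene set.

A seeded synthetic-data generator reproduces the statistical structure of
such experiments (Poisson occupancy, forward calibration curves, blank
noise tied to the MAD) so the whole pipeline is testable without
microscopy data.

## Worked example

```bash
python examples/quantify_secretion.py
```

```
droplets: 2000, single-cell: 451, multi-cell excluded: 75
estimated lambda: 0.304 (SE 0.012)
IgG-secreting cells (criteria passed, rate >= 3 IgG/s): 141

estimate vs ground truth (first 8 single-cell droplets):
 droplet_id  lactate_rate  lactate_rate_amol_s  ig_rate  ig_rate_molecules_s  is_secretor
          1         0.066                0.066   12.677               12.231         True
          2         0.078                0.078   11.316               11.466         True
          4         0.907                0.918    0.000                0.000        False
          7         0.511                0.514   35.382               34.835         True
```

2,000 droplets at λ = 0.3 yield 451 single-cell droplets (multi-cell
droplets are excluded); the recovered lactate rates (amol/s) and IgG rates
(molecules/s) track the simulated ground truth, and droplets whose
relocation series fails the detection criteria or stays below 3 IgG/s are
not called secretors. The other scripts in `examples/` demonstrate the
calibration limits, cell-state classifiers, and pathway scoring; the same
stages are available from a shell via `dropflux
simulate|calibrate|quantify|phenotype|stats|pathways|run`.

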