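# cycleplate

High-content cell-cycle screening analysis: per-nucleus DNA-content
normalization and binning, robust constrained four-parameter-logistic (4PL)
dose-response fitting, and quantitative comparison of cell-count versus
metabolic proxy viability readouts — together with a mechanism-aware
synthetic plate/image simulator so that every stage is testable without
laboratory data.

## The problem

Imaging-based proliferation screens count nuclei directly and, from the
integrated Hoechst intensity of each nucleus, classify cells into cell-cycle
bins. Plate-reader viability assays (CellTiter-Glo ATP luminescence, MTS
absorbance, CyQuant DNA fluorescence) instead report a bulk per-well signal
that is silently weighted by cell size and metabolic state. Cytostatic
drugs that arrest cells in S or G2/M typically *enlarge* them and increase
per-cell ATP, MTS activity and mitochondrial mass, so the proxy assays can
understate potency by more than tenfold or understate efficacy by tens of
percentage points relative to the true cell count — and biphasic mechanisms
(arrest at low dose, apoptosis at high dose) produce bell-shaped or
multiphasic proxy curves that no sigmoid fits at all.

`cycleplate` implements the analysis pipeline of such a screen and a
generative simulator of the phenomena that break the proxy assays, for
assay developers and computational biologists who need to validate
cell-cycle / viability analysis code against known ground truth.

## What is implemented

- **`cycleplate.simulate`** — seeded 384-well dose-response plates. A
  compound is a pair of Hill transitions over phenotype mixtures
  (G1 / S / G2M / endoreduplicated / sub-G1) with per-state cell-size and
  metabolism coupling; wells get per-cell feature tables (DNA, area,
  MitoTracker, TMRE) and bulk ATP / MTS / DNA-dye readouts with lognormal
  noise, plus a ground-truth sidecar.
- **`cycleplate.imaging`** — renders nuclei/mitochondria fields from
  per-cell tables (intensity-conserving Gaussian-blurred discs) and
  segments them back: Otsu threshold on log-compressed intensity,
  distance-transform watershed for touching nuclei, median-background-
  corrected integrated intensities, seeded-watershed cytoplasm regions.
- **`cycleplate.cellcycle`** — log2-transforms integrated DNA intensities,
  anchors the scale at the 2N mode of pooled DMSO controls, re-locates each
  well's own 2N peak inside a ±0.3 log2-unit search window, and classifies
  normalized DNA content into five bins:
  sub-G1 < 0.75 ≤ 2N < 1.25 ≤ S < 1.75 ≤ 4N < 2.5 ≤ >4N.
- **`cycleplate.doseresponse`** — fits the decreasing 4PL
  `y = bottom + span / (1 + 10^(hill·(x − logEC50)))` under the constraints
  20 < span < 100 and 0.5 < hill < 4 by iteratively reweighted least
  squares with a Tukey-biweight loss (c = 4.685 × re-estimated normalized
  MAD scale) and a deterministic multi-start grid; gates fits by
  robust RMSE < 1.5 × global control SD and SE(logEC50) < 1; derives EC50,
  EC90 (= logEC50 + log10(9)/hill) and Emax (= 100 − bottom); flags
  non-monotonic (rebounding) series.
- **`cycleplate.platecompare`** — percent-of-control normalization (blank
  subtraction for MTS/DNA-dye, none for ATP), signal-per-cell fold-change
  ratio curves, total mitochondrial mass (count × mean per-cell MitoTracker
  fold), and assay-format flags: |ΔlogEC50| > 1 or |ΔEmax| > 25 points,
  with conservative handling of censored values like `">-4.6"`.

## Worked example

Simulate an antimitotic compound that arrests cells in G2/M with a twofold
size increase, then fit every readout and compare formats:

```
cycleplate simulate --scenario mitotic_arrest --seed 7 --out demo
cycleplate profile  --cells demo/cells.tsv --wells demo/wells.tsv --out profiles.tsv
cycleplate fit      --wells demo/wells.tsv --out fits.tsv
cycleplate compare  --fits fits.tsv --out comparison.tsv
```

The fit table (selected columns):

```
    readout  log_ec50  se_log_ec50  hill   emax  rmse_robust  valid
count_truth    -8.447        0.008 2.051 72.686        1.580   True
        atp    -8.323        0.031 2.487 43.477        4.486   True
        mts    -8.299        0.031 2.061 47.320        3.849   True
    cyquant    -8.366        0.024 1.941 58.226        3.798   True
```

and the format comparison:

```
readout  delta_log_ec50  delta_emax  ec50_flag  emax_flag
    atp            0.12       29.21      False       True
    mts            0.15       25.37      False       True
cyquant            0.08       14.46      False      False
```

Reading: the cell count drops by 73 % at saturating dose, but the arrested
cells double in size, so the ATP and MTS signals fall by only ~44–47 % —
an Emax understatement of 25–29 percentage points, flagged (`emax_flag`).
The DNA-dye readout, insensitive to cell size, stays within the 25-point
band; its smaller residual gap reflects the extra DNA of accumulated 4N
cells. Potencies (logEC50) agree within 0.2 log units for all readouts, so
no EC50 flag is raised. Custom compounds can be described in a YAML
scenario file (see `cycleplate.io.load_scenario`).

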