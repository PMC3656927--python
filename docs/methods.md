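# Methods

## Generative model of a screening plate

A well's population is a mixture over five phenotype states. Each state
fixes a DNA-content law (in multiples of the diploid 2N content), a cell
size, and metabolic couplings:

| state       | DNA content              | notes                                   |
|-------------|--------------------------|-----------------------------------------|
| `G1`        | 1.0                      | reference size 1.0                      |
| `S`         | uniform on (1, 2)        | simplest law consistent with a continuous inter-peak region |
| `G2M`       | 2.0                      |                                         |
| `endoredup` | 4.0 (8N) or 8.0 (16N)    | `endoredup_high_fraction` (default 0.25) selects 16N |
| `subG1`     | uniform on (0.2, 0.75)   | apoptotic; default size 0.4 (shrinkage) |

Measured per-cell features: `dna_int = 2·10⁵ · content · LN(1, dna_cv)`,
`area = 400 px · size_multiplier · LN(1, area_cv)`,
`mito_int = area · mito_per_area`, `tmre_int = mito_int · tmre_per_mito`,
where `LN(1, cv)` is mean-one lognormal noise. Defaults: `dna_cv = 0.06`
(image-derived DNA histograms are broader than flow cytometry),
`area_cv = 0.15`, `readout_cv = 0.05` for bulk signals.

The untreated cycling mixture defaults to 60 % G1, 15 % S, 22 % G2/M, 3 %
sub-G1 — a plausible adherent-line profile chosen once as a configurable
placeholder (no canonical numeric profile exists to copy). Untreated
cycling states share the unit reference size: size effects are modeled as
drug-induced phenotypes, so the per-cell metabolic coupling examples
(e.g. "2× enlargement ⇒ 2× ATP/cell ratio") hold exactly in expectation.
The modest physiological size growth of untreated G2 cells is deliberately
not modeled; see Limitations.

A compound is one or two Hill transitions. With
`h(c) = 1 / (1 + 10^(hill·(logEC50 − log10 c)))`:

- the phenotype mixture interpolates linearly in Hill-response space from
  the untreated mixture to `primary_phenotype` (weight `h₁`), then on to
  `switch_phenotype` (weight `h₂`) when a second, higher-concentration
  transition exists — producing smooth biphasic profiles;
- the expected final count is
  `seed_count · 2^((duration/doubling_time)·(1 − arrest_efficacy_max·h₁)) · (1 − kill_fraction_at_switch·h₂)`,
  i.e. growth-rate inhibition by the primary response plus outright cell
  loss at the switch; realized counts are Poisson. Defaults
  (doubling 24 h, duration 48 h, seed 500) give two doublings in controls.

Bulk readouts are size-weighted sums over the well's cells:
ATP `= Σ area·atp_per_size × gain × LN(1, readout_cv)`, MTS analogous, and
the DNA-dye (CyQuant-like) signal `= Σ content × gain` over **non-sub-G1
cells only**, emulating a membrane-impermeable quencher that restricts the
dye to intact cells; ATP and MTS include all cells. `background_level` is
interpreted as a fraction of the mean control signal per readout (blank
wells read that level); ATP gets no background, matching its
no-blank-subtraction normalization. All randomness flows from one seed via
counter-based per-well substreams (`SeedSequence([seed, well_index])`), so
well order can never change results.

Built-in scenarios (`mitotic_arrest`, `dna_damage_biphasic`,
`s_phase_arrest`, `endoreduplication_switch`, `inactive`) encode the
classic mechanism classes; each uses a 20-point two-fold dilution series
and four replicate wells per concentration, the standard replicate
convention for plate proliferation assays.

## Imaging

Rendering draws each nucleus as a uniform disc (30 % of the cell
footprint) carrying exactly `dna_int`, blurs with a Gaussian PSF
(σ = 2 px), and keeps a 4σ margin so the summed intensity is conserved to
well under 1 %; the mitochondrial channel spreads `mito_int` over the full
cell disc, whose background staining defines the cell area. Placement is
uniform rejection sampling without overlap; an overdense field raises an
error rather than silently stacking cells.

Segmentation: foreground by Otsu's threshold on log-compressed intensity
(nuclei span ~1×–8× DNA content; a linear-domain threshold would discard
the dim 2N class when bright 8N nuclei dominate the histogram), small
objects removed below `min_area` (default 20 px), touching nuclei split by
watershed on the Euclidean distance transform, integrated intensities
corrected by the median non-foreground level, border-touching objects kept
but flagged. Cytoplasm regions grow from nucleus seeds by watershed on the
inverted mitochondrial image, masked to mitochondrial foreground ∪ nuclei;
regions are therefore disjoint and each contains its seed. A flat
mitochondrial image degenerates to the nuclear region alone. Blank or
saturated images yield an empty result plus a warning, never an exception.

## DNA-content normalization and binning

The 2N anchor is the dominant lower major mode of the pooled control log2
histogram, found by Gaussian-kernel density (bandwidth 0.04 log2 units,
argmax on a 0.005-unit grid, computed by histogram convolution — stable
under the peak broadening of image-derived data). Peaks reaching half the
global density maximum qualify as "major"; the lowest-position one is the
2N peak, so a strong 4N shoulder is never chosen, and near-equal bimodal
cases warn. At least 200 pooled control cells are required.

Each well's own 2N peak is then sought within ±0.3 log2 units of the
anchor; it must be a local density maximum strictly inside the window with
at least 25 % of the well's global density maximum. Wells with no such
peak (e.g. fully arrested 4N wells) fall back to the pooled anchor and are
flagged — which is what leaves a true 4N population at normalized content
2. Intensities are divided by the peak value, so the 2N mode maps to 1.

Bins are half-open, lower-inclusive on normalized linear DNA content:
sub-G1 (0, 0.75), 2N [0.75, 1.25), S [1.25, 1.75), 4N [1.75, 2.5),
>4N [2.5, ∞). The thresholds are treated as *linear* normalized content
values (2N = 1, 4N = 2); an alternative convention that applies them to
`1 + log2(content)` — identical anchors, logarithmic spacing — is
available via `classify_cells(..., scale="log2")`. Profiles from fewer
than 50 cells are reported but flagged unreliable. Fragmented apoptotic
nuclei may segment as several sub-G1 objects and inflate counts; this is a
known bias of nuclei counting, documented rather than corrected.

## Robust 4PL fitting

Model: decreasing `y = bottom + span/(1 + 10^(hill·(x − logEC50)))` on
percent-of-control responses versus log10 molar concentration, top free
(`top = bottom + span`), constraints 20 < span < 100, 0.5 < hill < 4
enforced by sigmoid box reparameterization (returned fits satisfy them
strictly). Replicates enter as individual points.

Optimization: iteratively reweighted least squares under the Tukey
biweight, tuning constant 4.685 × robust scale, scale = normalized MAD of
the current residuals re-estimated each iteration. Each start seeds its
initial weights from its own residuals, so gross outliers cannot steer the
first least-squares step out of the start's basin — this is what gives the
fit its breakdown resistance under clustered contamination. Deterministic
multi-start: logEC50 on a 0.5-log grid across the tested range × Hill
slope ∈ {1, 2}; initial asymptotes from the 5th/95th response percentiles.
Best solution by final robust loss; ties break toward smaller Hill, then
smaller |logEC50|. There is no random element in fitting.

Diagnostics: `rmse_robust = √(Σw r²/(Σw − 4))` with converged Tukey
weights `w` (the robust analogue of residual √χ²/dof, in percent units);
`se_log_ec50` from the robust-weighted linearized covariance
`s²(JᵀWJ)⁻¹` with the analytic Jacobian, reported as ∞ when the system is
ill-conditioned (cond > 10¹²). A fit is **valid** iff
`rmse_robust < 1.5 × global_sd` and `se_log_ec50 < 1`, where `global_sd`
is the standard deviation of percent-of-control values across the
experiment's DMSO control wells — the natural plate-noise scale,
computable from every dataset. A flat series is rejected through the SE
criterion (its EC50 is unidentifiable), not by special-casing.

EC90 sits `log10(9)/hill` above EC50 on the decreasing curve;
Emax = 100 − bottom. Non-monotonic series are detected on replicate means
with a 2×`global_sd` hysteresis: a rebound is flagged when the response
first falls below `100 − 2·global_sd` and later rises by more than
`2·global_sd`; monotone segments are reported alongside. Deliberately,
no double-Hill model is fitted — multiphasic curves are flagged, not fit.

## Plate comparison

Percent of control: `100·(raw − background)/(control mean − background)`,
background = blank-well mean for MTS and DNA-dye, zero for ATP. Ratio
curves divide replicate-mean signal percent by replicate-mean count
percent per concentration (both percent-of-control, so the ratio → 1 at
vanishing dose); doses where the mean count falls below 1 % of control are
omitted as unreliable. Total mitochondrial mass = count × per-cell
MitoTracker fold change, renormalized to the control product — a
percent-of-control series directly fittable by the 4PL machinery. Format
flags: |ΔlogEC50| > 1 log unit, |ΔEmax| > 25 points; censored inputs
(`">-4.6"`, `"<20"`) are one-sided bounds and a flag is raised only when
the bound *guarantees* the threshold is exceeded; an invalid proxy fit
against a valid count fit raises both flags with reason "no valid fit".

## Numerical choices

- KDE step 0.005 log2 units bounds peak-location quantization at ±0.0025;
  degenerate (single-valued) samples return their exact median instead.
- Robust scale floored at 10⁻⁸ so zero-residual (noiseless) fits cannot
  divide by zero; exact-model recovery is to optimizer tolerance (≤ 10⁻⁶).
- Loss comparisons across candidate solutions use each candidate's own
  converged scale; the stored `fit.scale` lets an external check evaluate
  the Tukey loss at a fixed scale, where the returned solution is a
  stationary point.
- Bin intervals are lower-inclusive half-open, so boundary values classify
  deterministically and independent of evaluation order.
- Well IDs follow 384-well row-major layout (A01…P24); pixel coordinates
  are 0-based row-major with areas in pixels, no physical calibration.

## What the simulator does and does not emulate

It reproduces: concentration-dependent mixtures of cell-cycle states with
lognormal staining noise; cytostatic arrest with enlargement and its
inflation of per-cell ATP/MTS; biphasic arrest→apoptosis switching and the
resulting bell-shaped per-cell ratios; membrane-integrity gating of the
DNA-dye signal; size/mitochondria/ATP coupling tight enough that total
mitochondrial mass reconstructs the ATP curve.

It does not emulate: pharmacokinetics, media exchange, or well-edge
effects; mitochondrial-function changes (a per-cell TMRE ratio field
exists, but no flux modeling); cell-cycle-dependent size or mitochondrial
growth in untreated cells; debris, imaging artifacts or illumination
gradients; mitosis-vs-G2 morphology differences. Tests passing on
simulated plates therefore establish the correctness of the *analysis*
under the stated generative assumptions, not the behavior of any
particular cell line or instrument.

## Problem sizes

Default analyses use 3000 pooled control cells for reference estimation,
2000–4500 cells per test well, 20-point two-fold dilution series with four
replicate wells, 100-series batches for fit-recovery studies, and
1024×1024 px rendered fields of 150–200 cells (~15 % coverage) for
segmentation round trips — sizes at which every stage's statistical
targets are comfortably resolved.

## Known limitations

- The per-well 2N peak search assumes drift under ±0.3 log2 units; larger
  staining drift falls back to the pooled anchor silently (flagged).
- The five-bin scheme cannot separate G2 from M, nor genuine tetraploid G1
  from G2/M; both are reported as 4N.
- Robust fitting resists isolated contamination, but outliers that
  conspire within the EC50 transition region can still bias any
  M-estimator; the validity gate, not the loss, is the backstop there.
- Censored-value comparisons are deliberately conservative: a bound that
  does not guarantee a threshold crossing yields no flag.
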