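# Methods

This note records the models implemented in `lysopipe`, the default
parameter choices and why, what the synthetic-data generators do and do
not emulate, and the numerical decisions a maintainer would need.

## Lipid model

Species are identified at sum-composition level:
`<CLASS> [O-]<carbons>:<double_bonds>[;<hydroxyls>]`, where the `O-`
prefix of the chain descriptor marks ether-linked (alkyl/alkenyl)
classes and is part of the class identity.  Carbon and double-bond
counts are summed over all radyl chains and the long-chain base; the
hydroxylation suffix is carried but ignored in chain arithmetic.  The
packaged taxonomy has 28 classes in seven working categories, with the
glycerophospholipids split by chain architecture (diacylGPL, etherGPL,
lysoGPL) because those groups behave differently in lysosomes.
Peculiarities:

* **BMP/PG** is a single merged class: direct-infusion MS cannot
  separate bis(monoacylglycero)phosphate from its mass-isomer
  phosphatidylglycerol.  The class is flagged as the lysosomal marker;
  the BMP component is recognisable by its polyunsaturated species.
* **CL** (cardiolipin) is rolled up as a diacylGPL (it is an all-acyl
  GPL) but additionally flagged as the mitochondrial marker, so purity
  metrics can treat it as a depletion control without a special
  category.
* **Chol** carries a fixed composition (27:1) because sterol
  nomenclature has no chain descriptor.

The taxonomy ships as an editable YAML file; class sets differ between
platforms and users are expected to extend it.

## Quantification and filtering

Single-standard ratio quantification: `molar = I/I_std × A_std` per
standard group.  Absent ("not identified") measurements propagate as
missing, distinct from measured zeros, because identification
bookkeeping (Venn overlaps) needs the distinction.  mol% is always on
the 0–100 scale.

The inclusion filter retains a species iff the median of its mol%
across the replicates of ≥1 sample type (fraction × treatment) is
**strictly** above the threshold (default 0.0001 mol%).  Absent
replicates count as 0, so one detection out of three cannot carry a
species.  The median is evaluated on pre-filter mol%, and
re-normalisation over retained species happens once afterwards — this
makes the rule order-independent and idempotent.  Whether the filter
should pool replicates across fractions was an open choice; grouping by
fraction × treatment is the default and the grouping is exposed.

## Differential abundance

Modelling scale is log2 of mol%, with zeros floored at half the
smallest positive mol% in the table (applied to zeros only) so every
filtered species stays testable.  Each contrast is a two-group OLS fit;
moderation follows the standard empirical-Bayes scheme: method-of-
moments fit of (d₀, s₀²) on log s²_g using digamma/trigamma moments,
posterior variance (d₀s₀² + d_g s²_g)/(d₀+d_g), and a t reference with
d₀+d_g df capped at the total residual df observed across species.
When the log-variances show no excess dispersion beyond chi-square
sampling, d₀ is infinite and the pooled mean variance is used — the
maximum-likelihood scale in that limit.  One unit test verifies the
whole fit against the reference R implementation (limma) on an
identical matrix; the R route is an oracle only, never the
implementation.  A plain two-sample t mode (`moderated=False`) exists
for comparison.

Significance is raw p < 0.05 by design, matching the workflow this
package reimplements; a Benjamini–Hochberg FDR column is emitted but
never drives the flag.  Contrasts name explicit (fraction, treatment)
conditions on both sides: within-fraction contrasts (e.g. released vs
untreated lysosomes) and the lysosome-vs-whole-cell comparison of one
treatment are both first-class, since both are scientifically needed.

Class roll-ups use mol%-weighted means for the per-class carbon and
double-bond averages (unweighted is a config option; the weighting is
the natural reading of "average number of carbons of the class" when
species abundances span decades).  Heatmap ordering uses Euclidean
distance with complete linkage; non-finite fold changes are imputed
with 0 (an absent class has no fold change) before distances; leaf
order is deterministic.

## Purity metrics

Yield, enrichment and recovery pair WCL/LYS columns by (treatment,
replicate) — both fractions derive from the same culture.  Aliquot
factors (default 1) rescale analysed aliquots to full samples and
cancel under common rescaling.  Replicate summaries are mean ± sd.  A
marker absent from a pair's WCL yields an infinite-enrichment flag
rather than an error; absent from LYS yields 0 (the depletion limit).
Recovery interprets the marker molar ratio as % of organelles
recovered; this is unbiased only if the marker is organelle-confined
and no marker species is censored by the detection limit (see below).

## Cytometry

Gates are axis-aligned rectangles in (mean Hoechst, total p-H3) with
half-open `[min, max)` containment, so gates sharing an edge are
disjoint and every cell gets exactly one label (or `unassigned`).
Percentages use all imaged cells of a condition as denominator.
`auto_gates` splits each axis at the valley of a two-class variance
split (Otsu) of the log10 feature and assembles the four quadrant
rectangles, bounded by the padded data range so coordinates stay
finite; it exists for synthetic/well-separated data and manual gates
always override it.  DNA-content histograms are equal-width over the
observed range unless edges are given.

## Vesicles

Max-entropy (Kapur) threshold: natural-log Shannon entropies with
0·ln 0 := 0, zero-probability bins skipped, candidate thresholds
exhaustively evaluated via cumulative sums, ties broken to the lowest
level.  Components are 8-connected (configurable); area = pixel count ×
pixel size²; the 0.1 µm² cutoff is inclusive (a particle at exactly the
cutoff is kept).  Per-vesicle channel intensity is the mean over the
mask after subtracting the image's modal gray level (the flat
background); vesicles with non-positive background-subtracted TMR are
excluded and counted.  All phase comparisons are unpaired two-tailed
t-tests on biological-replicate means, never on pooled vesicles.

## Synthetic study conditions

The generators' defaults are the package's fixed study conditions.

**Lipidome.** 28-class profiles for WCL and LYS anchored on the marker
values the purification is known to produce: BMP/PG 0.156 mol% (WCL) →
2.27 mol% (LYS), CL 3.5 mol% (WCL) → 0.02 mol% (LYS), LYS/WCL total
molar ratio 1.33% (1000 vs 13.3 pmol analysed); remaining classes
follow typical cultured mammalian-cell and lysosome compositions,
renormalised to 100.  Species templates give each class a realistic
carbon/double-bond spread (~300 species total); BMP/PG has separate
templates per fraction — monounsaturated-dominated in WCL (PG-like),
polyunsaturated-dominated in LYS (BMP-like) — which also produces a
small set of species detectable only in lysosomal fractions.  Planted
effects in released-cell lysosomes: log2FC +1 (SM), +0.7 (HexCer),
−0.5 (PC), +0.4 (every lysoGPL class); milder SM/HexCer effects in
released WCL; none elsewhere.  Because profiles are compositional,
planted per-species effects shift measured mol% fold changes by the
closure factor (≈ −0.1 log2 units under these conditions); recovery
tests budget for this.  Noise is multiplicative log-normal per
measurement with mean 1 and CV 0.2 (σ² = ln(1+CV²)), applied to species
and internal-standard intensities alike; the detection limit (5
intensity counts) is applied after noise.  Three replicates per
condition.  The capture-fraction scenario (`capture_spec`) holds the
marker conserved between fractions and disables the detection limit,
because it tests the recovery estimator, whose unbiasedness premise is
uncensored marker measurement.

**Cells.** Four populations with log10-normal features; planted mitotic
fractions 1.3% (untreated), 2.6% (synchronized), 15.4% (released) and
69% (released + shake-off); G2 cells carry twice the G1 total-Hoechst
signal and interphase DNA content is a G1/S/G2 mixture (G2-heavy after
synchronization).  Populations are well separated (≥6 sd in log space),
which is what makes threshold-based auto-gating appropriate.

**Vesicle images.** 256×256 fields at 0.065 µm/pixel; vesicles are
soft discs (logistic edge, width 0.15 px) of log-normal radius (mean
0.35 µm interphase, ×√1.5 mitotic, i.e. 1.5× area), amplitude 140 over
background 12 with Gaussian read noise σ=5 (SNR ≈ 28), placed without
overlap by rejection sampling.  True pH (4.7 interphase, 5.6 mitotic,
σ 0.15) maps to the FITC/TMR ratio through a strictly monotone
fluorescein-like titration curve (r_min 0.2, r_max 2.0, pKa 6.4).
Ground-truth masks are the exact discs; segmentation recovers mean
areas within ~12% (the thresholded logistic edge sits slightly outside
the true radius).

**What the generators do not emulate:** raw spectra, isotope patterns
and adducts; chromatographic or ionisation-efficiency structure beyond
a per-class response factor; cell-to-cell lineage or imaging artefacts
(debris, clumps, uneven illumination); 3-D vesicle structure or
overlapping organelles.  Passing tests therefore demonstrate the
correctness and calibration of the *computations* under the stated
noise model, not robustness to every artefact of real instruments.

## Problem sizes and determinism

Default runs use ~300 species × 18 samples, 1000–2000 cells per
condition, and six 256² image pairs — sizes chosen so a complete run
takes seconds and Monte-Carlo suites (50–100 simulations) finish in
minutes on one CPU while leaving estimator standard errors well inside
the tested tolerances.  All randomness flows through explicit integer
seeds (`numpy.random.default_rng`); tabular output uses a fixed float
format, so identical config + seed reproduces byte-identical tables.

## Known limitations

* Recovery and enrichment are ratio estimators of log-normal
  quantities and carry a small positive bias (≈ +(CV²) per noisy
  denominator); they are reported as replicate mean ± sd, not
  bias-corrected.
* The auto-gate valley split assumes two well-separated log-scale
  modes per axis; it will misplace thresholds on strongly overlapping
  populations and is not a substitute for expert manual gates.
* The moderated model assumes a common two-group design without batch
  covariates; replicate pairing is not modelled.
* Absolute pH is never reported — only the FITC/TMR ratio, which is
  monotone in pH but instrument-specific without a calibration curve.
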