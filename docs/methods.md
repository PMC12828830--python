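# Methods

This note documents the models and procedures implemented in `sphingoquant`,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic-data tests do and do not demonstrate about real data.

## Species model and nomenclature

A species is head group × sphingoid base (SPB) × N-acyl chain. Head groups
carry fixed glycan compositions (Cer none; HexCer/Hex2Cer/Hex3Cer one to
three hexoses; HexNAcHex3Cer adds one HexNAc; GM3 is dihexose + one NeuAc).
The base kind is a pure function of its double bonds and hydroxyls:
(1,2)→SPH, (2,2)→SPD, (0,2)→DHS, (0,3)→PHS; combinations outside these four
are rejected at parse time. Resolution is species-level: double-bond
positions and glycan linkage isomers (GlcCer vs GalCer, Gb3 vs isoGb3) are
not modelled, which matches level-2/3 quantification where isomers co-elute
or are not chromatographically distinguished.

Canonical names use the shorthand-2020 dialect (`Cer 18:1;O2/24:0;O`); the
legacy `d/t` dialect is normalised on input because supplementary panels
circulate in both. `parse ∘ format` is the identity on every canonical name
(property-tested).

Subclass labels split ceramides by base kind (Cer = SPH/SPD base, DHS-Cer,
PHS-Cer) but keep glyco classes whole, since base composition within a glyco
class is treated as a separate axis (`C{n}-SPH/D` merged view). Acyl classes
pool saturation (`C24` = 24:0 + 24:1 + ...) — the default because chain-length
biology (CerS specificity) is the axis of interest; a hydroxylation flag is
kept separately.

## Mass computation and annotation

Elemental formulas are assembled from the free base (CnH(2n+3−2db)NO(oh)),
the fatty acid (CnH(2n−2db)O(2+oh)) minus one amide-condensation water, plus
glycosidic residues (hexose C6H10O5, HexNAc C8H13NO5, NeuAc C11H17NO8).
Monoisotopic masses come from pyteomics' atomic-mass tables; supported
adducts are [M+H]+, [M+H−H2O]+ and [M+NH4]+ (positive mode). The library's
product ion is the doubly-dehydrated base fragment (m/z 264.27 for
sphingosine) — a stated convention, since real vendor methods may monitor
other fragments; measured libraries can be loaded from CSV.

Peak matching gates on |Δprecursor| and |Δproduct| ≤ 0.3 Da (unit-resolution
quadrupole) and |ΔRT| ≤ 0.3 min, then assigns greedily by ascending |ΔRT|
with one peak per library entry per injection. Greedy nearest-RT is
deterministic and order-independent (tested by shuffling); the tolerances
are configurable because they are instrument properties, not constants.
The synthetic retention model is a linear map of the equivalent carbon
number with per-class offsets — enough to make RT informative without
claiming chromatographic realism.

## Quantification

Single-point internal-standard quantification:
`conc = area/area_IS × conc_IS × volume_factor`, with `volume_factor = 10`
(20 µl plasma into 200 µl extraction solvent) and standards spiked at
10 nM. Standard selection prefers the exact head class and otherwise walks
the glycan chain Cer↔HexCer↔Hex2Cer↔Hex3Cer↔HexNAcHex3Cer (ties toward the
less glycosylated class); GM3 falls back to Hex2Cer, its ganglioside core.
Species with a class-matched standard report level 2; Hex3Cer,
HexNAcHex3Cer and phytoceramides report level 3 (surrogate standard). A
missing or non-positive standard signal invalidates only the dependent
species of that injection (NaN + logged warning), never the whole run.

## Drift correction and QC gates

Per species and batch, the pooled-QC responses define a piecewise-linear
trend over injection order (nearest-QC extrapolation at the batch edges);
each injection is divided by the local trend and rescaled to the grand
median of all QC responses, which aligns batches to a common level. The
correction is deliberately deterministic — no learning step — so that
filter decisions are reproducible bit for bit.

One consequence required a design decision: a trend interpolated *through*
every QC maps each QC exactly onto the grand median, so a CV computed
naively on corrected QCs is identically zero and the CV gate could never
reject. QC precision is therefore assessed leave-one-out: each QC is
corrected by the trend interpolated from the other QCs of its batch. Study
samples use the full trend. Admission requires CV < 25 % (strict) and
dilution-series R² > 0.8 (strict), with both boundary values rejected.

Dilution linearity is an OLS of log(area) on log(1/DF) over the 13 factors
(1…10,000); the log-log choice prevents the DF=1 point from dominating a
4-decade range. Practice varies on whether this fit is done on log- or
linear-scale signal, so the scale used is recorded in the QC report.
Points with non-positive area at high dilution are dropped (counted);
fewer than 4 usable points leaves R² undefined and the species rejected.

## Case-control statistics

Tests run on natural-log concentrations (the t statistic is base-invariant)
with Welch's unequal-variance form by default — "multiple t-tests" without
a stated variance assumption is safer read as Welch; the pooled form is a
flag. Reported fold changes are log2. BH adjustment is applied across all
tested species (statsmodels' step-up; verified against a literal step-up
oracle in tests).

Aggregations sum selected species per sample with missing cells contributing
nothing (completeness counted). Acyl-chain profiles normalise per sample to
proportions (even chains only by default, matching how chain remodelling is
usually displayed) and test proportions by Welch t + BH. Ratios divide
summed numerator by summed denominator species — restricted by default to
the C18-SPH/D backbone and C24 acyl, the dominant species present in every
subclass — and are tested on the log scale; `C24` pools all saturations
(configurable), a choice recorded because the narrower 24:0-only reading is
also defensible.

The adjusted odds ratio is a maximum-likelihood logistic fit (statsmodels)
of group on the exposure plus covariates; Wald 95 % CI exponentiated.
Separation, non-convergence and rank deficiency raise with diagnostics
rather than returning silent output.

ROC models score samples with an unpenalised in-sample logistic fit (age +
sex; significant GSL species; significant ceramide species; all significant
species at p_adj < 0.01) and compute AUC as the pairwise Mann–Whitney
statistic (ties = 1/2), which equals the trapezoidal ROC integral exactly.
Lipid models include age and sex by default (flag to exclude). The CI is a
seeded 2000-resample stratified bootstrap of the score/label pairs — chosen
over DeLong for implementation transparency; both are asymptotically
equivalent here. In-sample AUCs are optimistic by construction; the
synthetic study reports them as such.

The clinical table gates continuous rows on Shapiro–Wilk normality at 0.05
(Levene homogeneity recorded, pooling the t variance only when Levene
passes) and falls back to Mann–Whitney; categorical rows use Fisher's exact
test. Severity associations are per-species OLS of the outcome on log
concentration with age, sex, disease duration and LEDD as covariates, PD
samples only, BH across species.

## Lipid set enrichment

Sets are generated from the ontology as subclass × SPB-class (minimum size
3). Species are ranked by log2FC, descending, ties broken lexicographically
for a strict deterministic order. ES is the signed extremum of the running
sum with hit increments |metric|¹ normalised over set hits and miss
decrements 1/(N−|S|). The null permutes set labels (random same-size member
sets on the fixed ranking): NES = ES / mean(|ES_perm| of matching sign), and
p is the one-sided same-sign exceedance with the +1 continuity correction.
Set-label permutation was chosen over phenotype permutation because the
enrichment input here is a single ranking, not the sample-level matrix; the
alternative is noted as an open choice and NES reference values from other
implementations should be treated as approximate. All species are ranked by
default; a flag restricts the ranking to significant species (the narrower
reading of ranking "significantly altered lipids"). Default 1000
permutations, seed recorded in the output.

## Meta-analysis

Study effects are log2FCs with SEs (symmetric 95 % CIs convert via
SE = (hi−lo)/3.92). DerSimonian–Laird is the default pooling estimator —
the field's canonical moment estimator when the original pooling method is
not stated — with REML available behind a flag (bounded scalar
minimisation of the restricted likelihood). With τ² = 0 the pool reduces
exactly to the fixed-effect inverse-variance estimate; pooling is
permutation-invariant in study order. The implementation is verified
against hand-executed formulas and against R `metafor` as an independent
oracle. Default gene lists cover the lysosomal degradation arm (GBA1, GLB1,
GLA, NEU1/3/4, HEXA, HEXB, GM2A) and the synthesis arm (SPTLC1-3,
SPTSSA/B, KDSR, CERS1-6, DEGS1/2, FADS3).

## Synthetic-data generator

The generator is the package's stand-in for raw study data, letting every
pipeline stage be exercised end to end with known ground truth. Its
defaults encode the emulated study conditions:

* **Panel**: 119 species across all eight subclasses, SPBs C16–C19
  (SPH/SPD/DHS/PHS) and acyls C16–C26 including odd chains, monounsaturated
  and hydroxylated acyls. The composition is a stated design (the real
  per-species panel is supplement-only), deterministic and seed-independent.
* **Concentrations**: independent log-normals per species, CV 0.30
  (matching the reported subclass sd/mean ≈ 0.29), with control-group
  anchors on the C24 / C18-SPH/D subclass totals — HexCer 5734.3, Hex3Cer
  539.2, GM3 2210.5 nM from the study's printed control means; Cer 2800,
  Hex2Cer 1600, DHS-Cer 220, PHS-Cer 60, HexNAcHex3Cer 150 nM chosen at
  plasma-realistic scale where no value is printed. Within a subclass,
  species weights follow C24-dominant acyl and canonical-base abundance
  profiles.
* **Effects**: PD multipliers ×1.09 for HexCer/Hex3Cer/GM3 with C18-SPH/D
  bases (Hex2Cer deliberately null, as observed), ×0.90 for DHS-Cer, ×0.85
  for noncanonical-base (C16/C17/C19) ceramides, and a C22→C24
  redistribution (×0.93/×1.03, C20 ×1.05) within canonical ceramides.
* **Acquisition**: per-injection area = extract concentration × class
  response factor × drift × log-normal noise (CV 0.05 default). Response
  factors are shared between a species and its assigned standard — the
  level-2/3 working assumption, and the condition under which noise-free
  quantification is exactly invertible; `rf_spread` breaks it to study
  surrogate-standard bias. Drift is a smooth per-batch multiplicative trend
  (linear + one low-frequency sinusoid, per-species modulation, inter-batch
  offset). Pooled QCs (the mean of all extracts) run at the start, after
  every 10 study injections, and at the end of each batch; the 13-point
  dilution series is appended to the last batch.
* **Meta sets**: 18 studies per gene with group sizes drawn around 166
  cases / 140 controls, within-study log2-expression SD 1.0 (which
  reproduces the reported pooled-CI widths), between-study τ = 0.15, and
  per-gene true effects defaulting to the study-scale pooled estimates
  (GLA −0.47, GBA1 −0.27, KDSR +0.56, …).

All randomness flows from the single config seed; equal configs are
byte-identical.

### What the synthetic tests do and do not show

Passing tests demonstrate that the pipeline's arithmetic is correct, its
error control calibrated, and its estimators consistent under the generative
model. They do not show robustness to features the generator omits:
between-species correlation (real lipids share subject-level variance, so
real multivariate ROC models — AUC ≈ 0.8 at study scale — discriminate far
less than the synthetic ones, where independent species push in-sample AUC
above 0.95), heavy-tailed or missing-not-at-random signals, RT shifts
beyond jitter, or matrix effects on ionisation. The independence assumption
also makes synthetic subclass-total CVs smaller than real ones.

A power note recorded as a known limitation: with CV 0.30 and n = 250 per
group, a single species carrying a 9 % effect has |z| ≈ 3.3 against a
BH-realised cutoff near 3.0 — per-species detection ≈ 0.65. The designed
GSL effects are therefore found reliably at the subclass-total and
enrichment level, but individual-species recovery rates plateau near
0.65–0.70 for the ×1.09 species (≈ 0.9 for ×0.90, ≈ 1.0 for ×0.85); no
analysis choice can raise this, as it is the information limit of the
design.

## Problem sizes in the checks

The test suite and `scripts/acceptance.py` run the full study at its actual
scale (250 samples/group, ~590 injections, 119 species; 18-study meta sets)
once per seed, and use replicate counts of 100–500 for the calibration
simulations (null FDR, effect recovery, logistic/meta CI coverage) and
reduced cohorts (10–40/group) for structural round-trip checks — sizes at
which every Monte-Carlo bound asserted has comfortable margin.
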