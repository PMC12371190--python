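# Methods

## Scope and data model

The package analyses MBD-capture methylation sequencing at the level of
*regions*: enrichment read counts per genomic interval per sample, with a
matched input fraction where available.  Coordinates are uniformly 0-based
half-open (BED convention).  A cohort is a list of subject/tissue samples
(brain or blood; paired samples share a subject id) carrying the clinical
covariates used in modelling: age, gender, age at seizure onset, disease
duration, localisation, an aggregate binary "combined risk factors" flag
(collapsing family history/stroke/tumour/infection/TBI), prior surgery, and
a per-sample spike-in enrichment ratio measuring capture efficiency.
Missing clinical values stay missing at parse time and are median-imputed
(numeric) only inside design construction, with a log entry.  One packaged
discovery fixture transcribes the 21-subject clinical table; the published
counts for the "no MCD" group disagree between sections (3 vs 2) and the
fixture resolves to 2 so the group totals (13 FCD + 8 other) hold.  The
unparseable duration entry for one FCD IIIa subject is stored missing, as
is the age derived from it.

## Consensus regions

Per-sample peak calls are retained at fold enrichment strictly > 4 and
p strictly < 0.01 (all printed thresholds in the pipeline are strict
inequalities).  Within each sample, calls are merged first, so a sample
with stacked calls counts once; the support rule therefore counts distinct
samples.  The genome is fragmented at the union of all breakpoints by a
sweep line; fragments with support ≥ `min_support_samples` (default 3,
"more than 2 samples") are kept; adjacent kept fragments merge with support
equal to the maximum over parts (fragment merging is otherwise undefined);
merged regions overlapping a blacklist interval by ≥ 1 bp are removed.
The builder is verified against a per-base counting oracle on random small
genomes (property-tested), and its outputs are disjoint and sorted by
construction.

CpG counting assigns a CG dinucleotide to the window containing its C; the
G may be read from the reference just beyond the window end.  This
C-position rule makes counts additive over any partition of a contig into
half-open windows, with a boundary-straddling CG counted exactly once.
Feature annotation uses precedence promoter > exon > intron > intergenic by
any overlap, with the promoter defined as TSS ± 1 kb around the
strand-aware TSS; island status (island / shore within ± 1 kb / open sea)
is assigned independently.  Nearest-gene assignment takes any genebody
overlap as distance 0, otherwise the nearest genebody within 100 kb (ties:
smaller gap, then lexicographic gene id), else "intergenic".  Regions are
finally filtered at mean methyl-capture coverage strictly > 10; the
coverage filter applies to the methyl fraction (configurable), since the
published description does not say which fraction it used.

## Differential model

Counts follow a log-link negative binomial with variance mu + phi·mu²; the
offset is log(library size × spike enrichment ratio).  Library sizes are
median-of-ratios estimates (each sample's median count ratio against the
per-region geometric mean over all-positive rows), which plain column
totals cannot replace: with hundreds of genuinely shifted regions the
column sums absorb the signal and bias every fold change (we measured a
−0.21 log2 bias at 20% planted regions; the median-of-ratios estimate
removes it).  Designs contain an intercept, a single case indicator per
contrast, standardised numeric covariates, one-hot localisation, binary
risk/surgery/gender/tissue columns and the cell-proportion covariates;
constant and aliased columns are dropped greedily in declaration order
(deterministic, logged), and missing numeric covariates are median-imputed.

Dispersions are estimated per region by maximising the Cox–Reid adjusted
profile likelihood (NB log-likelihood minus ½ log det X'WX) over a fixed
log-spaced grid including 0, so the Poisson limit is attainable; the inner
fits use a dedicated Fisher-scoring routine for speed.  Raw estimates are
moderated toward a lowess trend on log mean abundance; the tagwise value
keeps weight 0.3 of the per-region estimate and 0.7 of the trend, which
matches the behaviour of default prior-df moderation at the ~5 residual
degrees of freedom typical here.  This weighting was chosen over the
opposite reading (0.7 raw) because per-region estimates at these sample
sizes are too noisy to carry most of the weight; with it, the null
rejection rate at p < 0.01 calibrates inside [0.005, 0.02] in a 16-sample
NB simulation, while the noisier weighting inflates it to ~0.03.

Testing is a likelihood-ratio chi-square with one degree of freedom between
the full and the group-dropped model at the shared tagwise dispersion
(statsmodels GLM fits, relative deviance tolerance 1e-8, ≤ 100 iterations;
all-zero rows are flagged and excluded).  DMRs are calls at raw p < 0.01
with direction = sign of the group coefficient; a Benjamini–Hochberg column
is emitted for reference but never gates.  The default contrast set covers
FCD vs other pathologies, the per-subtype contrasts IIa vs others and IIb
vs others (the published contrast list names "FCD subtypes versus other
pathologies" as a family; these two are the ones the biomarker stage
consumes), Ia / IIa+IIb / IIIa+IIId vs the remaining FCD subtypes, IIb vs
IIa, and IIIa vs IIId.  Whether brain and blood were modelled jointly is
not documented; the default fits both tissues with a tissue covariate and
`tissue_mode` exposes per-tissue analysis.

The synthetic generator is the mirror of this model: NB counts around a
log-linear predictor with per-region covariate coefficients, lognormal
library sizes around 83 × 10⁶ reads scaled down 10⁴× for desk-scale runs
(relative structure preserved), uniform spike ratios in [0.8, 1.25], and
planted effects by class — IIa-only, IIb-only, and a graded shared class
(IIb shifted twice as far as IIa) whose members can satisfy all three panel
contrasts at once.  Blood samples additionally mix a marker-region block
across cell-type profiles with Dirichlet-distributed true proportions
(concentration ≈ (3, 11, 6) for B/T/monocyte, i.e. T-cell dominated blood).
Covariate effect defaults are small (|log2| ≤ 0.25) except tissue, which is
deliberately dominant to reproduce the brain-vs-blood clustering that
motivates adjustment.  What the generator does not emulate: genomic
placement realism (regions are evenly spaced on one contig), read-level
artefacts, GC/CpG-dependent capture bias, and correlated regions; passing
tests therefore demonstrate statistical correctness of the estimators under
the assumed model, not robustness to those real-data failure modes.

## Deconvolution

Marker signal (log-CPM scale) is projected onto the cell-type reference by
minimising ‖y − Pw‖² subject to w ≥ 0 and Σw ≤ 1 — the inequality leaves
room for unmodelled cell types.  The QP is solved exactly by enumerating
active-constraint patterns and checking the KKT conditions (the number of
cell types is small; an SLSQP fallback covers k > 12).  Brain samples enter
the joint model with all-zero cell covariates.  The estimator is verified
for exact interpolation, KKT stationarity, zero residual inside the cone,
scale consistency, and recovery error < 0.05 at noise sd 0.05.

## Biomarkers

Per-region AUC is the exact pair-count statistic with 0.5 tie credit,
reported after orientation (max(A, 1−A) with a case-high/case-low flag);
it is invariant to monotone transforms and arm swaps.  Candidate
biomarkers must have DMR p < 0.01, AUC > 0.65 and CpG count > 4 (strict,
consistent with the other thresholds).  The intersection panel and its
three classes are pure set algebra over the per-contrast candidate sets;
the IIb-vs-IIa top pick breaks ties by CpG count then region id.

The clinical baseline is a bidirectional stepwise logistic regression
minimising AIC from the full covariate model, one add/drop per step,
deterministic given column order; perfect separation falls back to a tiny
ridge (1e-6) IRLS.  The penalty per parameter is configurable (default 2,
i.e. AIC).  Note a structural property of AIC selection: a pure-noise
covariate survives with probability P(chi²₁ > 2) ≈ 0.157, so with five
noise candidates the exactly-correct subset is selected in only ~43% of
replicates — a ceiling that no implementation of stepAIC-style selection
can exceed without changing the penalty; the unit tests assert this
calibrated retention rate rather than an unattainable exactness rate.

Combinatorial ROC enumerates all non-empty panel subsets up to
`max_subset_size` (default 3), each with and without the clinical score as
one extra feature, scores each by an in-sample logistic fit (AUC, and
accuracy at the Youden-optimal threshold), and ranks by AUC then accuracy.
The published count of "6884 interactive combinations" from 13 markers is
not derivable from the stated inputs (all subsets give 2·(2¹³−1) = 16382;
size ≤ 3 gives 754), so enumeration scope is explicit configuration and the
package reports the count it actually enumerates.  Bootstrap p-values use
label permutation with add-one smoothing, p = (k+1)/(B+1), never 0.

## Normalisation and PCA

log-CPM = log2((count + 0.5) / (library × spike) × 10⁶).  "GLM adjustment"
for visualisation is implemented as per-region OLS residualisation on the
nuisance covariates (residuals plus grand mean; idempotent), the standard
linear surrogate for the count-model adjustment used in testing.  PCA is a
region-centred (optionally unit-scaled, default on) SVD with a fixed sign
convention (largest-magnitude loading positive).  PC–covariate association
uses |Pearson r| for numeric covariates and the correlation ratio (square
root of the between-group variance fraction) for categorical ones, both in
[0, 1].

## Methyl-qPCR

Replicate Cts are averaged on the Ct scale (> 1 cycle spread is flagged);
amplification efficiency is fixed at 2.0.  Quantities are spike-normalised
per fraction, Q_f = 2^(Ct_spike_f − Ct_f), and percent methylation is
100·Q_bound/(Q_bound+Q_unbound) — invariant to any constant Ct offset and
strictly increasing in (Ct_unbound − Ct_bound).  An undetermined fraction
contributes zero quantity (flagged), never an imputed Ct; both fractions
undetermined yields a missing value.  Mann–Whitney U is exact by
enumeration for pooled n ≤ 20 without ties, otherwise the tie- and
continuity-corrected normal approximation; group summaries report mean ±
SEM (SEM missing below n = 2) and the combined panel is scored by the same
in-sample logistic ROC as the discovery stage.

## Problem sizes and numerical choices

Verification simulations use 2 000 regions × 16 samples for null
calibration, 600 regions × 40 samples for effect recovery, 400 regions ×
30 samples for the end-to-end panel check, 50 markers × 100 samples for
deconvolution and 12 samples × 3 targets for the qPCR round trip — sizes at
which the assertions are informative while the whole suite runs in a couple
of minutes.  GLM convergence is relative deviance < 1e-8; the dispersion
grid spans [0.005, 5] in 25 log steps plus 0; deconvolution KKT tolerances
are 1e-6/1e-8; ranking ties break deterministically (accuracy, then combo
id).  Degenerate inputs are defined behaviour: empty cohorts summarise to
zeros, empty peak sets produce empty consensus, all-zero count rows are
flagged out of testing, constant covariates are dropped with a log entry,
and contrasts with an empty arm or an over-wide design are skipped with a
warning rather than aborting the run.

## Known limitations

Counts are analysed at fixed consensus regions; the MACS-style caller that
produces per-sample peaks is upstream and out of scope, as are alignment
and read QC.  The LRT is asymptotic; at very small arms (e.g. 1 vs 4
subjects) its calibration is approximate and the package reports rather
than corrects this.  In-sample combinatorial AUC over 754 combinations is
optimistically biased by construction (an optional stratified k-fold CV
switch exists but is off by default, mirroring the apparent published
procedure).  Percent-methylation assumes perfect doubling per cycle and a
single spike per sample/fraction.  The offset-consistency property
(scaling one sample's depth and counts) holds exactly only at the group
mean — the group MLE is an exposure-weighted mean — and is therefore tested
as an approximation alongside the exact global-offset invariance.
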