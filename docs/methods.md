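# Methods

## Study design and model

The package targets the paired two-stratum design: N patients (n_AA + n_EA,
default 8 + 8), each contributing one tumor and one adjacent non-tumor
sample. Per feature the response is modeled as

    y_ijk = μ + τ_i + α_j + β_k + γ_jk + ε_ijk,
    τ_i ~ N(0, ω²),  ε_ijk ~ N(0, σ²),

with race j (between-patient) and tissue k (within-patient) fixed and
sum-to-zero coded. With complete pairs this split-plot layout admits a
closed-form fit:

- cell means give the fixed effects exactly (balanced least squares);
- within-patient differences d_i = y_tumor − y_adjacent cancel τ_i, so
  σ̂² = ½·Σ_j Σ_i (d_ij − d̄_j)² / (N − 2) with residual df = N − 2;
- ω̂² = max(0, MS_between-patient − σ̂²/2), from patient means within race.

The three tumor-vs-adjacent contrasts (AA, EA, and the equally ½/½-weighted
disease main effect ALL) are means of within-patient differences; their
standard errors use the **pooled** σ̂² across both races — the choice implied
by fitting one joint model rather than per-race paired t-tests — and
two-sided p-values come from t with df = N − 2. The ALL contrast weights the
races equally regardless of n_AA, n_EA, matching the tested hypothesis
rather than sample-size weighting.

At an interior optimum of the variance components this closed form coincides
with REML; the test suite verifies agreement with an independently coded
numeric REML oracle to 1e-6 in estimates and 1e-5 in p-values. At the
boundary ω̂² = 0 REML pools variance differently; the closed form keeps the
paired-difference estimator there because the contrasts only involve
within-patient differences, for which it remains exact. Zero-variance
(degenerate) features yield flagged rows with p = NaN and a reason code
instead of exceptions, so batch runs never abort.

## Preprocessing

**Probe filtering.** Probes with any QC flag (non-CpG context, SNP within
10 bp, repeat within 15 bp, multi-mapping) or on chrX/chrY are removed
before modeling. The removal tally reports per-flag counts; a probe with two
flags appears under both but is counted once in the removed total.

**β → M.** M = log2(b/(1−b)) with b clipped to [ε, 1−ε], ε = 1e-6 by
default. The clip only matters for β exactly 0 or 1, where M would be
infinite; at ε = 1e-6 the distortion is negligible relative to array noise.

**TMM normalization.** Count libraries are scaled by trimmed-mean-of-M
factors: reference = sample whose upper-quartile count fraction is closest
to the mean; per sample, M and A values over features positive in both
sample and reference; double trim (30% on M, 5% on A, tie-aware average
ranks); factor = 2^(inverse-variance-weighted mean of retained M) with
delta-method binomial weights; factors rescaled to geometric mean 1. The
implementation reproduces the canonical edgeR results to 4+ decimals (one
cross-check test runs edgeR through Rscript when available). Statistical
tests on counts run on log2(TMM-normalized CPM + 0.5) — a variance-
stabilizing scale appropriate for the Gaussian linear model; the pseudo-count
0.5 keeps zeros finite without distorting moderate counts.

## Calling rules

BH adjustment is applied separately within each (omic, contrast) family, so
each stratum's discovery list controls its own FDR. Strict inequalities are
used throughout:

- methylation: significant iff q < 0.05 and |Δβ| > 0.1, with Δβ the mean β
  difference tumor − adjacent within the stratum;
- mRNA/miRNA: significant iff q < 0.05. Fold change = ratio of group medians
  of normalized counts, with a 0.5 pseudo-count added to both medians only
  when either is zero. An optional |FC| > 2 filter exists for display subsets
  and never affects the core DE sets. Fold changes are computed on the
  TMM-normalized matrix by default (a `fc_on_raw` switch uses raw counts);
  medians are taken per stratum, consistently with Δβ.

## Integration

- **Promoter map**: gene → probes linked with region in {TSS1500, TSS200,
  UTR5, FirstExon} (the Illumina promoter-proximal labels; configurable).
- **DM genes / miRNAs**: ≥ 1 significant promoter DMC; supporting probes kept
  as provenance.
- **DMDE records**: one per (gene, supporting probe) with the gene DE in the
  matching contrast; reciprocal iff the probe's methylation direction opposes
  the expression direction. When promoter probes disagree in sign, each keeps
  its own record rather than averaging; a gene counts as reciprocal if any
  supporting probe is.
- **miRNA–target pairs**: DE miRNA × DE mRNA joined through the evidence-
  graded target database (default minimum: high_confidence, i.e.
  experimental or high-confidence entries); reciprocal iff directions oppose;
  non-reciprocal pairs retained with a flag.
- **Chains**: (probe, miRNA, gene) where the probe supports a reciprocal DMDE
  miRNA and the pair is reciprocal — the three directions necessarily
  alternate (hypo→up→down or hyper→down→up).
- **Mechanism-switch genes**: DE in both strata; ≥ 1 reciprocal miRNA driver
  DE in AA only; ≥ 1 reciprocal promoter DMC in EA only, with no significant
  promoter DMC in AA. Direction agreement between the strata is not required
  by default (`require_same_direction` enables it).
- **Correlation**: Pearson r between the supporting probe's M-values and
  log2(normalized expression + 0.5) across all samples of the record's
  stratum; the summary reports the fraction of records with |r| > 0.5.
  The absolute value is used because reciprocal regulation makes the
  expected sign negative; constant vectors yield r = NaN and are excluded
  from the denominator with a count.

## Synthetic cohorts

The generator emulates the linked structure of a real cohort, not its
genomic coordinates or batch structure:

- **β-values** are logit-normal: per-probe baseline (uniform β in
  0.15–0.85), patient effect (sd 0.5 logit by default), residual logit noise
  (sd 0.8), inverse-logit to (0,1). Planted effects are specified as a beta
  difference; since a fixed logit shift yields a baseline-dependent Δβ, the
  shift is calibrated per probe by Gauss–Hermite quadrature over the noise
  so the expected Δβ equals the requested value. Probes whose direction
  encodes a planted reciprocal relationship keep that direction (their
  baseline is re-centred if the target is out of range); free probes flip.
- **Counts** are negative binomial (gamma–Poisson, dispersion 0.1) with
  log-normal gene abundances, log-normal library sizes (sd 0.3, to exercise
  TMM), per-patient log-scale effects, and planted log2 fold changes on
  tumor samples of the target stratum.
- **Structure**: planted DMCs split into shared / AA-only / EA-only
  fractions (defaults EA-dominant, mirroring the methylation asymmetry of
  the motivating study design); DE features per omic likewise (defaults
  AA-dominant for miRNAs). Structural plantings draw disjoint feature sets:
  reciprocal DMDE genes (promoter probe with opposite direction), chains
  (promoter probe → miRNA → targets with alternating directions, pairs added
  to the target DB as experimental), and switch genes (shared DE gene,
  AA-only reciprocal miRNA driver in the DB, EA-only reciprocal promoter
  DMC). Decoy target pairs between non-DE features are added at 5× the
  planted pairs so integration specificity is measurable. Structural
  features sit on genes with abundance at or above the cohort median —
  a promoter- or miRNA-driven relationship is only observable for expressed
  genes.
- 2% of probes carry QC flags (never planted) to exercise filtering.

What passing tests on these cohorts do **not** show: robustness to batch
effects, probe cross-reactivity, cell-type composition, unpaired or
incomplete designs, or count models violating the NB assumption — none of
which the generator emulates.

## Calibration benchmarks and problem sizes

Two seeded benchmarks define the package's calibration claims (run by
`scripts/acceptance.py` and the test suite):

- **Methylation FDR**: 20 replicates of 5,000 CpGs, 8 + 8 paired patients,
  10% of sites with Δβ = 0.25 (patient sd 0.5, logit noise sd 0.8); the DMC
  rule must keep the mean false-discovery proportion ≤ 0.05 plus two
  Monte-Carlo standard errors.
- **Expression FDR**: 20 replicates of 5,000 genes of Gaussian log2
  expression (patient sd 0.5, residual sd 1.0), 10% planted effects of 1.5;
  same bound for the DE rule.

The structural-fidelity benchmark (EA-dominant methylation, AA-dominant
miRNA, 3,000 CpGs / 1,500 mRNAs / 300 miRNAs) validates the integration
logic end to end, so it uses strong planted effects (Δβ = 0.4 at logit noise
sd 0.5; log2 FC 2.5) that make single-feature recovery essentially
deterministic: a missed switch gene then indicates a rule defect rather than
sampling noise. The FDR benchmarks deliberately keep the noisier conditions.

## Numerical and design notes

- Validation is strict and total: malformed tables raise typed errors naming
  the offending patient/probe/sample; no silent coercion.
- Race/tissue tokens are case-sensitive exact strings; probe coordinates are
  1-based and provenance-only.
- Sample alignment between matrices and the design is by sample id, never by
  column order.
- All outputs are deterministically ordered (feature, then contrast in
  AA/EA/ALL order; integration tables sorted by identifiers), so reruns are
  bit-identical and tables are diffable.
- ω̂² truncation at 0 does not affect contrast inference (within-patient
  differences cancel the patient effect).
- BH q-values follow their p-values under permutation and satisfy
  p ≤ q ≤ 1; re-adjusting q-values is meaningless and not supported.

## Known limitations

- Only complete-pair, two-stratum designs; no covariates, no missing data,
  no moderated (empirical-Bayes) variances — by scope.
- The Gaussian model on log2 CPM is a pragmatic choice for small paired
  cohorts; count-model alternatives (NB GLMs) are out of scope.
- Enrichment/pathway analysis is out of scope; exported gene lists are
  suitable input for any enrichment tool.
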