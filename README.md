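# epichain

Integrative differential analysis of DNA methylation, miRNA expression and
mRNA expression in **paired tumor / adjacent non-tumor cohorts stratified by
race** (African American, AA; European American, EA), with a focus on
hepatocellular carcinoma-style study designs: small paired cohorts profiled
on an EPIC-style methylation array plus miRNA-seq and mRNA-seq.

The package answers three questions per molecular layer and then links the
layers:

1. which CpG sites / miRNAs / mRNAs change between tumor and adjacent tissue
   — within AA, within EA, and overall;
2. which genes are plausibly *epigenetically driven* (differentially
   methylated in their promoter **and** differentially expressed, in the
   reciprocal direction);
3. which genes switch epigenetic mechanism between strata (miRNA-driven in
   AA, promoter-methylation-driven in EA).

## The model

Each feature (CpG M-value, log2 normalized expression) is fit with a
split-plot mixed ANOVA:

    y_ijk = μ + τ_i + α_j + β_k + γ_jk + ε_ijk

with patient random effects τ_i ~ N(0, ω²), fixed race effects α_j, fixed
tissue (disease) effects β_k, their interaction γ_jk, and residuals
ε_ijk ~ N(0, σ²). Three tumor-vs-adjacent contrasts are tested per feature:

- **AA**: (β₁+γ₁₁) − (β₂+γ₁₂)
- **EA**: (β₁+γ₂₁) − (β₂+γ₂₂)
- **ALL**: (β₁−β₂) + ½(γ₁₁−γ₁₂) + ½(γ₂₁−γ₂₂) — the disease main effect with
  the races weighted equally.

Because every patient contributes one tumor and one adjacent sample, the
design is balanced within patient and the fit is closed-form: contrasts are
means of within-patient differences, the residual variance pools the
within-race scatter of those differences with df = N − 2, and ω² comes from
the between-patient mean square. The closed form is verified against a
numeric REML oracle in the test suite.

Downstream: Benjamini–Hochberg FDR within each (omic, contrast) family;
DMCs are called at q < 0.05 and |Δβ| > 0.1 (Δβ = mean β tumor − adjacent);
DE features at q < 0.05 (fold changes are ratios of group medians of
TMM-normalized counts). Integration is rule-based set algebra with full
provenance: promoter maps (TSS1500/TSS200/5'UTR/first exon), reciprocal DMDE
records, miRNA–target pairs from a user-supplied evidence-graded database,
DNAm → miRNA → mRNA chains with alternating directions, and mechanism-switch
genes.

Because studies of this design rarely share raw data, the package ships a
synthetic-cohort generator (`epichain.synthetic`) that emulates the full
linked structure — logit-normal β-values with calibrated planted effects,
negative-binomial counts, promoter links, target databases — with complete
ground truth, so every pipeline rule is testable end to end.

## Worked example

```python
import epichain as ec

cfg = ec.SimConfig(n_cpg=3000, n_mirna=300, n_mrna=1500,
                   dbeta_effect=0.40, beta_logit_sd=0.5, lfc_effect=2.5,
                   n_dmde=6, n_chains=3, n_switch=4, seed=1)
design, beta, mirna, mrna, ann, db, truth = ec.simulate(cfg)
res = ec.run_pipeline(ec.RunConfig(
    design=design, beta=beta, counts_mirna=mirna, counts_mrna=mrna,
    annotation=ann, targets=db, seed=1))
print(res.summary["differential_counts"])
```

The run summary prints the per-stratum count grid:

| stratum | DMCs | DM genes | DM miRNAs | DE mRNAs | DE miRNAs |
|---|---|---|---|---|---|
| AA | 156 | 6 | 3 | 111 | 35 |
| EA | 371 | 10 | 3 | 141 | 17 |
| ALL | 392 | 11 | 3 | 171 | 42 |

This cohort was simulated with EA-dominant methylation effects and
AA-dominant miRNA effects, and the analysis recovers exactly that asymmetry:
EA has 2.4× the DMCs of AA while AA has 2× the DE miRNAs. All four planted
mechanism-switch genes are recovered with no false positives
(`res.switch_genes`), and 89% of the 35 DMDE records show methylation–
expression correlation |r| > 0.5 across samples.

The same analysis runs from the shell on TSV/CSV inputs:

```
epichain simulate --config sim.yaml --out cohort/
epichain run --config run.yaml          # preprocess → test → call → integrate
epichain report RUN_DIR                 # Markdown summary of the count grids
```

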