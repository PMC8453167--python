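"""Self-calibration studies: FDR control, parameter recovery, structural
fidelity.

These functions define the package's standard simulation benchmarks and are
used by the acceptance script and the test suite.  Each replicate generates a
cohort with the stated conditions, runs the relevant slice of the pipeline
from scratch, and scores the calls against the generator's ground truth.

Conditions
----------
* Methylation FDR: 5,000 CpGs for 8 AA + 8 EA paired patients, 10% of sites
  carrying a disease effect of 0.25 on the beta scale (patient sd 0.5, logit
  noise sd 0.8); DMC rule q < 0.05 and |delta beta| > 0.1 on the pooled
  disease contrast.
* Expression FDR: 5,000 genes of Gaussian log2 expression (patient sd 0.5,
  residual sd 1.0), 10% carrying an effect of 1.5; DE rule q < 0.05.
* Parameter recovery: 200 features with a planted effect of 1.0 at residual
  sd 1.0, 8 + 8 patients.
* Structural fidelity: a smaller cohort with EA-dominant methylation and
  AA-dominant miRNA effects, run end to end.  This benchmark validates the
  integration *logic*, so it uses strong planted effects (delta beta 0.4 at
  logit noise sd 0.5, log2 fold change 2.5) that make single-feature recovery
  essentially deterministic; the FDR benchmarks above retain the noisier
  conditions.
"""

from __future__ import annotations

import numpy as np

from .anova import run_all
from .differential import bh_adjust, call_significant, delta_beta
from .io_formats import OmicsMatrix
from .pipeline import RunConfig, RunResult, run_pipeline
from .preprocess import beta_to_m, filter_probes
from .synthetic import (
    GroundTruth,
    SimConfig,
    make_design,
    simulate,
    simulate_gaussian_expression,
)

DMC_FDR_CONFIG = dict(
    n_cpg=5000,
    n_mirna=10,
    n_mrna=10,
    frac_dmc_shared=0.10,
    frac_dmc_aa_only=0.0,
    frac_dmc_ea_only=0.0,
    frac_de_mrna_shared=0.0,
    frac_de_mrna_aa_only=0.0,
    frac_de_mrna_ea_only=0.0,
    frac_de_mirna_shared=0.0,
    frac_de_mirna_aa_only=0.0,
    frac_de_mirna_ea_only=0.0,
    dbeta_effect=0.25,
    beta_logit_sd=0.8,
    patient_sd=0.5,
    n_dmde=0,
    n_chains=0,
    n_switch=0,
    frac_flagged=0.0,
)

STRUCTURAL_CONFIG = dict(
    n_cpg=3000,
    n_mirna=300,
    n_mrna=1500,
    dbeta_effect=0.40,
    beta_logit_sd=0.5,
    lfc_effect=2.5,
    n_dmde=6,
    n_chains=3,
    n_switch=4,
)


def dmc_fdp_replicate(seed: int, q_max: float = 0.05, dbeta_min: float = 0.1) -> float:
    """False-discovery proportion of DMC calls on one synthetic replicate."""
    config = SimConfig(seed=seed, **DMC_FDR_CONFIG)
    design, beta, _, _, annotation, _, truth = simulate(config)
    kept, _ = filter_probes(beta, annotation)
    results = run_all(beta_to_m(kept), design)
    fam = results[results["contrast"] == "ALL"].copy()
    fam["q"] = bh_adjust(fam["p"].to_numpy())
    calls = call_significant(
        fam, delta_beta(kept, design, "ALL"), "methylation", q_max, dbeta_min
    )
    called = set(calls[calls["significant"]]["feature_id"])
    fp = len(called - truth.dmc["ALL"])
    return fp / max(1, len(called))


def de_fdp_replicate(seed: int, q_max: float = 0.05) -> float:
    """False-discovery proportion of DE calls on Gaussian log-expression."""
    design = make_design(8, 8)
    matrix, planted = simulate_gaussian_expression(
        n_features=5000, design=design, effect_size=1.5, frac_de=0.10,
        patient_sd=0.5, residual_sd=1.0, seed=seed,
    )
    results = run_all(matrix, design)
    fam = results[results["contrast"] == "ALL"].copy()
    fam["q"] = bh_adjust(fam["p"].to_numpy())
    called = set(fam[fam["q"] < q_max]["feature_id"])
    fp = len(called - set(planted))
    return fp / max(1, len(called))


def mean_fdp(replicate, seeds) -> tuple[float, float]:
    """Mean FDP over seeded replicates plus its Monte-Carlo standard error."""
    fdps = np.array([replicate(s) for s in seeds])
    return float(fdps.mean()), float(fdps.std(ddof=1) / np.sqrt(len(fdps)))


def effect_recovery_bias(seed: int, n_features: int = 200,
                         effect: float = 1.0) -> float:
    """Mean signed error of the pooled-contrast estimate on planted effects."""
    design = make_design(8, 8)
    matrix, planted = simulate_gaussian_expression(
        n_features=n_features, design=design, effect_size=effect, frac_de=1.0,
        patient_sd=0.5, residual_sd=1.0, seed=seed,
    )
    results = run_all(matrix, design)
    fam = results[results["contrast"] == "ALL"].set_index("feature_id")
    genes = sorted(planted)
    est = fam.loc[genes, "estimate"].to_numpy()
    true = np.array([planted[g] for g in genes])
    return float(np.mean(est - true))


def structural_fidelity_run(seed: int) -> tuple[RunResult, GroundTruth]:
    """End-to-end run on an EA-methylation / AA-miRNA dominant cohort."""
    config = SimConfig(seed=seed, **STRUCTURAL_CONFIG)
    design, beta, mirna, mrna, annotation, targets, truth = simulate(config)
    rc = RunConfig(
        design=design, beta=beta, counts_mirna=mirna, counts_mrna=mrna,
        annotation=annotation, targets=targets, seed=seed,
    )
    return run_pipeline(rc), truth
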