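"""Synthetic paired two-stratum cohorts with known ground truth.

The generator emulates the structure of a paired tumor/adjacent multi-omics
study over two racial strata (AA, EA): a logit-normal beta-value matrix with
planted disease and race-by-disease methylation effects, negative-binomial
miRNA and mRNA count matrices with planted fold changes, a probe annotation
whose promoter links realise reciprocal DMDE genes, full
methylation -> miRNA -> mRNA chains and mechanism-switch genes, and a target
database holding the planted reciprocal pairs plus decoys.

Planted methylation effects are specified as a beta difference; because the
signal is added on the logit scale, the generator calibrates the logit shift
per probe (by quadrature over the noise distribution) so the *expected* beta
difference at that probe's baseline equals the requested value.

Every random draw flows from a single integer seed; the same seed reproduces
the cohort bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import ConsistencyError, ParameterError
from .io_formats import (
    AnnotationTable,
    Link,
    OmicsMatrix,
    StudyDesign,
    TargetDB,
)

STRATA = ("AA", "EA", "ALL")


@dataclass
class SimConfig:
    """Cohort and effect-planting configuration.

    Defaults emulate the study conditions this package targets: 8 AA + 8 EA
    patients with paired tumor/adjacent samples, methylation effects dominated
    by EA and miRNA effects dominated by AA, a planted beta difference of 0.25
    and planted log2 fold change of 1.5.
    """

    n_aa: int = 8
    n_ea: int = 8
    n_cpg: int = 5000
    n_mirna: int = 400
    n_mrna: int = 3000
    # methylation planting (fractions of n_cpg)
    frac_dmc_shared: float = 0.04
    frac_dmc_aa_only: float = 0.01
    frac_dmc_ea_only: float = 0.08
    # expression planting (fractions of the omic's feature count)
    frac_de_mrna_shared: float = 0.05
    frac_de_mrna_aa_only: float = 0.02
    frac_de_mrna_ea_only: float = 0.04
    frac_de_mirna_shared: float = 0.03
    frac_de_mirna_aa_only: float = 0.08
    frac_de_mirna_ea_only: float = 0.02
    # effect sizes
    dbeta_effect: float = 0.25
    lfc_effect: float = 1.5
    # noise
    beta_logit_sd: float = 0.8
    patient_sd: float = 0.5
    nb_dispersion: float = 0.1
    mean_depth: float = 5e5
    # structural planting
    n_dmde: int = 10
    n_chains: int = 5
    n_switch: int = 5
    chain_probes_per_mirna: int = 1
    chain_targets_per_mirna: int = 1
    multi_probe_promoters: bool = False
    decoy_target_factor: int = 5
    frac_flagged: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_aa < 2 or self.n_ea < 2:
            raise ParameterError("need >=2 patients per stratum")
        for name in ("frac_dmc", "frac_de_mrna", "frac_de_mirna"):
            total = sum(
                getattr(self, f"{name}_{s}") for s in ("shared", "aa_only", "ea_only")
            )
            if not 0 <= total <= 1:
                raise ParameterError(f"{name} fractions must sum to [0, 1], got {total}")
        if not 0 <= self.frac_flagged < 1:
            raise ParameterError("frac_flagged must be in [0, 1)")
        if self.nb_dispersion <= 0 or self.mean_depth <= 0:
            raise ParameterError("nb_dispersion and mean_depth must be positive")
        # structural feasibility: planted structures draw disjoint features
        n_shared_mrna = int(self.frac_de_mrna_shared * self.n_mrna)
        need_mrna = (
            self.n_dmde
            + self.n_chains * self.chain_targets_per_mirna
            + self.n_switch
        )
        if need_mrna > n_shared_mrna:
            raise ParameterError(
                f"structural planting needs {need_mrna} shared DE mRNAs, "
                f"only {n_shared_mrna} available"
            )
        if self.n_chains > int(self.frac_de_mirna_shared * self.n_mirna):
            raise ParameterError("not enough shared DE miRNAs for planted chains")
        if self.n_switch > int(self.frac_de_mirna_aa_only * self.n_mirna):
            raise ParameterError("not enough AA-only DE miRNAs for switch genes")
        n_clean = self.n_cpg - int(self.frac_flagged * self.n_cpg)
        n_dmc_shared = int(self.frac_dmc_shared * self.n_cpg)
        probes_needed = (
            self.n_dmde * (2 if self.multi_probe_promoters else 1)
            + self.n_chains * self.chain_probes_per_mirna
        )
        if probes_needed > n_dmc_shared:
            raise ParameterError(
                f"structural planting needs {probes_needed} shared DMCs, "
                f"only {n_dmc_shared} available"
            )
        if self.n_switch > int(self.frac_dmc_ea_only * self.n_cpg):
            raise ParameterError("not enough EA-only DMCs for switch genes")
        n_dmc = n_dmc_shared + int(self.frac_dmc_aa_only * self.n_cpg) + int(
            self.frac_dmc_ea_only * self.n_cpg
        )
        if n_dmc > n_clean:
            raise ParameterError("planted DMCs exceed clean probes")


@dataclass
class GroundTruth:
    """Planted truth for every downstream call category."""

    dmc: dict[str, set]            # stratum -> probe ids with a true effect
    de_mrna: dict[str, set]        # stratum -> gene ids
    de_mirna: dict[str, set]       # stratum -> mirna ids
    dmde_genes: dict[str, list]    # gene -> supporting probe ids
    dmde_mirnas: dict[str, list]   # mirna -> supporting probe ids
    chains: list                   # (probe, mirna, gene) triples
    switch_genes: dict[str, dict]  # gene -> {aa_mirnas, ea_probes}
    effects: dict[str, float]
    universe: dict[str, set]       # category -> all feature ids of that omic


# ---------------------------------------------------------------------------
# beta-shift calibration

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(40)


def _expected_beta(mu: float, sd: float) -> float:
    """E[expit(mu + Z)], Z ~ N(0, sd^2), by Gauss-Hermite quadrature."""
    z = np.sqrt(2.0) * sd * _GH_NODES
    return float(np.sum(_GH_WEIGHTS * expit(mu + z)) / np.sqrt(np.pi))


def calibrate_logit_shift(mu: float, sd: float, target_dbeta: float) -> float:
    """Logit shift delta with E[beta(mu+delta)] - E[beta(mu)] = target_dbeta."""
    base = _expected_beta(mu, sd)
    goal = base + target_dbeta
    if not 0.001 < goal < 0.999:
        raise ParameterError(
            f"target beta difference {target_dbeta} infeasible at baseline {base:.3f}"
        )
    return brentq(lambda d: _expected_beta(mu + d, sd) - goal, -30.0, 30.0, xtol=1e-10)


# ---------------------------------------------------------------------------
# generators


def make_design(n_aa: int, n_ea: int) -> StudyDesign:
    """Paired tumor/adjacent design with the given stratum sizes."""
    rows = []
    for race, n in (("AA", n_aa), ("EA", n_ea)):
        for i in range(n):
            patient = f"{race}{i + 1:02d}"
            for tissue, tag in (("tumor", "T"), ("adjacent", "N")):
                rows.append(
                    {
                        "sample_id": f"{patient}_{tag}",
                        "patient_id": patient,
                        "race": race,
                        "tissue": tissue,
                    }
                )
    return StudyDesign(pd.DataFrame(rows))


def _tumor_mask(design: StudyDesign, stratum: str) -> np.ndarray:
    t = design.table
    mask = (t["tissue"] == "tumor").to_numpy()
    if stratum != "shared":
        race = "AA" if stratum == "aa_only" else "EA"
        mask &= (t["race"] == race).to_numpy()
    return mask


def _plant_partition(rng, ids: list[str], fracs: dict[str, float], total: int):
    """Split the first sum(counts) shuffled ids into shared/aa_only/ea_only."""
    ids = list(ids)
    rng.shuffle(ids)
    out: dict[str, list[str]] = {}
    start = 0
    for stratum, frac in fracs.items():
        k = int(frac * total)
        out[stratum] = ids[start : start + k]
        start += k
    out["null"] = ids[start:]
    return out


def simulate(config: SimConfig):
    """Generate a fully linked cohort.

    Returns ``(design, beta, mirna_counts, mrna_counts, annotation, target_db,
    truth)``; all tables pass the io_formats validators and the same seed
    reproduces all outputs bit-exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = make_design(config.n_aa, config.n_ea)
    n_samples = len(design.sample_ids)
    n_patients = design.n_aa + design.n_ea
    patient_idx = pd.Categorical(
        design.table["patient_id"], categories=design.patients
    ).codes

    probe_ids = [f"cg{i:07d}" for i in range(config.n_cpg)]
    mirna_ids = [f"miR-{i:04d}" for i in range(config.n_mirna)]
    mrna_ids = [f"GENE{i:05d}" for i in range(config.n_mrna)]

    # -- partition probes: flagged probes are never planted ------------------
    n_flagged = int(config.frac_flagged * config.n_cpg)
    flagged = probe_ids[config.n_cpg - n_flagged :]
    clean = probe_ids[: config.n_cpg - n_flagged]
    dmc_sets = _plant_partition(
        rng,
        clean,
        {
            "shared": config.frac_dmc_shared,
            "aa_only": config.frac_dmc_aa_only,
            "ea_only": config.frac_dmc_ea_only,
        },
        config.n_cpg,
    )
    de_mrna_sets = _plant_partition(
        rng,
        mrna_ids,
        {
            "shared": config.frac_de_mrna_shared,
            "aa_only": config.frac_de_mrna_aa_only,
            "ea_only": config.frac_de_mrna_ea_only,
        },
        config.n_mrna,
    )
    de_mirna_sets = _plant_partition(
        rng,
        mirna_ids,
        {
            "shared": config.frac_de_mirna_shared,
            "aa_only": config.frac_de_mirna_aa_only,
            "ea_only": config.frac_de_mirna_ea_only,
        },
        config.n_mirna,
    )

    # signed effect per planted feature (direction random)
    meth_dir = {
        p: int(d)
        for s in ("shared", "aa_only", "ea_only")
        for p, d in zip(dmc_sets[s], rng.choice([-1, 1], size=len(dmc_sets[s])))
    }
    mrna_dir = {
        g: int(d)
        for s in ("shared", "aa_only", "ea_only")
        for g, d in zip(de_mrna_sets[s], rng.choice([-1, 1], size=len(de_mrna_sets[s])))
    }
    mirna_dir = {
        m: int(d)
        for s in ("shared", "aa_only", "ea_only")
        for m, d in zip(
            de_mirna_sets[s], rng.choice([-1, 1], size=len(de_mirna_sets[s]))
        )
    }

    # -- structural planting (disjoint picks from the shared pools) ----------
    shared_mrna = list(de_mrna_sets["shared"])
    shared_mirna = list(de_mirna_sets["shared"])
    shared_dmc = list(dmc_sets["shared"])

    dmde_genes_list = [shared_mrna.pop() for _ in range(config.n_dmde)]
    chain_targets = [
        [shared_mrna.pop() for _ in range(config.chain_targets_per_mirna)]
        for _ in range(config.n_chains)
    ]
    switch_genes_list = [shared_mrna.pop() for _ in range(config.n_switch)]
    chain_mirnas = [shared_mirna.pop() for _ in range(config.n_chains)]
    switch_mirnas = list(de_mirna_sets["aa_only"][: config.n_switch])
    switch_probes = list(dmc_sets["ea_only"][: config.n_switch])

    links: dict[str, list[Link]] = {p: [] for p in probe_ids}
    dmde_truth: dict[str, list] = {}
    dmde_mirna_truth: dict[str, list] = {}
    chain_truth: list[tuple[str, str, str]] = []
    switch_truth: dict[str, dict] = {}
    target_rows: list[dict] = []

    # reciprocal DMDE mRNAs: promoter probe methylated opposite to expression
    for gene in dmde_genes_list:
        probe = shared_dmc.pop()
        meth_dir[probe] = -mrna_dir[gene]
        links[probe].append(Link(gene, "TSS200", "mrna"))
        dmde_truth[gene] = [probe]
        if config.multi_probe_promoters:
            probe2 = shared_dmc.pop()
            meth_dir[probe2] = mrna_dir[gene]  # non-reciprocal second probe
            links[probe2].append(Link(gene, "TSS1500", "mrna"))
            dmde_truth[gene].append(probe2)

    # chains: promoter DMC -> miRNA -> targets, directions alternating
    for mirna, targets in zip(chain_mirnas, chain_targets):
        probes = []
        for _ in range(config.chain_probes_per_mirna):
            probe = shared_dmc.pop()
            meth_dir[probe] = -mirna_dir[mirna]
            links[probe].append(Link(mirna, "TSS1500", "mirna"))
            probes.append(probe)
        dmde_mirna_truth[mirna] = probes
        for gene in targets:
            mrna_dir[gene] = -mirna_dir[mirna]
            target_rows.append(
                {"mirna_id": mirna, "gene_id": gene, "evidence": "experimental"}
            )
            for probe in probes:
                chain_truth.append((probe, mirna, gene))

    # mechanism-switch genes: AA-only miRNA driver, EA-only promoter DMC
    for gene, mirna, probe in zip(switch_genes_list, switch_mirnas, switch_probes):
        mirna_dir[mirna] = -mrna_dir[gene]
        meth_dir[probe] = -mrna_dir[gene]
        links[probe].append(Link(gene, "TSS200", "mrna"))
        target_rows.append(
            {"mirna_id": mirna, "gene_id": gene, "evidence": "high_confidence"}
        )
        switch_truth[gene] = {"aa_mirnas": [mirna], "ea_probes": [probe]}

    # decoy promoter links on null probes to null genes (and some gene bodies)
    null_probes = list(dmc_sets["null"])
    rng.shuffle(null_probes)
    null_genes = [g for g in de_mrna_sets["null"]]
    n_decoy_links = min(len(null_probes) // 2, len(null_genes), 200)
    for probe, gene in zip(null_probes[:n_decoy_links], null_genes[:n_decoy_links]):
        region = str(rng.choice(["TSS1500", "TSS200", "Body", "UTR3"]))
        links[probe].append(Link(gene, region, "mrna"))

    # decoy target pairs between non-DE miRNAs and non-DE genes
    n_planted_pairs = len(target_rows)
    null_mirnas = list(de_mirna_sets["null"])
    decoy_genes = null_genes[n_decoy_links:]
    n_decoys = min(
        config.decoy_target_factor * max(1, n_planted_pairs),
        len(null_mirnas) * max(1, len(decoy_genes)),
    )
    seen_pairs = {(r["mirna_id"], r["gene_id"]) for r in target_rows}
    k = 0
    while k < n_decoys and decoy_genes and null_mirnas:
        m = null_mirnas[int(rng.integers(len(null_mirnas)))]
        g = decoy_genes[int(rng.integers(len(decoy_genes)))]
        if (m, g) in seen_pairs:
            k += 1  # tolerate collisions; pair density is low
            continue
        seen_pairs.add((m, g))
        evidence = str(rng.choice(["experimental", "high_confidence", "moderate"]))
        target_rows.append({"mirna_id": m, "gene_id": g, "evidence": evidence})
        k += 1

    # -- beta matrix ---------------------------------------------------------
    baseline = rng.uniform(0.15, 0.85, size=config.n_cpg)
    mu = logit(baseline)
    total_sd = float(np.hypot(config.patient_sd, config.beta_logit_sd))

    # probes whose direction encodes a planted reciprocal relationship must
    # keep it; their baseline is re-centred if the target is out of range.
    direction_fixed = (
        {p for probes in dmde_truth.values() for p in probes}
        | {p for probes in dmde_mirna_truth.values() for p in probes}
        | set(switch_probes)
    )
    shift = np.zeros(config.n_cpg)
    probe_pos = {p: i for i, p in enumerate(probe_ids)}
    for stratum in ("shared", "aa_only", "ea_only"):
        for p in dmc_sets[stratum]:
            i = probe_pos[p]
            d = meth_dir[p]
            target = d * config.dbeta_effect
            base = _expected_beta(mu[i], total_sd)
            if not 0.02 < base + target < 0.98:
                if p in direction_fixed:
                    mu[i] = logit(np.clip(0.5 - target / 2.0, 0.1, 0.9))
                else:  # free probes just flip direction
                    d = -d
                    meth_dir[p] = d
                    target = -target
            shift[i] = calibrate_logit_shift(mu[i], total_sd, target)

    tau = rng.normal(0.0, config.patient_sd, size=(config.n_cpg, n_patients))
    eps = rng.normal(0.0, config.beta_logit_sd, size=(config.n_cpg, n_samples))
    y = mu[:, None] + tau[:, patient_idx] + eps
    for stratum in ("shared", "aa_only", "ea_only"):
        mask = _tumor_mask(design, stratum)
        idx = [probe_pos[p] for p in dmc_sets[stratum]]
        if idx:
            y[np.ix_(idx, np.where(mask)[0])] += shift[idx][:, None]
    beta_vals = expit(y)
    beta = OmicsMatrix(probe_ids, design.sample_ids, beta_vals, "beta")

    # -- count matrices ------------------------------------------------------
    # structural features sit on adequately expressed genes: a promoter- or
    # miRNA-driven relationship is only observable when the gene is expressed
    structural_features = (
        set(dmde_truth) | set(dmde_mirna_truth) | set(switch_truth)
        | set(switch_mirnas)
        | {g for targets in chain_targets for g in targets}
    )

    def make_counts(feature_ids, dir_map, sets):
        n = len(feature_ids)
        rel = rng.lognormal(mean=0.0, sigma=1.5, size=n)
        floor = float(np.median(rel))
        for i, f in enumerate(feature_ids):
            if f in structural_features:
                rel[i] = max(rel[i], floor)
        lam = rel / rel.sum() * config.mean_depth
        libfac = rng.lognormal(mean=0.0, sigma=0.3, size=n_samples)
        tau_c = rng.normal(0.0, config.patient_sd, size=(n, n_patients))
        log2mean = np.log2(lam)[:, None] + tau_c[:, patient_idx]
        pos = {f: i for i, f in enumerate(feature_ids)}
        for stratum in ("shared", "aa_only", "ea_only"):
            mask = _tumor_mask(design, stratum)
            idx = [pos[f] for f in sets[stratum]]
            if idx:
                eff = np.array([dir_map[feature_ids[i]] for i in idx], dtype=float)
                log2mean[np.ix_(idx, np.where(mask)[0])] += (
                    eff[:, None] * config.lfc_effect
                )
        mean = (2.0 ** log2mean) * libfac[None, :]
        shape = 1.0 / config.nb_dispersion
        counts = rng.poisson(rng.gamma(shape, mean / shape)).astype(float)
        return OmicsMatrix(list(feature_ids), design.sample_ids, counts, "counts")

    mirna_counts = make_counts(mirna_ids, mirna_dir, de_mirna_sets)
    mrna_counts = make_counts(mrna_ids, mrna_dir, de_mrna_sets)

    # -- annotation ----------------------------------------------------------
    flag_pool = ["non_cpg", "snp_within_10bp", "repeat_within_15bp", "multi_hit",
                 "sex_chrom"]
    ann_rows = []
    flagged_set = set(flagged)
    for i, p in enumerate(probe_ids):
        if p in flagged_set:
            flag = flag_pool[i % len(flag_pool)]
            chrom = "chrX" if flag == "sex_chrom" else f"chr{1 + i % 22}"
            flags = frozenset({flag})
        else:
            chrom = f"chr{1 + i % 22}"
            flags = frozenset()
        ann_rows.append(
            {
                "probe_id": p,
                "chrom": chrom,
                "pos": 1000 + 137 * i,
                "qc_flags": flags,
                "links": tuple(links[p]),
            }
        )
    annotation = AnnotationTable(pd.DataFrame(ann_rows))
    target_db = TargetDB(pd.DataFrame(target_rows, columns=["mirna_id", "gene_id", "evidence"]))

    # -- truth ---------------------------------------------------------------
    def strat_sets(sets):
        return {
            "AA": set(sets["shared"]) | set(sets["aa_only"]),
            "EA": set(sets["shared"]) | set(sets["ea_only"]),
            "ALL": set(sets["shared"]) | set(sets["aa_only"]) | set(sets["ea_only"]),
        }

    truth = GroundTruth(
        dmc=strat_sets(dmc_sets),
        de_mrna=strat_sets(de_mrna_sets),
        de_mirna=strat_sets(de_mirna_sets),
        dmde_genes=dmde_truth,
        dmde_mirnas=dmde_mirna_truth,
        chains=chain_truth,
        switch_genes=switch_truth,
        effects={
            "dbeta_effect": config.dbeta_effect,
            "lfc_effect": config.lfc_effect,
        },
        universe={
            "dmc": set(probe_ids),
            "de_mrna": set(mrna_ids),
            "de_mirna": set(mirna_ids),
        },
    )
    return design, beta, mirna_counts, mrna_counts, annotation, target_db, truth


def simulate_gaussian_expression(
    n_features: int,
    design: StudyDesign,
    effect_size: float,
    frac_de: float,
    patient_sd: float,
    residual_sd: float,
    seed: int,
) -> tuple[OmicsMatrix, dict]:
    """Gaussian log-expression with a planted disease effect (both strata).

    A direct generator for calibration studies of the linear model: per-gene
    baseline, patient random effect (sd ``patient_sd``), residual noise
    (sd ``residual_sd``), and a signed shift of ``effect_size`` on the tumor
    samples of a random ``frac_de`` fraction of genes.  Returns the matrix
    (kind ``normalized``, already on the log scale) and a mapping of planted
    gene to its signed effect.
    """
    rng = np.random.default_rng(seed)
    features = [f"G{i:05d}" for i in range(n_features)]
    n_samples = len(design.sample_ids)
    n_patients = len(design.patients)
    patient_idx = pd.Categorical(
        design.table["patient_id"], categories=design.patients
    ).codes
    tumor = (design.table["tissue"] == "tumor").to_numpy()

    n_de = int(frac_de * n_features)
    planted = list(rng.choice(n_features, size=n_de, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_de)

    base = rng.normal(6.0, 2.0, size=n_features)
    tau = rng.normal(0.0, patient_sd, size=(n_features, n_patients))
    eps = rng.normal(0.0, residual_sd, size=(n_features, n_samples))
    y = base[:, None] + tau[:, patient_idx] + eps
    for i, s in zip(planted, signs):
        y[i, tumor] += s * effect_size
    matrix = OmicsMatrix(features, design.sample_ids, y, "normalized")
    return matrix, {features[i]: float(s) * effect_size
                    for i, s in zip(planted, signs)}


def truth_eval(calls: dict[str, dict[str, set]], truth: GroundTruth) -> pd.DataFrame:
    """Sensitivity and false-discovery proportion per category and stratum.

    ``calls`` maps category (dmc, de_mrna, de_mirna) to stratum to the set of
    called identifiers.  FDP = false calls / max(1, total calls);
    sensitivity = recovered / planted.
    """
    rows = []
    for category, by_stratum in calls.items():
        if category not in truth.universe:
            raise ConsistencyError(f"unknown category {category!r}")
        universe = truth.universe[category]
        truth_sets = getattr(truth, category)
        for stratum, called in by_stratum.items():
            called = set(called)
            unknown = called - universe
            if unknown:
                raise ConsistencyError(
                    f"unknown identifier(s) in {category}/{stratum}: "
                    f"{sorted(unknown)[:5]}"
                )
            true_set = truth_sets[stratum]
            tp = len(called & true_set)
            fp = len(called - true_set)
            rows.append(
                {
                    "category": category,
                    "stratum": stratum,
                    "n_called": len(called),
                    "n_true": len(true_set),
                    "tp": tp,
                    "fp": fp,
                    "sensitivity": tp / len(true_set) if true_set else np.nan,
                    "fdp": fp / max(1, len(called)),
                }
            )
    return pd.DataFrame(rows)
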