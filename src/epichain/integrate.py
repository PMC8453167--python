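"""Cross-layer integration of methylation, miRNA and mRNA calls.

The integration layers, in order:

1. promoter map — which CpG probes sit in which gene's promoter
   (default promoter labels: TSS1500, TSS200, UTR5, FirstExon);
2. DM genes / DM miRNAs — genes with at least one significant DMC in the
   promoter;
3. DMDE records — DM genes that are also differentially expressed, flagged
   reciprocal when the methylation direction opposes the expression
   direction (hyper+down or hypo+up);
4. miRNA-target pairs — DE miRNA and DE target mRNA joined through the
   target database, flagged reciprocal when their directions oppose;
5. chains — promoter DMC -> DE miRNA -> DE target mRNA with both links
   reciprocal, so the three directions alternate;
6. mechanism-switch genes — genes DE in both strata whose epigenetic driver
   is miRNA-only in AA and promoter-methylation-only in EA;
7. methylation-expression correlation over the DMDE records.

Every record carries the identifiers that support it, so each call can be
traced back to the probes, miRNAs and thresholds that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError
from .io_formats import AnnotationTable, OmicsMatrix, StudyDesign, TargetDB

PROMOTER_REGIONS_DEFAULT = frozenset({"TSS1500", "TSS200", "UTR5", "FirstExon"})


@dataclass
class PromoterMap:
    """gene_id -> promoter probes, with each gene's class (mrna | mirna)."""

    probes: dict[str, list[str]]
    gene_class: dict[str, str]
    promoter_regions: frozenset[str]

    def genes(self, gene_class: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == gene_class]


def build_promoter_map(
    annotation: AnnotationTable,
    promoter_regions: frozenset[str] | set[str] = PROMOTER_REGIONS_DEFAULT,
) -> PromoterMap:
    """Collect each gene's promoter CpGs; genes with none are omitted."""
    if not promoter_regions:
        raise ParameterError("promoter_regions must be non-empty")
    promoter_regions = frozenset(promoter_regions)
    probes: dict[str, list[str]] = {}
    gene_class: dict[str, str] = {}
    for _, row in annotation.table.iterrows():
        for link in row["links"]:
            if link.region in promoter_regions:
                probes.setdefault(link.gene_id, []).append(row["probe_id"])
                gene_class[link.gene_id] = link.gene_class
    return PromoterMap(probes, gene_class, promoter_regions)


def dm_genes(dmcs: pd.DataFrame, pmap: PromoterMap) -> pd.DataFrame:
    """Map significant DMCs to DM genes/miRNAs through the promoter map.

    ``dmcs`` is a methylation call table (one contrast); the output has one
    row per (gene, supporting probe) with the probe's delta-beta, restricted
    to significant probes.
    """
    sig = dmcs[dmcs["significant"]]
    effect = dict(zip(sig["feature_id"], sig["effect"]))
    rows = []
    for gene, probes in pmap.probes.items():
        for probe in probes:
            if probe in effect:
                rows.append(
                    {
                        "gene_id": gene,
                        "gene_class": pmap.gene_class[gene],
                        "probe_id": probe,
                        "dbeta": effect[probe],
                    }
                )
    out = pd.DataFrame(rows, columns=["gene_id", "gene_class", "probe_id", "dbeta"])
    return out.sort_values(["gene_id", "probe_id"], kind="stable").reset_index(drop=True)


def select_dmde(dm: pd.DataFrame, de: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """DMDE records: DM genes that are also DE, one row per supporting probe.

    ``dm`` is the :func:`dm_genes` output restricted to one gene class;
    ``de`` is the matching expression call table for the same contrast.
    A record is reciprocal when the probe's methylation direction opposes the
    gene's expression direction; a gene counts as reciprocal DMDE when at
    least one of its supporting probes is reciprocal.
    """
    sig = de[de["significant"]]
    expr_dir = dict(zip(sig["feature_id"], sig["direction"]))
    rows = []
    for _, r in dm.iterrows():
        if r["gene_id"] not in expr_dir:
            continue
        direction = expr_dir[r["gene_id"]]
        reciprocal = (r["dbeta"] > 0 and direction == "down") or (
            r["dbeta"] < 0 and direction == "up"
        )
        rows.append(
            {
                "gene_id": r["gene_id"],
                "gene_class": r["gene_class"],
                "contrast": contrast,
                "probe_id": r["probe_id"],
                "dbeta": r["dbeta"],
                "expr_direction": direction,
                "reciprocal": reciprocal,
            }
        )
    cols = ["gene_id", "gene_class", "contrast", "probe_id", "dbeta",
            "expr_direction", "reciprocal"]
    out = pd.DataFrame(rows, columns=cols)
    out["reciprocal"] = out["reciprocal"].astype(bool)
    return out.sort_values(["gene_id", "probe_id"], kind="stable").reset_index(drop=True)


def match_targets(
    de_mirna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    db: TargetDB,
    evidence_min: str = "high_confidence",
) -> pd.DataFrame:
    """Join DE miRNAs to their DE target genes through the target database.

    Pairs must be in the database at evidence at least ``evidence_min``
    (experimental > high_confidence > moderate).  Reciprocal means the miRNA
    and target directions oppose; non-reciprocal pairs are kept with the flag
    set to False.
    """
    mir = de_mirna[de_mirna["significant"]]
    rna = de_mrna[de_mrna["significant"]]
    mir_dir = dict(zip(mir["feature_id"], mir["direction"]))
    rna_dir = dict(zip(rna["feature_id"], rna["direction"]))
    rows = []
    for _, r in db.at_least(evidence_min).iterrows():
        if r["mirna_id"] in mir_dir and r["gene_id"] in rna_dir:
            md, gd = mir_dir[r["mirna_id"]], rna_dir[r["gene_id"]]
            rows.append(
                {
                    "mirna_id": r["mirna_id"],
                    "gene_id": r["gene_id"],
                    "evidence": r["evidence"],
                    "mirna_direction": md,
                    "target_direction": gd,
                    "reciprocal": md != gd,
                }
            )
    cols = ["mirna_id", "gene_id", "evidence", "mirna_direction",
            "target_direction", "reciprocal"]
    out = pd.DataFrame(rows, columns=cols)
    out["reciprocal"] = out["reciprocal"].astype(bool)
    return out.sort_values(["mirna_id", "gene_id"], kind="stable").reset_index(drop=True)


def build_chains(dmde_mirna: pd.DataFrame, target_pairs: pd.DataFrame) -> pd.DataFrame:
    """Methylation -> miRNA -> target chains.

    One chain per (probe, mirna, gene) where the probe supports a reciprocal
    DMDE miRNA and the (mirna, gene) pair is a reciprocal target pair.  By
    construction the three directions alternate (hypo -> up -> down or
    hyper -> down -> up).
    """
    mir = dmde_mirna[dmde_mirna["reciprocal"]]
    pairs = target_pairs[target_pairs["reciprocal"]]
    rows = []
    for _, m in mir.iterrows():
        meth_dir = "hyper" if m["dbeta"] > 0 else "hypo"
        for _, p in pairs[pairs["mirna_id"] == m["gene_id"]].iterrows():
            rows.append(
                {
                    "probe_id": m["probe_id"],
                    "mirna_id": p["mirna_id"],
                    "gene_id": p["gene_id"],
                    "meth_direction": meth_dir,
                    "mirna_direction": p["mirna_direction"],
                    "target_direction": p["target_direction"],
                }
            )
    cols = ["probe_id", "mirna_id", "gene_id", "meth_direction",
            "mirna_direction", "target_direction"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["probe_id", "mirna_id", "gene_id"],
                           kind="stable").reset_index(drop=True)


def detect_switch(
    calls_aa: dict[str, pd.DataFrame],
    calls_ea: dict[str, pd.DataFrame],
    db: TargetDB,
    pmap: PromoterMap,
    evidence_min: str = "high_confidence",
    require_same_direction: bool = False,
) -> pd.DataFrame:
    """Genes regulated by different epigenetic mechanisms in the two strata.

    A gene qualifies when (a) it is DE in both AA and EA; (b) at least one
    miRNA that is DE in AA but not in EA targets it reciprocally in AA;
    (c) at least one of its promoter probes is a reciprocal DMC in EA while
    the gene has no significant promoter DMC in AA.  ``calls_aa``/``calls_ea``
    map omic name (methylation, mrna, mirna) to the stratum's call table.
    """

    def sig(calls: dict[str, pd.DataFrame], omic: str) -> pd.DataFrame:
        t = calls[omic]
        return t[t["significant"]]

    de_mrna_aa = sig(calls_aa, "mrna")
    de_mrna_ea = sig(calls_ea, "mrna")
    dir_aa = dict(zip(de_mrna_aa["feature_id"], de_mrna_aa["direction"]))
    dir_ea = dict(zip(de_mrna_ea["feature_id"], de_mrna_ea["direction"]))
    both_de = set(dir_aa) & set(dir_ea)

    mir_aa = sig(calls_aa, "mirna")
    mir_ea_set = set(sig(calls_ea, "mirna")["feature_id"])
    mir_aa_dir = dict(zip(mir_aa["feature_id"], mir_aa["direction"]))

    dmc_aa = sig(calls_aa, "methylation")
    dmc_ea = sig(calls_ea, "methylation")
    dmc_aa_set = set(dmc_aa["feature_id"])
    dbeta_ea = dict(zip(dmc_ea["feature_id"], dmc_ea["effect"]))

    targets = db.at_least(evidence_min)
    targets_of: dict[str, list[str]] = {}
    for _, r in targets.iterrows():
        targets_of.setdefault(r["gene_id"], []).append(r["mirna_id"])

    rows = []
    for gene in sorted(both_de):
        if require_same_direction and dir_aa[gene] != dir_ea[gene]:
            continue
        # (b) AA-exclusive reciprocal miRNA drivers
        aa_mirnas = sorted(
            m
            for m in targets_of.get(gene, [])
            if m in mir_aa_dir
            and m not in mir_ea_set
            and mir_aa_dir[m] != dir_aa[gene]
        )
        if not aa_mirnas:
            continue
        # (c) EA-exclusive reciprocal promoter methylation
        promoter_probes = pmap.probes.get(gene, [])
        if any(p in dmc_aa_set for p in promoter_probes):
            continue  # gene is DM in AA: not methylation-exclusive to EA
        ea_probes = sorted(
            p
            for p in promoter_probes
            if p in dbeta_ea
            and (
                (dbeta_ea[p] > 0 and dir_ea[gene] == "down")
                or (dbeta_ea[p] < 0 and dir_ea[gene] == "up")
            )
        )
        if not ea_probes:
            continue
        rows.append(
            {
                "gene_id": gene,
                "aa_mirnas": ";".join(aa_mirnas),
                "ea_probes": ";".join(ea_probes),
                "gene_direction_aa": dir_aa[gene],
                "gene_direction_ea": dir_ea[gene],
            }
        )
    cols = ["gene_id", "aa_mirnas", "ea_probes",
            "gene_direction_aa", "gene_direction_ea"]
    return pd.DataFrame(rows, columns=cols)


def correlate_meth_expr(
    meth: OmicsMatrix,
    expr: OmicsMatrix,
    dmde: pd.DataFrame,
    design: StudyDesign,
    r_min: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Pearson correlation between each DMDE record's probe and gene.

    The correlation is computed across all samples of the record's stratum
    (tumor and adjacent pooled) between the probe's methylation values and
    log2(normalized expression + 0.5).  The summary reports the fraction of
    records with |r| > ``r_min``; constant vectors give r = NaN and are
    excluded from the denominator.
    """
    meth_df = meth.to_frame()
    expr_df = np.log2(expr.to_frame() + 0.5)
    rows = []
    n_excluded = 0
    for _, rec in dmde.iterrows():
        stratum = rec["contrast"]
        samples = design.samples(race=None if stratum == "ALL" else stratum)
        if len(samples) < 3:
            raise ConsistencyError("need >=3 shared samples for correlation")
        x = meth_df.loc[rec["probe_id"], samples].to_numpy(dtype=float)
        y = expr_df.loc[rec["gene_id"], samples].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
            n_excluded += 1
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append(
            {
                "gene_id": rec["gene_id"],
                "probe_id": rec["probe_id"],
                "contrast": stratum,
                "r": r,
            }
        )
    out = pd.DataFrame(rows, columns=["gene_id", "probe_id", "contrast", "r"])
    valid = out["r"].dropna()
    summary = {
        "n_records": int(len(out)),
        "n_excluded_constant": int(n_excluded),
        "fraction_abs_r_gt_threshold": (
            float((valid.abs() > r_min).mean()) if len(valid) else float("nan")
        ),
        "r_threshold": float(r_min),
    }
    return out, summary


def overlap_summary(sets_by_stratum: dict[str, set]) -> dict:
    """AA/EA overlap bookkeeping for one category of calls."""
    aa = set(sets_by_stratum.get("AA", set()))
    ea = set(sets_by_stratum.get("EA", set()))
    out = {
        "AA_total": len(aa),
        "EA_total": len(ea),
        "overlap": len(aa & ea),
        "AA_only": len(aa - ea),
        "EA_only": len(ea - aa),
    }
    if "ALL" in sets_by_stratum:
        out["ALL_total"] = len(set(sets_by_stratum["ALL"]))
    return out
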