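"""One-command driver: preprocess -> model -> calls -> integration -> report.

``run_pipeline`` executes the whole analysis on validated inputs (paths or
in-memory objects), returns a :class:`RunResult`, and — when an output
directory is given — writes one TSV per result family plus ``run_summary.json``
holding the two count grids (per-stratum differential counts; integration
counts with reciprocal subsets), every threshold, and the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, integrate, preprocess
from .anova import run_all
from .errors import EpichainError
from .io_formats import (
    AnnotationTable,
    CONTRASTS,
    OmicsMatrix,
    StudyDesign,
    TargetDB,
    read_annotation,
    read_design,
    read_matrix,
    read_target_db,
    write_results,
)

logger = logging.getLogger("epichain")

OMICS = ("methylation", "mrna", "mirna")


@dataclass
class RunConfig:
    """Inputs, thresholds and toggles for a full pipeline run."""

    design: object  # path or StudyDesign
    beta: object  # path or OmicsMatrix[beta]
    counts_mirna: object  # path or OmicsMatrix[counts]
    counts_mrna: object  # path or OmicsMatrix[counts]
    annotation: object  # path or AnnotationTable
    targets: object  # path or TargetDB
    out_dir: str | None = None
    epsilon: float = 1e-6
    trim_m: float = 0.30
    trim_a: float = 0.05
    q_max: float = 0.05
    dbeta_min: float = 0.1
    fc_min: float | None = None
    fc_on_raw: bool = False
    promoter_regions: tuple = tuple(sorted(integrate.PROMOTER_REGIONS_DEFAULT))
    evidence_min: str = "high_confidence"
    require_same_direction: bool = False
    seed: int = 0

    def thresholds(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "trim_m": self.trim_m,
            "trim_a": self.trim_a,
            "q_max": self.q_max,
            "dbeta_min": self.dbeta_min,
            "fc_min": self.fc_min,
            "fc_on_raw": self.fc_on_raw,
            "promoter_regions": list(self.promoter_regions),
            "evidence_min": self.evidence_min,
            "require_same_direction": self.require_same_direction,
            "seed": self.seed,
        }


@dataclass
class RunResult:
    """Everything a run produced, keyed the way the TSV outputs are."""

    config: RunConfig
    design: StudyDesign
    filter_tally: preprocess.FilterTally
    tmm: dict  # omic -> TMMFactors
    calls: dict  # omic -> call table (all contrasts)
    dmde: pd.DataFrame
    target_pairs: pd.DataFrame
    chains: pd.DataFrame
    switch_genes: pd.DataFrame
    correlations: pd.DataFrame
    correlation_summary: dict
    summary: dict


def _load(obj, reader):
    if isinstance(obj, (str, Path)):
        return reader(obj)
    return obj


def _sets_by_contrast(calls: pd.DataFrame) -> dict[str, set]:
    out = {}
    for c in CONTRASTS:
        sub = calls[(calls["contrast"] == c) & calls["significant"]]
        out[c] = set(sub["feature_id"])
    return out


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage in order and assemble the run summary."""
    design = _load(config.design, read_design)
    beta = _load(config.beta, lambda p: read_matrix(p, "beta"))
    counts_mirna = _load(config.counts_mirna, lambda p: read_matrix(p, "counts"))
    counts_mrna = _load(config.counts_mrna, lambda p: read_matrix(p, "counts"))
    annotation = _load(config.annotation, read_annotation)
    targets = _load(config.targets, read_target_db)

    # -- preprocess ----------------------------------------------------------
    try:
        beta_f, tally = preprocess.filter_probes(beta, annotation)
        mvals = preprocess.beta_to_m(beta_f, config.epsilon)
        tmm = {}
        norm = {}
        logm = {}
        for omic, counts in (("mirna", counts_mirna), ("mrna", counts_mrna)):
            tmm[omic], norm[omic] = preprocess.tmm_normalize(
                counts, config.trim_m, config.trim_a
            )
            logm[omic] = preprocess.log_expression(norm[omic])
        logger.info(
            "preprocess: kept %d/%d probes", tally.kept_total,
            tally.kept_total + tally.removed_total,
        )
    except EpichainError:
        logger.error("stage failed: preprocess")
        raise

    # -- per-feature model and calls ----------------------------------------
    try:
        results = {
            "methylation": run_all(mvals, design),
            "mrna": run_all(logm["mrna"], design),
            "mirna": run_all(logm["mirna"], design),
        }
        calls = {}
        for omic in OMICS:
            pieces = []
            for c in CONTRASTS:
                fam = results[omic][results[omic]["contrast"] == c].copy()
                fam["q"] = differential.bh_adjust(fam["p"].to_numpy())
                if omic == "methylation":
                    eff = differential.delta_beta(beta_f, design, c)
                else:
                    fc_matrix = (
                        (counts_mirna if omic == "mirna" else counts_mrna)
                        if config.fc_on_raw
                        else norm[omic]
                    )
                    eff = differential.fold_change(fc_matrix, design, c)
                pieces.append(
                    differential.call_significant(
                        fam, eff, omic, config.q_max, config.dbeta_min, config.fc_min
                    )
                )
            calls[omic] = pd.concat(pieces, ignore_index=True)
    except EpichainError:
        logger.error("stage failed: model/calls")
        raise

    # -- integration ---------------------------------------------------------
    try:
        pmap = integrate.build_promoter_map(
            annotation, frozenset(config.promoter_regions)
        )
        dmde_frames, pair_frames, chain_frames = [], [], []
        for c in CONTRASTS:
            meth_c = calls["methylation"][calls["methylation"]["contrast"] == c]
            mrna_c = calls["mrna"][calls["mrna"]["contrast"] == c]
            mirna_c = calls["mirna"][calls["mirna"]["contrast"] == c]
            dm = integrate.dm_genes(meth_c, pmap)
            dmde_mrna = integrate.select_dmde(
                dm[dm["gene_class"] == "mrna"], mrna_c, c
            )
            dmde_mirna = integrate.select_dmde(
                dm[dm["gene_class"] == "mirna"], mirna_c, c
            )
            pairs = integrate.match_targets(
                mirna_c, mrna_c, targets, config.evidence_min
            )
            pairs.insert(0, "contrast", c)
            chains = integrate.build_chains(dmde_mirna, pairs)
            chains.insert(0, "contrast", c)
            dmde_frames.append(pd.concat([dmde_mrna, dmde_mirna], ignore_index=True))
            pair_frames.append(pairs)
            chain_frames.append(chains)
        def concat(frames):
            kept = [f for f in frames if not f.empty]
            return pd.concat(kept, ignore_index=True) if kept else frames[0]

        dmde = concat(dmde_frames)
        target_pairs = concat(pair_frames)
        chains = concat(chain_frames)

        def calls_of(stratum):
            return {
                omic: calls[omic][calls[omic]["contrast"] == stratum]
                for omic in OMICS
            }

        switch = integrate.detect_switch(
            calls_of("AA"), calls_of("EA"), targets, pmap,
            config.evidence_min, config.require_same_direction,
        )

        corr_pieces, excl = [], 0
        frac_num, frac_den = 0, 0
        for gene_class, expr in (("mrna", norm["mrna"]), ("mirna", norm["mirna"])):
            sub = dmde[dmde["gene_class"] == gene_class]
            if sub.empty:
                continue
            tab, summ = integrate.correlate_meth_expr(mvals, expr, sub, design)
            corr_pieces.append(tab)
            excl += summ["n_excluded_constant"]
            valid = tab["r"].dropna()
            frac_num += int((valid.abs() > 0.5).sum())
            frac_den += int(len(valid))
        correlations = (
            pd.concat(corr_pieces, ignore_index=True)
            if corr_pieces
            else pd.DataFrame(columns=["gene_id", "probe_id", "contrast", "r"])
        )
        corr_summary = {
            "n_records": int(len(correlations)),
            "n_excluded_constant": int(excl),
            "fraction_abs_r_gt_threshold": (
                frac_num / frac_den if frac_den else float("nan")
            ),
            "r_threshold": 0.5,
        }
    except EpichainError:
        logger.error("stage failed: integrate")
        raise

    # -- count grids ---------------------------------------------------------
    differential_grid = {}
    dm_sets = {"genes": {}, "mirnas": {}}
    for c in CONTRASTS:
        meth_c = calls["methylation"][calls["methylation"]["contrast"] == c]
        dm = integrate.dm_genes(meth_c, pmap)
        dm_gene_set = set(dm[dm["gene_class"] == "mrna"]["gene_id"])
        dm_mirna_set = set(dm[dm["gene_class"] == "mirna"]["gene_id"])
        dm_sets["genes"][c] = dm_gene_set
        dm_sets["mirnas"][c] = dm_mirna_set
        differential_grid[c] = {
            "DMCs": int(meth_c["significant"].sum()),
            "DM_genes": len(dm_gene_set),
            "DM_miRNAs": len(dm_mirna_set),
            "DE_mRNAs": int(
                calls["mrna"][calls["mrna"]["contrast"] == c]["significant"].sum()
            ),
            "DE_miRNAs": int(
                calls["mirna"][calls["mirna"]["contrast"] == c]["significant"].sum()
            ),
        }

    integration_grid = {}
    for c in CONTRASTS:
        d = dmde[dmde["contrast"] == c]
        p = target_pairs[target_pairs["contrast"] == c]
        dg = d[d["gene_class"] == "mrna"]
        dmir = d[d["gene_class"] == "mirna"]
        integration_grid[c] = {
            "DM_genes": len(dm_sets["genes"][c]),
            "DMDE_genes": dg["gene_id"].nunique(),
            "DMDE_genes_reciprocal": dg[dg["reciprocal"]]["gene_id"].nunique(),
            "DM_miRNAs": len(dm_sets["mirnas"][c]),
            "DMDE_miRNAs": dmir["gene_id"].nunique(),
            "DMDE_miRNAs_reciprocal": dmir[dmir["reciprocal"]]["gene_id"].nunique(),
            "target_pairs": int(len(p)),
            "target_pairs_reciprocal": int(p["reciprocal"].sum()),
        }

    overlaps = {}
    for name, table, key in (
        ("DMCs", calls["methylation"], "feature_id"),
        ("DE_mRNAs", calls["mrna"], "feature_id"),
        ("DE_miRNAs", calls["mirna"], "feature_id"),
    ):
        overlaps[name] = integrate.overlap_summary(_sets_by_contrast(table))
    overlaps["DM_genes"] = integrate.overlap_summary(dm_sets["genes"])
    overlaps["DM_miRNAs"] = integrate.overlap_summary(dm_sets["mirnas"])

    summary = {
        "differential_counts": differential_grid,
        "integration_counts": integration_grid,
        "overlaps": overlaps,
        "switch_genes": int(len(switch)),
        "correlation": corr_summary,
        "probe_filter": {
            "kept": tally.kept_total,
            "removed": tally.removed_total,
            "per_flag": tally.per_flag,
        },
        "thresholds": config.thresholds(),
        "n_patients": {"AA": design.n_aa, "EA": design.n_ea},
    }

    result = RunResult(
        config=config,
        design=design,
        filter_tally=tally,
        tmm=tmm,
        calls=calls,
        dmde=dmde,
        target_pairs=target_pairs,
        chains=chains,
        switch_genes=switch,
        correlations=correlations,
        correlation_summary=corr_summary,
        summary=summary,
    )
    if config.out_dir is not None:
        write_run(result, config.out_dir)
    return result


def write_run(result: RunResult, out_dir: str | Path) -> None:
    """Write every result family as TSV plus ``run_summary.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for omic in OMICS:
        write_results(result.calls[omic], out / f"calls_{omic}.tsv")
    write_results(result.dmde, out / "dmde.tsv")
    write_results(result.target_pairs, out / "target_pairs.tsv")
    write_results(result.chains, out / "chains.tsv")
    write_results(result.switch_genes, out / "switch_genes.tsv")
    write_results(result.correlations, out / "correlations.tsv")
    (out / "overlap_summary.json").write_text(
        json.dumps(result.summary["overlaps"], indent=2, sort_keys=True) + "\n"
    )
    (out / "run_summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n"
    )


def render_report(run_dir: str | Path) -> str:
    """Render a Markdown report of a finished run directory."""
    run_dir = Path(run_dir)
    summary = json.loads((run_dir / "run_summary.json").read_text())
    lines = ["# Pipeline run report", ""]
    lines.append("## Differential counts per stratum")
    lines.append("")
    grid = summary["differential_counts"]
    cols = ["DMCs", "DM_genes", "DM_miRNAs", "DE_mRNAs", "DE_miRNAs"]
    lines.append("| stratum | " + " | ".join(cols) + " |")
    lines.append("|---" * (len(cols) + 1) + "|")
    for c in CONTRASTS:
        lines.append(
            "| " + c + " | " + " | ".join(str(grid[c][k]) for k in cols) + " |"
        )
    lines.append("")
    lines.append("## Integration counts per stratum (reciprocal in parentheses)")
    lines.append("")
    igrid = summary["integration_counts"]
    lines.append("| stratum | DM genes | DMDE genes | DM miRNAs | DMDE miRNAs | miRNA-target pairs |")
    lines.append("|---|---|---|---|---|---|")
    for c in CONTRASTS:
        g = igrid[c]
        lines.append(
            f"| {c} | {g['DM_genes']} | {g['DMDE_genes']} ({g['DMDE_genes_reciprocal']}) "
            f"| {g['DM_miRNAs']} | {g['DMDE_miRNAs']} ({g['DMDE_miRNAs_reciprocal']}) "
            f"| {g['target_pairs']} ({g['target_pairs_reciprocal']}) |"
        )
    lines.append("")
    lines.append("## Overlaps (AA vs EA)")
    lines.append("")
    for name, ov in summary["overlaps"].items():
        lines.append(
            f"- {name}: AA {ov['AA_total']}, EA {ov['EA_total']}, "
            f"overlap {ov['overlap']} (AA-only {ov['AA_only']}, EA-only {ov['EA_only']})"
        )
    lines.append("")
    lines.append(f"Mechanism-switch genes: {summary['switch_genes']}")
    corr = summary["correlation"]
    if corr["n_records"]:
        lines.append(
            f"Methylation-expression correlation: {corr['fraction_abs_r_gt_threshold']:.0%} "
            f"of {corr['n_records']} DMDE records with |r| > {corr['r_threshold']}"
        )
    lines.append("")
    return "\n".join(lines)
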