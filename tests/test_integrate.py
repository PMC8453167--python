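"""Cross-layer integration rules: promoter maps, DMDE, target pairs, chains,
mechanism-switch genes, correlations and overlap bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from _oracles import textbook_pearson
from epichain.errors import ParameterError
from epichain.integrate import (
    build_chains,
    build_promoter_map,
    correlate_meth_expr,
    detect_switch,
    dm_genes,
    match_targets,
    overlap_summary,
    select_dmde,
)
from epichain.io_formats import AnnotationTable, Link, OmicsMatrix, TargetDB
from epichain.synthetic import make_design


def _annotation(link_spec):
    """link_spec: probe -> list of (gene, region, cls)."""
    rows = []
    for i, (probe, links) in enumerate(link_spec.items()):
        rows.append(
            {
                "probe_id": probe,
                "chrom": "chr1",
                "pos": 100 + i,
                "qc_flags": frozenset(),
                "links": tuple(Link(*l) for l in links),
            }
        )
    return AnnotationTable(pd.DataFrame(rows))


BASIC_ANN = {
    "cg1": [("GENEA", "TSS200", "mrna")],
    "cg2": [("GENEA", "Body", "mrna")],
    "cg3": [("MIR589", "TSS1500", "mirna")],
}


def _calls(rows, omic, contrast="AA"):
    """rows: (feature, effect, significant)."""
    df = pd.DataFrame(rows, columns=["feature_id", "effect", "significant"])
    df["contrast"] = contrast
    df["omic"] = omic
    if omic == "methylation":
        df["direction"] = np.where(df["effect"] > 0, "up", "down")
    else:
        df["direction"] = np.where(df["effect"] > 1, "up", "down")
    df["q"] = np.where(df["significant"], 0.01, 0.5)
    return df


class TestPromoterMap:
    def test_default_regions_filter(self):
        pmap = build_promoter_map(_annotation(BASIC_ANN))
        assert pmap.probes == {"GENEA": ["cg1"], "MIR589": ["cg3"]}
        assert pmap.gene_class == {"GENEA": "mrna", "MIR589": "mirna"}

    def test_custom_regions(self):
        pmap = build_promoter_map(_annotation(BASIC_ANN), {"Body"})
        assert pmap.probes == {"GENEA": ["cg2"]}

    def test_probe_in_two_promoters_appears_under_both(self):
        ann = _annotation(
            {"cg9": [("G1", "TSS200", "mrna"), ("G2", "TSS1500", "mrna")]}
        )
        pmap = build_promoter_map(ann)
        assert pmap.probes == {"G1": ["cg9"], "G2": ["cg9"]}

    def test_empty_regions_rejected(self):
        with pytest.raises(ParameterError):
            build_promoter_map(_annotation(BASIC_ANN), set())


class TestDmGenes:
    def test_body_probe_and_nonsignificant_probe_ignored(self):
        pmap = build_promoter_map(_annotation(BASIC_ANN))
        dmcs = _calls(
            [("cg1", 0.2, True), ("cg2", 0.3, True), ("cg3", 0.2, False)],
            "methylation",
        )
        dm = dm_genes(dmcs, pmap)
        assert set(dm["gene_id"]) == {"GENEA"}
        assert dm["probe_id"].tolist() == ["cg1"]

    def test_empty_dmc_set(self):
        pmap = build_promoter_map(_annotation(BASIC_ANN))
        dm = dm_genes(_calls([("cg1", 0.2, False)], "methylation"), pmap)
        assert dm.empty

    def test_opposite_sign_probes_both_retained(self):
        ann = _annotation(
            {"cgA": [("G1", "TSS200", "mrna")], "cgB": [("G1", "TSS1500", "mrna")]}
        )
        pmap = build_promoter_map(ann)
        dm = dm_genes(
            _calls([("cgA", 0.2, True), ("cgB", -0.2, True)], "methylation"), pmap
        )
        assert len(dm) == 2
        assert set(dm["gene_id"]) == {"G1"}


class TestSelectDmde:
    def _dm(self, dbeta):
        return pd.DataFrame(
            [{"gene_id": "GENEA", "gene_class": "mrna", "probe_id": "cg1",
              "dbeta": dbeta}]
        )

    def test_hyper_plus_down_is_reciprocal(self):
        de = _calls([("GENEA", 0.4, True)], "mrna")
        out = select_dmde(self._dm(0.2), de, "AA")
        assert out["reciprocal"].tolist() == [True]
        assert out["expr_direction"].tolist() == ["down"]

    def test_hyper_plus_up_kept_non_reciprocal(self):
        de = _calls([("GENEA", 2.4, True)], "mrna")
        out = select_dmde(self._dm(0.2), de, "AA")
        assert out["reciprocal"].tolist() == [False]

    def test_non_de_gene_excluded(self):
        de = _calls([("GENEA", 0.4, False)], "mrna")
        assert select_dmde(self._dm(0.2), de, "AA").empty

    def test_hypomethylated_mirna_up(self):
        dm = pd.DataFrame(
            [{"gene_id": "MIR589", "gene_class": "mirna", "probe_id": "cg3",
              "dbeta": -0.15}]
        )
        de = _calls([("MIR589", 3.0, True)], "mirna", contrast="EA")
        out = select_dmde(dm, de, "EA")
        assert out["reciprocal"].tolist() == [True]
        assert out["contrast"].tolist() == ["EA"]


class TestMatchTargets:
    DB = TargetDB(
        pd.DataFrame(
            {
                "mirna_id": ["m1", "m1", "m2"],
                "gene_id": ["g1", "g2", "g3"],
                "evidence": ["experimental", "moderate", "high_confidence"],
            }
        )
    )

    def test_reciprocal_pair_kept(self):
        pairs = match_targets(
            _calls([("m1", 2.5, True)], "mirna"),
            _calls([("g1", 0.3, True)], "mrna"),
            self.DB,
        )
        assert len(pairs) == 1
        assert pairs["reciprocal"].iloc[0]

    def test_same_direction_pair_flagged_not_dropped(self):
        pairs = match_targets(
            _calls([("m1", 2.5, True)], "mirna"),
            _calls([("g1", 3.0, True)], "mrna"),
            self.DB,
        )
        assert len(pairs) == 1 and not pairs["reciprocal"].iloc[0]

    def test_evidence_threshold_excludes_moderate(self):
        pairs = match_targets(
            _calls([("m1", 2.5, True)], "mirna"),
            _calls([("g2", 0.3, True)], "mrna"),
            self.DB,
            evidence_min="high_confidence",
        )
        assert pairs.empty

    def test_one_mirna_many_targets(self):
        db = TargetDB(
            pd.DataFrame(
                {
                    "mirna_id": ["mx"] * 18,
                    "gene_id": [f"t{i}" for i in range(18)],
                    "evidence": ["experimental"] * 18,
                }
            )
        )
        pairs = match_targets(
            _calls([("mx", 2.0, True)], "mirna"),
            _calls([(f"t{i}", 0.4, True) for i in range(18)], "mrna"),
            db,
        )
        assert len(pairs) == 18 and pairs["reciprocal"].all()


class TestBuildChains:
    def test_product_count_and_direction_alternation(self):
        dmde = pd.DataFrame(
            [
                {"gene_id": "mx", "gene_class": "mirna", "contrast": "AA",
                 "probe_id": p, "dbeta": -0.2, "expr_direction": "up",
                 "reciprocal": True}
                for p in ("cgA", "cgB")
            ]
        )
        pairs = pd.DataFrame(
            [
                {"mirna_id": "mx", "gene_id": f"g{i}", "evidence": "experimental",
                 "mirna_direction": "up", "target_direction": "down",
                 "reciprocal": True}
                for i in range(3)
            ]
        )
        chains = build_chains(dmde, pairs)
        assert len(chains) == 6
        assert (chains["meth_direction"] == "hypo").all()
        assert (chains["mirna_direction"] == "up").all()
        assert (chains["target_direction"] == "down").all()

    def test_no_reciprocal_dmde_mirna_gives_empty(self):
        dmde = pd.DataFrame(
            [{"gene_id": "mx", "gene_class": "mirna", "contrast": "AA",
              "probe_id": "cgA", "dbeta": 0.2, "expr_direction": "up",
              "reciprocal": False}]
        )
        pairs = pd.DataFrame(
            columns=["mirna_id", "gene_id", "evidence", "mirna_direction",
                     "target_direction", "reciprocal"]
        )
        assert build_chains(dmde, pairs).empty


def _stratum_calls(meth, mrna, mirna, contrast):
    return {
        "methylation": _calls(meth, "methylation", contrast),
        "mrna": _calls(mrna, "mrna", contrast),
        "mirna": _calls(mirna, "mirna", contrast),
    }


class TestDetectSwitch:
    DB = TargetDB(
        pd.DataFrame(
            {"mirna_id": ["mS"], "gene_id": ["G"], "evidence": ["experimental"]}
        )
    )
    PMAP_ANN = {"cgZ": [("G", "TSS200", "mrna")]}

    def _run(self, *, gene_de_aa=True, gene_de_ea=True, mirna_de_ea=False,
             probe_dm_aa=False):
        pmap = build_promoter_map(_annotation(self.PMAP_ANN))
        calls_aa = _stratum_calls(
            meth=[("cgZ", 0.3, probe_dm_aa)],
            mrna=[("G", 0.3, gene_de_aa)],   # G down in AA
            mirna=[("mS", 3.0, True)],       # mS up in AA
            contrast="AA",
        )
        calls_ea = _stratum_calls(
            meth=[("cgZ", 0.3, True)],       # cgZ hyper in EA
            mrna=[("G", 0.3, gene_de_ea)],   # G down in EA
            mirna=[("mS", 3.0, mirna_de_ea)],
            contrast="EA",
        )
        return detect_switch(calls_aa, calls_ea, self.DB, pmap)

    def test_full_rule_trace_yields_record(self):
        out = self._run()
        assert out["gene_id"].tolist() == ["G"]
        assert out["aa_mirnas"].tolist() == ["mS"]
        assert out["ea_probes"].tolist() == ["cgZ"]

    def test_gene_de_in_one_race_only_excluded(self):
        assert self._run(gene_de_ea=False).empty

    def test_mirna_also_de_in_ea_breaks_exclusivity(self):
        assert self._run(mirna_de_ea=True).empty

    def test_gene_dm_in_aa_breaks_exclusivity(self):
        assert self._run(probe_dm_aa=True).empty


class TestCorrelation:
    def _dmde(self):
        return pd.DataFrame(
            [{"gene_id": "G", "gene_class": "mrna", "contrast": "AA",
              "probe_id": "cg1", "dbeta": 0.2, "expr_direction": "down",
              "reciprocal": True}]
        )

    def _matrices(self, design, meth_vals, expr_vals):
        meth = OmicsMatrix(["cg1"], design.sample_ids,
                           np.asarray(meth_vals, float)[None, :], "mvalue")
        expr = OmicsMatrix(["G"], design.sample_ids,
                           np.asarray(expr_vals, float)[None, :], "normalized")
        return meth, expr

    def test_perfect_anticorrelation(self):
        design = make_design(2, 2)
        x = np.arange(8, dtype=float)
        meth, expr = self._matrices(design, x, 2.0 ** (8 - x) - 0.5)
        table, summary = correlate_meth_expr(meth, expr, self._dmde(), design)
        # AA stratum: 4 samples; log2(expr + 0.5) is exactly linear in -x
        assert table["r"].iloc[0] == pytest.approx(-1.0)
        assert summary["fraction_abs_r_gt_threshold"] == 1.0

    def test_constant_vector_excluded_with_count(self):
        design = make_design(2, 2)
        meth, expr = self._matrices(design, np.zeros(8), np.arange(8.0))
        table, summary = correlate_meth_expr(meth, expr, self._dmde(), design)
        assert np.isnan(table["r"].iloc[0])
        assert summary["n_excluded_constant"] == 1
        assert np.isnan(summary["fraction_abs_r_gt_threshold"])

    def test_matches_textbook_formula_on_random_pairs(self):
        design = make_design(10, 10)
        rng = np.random.default_rng(14)
        meth_vals = rng.normal(size=40)
        expr_vals = rng.lognormal(3, 1, size=40)
        meth, expr = self._matrices(design, meth_vals, expr_vals)
        dmde = self._dmde()
        dmde["contrast"] = "ALL"
        table, _ = correlate_meth_expr(meth, expr, dmde, design)
        expected = textbook_pearson(meth_vals, np.log2(expr_vals + 0.5))
        assert table["r"].iloc[0] == pytest.approx(expected, abs=1e-12)


class TestOverlapSummary:
    def test_basic_set_algebra(self):
        out = overlap_summary({"AA": {"a", "b"}, "EA": {"b", "c"}})
        assert out == {"AA_total": 2, "EA_total": 2, "overlap": 1,
                       "AA_only": 1, "EA_only": 1}

    def test_disjoint_sets(self):
        out = overlap_summary({"AA": {"a"}, "EA": {"b"}, "ALL": {"a", "b"}})
        assert out["overlap"] == 0 and out["ALL_total"] == 2

    def test_totals_reconcile(self):
        rng = np.random.default_rng(4)
        aa = set(rng.choice(100, 30, replace=False))
        ea = set(rng.choice(100, 40, replace=False))
        out = overlap_summary({"AA": aa, "EA": ea})
        assert out["AA_only"] + out["overlap"] == out["AA_total"]
        assert out["EA_only"] + out["overlap"] == out["EA_total"]
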