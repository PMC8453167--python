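"""Closed-form split-plot mixed ANOVA: hand examples, oracle equivalence,
invariances, and the Model/Results front end."""

import numpy as np
import pandas as pd
import pytest

from _oracles import reml_mixed_oracle
from conftest import random_matrix
from epichain.anova import (
    REASON_ZERO_VARIANCE,
    MixedTissueAnova,
    contrast_test,
    fit_feature,
    run_all,
)
from epichain.errors import DegreesOfFreedomError
from epichain.io_formats import OmicsMatrix
from epichain.synthetic import make_design


def _paired_response(design, diffs, base=10.0):
    """Build a response vector realizing given within-patient differences."""
    y = np.zeros(len(design.sample_ids))
    order = {s: i for i, s in enumerate(design.sample_ids)}
    for patient, d in diffs.items():
        y[order[design.sample_of(patient, "adjacent")]] = base
        y[order[design.sample_of(patient, "tumor")]] = base + d
    return y


class TestFitFeature:
    def test_constant_response_is_degenerate(self, design_2x2):
        fit = fit_feature(np.full(8, 3.0), design_2x2)
        assert fit.degenerate
        assert fit.sigma2 == 0.0
        assert all(v == 0.0 for v in fit.race_effects.values())
        result = contrast_test(fit, "AA")
        assert np.isnan(result.p)
        assert result.reason == REASON_ZERO_VARIANCE

    def test_hand_worked_cell_means(self, design_2x2):
        """AA paired diffs {2,4}, EA diffs {0,2}: disease effect 3 in AA, 1 in EA."""
        y = _paired_response(
            design_2x2, {"AA01": 2.0, "AA02": 4.0, "EA01": 0.0, "EA02": 2.0}
        )
        fit = fit_feature(y, design_2x2)
        assert fit.cell_means[("AA", "tumor")] - fit.cell_means[("AA", "adjacent")] == 3
        assert fit.cell_means[("EA", "tumor")] - fit.cell_means[("EA", "adjacent")] == 1
        # contrasts: AA 3, EA 1, ALL 2
        assert contrast_test(fit, "AA").estimate == pytest.approx(3.0)
        assert contrast_test(fit, "EA").estimate == pytest.approx(1.0)
        assert contrast_test(fit, "ALL").estimate == pytest.approx(2.0)
        # pooled sigma2 from within-race scatter of diffs: SS = 2 + 2, df = 2
        assert fit.sigma2 == pytest.approx(0.5 * 4.0 / 2.0)
        assert fit.residual_df == 2

    def test_race_label_swap_symmetry(self, design_2x2):
        rng = np.random.default_rng(3)
        y = rng.normal(size=8)
        fit = fit_feature(y, design_2x2)
        swapped = design_2x2.table.copy()
        swapped["race"] = swapped["race"].map({"AA": "EA", "EA": "AA"})
        from epichain.io_formats import StudyDesign

        fit_sw = fit_feature(y, StudyDesign(swapped))
        assert fit_sw.cell_means[("AA", "tumor")] == fit.cell_means[("EA", "tumor")]
        assert fit_sw.sigma2 == pytest.approx(fit.sigma2)

    def test_sum_to_zero_identification(self, design_2x2):
        rng = np.random.default_rng(4)
        fit = fit_feature(rng.normal(size=8), design_2x2)
        assert sum(fit.race_effects.values()) == pytest.approx(0.0, abs=1e-12)
        assert sum(fit.disease_effects.values()) == pytest.approx(0.0, abs=1e-12)
        for r in ("AA", "EA"):
            assert sum(fit.interaction[(r, t)] for t in ("tumor", "adjacent")) == (
                pytest.approx(0.0, abs=1e-12)
            )

    def test_too_few_patients_rejected(self):
        design = make_design(2, 2)
        t = design.table[design.table["patient_id"] != "EA02"]
        from epichain.io_formats import StudyDesign

        with pytest.raises(DegreesOfFreedomError):
            fit_feature(np.zeros(6), StudyDesign(t.reset_index(drop=True)))


class TestOracleEquivalence:
    def test_hand_example_matches_reml_oracle(self, design_2x2):
        y = _paired_response(
            design_2x2, {"AA01": 2.0, "AA02": 4.0, "EA01": 0.0, "EA02": 2.0}
        )
        # add patient-level offsets: contrasts are unaffected, REML interior
        offsets = {"AA01": 1.0, "AA02": -2.0, "EA01": 3.0, "EA02": 0.5}
        order = {s: i for i, s in enumerate(design_2x2.sample_ids)}
        for p, o in offsets.items():
            for tissue in ("tumor", "adjacent"):
                y[order[design_2x2.sample_of(p, tissue)]] += o
        fit = fit_feature(y, design_2x2)
        oracle = reml_mixed_oracle(y, design_2x2)
        for which in ("AA", "EA", "ALL"):
            got = contrast_test(fit, which)
            assert got.estimate == pytest.approx(oracle[which]["estimate"], abs=1e-8)
            assert got.p == pytest.approx(oracle[which]["p"], abs=1e-6)

    def test_random_datasets_interior_optimum(self):
        """Closed form equals numeric REML wherever the patient variance
        estimate is interior (the equivalence breaks only at omega2 = 0,
        where REML pools differently)."""
        rng = np.random.default_rng(20)
        checked = 0
        while checked < 8:
            design = make_design(int(rng.integers(2, 5)), int(rng.integers(2, 5)))
            pat = {p: rng.normal(0, 1.5) for p in design.patients}
            y = np.array(
                [
                    pat[row.patient_id]
                    + rng.normal(0, 1)
                    + (rng.uniform(-1, 1) if row.tissue == "tumor" else 0.0)
                    for row in design.table.itertuples()
                ]
            )
            fit = fit_feature(y, design)
            if fit.omega2 <= 0.05 * fit.sigma2:
                continue
            oracle = reml_mixed_oracle(y, design)
            assert fit.sigma2 == pytest.approx(oracle["sigma2"], rel=1e-5)
            assert fit.omega2 == pytest.approx(oracle["omega2"], rel=1e-4, abs=1e-6)
            for which in ("AA", "EA", "ALL"):
                got = contrast_test(fit, which)
                assert got.estimate == pytest.approx(
                    oracle[which]["estimate"], abs=1e-6
                )
                assert got.p == pytest.approx(oracle[which]["p"], abs=1e-5)
            checked += 1


class TestInvariances:
    def test_aa_contrast_equals_mean_of_aa_differences(self, design_8x8):
        rng = np.random.default_rng(8)
        y = rng.normal(size=32)
        fit = fit_feature(y, design_8x8)
        order = {s: i for i, s in enumerate(design_8x8.sample_ids)}
        diffs = [
            y[order[design_8x8.sample_of(p, "tumor")]]
            - y[order[design_8x8.sample_of(p, "adjacent")]]
            for p in design_8x8.patients
            if design_8x8.patient_race()[p] == "AA"
        ]
        assert contrast_test(fit, "AA").estimate == pytest.approx(
            np.mean(diffs), abs=1e-12
        )

    def test_location_scale_equivariance(self, design_2x2):
        rng = np.random.default_rng(12)
        y = rng.normal(size=8)
        base = {w: contrast_test(fit_feature(y, design_2x2), w) for w in ("AA", "ALL")}
        shifted = fit_feature(y + 7.5, design_2x2)
        assert shifted.grand_mean == pytest.approx(
            fit_feature(y, design_2x2).grand_mean + 7.5
        )
        scaled = {w: contrast_test(fit_feature(3.0 * y, design_2x2), w)
                  for w in ("AA", "ALL")}
        for w in ("AA", "ALL"):
            assert contrast_test(shifted, w).estimate == pytest.approx(
                base[w].estimate, abs=1e-10
            )
            assert scaled[w].estimate == pytest.approx(3.0 * base[w].estimate)
            assert scaled[w].t == pytest.approx(base[w].t, abs=1e-10)
            assert scaled[w].p == pytest.approx(base[w].p, abs=1e-12)

    def test_equal_difference_sets_give_identical_race_results(self, design_2x2):
        y = _paired_response(
            design_2x2, {"AA01": 1.0, "AA02": 3.0, "EA01": 1.0, "EA02": 3.0}
        )
        fit = fit_feature(y, design_2x2)
        aa, ea = contrast_test(fit, "AA"), contrast_test(fit, "EA")
        assert (aa.estimate, aa.se, aa.p) == (ea.estimate, ea.se, ea.p)


class TestRunAll:
    def test_three_rows_per_feature_ordered(self, design_2x2):
        m = random_matrix(design_2x2, 10, seed=1)
        out = run_all(m, design_2x2)
        assert len(out) == 30
        assert out["contrast"].tolist()[:3] == ["AA", "EA", "ALL"]
        assert out.groupby("feature_id").size().eq(3).all()

    def test_batch_matches_per_feature_path(self, design_8x8):
        m = random_matrix(design_8x8, 20, seed=2)
        out = run_all(m, design_8x8)
        for i, feat in enumerate(m.features[:5]):
            fit = fit_feature(m.values[i], design_8x8, feat)
            for which in ("AA", "EA", "ALL"):
                row = out[(out["feature_id"] == feat) & (out["contrast"] == which)]
                ref = contrast_test(fit, which)
                assert row["estimate"].iloc[0] == pytest.approx(ref.estimate, abs=1e-12)
                assert row["p"].iloc[0] == pytest.approx(ref.p, abs=1e-12)

    def test_column_permutation_invariance(self, design_2x2):
        m = random_matrix(design_2x2, 6, seed=3)
        perm = list(reversed(range(8)))
        m2 = OmicsMatrix(
            list(m.features),
            [m.samples[j] for j in perm],
            m.values[:, perm],
            m.kind,
        )
        pd.testing.assert_frame_equal(run_all(m, design_2x2), run_all(m2, design_2x2))

    def test_degenerate_feature_flagged_not_fatal(self, design_2x2):
        m = random_matrix(design_2x2, 3, seed=4)
        m.values[1, :] = 5.0
        out = run_all(m, design_2x2)
        flagged = out[out["feature_id"] == "f1"]
        assert flagged["p"].isna().all()
        assert (flagged["reason"] == REASON_ZERO_VARIANCE).all()
        assert out[out["feature_id"] != "f1"]["p"].notna().all()

    def test_null_type_one_error_near_nominal(self, design_8x8):
        """On 2000 null features the ALL-contrast p-values are uniform enough
        that the 0.05 rejection rate is within 3 Monte-Carlo SEs."""
        m = random_matrix(design_8x8, 2000, seed=55)
        out = run_all(m, design_8x8)
        p = out[out["contrast"] == "ALL"]["p"].to_numpy()
        frac = (p < 0.05).mean()
        mc_se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < 3 * mc_se


class TestModelResults:
    def test_model_fit_contrasts_roundtrip(self, design_2x2):
        m = random_matrix(design_2x2, 4, seed=6)
        res = MixedTissueAnova(m, design_2x2).fit()
        pd.testing.assert_frame_equal(res.contrasts(), run_all(m, design_2x2))

    def test_from_dataframe_and_summary(self, design_2x2):
        frame = pd.DataFrame(
            np.random.default_rng(7).normal(size=(3, 8)),
            index=["a", "b", "c"],
            columns=design_2x2.sample_ids,
        )
        res = MixedTissueAnova.from_dataframe(frame, design_2x2).fit()
        text = res.summary()
        assert "Residual df: 2" in text
        assert "Patients: 2 AA + 2 EA" in text
        fit = res.feature_fit("b")
        assert fit.feature_id == "b"
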