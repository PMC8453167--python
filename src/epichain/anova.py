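"""Split-plot mixed ANOVA for paired tumor/adjacent samples in two strata.

Model
-----
For one feature, the response of patient i (race j, tissue k) is

    y_ijk = mu + tau_i + alpha_j + beta_k + gamma_jk + eps_ijk

with tau_i ~ N(0, omega^2) the random patient effect and
eps_ijk ~ N(0, sigma^2) the residual.  Race (between-patient) and tissue
(within-patient) are fixed, sum-to-zero coded.  With complete pairs the
design is balanced within patient, and the model has a closed form:

* cell means give the fixed effects exactly;
* within-patient differences d_i = y_tumor - y_adjacent cancel tau_i, so
  sigma^2 is estimated from their within-race scatter:
      sigma2_hat = 0.5 * sum_j sum_i (d_ij - dbar_j)^2 / (N - 2),
  with N the total number of patients and residual df = N - 2;
* omega^2 comes from the between-patient mean square of patient means,
  truncated at zero.

Three contrasts are tested, all on t with df = N - 2 and the pooled sigma2:

    AA   tumor - adjacent within AA        se = sqrt(2*sigma2/n_AA)
    EA   tumor - adjacent within EA        se = sqrt(2*sigma2/n_EA)
    ALL  equally weighted mean of the two  se = sqrt(sigma2/2*(1/n_AA+1/n_EA))

The ALL contrast weights the races 1/2, 1/2 regardless of the group sizes
(it tests the disease main effect plus the average interaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegreesOfFreedomError
from .io_formats import CONTRASTS, OmicsMatrix, RACES, StudyDesign, TISSUES

REASON_OK = ""
REASON_ZERO_VARIANCE = "zero_variance"


@dataclass
class MixedAnovaFit:
    """Closed-form fit of the split-plot model for one feature."""

    grand_mean: float
    race_effects: dict[str, float]
    disease_effects: dict[str, float]
    interaction: dict[tuple[str, str], float]
    sigma2: float
    omega2: float
    residual_df: int
    cell_means: dict[tuple[str, str], float]
    n_per_race: dict[str, int]
    degenerate: bool = False
    feature_id: str = ""


@dataclass
class ContrastResult:
    """One contrast of one feature: estimate, se, t, p (q filled later)."""

    feature_id: str
    contrast: str
    estimate: float
    se: float
    t: float
    df: int
    p: float
    q: float = np.nan
    reason: str = REASON_OK


def _design_arrays(design: StudyDesign):
    """Per-patient (race, tumor-sample-idx, adjacent-sample-idx) lookups for a
    sample-ordered matrix."""
    order = {s: i for i, s in enumerate(design.sample_ids)}
    patients = design.patients
    race = np.array([design.patient_race()[p] for p in patients])
    tum = np.array([order[design.sample_of(p, "tumor")] for p in patients])
    adj = np.array([order[design.sample_of(p, "adjacent")] for p in patients])
    return patients, race, tum, adj


def fit_feature(y, design: StudyDesign, feature_id: str = "") -> MixedAnovaFit:
    """Fit the split-plot model to one feature's per-sample responses.

    ``y`` is ordered like ``design.sample_ids``.
    """
    y = np.asarray(y, dtype=float)
    if design.n_aa < 2 or design.n_ea < 2:
        raise DegreesOfFreedomError(
            f"need >=2 patients per race, got n_AA={design.n_aa}, n_EA={design.n_ea}"
        )
    patients, race, tum, adj = _design_arrays(design)
    n = {r: int((race == r).sum()) for r in RACES}
    N = len(patients)

    cell_means: dict[tuple[str, str], float] = {}
    for r in RACES:
        mask = race == r
        cell_means[(r, "tumor")] = float(y[tum[mask]].mean())
        cell_means[(r, "adjacent")] = float(y[adj[mask]].mean())

    # sum-to-zero fixed effects from the 2x2 cell-mean table
    mu = float(np.mean([cell_means[(r, t)] for r in RACES for t in TISSUES]))
    race_eff = {
        r: float(np.mean([cell_means[(r, t)] for t in TISSUES]) - mu) for r in RACES
    }
    dis_eff = {
        t: float(np.mean([cell_means[(r, t)] for r in RACES]) - mu) for t in TISSUES
    }
    inter = {
        (r, t): float(cell_means[(r, t)] - mu - race_eff[r] - dis_eff[t])
        for r in RACES
        for t in TISSUES
    }

    d = y[tum] - y[adj]
    m = (y[tum] + y[adj]) / 2.0
    ss_d = 0.0
    ss_m = 0.0
    for r in RACES:
        mask = race == r
        ss_d += float(((d[mask] - d[mask].mean()) ** 2).sum())
        ss_m += float(((m[mask] - m[mask].mean()) ** 2).sum())
    df = N - 2
    sigma2 = 0.5 * ss_d / df
    omega2 = max(0.0, ss_m / df - sigma2 / 2.0)
    degenerate = sigma2 == 0.0

    return MixedAnovaFit(
        grand_mean=mu,
        race_effects=race_eff,
        disease_effects=dis_eff,
        interaction=inter,
        sigma2=sigma2,
        omega2=omega2,
        residual_df=df,
        cell_means=cell_means,
        n_per_race=n,
        degenerate=degenerate,
        feature_id=feature_id,
    )


def contrast_test(fit: MixedAnovaFit, which: str) -> ContrastResult:
    """Test one of the three tumor-vs-adjacent contrasts on a fitted feature."""
    if which not in CONTRASTS:
        raise ValueError(f"unknown contrast {which!r}")
    n_aa, n_ea = fit.n_per_race["AA"], fit.n_per_race["EA"]
    diff = {
        r: fit.cell_means[(r, "tumor")] - fit.cell_means[(r, "adjacent")] for r in RACES
    }
    if which == "ALL":
        estimate = 0.5 * (diff["AA"] + diff["EA"])
        var = fit.sigma2 / 2.0 * (1.0 / n_aa + 1.0 / n_ea)
    else:
        estimate = diff[which]
        var = 2.0 * fit.sigma2 / (n_aa if which == "AA" else n_ea)

    if fit.degenerate:
        return ContrastResult(
            fit.feature_id, which, float(estimate), np.nan, np.nan,
            fit.residual_df, np.nan, reason=REASON_ZERO_VARIANCE,
        )
    se = float(np.sqrt(var))
    t = float(estimate / se)
    p = float(2.0 * stats.t.sf(abs(t), fit.residual_df))
    return ContrastResult(fit.feature_id, which, float(estimate), se, t,
                          fit.residual_df, p)


def run_all(matrix: OmicsMatrix, design: StudyDesign) -> pd.DataFrame:
    """Fit every feature and test all three contrasts (vectorized).

    Returns a table with 3 rows per feature, ordered by (feature, contrast)
    with contrasts in AA, EA, ALL order; degenerate features get p = NaN and
    a reason code rather than aborting the batch.
    """
    matrix.check_samples(design)
    matrix = matrix.align_samples(design.sample_ids)
    if design.n_aa < 2 or design.n_ea < 2:
        raise DegreesOfFreedomError(
            f"need >=2 patients per race, got n_AA={design.n_aa}, n_EA={design.n_ea}"
        )
    patients, race, tum, adj = _design_arrays(design)
    N = len(patients)
    df = N - 2
    n_aa = int((race == "AA").sum())
    n_ea = int((race == "EA").sum())

    Y = matrix.values  # features x samples
    D = Y[:, tum] - Y[:, adj]  # features x patients
    aa = race == "AA"
    ea = race == "EA"
    dbar_aa = D[:, aa].mean(axis=1)
    dbar_ea = D[:, ea].mean(axis=1)
    ss = ((D[:, aa] - dbar_aa[:, None]) ** 2).sum(axis=1) + (
        (D[:, ea] - dbar_ea[:, None]) ** 2
    ).sum(axis=1)
    sigma2 = 0.5 * ss / df
    degenerate = sigma2 == 0.0

    est = {
        "AA": dbar_aa,
        "EA": dbar_ea,
        "ALL": 0.5 * (dbar_aa + dbar_ea),
    }
    var = {
        "AA": 2.0 * sigma2 / n_aa,
        "EA": 2.0 * sigma2 / n_ea,
        "ALL": sigma2 / 2.0 * (1.0 / n_aa + 1.0 / n_ea),
    }

    frames = []
    for which in CONTRASTS:
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(var[which])
            t = est[which] / se
            p = 2.0 * stats.t.sf(np.abs(t), df)
        se = np.where(degenerate, np.nan, se)
        t = np.where(degenerate, np.nan, t)
        p = np.where(degenerate, np.nan, p)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": matrix.features,
                    "contrast": which,
                    "estimate": est[which],
                    "se": se,
                    "t": t,
                    "df": df,
                    "p": p,
                    "q": np.nan,
                    "reason": np.where(degenerate, REASON_ZERO_VARIANCE, REASON_OK),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    order = {c: i for i, c in enumerate(CONTRASTS)}
    out = out.sort_values(
        ["feature_id", "contrast"],
        key=lambda s: s.map(order) if s.name == "contrast" else s,
        kind="stable",
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Model / Results front end


class MixedTissueAnova:
    """Per-feature split-plot mixed ANOVA over a feature-by-sample matrix.

    Parameters
    ----------
    endog : OmicsMatrix
        M-values or log2 normalized expression, one row per feature.
    design : StudyDesign
        Paired tumor/adjacent layout over the two racial strata.

    ``fit()`` returns a :class:`MixedTissueAnovaResults`.
    """

    def __init__(self, endog: OmicsMatrix, design: StudyDesign):
        endog.check_samples(design)
        self.endog = endog.align_samples(design.sample_ids)
        self.design = design

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, design: StudyDesign,
                       kind: str = "mvalue") -> "MixedTissueAnova":
        m = OmicsMatrix(list(frame.index.astype(str)), list(frame.columns),
                        frame.to_numpy(dtype=float), kind)
        return cls(m, design)

    def fit(self) -> "MixedTissueAnovaResults":
        table = run_all(self.endog, self.design)
        return MixedTissueAnovaResults(self, table)


class MixedTissueAnovaResults:
    """Results of :class:`MixedTissueAnova`: per-feature contrast estimates,
    standard errors, t statistics and two-sided p-values."""

    def __init__(self, model: MixedTissueAnova, table: pd.DataFrame):
        self.model = model
        self._table = table

    def contrasts(self) -> pd.DataFrame:
        """The full (feature x contrast) result table."""
        return self._table.copy()

    def feature_fit(self, feature_id: str) -> MixedAnovaFit:
        """Closed-form parameter estimates for a single feature."""
        idx = self.model.endog.features.index(feature_id)
        return fit_feature(self.model.endog.values[idx], self.model.design, feature_id)

    def summary(self, max_features: int = 10) -> str:
        """Plain-text summary of the fit (first ``max_features`` features)."""
        d = self.model.design
        t = self._table
        lines = [
            "Split-plot mixed ANOVA (tumor vs adjacent, two strata)",
            "=" * 56,
            f"Features: {len(self.model.endog.features)}   "
            f"Patients: {d.n_aa} AA + {d.n_ea} EA (paired)",
            f"Residual df: {d.n_aa + d.n_ea - 2}",
            "",
            t.head(3 * max_features).to_string(index=False,
                                               float_format=lambda v: f"{v:.4g}"),
        ]
        n_deg = int((t["reason"] == REASON_ZERO_VARIANCE).sum()) // 3
        if n_deg:
            lines.append(f"\n{n_deg} feature(s) degenerate (zero variance).")
        return "\n".join(lines)
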