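"""BH adjustment, effect sizes (delta-beta, fold change) and significance calls.

Calling rules
-------------
methylation  significant iff q < q_max and |delta_beta| > dbeta_min
             (defaults 0.05 and 0.1)
mrna/mirna   significant iff q < q_max (default 0.05); an optional fold-change
             filter max(FC, 1/FC) > fc_min exists for display subsets only and
             is off by default.

BH is applied separately within each (omic, contrast) family; delta-beta is
the mean beta difference tumor minus adjacent within a stratum; fold change is
the ratio of group medians of normalized counts, with a 0.5 pseudo-count
applied only when a median is zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError
from .io_formats import OmicsMatrix, StudyDesign


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are excluded from the ranking and returned as NaN.  The
    result follows its input's order, so it is stable under permutation.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def delta_beta(beta: OmicsMatrix, design: StudyDesign, stratum: str) -> pd.Series:
    """Per-feature mean beta over tumor minus mean beta over adjacent samples
    of a stratum (``ALL`` pools both races)."""
    race = None if stratum == "ALL" else stratum
    tum = design.samples(race=race, tissue="tumor")
    adj = design.samples(race=race, tissue="adjacent")
    if not tum or not adj:
        raise ConsistencyError(f"stratum {stratum!r} empty in design")
    df = beta.to_frame()
    return df[tum].mean(axis=1) - df[adj].mean(axis=1)


def fold_change(
    counts: OmicsMatrix, design: StudyDesign, stratum: str, pseudo: float = 0.5
) -> pd.Series:
    """Per-feature ratio of tumor to adjacent group medians within a stratum.

    The pseudo-count is added to *both* medians only when either of them is
    zero, so typical values are untouched while zeros never divide.
    """
    race = None if stratum == "ALL" else stratum
    tum = design.samples(race=race, tissue="tumor")
    adj = design.samples(race=race, tissue="adjacent")
    if not tum or not adj:
        raise ConsistencyError(f"stratum {stratum!r} empty in design")
    df = counts.to_frame()
    med_t = df[tum].median(axis=1)
    med_a = df[adj].median(axis=1)
    zero = (med_t == 0) | (med_a == 0)
    c = np.where(zero, pseudo, 0.0)
    return (med_t + c) / (med_a + c)


def call_significant(
    results: pd.DataFrame,
    effects: pd.Series,
    omic: str,
    q_max: float = 0.05,
    dbeta_min: float = 0.1,
    fc_min: float | None = None,
) -> pd.DataFrame:
    """Turn one (omic, contrast) family of contrast results into calls.

    ``results`` must already carry q (from :func:`bh_adjust` applied to this
    family); ``effects`` maps feature_id to delta-beta (methylation) or fold
    change (counts).  ``fc_min`` applies the optional display-set filter
    max(FC, 1/FC) > fc_min on top of the core rule; it never relaxes it.
    """
    feats = set(results["feature_id"])
    if feats != set(effects.index):
        raise ConsistencyError(
            "feature sets of results and effects differ "
            f"(e.g. {sorted(feats ^ set(effects.index))[:5]})"
        )
    out = results.copy()
    out["omic"] = omic
    out["effect"] = out["feature_id"].map(effects).astype(float)
    if omic == "methylation":
        out["direction"] = np.where(out["effect"] > 0, "up", "down")
        sig = (out["q"] < q_max) & (out["effect"].abs() > dbeta_min)
    else:
        out["direction"] = np.where(out["effect"] > 1, "up", "down")
        sig = out["q"] < q_max
        if fc_min is not None:
            ratio = np.maximum(out["effect"], 1.0 / out["effect"])
            sig &= ratio > fc_min
    out["significant"] = sig.fillna(False).astype(bool)
    return out
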