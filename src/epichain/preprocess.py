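"""Probe filtering, beta-to-M conversion, and TMM normalization.

These are the steps between raw matrices and the statistical model: CpG probes
with QC issues (sex chromosomes, non-CpG context, SNP within 10 bp, repeat
within 15 bp, multi-mapping) are dropped; beta values are moved to the M scale
log2(beta/(1-beta)) where a Gaussian linear model is appropriate; and count
libraries are scaled by trimmed-mean-of-M-values (TMM) factors so that
composition differences between libraries do not masquerade as differential
expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import AnnotationError, NormalizationError, ParameterError
from .io_formats import AnnotationTable, OmicsMatrix

SEX_CHROMS = frozenset({"chrX", "chrY"})


@dataclass
class FilterTally:
    """Per-flag removal counts; a probe flagged twice is tallied under each
    flag but counted once in ``removed_total``."""

    per_flag: dict[str, int]
    removed_total: int
    kept_total: int


def filter_probes(
    matrix: OmicsMatrix, annotation: AnnotationTable
) -> tuple[OmicsMatrix, FilterTally]:
    """Drop probes with any QC flag or on chrX/chrY; keep original order."""
    ann = annotation.table.set_index("probe_id")
    missing = [f for f in matrix.features if f not in ann.index]
    if missing:
        raise AnnotationError(f"probe {missing[0]!r} missing from annotation")

    per_flag: dict[str, int] = {}
    keep: list[str] = []
    removed = 0
    for probe in matrix.features:
        row = ann.loc[probe]
        flags = set(row["qc_flags"])
        if row["chrom"] in SEX_CHROMS:
            flags.add("sex_chrom")
        if flags:
            removed += 1
            for f in flags:
                per_flag[f] = per_flag.get(f, 0) + 1
        else:
            keep.append(probe)
    kept = matrix.subset_features(keep)
    return kept, FilterTally(per_flag, removed, len(keep))


def beta_to_m(beta, epsilon: float = 1e-6):
    """Convert beta values to M-values, log2(b/(1-b)) with b clipped to
    [epsilon, 1-epsilon].

    Accepts a scalar, an array, or an OmicsMatrix of kind ``beta`` (returning
    an OmicsMatrix of kind ``mvalue`` with the same shape).
    """
    if not (0 < epsilon < 0.5):
        raise ParameterError(f"epsilon must be in (0, 0.5), got {epsilon}")
    if isinstance(beta, OmicsMatrix):
        vals = beta_to_m(beta.values, epsilon)
        return OmicsMatrix(list(beta.features), list(beta.samples), vals, "mvalue")
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1 - epsilon)
    out = np.log2(b / (1 - b))
    return out if out.ndim else float(out)


@dataclass
class TMMFactors:
    """Per-sample library sizes and TMM scaling factors (geometric mean 1)."""

    library_size: dict[str, float]
    factor: dict[str, float]
    reference_sample: str


def _upper_quartile_fraction(counts: np.ndarray, libsize: float) -> float:
    return float(np.quantile(counts, 0.75)) / libsize


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """log2 scaling factor of ``obs`` against ``ref`` (doubly trimmed,
    precision-weighted mean of M values)."""
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise NormalizationError("no feature positive in both sample and reference")
    o = obs[both] / n_obs
    r = ref[both] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # delta-method binomial variance of M; weight = 1/variance
    var = (n_obs - obs[both]) / (n_obs * obs[both]) + (n_ref - ref[both]) / (
        n_ref * ref[both]
    )

    # double trim on tie-aware (average) ranks so tied M values stay together
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / var[keep]
    return float(np.sum(w * m[keep]) / np.sum(w))


def tmm_normalize(
    counts: OmicsMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> tuple[TMMFactors, OmicsMatrix]:
    """TMM normalization of a count matrix.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean across samples.  Each sample's factor is
    2**(precision-weighted mean of doubly trimmed M values) against the
    reference; factors are rescaled to geometric mean 1.  The normalized
    matrix is counts per million of the effective library size
    (library_size * factor).
    """
    if len(counts.samples) < 2:
        raise ParameterError("TMM requires at least 2 samples")
    if counts.kind != "counts":
        raise ParameterError(f"TMM expects a counts matrix, got kind={counts.kind!r}")
    x = counts.values
    libsizes = x.sum(axis=0)
    if (libsizes <= 0).any():
        bad = counts.samples[int(np.argmin(libsizes))]
        raise NormalizationError(f"sample {bad!r} has zero library size")

    uq = np.array(
        [_upper_quartile_fraction(x[:, j], libsizes[j]) for j in range(x.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = x[:, ref_idx]
    n_ref = libsizes[ref_idx]

    log_factors = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_idx:
            continue
        try:
            log_factors[j] = _tmm_pair_factor(
                x[:, j], ref, libsizes[j], n_ref, trim_m, trim_a
            )
        except NormalizationError:
            raise NormalizationError(
                f"sample {counts.samples[j]!r} shares no positive feature "
                "with the reference"
            ) from None
    # rescale so the geometric mean of 2**log_factors is exactly 1
    log_factors -= log_factors.mean()
    factors = 2.0 ** log_factors

    eff = libsizes * factors
    normalized = x / eff[np.newaxis, :] * 1e6
    tmm = TMMFactors(
        library_size=dict(zip(counts.samples, map(float, libsizes))),
        factor=dict(zip(counts.samples, map(float, factors))),
        reference_sample=counts.samples[ref_idx],
    )
    out = OmicsMatrix(list(counts.features), list(counts.samples), normalized, "normalized")
    return tmm, out


def log_expression(normalized: OmicsMatrix, pseudo: float = 0.5) -> OmicsMatrix:
    """log2(normalized + pseudo); the scale on which count data enter the
    linear model."""
    vals = np.log2(normalized.values + pseudo)
    return OmicsMatrix(list(normalized.features), list(normalized.samples), vals, "normalized")
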