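"""Readers, writers and validated in-memory containers for every external table.

File dialects
-------------
design CSV      sample_id,patient_id,race,tissue  (race: AA|EA; tissue: tumor|adjacent)
matrix TSV      feature_id then one column per sample
annotation TSV  probe_id, chrom, pos, qc_flags (comma-joined, may be empty),
                links (semicolon-joined ``gene:region:class`` triples)
target DB TSV   mirna_id, gene_id, evidence

Tokens are case-sensitive exact strings. Positions are 1-based inclusive and are
carried only as provenance, never used in arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import (
    AnnotationError,
    DesignError,
    FormatError,
    MatrixValueError,
)

RACES = ("AA", "EA")
TISSUES = ("tumor", "adjacent")
CONTRASTS = ("AA", "EA", "ALL")
MATRIX_KINDS = ("beta", "mvalue", "counts", "normalized")
QC_FLAGS = frozenset(
    {"sex_chrom", "non_cpg", "snp_within_10bp", "repeat_within_15bp", "multi_hit"}
)
REGIONS = ("TSS1500", "TSS200", "UTR5", "FirstExon", "Body", "UTR3")
GENE_CLASSES = ("mrna", "mirna")
EVIDENCE_LEVELS = ("experimental", "high_confidence", "moderate")
# evidence rank: lower is stronger
EVIDENCE_RANK = {level: i for i, level in enumerate(EVIDENCE_LEVELS)}


@dataclass(frozen=True)
class StudyDesign:
    """Paired tumor/adjacent layout over two racial strata.

    Wraps a validated table with one row per sample.  Every patient appears
    exactly twice (once per tissue) and belongs to exactly one race, which is
    the grouping structure the mixed ANOVA relies on.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["sample_id", "patient_id", "race", "tissue"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FormatError(f"design table missing column(s): {', '.join(missing)}")
        bad_race = set(t["race"]) - set(RACES)
        if bad_race:
            raise MatrixValueError(f"unknown race token(s): {sorted(bad_race)}")
        bad_tissue = set(t["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise MatrixValueError(f"unknown tissue token(s): {sorted(bad_tissue)}")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise DesignError(f"duplicate sample_id(s): {dups}")
        for patient, grp in t.groupby("patient_id", sort=False):
            if len(grp) != 2 or set(grp["tissue"]) != set(TISSUES):
                raise DesignError(
                    f"patient {patient!r} must have exactly one tumor and one "
                    f"adjacent sample, found tissues {grp['tissue'].tolist()}"
                )
            if grp["race"].nunique() != 1:
                raise DesignError(f"patient {patient!r} maps to more than one race")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def patients(self) -> list[str]:
        return self.table["patient_id"].drop_duplicates().tolist()

    def n_patients(self, race: str | None = None) -> int:
        t = self.table
        if race is not None:
            t = t[t["race"] == race]
        return t["patient_id"].nunique()

    @property
    def n_aa(self) -> int:
        return self.n_patients("AA")

    @property
    def n_ea(self) -> int:
        return self.n_patients("EA")

    def samples(self, race: str | None = None, tissue: str | None = None) -> list[str]:
        t = self.table
        if race is not None and race != "ALL":
            t = t[t["race"] == race]
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        return t["sample_id"].tolist()

    def patient_race(self) -> dict[str, str]:
        return dict(
            self.table.drop_duplicates("patient_id")[["patient_id", "race"]].values
        )

    def sample_of(self, patient: str, tissue: str) -> str:
        t = self.table
        row = t[(t["patient_id"] == patient) & (t["tissue"] == tissue)]
        return row["sample_id"].iloc[0]


@dataclass
class OmicsMatrix:
    """One feature-by-sample numeric matrix with a declared value kind."""

    features: list[str]
    samples: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise MatrixValueError(f"unknown matrix kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if len(set(self.features)) != len(self.features):
            seen: set[str] = set()
            dup = next(f for f in self.features if f in seen or seen.add(f))
            raise FormatError(f"duplicate feature_id {dup!r}")
        if not np.isfinite(self.values).all():
            raise MatrixValueError("matrix contains non-finite values")
        if self.kind == "beta":
            if self.values.min() < 0 or self.values.max() > 1:
                raise MatrixValueError("beta values must lie in [0, 1]")
        elif self.kind == "counts":
            if self.values.min() < 0:
                raise MatrixValueError("counts must be non-negative")
            if not np.allclose(self.values, np.round(self.values)):
                raise MatrixValueError("counts must be integral")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.samples)

    def subset_features(self, keep: Iterable[str]) -> "OmicsMatrix":
        keep = set(keep)
        idx = [i for i, f in enumerate(self.features) if f in keep]
        return OmicsMatrix(
            [self.features[i] for i in idx],
            list(self.samples),
            self.values[idx, :],
            self.kind,
        )

    def align_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        """Reorder columns to the given sample order (all must be present)."""
        pos = {s: j for j, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise FormatError(f"matrix missing sample(s): {missing}")
        cols = [pos[s] for s in sample_ids]
        return OmicsMatrix(list(self.features), list(sample_ids), self.values[:, cols], self.kind)

    def check_samples(self, design: StudyDesign) -> None:
        if set(self.samples) != set(design.sample_ids):
            raise FormatError(
                "matrix sample set does not match design sample set "
                f"(matrix-only: {sorted(set(self.samples) - set(design.sample_ids))[:5]}, "
                f"design-only: {sorted(set(design.sample_ids) - set(self.samples))[:5]})"
            )


class Link(NamedTuple):
    gene_id: str
    region: str
    gene_class: str


@dataclass
class AnnotationTable:
    """CpG probe QC flags and probe-to-(gene, region) links."""

    table: pd.DataFrame  # probe_id, chrom, pos, qc_flags (frozenset), links (tuple[Link])

    def __post_init__(self) -> None:
        t = self.table
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise FormatError(f"duplicate probe_id {dup!r}")
        for flags in t["qc_flags"]:
            bad = set(flags) - QC_FLAGS
            if bad:
                raise FormatError(f"unknown qc flag(s): {sorted(bad)}")
        for links in t["links"]:
            for link in links:
                if not link.gene_id:
                    raise FormatError("annotation link with empty gene_id")
                if link.region not in REGIONS:
                    raise FormatError(f"unknown region token {link.region!r}")
                if link.gene_class not in GENE_CLASSES:
                    raise FormatError(f"unknown gene class {link.gene_class!r}")

    @property
    def probe_ids(self) -> list[str]:
        return self.table["probe_id"].tolist()

    def row(self, probe_id: str) -> pd.Series:
        t = self.table
        hit = t[t["probe_id"] == probe_id]
        if hit.empty:
            raise AnnotationError(f"probe {probe_id!r} not in annotation")
        return hit.iloc[0]


@dataclass
class TargetDB:
    """miRNA-to-target-gene pairs with an evidence level."""

    table: pd.DataFrame  # mirna_id, gene_id, evidence

    def __post_init__(self) -> None:
        t = self.table
        if t.duplicated(subset=["mirna_id", "gene_id"]).any():
            row = t[t.duplicated(subset=["mirna_id", "gene_id"])].iloc[0]
            raise FormatError(
                f"duplicate target pair ({row['mirna_id']!r}, {row['gene_id']!r})"
            )
        bad = set(t["evidence"]) - set(EVIDENCE_LEVELS)
        if bad:
            raise FormatError(f"unknown evidence token(s): {sorted(bad)}")

    def at_least(self, evidence_min: str) -> pd.DataFrame:
        if evidence_min not in EVIDENCE_RANK:
            raise FormatError(f"unknown evidence token {evidence_min!r}")
        rank = self.table["evidence"].map(EVIDENCE_RANK)
        return self.table[rank <= EVIDENCE_RANK[evidence_min]]


# ---------------------------------------------------------------------------
# readers


def read_design(path: str | Path) -> StudyDesign:
    """Read and validate the sample-sheet CSV."""
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    return StudyDesign(df.reset_index(drop=True))


def read_matrix(path: str | Path, kind: str) -> OmicsMatrix:
    """Read a feature-by-sample TSV with a declared value kind."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    feature_col = df.columns[0]
    features = df[feature_col].tolist()
    body = df.drop(columns=[feature_col])
    try:
        values = body.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(body.columns):
            for i, v in enumerate(body[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric cell at row {features[i]!r}, column {col!r}: {v!r}"
                    ) from None
        raise
    return OmicsMatrix(features, list(body.columns), values, kind)


def _parse_flags(text: str) -> frozenset[str]:
    text = "" if pd.isna(text) else str(text).strip()
    if not text:
        return frozenset()
    return frozenset(tok.strip() for tok in text.split(",") if tok.strip())


def _parse_links(text: str) -> tuple[Link, ...]:
    text = "" if pd.isna(text) else str(text).strip()
    if not text:
        return ()
    links = []
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        parts = item.split(":")
        if len(parts) != 3:
            raise FormatError(f"malformed link {item!r}, expected gene:region:class")
        links.append(Link(parts[0].strip(), parts[1].strip(), parts[2].strip()))
    return tuple(links)


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read the probe annotation TSV (QC flags + gene/region links)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str, "chrom": str}, keep_default_na=False
    )
    required = ["probe_id", "chrom", "pos", "qc_flags", "links"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"annotation missing column(s): {', '.join(missing)}")
    out = pd.DataFrame(
        {
            "probe_id": df["probe_id"],
            "chrom": df["chrom"],
            "pos": df["pos"].astype(int),
            "qc_flags": [_parse_flags(v) for v in df["qc_flags"]],
            "links": [_parse_links(v) for v in df["links"]],
        }
    )
    if (out["pos"] < 0).any():
        raise FormatError("negative probe position")
    return AnnotationTable(out)


def read_target_db(path: str | Path) -> TargetDB:
    """Read the miRNA-to-target TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["mirna_id", "gene_id", "evidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"target DB missing column(s): {', '.join(missing)}")
    return TargetDB(df[required].reset_index(drop=True))


# ---------------------------------------------------------------------------
# writers


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.table.to_csv(path, index=False)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def write_annotation(annotation: AnnotationTable, path: str | Path) -> None:
    t = annotation.table
    out = pd.DataFrame(
        {
            "probe_id": t["probe_id"],
            "chrom": t["chrom"],
            "pos": t["pos"],
            "qc_flags": [",".join(sorted(f)) for f in t["qc_flags"]],
            "links": [
                ";".join(f"{l.gene_id}:{l.region}:{l.gene_class}" for l in links)
                for links in t["links"]
            ],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_target_db(db: TargetDB, path: str | Path) -> None:
    db.table.to_csv(path, sep="\t", index=False)


def write_results(result: pd.DataFrame, path: str | Path, summary: dict | None = None) -> None:
    """Write a pipeline result table as TSV with stable column order.

    Floats are written at full precision so a re-read reproduces the table
    bit-exactly.  If ``summary`` is given, a JSON run summary is written next
    to the table (same stem, ``.json`` suffix).
    """
    path = Path(path)
    result.to_csv(path, sep="\t", index=False)
    if summary is not None:
        summary_path = path.with_suffix(".json")
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
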