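"""Core domain types and file I/O shared by every analysis stage.

Expression values are log2-scale intensities (features x samples); clinical
outcome is disease-free survival (DFS) in years with a binary event flag.
Genomic coordinates are 0-based half-open (BED convention) throughout.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ORIENTATIONS = ("divergent", "convergent", "embedded")
CLASS_TAGS = ("SAGP", "NGN", "PNG")
GRADES = ("G1", "G2", "G3", "unknown")
SUBTYPES = ("basal", "non_basal", "normal_tissue", "unknown")


class DataModelError(ValueError):
    """Raised on invariant violations in domain objects or input files."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values indexed by feature id and sample id."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DataModelError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataModelError("duplicate sample ids")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataModelError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(self.feature_ids) < 2 or len(self.sample_ids) < 3:
            raise DataModelError("need at least 2 features and 3 samples")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataModelError(
                f"non-finite value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        self._row_index = {f: i for i, f in enumerate(self.feature_ids)}
        self._col_index = {s: j for j, s in enumerate(self.sample_ids)}

    def row(self, feature_id: str) -> np.ndarray:
        try:
            return self.values[self._row_index[feature_id]]
        except KeyError:
            raise DataModelError(f"unknown feature id {feature_id!r}") from None

    def has_feature(self, feature_id: str) -> bool:
        return feature_id in self._row_index

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        cols = [self._col_index[s] for s in sample_ids]
        return ExpressionMatrix(
            list(self.feature_ids), list(sample_ids), self.values[:, cols]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )


@dataclass
class ClinicalRecord:
    """Per-sample survival outcome plus grade/subtype/cohort labels."""

    sample_id: str
    dfs_years: float
    event: int
    grade: str = "unknown"
    subtype: str = "unknown"
    cohort: str = "unknown"

    def __post_init__(self) -> None:
        self.dfs_years = float(self.dfs_years)
        if self.dfs_years < 0:
            raise DataModelError(f"negative DFS time for {self.sample_id!r}")
        if self.event not in (0, 1):
            raise DataModelError(
                f"event must be 0/1 for {self.sample_id!r}, got {self.event!r}"
            )
        self.event = int(self.event)
        if self.grade not in GRADES:
            raise DataModelError(f"unknown grade {self.grade!r}")
        if self.subtype not in SUBTYPES:
            raise DataModelError(f"unknown subtype {self.subtype!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise DataModelError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise DataModelError(f"strand must be +/-, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenePairAnnotation:
    """Two partner genes sharing a locus, with orientation and control class."""

    pair_id: str
    gene_a: str
    gene_b: str
    orientation: str
    interval_a: GenomicInterval
    interval_b: GenomicInterval
    class_tag: str = "SAGP"

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise DataModelError(f"pair {self.pair_id!r}: identical partner genes")
        if self.orientation not in ORIENTATIONS:
            raise DataModelError(f"unknown orientation {self.orientation!r}")
        if self.class_tag not in CLASS_TAGS:
            raise DataModelError(f"unknown class tag {self.class_tag!r}")


@dataclass
class CohortBundle:
    """One cohort's expression matrix plus its clinical table."""

    expression: ExpressionMatrix
    clinical: list[ClinicalRecord]
    name: str

    def __post_init__(self) -> None:
        known = set(self.expression.sample_ids)
        for rec in self.clinical:
            if rec.sample_id not in known:
                raise DataModelError(
                    f"clinical sample {rec.sample_id!r} absent from expression"
                )
        self._by_sample = {r.sample_id: r for r in self.clinical}

    def select_samples(self, subgroup: str | None) -> list[str]:
        """Sample ids matching a filter like ``"grade=G3,subtype=basal"``.

        ``None`` or ``"all"`` selects every sample with a clinical record.
        """
        if subgroup in (None, "", "all"):
            return [r.sample_id for r in self.clinical]
        clauses = []
        for clause in subgroup.split(","):
            key, _, val = clause.partition("=")
            key = key.strip()
            if key not in ("grade", "subtype", "cohort"):
                raise DataModelError(f"unknown subgroup field {key!r}")
            clauses.append((key, val.strip()))
        return [
            r.sample_id
            for r in self.clinical
            if all(getattr(r, k) == v for k, v in clauses)
        ]

    def survival_arrays(
        self, sample_ids: Sequence[str] | None = None
    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        ids = list(sample_ids) if sample_ids is not None else [
            r.sample_id for r in self.clinical
        ]
        times = np.array([self._by_sample[s].dfs_years for s in ids])
        events = np.array([self._by_sample[s].event for s in ids], dtype=int)
        return times, events, ids


# ---------------------------------------------------------------------------
# Readers / writers (tab-delimited; see package docs for column layouts)
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix: first column feature id, header = samples.

    Missing or non-numeric cells are rejected (matrices are expected complete
    after upstream preprocessing); the error names the offending cell.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise DataModelError(f"{path}: duplicate sample columns")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    feature_ids = [str(f) for f in df.index]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() | df.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise DataModelError(
            f"{path}: non-numeric value at feature {feature_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(feature_ids, sample_ids, numeric.to_numpy(float))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical TSV with sample_id, dfs_years, event (+ optional labels)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "dfs_years", "event"}
    missing = required - set(df.columns)
    if missing:
        raise DataModelError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            ClinicalRecord(
                sample_id=str(d["sample_id"]),
                dfs_years=float(d["dfs_years"]),
                event=int(d["event"]),
                grade=str(d.get("grade", "unknown")),
                subtype=str(d.get("subtype", "unknown")),
                cohort=str(d.get("cohort", "unknown")),
            )
        )
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "dfs_years": r.dfs_years,
                "event": r.event,
                "grade": r.grade,
                "subtype": r.subtype,
                "cohort": r.cohort,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


_PAIR_COLUMNS = [
    "pair_id", "gene_a", "gene_b", "orientation", "chrom",
    "startA", "endA", "strandA", "startB", "endB", "strandB", "class_tag",
]


def read_gene_pairs(path: str | Path) -> list[GenePairAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise DataModelError(f"{path}: missing columns {sorted(missing)}")
    pairs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        pairs.append(
            GenePairAnnotation(
                pair_id=d["pair_id"],
                gene_a=d["gene_a"],
                gene_b=d["gene_b"],
                orientation=d["orientation"],
                interval_a=GenomicInterval(
                    d["chrom"], int(d["startA"]), int(d["endA"]), d["strandA"]
                ),
                interval_b=GenomicInterval(
                    d["chrom"], int(d["startB"]), int(d["endB"]), d["strandB"]
                ),
                class_tag=d["class_tag"],
            )
        )
    return pairs


def write_gene_pairs(pairs: Sequence[GenePairAnnotation], path: str | Path) -> None:
    rows = []
    for p in pairs:
        rows.append(
            {
                "pair_id": p.pair_id, "gene_a": p.gene_a, "gene_b": p.gene_b,
                "orientation": p.orientation, "chrom": p.interval_a.chrom,
                "startA": p.interval_a.start, "endA": p.interval_a.end,
                "strandA": p.interval_a.strand, "startB": p.interval_b.start,
                "endB": p.interval_b.end, "strandB": p.interval_b.strand,
                "class_tag": p.class_tag,
            }
        )
    pd.DataFrame(rows, columns=_PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peaks(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file of (unstranded) peak intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise DataModelError(f"{path}: BED needs at least 3 columns")
    return [
        GenomicInterval(str(r[0]), int(r[1]), int(r[2]))
        for r in df.itertuples(index=False)
    ]


def read_cnv_snps(path: str | Path) -> pd.DataFrame:
    """Read a SNP copy-number TSV with columns chrom, pos, value."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "value"} - set(df.columns)
    if missing:
        raise DataModelError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Expression standardization
# ---------------------------------------------------------------------------

def standardize(
    expr: ExpressionMatrix, feature_ids: Sequence[str] | None = None
) -> ExpressionMatrix:
    """Z-score the listed feature rows across this cohort's samples.

    Uses population standard deviation; constant rows map to all-zero. Applied
    per cohort so that rotation about the origin (rotated 2-D grouping) and
    quantile-scale cutoffs are meaningful on a cohort-relative scale.
    """
    if feature_ids is None:
        feature_ids = expr.feature_ids
    values = expr.values.copy()
    for fid in feature_ids:
        if not expr.has_feature(fid):
            raise DataModelError(f"unknown feature id {fid!r}")
        i = expr._row_index[fid]
        row = values[i]
        sd = row.std()
        if sd == 0:
            values[i] = 0.0
        else:
            values[i] = (row - row.mean()) / sd
    return ExpressionMatrix(list(expr.feature_ids), list(expr.sample_ids), values)
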