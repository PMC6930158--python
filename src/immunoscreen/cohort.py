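"""Cohort data model: expression matrix, clinical table, survival data.

All downstream analyses consume these types only.  Expression is a
gene x sample matrix of log2 intensities; the clinical table carries
relapse-free survival (RFS, months), pathological complete response
(pCR), subtype, treatment and the standard prognostic covariates.
Samples are always aligned by explicit ID join, never by position.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyCohortError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: clinical columns beyond the mandatory three; created as all-missing when absent
OPTIONAL_CLINICAL_COLUMNS = ("pcr", "subtype", "treatment", "nodal_status", "grade", "age")
MANDATORY_CLINICAL_COLUMNS = ("sample_id", "rfs_time", "rfs_event")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample log2 expression values.

    ``data`` is a DataFrame indexed by unique uppercase gene symbols with
    unique sample IDs as columns; missing values are NaN.  Each gene must
    have at least two finite values, otherwise no pairwise analysis is
    possible for it.
    """

    data: pd.DataFrame

    def __post_init__(self):
        idx = self.data.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate gene symbols: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = sorted(self.data.columns[self.data.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("empty expression matrix")
        finite = np.isfinite(self.data.to_numpy(dtype=float))
        bad = finite.sum(axis=1) < 2
        if bad.any():
            names = list(self.data.index[bad][:5])
            raise ValidationError(
                f"genes with fewer than two finite values: {names}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def gene_values(self, gene: str) -> pd.Series:
        """Expression vector of one gene across samples (NaN allowed)."""
        if gene not in self.data.index:
            raise KeyError(gene)
        return self.data.loc[gene]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(genes)])


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample clinical annotations.

    Mandatory: sample_id, rfs_time (months), rfs_event (0/1).  Optional
    columns (pcr, subtype, treatment, nodal_status, grade, age) are
    created as missing when absent; unknown extra columns are preserved
    untouched.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data
        for col in MANDATORY_CLINICAL_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"missing mandatory clinical column '{col}'")
        if df["sample_id"].duplicated().any():
            dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
            raise ValidationError(f"duplicate sample IDs in clinical table: {dups[:5]}")
        ev = df["rfs_event"]
        bad_ev = ev.dropna()[~ev.dropna().isin([0, 1])]
        if len(bad_ev):
            raise ValidationError(f"rfs_event values outside {{0,1}}: {sorted(bad_ev.unique())}")
        t = pd.to_numeric(df["rfs_time"], errors="coerce")
        has_event = ev.notna()
        bad_t = has_event & (~np.isfinite(t) | (t < 0))
        if bad_t.any():
            ids = list(df.loc[bad_t, "sample_id"][:5])
            raise ValidationError(f"negative or non-finite rfs_time for samples {ids}")
        if "grade" in df.columns:
            g = df["grade"].dropna()
            if len(g) and not g.isin([1, 2, 3]).all():
                raise ValidationError("grade values must be in {1,2,3} or missing")
        if "pcr" in df.columns:
            p = df["pcr"].dropna()
            if len(p) and not p.isin([0, 1]).all():
                raise ValidationError("pcr values must be in {0,1} or missing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def column(self, name: str) -> pd.Series:
        return self.data.set_index("sample_id")[name]

    def subset(self, sample_ids) -> "ClinicalTable":
        df = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return ClinicalTable(df)

    def survival(self) -> "SurvivalData":
        return SurvivalData.from_clinical(self)


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored survival endpoint: time (months) and event (0/1).

    Samples with missing time or event carry NaN and are excluded by the
    analyses that require complete survival information.
    """

    time: np.ndarray
    event: np.ndarray
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=float)
        if t.shape != e.shape or t.ndim != 1:
            raise ValidationError("time and event must be 1-D arrays of equal length")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        if self.sample_ids is not None and len(self.sample_ids) != len(t):
            raise ValidationError("sample_ids length mismatch")

    @classmethod
    def from_clinical(cls, clin: ClinicalTable) -> "SurvivalData":
        df = clin.data
        return cls(
            time=pd.to_numeric(df["rfs_time"], errors="coerce").to_numpy(dtype=float),
            event=pd.to_numeric(df["rfs_event"], errors="coerce").to_numpy(dtype=float),
            sample_ids=tuple(df["sample_id"]),
        )

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(np.nansum(self.event == 1))

    def complete_mask(self) -> np.ndarray:
        return np.isfinite(self.time) & np.isfinite(self.event)

    def select(self, mask) -> "SurvivalData":
        mask = np.asarray(mask)
        ids = None
        if self.sample_ids is not None:
            ids = tuple(np.asarray(self.sample_ids, dtype=object)[mask])
        return SurvivalData(self.time[mask], self.event[mask], ids)


# ---------------------------------------------------------------------------
# readers / writers


def _parse_cell(text: str, line_no: int, col_no: int) -> float:
    s = text.strip()
    if s in ("NA", ""):
        return math.nan
    try:
        return float(s)
    except ValueError:
        raise ParseError(
            f"non-numeric expression value {s!r} at line {line_no}, column {col_no}"
        ) from None


def load_expression(path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    First header column must be literally ``gene``; remaining header
    fields are sample IDs.  Cells are numeric or ``NA``.  Duplicate gene
    symbols are collapsed by per-cell mean (logged).
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0].strip() != "gene":
        raise ParseError(
            f"line 1: first header column must be 'gene', found {header[0]!r}"
        )
    samples = [s.strip() for s in header[1:]]
    if not samples:
        raise ParseError("line 1: header contains no sample IDs")
    genes: list[str] = []
    rows: list[list[float]] = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(samples) + 1:
            raise ParseError(
                f"line {i}: expected {len(samples) + 1} fields, found {len(fields)}"
            )
        genes.append(fields[0].strip().upper())
        rows.append([_parse_cell(v, i, j) for j, v in enumerate(fields[1:], start=2)])
    if not genes:
        raise ParseError(f"{path}: no gene rows")
    df = pd.DataFrame(rows, index=genes, columns=samples, dtype=float)
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene symbol rows by mean", n_dup)
        order = list(dict.fromkeys(genes))
        df = df.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write the standard TSV (header 'gene', missing as NA, full precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(expr.samples) + "\n")
        values = expr.data.to_numpy(dtype=float)
        for g, row in zip(expr.genes, values):
            cells = ["NA" if not np.isfinite(v) else repr(float(v)) for v in row]
            fh.write(g + "\t" + "\t".join(cells) + "\n")


def load_clinical(path) -> ClinicalTable:
    """Read the clinical CSV; 'NA' or empty cells become missing."""
    df = pd.read_csv(
        path,
        na_values=["NA", ""],
        keep_default_na=False,
        dtype={"sample_id": str, "subtype": str, "treatment": str},
    )
    for col in MANDATORY_CLINICAL_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing mandatory column '{col}'")
    for col in OPTIONAL_CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in ("rfs_time", "rfs_event", "pcr", "nodal_status", "grade", "age"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.data.to_csv(path, index=False, na_rep="NA")


def join_cohort(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    subtype_filter: str | None = None,
    treatment_filter: str | None = None,
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Inner-join expression and clinical tables on sample ID.

    Optional ``subtype_filter`` / ``treatment_filter`` restrict the
    cohort by the corresponding clinical labels.  Sample order follows
    the expression matrix.  Dropped-sample counts are logged.
    """
    cdf = clin.data
    if subtype_filter is not None:
        cdf = cdf[cdf["subtype"] == subtype_filter]
    if treatment_filter is not None:
        cdf = cdf[cdf["treatment"] == treatment_filter]
    keep = set(cdf["sample_id"])
    joined_ids = [s for s in expr.samples if s in keep]
    if not joined_ids:
        raise EmptyCohortError(
            "no samples shared between expression matrix and (filtered) clinical table"
        )
    n_expr_drop = expr.n_samples - len(joined_ids)
    n_clin_drop = len(cdf) - len(joined_ids)
    if n_expr_drop or n_clin_drop:
        logger.info(
            "join_cohort: kept %d samples (dropped %d expression-only, %d clinical-only)",
            len(joined_ids), n_expr_drop, n_clin_drop,
        )
    sub_clin = ClinicalTable(
        cdf.set_index("sample_id").loc[joined_ids].reset_index()
    )
    return expr.subset_samples(joined_ids), sub_clin
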