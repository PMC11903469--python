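"""Cohort containers and I/O: expression matrices, clinical tables, QC and alignment.

The analysis consumes two tab-delimited inputs: a genes x samples matrix of
normalized linear expression values (NanoString normalized counts or linear
TPM) and a per-sample clinical table carrying treatment arm, molecular
subgroup labels, timepoint and three right-censored endpoints (DOR, EFS,
PFS).  This module validates both, applies the sample-level QC and
duplicate-subject rules used upstream of signature discovery, and aligns
them into a single :class:`Cohort`.
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENDPOINTS = ("DOR", "EFS", "PFS")

#: Column schema of the clinical TSV, in canonical order.
CLINICAL_COLUMNS = (
    "sample_id",
    "subject_id",
    "arm",
    "timepoint",
    "collection_date",
    "batch_id",
    "coding_read_fraction",
    "coo",
    "hgbl_flag",
    "double_expressor_flag",
    "myc_rearranged_flag",
    "responder_flag",
    "dor_time",
    "dor_event",
    "efs_time",
    "efs_event",
    "pfs_time",
    "pfs_event",
)

_ARMS = {"axi-cel", "SOC"}
_TIMEPOINTS = {"pretreatment", "progression"}
_COO = {"GCB", "non-GCB", "unknown"}
_TRISTATE = {"yes", "no", "not_applicable"}
_YESNO = {"yes", "no"}


class CohortValidationError(ValueError):
    """Raised when an input violates the cohort schema or its invariants."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative linear expression values.

    Parameters
    ----------
    gene_ids : list of str
        Unique transcript/gene symbols, one per row of ``values``.
    sample_ids : list of str
        Unique sample identifiers, one per column of ``values``.
    values : ndarray of shape (n_genes, n_samples)
        Finite, non-negative expression values on the linear scale.
    unit_label : str
        Free-text unit, e.g. ``"nanostring_linear_count"`` or ``"tpm"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit_label: str = "nanostring_linear_count"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CohortValidationError("expression values must be 2-D")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CohortValidationError(
                f"value grid {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise CohortValidationError(f"duplicate {label} ids: {sorted(dupes)}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            raise CohortValidationError(
                f"non-finite expression values at {self._coords(bad)}"
            )
        neg = self.values < 0
        if neg.any():
            raise CohortValidationError(
                f"negative expression values at {self._coords(neg)}"
            )

    def _coords(self, mask: np.ndarray) -> list[tuple[str, str]]:
        gi, si = np.nonzero(mask)
        return [(self.gene_ids[g], self.sample_ids[s]) for g, s in zip(gi[:5], si[:5])]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, cols].copy(),
            unit_label=self.unit_label,
        )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise CohortValidationError(f"genes absent from matrix: {missing}")
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :].copy(),
            unit_label=self.unit_label,
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations with three censored endpoints.

    Wraps a DataFrame with :data:`CLINICAL_COLUMNS`.  Endpoint availability is
    encoded by NaN in the time/event columns; duration of response (DOR) is
    forced unavailable for non-responders because DOR is undefined for
    patients who never responded.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise CohortValidationError(f"clinical table missing columns: {missing}")
        df = df[list(CLINICAL_COLUMNS)].reset_index(drop=True)
        df["sample_id"] = df["sample_id"].astype(str)
        df["subject_id"] = df["subject_id"].astype(str)
        dupes = _duplicates(df["sample_id"].tolist())
        if dupes:
            raise CohortValidationError(f"duplicate sample ids: {sorted(dupes)}")
        for col, allowed in (
            ("arm", _ARMS),
            ("timepoint", _TIMEPOINTS),
            ("coo", _COO),
            ("hgbl_flag", _TRISTATE),
            ("double_expressor_flag", _TRISTATE),
            ("myc_rearranged_flag", _TRISTATE),
            ("responder_flag", _YESNO),
        ):
            bad = set(df[col].dropna()) - allowed
            if bad:
                raise CohortValidationError(f"invalid {col} values: {sorted(bad)}")
        df["collection_date"] = df["collection_date"].map(_parse_date)
        for col in ("batch_id",):
            df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
        df["coding_read_fraction"] = pd.to_numeric(
            df["coding_read_fraction"], errors="raise"
        )
        frac = df["coding_read_fraction"].dropna()
        if ((frac < 0) | (frac > 1)).any():
            raise CohortValidationError("coding_read_fraction outside [0, 1]")

        # responder gating: DOR is undefined for non-responders
        nonresp = df["responder_flag"] == "no"
        df.loc[nonresp, ["dor_time", "dor_event"]] = np.nan

        for ep in ENDPOINTS:
            tcol, ecol = f"{ep.lower()}_time", f"{ep.lower()}_event"
            df[tcol] = pd.to_numeric(df[tcol], errors="raise")
            df[ecol] = pd.to_numeric(df[ecol], errors="raise")
            avail = df[tcol].notna()
            if (df.loc[avail, tcol] <= 0).any():
                bad_ids = df.loc[avail & (df[tcol] <= 0), "sample_id"].tolist()
                raise CohortValidationError(
                    f"non-positive {ep} time for samples {bad_ids}"
                )
            ev = df.loc[avail, ecol]
            if ev.isna().any() or (~ev.isin([0, 1])).any():
                raise CohortValidationError(f"{ep} event indicator must be 0 or 1")
            df.loc[~avail, ecol] = np.nan
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def __len__(self) -> int:
        return len(self.data)

    def endpoint_available(self, endpoint: str) -> np.ndarray:
        """Boolean mask over samples with the endpoint observed."""
        _check_endpoint(endpoint)
        return self.data[f"{endpoint.lower()}_time"].notna().to_numpy()

    def endpoint_arrays(self, endpoint: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (mask, time, event) for an endpoint; time/event on available samples."""
        mask = self.endpoint_available(endpoint)
        t = self.data.loc[mask, f"{endpoint.lower()}_time"].to_numpy(float)
        e = self.data.loc[mask, f"{endpoint.lower()}_event"].to_numpy(float).astype(int)
        return mask, t, e

    def subset(self, sample_ids: list[str]) -> "ClinicalTable":
        df = self.data.set_index("sample_id", drop=False).loc[list(sample_ids)]
        return ClinicalTable(df.reset_index(drop=True))


@dataclass
class Cohort:
    """Expression matrix and clinical table restricted to the same samples, co-ordered."""

    expression: ExpressionMatrix
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.clinical.sample_ids:
            raise CohortValidationError(
                "expression and clinical sample ids differ or are ordered differently"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    def subset_samples(self, sample_ids: list[str]) -> "Cohort":
        return Cohort(
            self.expression.subset_samples(sample_ids),
            self.clinical.subset(sample_ids),
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path, unit_label: str = "nanostring_linear_count") -> ExpressionMatrix:
    """Read a genes-in-rows TSV (first column ``gene_id``, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise CohortValidationError("expression file needs gene_id plus >=1 sample column")
    gene_col = df.columns[0]
    genes = df[gene_col].tolist()
    samples = [str(c) for c in df.columns[1:]]
    vals = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    nonnum = np.isnan(vals) & df.iloc[:, 1:].notna().to_numpy()
    if nonnum.any():
        g, s = np.nonzero(nonnum)
        raise CohortValidationError(
            f"non-numeric expression value at gene {genes[g[0]]!r}, sample {samples[s[0]]!r}"
        )
    return ExpressionMatrix(genes, samples, vals, unit_label=unit_label)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_clinical_table(path) -> ClinicalTable:
    """Read the per-sample clinical TSV (see :data:`CLINICAL_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"clinical file missing columns: {missing}")
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    df = clinical.data.copy()
    df["collection_date"] = df["collection_date"].map(
        lambda d: d.isoformat() if isinstance(d, _dt.date) else ""
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# QC and deduplication


def qc_filter_coding_fraction(
    clinical: ClinicalTable, min_fraction: float = 0.10
) -> ClinicalTable:
    """Drop samples whose fraction of reads mapped to coding sequence is <= threshold.

    Samples lacking the metric are retained untouched.  Retention is strictly
    greater than ``min_fraction`` (a sample at exactly the threshold is
    removed).
    """
    frac = clinical.data["coding_read_fraction"]
    if frac.isna().all():
        warnings.warn(
            "coding_read_fraction absent for all samples; QC filter is a no-op",
            stacklevel=2,
        )
        return ClinicalTable(clinical.data.copy())
    keep = frac.isna() | (frac > min_fraction)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "coding-fraction QC removed %d/%d samples (threshold <= %g)",
            n_removed, len(clinical), min_fraction,
        )
    return ClinicalTable(clinical.data.loc[keep].reset_index(drop=True))


def dedup_subject_samples(clinical: ClinicalTable) -> ClinicalTable:
    """Resolve subjects with multiple pretreatment samples to a single sample.

    For each subject with several pretreatment samples, the sample with the
    latest collection date is kept; date ties are broken toward the lower
    molecular batch id (the sample analyzed first).  A tie on both is
    undecidable and fatal.  Progression samples are untouched.
    """
    df = clinical.data
    pre = df[df["timepoint"] == "pretreatment"]
    keep_ids: list[str] = df.loc[df["timepoint"] != "pretreatment", "sample_id"].tolist()
    for subject, grp in pre.groupby("subject_id", sort=False):
        if len(grp) == 1:
            keep_ids.append(grp["sample_id"].iloc[0])
            continue
        if grp["collection_date"].isna().any() or grp["batch_id"].isna().any():
            raise CohortValidationError(
                f"subject {subject!r} has duplicate pretreatment samples but "
                "missing collection_date or batch_id"
            )
        latest = grp["collection_date"].max()
        cand = grp[grp["collection_date"] == latest]
        if len(cand) > 1:
            low = cand["batch_id"].min()
            cand = cand[cand["batch_id"] == low]
            if len(cand) > 1:
                raise CohortValidationError(
                    f"subject {subject!r}: tied collection date and batch id; "
                    "cannot resolve duplicate samples"
                )
        keep_ids.append(cand["sample_id"].iloc[0])
        logger.info(
            "subject %s: kept sample %s of %d duplicates",
            subject, cand["sample_id"].iloc[0], len(grp),
        )
    keep = df["sample_id"].isin(keep_ids)
    return ClinicalTable(df.loc[keep].reset_index(drop=True))


def align_cohort(expr: ExpressionMatrix, clinical: ClinicalTable) -> Cohort:
    """Restrict both inputs to their shared samples, ordered as in the expression matrix."""
    expr_ids = set(expr.sample_ids)
    clin_ids = set(clinical.sample_ids)
    shared = [s for s in expr.sample_ids if s in clin_ids]
    if not shared:
        raise CohortValidationError(
            "expression and clinical tables share no sample ids"
        )
    dropped_expr = sorted(expr_ids - clin_ids)
    dropped_clin = sorted(clin_ids - expr_ids)
    if dropped_expr:
        logger.info("align: dropped %d expression-only samples", len(dropped_expr))
    if dropped_clin:
        logger.info("align: dropped %d clinical-only samples", len(dropped_clin))
    return Cohort(expr.subset_samples(shared), clinical.subset(shared))


# ---------------------------------------------------------------------------
# helpers


def _duplicates(ids: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _parse_date(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, _dt.date):
        return value
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return None
    try:
        return _dt.date.fromisoformat(s)
    except ValueError as exc:
        raise CohortValidationError(
            f"collection_date {value!r} is not ISO-8601 (YYYY-MM-DD)"
        ) from exc


def _check_endpoint(endpoint: str) -> None:
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
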