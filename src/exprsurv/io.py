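"""Cohort table ingestion, validation and export.

Cohort tables are delimited text (TSV/CSV) with a header; missing values
are empty fields or "NA".  A column mapping translates the caller's column
names onto the canonical field names the analyses expect; malformed rows
are rejected individually with their line numbers logged, never silently
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .survival import ValidationError

__all__ = ["CohortTable", "load_cohort", "write_cohort", "DEFAULT_MAPPING"]

logger = logging.getLogger(__name__)

# canonical field -> expected column name
DEFAULT_MAPPING = {
    "sample_id": "sample_id",
    "relative_expression": "relative_expression",
    "os_months": "os_months",
    "os_event": "os_event",
    "efs_months": "efs_months",
    "efs_event": "efs_event",
    "ct_target": "ct_target",
    "ct_reference": "ct_reference",
    "cr_achieved": "cr_achieved",
    "cohort": "cohort",
    "flt3_itd": "flt3_itd",
    "npm1": "npm1",
    "cebpa": "cebpa",
    "fab_m3": "fab_m3",
}

_TIME_FIELDS = ("os_months", "efs_months")
_BOOL_FIELDS = ("os_event", "efs_event", "cr_achieved", "flt3_itd", "npm1", "cebpa", "fab_m3")
_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}


@dataclass
class CohortTable:
    """Validated per-sample table plus its column mapping and provenance."""

    table: pd.DataFrame
    mapping: dict = field(default_factory=lambda: dict(DEFAULT_MAPPING))
    provenance: str = "memory"
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.table)

    def require(self, *fields: str) -> "CohortTable":
        missing = [f for f in fields if f not in self.table.columns]
        if missing:
            raise ValidationError(f"cohort lacks required field(s): {missing}")
        return self

    def exclude_fab_m3(self) -> "CohortTable":
        """Row-filter flag: drop FAB-M3 (promyelocytic) cases before analysis."""
        if "fab_m3" not in self.table.columns:
            return self
        keep = self.table["fab_m3"].fillna(0).astype(float) == 0
        dropped = int((~keep).sum())
        if dropped:
            logger.info("excluded %d FAB-M3 rows", dropped)
        return CohortTable(
            table=self.table[keep].reset_index(drop=True),
            mapping=self.mapping,
            provenance=self.provenance + "|fab_m3_excluded",
            n_rejected=self.n_rejected,
        )


def _coerce_bool(series: pd.Series, colname: str):
    """Map {0,1,true,false,...} onto floats with NaN for missing; None on failure."""
    def conv(v):
        if pd.isna(v):
            return np.nan
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return 1.0
        if s in _FALSY:
            return 0.0
        return None

    out = series.map(conv)
    return out


def load_cohort(
    path: str | Path,
    mapping: dict | None = None,
    delimiter: str | None = None,
) -> CohortTable:
    """Load and validate a delimited cohort table.

    The delimiter is taken from the file extension (.tsv/.txt -> tab,
    .csv -> comma) unless declared.  Rows violating field invariants
    (non-positive survival time, unparseable event flag, non-positive
    expression) are rejected with a warning naming the 1-based data line
    number; the count of rejected rows is retained on the result.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such cohort file: {path}")
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=delimiter, na_values=["NA", ""], dtype="object")
    if df.empty:
        raise ValidationError(f"cohort file {path} has no data rows")

    mapping = dict(DEFAULT_MAPPING if mapping is None else mapping)
    rename = {col: fld for fld, col in mapping.items() if col in df.columns}
    df = df.rename(columns=rename)

    bad = pd.Series(False, index=df.index)
    reasons: dict[int, str] = {}

    for fld in ("relative_expression", "ct_target", "ct_reference", *_TIME_FIELDS):
        if fld in df.columns:
            values = pd.to_numeric(df[fld], errors="coerce")
            invalid = df[fld].notna() & (values.isna() | (values <= 0))
            for i in df.index[invalid]:
                bad[i] = True
                reasons.setdefault(i, f"{fld} must be a positive number")
            df[fld] = values.where(~invalid)

    for fld in _BOOL_FIELDS:
        if fld in df.columns:
            coerced = _coerce_bool(df[fld], fld)
            invalid = coerced.map(lambda v: v is None)
            for i in df.index[invalid]:
                bad[i] = True
                reasons.setdefault(i, f"{fld} is not a boolean flag")
            df[fld] = coerced.where(~invalid).astype(float)

    for i, why in sorted(reasons.items()):
        logger.warning("row rejected (line %d): %s", i + 2, why)  # +2: header + 1-based

    clean = df[~bad].reset_index(drop=True)
    if clean.empty:
        raise ValidationError(f"cohort file {path}: zero valid rows after validation")

    has_expr = "relative_expression" in clean.columns and clean["relative_expression"].notna()
    has_ct = (
        "ct_target" in clean.columns
        and "ct_reference" in clean.columns
        and clean["ct_target"].notna()
        & clean["ct_reference"].notna()
    )
    if "ct_target" in clean.columns and "ct_reference" in clean.columns:
        from .expression import relative_expression

        need = (
            ~has_expr if isinstance(has_expr, pd.Series) else pd.Series(True, index=clean.index)
        ) & has_ct
        if need.any():
            if "relative_expression" not in clean.columns:
                clean["relative_expression"] = np.nan
            clean.loc[need, "relative_expression"] = relative_expression(
                clean.loc[need, "ct_target"].astype(float),
                clean.loc[need, "ct_reference"].astype(float),
            )

    return CohortTable(
        table=clean,
        mapping=mapping,
        provenance=str(path),
        n_rejected=int(bad.sum()),
    )


def write_cohort(cohort: CohortTable | pd.DataFrame, path: str | Path, delimiter: str = "\t") -> Path:
    """Write a cohort table as delimited text with header; NA for missing."""
    df = cohort.table if isinstance(cohort, CohortTable) else cohort
    path = Path(path)
    df.to_csv(path, sep=delimiter, index=False, na_rep="NA")
    return path
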