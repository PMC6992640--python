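"""Schema-validated reading and writing of the tabular formats the pipeline consumes.

Every stage exchanges plain CSV/TSV tables; this module pins down their
column layouts so downstream code operates on validated frames and typed
records rather than raw files.  Doses are stored in micromolar throughout;
readers convert declared-unit columns on ingest.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

#: recognised semantic types for schema columns
_SEMANTIC_TYPES = {"label", "number", "integer", "flag"}

#: multiplicative factors to µM for declared dose units
DOSE_UNIT_TO_UM = {"uM": 1.0, "nM": 1e-3, "mM": 1e3, "M": 1e6}


@dataclass(frozen=True)
class TableSchema:
    """Declared layout of one pipeline table.

    Parameters
    ----------
    name:
        Short identifier used in error messages.
    columns:
        Ordered ``(column name, semantic type)`` pairs; semantic types are
        ``label`` (string), ``number`` (float), ``integer`` and ``flag``
        (0/1 boolean).
    dialect:
        ``"comma"`` or ``"tab"``.
    key:
        Optional subset of column names whose combination must be unique
        per row.
    """

    name: str
    columns: tuple[tuple[str, str], ...]
    dialect: str = "comma"
    key: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError("schema requires at least one column")
        names = [c for c, _ in self.columns]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate column names in schema {self.name!r}")
        for cname, ctype in self.columns:
            if ctype not in _SEMANTIC_TYPES:
                raise ValueError(f"unknown semantic type {ctype!r} for column {cname!r}")
        if self.dialect not in ("comma", "tab"):
            raise ValueError(f"unknown dialect {self.dialect!r}")

    @property
    def column_names(self) -> list[str]:
        return [c for c, _ in self.columns]

    @property
    def sep(self) -> str:
        return "," if self.dialect == "comma" else "\t"


@dataclass(frozen=True)
class ScreenMeasurement:
    """One well of a luminescence viability screen.

    ``signal`` is total photon flux per second (or a pre-normalized
    viability when the plate reader already reports percent of control);
    ``role`` distinguishes vehicle-control wells (0.1% DMSO, dose 0) from
    drug-treated wells.
    """

    model_id: str
    drug_id: str
    dose: float  # µM; 0 for vehicle wells
    replicate: int
    signal: float
    role: str  # "vehicle" | "treated"

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValidationError(
                f"signal must be non-negative, got {self.signal} "
                f"({self.model_id}/{self.drug_id})"
            )
        if self.role not in ("vehicle", "treated"):
            raise ValidationError(f"unknown role {self.role!r}")
        if self.role == "vehicle" and self.dose != 0:
            raise ValidationError(
                f"vehicle well must have dose 0, got {self.dose} "
                f"({self.model_id}/{self.drug_id})"
            )
        if self.replicate < 1 or int(self.replicate) != self.replicate:
            raise ValidationError(f"replicate must be a positive integer, got {self.replicate}")


# ---------------------------------------------------------------------------
# canonical schemas
# ---------------------------------------------------------------------------

WELLS_SCHEMA = TableSchema(
    name="wells",
    columns=(
        ("model", "label"),
        ("drug", "label"),
        ("dose_uM", "number"),
        ("replicate", "integer"),
        ("signal", "number"),
        ("role", "label"),
    ),
    key=("model", "drug", "dose_uM", "replicate"),
)

VIABILITY_SCHEMA = TableSchema(
    name="viability",
    columns=(
        ("model", "label"),
        ("drug", "label"),
        ("dose_uM", "number"),
        ("viability_pct", "number"),
        ("n_reps", "integer"),
        ("sd", "number"),
        ("artifact_flag", "flag"),
    ),
    key=("model", "drug", "dose_uM"),
)

DOSE_RESPONSE_SCHEMA = TableSchema(
    name="dose_response",
    columns=(
        ("series_id", "label"),
        ("drug1", "label"),
        ("drug2", "label"),
        ("ratio", "number"),
        ("total_dose_uM", "number"),
        ("fa", "number"),
    ),
    key=("series_id", "total_dose_uM"),
)

CLINICAL_SCHEMA = TableSchema(
    name="clinical",
    columns=(
        ("sample", "label"),
        ("subtype", "label"),
        ("er", "integer"),
        ("pr", "integer"),
        ("her2", "integer"),
        ("age", "number"),
        ("ln_status", "integer"),
        ("diff_score", "number"),
        ("prolif_score", "number"),
    ),
    key=("sample",),
)

SURVIVAL_SCHEMA = TableSchema(
    name="survival",
    columns=(
        ("sample", "label"),
        ("endpoint", "label"),
        ("time_months", "number"),
        ("event", "flag"),
    ),
    key=("sample", "endpoint"),
)

SCHEMAS = {
    s.name: s
    for s in (
        WELLS_SCHEMA,
        VIABILITY_SCHEMA,
        DOSE_RESPONSE_SCHEMA,
        CLINICAL_SCHEMA,
        SURVIVAL_SCHEMA,
    )
}


# ---------------------------------------------------------------------------
# generic table I/O
# ---------------------------------------------------------------------------


def _coerce_column(series: pd.Series, ctype: str, table: str, column: str) -> pd.Series:
    if ctype == "label":
        return series.astype(str)
    numeric = pd.to_numeric(series, errors="coerce")
    bad = numeric.isna() & series.notna()
    if bad.any():
        # +2: 1-based line numbers plus the header line
        lines = [int(i) + 2 for i in series.index[bad][:5]]
        raise ValidationError(
            f"{table}: non-numeric value in column {column!r} at line(s) {lines}"
        )
    if numeric.isna().any():
        raise ValidationError(f"{table}: missing value in column {column!r}")
    # re-parse with Python's strtod: pandas' fast parser is not round-trip exact
    numeric = series.astype(float)
    if ctype == "integer":
        as_int = numeric.astype(int)
        if (as_int != numeric).any():
            raise ValidationError(f"{table}: non-integer value in column {column!r}")
        return as_int
    if ctype == "flag":
        as_int = numeric.astype(int)
        if not as_int.isin((0, 1)).all():
            raise ValidationError(f"{table}: flag column {column!r} must be 0/1")
        return as_int.astype(bool)
    return numeric.astype(float)


def read_table(path: str | Path | io.TextIOBase, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a table against *schema*.

    The header must contain every schema column (order-insensitive; extra
    columns are dropped).  Returns a frame with columns in schema order and
    semantic dtypes applied.  Raises :class:`SchemaError` for a missing
    column and :class:`ValidationError` for bad cell values or duplicate
    keys.
    """
    df = pd.read_csv(path, sep=schema.sep, dtype=str, encoding="utf-8")
    missing = [c for c in schema.column_names if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema.name}: missing required column(s) {', '.join(repr(m) for m in missing)}"
        )
    df = df[schema.column_names]
    out = pd.DataFrame(
        {c: _coerce_column(df[c], t, schema.name, c) for c, t in schema.columns}
    )
    if schema.key:
        dup = out.duplicated(subset=list(schema.key))
        if dup.any():
            first = out.loc[dup.idxmax(), list(schema.key)].tolist()
            raise ValidationError(
                f"{schema.name}: duplicate key {tuple(first)} on {schema.key}"
            )
    return out


def write_table(df: pd.DataFrame, path: str | Path, schema: TableSchema) -> None:
    """Write *df* in the schema's declared dialect, UTF-8, full float precision."""
    missing = [c for c in schema.column_names if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema.name}: records lack column(s) {missing}")
    out = df[schema.column_names].copy()
    for c, t in schema.columns:
        if t == "flag":
            out[c] = out[c].astype(bool).astype(int)
    out.to_csv(path, sep=schema.sep, index=False, encoding="utf-8")


def read_screen_table(
    path: str | Path | io.TextIOBase, schema: TableSchema = WELLS_SCHEMA
) -> list[ScreenMeasurement]:
    """Parse a wells table into validated :class:`ScreenMeasurement` records."""
    df = read_table(path, schema)
    return [
        ScreenMeasurement(
            model_id=r.model,
            drug_id=r.drug,
            dose=float(r.dose_uM),
            replicate=int(r.replicate),
            signal=float(r.signal),
            role=str(r.role),
        )
        for r in df.itertuples(index=False)
    ]


def measurements_to_frame(records: Sequence[ScreenMeasurement]) -> pd.DataFrame:
    """Inverse of :func:`read_screen_table`: records back into a wells frame."""
    return pd.DataFrame(
        {
            "model": [r.model_id for r in records],
            "drug": [r.drug_id for r in records],
            "dose_uM": [r.dose for r in records],
            "replicate": [r.replicate for r in records],
            "signal": [r.signal for r in records],
            "role": [r.role for r in records],
        }
    )


def write_results(
    records: Sequence[ScreenMeasurement] | pd.DataFrame,
    path: str | Path,
    schema: TableSchema,
) -> None:
    """Serialize *records* (typed records or a frame) under *schema*."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = measurements_to_frame(list(records))
        if not len(df):
            df = pd.DataFrame(columns=schema.column_names)
    write_table(df, path, schema)


# ---------------------------------------------------------------------------
# expression matrix (genes x samples TSV, first column = gene symbol)
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read a genes-by-samples TSV into a samples-by-genes float frame."""
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"expression: duplicate gene symbol(s) {dupes}")
    if df.columns.duplicated().any():
        raise ValidationError("expression: duplicate sample labels")
    try:
        mat = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"expression: non-numeric cell ({exc})") from exc
    return mat.T  # samples x genes internally


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    """Write a samples-by-genes frame as the genes-by-samples TSV on disk."""
    out = expr.T
    out.index.name = "gene"
    out.to_csv(path, sep="\t", encoding="utf-8")
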