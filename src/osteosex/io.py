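"""Domain types and file I/O for reference samples and fitted models.

Reference samples are CSV tables with a header row (comma, semicolon or tab
delimited): one row per individual, an id column, a sex column and one
column per measurement (mm). Fitted models travel as JSON "model files"
holding the coefficients, intercept and enough metadata (sex coding,
priors, score means) to apply published equations to new cases.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("osteosex")

FEMALE = "F"
MALE = "M"
UNKNOWN = "unknown"

#: accepted spellings for the sex column (lower-cased before lookup)
SEX_SYNONYMS = {
    "f": FEMALE,
    "female": FEMALE,
    "0": FEMALE,
    "m": MALE,
    "male": MALE,
    "1": MALE,
    "unknown": UNKNOWN,
    "u": UNKNOWN,
    "?": UNKNOWN,
    "": UNKNOWN,
    "nan": UNKNOWN,
}


class SchemaError(ValueError):
    """Raised when a file's structure does not match the expected schema."""


def parse_sex(value: object) -> str:
    """Normalize a raw sex value to ``F``, ``M`` or ``unknown``.

    Raises ``ValueError`` for values not in the synonym table.
    """
    text = str(value).strip().lower()
    try:
        return SEX_SYNONYMS[text]
    except KeyError:
        raise ValueError(f"unparseable sex value {value!r}") from None


@dataclass
class MeasurementRecord:
    """One individual: id, sex, optional age and named measurements in mm.

    ``side_substituted`` flags measurements taken on the left side when the
    right was unavailable (metadata only; values are used as-is).
    """

    id: str
    sex: str
    measurements: dict[str, float]
    age_years: float | None = None
    side_substituted: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE, UNKNOWN):
            raise ValueError(f"sex must be F, M or unknown, got {self.sex!r}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"age_years must be non-negative, got {self.age_years}")
        for name, value in self.measurements.items():
            if not (value > 0) or not math.isfinite(value):
                raise ValueError(
                    f"measurement {name!r} of record {self.id!r} must be a "
                    f"positive finite number, got {value}"
                )

    def has_all(self, variables: Iterable[str]) -> bool:
        return all(v in self.measurements for v in variables)


@dataclass
class ReferenceSample:
    """Known-sex individuals sharing a common ordered set of measurements."""

    records: list[MeasurementRecord]
    variables: list[str]

    def __post_init__(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")
        for r in self.records:
            if r.sex not in (FEMALE, MALE):
                raise ValueError(
                    f"reference record {r.id!r} must have known sex F or M"
                )
            missing = [v for v in self.variables if v not in r.measurements]
            if missing:
                raise ValueError(f"record {r.id!r} is missing {missing}")
        for sex in (FEMALE, MALE):
            if sum(1 for r in self.records if r.sex == sex) < 2:
                raise ValueError(f"need at least 2 records of sex {sex}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_f(self) -> int:
        return sum(1 for r in self.records if r.sex == FEMALE)

    @property
    def n_m(self) -> int:
        return sum(1 for r in self.records if r.sex == MALE)

    def matrix(self, variables: Sequence[str] | None = None) -> np.ndarray:
        """(n, p) array of measurement values in variable order."""
        variables = list(variables) if variables is not None else self.variables
        return np.array(
            [[r.measurements[v] for v in variables] for r in self.records],
            dtype=float,
        )

    def sex_array(self) -> np.ndarray:
        """Array of 'F'/'M' labels aligned with :meth:`matrix` rows."""
        return np.array([r.sex for r in self.records])

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, indices: Sequence[int], *, suffix_duplicates: bool = False) -> "ReferenceSample":
        """Sample restricted to ``indices`` (with repeats allowed when
        ``suffix_duplicates`` is set, as in bootstrap resampling)."""
        chosen = [self.records[i] for i in indices]
        if suffix_duplicates:
            chosen = [
                dataclasses.replace(r, id=f"{r.id}#{k}")
                for k, r in enumerate(chosen)
            ]
        return ReferenceSample(records=chosen, variables=list(self.variables))

    def drop_index(self, index: int) -> "ReferenceSample":
        records = self.records[:index] + self.records[index + 1 :]
        return ReferenceSample(records=records, variables=list(self.variables))


@dataclass
class ModelFile:
    """Serializable container for a fitted or published equation.

    ``coefficients`` keys must exactly match ``variables``; ``metadata``
    carries sex coding, priors, per-sex counts, score means and provenance
    so that published equations under either coding convention load
    unambiguously.
    """

    model_kind: str  # "lda" or "logr"
    variables: list[str]
    coefficients: dict[str, float]
    intercept: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_kind not in ("lda", "logr"):
            raise SchemaError(f"unknown model_kind {self.model_kind!r}")
        if set(self.coefficients) != set(self.variables):
            raise SchemaError(
                f"coefficient keys {sorted(self.coefficients)} do not match "
                f"variables {self.variables}"
            )


def read_reference_csv(
    path: str | Path,
    variable_columns: Sequence[str],
    sex_column: str = "sex",
    id_column: str = "id",
    age_column: str | None = None,
) -> ReferenceSample:
    """Load a reference sample, list-wise dropping rows with missing values.

    Rows missing any of ``variable_columns`` are dropped and the count
    logged; rows whose sex is unknown are rejected (a reference sample must
    be fully labeled). Delimiter is auto-detected among comma, semicolon
    and tab.
    """
    df = _read_table(path)
    for col in [id_column, sex_column, *variable_columns]:
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not found in {path}")

    records: list[MeasurementRecord] = []
    n_dropped = 0
    for pos, (_, row) in enumerate(df.iterrows()):
        values = row[list(variable_columns)]
        if values.isna().any():
            n_dropped += 1
            continue
        try:
            sex = parse_sex(row[sex_column])
        except ValueError as exc:
            raise ValueError(f"row {pos + 2}: {exc}") from None  # +2: header, 1-based
        if sex == UNKNOWN:
            raise ValueError(
                f"row {pos + 2}: reference samples require known sex (F/M)"
            )
        age = None
        if age_column is not None and age_column in df.columns:
            raw_age = row[age_column]
            age = float(raw_age) if pd.notna(raw_age) else None
        records.append(
            MeasurementRecord(
                id=str(row[id_column]),
                sex=sex,
                measurements={v: float(row[v]) for v in variable_columns},
                age_years=age,
            )
        )
    if n_dropped:
        logger.info(
            "dropped %d of %d rows with missing values in %s",
            n_dropped, len(df), list(variable_columns),
        )
    sample = ReferenceSample(records=records, variables=list(variable_columns))
    return sample


def read_cases_csv(
    path: str | Path,
    variable_columns: Sequence[str],
    id_column: str = "id",
) -> list[MeasurementRecord]:
    """Load unknown cases (no sex required) for classification."""
    df = _read_table(path)
    for col in [id_column, *variable_columns]:
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not found in {path}")
    cases = []
    for _, row in df.iterrows():
        if row[list(variable_columns)].isna().any():
            logger.info("case %s skipped: missing measurements", row[id_column])
            continue
        cases.append(
            MeasurementRecord(
                id=str(row[id_column]),
                sex=UNKNOWN,
                measurements={v: float(row[v]) for v in variable_columns},
            )
        )
    return cases


def write_reference_csv(sample: ReferenceSample, path: str | Path) -> None:
    rows = []
    for r in sample.records:
        row: dict[str, object] = {"id": r.id, "sex": r.sex}
        if r.age_years is not None:
            row["age_years"] = r.age_years
        row.update({v: r.measurements[v] for v in sample.variables})
        rows.append(row)
    # repr-based float formatting so a write/read cycle is value-exact
    pd.DataFrame(rows).to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = path.open().readline()
    # pick the delimiter (comma/semicolon/tab) splitting the header widest,
    # then parse with bit-exact float conversion
    sep = max((",", ";", "\t"), key=header.count)
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


_MODEL_SCHEMA_VERSION = 1


def write_model(model_file: ModelFile, path: str | Path) -> None:
    """Serialize a model to JSON at full double precision."""
    payload = {
        "schema_version": _MODEL_SCHEMA_VERSION,
        "model_kind": model_file.model_kind,
        "variables": list(model_file.variables),
        "coefficients": dict(model_file.coefficients),
        "intercept": model_file.intercept,
        "metadata": model_file.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model(path: str | Path) -> ModelFile:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {path}: {exc}") from None
    required = {"model_kind", "variables", "coefficients", "intercept"}
    missing = required - set(payload)
    if missing:
        raise SchemaError(f"model file {path} is missing fields {sorted(missing)}")
    return ModelFile(
        model_kind=payload["model_kind"],
        variables=list(payload["variables"]),
        coefficients={k: float(v) for k, v in payload["coefficients"].items()},
        intercept=float(payload["intercept"]),
        metadata=payload.get("metadata", {}),
    )
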