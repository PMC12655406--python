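"""Schema-validated CSV input/output.

All pipeline tables travel as UTF-8 comma-separated CSV with a "." decimal
point; a dialect flag supports the ";" separator / "," decimal convention
common in continental European exports.  Numbers are serialized at full
precision (repr round-trip), so write-then-read reproduces values exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import BREAD_CATEGORIES
from .synthetic import EVENT_COLUMNS, PERSON_COLUMNS, SAMPLE_COLUMNS


class SchemaError(ValueError):
    pass


_SCHEMAS: dict[str, dict] = {
    "persons": {
        "columns": PERSON_COLUMNS,
        "dtypes": {},
        "checks": [],
    },
    "events": {
        "columns": EVENT_COLUMNS,
        "dtypes": {"recall_day": int, "amount": float},
        "checks": [
            ("amount", lambda s: s > 0, "amount must be > 0"),
            ("recall_day", lambda s: s >= 1, "recall_day must be >= 1"),
            (
                "bread_category",
                lambda s: s.isin(BREAD_CATEGORIES),
                f"bread_category must be one of {BREAD_CATEGORIES}",
            ),
        ],
    },
    "samples": {
        "columns": SAMPLE_COLUMNS,
        "dtypes": {"fibre": float},
        "checks": [("fibre", lambda s: s >= 0, "fibre must be >= 0")],
    },
    "densities": {
        "columns": ["bread_category", "fibre_density"],
        "dtypes": {"fibre_density": float},
        "checks": [("fibre_density", lambda s: s > 0, "fibre_density must be > 0")],
    },
    "habitual": {
        "columns": [
            "person_id", "quantity", "category", "prob",
            "usual_amount_on_consumption_days", "habitual",
            "sigma2_between", "sigma2_within",
        ],
        "dtypes": {
            "prob": float, "usual_amount_on_consumption_days": float,
            "habitual": float, "sigma2_between": float, "sigma2_within": float,
        },
        "checks": [
            ("prob", lambda s: (s >= 0) & (s <= 1), "prob must be in [0, 1]"),
            ("habitual", lambda s: s >= 0, "habitual must be >= 0"),
        ],
    },
}


def _read(path: Path, dialect: str) -> pd.DataFrame:
    if dialect == "eu":
        return pd.read_csv(path, sep=";", decimal=",", float_precision="round_trip")
    return pd.read_csv(path, float_precision="round_trip")


def validate_csv(
    path: str | Path,
    schema_name: str,
    dialect: str = "standard",
) -> tuple[pd.DataFrame, list[str]]:
    """Read ``path``, check the header and row-level constraints.

    Returns (frame, errors); ``errors`` lists human-readable violations with
    1-based data line numbers (header is line 1).  An unknown schema or a
    wrong header raises :class:`SchemaError` immediately.
    """
    if schema_name not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}; known: {sorted(_SCHEMAS)}")
    schema = _SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = _read(path, dialect)
    if list(df.columns) != schema["columns"]:
        raise SchemaError(
            f"{path}: header mismatch for schema {schema_name!r}; "
            f"expected {schema['columns']}, got {list(df.columns)}"
        )
    errors: list[str] = []
    for col, dtype in schema["dtypes"].items():
        try:
            df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            errors.append(f"{path}: column {col!r} not coercible to {dtype.__name__}: {exc}")
    for col, check, message in schema["checks"]:
        if col not in df.columns or not len(df):
            continue
        ok = check(df[col])
        for row in df.index[~ok.fillna(False)]:
            errors.append(f"{path}: line {row + 2}: {message} (got {df.at[row, col]!r})")
    return df, errors


def read_csv_checked(path: str | Path, schema_name: str, dialect: str = "standard") -> pd.DataFrame:
    """Like :func:`validate_csv` but raises on the first violation."""
    df, errors = validate_csv(path, schema_name, dialect=dialect)
    if errors:
        raise SchemaError("; ".join(errors))
    return df


def write_csv(df: pd.DataFrame, path: str | Path, dialect: str = "standard") -> None:
    """Write with full-precision floats (repr round-trip)."""
    kwargs = {"sep": ";", "decimal": ","} if dialect == "eu" else {}
    df.to_csv(path, index=False, float_format=None, **kwargs)


def densities_to_frame(densities: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {"bread_category": list(densities), "fibre_density": list(densities.values())}
    )


def frame_to_densities(df: pd.DataFrame) -> dict[str, float]:
    return dict(zip(df["bread_category"], df["fibre_density"].astype(float)))


def round_half_away(x: float, decimals: int = 1) -> float:
    """Presentation rounding: half away from zero (as survey tables print)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)
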