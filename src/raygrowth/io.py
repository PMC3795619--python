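"""CSV input/output for size-at-age records, reader matrices and results.

Size-at-age CSV columns: species, age, disc_width, and optionally
total_length, sex, readability.  Reader-matrix CSV columns: animal_id,
reader_1..reader_R, and optionally readability.  Lines starting with ``#``
are treated as comments; result files written by this package carry a
``# seed=... config_hash=...`` provenance header.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import SizeAtAgeRecord
from .precision import ReaderMatrix

__all__ = [
    "read_size_at_age",
    "write_size_at_age",
    "read_reader_matrix",
    "write_reader_matrix",
    "records_to_frame",
    "write_table",
]

_OPTIONAL = ("total_length", "sex", "readability")


class CsvFormatError(ValueError):
    pass


def records_to_frame(records: Sequence[SizeAtAgeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [r.species for r in records],
            "age": [r.age for r in records],
            "disc_width": [r.disc_width for r in records],
            "total_length": [r.total_length for r in records],
            "sex": [r.sex for r in records],
            "readability": [r.readability for r in records],
        }
    )


def read_size_at_age(path) -> list[SizeAtAgeRecord]:
    """Read and validate a size-at-age CSV; row errors carry line numbers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"size-at-age file not found: {path}")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = {"species", "age", "disc_width"} - set(df.columns)
    if missing:
        raise CsvFormatError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            records.append(
                SizeAtAgeRecord(
                    species=str(row["species"]),
                    age=float(row["age"]),
                    disc_width=float(row["disc_width"]),
                    total_length=(
                        float(row["total_length"])
                        if "total_length" in df.columns and pd.notna(row["total_length"])
                        else None
                    ),
                    sex=(
                        str(row["sex"])
                        if "sex" in df.columns and pd.notna(row["sex"])
                        else None
                    ),
                    readability=(
                        int(row["readability"])
                        if "readability" in df.columns and pd.notna(row["readability"])
                        else None
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            raise CsvFormatError(f"{path}, line {line}: {exc}") from exc
    return records


def write_size_at_age(path, records: Sequence[SizeAtAgeRecord], header: Optional[str] = None) -> None:
    df = records_to_frame(records)
    _write_csv(path, df, header)


def read_reader_matrix(path) -> ReaderMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reader-matrix file not found: {path}")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "animal_id" not in df.columns:
        raise CsvFormatError(f"{path}: missing 'animal_id' column")
    reader_cols = [c for c in df.columns if c.startswith("reader_")]
    if len(reader_cols) < 2:
        raise CsvFormatError(f"{path}: need >= 2 reader_* columns")
    readability = (
        df["readability"].to_numpy(dtype=int) if "readability" in df.columns else None
    )
    return ReaderMatrix(
        animal_ids=df["animal_id"].tolist(),
        reads=df[reader_cols].to_numpy(dtype=float),
        readability=readability,
    )


def write_reader_matrix(path, matrix: ReaderMatrix, header: Optional[str] = None) -> None:
    data = {"animal_id": list(matrix.animal_ids)}
    for j in range(matrix.n_readers):
        data[f"reader_{j + 1}"] = matrix.reads[:, j]
    if matrix.readability is not None:
        data["readability"] = matrix.readability
    _write_csv(path, pd.DataFrame(data), header)


def write_table(path, df: pd.DataFrame, header: Optional[str] = None) -> None:
    """Write a results table with an optional ``#``-comment provenance line."""
    _write_csv(path, df, header)


def _write_csv(path, df: pd.DataFrame, header: Optional[str]) -> None:
    buf = _io.StringIO()
    if header:
        buf.write(f"# {header}\n")
    df.to_csv(buf, index=False, lineterminator="\n", float_format="%.17g")
    Path(path).write_text(buf.getvalue())
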