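"""File formats: FASTA sequences, TSV tables and matrices, JSON results.

FASTA reading is strict: unique ids (after first-whitespace truncation),
nonempty records, IUPAC characters only; violations report line numbers.
Sequences are stored uppercase regardless of input case.  Matrices round-trip
through TSV at full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .primers import IUPAC_SETS
from .simulate import SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_alignment_fasta",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_json_result",
]

_VALID_CHARS = frozenset(IUPAC_SETS) | frozenset("-.")
FASTA_WRAP = 70


def read_fasta(path: str | Path, allow_gaps: bool = False) -> list[SequenceRecord]:
    """Parse a FASTA file into identified uppercase sequences.

    Ids are headers truncated at the first whitespace.  Duplicate ids, empty
    records and non-IUPAC characters raise ``ValueError`` with line numbers.
    """
    valid = _VALID_CHARS if allow_gaps else frozenset(IUPAC_SETS)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    current_id: str | None = None
    current_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"empty record {current_id!r} at line {current_line}")
        records.append(SequenceRecord(current_id, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ValueError(f"empty FASTA header at line {lineno}")
                if header in seen:
                    raise ValueError(
                        f"duplicate FASTA id {header!r} at line {lineno} "
                        f"(first seen at line {seen[header]})"
                    )
                seen[header] = lineno
                current_id, current_line, chunks = header, lineno, []
            else:
                if current_id is None:
                    raise ValueError(f"sequence data before any header at line {lineno}")
                up = line.upper()
                bad = set(up) - valid
                if bad:
                    raise ValueError(
                        f"invalid character(s) {sorted(bad)} in record {current_id!r} "
                        f"at line {lineno}"
                    )
                chunks.append(up)
    flush()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 70 columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), FASTA_WRAP):
                fh.write(rec.sequence[i : i + FASTA_WRAP] + "\n")


def read_alignment_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read an aligned FASTA (gaps allowed); rows must be equal length."""
    records = read_fasta(path, allow_gaps=True)
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"alignment rows have unequal lengths {sorted(lengths)}")
    return records


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled matrix as TSV at full float precision."""
    # pandas' default float repr is shortest-round-trip, so values survive exactly
    df.to_csv(path, sep="\t", index=True, index_label="id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a labelled matrix written by :func:`write_matrix_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col="id", float_precision="round_trip")
    df.index.name = None
    return df


def write_json_result(obj, path: str | Path) -> None:
    """Serialise a result object (dataclass-like or dict) as indented JSON."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dataclass_fields__"):
            return {k: getattr(o, k) for k in o.__dataclass_fields__}
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
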