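"""Per-sequence %G+C and tetranucleotide frequency profiles.

Profiles are the classic alignment-free genomic signature: the 256-vector of
overlapping 4-mer frequencies counted on the coding strand with single
nucleotide steps.  No reverse-complement folding is applied — the strand
carries signal here, since all inputs are coding-strand gene sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KMERS",
    "GCRecord",
    "gc_content",
    "classify_gc",
    "tetra_profile",
    "profile_matrix",
]

#: All 256 tetranucleotides in lexicographic order (AAAA ... TTTT); the fixed
#: column order of every profile.
KMERS: tuple[str, ...] = tuple("".join(p) for p in product("ACGT", repeat=4))

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

GC_THRESHOLD_DEFAULT = 0.45  # midpoint of the ~0.40 / ~0.50 composition modes


@dataclass(frozen=True)
class GCRecord:
    sequence_id: str
    gc: float
    gc_class: str  # "high" | "low"


def gc_content(seq: str) -> float:
    """Fraction (G+C)/(A+C+G+T), ignoring ambiguous bases entirely.

    Raises ``ValueError`` if the sequence contains no unambiguous base.
    """
    s = seq.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    return (counts["G"] + counts["C"]) / denom


def classify_gc(gc: float, threshold: float = GC_THRESHOLD_DEFAULT) -> str:
    """Binary GC class: ``"high"`` iff gc >= threshold, else ``"low"``."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must lie in [0, 1], got {gc}")
    return "high" if gc >= threshold else "low"


def gc_records(
    seqs: Iterable[tuple[str, str]], threshold: float = GC_THRESHOLD_DEFAULT
) -> pd.DataFrame:
    """GC table for (id, sequence) pairs: columns id, gc, gc_class."""
    rows = []
    for sid, seq in seqs:
        gc = gc_content(seq)
        rows.append({"id": sid, "gc": gc, "gc_class": classify_gc(gc, threshold)})
    return pd.DataFrame(rows)


def _encode(seq: str) -> np.ndarray:
    """Map bases to 0..3; ambiguous characters become -1."""
    s = seq.upper()
    codes = np.full(len(s), -1, dtype=np.int64)
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def tetra_profile(
    seq: str, norm: Literal["windows", "length"] = "windows", k: int = 4
) -> np.ndarray:
    """Overlapping k-mer frequency vector (k=4: 256 features) of one sequence.

    Windows slide by single-nucleotide steps along the given (coding) strand;
    a window containing any ambiguous base is skipped.  With ``norm="windows"``
    counts are divided by the number of counted windows, making the profile a
    proper frequency distribution; ``norm="length"`` divides by sequence
    length instead.
    """
    if len(seq) < k:
        raise ValueError(f"sequence shorter than {k} nt")
    codes = _encode(seq)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    if not valid.any():
        raise ValueError("no unambiguous windows to count")
    idx = win[valid] @ (4 ** np.arange(k - 1, -1, -1))
    counts = np.bincount(idx, minlength=4**k).astype(float)
    denom = float(valid.sum()) if norm == "windows" else float(len(seq))
    return counts / denom


def profile_matrix(
    seqs: Sequence[tuple[str, str]], norm: Literal["windows", "length"] = "windows"
) -> pd.DataFrame:
    """Stack per-sequence profiles into an n x 256 DataFrame.

    Row order follows input order; columns are ``KMERS``.  Any sequence that
    cannot be profiled aborts with its id in the error message.
    """
    if len(seqs) < 2:
        raise ValueError("profile matrix requires at least 2 sequences")
    ids, rows = [], []
    for sid, seq in seqs:
        try:
            rows.append(tetra_profile(seq, norm=norm))
        except ValueError as exc:
            raise ValueError(f"cannot profile sequence {sid!r}: {exc}") from exc
        ids.append(sid)
    return pd.DataFrame(np.vstack(rows), index=ids, columns=list(KMERS))
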