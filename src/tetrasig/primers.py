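"""Degenerate-primer algebra and arrangement-specific in-silico PCR.

A degenerate primer is an IUPAC-coded oligonucleotide standing for the set of
all its concrete expansions; its degeneracy is the size of that set.  The
in-silico screen mirrors a PCR targeting a specific two-gene arrangement:
a product is called only when a forward-strand match of the forward primer
lies upstream of a reverse-strand match of the reverse primer, with the
spanned length inside the expected size window — templates carrying the sites
in the wrong mutual orientation or at the wrong spacing yield nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Literal

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "DegeneratePrimer",
    "AmpliconRecord",
    "degeneracy",
    "expand",
    "back_translate",
    "match_sites",
    "insilico_pcr",
    "trim_translate",
]

#: IUPAC code -> set of concrete bases it denotes (the 15 standard codes;
#: Biopython's legacy 'X' alias is excluded).
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"
}
_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

EXPAND_CAP_DEFAULT = 65_536


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-coded oligonucleotide with an orientation."""

    name: str
    residues: str
    orientation: Literal["forward", "reverse"] = "forward"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("primer residues must be nonempty")
        for i, c in enumerate(self.residues.upper()):
            if c not in IUPAC_SETS:
                raise ValueError(f"invalid IUPAC code {c!r} at position {i} in primer {self.name!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward|reverse, got {self.orientation!r}")

    def reverse_complement(self) -> str:
        return self.residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconRecord:
    """One predicted product on a template's given strand (0-based half-open)."""

    template_id: str
    start: int
    end: int
    fwd_primer: str
    rev_primer: str

    @property
    def product_length(self) -> int:
        return self.end - self.start


def degeneracy(primer: DegeneratePrimer | str) -> int:
    """Number of distinct concrete expansions: product of per-position base counts."""
    residues = primer.residues if isinstance(primer, DegeneratePrimer) else primer.upper()
    total = 1
    for i, c in enumerate(residues):
        if c not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {c!r} at position {i}")
        total *= len(IUPAC_SETS[c])
    return total


def expand(primer: DegeneratePrimer | str, cap: int = EXPAND_CAP_DEFAULT) -> set[str]:
    """Enumerate every concrete sequence the primer stands for.

    Refuses primers above ``cap`` expansions; use :func:`match_sites` for
    those instead of enumerating.
    """
    residues = primer.residues if isinstance(primer, DegeneratePrimer) else primer.upper()
    d = degeneracy(residues)
    if d > cap:
        raise ValueError(
            f"degeneracy {d} exceeds expansion cap {cap}; match against templates "
            "with match_sites() instead of enumerating"
        )
    choices = [sorted(IUPAC_SETS[c]) for c in residues]
    return {"".join(p) for p in product(*choices)}


def back_translate(protein_motif: str, name: str = "backtranslated",
                   orientation: Literal["forward", "reverse"] = "forward") -> DegeneratePrimer:
    """Minimal degenerate primer covering every codon of each residue.

    For each amino acid the three codon positions are collapsed to the
    smallest IUPAC code containing all observed bases, so every codon of the
    residue matches the primer (full coverage, no codon-usage weighting).
    """
    table = unambiguous_dna_by_id[1]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    out = []
    for i, aa in enumerate(protein_motif.upper()):
        codons = by_aa.get(aa)
        if codons is None:
            raise ValueError(f"unknown amino acid {aa!r} at position {i}")
        for pos in range(3):
            bases = frozenset(c[pos] for c in codons)
            out.append(_SET_TO_CODE[bases])
    return DegeneratePrimer(name=name, residues="".join(out), orientation=orientation)


def _mismatches(window: str, residues: str, limit: int) -> int:
    """Count IUPAC mismatches, bailing out early past `limit`."""
    mm = 0
    for b, c in zip(window, residues):
        if b not in IUPAC_SETS[c]:
            mm += 1
            if mm > limit:
                break
    return mm


def match_sites(
    template: str, primer: DegeneratePrimer | str, max_mismatches: int = 0
) -> list[tuple[int, str]]:
    """All template positions matched by the primer on either strand.

    A primer code matches a base iff the base belongs to the code's set.  A
    ``(pos, "forward")`` hit means the primer matches ``template[pos:pos+m]``;
    ``(pos, "reverse")`` means its reverse complement does.  Results are
    sorted by position, forward before reverse at ties.
    """
    residues = primer.residues if isinstance(primer, DegeneratePrimer) else primer.upper()
    t = template.upper()
    m = len(residues)
    rc = residues.translate(_COMPLEMENT)[::-1]
    hits: list[tuple[int, str]] = []
    for pos in range(len(t) - m + 1):
        window = t[pos : pos + m]
        if _mismatches(window, residues, max_mismatches) <= max_mismatches:
            hits.append((pos, "forward"))
        if _mismatches(window, rc, max_mismatches) <= max_mismatches:
            hits.append((pos, "reverse"))
    return hits


def insilico_pcr(
    template: str,
    fwd: DegeneratePrimer | str,
    rev: DegeneratePrimer | str,
    size_window: tuple[int, int],
    max_mismatches: int = 0,
    template_id: str = "template",
) -> list[AmpliconRecord]:
    """Predict products of an arrangement-specific PCR on one template.

    A product requires a forward-strand site of ``fwd`` upstream of a
    reverse-strand site of ``rev``, with the primer-inclusive span inside
    ``size_window``.  Sites in the wrong mutual orientation, or spans outside
    the window, produce nothing.  Records are sorted by start coordinate.
    """
    lo, hi = size_window
    if lo > hi:
        raise ValueError(f"invalid size window {size_window}: min > max")
    fwd_name = fwd.name if isinstance(fwd, DegeneratePrimer) else "fwd"
    rev_name = rev.name if isinstance(rev, DegeneratePrimer) else "rev"
    rev_len = len(rev.residues if isinstance(rev, DegeneratePrimer) else rev)
    fwd_hits = [p for p, s in match_sites(template, fwd, max_mismatches) if s == "forward"]
    rev_hits = [p for p, s in match_sites(template, rev, max_mismatches) if s == "reverse"]
    records = []
    for f in fwd_hits:
        for r in rev_hits:
            end = r + rev_len
            length = end - f
            if f < r and lo <= length <= hi:
                records.append(
                    AmpliconRecord(
                        template_id=template_id, start=f, end=end,
                        fwd_primer=fwd_name, rev_primer=rev_name,
                    )
                )
    records.sort(key=lambda a: (a.start, a.end))
    return records


def trim_translate(amplicon: str, gene_anchor: int = 0, frame: int = 0) -> str:
    """Translate the target-gene portion of an amplicon.

    The amplicon is trimmed at ``gene_anchor`` (0-based offset of the gene
    portion), shifted into ``frame`` (0|1|2), and translated with the standard
    genetic code; a trailing partial codon is dropped and internal stops
    render as ``*``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    region = amplicon.upper()[gene_anchor + frame :]
    usable = len(region) - len(region) % 3
    if usable < 3:
        raise ValueError("trimmed region shorter than one codon")
    return str(Seq(region[:usable]).translate())
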