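"""Synthetic gene-like sequence generator with planted compositional structure.

Sequences are drawn from per-group 3rd-order Markov chains, so groups are
distinguishable exactly at the tetranucleotide level — the order on which the
downstream genomic-signature statistic operates.  The per-step base weights
constrain G+C by construction: within every 3-mer context the probability mass
on {G, C} equals the group's target GC fraction, so the chain's GC content is
on target at every bias strength, while the bias perturbation redistributes
mass *within* the {A, T} and {G, C} pairs and across contexts.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

BASES = "ACGT"
_AT = np.array([0, 3])  # indices of A, T in BASES
_GC = np.array([1, 2])  # indices of C, G

__all__ = [
    "GroupSpec",
    "Scenario",
    "SequenceRecord",
    "simulate_gene",
    "simulate_dataset",
    "simulate_alignment",
    "six_group_scenario",
    "transition_matrix",
]


@dataclass(frozen=True)
class SequenceRecord:
    """An identified coding-strand DNA sequence."""

    id: str
    sequence: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class GroupSpec:
    """Parameters of one planted compositional subgroup.

    Parameters
    ----------
    group_id:
        Unique label for the group.
    n_sequences:
        Number of sequences to generate (>= 1).
    length_range:
        Inclusive ``(min_nt, max_nt)`` bounds on sequence length; lengths are
        drawn uniformly from this range.  ``min_nt`` must be >= 100.
    target_gc:
        Stationary G+C fraction of the generating chain, strictly in (0, 1).
    bias_strength:
        Nonnegative scalar scaling how far the group's 3rd-order transition
        weights deviate from the GC-only baseline.  0 gives a context-free
        i.i.d. base model.
    seed:
        Integer seed for the group's private random stream.
    """

    group_id: str
    n_sequences: int
    length_range: tuple[int, int]
    target_gc: float
    bias_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError(f"n_sequences must be >= 1, got {self.n_sequences}")
        lo, hi = self.length_range
        if lo < 100:
            raise ValueError(f"minimum length must be >= 100 nt, got {lo}")
        if lo > hi:
            raise ValueError(f"length_range must satisfy min <= max, got {self.length_range}")
        if not 0.0 < self.target_gc < 1.0:
            raise ValueError(f"target_gc must lie strictly in (0, 1), got {self.target_gc}")
        if self.bias_strength < 0:
            raise ValueError(f"bias_strength must be nonnegative, got {self.bias_strength}")


@dataclass(frozen=True)
class Scenario:
    """A full simulation scenario: groups plus optional decoration/stations.

    ``station_counts`` maps a station label to per-group sequence counts; the
    per-group counts must total each group's ``n_sequences`` exactly, so the
    assignment is deterministic.  ``template_decoration`` optionally embeds a
    forward primer site and the reverse complement of a reverse primer site at
    a fixed spacing inside every sequence, producing amplifiable templates.
    """

    groups: tuple[GroupSpec, ...]
    master_seed: int = 0
    station_counts: Mapping[str, Mapping[str, int]] | None = None
    fwd_site: str | None = None
    rev_site: str | None = None
    site_spacing: int | None = None
    orf_mode: bool = False

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("scenario must contain at least one group")
        ids = [g.group_id for g in self.groups]
        if len(set(ids)) != len(ids):
            raise ValueError(f"group_ids must be unique, got {ids}")
        decorated = (self.fwd_site, self.rev_site, self.site_spacing)
        if any(x is not None for x in decorated) and any(x is None for x in decorated):
            raise ValueError("fwd_site, rev_site and site_spacing must be set together")
        if self.station_counts is not None:
            totals: dict[str, int] = {g: 0 for g in ids}
            for station, per_group in self.station_counts.items():
                for gid, n in per_group.items():
                    if gid not in totals:
                        raise ValueError(f"station {station!r} references unknown group {gid!r}")
                    totals[gid] += n
            for g in self.groups:
                if totals[g.group_id] != g.n_sequences:
                    raise ValueError(
                        f"station counts for group {g.group_id!r} total {totals[g.group_id]}, "
                        f"expected {g.n_sequences}"
                    )

    @property
    def template_decoration(self) -> bool:
        return self.fwd_site is not None


def _group_rng(master_seed: int, group_id: str) -> np.random.Generator:
    """Derive a reproducible per-group stream from (master seed, group id)."""
    digest = hashlib.sha256(f"{master_seed}:{group_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def transition_matrix(spec: GroupSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """64 x 4 transition probabilities P(next base | 3-mer context).

    Baseline (bias 0): P(A)=P(T)=(1-gc)/2 and P(C)=P(G)=gc/2 in every context.
    The bias multiplies each weight by exp(bias * eps) with eps ~ N(0,1) drawn
    once from the group seed, then renormalises the {A,T} pair to (1-gc) and
    the {C,G} pair to gc — per-step GC stays exactly on target.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    gc = spec.target_gc
    base = np.empty((64, 4))
    base[:, _AT] = (1.0 - gc) / 2.0
    base[:, _GC] = gc / 2.0
    if spec.bias_strength > 0:
        eps = rng.standard_normal((64, 4))
        w = base * np.exp(spec.bias_strength * eps)
        at = w[:, _AT]
        gcw = w[:, _GC]
        w[:, _AT] = at / at.sum(axis=1, keepdims=True) * (1.0 - gc)
        w[:, _GC] = gcw / gcw.sum(axis=1, keepdims=True) * gc
        base = w
    return base


def _draw_chain(trans: np.ndarray, length: int, rng: np.random.Generator) -> str:
    """Sample one sequence of `length` nt from a 3rd-order chain.

    The first 3-mer is uniform over the 64 contexts.
    """
    cum = np.cumsum(trans, axis=1)
    cum[:, -1] = 1.0  # guard rounding
    ctx = int(rng.integers(64))
    out = [BASES[(ctx >> 4) & 3], BASES[(ctx >> 2) & 3], BASES[ctx & 3]]
    if length <= 3:
        return "".join(out[:length])
    u = rng.random(length - 3)
    for i in range(length - 3):
        b = int(np.searchsorted(cum[ctx], u[i], side="right"))
        out.append(BASES[b])
        ctx = ((ctx << 2) & 0x3F) | b
    return "".join(out)


def _strip_inframe_stops(seq: str, rng: np.random.Generator) -> str:
    """Prepend ATG and replace in-frame stop codons, preserving length."""
    s = list("ATG" + seq[3:])
    stops = {"TAA", "TAG", "TGA"}
    for i in range(0, len(s) - 2, 3):
        while "".join(s[i : i + 3]) in stops:
            s[i + 2] = BASES[int(rng.integers(4))]
    return "".join(s)


def simulate_gene(
    spec: GroupSpec,
    length: int,
    rng: np.random.Generator | None = None,
    trans: np.ndarray | None = None,
) -> str:
    """Generate one sequence of the requested length from the group's chain.

    ``length`` must fall inside ``spec.length_range``.  When ``rng`` is omitted
    a fresh stream seeded from ``spec.seed`` is used (after consuming the bias
    draw), so repeated calls with the same spec reproduce the same sequence.
    """
    lo, hi = spec.length_range
    if not lo <= length <= hi:
        raise ValueError(f"length {length} outside length_range {spec.length_range}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
        trans = transition_matrix(spec, rng)
    elif trans is None:
        trans = transition_matrix(spec, np.random.default_rng(spec.seed))
    return _draw_chain(trans, length, rng)


def _decorate(
    core: str, fwd_site: str, rev_site: str, spacing: int, rng: np.random.Generator
) -> str:
    """Embed fwd site and reverse-complemented rev site `spacing` nt apart.

    The decorated template reads: [core prefix] fwd_site [insert] revcomp(rev_site)
    [core suffix], where the insert length makes the fwd-start -> rev-end span
    equal `spacing`.
    """
    comp = str.maketrans("ACGT", "TGCA")
    rc_rev = rev_site.translate(comp)[::-1]
    insert_len = spacing - len(fwd_site) - len(rev_site)
    if insert_len < 0:
        raise ValueError("site_spacing shorter than the two primer sites")
    if len(core) < insert_len:
        raise ValueError("core sequence shorter than required insert")
    insert = core[:insert_len]
    rest = core[insert_len:]
    half = len(rest) // 2
    return rest[:half] + fwd_site + insert + rc_rev + rest[half:]


def simulate_dataset(scenario: Scenario):
    """Simulate every group of a scenario.

    Returns
    -------
    records : list[SequenceRecord]
        All sequences, in group order then within-group index order.
    manifest : pandas.DataFrame
        Columns ``id``, ``group``, ``station`` (station empty string when the
        scenario has no station plan).  Carries the planted truth; FASTA
        headers hold only the id.
    """
    import pandas as pd

    records: list[SequenceRecord] = []
    rows = []
    for g in scenario.groups:
        spec = dataclasses.replace(g, seed=g.seed)
        rng = _group_rng(scenario.master_seed, g.group_id)
        trans = transition_matrix(spec, np.random.default_rng(spec.seed))
        lo, hi = spec.length_range
        for i in range(spec.n_sequences):
            length = int(rng.integers(lo, hi + 1))
            seq = _draw_chain(trans, length, rng)
            if scenario.orf_mode:
                seq = _strip_inframe_stops(seq, rng)
            if scenario.template_decoration:
                seq = _decorate(
                    seq, scenario.fwd_site, scenario.rev_site, scenario.site_spacing, rng
                )
            rid = f"{g.group_id}_{i:03d}"
            records.append(SequenceRecord(rid, seq))
            rows.append({"id": rid, "group": g.group_id, "station": ""})
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in scenario output")
    manifest = pd.DataFrame(rows)
    if scenario.station_counts is not None:
        per_group_ids: dict[str, list[str]] = {}
        for row in rows:
            per_group_ids.setdefault(row["group"], []).append(row["id"])
        assignment: dict[str, str] = {}
        cursor = {gid: 0 for gid in per_group_ids}
        for station, per_group in scenario.station_counts.items():
            for gid, n in per_group.items():
                start = cursor[gid]
                for rid in per_group_ids[gid][start : start + n]:
                    assignment[rid] = station
                cursor[gid] = start + n
        manifest["station"] = manifest["id"].map(assignment)
    return records, manifest


def simulate_alignment(
    n_sequences: int,
    length: int,
    substitution_prob: float,
    seed: int = 0,
    alphabet: str = BASES,
) -> list[str]:
    """Gap-free alignment: a random ancestor plus i.i.d. per-site substitutions.

    Each row differs from the ancestor at each site independently with
    probability ``substitution_prob`` (substituting to a uniform random other
    symbol), so expected column diversity rises monotonically with the rate.
    """
    if not 0.0 <= substitution_prob <= 1.0:
        raise ValueError("substitution_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = len(alphabet)
    ancestor = rng.integers(k, size=length)
    rows = []
    for _ in range(n_sequences):
        mask = rng.random(length) < substitution_prob
        shift = rng.integers(1, k, size=length)
        row = np.where(mask, (ancestor + shift) % k, ancestor)
        rows.append("".join(alphabet[int(b)] for b in row))
    return rows


def six_group_scenario(
    master_seed: int = 0,
    bias_strength: float = 2.0,
    length_range: tuple[int, int] = (450, 530),
) -> Scenario:
    """The default survey-emulation scenario: six planted subgroups, n = 139.

    One high-GC group (target 0.50, 17 sequences) and five low-GC groups
    (target 0.40; sizes 25, 25, 24, 24, 24) with pairwise-distinct transition
    biases, spread across four island stations so that the high-GC fraction
    differs sharply between stations (25.0%, 18.0%, 2.0%, 0.0%).
    """
    sizes = {"hi1": 17, "lo1": 25, "lo2": 25, "lo3": 24, "lo4": 24, "lo5": 24}
    groups = tuple(
        GroupSpec(
            group_id=gid,
            n_sequences=n,
            length_range=length_range,
            target_gc=0.50 if gid.startswith("hi") else 0.40,
            bias_strength=bias_strength,
            seed=master_seed * 1000 + idx,
        )
        for idx, (gid, n) in enumerate(sizes.items())
    )
    station_counts = {
        "Malden": {"hi1": 5, "lo1": 8, "lo2": 7, "lo3": 0, "lo4": 0, "lo5": 0},
        "Millennium": {"hi1": 11, "lo1": 17, "lo2": 18, "lo3": 15, "lo4": 0, "lo5": 0},
        "Starbuck": {"hi1": 1, "lo1": 0, "lo2": 0, "lo3": 9, "lo4": 24, "lo5": 17},
        "Flint": {"hi1": 0, "lo1": 0, "lo2": 0, "lo3": 0, "lo4": 0, "lo5": 7},
    }
    return Scenario(groups=groups, master_seed=master_seed, station_counts=station_counts)
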