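"""Alignment filtering, ancestral-block assignment and synteny calling.

The Brassicaceae share 24 conserved ancestral karyotype blocks (labelled A
through X).  Short genotyping-by-sequencing tag sequences (69 bp) aligned to
a reference genome place mapped loci inside those blocks; runs of >= 3
consecutive loci carrying the same block label along a linkage group are
synteny blocks, while isolated one- or two-locus runs at near-perfect
identity are small insertions.  Markers aligned genome-wide under strict
thresholds are further classified by genome specificity (unique to the A, B
or C genome, multi-hit, or unaligned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

BLOCK_LABELS = tuple("ABCDEFGHIJKLMNOPQRSTUVWX")


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise hit of a query (marker tag or gene model) on a reference.

    Coordinates are 1-based inclusive with ``subject_start <= subject_end``;
    the original orientation is kept in ``strand``.
    """

    query_id: str
    subject_genome: str
    subject_chrom: str
    subject_start: int
    subject_end: int
    strand: str
    percent_identity: float
    align_length: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.subject_start > self.subject_end:
            raise ValueError(f"{self.query_id}: start > end after normalization")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.query_id}: bad strand {self.strand!r}")
        if self.e_value < 0:
            raise ValueError(f"{self.query_id}: negative e-value")

    @property
    def midpoint(self) -> float:
        return (self.subject_start + self.subject_end) / 2.0


@dataclass(frozen=True)
class AlignmentFilterProfile:
    """E-value and match-length thresholds.

    Two presets mirror the two analysis stages: ``ancestral`` (E <= 1e-6,
    length strictly over 40 bp) for placing 69-bp tags in ancestral blocks,
    and ``genome`` (E <= 1e-20, length >= 60 bp) for whole-genome
    comparisons where only near-full-length tag matches are trusted.
    """

    max_e: float
    min_len: int
    len_strict: bool

    @classmethod
    def ancestral(cls) -> "AlignmentFilterProfile":
        return cls(max_e=1e-6, min_len=40, len_strict=True)

    @classmethod
    def genome(cls) -> "AlignmentFilterProfile":
        return cls(max_e=1e-20, min_len=60, len_strict=False)

    def passes(self, rec: AlignmentRecord) -> bool:
        if rec.e_value > self.max_e:
            return False
        if self.len_strict:
            return rec.align_length > self.min_len
        return rec.align_length >= self.min_len


def filter_alignments(
    records: Sequence[AlignmentRecord], profile: AlignmentFilterProfile
) -> list[AlignmentRecord]:
    """Keep records passing the profile; stable order, input untouched."""
    return [r for r in records if profile.passes(r)]


@dataclass(frozen=True)
class AncestralBlockDef:
    """A labelled interval (1-based inclusive) of a reference chromosome."""

    block_label: str
    reference_chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.block_label not in BLOCK_LABELS:
            raise ValueError(f"unknown block label {self.block_label!r}")
        if self.start > self.end:
            raise ValueError(f"block {self.block_label}: empty interval")

    def contains(self, chrom: str, pos: float) -> bool:
        return chrom == self.reference_chrom and self.start <= pos <= self.end


def validate_block_defs(defs: Sequence[AncestralBlockDef]) -> None:
    """Intervals of one block set must not overlap on the same chromosome."""
    by_chrom: dict[str, list[AncestralBlockDef]] = {}
    for d in defs:
        by_chrom.setdefault(d.reference_chrom, []).append(d)
    for chrom, ds in by_chrom.items():
        ds = sorted(ds, key=lambda d: d.start)
        for a, b in zip(ds, ds[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping block intervals on {chrom}: {a.block_label}/{b.block_label}"
                )


def blocks_for_hit(
    rec: AlignmentRecord, defs: Sequence[AncestralBlockDef]
) -> list[str]:
    """Block labels whose interval contains the hit midpoint (0 or 1 with
    non-overlapping defs)."""
    return [d.block_label for d in defs if d.contains(rec.subject_chrom, rec.midpoint)]


@dataclass
class BlockAssignment:
    locus_id: str
    block_label: str | None
    support: list[AlignmentRecord] = field(default_factory=list)
    adjacency_consistent: bool = False
    bin_consistent: bool = False
    tie_unresolved: bool = False

    def __post_init__(self) -> None:
        if self.block_label is not None and not self.support:
            raise ValueError(f"{self.locus_id}: assigned without support")


@dataclass(frozen=True)
class _Candidate:
    """Per-locus evidence for one block label."""

    best_len: int
    best_e: float
    best_ident: float
    n_markers: int
    support: tuple[AlignmentRecord, ...]


def _candidates(
    marker_hits: Mapping[str, Sequence[AlignmentRecord]],
    defs: Sequence[AncestralBlockDef],
) -> dict[str, _Candidate]:
    per_block: dict[str, list[tuple[str, AlignmentRecord]]] = {}
    for marker_id, hits in marker_hits.items():
        for rec in hits:
            for label in blocks_for_hit(rec, defs):
                per_block.setdefault(label, []).append((marker_id, rec))
    out = {}
    for label, pairs in per_block.items():
        recs = tuple(r for _, r in pairs)
        out[label] = _Candidate(
            best_len=max(r.align_length for r in recs),
            best_e=min(r.e_value for r in recs),
            best_ident=max(r.percent_identity for r in recs),
            n_markers=len({m for m, _ in pairs}),
            support=recs,
        )
    return out


def _unique_max(cands: dict[str, _Candidate], key) -> str | None:
    best = max(key(c) for c in cands.values())
    winners = sorted(l for l, c in cands.items() if key(c) == best)
    return winners[0] if len(winners) == 1 else None


def _resolve(
    cands: dict[str, _Candidate],
    left: str | None,
    right: str | None,
) -> tuple[str | None, bool, bool, bool]:
    """Ordered criteria; the first that discriminates wins.

    Returns (label, adjacency_used, bin_used, tie_unresolved).
    """
    if not cands:
        return None, False, False, False
    if len(cands) == 1:
        return next(iter(cands)), False, False, False
    # (1) agreement with both flanking assigned loci
    if left is not None and left == right and left in cands:
        return left, True, False, False
    # (2) agreement among co-binned markers: the block supported by the most
    # distinct member markers, if unique
    label = _unique_max(cands, lambda c: c.n_markers)
    if label is not None and cands[label].n_markers > 1:
        return label, False, True, False
    # (3) longest match, (4) smallest E, (5) highest identity
    for key in (
        lambda c: c.best_len,
        lambda c: -c.best_e,
        lambda c: c.best_ident,
    ):
        label = _unique_max(cands, key)
        if label is not None:
            return label, False, False, False
    return None, False, False, True


def assign_blocks(
    ordered_loci: Sequence[tuple[str, Mapping[str, Sequence[AlignmentRecord]]]],
    block_defs: Sequence[AncestralBlockDef],
) -> list[BlockAssignment]:
    """Assign each mapped locus to at most one ancestral block.

    ``ordered_loci`` lists, in map order along one linkage group, each locus
    id with its member markers' filtered hits.  Candidate blocks come from
    hit midpoints intersected with the block intervals.  Candidates are
    scored by ordered criteria: agreement with both flanking assigned loci,
    agreement among co-binned markers, longest match, smallest E-value,
    highest identity; the first criterion that discriminates wins.  Two
    passes are made: the first assigns without adjacency, the second
    re-checks adjacency against the provisional assignments.  Unresolved
    ties stay unassigned with ``tie_unresolved`` set.
    """
    validate_block_defs(block_defs)
    cands = [_candidates(hits, block_defs) for _, hits in ordered_loci]

    def nearest(assigned: list[str | None], i: int, step: int) -> str | None:
        j = i + step
        while 0 <= j < len(assigned):
            if assigned[j] is not None:
                return assigned[j]
            j += step
        return None

    # pass 1: no adjacency information yet
    provisional: list[str | None] = []
    for c in cands:
        label, _, _, _ = _resolve(c, None, None)
        provisional.append(label)

    out: list[BlockAssignment] = []
    for i, (locus_id, _) in enumerate(ordered_loci):
        left = nearest(provisional, i, -1)
        right = nearest(provisional, i, +1)
        label, adj, binc, tie = _resolve(cands[i], left, right)
        support = list(cands[i][label].support) if label else []
        out.append(
            BlockAssignment(
                locus_id=locus_id,
                block_label=label,
                support=support,
                adjacency_consistent=adj,
                bin_consistent=binc,
                tie_unresolved=tie,
            )
        )
    return out


class SyntenyKind(str, Enum):
    SYNTENY_BLOCK = "synteny_block"
    INSERTION = "insertion"


@dataclass(frozen=True)
class SyntenyCall:
    lg: str
    block_label: str
    first_index: int
    last_index: int
    span_cm: float
    locus_count: int
    kind: SyntenyKind

    def __post_init__(self) -> None:
        if self.kind is SyntenyKind.SYNTENY_BLOCK and self.locus_count < 3:
            raise ValueError("synteny block needs >= 3 loci")
        if self.kind is SyntenyKind.INSERTION and self.locus_count not in (1, 2):
            raise ValueError("insertion is 1-2 loci")


def call_synteny_blocks(
    assignments: Sequence[BlockAssignment],
    positions_cm: Sequence[float],
    lg: str = "",
    identity_floor: float = 99.0,
    break_on_unassigned: bool = False,
) -> list[SyntenyCall]:
    """Call synteny blocks and small insertions along one linkage group.

    Maximal runs of >= 3 consecutive same-block loci become synteny blocks.
    Runs of 1-2 loci become insertions only when every supporting alignment
    reaches ``identity_floor`` percent identity ("nearly 100 %"); other
    short runs yield no call.  Unassigned loci are transparent by default
    (assigned loci are sparse on real maps); ``break_on_unassigned`` makes
    them terminate runs.
    """
    if len(assignments) != len(positions_cm):
        raise ValueError("assignments and positions differ in length")
    indexed = [
        (i, a) for i, a in enumerate(assignments) if a.block_label is not None
    ]
    calls: list[SyntenyCall] = []
    run: list[tuple[int, BlockAssignment]] = []

    def flush() -> None:
        if not run:
            return
        label = run[0][1].block_label
        first, last = run[0][0], run[-1][0]
        span = positions_cm[last] - positions_cm[first]
        n = len(run)
        if n >= 3:
            calls.append(
                SyntenyCall(lg, label, first, last, span, n, SyntenyKind.SYNTENY_BLOCK)
            )
        elif all(
            rec.percent_identity >= identity_floor
            for _, a in run
            for rec in a.support
        ):
            calls.append(
                SyntenyCall(lg, label, first, last, span, n, SyntenyKind.INSERTION)
            )
        run.clear()

    prev_index: int | None = None
    for i, a in indexed:
        if run and (
            a.block_label != run[-1][1].block_label
            or (break_on_unassigned and prev_index is not None and i - prev_index > 1)
        ):
            flush()
        run.append((i, a))
        prev_index = i
    flush()
    return calls


class Specificity(str, Enum):
    UNIQUE_A = "unique_A"
    UNIQUE_B = "unique_B"
    UNIQUE_C = "unique_C"
    MULTI = "multi"
    UNALIGNED = "unaligned"


def genome_specificity(
    hits: Sequence[AlignmentRecord],
    genome_of: Mapping[str, str],
) -> Specificity:
    """Classify one marker by where its (pre-filtered) hits land.

    ``genome_of`` maps subject-genome labels (e.g. ``Ar``, ``An``) to the
    basic genome letter A/B/C.  Unique means a single hit location on a
    single basic genome; two or more locations or genomes is ``multi``.
    """
    locations = {
        (genome_of[h.subject_genome], h.subject_chrom, h.subject_start) for h in hits
    }
    genomes = {g for g, _, _ in locations}
    if not locations:
        return Specificity.UNALIGNED
    if len(locations) == 1:
        return Specificity[f"UNIQUE_{next(iter(genomes))}"]
    return Specificity.MULTI


def specificity_counts(
    hits_by_marker: Mapping[str, Sequence[AlignmentRecord]],
    genome_of: Mapping[str, str],
) -> dict[Specificity, int]:
    counts = {s: 0 for s in Specificity}
    for hits in hits_by_marker.values():
        counts[genome_specificity(hits, genome_of)] += 1
    return counts
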