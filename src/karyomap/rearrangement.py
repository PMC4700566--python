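"""Inversion and translocation calling between two coordinate systems.

Anchors are loci (or genes) with a position in system A — a genetic map in
cM or a genome assembly in bp — and a matching position in system B (always
bp).  Inversions appear as maximal runs of anchors whose system-B order is
reversed relative to system A; a genetic-map run is only trusted when its
span exceeds the resolving power of the mapping population (100/n cM), and
spans up to twice that bound (or 1 Mb for assembly-assembly comparisons)
count as "small".  Translocations appear as runs of anchors that jump to a
different system-B chromosome: between two assemblies, a run of at least
five successive genes; against a genetic map, markers of one locus or of
two adjacent loci hitting different chromosomes at 100 % unique identity,
confirmed by re-detecting the candidate under random perturbations of the
neighbouring locus order.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_map import ResolutionModel

log = logging.getLogger(__name__)

SMALL_MAX_BP = 1_000_000  # physical small/large boundary


class Unit(str, Enum):
    GENETIC = "genetic"
    PHYSICAL = "physical"


class SizeClass(str, Enum):
    SMALL = "small"
    LARGE = "large"


class Direction(str, Enum):
    A_TO_B = "a_to_b"
    B_TO_A = "b_to_a"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class Anchor:
    """A shared coordinate between two systems."""

    id: str
    chrom_a: str
    coord_a: float
    chrom_b: str
    coord_b: float
    identity: float = 100.0
    unique_b: bool = True

    def __post_init__(self) -> None:
        if self.coord_a < 0 or self.coord_b < 0:
            raise ValueError(f"anchor {self.id}: negative coordinate")


@dataclass(frozen=True)
class InversionEvent:
    comparison: str
    chrom: str
    anchor_ids: tuple[str, ...]
    span_a: float
    size_class: SizeClass

    def __post_init__(self) -> None:
        if len(self.anchor_ids) < 2:
            raise ValueError("an inversion needs >= 2 anchors")


@dataclass(frozen=True)
class TranslocationEvent:
    comparison: str
    source_chrom: str
    target_chrom: str
    direction: Direction
    supporting_anchors: tuple[str, ...]
    confirmed: bool = False
    locus_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.source_chrom == self.target_chrom:
            raise ValueError("source and target chromosome coincide")


def _dense_ranks(values: Sequence[float]) -> list[int]:
    order = sorted(set(values))
    rank = {v: i for i, v in enumerate(order)}
    return [rank[v] for v in values]


def detect_inversions(
    anchors: Sequence[Anchor],
    resolution: ResolutionModel,
    unit: Unit,
    comparison: str = "",
) -> list[InversionEvent]:
    """Report maximal strictly-decreasing runs of system-B rank along system A.

    Anchors must lie on one chromosome pair and be sorted by ``coord_a``.
    Co-located anchors (members of one map bin) share both their A position
    and their B rank; a run must change rank to count, so a tied pair alone
    is never an event.  A genetic-unit run is an event only when its
    ``coord_a`` span exceeds the population's resolving power (100/n cM,
    unrounded); spans at or below twice that bound are "small".  Physical-
    unit runs have no lower span bound (assemblies resolve to the base
    pair); spans at or below 1 Mb are "small".  A single decreasing run
    covering every anchor is a whole-chromosome orientation flip, which is
    logged and not called.
    """
    if len(anchors) < 2:
        return []
    if len({a.chrom_a for a in anchors}) != 1 or len({a.chrom_b for a in anchors}) != 1:
        raise ValueError("detect_inversions expects a single chromosome pair")
    coords_a = [a.coord_a for a in anchors]
    if any(b < a for a, b in zip(coords_a, coords_a[1:])):
        raise ValueError("anchors must be sorted by coord_a")

    ranks = _dense_ranks([a.coord_b for a in anchors])

    # maximal strictly-decreasing runs over the rank sequence
    runs: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(ranks) + 1):
        if i == len(ranks) or ranks[i] >= ranks[i - 1]:
            if i - start >= 2:
                runs.append((start, i - 1))
            start = i

    if unit is Unit.GENETIC:
        min_span = resolution.min_cm_exact
        small_max = resolution.small_max_cm
    else:
        min_span = 0.0
        small_max = SMALL_MAX_BP

    events: list[InversionEvent] = []
    for s, e in runs:
        if s == 0 and e == len(ranks) - 1:
            log.info(
                "%s %s: whole-chromosome decreasing order treated as orientation "
                "flip, not an inversion",
                comparison,
                anchors[0].chrom_a,
            )
            continue
        span = anchors[e].coord_a - anchors[s].coord_a
        if span <= min_span:
            continue
        events.append(
            InversionEvent(
                comparison=comparison,
                chrom=anchors[0].chrom_a,
                anchor_ids=tuple(a.id for a in anchors[s : e + 1]),
                span_a=span,
                size_class=SizeClass.SMALL if span <= small_max else SizeClass.LARGE,
            )
        )
    return events


def detect_translocations_genome_pair(
    anchors: Sequence[Anchor],
    min_run: int = 5,
    comparison: str = "",
) -> list[TranslocationEvent]:
    """Runs of successive gene anchors jumping to a non-home chromosome.

    For each source chromosome the "home" target is the modal ``chrom_b``;
    every maximal run of at least ``min_run`` successive anchors sharing a
    different target chromosome is one translocation (direction a_to_b).
    The default ``min_run`` of 5 reads "more than four successive genes"
    strictly.
    """
    events: list[TranslocationEvent] = []
    by_chrom: dict[str, list[Anchor]] = {}
    for a in anchors:
        by_chrom.setdefault(a.chrom_a, []).append(a)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda a: a.coord_a)
        home = Counter(a.chrom_b for a in group).most_common(1)[0][0]
        i = 0
        while i < len(group):
            j = i
            while j < len(group) and group[j].chrom_b == group[i].chrom_b:
                j += 1
            target = group[i].chrom_b
            if target != home and j - i >= min_run:
                events.append(
                    TranslocationEvent(
                        comparison=comparison,
                        source_chrom=chrom,
                        target_chrom=target,
                        direction=Direction.A_TO_B,
                        supporting_anchors=tuple(a.id for a in group[i:j]),
                        confirmed=True,
                    )
                )
            i = j
    return events


@dataclass(frozen=True)
class MapLocus:
    """One map locus with its markers' target-genome hits.

    ``hits`` maps marker id to (target chromosome, percent identity,
    unique-hit flag).  Only 100 %-identity unique hits support a
    translocation candidate.
    """

    locus_id: str
    hits: tuple[tuple[str, str, float, bool], ...]  # (marker, chrom_b, identity, unique)

    def qualifying(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for marker, chrom_b, ident, unique in self.hits:
            if unique and abs(ident - 100.0) <= 1e-9:
                out.setdefault(chrom_b, set()).add(marker)
        return out


def detect_translocations_map(
    loci: Sequence[MapLocus],
    lg: str,
    comparison: str = "",
) -> list[TranslocationEvent]:
    """Candidate translocations from a genetic map against a target genome.

    A candidate arises wherever the markers of one locus — or of two
    adjacent loci, when neither locus qualifies alone — hit two or more
    distinct target chromosomes with 100 % unique identity.  Candidates are
    unconfirmed until :func:`confirm_by_perturbation`.
    """
    events: list[TranslocationEvent] = []
    solo = []
    for locus in loci:
        chroms = locus.qualifying()
        solo.append(len(chroms) >= 2)
        if len(chroms) >= 2:
            events.append(_candidate(comparison, lg, (locus,), chroms))
    for i in range(len(loci) - 1):
        if solo[i] or solo[i + 1]:
            continue
        merged: dict[str, set[str]] = {}
        for locus in (loci[i], loci[i + 1]):
            for chrom, markers in locus.qualifying().items():
                merged.setdefault(chrom, set()).update(markers)
        if len(merged) >= 2:
            events.append(_candidate(comparison, lg, (loci[i], loci[i + 1]), merged))
    return events


def _candidate(
    comparison: str,
    lg: str,
    loci: tuple[MapLocus, ...],
    chroms: dict[str, set[str]],
) -> TranslocationEvent:
    targets = sorted(chroms)
    return TranslocationEvent(
        comparison=comparison,
        source_chrom=lg,
        target_chrom="|".join(targets),
        direction=Direction.UNDETERMINED,
        supporting_anchors=tuple(sorted(m for ms in chroms.values() for m in ms)),
        confirmed=False,
        locus_ids=tuple(l.locus_id for l in loci),
    )


def _signature(ev: TranslocationEvent) -> tuple:
    return (ev.target_chrom, ev.supporting_anchors)


def confirm_by_perturbation(
    loci: Sequence[MapLocus],
    lg: str,
    candidate: TranslocationEvent,
    window: int = 2,
    n_reps: int = 20,
    seed: int = 0,
    comparison: str = "",
) -> bool:
    """Re-detect a candidate under random local reorderings of the map.

    Each replicate permutes the locus order within ``window`` loci of the
    candidate (seeded) and re-runs detection; the candidate is confirmed
    only if an event with the same markers and target chromosomes recurs in
    every replicate.  With ``n_reps == 0`` the candidate is vacuously
    confirmed and flagged "unperturbed" in the log.
    """
    if n_reps == 0:
        log.warning("candidate on %s confirmed unperturbed (n_reps=0)", lg)
        return True
    idx = [i for i, l in enumerate(loci) if l.locus_id in candidate.locus_ids]
    if not idx:
        raise ValueError("candidate loci not present in the map")
    lo = max(0, min(idx) - window)
    hi = min(len(loci), max(idx) + window + 1)
    rng = np.random.default_rng(seed)
    want = _signature(candidate)
    for _ in range(n_reps):
        order = np.arange(len(loci))
        order[lo:hi] = lo + rng.permutation(hi - lo)
        perturbed = [loci[i] for i in order]
        found = {
            _signature(ev) for ev in detect_translocations_map(perturbed, lg, comparison)
        }
        if want not in found:
            return False
    return True


# --- Table-style event summaries -------------------------------------------

INV_COLUMNS = ["Aj-Ar", "Aj-An", "An-Ar"]
TRANS_COLUMNS = ["Aj-Ar", "Aj-An", "Ar>An", "An>Ar"]


def tabulate_events(
    inversions: Sequence[InversionEvent],
    translocations: Sequence[TranslocationEvent],
) -> pd.DataFrame:
    """Per-chromosome counts: inversion total/small per comparison and
    translocation counts per directional comparison label."""
    chroms = sorted(
        {e.chrom for e in inversions} | {e.source_chrom for e in translocations}
    )
    rows = []
    for chrom in chroms:
        row: dict[str, object] = {"chrom": chrom}
        for comp in sorted({e.comparison for e in inversions}):
            evs = [e for e in inversions if e.chrom == chrom and e.comparison == comp]
            row[f"inv_{comp}_total"] = len(evs)
            row[f"inv_{comp}_small"] = sum(
                e.size_class is SizeClass.SMALL for e in evs
            )
        for comp in sorted({e.comparison for e in translocations}):
            row[f"trans_{comp}"] = sum(
                1
                for e in translocations
                if e.source_chrom == chrom and e.comparison == comp
            )
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)


def summarize_events(per_chrom: pd.DataFrame) -> pd.DataFrame:
    """Append a recomputed totals row to a per-chromosome count table.

    The first column is the chromosome label; every other column is numeric
    and summed.  Cells are conventionally reported as "total(small)" pairs
    held in separate ``*_total``/``*_small`` columns.
    """
    label_col = per_chrom.columns[0]
    num = per_chrom.drop(columns=label_col)
    totals = {label_col: "total", **num.sum().to_dict()}
    return pd.concat([per_chrom, pd.DataFrame([totals])], ignore_index=True)


def large_event_total(summary: pd.DataFrame, comparisons: Sequence[str]) -> int:
    """Grand total of large inversions: sum over comparisons of total - small."""
    totals = summary[summary.iloc[:, 0] == "total"].iloc[0]
    return int(
        sum(
            totals[f"inv_{c}_total"] - totals[f"inv_{c}_small"] for c in comparisons
        )
    )
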