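"""Marker quality control, bin-locus classification and genetic-map summaries.

An F2 mapping population has limited recombination, so many genotyping-by-
sequencing markers co-segregate perfectly and collapse onto a single map
position.  Such a position is a *bin locus*; the marker chosen to stand for
it (the one with the least missing data) is its *representative*.  This
module provides the quality filters applied before mapping, the missing-
tolerant co-segregation partition that defines bins, the segregation-
distortion chi-square test, per-linkage-group map summaries, and the
population-size resolution model (the shortest genetic distance the
population can resolve, 100/n cM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

MISSING = "-"

#: integer encodings used internally; missing is always -1
_DOMINANT_CODES = {"0": 0, "1": 1, MISSING: -1}
_CODOMINANT_CODES = {"A": 0, "H": 1, "B": 2, MISSING: -1}


class MarkerType(str, Enum):
    DOMINANT = "dominant_presence_absence"
    CODOMINANT = "codominant_snp"


@dataclass(frozen=True)
class Marker:
    """A genotyped marker scored across one population.

    ``calls`` uses string codes: ``{"1","0","-"}`` for dominant
    presence/absence markers, ``{"A","H","B","-"}`` for codominant SNPs
    (``-`` is missing).  ``q_score`` is the genotyping quality value
    (-log10 of the minimum FDR at which the call is significant); it is
    only defined for SNP markers.
    """

    id: str
    marker_type: MarkerType
    calls: tuple[str, ...]
    q_score: float | None = None

    def __post_init__(self) -> None:
        codes = (
            _DOMINANT_CODES
            if self.marker_type is MarkerType.DOMINANT
            else _CODOMINANT_CODES
        )
        bad = set(self.calls) - codes.keys()
        if bad:
            raise ValueError(f"marker {self.id}: invalid call codes {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return len(self.calls)

    @property
    def missing_fraction(self) -> float:
        if not self.calls:
            return 1.0
        return sum(c == MISSING for c in self.calls) / len(self.calls)

    @property
    def call_rate(self) -> float:
        return 1.0 - self.missing_fraction

    def encoded(self) -> np.ndarray:
        codes = (
            _DOMINANT_CODES
            if self.marker_type is MarkerType.DOMINANT
            else _CODOMINANT_CODES
        )
        return np.array([codes[c] for c in self.calls], dtype=np.int8)


@dataclass(frozen=True)
class QCProfile:
    """Quality thresholds: call rate and Q are strict ``>``, missing is ``<=``.

    ``max_missing_representative`` additionally caps the missing fraction of
    a bin-locus representative (mapping preset only).
    """

    min_call_rate: float = 0.90
    min_q: float = 2.0
    max_missing: float = 0.10
    max_missing_representative: float | None = None

    @classmethod
    def mapping(cls) -> "QCProfile":
        return cls(max_missing=0.10, max_missing_representative=0.05)

    @classmethod
    def diversity(cls) -> "QCProfile":
        return cls(max_missing=0.05)


def filter_markers(markers: Sequence[Marker], profile: QCProfile) -> list[Marker]:
    """Return the markers passing every rule of ``profile``, order preserved.

    Call rate must strictly exceed ``min_call_rate``; missing fraction must
    not exceed ``max_missing``; SNP markers must additionally carry a
    ``q_score`` strictly above ``min_q``.  An SNP lacking a Q score is
    rejected with a logged warning rather than aborting the run.
    """
    kept: list[Marker] = []
    for m in markers:
        if m.call_rate <= profile.min_call_rate:
            continue
        if m.missing_fraction > profile.max_missing:
            continue
        if m.marker_type is MarkerType.CODOMINANT:
            if m.q_score is None:
                log.warning("marker %s: no Q score under a Q-requiring profile; rejected", m.id)
                continue
            if m.q_score <= profile.min_q:
                continue
        kept.append(m)
    return kept


@dataclass(frozen=True)
class BinPartition:
    """Partition of markers into co-segregation bins.

    ``bins`` maps a deterministic bin id (the lexicographically smallest
    member id) to the sorted tuple of member ids.  ``all_missing`` flags
    markers whose calls were entirely missing; they form singleton bins.
    """

    bins: dict[str, tuple[str, ...]]
    all_missing: frozenset[str] = field(default_factory=frozenset)

    def bin_of(self, marker_id: str) -> str:
        for bid, members in self.bins.items():
            if marker_id in members:
                return bid
        raise KeyError(marker_id)

    def as_sets(self) -> set[frozenset[str]]:
        return {frozenset(v) for v in self.bins.values()}


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def classify_bins(markers: Sequence[Marker]) -> BinPartition:
    """Partition markers into bins of zero observed recombination.

    Two markers are pairwise compatible when there is no individual at which
    both calls are non-missing and disagree; bins are the transitive closure
    of this relation.  Markers with all calls missing are compatible with
    everything and are therefore held out as flagged singleton bins.
    """
    if not markers:
        return BinPartition(bins={})
    n = {m.n_individuals for m in markers}
    if len(n) != 1:
        raise ValueError("markers genotyped on differing numbers of individuals")

    ids = [m.id for m in markers]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate marker ids")
    enc = np.stack([m.encoded() for m in markers])
    all_missing = [i for i in range(len(markers)) if np.all(enc[i] < 0)]
    live = [i for i in range(len(markers)) if i not in set(all_missing)]

    uf = _UnionFind(len(markers))
    for a_pos, i in enumerate(live):
        ei = enc[i]
        for j in live[a_pos + 1 :]:
            ej = enc[j]
            conflict = np.any((ei >= 0) & (ej >= 0) & (ei != ej))
            if not conflict:
                uf.union(i, j)

    groups: dict[int, list[str]] = {}
    for i in live:
        groups.setdefault(uf.find(i), []).append(ids[i])
    bins = {min(members): tuple(sorted(members)) for members in groups.values()}
    for i in all_missing:
        bins[ids[i]] = (ids[i],)
    return BinPartition(bins=bins, all_missing=frozenset(ids[i] for i in all_missing))


@dataclass(frozen=True)
class BinLocus:
    """One genetic position: a bin locus (>=2 members) or single-marker locus."""

    locus_id: str
    lg: str
    position_cm: float
    member_marker_ids: tuple[str, ...]
    representative_id: str

    def __post_init__(self) -> None:
        if not self.member_marker_ids:
            raise ValueError(f"locus {self.locus_id}: no members")
        if self.representative_id not in self.member_marker_ids:
            raise ValueError(f"locus {self.locus_id}: representative not a member")

    @property
    def is_bin(self) -> bool:
        return len(self.member_marker_ids) >= 2


def choose_representative(members: Sequence[Marker]) -> Marker:
    """Least missing data wins; ties broken lexicographically by id."""
    return min(members, key=lambda m: (m.missing_fraction, m.id))


@dataclass(frozen=True)
class GeneticMap:
    """Ordered linkage groups of loci with non-decreasing cM positions."""

    linkage_groups: tuple[tuple[str, tuple[BinLocus, ...]], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for lg, loci in self.linkage_groups:
            pos = [l.position_cm for l in loci]
            if any(b < a for a, b in zip(pos, pos[1:])):
                raise ValueError(f"{lg}: cM positions not non-decreasing")
            for locus in loci:
                for mid in locus.member_marker_ids:
                    if mid in seen:
                        raise ValueError(f"marker {mid} appears in two loci")
                    seen.add(mid)

    @property
    def n_loci(self) -> int:
        return sum(len(loci) for _, loci in self.linkage_groups)


_SUMMARY_COLS = [
    "lg",
    "single_marker_loci",
    "bin_loci",
    "total_loci",
    "mapped_markers",
    "coverage_cm",
]


def _append_totals(rows: pd.DataFrame) -> pd.DataFrame:
    """Add subgenome subtotals (by LG-letter prefix), grand total and mean."""
    num = rows.drop(columns="lg")
    out = [rows]
    for prefix in sorted({lg[0] for lg in rows["lg"]}):
        sub = rows[rows["lg"].str.startswith(prefix)].drop(columns="lg")
        out.append(
            pd.DataFrame([{"lg": f"subtotal_{prefix}", **sub.sum().to_dict()}])
        )
    total = {"lg": "total", **num.sum().to_dict()}
    mean = {"lg": "mean_per_lg", **(num.sum() / len(rows)).round(1).to_dict()}
    out.append(pd.DataFrame([total, mean]))
    return pd.concat(out, ignore_index=True)[_SUMMARY_COLS]


def summarize_map(gmap: GeneticMap) -> pd.DataFrame:
    """Per-LG locus/marker counts and coverage, with subtotals, totals, means.

    Coverage of a linkage group is max(cM) - min(cM); a one-locus group has
    coverage 0.
    """
    rows = []
    for lg, loci in gmap.linkage_groups:
        pos = [l.position_cm for l in loci]
        rows.append(
            {
                "lg": lg,
                "single_marker_loci": sum(not l.is_bin for l in loci),
                "bin_loci": sum(l.is_bin for l in loci),
                "total_loci": len(loci),
                "mapped_markers": sum(len(l.member_marker_ids) for l in loci),
                "coverage_cm": (max(pos) - min(pos)) if pos else 0.0,
            }
        )
    return _append_totals(pd.DataFrame(rows, columns=_SUMMARY_COLS))


def summarize_locus_counts(per_lg: pd.DataFrame) -> pd.DataFrame:
    """Recompute subtotals/totals/means from an already-tabulated per-LG table.

    Accepts the same columns as :func:`summarize_map` output rows (one row
    per linkage group) and appends the derived rows, recomputed from scratch.
    """
    missing = set(_SUMMARY_COLS) - set(per_lg.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return _append_totals(per_lg[_SUMMARY_COLS].reset_index(drop=True))


def marker_accounting(n_selected: int, n_mapped: int) -> int:
    """Markers selected for mapping but not placed in any linkage group."""
    if n_mapped > n_selected:
        raise ValueError("mapped exceeds selected")
    return n_selected - n_mapped


def single_locus_share(n_single: int, n_total_loci: int) -> float:
    """Percentage of loci detected by a single marker (0-100)."""
    if n_total_loci <= 0:
        raise ValueError("no loci")
    return 100.0 * n_single / n_total_loci


_EXPECTED_RATIOS = {
    MarkerType.DOMINANT: np.array([3.0, 1.0]),
    MarkerType.CODOMINANT: np.array([1.0, 2.0, 1.0]),
}


def distortion_test(
    observed: Sequence[int], marker_type: MarkerType
) -> tuple[float, int, float]:
    """Pearson chi-square of observed genotype-class counts against the F2
    expectation (3:1 dominant, 1:2:1 codominant).

    Returns ``(chi2, df, p)`` with ``df = classes - 1``.
    """
    ratio = _EXPECTED_RATIOS[marker_type]
    obs = np.asarray(observed, dtype=float)
    if obs.shape != ratio.shape:
        raise ValueError(
            f"expected {len(ratio)} genotype classes for {marker_type.value}, got {len(obs)}"
        )
    total = obs.sum()
    if total <= 0:
        raise ValueError("zero total count")
    expected = ratio / ratio.sum() * total
    chi2, p = stats.chisquare(obs, expected)
    return float(chi2), len(obs) - 1, float(p)


def flag_distorted(
    counts_by_marker: Mapping[str, tuple[Sequence[int], MarkerType]],
    alpha: float = 0.05,
) -> dict[str, bool]:
    """Flag markers whose segregation departs from the F2 ratio at level alpha.

    No multiple-testing correction is applied; distorted markers are flagged,
    not removed (removal is the caller's choice via ``drop_distorted``).
    """
    return {
        mid: distortion_test(obs, mt)[2] < alpha
        for mid, (obs, mt) in counts_by_marker.items()
    }


@dataclass(frozen=True)
class ResolutionModel:
    """Resolving power of a mapping population of size ``n``.

    The shortest resolvable genetic distance is 100/n cM (one recombinant in
    n gametes scored as percent); distances up to twice that bound delimit
    the "small" rearrangement class.  ``min_cm`` is the one-decimal value
    used in reports; ``min_cm_exact`` retains full precision for
    comparisons.  ``mb_per_cm`` converts map distance to an approximate
    physical distance given a genome size and map length.
    """

    population_size: int
    genome_size_mb: float
    map_length_cm: float

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        if self.map_length_cm <= 0 or self.genome_size_mb <= 0:
            raise ValueError("genome size and map length must be positive")

    @property
    def min_cm_exact(self) -> float:
        return 100.0 / self.population_size

    @property
    def min_cm(self) -> float:
        return round(self.min_cm_exact, 1)

    @property
    def small_max_cm(self) -> float:
        return 2.0 * self.min_cm_exact

    @property
    def mb_per_cm(self) -> float:
        return self.genome_size_mb / self.map_length_cm


def resolution_model(
    pop_size: int, genome_size_mb: float = 485.0, map_length_cm: float = 828.4
) -> ResolutionModel:
    """Build the resolution model; defaults describe an A subgenome of
    roughly 485 Mb mapped over 828.4 cM."""
    return ResolutionModel(pop_size, genome_size_mb, map_length_cm)
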