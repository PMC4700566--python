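"""Seeded simulators with planted truth for every pipeline stage.

Three generators stand in for data that cannot be redistributed: an F2
mapping population (Haldane recombination, co-segregating marker bins, MCAR
missingness, optional segregation distortion via gametic selection), pairs
of rearranged genomes as anchor sets (collinear backbone with planted
inversions and translocations), and structured diversity panels under the
Balding-Nichols model with optional admixture.  Every generator is
deterministic given its spec and seed and serializes its planted truth
alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genetic_map import BinLocus, GeneticMap, Marker, MarkerType, choose_representative
from .popgen import GenotypePanel
from .rearrangement import Anchor

__all__ = [
    "LocusSpec",
    "SimMapSpec",
    "study_map_spec",
    "F2Simulation",
    "simulate_f2",
    "SimGenomeSpec",
    "PlantedInversion",
    "PlantedTranslocation",
    "GenomeSimulation",
    "simulate_rearranged_genomes",
    "SimPanelSpec",
    "PanelSimulation",
    "simulate_panel",
]


def haldane_r(d_cm: float) -> float:
    """Map distance (cM) to recombination fraction, no interference."""
    return (1.0 - math.exp(-2.0 * d_cm / 100.0)) / 2.0


def kosambi_r(d_cm: float) -> float:
    """Kosambi map function (positive interference)."""
    return 0.5 * math.tanh(2.0 * d_cm / 100.0)


_MAP_FUNCTIONS = {"haldane": haldane_r, "kosambi": kosambi_r}


# --------------------------------------------------------------------------
# F2 mapping population
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusSpec:
    """One genetic position carrying ``n_markers`` perfectly co-segregating
    markers (a bin when >= 2)."""

    lg: str
    position_cm: float
    n_markers: int = 1
    marker_type: MarkerType = MarkerType.CODOMINANT
    distortion_s: float = 0.0  # gametic survival penalty for allele 1


@dataclass(frozen=True)
class SimMapSpec:
    loci: tuple[LocusSpec, ...]
    missing_rate: float = 0.03
    map_function: str = "haldane"

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing rate outside [0,1]")
        if self.map_function not in _MAP_FUNCTIONS:
            raise ValueError(f"unknown map function {self.map_function!r}")
        lengths = {}
        for l in self.loci:
            if l.position_cm < 0:
                raise ValueError("negative cM position")
            if l.n_markers < 1:
                raise ValueError("locus with no markers")
            if not 0.0 <= l.distortion_s < 1.0:
                raise ValueError("distortion s outside [0,1)")


# Printed characteristics of the 18-linkage-group intercross map this
# generator emulates: (LG, coverage cM, single-marker loci, bin loci,
# mapped markers).
_STUDY_LGS: tuple[tuple[str, float, int, int, int], ...] = (
    ("A01", 91.0, 62, 32, 274),
    ("A02", 72.3, 75, 21, 189),
    ("A03", 94.9, 72, 26, 163),
    ("A04", 63.3, 48, 13, 133),
    ("A05", 94.4, 71, 24, 150),
    ("A06", 98.2, 80, 25, 160),
    ("A07", 71.5, 40, 31, 163),
    ("A08", 66.4, 59, 26, 177),
    ("A09", 108.0, 62, 38, 311),
    ("A10", 68.4, 71, 12, 144),
    ("B01", 62.8, 41, 26, 171),
    ("B02", 105.1, 67, 39, 236),
    ("B03", 59.8, 69, 17, 230),
    ("B04", 115.4, 66, 17, 139),
    ("B05", 102.2, 51, 19, 125),
    ("B06", 75.8, 50, 11, 79),
    ("B07", 102.2, 60, 39, 246),
    ("B08", 126.7, 88, 22, 239),
)

STUDY_POPULATION_SIZE = 168
DOMINANT_MARKER_FRACTION = 0.5  # tag markers are a mix of SNPs and presence/absence


def study_map_spec(seed: int = 0) -> SimMapSpec:
    """A map spec shaped like the real intercross map: 18 linkage groups
    with the published coverage, single/bin locus counts and marker totals;
    locus positions and bin sizes are randomized with the given seed."""
    rng = np.random.default_rng(seed)
    loci: list[LocusSpec] = []
    for lg, length, n_single, n_bins, n_markers in _STUDY_LGS:
        n_loci = n_single + n_bins
        pos = np.sort(rng.uniform(0.0, length, size=n_loci))
        # distribute the extra markers over the bin loci (each bin >= 2)
        extra = n_markers - n_single - 2 * n_bins
        alloc = np.full(n_bins, 2, dtype=int)
        if n_bins and extra > 0:
            alloc += rng.multinomial(extra, np.full(n_bins, 1.0 / n_bins))
        is_bin = np.zeros(n_loci, dtype=bool)
        is_bin[rng.choice(n_loci, size=n_bins, replace=False)] = True
        b = 0
        for i in range(n_loci):
            mtype = (
                MarkerType.DOMINANT
                if rng.random() < DOMINANT_MARKER_FRACTION
                else MarkerType.CODOMINANT
            )
            if is_bin[i]:
                loci.append(LocusSpec(lg, float(pos[i]), int(alloc[b]), mtype))
                b += 1
            else:
                loci.append(LocusSpec(lg, float(pos[i]), 1, mtype))
    return SimMapSpec(loci=tuple(loci))


@dataclass(frozen=True)
class F2Simulation:
    markers: tuple[Marker, ...]
    dosages: pd.DataFrame  # loci x individuals, pre-missingness truth
    truth: pd.DataFrame  # marker_id, lg, position_cm, locus_id, marker_type
    gametes: dict[str, np.ndarray] = field(default_factory=dict)  # lg -> 2n x loci

    def true_bins(self) -> set[frozenset[str]]:
        return {
            frozenset(g["marker_id"]) for _, g in self.truth.groupby("locus_id")
        }

    def to_genetic_map(self) -> GeneticMap:
        """The planted map: loci ordered by position, representative = least
        missing member (ties by id)."""
        by_id = {m.id: m for m in self.markers}
        lgs = []
        for lg, g in self.truth.groupby("lg", sort=True):
            loci = []
            for locus_id, gl in sorted(
                g.groupby("locus_id"), key=lambda kv: kv[1]["position_cm"].iloc[0]
            ):
                members = [by_id[m] for m in gl["marker_id"]]
                rep = choose_representative(members)
                loci.append(
                    BinLocus(
                        locus_id=str(locus_id),
                        lg=str(lg),
                        position_cm=float(gl["position_cm"].iloc[0]),
                        member_marker_ids=tuple(sorted(gl["marker_id"])),
                        representative_id=rep.id,
                    )
                )
            lgs.append((str(lg), tuple(loci)))
        return GeneticMap(linkage_groups=tuple(lgs))


def _simulate_gametes(
    rng: np.random.Generator,
    n_gametes: int,
    r: np.ndarray,
    distortion_s: np.ndarray,
) -> np.ndarray:
    """Alleles (0/1) for n_gametes gametes over the loci of one linkage
    group; gametes carrying allele 1 at a distorted locus survive with
    probability 1-s (rejection sampling)."""
    n_loci = len(r) + 1

    def draw(k: int) -> np.ndarray:
        first = rng.integers(0, 2, size=(k, 1))
        switches = rng.random((k, len(r))) < r[None, :]
        return (first + np.concatenate(
            [np.zeros((k, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1
        )) % 2

    gametes = draw(n_gametes)
    if np.any(distortion_s > 0):
        alive = np.zeros(n_gametes, dtype=bool)
        while not np.all(alive):
            dead = np.flatnonzero(~alive)
            survive = np.ones(len(dead), dtype=bool)
            for locus in np.flatnonzero(distortion_s > 0):
                carriers = gametes[dead, locus] == 1
                killed = rng.random(len(dead)) < distortion_s[locus]
                survive &= ~(carriers & killed)
            alive[dead[survive]] = True
            redraw = dead[~survive]
            if len(redraw):
                gametes[redraw] = draw(len(redraw))
    return gametes


def simulate_f2(spec: SimMapSpec, n: int, seed: int) -> F2Simulation:
    """Simulate an F2 population of ``n`` individuals.

    Each individual inherits two independent gametes per linkage group;
    crossovers follow the configured map function (Haldane default, no
    interference: adjacent-locus recombination r = (1 - e^(-2d/100))/2).
    Codominant loci report dosage codes A/H/B; dominant loci collapse the
    heterozygote with band presence (3:1 expectation).  Missingness is MCAR
    at the spec rate.  All markers of one locus share the underlying
    segregation pattern exactly (bins differ only through missingness).
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    map_fn = _MAP_FUNCTIONS[spec.map_function]

    markers: list[Marker] = []
    truth_rows: list[dict] = []
    dosage_cols: dict[str, np.ndarray] = {}
    gametes_by_lg: dict[str, np.ndarray] = {}

    by_lg: dict[str, list[LocusSpec]] = {}
    for l in spec.loci:
        by_lg.setdefault(l.lg, []).append(l)

    for lg in sorted(by_lg):
        loci = sorted(by_lg[lg], key=lambda l: l.position_cm)
        pos = np.array([l.position_cm for l in loci])
        r = np.array([map_fn(d) for d in np.diff(pos)])
        s = np.array([l.distortion_s for l in loci])
        gametes = _simulate_gametes(rng, 2 * n, r, s)
        gametes_by_lg[lg] = gametes
        dosage = gametes[0::2] + gametes[1::2]  # n x loci

        for li, locus in enumerate(loci):
            locus_id = f"{lg}_L{li:03d}"
            dosage_cols[locus_id] = dosage[:, li]
            for k in range(locus.n_markers):
                mid = f"{locus_id}_m{k}"
                if locus.marker_type is MarkerType.CODOMINANT:
                    codes = np.array(["A", "H", "B"])[dosage[:, li]]
                else:
                    codes = np.where(dosage[:, li] >= 1, "1", "0")
                if spec.missing_rate > 0:
                    miss = rng.random(n) < spec.missing_rate
                    codes = np.where(miss, "-", codes)
                markers.append(
                    Marker(
                        id=mid,
                        marker_type=locus.marker_type,
                        calls=tuple(codes.tolist()),
                        q_score=5.0
                        if locus.marker_type is MarkerType.CODOMINANT
                        else None,
                    )
                )
                truth_rows.append(
                    {
                        "marker_id": mid,
                        "lg": lg,
                        "position_cm": locus.position_cm,
                        "locus_id": locus_id,
                        "marker_type": locus.marker_type.value,
                    }
                )

    return F2Simulation(
        markers=tuple(markers),
        dosages=pd.DataFrame(dosage_cols),
        truth=pd.DataFrame(truth_rows),
        gametes=gametes_by_lg,
    )


# --------------------------------------------------------------------------
# Rearranged genome anchor sets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedInversion:
    chrom: str
    first_anchor: int
    n_anchors: int

    def __post_init__(self) -> None:
        if self.n_anchors < 2:
            raise ValueError("inversion needs >= 2 anchors")


@dataclass(frozen=True)
class PlantedTranslocation:
    source_chrom: str
    target_chrom: str
    first_anchor: int
    n_anchors: int

    def __post_init__(self) -> None:
        if self.source_chrom == self.target_chrom:
            raise ValueError("translocation target equals source")
        if self.n_anchors < 1:
            raise ValueError("empty translocation run")


@dataclass(frozen=True)
class SimGenomeSpec:
    """Chromosomes as (id, length in a-units, anchor count); coord_b is bp,
    ``b_per_a`` scaling a-units to bp (1 for bp-vs-bp comparisons, ~1e6/0.585
    for cM-vs-bp)."""

    chromosomes: tuple[tuple[str, float, int], ...]
    inversions: tuple[PlantedInversion, ...] = ()
    translocations: tuple[PlantedTranslocation, ...] = ()
    b_per_a: float = 1.0
    jitter_frac: float = 0.05  # of mean spacing; small enough to keep order

    def __post_init__(self) -> None:
        lengths = {c: n for c, _, n in self.chromosomes}
        used: dict[str, set[int]] = {c: set() for c, _, _ in self.chromosomes}
        for ev in (*self.inversions, *self.translocations):
            chrom = ev.chrom if isinstance(ev, PlantedInversion) else ev.source_chrom
            span = set(range(ev.first_anchor, ev.first_anchor + ev.n_anchors))
            if chrom not in used:
                raise ValueError(f"unknown chromosome {chrom}")
            if max(span) >= lengths[chrom]:
                raise ValueError(f"planted event beyond {chrom} bounds")
            if used[chrom] & span:
                raise ValueError(f"overlapping planted events on {chrom}")
            used[chrom] |= span


@dataclass(frozen=True)
class GenomeSimulation:
    anchors: dict[str, tuple[Anchor, ...]]  # per source chromosome, a-sorted
    truth: pd.DataFrame  # kind, chrom, target_chrom, first, last, anchor ids


def simulate_rearranged_genomes(spec: SimGenomeSpec, seed: int) -> GenomeSimulation:
    """Collinear anchor backbone with planted inversions and translocations.

    Anchors sit on an even grid with uniform positional jitter bounded well
    below the spacing, so the backbone is strictly collinear; a planted
    inversion reverses the coord_b order of its anchor run, a planted
    translocation rewrites the run's target chromosome.
    """
    rng = np.random.default_rng(seed)
    anchors: dict[str, tuple[Anchor, ...]] = {}
    truth_rows: list[dict] = []
    for chrom, length, n in spec.chromosomes:
        spacing = length / n
        base = (np.arange(n) + 0.5) * spacing
        coord_a = base + rng.uniform(-0.4, 0.4, size=n) * spacing
        coord_b = (
            base * spec.b_per_a
            + rng.uniform(-spec.jitter_frac, spec.jitter_frac, size=n)
            * spacing
            * spec.b_per_a
        )
        chrom_b = np.array([chrom] * n, dtype=object)
        ids = [f"{chrom}_a{i:04d}" for i in range(n)]

        for inv in spec.inversions:
            if inv.chrom != chrom:
                continue
            sl = slice(inv.first_anchor, inv.first_anchor + inv.n_anchors)
            coord_b[sl] = coord_b[sl][::-1]
            truth_rows.append(
                {
                    "kind": "inversion",
                    "chrom": chrom,
                    "target_chrom": chrom,
                    "first": inv.first_anchor,
                    "last": inv.first_anchor + inv.n_anchors - 1,
                    "anchor_ids": ",".join(ids[sl]),
                    "span_a": float(coord_a[sl][-1] - coord_a[sl][0]),
                }
            )
        for tr in spec.translocations:
            if tr.source_chrom != chrom:
                continue
            sl = slice(tr.first_anchor, tr.first_anchor + tr.n_anchors)
            chrom_b[sl] = tr.target_chrom
            truth_rows.append(
                {
                    "kind": "translocation",
                    "chrom": chrom,
                    "target_chrom": tr.target_chrom,
                    "first": tr.first_anchor,
                    "last": tr.first_anchor + tr.n_anchors - 1,
                    "anchor_ids": ",".join(ids[sl]),
                    "span_a": float(coord_a[sl][-1] - coord_a[sl][0]),
                }
            )

        anchors[chrom] = tuple(
            Anchor(
                id=ids[i],
                chrom_a=chrom,
                coord_a=float(coord_a[i]),
                chrom_b=str(chrom_b[i]),
                coord_b=float(coord_b[i]),
            )
            for i in range(n)
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["kind", "chrom", "target_chrom", "first", "last", "anchor_ids", "span_a"],
    )
    return GenomeSimulation(anchors=anchors, truth=truth)


# --------------------------------------------------------------------------
# Structured diversity panel (Balding-Nichols)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimPanelSpec:
    """K populations with per-population divergence F, L biallelic markers.

    ``admixture`` (accessions x K, rows summing to 1) defaults to pure
    membership with ``accessions_per_pop`` accessions in each population.
    The 26-accession, three-species panel the pipeline targets corresponds
    to K=3 with 8-9 accessions per population.
    """

    n_pops: int = 3
    f_divergence: tuple[float, ...] = (0.3, 0.3, 0.3)
    n_markers: int = 1000
    accessions_per_pop: int = 8
    admixture: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.f_divergence) != self.n_pops:
            raise ValueError("need one F per population")
        if any(not 0.0 < f < 1.0 for f in self.f_divergence):
            raise ValueError("F must lie in (0,1)")
        if self.admixture is not None:
            for row in self.admixture:
                if len(row) != self.n_pops:
                    raise ValueError("admixture row length != K")
                if abs(sum(row) - 1.0) > 1e-9:
                    raise ValueError("admixture rows must sum to 1")


@dataclass(frozen=True)
class PanelSimulation:
    panel: GenotypePanel
    truth: pd.DataFrame  # accession, memberships per population
    pop_freqs: np.ndarray  # K x L


def simulate_panel(spec: SimPanelSpec, seed: int) -> PanelSimulation:
    """Balding-Nichols panel: ancestral frequency p ~ U(0.05, 0.95); each
    population draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F); an
    accession's expected frequency is its membership-weighted mix and its
    genotype is Binomial(2, frequency) dosage."""
    rng = np.random.default_rng(seed)
    K, L = spec.n_pops, spec.n_markers
    p_anc = rng.uniform(0.05, 0.95, size=L)
    pop_freqs = np.empty((K, L))
    for k in range(K):
        f = spec.f_divergence[k]
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        pop_freqs[k] = rng.beta(a, b)

    if spec.admixture is not None:
        q = np.asarray(spec.admixture, float)
        names = [f"acc{i:03d}" for i in range(len(q))]
    else:
        q = np.repeat(np.eye(K), spec.accessions_per_pop, axis=0)
        names = [
            f"P{k}_{i}" for k in range(K) for i in range(spec.accessions_per_pop)
        ]

    acc_freq = q @ pop_freqs
    dosage = rng.binomial(2, acc_freq).astype(float)
    panel = GenotypePanel(
        accessions=tuple(names),
        markers=tuple(f"L{j:05d}" for j in range(L)),
        calls=dosage,
        marker_ploidy=np.full(L, 2),
    )
    truth = pd.DataFrame(q, index=names, columns=[f"pop{k}" for k in range(K)])
    truth.insert(0, "accession", names)
    truth = truth.reset_index(drop=True)
    return PanelSimulation(panel=panel, truth=truth, pop_freqs=pop_freqs)
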