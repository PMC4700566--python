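"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are TSV.  Genotype matrices have one row per marker (id, type,
then one column per individual) with codes 1/0/- (dominant) or A/H/B/-
(codominant).  Alignments use the 12-column BLAST tabular layout (outfmt 6)
plus a sidecar mapping subject sequence ids to genome labels.  Block
definitions are BED-like (0-based half-open on disk, converted to the
internal 1-based inclusive convention).  Trees go out as Newick.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .block_synteny import AlignmentRecord, AncestralBlockDef
from .genetic_map import BinLocus, GeneticMap, Marker, MarkerType
from .popgen import DistanceMatrix, GenotypePanel
from .rearrangement import Anchor

log = logging.getLogger(__name__)

_TYPE_CODES = {
    "dominant": MarkerType.DOMINANT,
    "codominant": MarkerType.CODOMINANT,
    MarkerType.DOMINANT.value: MarkerType.DOMINANT,
    MarkerType.CODOMINANT.value: MarkerType.CODOMINANT,
}


def bundled_table(name: str) -> pd.DataFrame:
    """A table shipped with the package (published per-LG and per-chromosome
    count tables used as inputs)."""
    with resources.files("karyomap.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def read_genotype_tsv(path: str | Path) -> list[Marker]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("-")
    if df.columns[0] != "id" or df.columns[1] != "type":
        raise ValueError("genotype TSV must start with columns: id, type")
    has_q = "q_score" in df.columns
    individual_cols = [c for c in df.columns[2:] if c != "q_score"]
    markers = []
    for _, row in df.iterrows():
        q = None
        if has_q and row["q_score"] not in ("-", ""):
            q = float(row["q_score"])
        markers.append(
            Marker(
                id=row["id"],
                marker_type=_TYPE_CODES[row["type"]],
                calls=tuple(row[c] for c in individual_cols),
                q_score=q,
            )
        )
    return markers


def write_genotype_tsv(markers: Sequence[Marker], path: str | Path) -> None:
    n = markers[0].n_individuals if markers else 0
    cols = [f"ind{i:03d}" for i in range(n)]
    rows = []
    for m in markers:
        rows.append(
            {
                "id": m.id,
                "type": "dominant" if m.marker_type is MarkerType.DOMINANT else "codominant",
                "q_score": "" if m.q_score is None else m.q_score,
                **dict(zip(cols, m.calls)),
            }
        )
    pd.DataFrame(rows, columns=["id", "type", "q_score", *cols]).to_csv(
        path, sep="\t", index=False
    )


def read_map_tsv(path: str | Path) -> pd.DataFrame:
    """Genetic map file: marker_id, lg, cM."""
    df = pd.read_csv(path, sep="\t")
    need = {"marker_id", "lg", "cM"}
    if not need <= set(df.columns):
        raise ValueError(f"map TSV needs columns {sorted(need)}")
    return df


def genetic_map_from_table(map_df: pd.DataFrame, markers: Sequence[Marker]) -> GeneticMap:
    """Assemble a GeneticMap: markers sharing an (lg, cM) position form one
    locus; the least-missing member (ties by id) is its representative."""
    by_id = {m.id: m for m in markers}
    lgs = []
    for lg, g in map_df.groupby("lg", sort=True):
        loci = []
        for i, (pos, gl) in enumerate(sorted(g.groupby("cM"))):
            member_ids = tuple(sorted(gl["marker_id"]))
            known = [by_id[m] for m in member_ids if m in by_id]
            rep = (
                min(known, key=lambda m: (m.missing_fraction, m.id)).id
                if known
                else member_ids[0]
            )
            loci.append(
                BinLocus(
                    locus_id=f"{lg}_L{i:03d}",
                    lg=str(lg),
                    position_cm=float(pos),
                    member_marker_ids=member_ids,
                    representative_id=rep,
                )
            )
        lgs.append((str(lg), tuple(loci)))
    return GeneticMap(linkage_groups=tuple(lgs))


BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(
    path: str | Path, genome_of_subject: Mapping[str, str] | None = None
) -> list[AlignmentRecord]:
    """Parse 12-column BLAST tabular output; malformed rows are skipped with
    a logged warning.  Subject coordinates are normalized to start <= end
    with the orientation kept as strand."""
    records: list[AlignmentRecord] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if len(parts) < 12:
                    raise ValueError("fewer than 12 columns")
                row = dict(zip(BLAST6_COLUMNS, parts))
                sstart, send = int(row["sstart"]), int(row["send"])
                strand = "+" if sstart <= send else "-"
                sseqid = row["sseqid"]
                genome = (
                    genome_of_subject.get(sseqid, "other")
                    if genome_of_subject
                    else "other"
                )
                records.append(
                    AlignmentRecord(
                        query_id=row["qseqid"],
                        subject_genome=genome,
                        subject_chrom=sseqid,
                        subject_start=min(sstart, send),
                        subject_end=max(sstart, send),
                        strand=strand,
                        percent_identity=float(row["pident"]),
                        align_length=int(row["length"]),
                        e_value=float(row["evalue"]),
                        bit_score=float(row["bitscore"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                skipped += 1
                log.warning("%s:%d malformed alignment row (%s); skipped (%d so far)",
                            path, lineno, exc, skipped)
    return records


def read_subject_genomes(path: str | Path) -> dict[str, str]:
    """Sidecar TSV mapping sseqid -> genome label (e.g. Ar, An, At)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sseqid", "genome"])
    return dict(zip(df["sseqid"], df["genome"]))


def read_block_defs(path: str | Path) -> list[AncestralBlockDef]:
    """BED-like block definitions: chrom, start, end, block_label with
    0-based half-open intervals on disk -> 1-based inclusive internally."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "block_label"]
    )
    return [
        AncestralBlockDef(
            block_label=str(r.block_label),
            reference_chrom=str(r.chrom),
            start=int(r.start) + 1,
            end=int(r.end),
        )
        for r in df.itertuples()
    ]


def read_anchor_tsv(path: str | Path) -> tuple[list[Anchor], str]:
    """Anchor table: id, chrom_a, coord_a, unit, chrom_b, coord_b, identity,
    unique_b.  Returns the anchors and the (single) unit tag."""
    df = pd.read_csv(path, sep="\t")
    units = set(df["unit"])
    if len(units) != 1:
        raise ValueError("mixed coordinate units in one anchor set")
    anchors = [
        Anchor(
            id=str(r.id),
            chrom_a=str(r.chrom_a),
            coord_a=float(r.coord_a),
            chrom_b=str(r.chrom_b),
            coord_b=float(r.coord_b),
            identity=float(r.identity),
            unique_b=bool(r.unique_b),
        )
        for r in df.itertuples()
    ]
    return anchors, units.pop()


def write_anchor_tsv(anchors: Sequence[Anchor], unit: str, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": a.id, "chrom_a": a.chrom_a, "coord_a": a.coord_a,
                "unit": unit, "chrom_b": a.chrom_b, "coord_b": a.coord_b,
                "identity": a.identity, "unique_b": a.unique_b,
            }
            for a in anchors
        ]
    ).to_csv(path, sep="\t", index=False)


def read_structure_runs(path: str | Path) -> pd.DataFrame:
    """Admixture-run likelihood summaries: K, replicate, ln_prob."""
    df = pd.read_csv(path, sep="\t")
    need = {"K", "replicate", "ln_prob"}
    if not need <= set(df.columns):
        raise ValueError(f"structure-run TSV needs columns {sorted(need)}")
    return df


def read_panel_tsv(path: str | Path, metadata: pd.DataFrame | None = None) -> GenotypePanel:
    """Diversity panel as a genotype TSV (rows markers) -> dosage matrix."""
    markers = read_genotype_tsv(path)
    names = tuple(f"ind{i:03d}" for i in range(markers[0].n_individuals))
    dosage = np.full((len(names), len(markers)), np.nan)
    ploidy = np.empty(len(markers), dtype=int)
    for j, m in enumerate(markers):
        enc = m.encoded().astype(float)
        enc[enc < 0] = np.nan
        dosage[:, j] = enc
        ploidy[j] = 2 if m.marker_type is MarkerType.CODOMINANT else 1
    return GenotypePanel(
        accessions=names,
        markers=tuple(m.id for m in markers),
        calls=dosage,
        marker_ploidy=ploidy,
        metadata=metadata,
    )


def write_distance_matrix(dist: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dist.values, index=dist.labels, columns=dist.labels).to_csv(
        path, sep="\t"
    )


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(tuple(df.index), df.to_numpy(float))
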