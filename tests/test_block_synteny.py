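"""Alignment filtering, block assignment, synteny calls, genome specificity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from karyomap.block_synteny import (
    AlignmentFilterProfile,
    AlignmentRecord,
    AncestralBlockDef,
    BlockAssignment,
    SyntenyKind,
    Specificity,
    assign_blocks,
    blocks_for_hit,
    call_synteny_blocks,
    filter_alignments,
    genome_specificity,
    specificity_counts,
    validate_block_defs,
)


def hit(q="q", chrom="chr1", pos=100, length=60, e=1e-30, ident=99.5, genome="At"):
    return AlignmentRecord(
        query_id=q,
        subject_genome=genome,
        subject_chrom=chrom,
        subject_start=pos,
        subject_end=pos + length - 1,
        strand="+",
        percent_identity=ident,
        align_length=length,
        e_value=e,
        bit_score=100.0,
    )


# --- filtering -------------------------------------------------------------

class TestFilterAlignments:
    def test_ancestral_profile_keeps_passing_hit(self):
        assert filter_alignments([hit(e=1e-7, length=45)], AlignmentFilterProfile.ancestral())

    def test_length_strictly_over_40(self):
        # e-value exactly at the cap passes; length exactly 40 does not
        assert filter_alignments([hit(e=1e-6, length=40)], AlignmentFilterProfile.ancestral()) == []
        assert filter_alignments([hit(e=1e-6, length=41)], AlignmentFilterProfile.ancestral())

    def test_genome_profile_length_inclusive(self):
        assert filter_alignments([hit(e=1e-20, length=60)], AlignmentFilterProfile.genome())
        assert filter_alignments([hit(e=1e-20, length=59)], AlignmentFilterProfile.genome()) == []

    def test_matches_rowwise_scan_never_grows_idempotent(self, rng):
        records = [
            hit(q=f"q{i}", e=10.0 ** -rng.integers(0, 40), length=int(rng.integers(20, 70)))
            for i in range(500)
        ]
        prof = AlignmentFilterProfile.ancestral()
        kept = filter_alignments(records, prof)
        expected = [r for r in records if r.e_value <= 1e-6 and r.align_length > 40]
        assert kept == expected
        assert len(kept) <= len(records)
        assert filter_alignments(kept, prof) == kept


# --- block definitions and assignment --------------------------------------

DEFS = [
    AncestralBlockDef("F", "chr1", 1, 1_000_000),
    AncestralBlockDef("R", "chr1", 2_000_001, 3_000_000),
    AncestralBlockDef("C", "chr2", 1, 1_000_000),
    AncestralBlockDef("J", "chr3", 1, 1_000_000),
]


class TestBlockDefs:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            validate_block_defs(
                [
                    AncestralBlockDef("A", "chr1", 1, 100),
                    AncestralBlockDef("B", "chr1", 50, 200),
                ]
            )

    def test_midpoint_intersection(self):
        # hit straddling the boundary is placed by its midpoint, once
        rec = hit(pos=999_950, length=60)  # midpoint 999_979.5, inside F
        assert blocks_for_hit(rec, DEFS) == ["F"]
        assert blocks_for_hit(hit(chrom="chrX"), DEFS) == []


class TestAssignBlocks:
    def test_single_candidate_wins(self):
        asg = assign_blocks([("L1", {"m1": [hit()]})], DEFS)
        assert asg[0].block_label == "F"
        assert not asg[0].adjacency_consistent

    def test_adjacency_breaks_tie(self):
        # middle locus hits both F and R equally well; neighbors are F
        loci = [
            ("L1", {"m1": [hit(q="m1")]}),
            ("L2", {"m2": [hit(q="m2"), hit(q="m2", pos=2_500_000)]}),
            ("L3", {"m3": [hit(q="m3")]}),
        ]
        asg = assign_blocks(loci, DEFS)
        assert [a.block_label for a in asg] == ["F", "F", "F"]
        assert asg[1].adjacency_consistent

    def test_cobin_majority_breaks_tie(self):
        # two of three member markers support F
        loci = [
            (
                "L1",
                {
                    "m1": [hit(q="m1")],
                    "m2": [hit(q="m2")],
                    "m3": [hit(q="m3", pos=2_500_000)],
                },
            )
        ]
        asg = assign_blocks(loci, DEFS)
        assert asg[0].block_label == "F"
        assert asg[0].bin_consistent

    def test_length_then_evalue_then_identity(self):
        loci = [("L1", {"m": [hit(length=65), hit(pos=2_500_000, length=60)]})]
        assert assign_blocks(loci, DEFS)[0].block_label == "F"
        loci = [("L1", {"m": [hit(e=1e-40), hit(pos=2_500_000, e=1e-30)]})]
        assert assign_blocks(loci, DEFS)[0].block_label == "F"
        loci = [("L1", {"m": [hit(ident=98.0), hit(pos=2_500_000, ident=99.9)]})]
        assert assign_blocks(loci, DEFS)[0].block_label == "R"

    def test_unresolvable_tie_flagged_unassigned(self):
        loci = [("L1", {"m": [hit(), hit(pos=2_500_000)]})]
        a = assign_blocks(loci, DEFS)[0]
        assert a.block_label is None
        assert a.tie_unresolved

    def test_no_invented_labels_and_truth_recovery(self, rng):
        # planted truth: alternating blocks along one LG; every candidate
        # set contains the truth, adjacency-informative loci recover it.
        planted = ["F"] * 5 + ["R"] * 5 + ["F"] * 5
        loci = []
        for i, label in enumerate(planted):
            pos = 100 if label == "F" else 2_500_000
            hits = {f"m{i}": [hit(q=f"m{i}", pos=pos)]}
            if rng.random() < 0.4:  # add a decoy candidate
                hits[f"m{i}"].append(hit(q=f"m{i}", chrom="chr2", length=55))
            loci.append((f"L{i}", hits))
        asg = assign_blocks(loci, DEFS)
        for a, label in zip(asg, planted):
            assert a.block_label == label
        # labels only ever drawn from candidate sets
        for (lid, hits), a in zip(loci, asg):
            cands = {b for hs in hits.values() for h in hs for b in blocks_for_hit(h, DEFS)}
            assert a.block_label in cands


# --- synteny calling -------------------------------------------------------

def assignment(i, label, ident=99.5):
    chrom = {"J": "chr3", "C": "chr2", "F": "chr1"}[label]
    return BlockAssignment(f"x{i}", label, [hit(q=f"x{i}", chrom=chrom, ident=ident)])


def oracle_calls(labels, idents, floor=99.0):
    """Brute-force run enumeration over an assigned-label sequence."""
    calls, i = [], 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        n = j - i
        if n >= 3:
            calls.append((labels[i], "synteny_block", i, j - 1))
        elif all(idents[k] >= floor for k in range(i, j)):
            calls.append((labels[i], "insertion", i, j - 1))
        i = j
    return calls


class TestCallSynteny:
    def test_three_in_a_row_is_block(self):
        asg = [assignment(i, "J") for i in range(3)]
        calls = call_synteny_blocks(asg, [0.0, 1.0, 2.0], lg="A05")
        assert [(c.block_label, c.kind) for c in calls] == [("J", SyntenyKind.SYNTENY_BLOCK)]

    def test_short_low_identity_run_uncalled(self):
        asg = [assignment(i, "J", ident=95.0) for i in range(2)]
        assert call_synteny_blocks(asg, [0.0, 1.0]) == []

    def test_insertion_within_block(self):
        # J,J,J,C,J,J,J with the C locus at 100 % identity
        labels = ["J", "J", "J", "C", "J", "J", "J"]
        asg = [
            assignment(i, l, ident=100.0 if l == "C" else 99.5)
            for i, l in enumerate(labels)
        ]
        calls = call_synteny_blocks(asg, [float(i) for i in range(7)], lg="A05")
        kinds = [(c.block_label, c.kind) for c in calls]
        assert ("C", SyntenyKind.INSERTION) in kinds
        assert all(
            k is SyntenyKind.SYNTENY_BLOCK for b, k in kinds if b == "J"
        )

    def test_unassigned_transparent_by_default(self):
        asg = [assignment(0, "J"), BlockAssignment("gap", None), assignment(2, "J"), assignment(3, "J")]
        calls = call_synteny_blocks(asg, [0.0, 1.0, 2.0, 3.0])
        assert [(c.kind, c.locus_count) for c in calls] == [(SyntenyKind.SYNTENY_BLOCK, 3)]
        strict = call_synteny_blocks(asg, [0.0, 1.0, 2.0, 3.0], break_on_unassigned=True)
        assert all(c.kind is not SyntenyKind.SYNTENY_BLOCK for c in strict)

    def test_empty_lg(self):
        assert call_synteny_blocks([], []) == []

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seq=st.lists(st.sampled_from("JCF"), min_size=1, max_size=30),
        hi=st.lists(st.booleans(), min_size=30, max_size=30),
    )
    def test_matches_run_enumeration_oracle(self, seq, hi):
        idents = [100.0 if h else 95.0 for h in hi[: len(seq)]]
        asg = [assignment(i, l, ident=idents[i]) for i, l in enumerate(seq)]
        pos = [float(i) for i in range(len(seq))]
        got = [
            (c.block_label, c.kind.value, c.first_index, c.last_index)
            for c in call_synteny_blocks(asg, pos)
        ]
        assert got == oracle_calls(list(seq), idents)
        # spans never overlap and cover only assigned loci
        spans = [(c.first_index, c.last_index) for c in call_synteny_blocks(asg, pos)]
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 < a2


# --- genome specificity ----------------------------------------------------

GENOME_OF = {"Ar": "A", "An": "A", "Bj": "B", "Cn": "C"}


class TestSpecificity:
    def test_unique_single_hit(self):
        assert genome_specificity([hit(genome="Ar")], GENOME_OF) is Specificity.UNIQUE_A

    def test_two_genomes_multi(self):
        hits = [hit(genome="Ar"), hit(genome="Cn", chrom="C01")]
        assert genome_specificity(hits, GENOME_OF) is Specificity.MULTI

    def test_two_locations_one_genome_multi(self):
        hits = [hit(genome="Ar"), hit(genome="Ar", pos=5_000_000)]
        assert genome_specificity(hits, GENOME_OF) is Specificity.MULTI

    def test_no_hits_unaligned(self):
        assert genome_specificity([], GENOME_OF) is Specificity.UNALIGNED

    def test_counts_equal_independent_tally(self, rng):
        genomes = np.array(["Ar", "An", "Bj", "Cn"])
        hits_by_marker = {}
        for i in range(200):
            k = int(rng.integers(0, 3))
            hits_by_marker[f"m{i}"] = [
                hit(q=f"m{i}", genome=str(rng.choice(genomes)), pos=int(rng.integers(1, 10) * 1000))
                for _ in range(k)
            ]
        counts = specificity_counts(hits_by_marker, GENOME_OF)
        assert sum(counts.values()) == 200
        tally = {s: 0 for s in Specificity}
        for hits in hits_by_marker.values():
            locs = {(GENOME_OF[h.subject_genome], h.subject_chrom, h.subject_start) for h in hits}
            gens = {g for g, _, _ in locs}
            if not locs:
                tally[Specificity.UNALIGNED] += 1
            elif len(locs) == 1:
                tally[Specificity[f"UNIQUE_{gens.pop()}"]] += 1
            else:
                tally[Specificity.MULTI] += 1
        assert counts == tally
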