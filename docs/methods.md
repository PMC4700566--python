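# Methods

This note records the models the package implements, the defaults it ships,
and the choices made where the underlying procedures were genuinely open.

## Bin loci and marker quality control

An F2 population of n individuals observes at most 2n informative gametes,
so markers separated by less than one recombination event collapse onto a
shared position ("bin locus").  Mapping software decides this implicitly
during ordering; `classify_bins` makes it explicit and reproducible: two
markers are compatible when no individual carries non-missing, disagreeing
calls for both, and bins are connected components of the compatibility
graph.  This is deliberately missing-tolerant — a marker with heavy
missingness can join a bin it never contradicts — which mirrors how bin
representatives are chosen (least missing data, ties broken
lexicographically by id for determinism).  Markers with every call missing
are compatible with everything; they are held out as flagged singletons
rather than being allowed to glue unrelated bins together.

QC thresholds follow the marker system's conventions: call rate strictly
above 0.90, SNP quality Q strictly above 2.0 (Q is −log10 of the minimum
false-discovery rate at which the call is significant; presence/absence
markers carry no Q), and missing-data caps of ≤ 10 % for a mapping
population and ≤ 5 % for a diversity panel, with bin representatives in the
mapping preset additionally capped at 5 %.  Strict versus inclusive
comparisons match the wording of the thresholds ("> 90 %", "≤ 5 %").

Segregation distortion is a Pearson χ² against the F2 expectation (3:1 for
dominant presence/absence, 1:2:1 for codominant), df = classes − 1, with no
multiple-testing correction.  Distorted markers are flagged, never silently
removed; dropping them is an explicit caller decision (default α = 0.05).

## Resolution model

The shortest resolvable genetic distance is 100/n cM (one recombinant among
n F2 individuals on the percent scale); for the emulated population of 168
that is 0.5952 cM, reported at one decimal as 0.6.  Rearrangements spanning
up to twice the bound are classed "small".  Comparisons use the unrounded
bound; reports use the rounded one.  The genetic↔physical conversion
(genome_size_mb / map_length_cm, 485/828.4 ≈ 0.585 Mb/cM by default) is
kept separate from the 1 Mb small/large threshold used for
assembly-to-assembly calls: the two constants are not forced to agree, and
both are configurable.

## Ancestral-block assignment and synteny

Alignments are 12-column BLAST tabular records, coordinate-normalized on
read.  Two filter presets exist: `ancestral` (E ≤ 1e−6, length strictly
over 40 bp) for placing 69-bp tags into ancestral-block intervals, and
`genome` (E ≤ 1e−20, length ≥ 60 bp) for whole-genome comparisons.  A hit
is placed in a block by its midpoint — blocks are megabase-scale and tags
are 69 bp, so this avoids boundary double-assignment.

Block definitions are user-supplied BED-like intervals (0-based half-open
on disk, 1-based inclusive internally) over the 24-label A–X schema; the
package does not derive block coordinates itself.

Per-locus candidates are resolved by ordered criteria — agreement with both
flanking assigned loci, agreement among co-binned markers, longest match,
smallest E, highest identity — first discriminating criterion wins, in two
passes so adjacency can use provisional assignments.  Unresolved ties stay
unassigned and flagged.  Synteny calls are maximal runs of ≥ 3 same-block
loci; 1–2-locus runs qualify as insertions only when every supporting hit
reaches the identity floor (default 99.0 %, "nearly 100 %").  Unassigned
loci are transparent by default because on real maps only a minority of
loci align at all; a strict mode that breaks runs is available.

## Rearrangement calling

Inversions: anchors on one chromosome pair, sorted by map position, receive
dense ranks in physical order (co-binned anchors share a rank, and a run
must change rank to count).  Maximal strictly decreasing rank runs of ≥ 2
anchors are candidate inversions; genetic-unit runs must span more than the
resolution bound, and a single run covering every anchor is treated as a
whole-chromosome orientation flip, not an inversion.  Restricting to
strictly monotone runs implements the exclusion of "complicated" jumbled
regions: a scrambled, non-monotone region decomposes into short runs that
fail the span test rather than producing one unsupported event.

Genome-pair translocations: on each source chromosome the modal target
chromosome is "home"; maximal runs of ≥ min_run anchors sharing a non-home
target become events.  "More than four successive genes" is read strictly
as min_run = 5; min_run is exposed for the inclusive reading.

Map-based translocations are candidates only: markers of one locus — or of
two adjacent loci when neither qualifies alone — hitting ≥ 2 target
chromosomes with unique 100 %-identity alignments (tolerance 1e−9 on the
identity).  Confirmation re-runs detection under `n_reps` seeded random
permutations of the locus order within ±`window` loci of the candidate
(defaults 20 and 2); the candidate must recur in every replicate.  This
permutation stands in for re-running the original mapping software, which
is out of scope; `n_reps = 0` confirms vacuously and is flagged.

Event summaries are per-chromosome × per-comparison count tables whose
totals row is always recomputed from the rows; the large-event total is
Σ(total − small) over comparisons.

## Population genetics

Group allele frequencies: codominant markers contribute dosage/(2·n),
dominant markers band-presence/n.  Dominant markers are scored on band-state
frequencies without a Hardy–Weinberg correction — the marker system mixes
SNPs and presence/absence tags and no correction is defensible for the
mixture; this overstates distances slightly for dominant-heavy panels and
is a documented limitation.

Nei (1972) standard distance is computed over markers with data in both
groups; complete non-identity returns +infinity, which UPGMA refuses rather
than silently capping (an explicit cap is available).  "Nei's coefficient"
is ambiguous across software; the 1972 standard distance is the default and
the implementation point for alternatives.

UPGMA merges the closest pair at height d/2 with size-weighted distance
averaging.  Ties are broken by the smallest member leaf labels, making the
tree invariant to input order; children are ordered the same way so Newick
output is canonical.  The implementation is in-package because the
tie-break and node-height access are contractual; scipy's independent
average-linkage cophenetic matrix is the test oracle.

Evanno ΔK aligns replicates by id and computes
mean_r |L_r(K+1) − 2L_r(K) + L_r(K−1)| / sd(L(K)) with the sample sd
(ddof = 1); with balanced replicates this equals the classical mean-based
second difference.  Interior K only; zero sd is an error.  The MCMC itself
is consumed as a (K, replicate, ln_prob) table, never run.

## Synthetic data

The generators' defaults encode the study design they emulate: an F2 of 168
individuals over 18 linkage groups whose lengths, single/bin locus counts
and marker totals match the published map table (1570 loci, 3329 markers;
`study_map_spec` randomizes only positions and bin sizes); a diversity
panel of K = 3 populations with 8 accessions each at F = 0.3, L = 1000
markers, mimicking a three-species, 26-accession panel.  The default
missing rate is 3 % — mapping markers were selected at ≤ 5–10 % missingness,
so a mid-single-digit rate is realistic.  Marker types are an even SNP /
presence-absence mix.

F2 gametes follow a Markov chain along each linkage group with switch
probability equal to the adjacent-interval recombination fraction; Haldane
(no interference) is the default because its r = (1 − e^(−2d/100))/2 gives
a closed-form oracle, Kosambi is available by flag.  Distortion is modeled
as gametic selection (carriers of the disfavored allele survive with
probability 1 − s, rejection-sampled) — one concrete mechanism among
several consistent with observed distortion.  Missingness is MCAR.

Genome anchor sets are an evenly spaced backbone with sub-spacing jitter
(guaranteeing collinearity), into which inversions (reversed coord_b order)
and translocations (rewritten target chromosome) are planted
non-overlappingly.  Panels follow Balding–Nichols: ancestral frequency
p ~ U(0.05, 0.95), population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F),
genotype ~ Binomial(2, membership-weighted frequency).

What the simulators do not capture: linkage disequilibrium within
populations, genotyping error beyond MCAR missingness, sequence-level tag
behavior (paralogy, multi-mapping), assembly errors, and real map-order
noise.  Passing recovery tests therefore demonstrates correctness of the
detection rules under their stated assumptions, not robustness to every
artifact of real data.

## Numerical and scale choices

Acceptance-style checks run at deliberately modest sizes chosen as the
smallest that make the statistics sharp: recombination recovery uses
n = 10,000 individuals (3 binomial SEs ≈ 0.006 around r = 0.0906), cluster
recovery uses 100 seeds of a 24-accession × 1000-marker panel, planted
rearrangement recovery uses 3 chromosomes × 45 anchors.  UPGMA equivalence
is asserted to 1e−9; identity "100 %" to 1e−9; ultrametricity to 1e−9.
Published per-linkage-group and per-chromosome count tables are bundled as
inputs, and every subtotal, total and mean is recomputed from the rows at
run time (the bundled map-coverage rows sum to 1578.4 cM; means are
reported at one decimal).

Known limitations: no imputation of missing genotypes; no re-estimation of
recombination fractions (locus order and cM positions are inputs);
homoeologous-exchange and duplication/deletion events are described by the
block output but not evented; reciprocal translocation directions are
reported separately, never merged.
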