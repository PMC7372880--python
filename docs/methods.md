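# Methods

This note documents the models, conventions and design choices behind the
pipeline, in the order data flows through it.

## Coordinates, alphabets, identity

All coordinates are 0-based, half-open, on the forward strand of the input
contig; strand is stored separately. Nucleotides are uppercase `ACGTN`
(`N` translates to `X`; `X` never satisfies a motif position). Percent
identity is the number of identical aligned residue pairs in an optimal
global alignment, divided by the length of the shorter sequence — the
convention of greedy incremental clustering tools — with an
alignment-columns denominator available for sensitivity analysis.
Alignments are Needleman–Wunsch with affine gaps: BLOSUM62 with gap
open 10 / extend 0.5 for proteins, match +2 / mismatch −3 with gap
open 5 / extend 2 for nucleotides. These scoring choices are conventional
defaults; they are configurable and echoed into every run report.

All thresholds in the pipeline are inclusive (identity ≥ cutoff joins the
upper band). Boundary behavior is unit-tested at exactly 40/55/97.

## ORF model

An ORF is a maximal run within one of the six frames, from an ATG — or
from the contig edge, flagged `has_start = False` — to the first in-frame
stop codon, or the contig edge, flagged `has_stop = False`. Runs anchored
by *neither* an ATG nor a stop carry no reading-frame evidence and are not
reported; runs with one anchor are exactly the 5'- or 3'-truncated partial
genes the curation stage must classify. Nested ORFs at internal ATGs are
not reported separately. The discovery scan uses `min_aa = 100` so that
partial CYPs (well under 400 aa) are still seen; the ≥ 400 aa requirement
applies only at full-length curation.

## CYP detection and curation

Detection replaces a profile-HMM search with deterministic degenerate
patterns for the four motifs every catalytically competent plant CYP
carries, ordered I-helix < ExxR < PERF < heme along the protein:

| motif   | pattern      | tolerance                         |
|---------|--------------|-----------------------------------|
| I-helix | `AGx[DE]T`   | ≤ 1 mismatch                      |
| ExxR    | `ExxR`       | exact                             |
| PERF    | `FxPxRx`     | ≤ 1 mismatch                      |
| heme    | `FxxGxRxCxG` | C invariant, ≤ 2 mismatches elsewhere |

The patterns are the union of the A-type and non-A-type consensus forms,
so one model set detects both groups. A protein is CYP-like when a heme
hit plus at least two of the other three motifs can be selected in the
canonical order without overlap; the selection minimizes total mismatches
and then prefers the earliest positions, and is recorded per call. Random
sequence occasionally contains a spurious zero-mismatch `ExxR` (expected
about one per 400 residues), so the selected K-helix can differ from a
planted one in a minority of synthetic proteins; consensus calling is
robust to this because the planted instances dominate every column. The
heme selection is anchored by the invariant cysteine and is empirically
exact on the synthetic sets.

Full length requires: ATG start with leading M, in-contig stop, ≥ 400
residues, and the heme cysteine offset (protein length minus cysteine
index) inside [35, 65] — a deliberately tolerant window around the
canonical ~50 residues. Every violated clause is recorded
(`no_start`, `no_stop`, `too_short`, `heme_offset`, `no_heme`,
`bad_order`), so the synthetic tests can assert not just the verdict but
its reason.

pI uses a fixed Bjellqvist-style pKa table (N-term 7.5, C-term 3.55,
D 4.05, E 4.45, H 5.98, C 9.0, Y 10.0, K 10.0, R 12.0) and bisection on
pH ∈ [0, 14] to |charge| < 1e-4; a 0.001-pH grid scan is the test oracle.
Molecular weight is the sum of average residue masses plus one water,
reported in kDa.

## Redundancy removal and contig merging

Deduplication is greedy incremental clustering: sequences sorted longest
first (ties by id), each joining the first earlier representative at or
above the threshold. The pipeline runs a 100 % pass before merging and a
97 % pass on partial contigs afterwards, mirroring the two-stage
convention of transcriptome CYP surveys. An optional shared-k-mer screen
(k = 11 nucleotide, k = 5 protein) skips pairs that provably cannot reach
the threshold; a gapless pair at identity *p* destroys at most *k*
k-mers per mismatch, giving the bound used, and a 50 % safety factor
absorbs gapped alignments. The screen is validated by comparing screened
and unscreened clusterings on the synthetic corpus.

Contig merging joins pairs whose longest suffix–prefix overlap spans at
least 15 % of the shorter contig at ≥ 97 % ungapped identity, takes the
longer contig's base at disagreements, and iterates to a fixpoint with a
deterministic processing order. Candidate pairs are screened by shared
11-mers (at least 20, sound for the identity/overlap regime the config can
demand; below that regime every pair is tested).

## Nomenclature

Queries are classified against a labelled reference panel by maximum
global identity (ties by panel order): ≥ 97 % inherits the reference's
full name as an allelic variant, ≥ 55 % is a new member of the
reference's subfamily, ≥ 40 % a new subfamily of its family, and below
40 % a new family whose clan is inherited from the best hit but flagged
low-confidence — there is no accepted rule for clan placement below the
family cutoff, so the flag marks these calls for manual review. A-type
status is clan CYP71 membership. Note that with a panel of subfamily
representatives, an allelic variant of an *unnamed* member classifies as a
new member of the correct subfamily (its ≥ 97 % partner is not in the
panel); variant status relative to the panel is exercised separately in
tests.

## Logos and consensus

Windows are cut at each call's selected motif hit. The published A-type
and non-A-type logos frame the same anchors slightly differently, so the
builder supports asymmetric flanks, with presets per motif and group
(e.g. the heme window opens one residue before the detection anchor).
Information content is the uncorrected logo convention
`IC = log2(20) − H` with gaps/`X` excluded from the column denominator —
chosen so pure, uniform and two-letter columns have the exact analytic
values 4.3219 / 0 / 3.3219 bits; a Schneider-style small-sample correction
is available behind a flag. Consensus: a residue strictly above the
majority fraction (default 0.5) prints as itself; else if the top two
jointly reach 0.8 and each reaches 0.25, `[X/Y]` alphabetically; else
`x`. The majority rule is strict-greater so an exact 50/50 two-residue
column prints as a pair rather than arbitrarily as one letter.

## Microsatellites

Perfect tandem repeats of primitive 2–6 nt units: at least six units for
dinucleotides, five for tri- through hexanucleotides. A run reportable at
several unit lengths is reported once at the smallest (primitive) unit,
which also excludes mononucleotide runs by construction. Unit labels are
canonicalized to the lexicographically smallest rotation; no
reverse-complement folding because transcripts are stranded. Repeat counts
are the integer part of the run. Simple hits separated by ≤ 100 nt are
additionally grouped into compound hits; summaries report simple counts
per unit length and compound events separately, covering both counting
conventions.

## Family-count statistics

The bundled fixture is a 54-family × 5-species full-length CYP count
table (9 clans). It is guarded: the species column sums must equal
221/157/462/374/244 before any statistic is reported, and each comparison
records its expected degrees of freedom. Pearson chi-square is computed
without continuity correction after dropping zero-margin rows/columns
(recorded, not silent); p-values come from the regularized upper
incomplete gamma function and are verified against an independent
series/continued-fraction implementation to 1e-10 for df 1–250. Five of
the six published comparisons reproduce exactly at one decimal with their
printed df; the two-species family-level comparison computes X² = 17.9
(df 37 as printed) from the published table, and the report surfaces the
discrepancy with the printed 18.6 rather than adjusting either number —
no transfer of counts between families consistent with the other five
statistics yields 18.6, so the printed value cannot be derived from the
printed table.

## Trees and pairing

Distances are p-distances (1 − identity/100) from pairwise global
alignment; trees are canonical Saitou–Nei neighbor joining with
deterministic tie-breaking (smallest sorted label pair) and negative
branch estimates clamped to zero with a log entry. NJ is exact on
additive matrices (path-length error < 1e-9 in tests, cross-checked
against an independent implementation). Per family, allelic variants are
collapsed (97 % protein clustering per species) before tree building so
the pairing statistic measures orthology rather than allelism. The
pairing statistic is the fraction of one species' leaves whose nearest
non-self leaf (by distance, ties by label) belongs to the other species;
on perfect planted pairs it is 1.0, and under the default study
conditions (20 % missing orthologs, 30 % partials) its expectation is
roughly 0.8 × 0.7 ≈ 0.56 among full-length leaves.

## The synthetic generator

The generator defines the study conditions all recovery claims refer to.
Defaults: 16 families (half A-type, i.e. clan CYP71), 3 subfamilies per
family, 6 members per subfamily — every member has a home transcript in
species `spA` and an `spB` ortholog at 90 % identity with probability
0.8; transcripts acquire allelic variants with probability 0.25 and are
truncated (5' by 20–60 % of the CDS, or 3' by the stop plus ≤ 30 codons)
with probability 0.3; 100 decoy ORF transcripts; UTRs of 40–120 nt; 55
planted SSRs spanning unit lengths 2–6 (30 di-, 10 tri-, 5 each
tetra/penta/hexa). This yields ~600 CYP transcripts (comfortably above
500 at any seed), ~450 of them full length. Identity bands place subfamily seeds at 47 % to their family
seed, members at 65 % to their subfamily seed, and alleles at 99 %
nucleotide identity to their source CDS (inheriting its codons), so the
40/55/97 cutoffs separate cleanly and allelic variants collapse at both
the nucleotide and protein level.

Construction details that matter for the tests: proteins are 460–601
residues with single-residue runs capped at four (tryptophan and
methionine have a single codon, so a five-run would force a perfect
trinucleotide repeat in every possible coding sequence and collide with
the SSR ground truth); the heme cysteine is planted 46–54 residues from
the C-terminus; motif layouts follow the A-type/non-A-type consensus
forms, with unconstrained positions drawn uniformly over the 20 amino
acids
(uniform background makes the information content of a free column 0
bits in expectation); the `[D/E]` I-helix column of non-A-type proteins
is cycled deterministically (D, E, D, E, A) across full-length
transcripts so its column frequencies land in the pair-rule region
regardless of which transcripts end up partial. Reverse translation draws
synonymous codons uniformly; a forced in-frame stop just upstream of the
ATG pins the ORF start. Each transcript is rejection-sampled until its
only detectable SSRs are the planted ones, and each decoy until none of
its ORFs is CYP-like — so sensitivity/specificity claims are exact by
construction, not approximate.

What passing these tests shows — and does not show. They demonstrate that
the pipeline's logic is correct under its own assumptions: clean
substitution-only divergence, uniform background composition, planted
motifs that match the detection patterns, no indels, no sequencing error,
no chimeric or fragmented assemblies beyond simple truncation. Real
assemblies violate all of these to varying degrees; on real data the
motif tolerances and the heme-offset window become genuine sensitivity
knobs, and the reported failure reasons are the intended audit trail.

## Problem sizes and determinism

Default-scale runs (~700 contigs) complete in a few minutes on one CPU;
unit and property tests use smaller configurations (e.g. 3 × 2 × 2
families for truth-table checks, ≤ 12 sequences for clustering oracles,
≤ 8 residues for exhaustive alignment enumeration, 4–8 taxa for NJ
exactness). All randomness flows from a single seeded generator;
identical configurations produce byte-identical outputs, which the test
suite asserts by comparing full output trees across double runs.

## Known limitations

* Detection is pattern-based; highly divergent CYPs that a profile HMM
  would catch through distributed signal can be missed, and the fixed
  four-motif order rejects genuine rearrangements (rare in plant CYPs).
* The nomenclature stage requires a labelled panel; it issues provisional
  placements, not official names.
* Contig merging is suffix–prefix only (no containment-aware consensus,
  no read-level evidence).
* NJ trees are distance-based substitutes for likelihood phylogenies and
  carry no support values; the pairing statistic is a
  topological-neighborhood summary, not a test of orthology.
* The pI/MW calculators use a fixed pKa table and average masses; they
  match the cited web tool's conventions, not experimental values.
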