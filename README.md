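# cypminer

Mining, curation and comparative analysis of cytochrome P450 (CYP) gene
families in de novo plant transcriptome assemblies.

Plant CYP monooxygenases form one of the largest enzyme families and drive
much of plant secondary metabolism. Cataloguing a species' CYP complement
from RNA-seq assemblies is a standard first step toward finding pathway
candidates, but it involves a long chain of small decisions: which ORFs are
CYP-like, which transcripts are full length, how to collapse redundant
contigs, how to name what remains, and how to compare the resulting family
complements across species. `cypminer` implements that chain as a tested,
deterministic pipeline, aimed at researchers who want each step inspectable
rather than buried in a one-off script collection.

## What it does

* **Six-frame ORF mining** (`orfmine`) over assembled contigs, retaining
  edge-open runs as partial-gene candidates.
* **Motif-anchored CYP detection** (`cyp_detect`): deterministic degenerate
  scanning for the four hallmark motifs in their canonical order
  — I-helix `AGx[D/E]T`, K-helix `ExxR`, PERF `FxPxRx`, and the
  heme-binding signature `FxxGxRxCxG` whose invariant cysteine coordinates
  the heme iron. A protein is *full length* when it starts with M, ends at
  a stop codon, spans ≥ 400 residues, and carries the heme cysteine about
  50 residues (window 35–65) from the C-terminus; every violated clause is
  reported as a failure reason. Theoretical pI (Bjellqvist pKa set,
  bisection) and molecular weight are computed for full-length calls.
* **Redundancy handling** (`redundancy`): optimal Needleman–Wunsch global
  identity (affine gaps, BLOSUM62 for proteins), CD-HIT-style greedy
  clustering with inclusive thresholds, and suffix–prefix contig merging
  (≥ 97 % identity over ≥ 15 % of the shorter contig).
* **Nomenclature** (`nomenclature`): classification against a labelled
  reference panel with the standard cutoffs — ≥ 40 % amino-acid identity
  joins a family, ≥ 55 % a subfamily, ≥ 97 % marks an allelic variant —
  and the A-type (CYP71 clan) / non-A-type split.
* **Sequence logos** (`motifs_logo`): per-column information content
  `IC = log2(20) − H` and consensus strings in the field's notation
  (`x`, `[D/E]`).
* **Microsatellites** (`ssrfind`): MISA-style perfect-repeat detection
  (di ≥ 6 units, tri–hexa ≥ 5 units, compounds within 100 nt).
* **Family statistics** (`famstats`): clan/family × species contingency
  tables and Pearson chi-square tests, with a bundled five-species CYP
  count table (two *Jacobaea* species, sunflower, lettuce, Arabidopsis)
  whose published comparisons the package recomputes and checks.
* **Phylogenies** (`phylo`): p-distance neighbor-joining trees per family
  (exact on additive matrices) and an ortholog-pairing statistic: the
  fraction of one species' leaves whose nearest neighbor belongs to the
  other species.
* **Synthetic transcriptomes** (`synthgen`): a seeded generator that plants
  families, subfamilies and allelic variants in controlled identity bands,
  ortholog pairs across two species tags, UTRs with microsatellites,
  truncated partials and motif-free decoys — with a full truth table, so
  every stage above is testable without downloading anything.

## Worked example

```bash
cypminer all --seed 1 --out run1
```

simulates a two-species transcriptome (16 families × 3 subfamilies × 6
members, plus orthologs, alleles, partials and 100 decoys — 714 contigs)
and runs every stage. The run prints the curation summary

```json
{"n_full_length": 463, "n_partial_contigs": 151, "n_partial_clusters": 151}
```

meaning 463 contigs passed both full-length criteria and 151 were CYP-like
but partial — exactly matching the generator's truth table. In
`run1/consensus.json` the recovered motif consensi are

```json
{"A-type":     {"heme": "PFGxGRRxCP",  "PERF": "FxPERF", "I-helix": "AGxDT",      "ExxR": "ExxR"},
 "non-A-type": {"heme": "xFxxGxRxCxG", "PERF": "FxPxRx", "I-helix": "AGx[D/E]TT", "ExxR": "ExxR"}}
```

— the A-type and non-A-type signature forms the generator planted.
`run1/table_stats.json` holds the five-species count-table statistics, e.g.
the clan-level comparison `X² = 42.0, df = 32` (distributions comparable
across species) and the family-level `X² = 466.7, df = 212` (strongly
heterogeneous, driven by the multi-family clans). The statistics
subcommand prints the same with a pass/fail column:

```bash
cypminer stats
```

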