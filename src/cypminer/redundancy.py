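"""Pairwise global identity, greedy identity clustering and contig merging.

The percent-identity engine behind the nomenclature cutoffs (40/55/97 %) and
the redundancy-removal passes.  Alignments are optimal Needleman-Wunsch with
affine gaps via Biopython's :class:`Bio.Align.PairwiseAligner`; the percent
identity uses the shorter-sequence denominator by default (the convention of
greedy incremental clustering tools such as CD-HIT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import NucleotideRecord, ProteinRecord

logger = logging.getLogger(__name__)

Record = NucleotideRecord | ProteinRecord


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    matches: int
    identity_pct: float
    score: float


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scoring with affine gap costs (open includes first gap)."""

    matrix: str | None = "BLOSUM62"  # None -> match/mismatch
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 10.0
    gap_extend: float = 0.5


#: Protein default: BLOSUM62, gap open 10 / extend 0.5.
PROTEIN_SCORING = ScoringScheme()
#: Nucleotide default: match +2 / mismatch -3, gap open 5 / extend 2.
NUCLEOTIDE_SCORING = ScoringScheme(matrix=None, match=2.0, mismatch=-3.0,
                                   gap_open=5.0, gap_extend=2.0)


@dataclass(frozen=True)
class ClusterConfig:
    threshold: float = 97.0
    level: Literal["nucleotide", "protein"] = "nucleotide"
    denominator: Literal["shorter_seq", "alignment_cols"] = "shorter_seq"
    kmer_prefilter: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 100:
            raise ValueError("threshold must be in (0, 100]")


@dataclass(frozen=True)
class MergeConfig:
    min_identity: float = 97.0
    min_overlap_frac: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if not 0 < self.min_overlap_frac <= 1:
            raise ValueError("min_overlap_frac must be in (0, 1]")


@dataclass
class Cluster:
    representative: Record
    members: list[tuple[Record, float]] = field(default_factory=list)


_ALIGNER_CACHE: dict[ScoringScheme, Align.PairwiseAligner] = {}


def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aln = _ALIGNER_CACHE.get(scoring)
    if aln is not None:
        return aln
    aln = Align.PairwiseAligner()
    aln.mode = "global"
    if scoring.matrix is not None:
        aln.substitution_matrix = substitution_matrices.load(scoring.matrix)
    else:
        aln.match_score = scoring.match
        aln.mismatch_score = scoring.mismatch
    aln.open_gap_score = -scoring.gap_open
    aln.extend_gap_score = -scoring.gap_extend
    _ALIGNER_CACHE[scoring] = aln
    return aln


def global_align(
    a: str,
    b: str,
    scoring: ScoringScheme = PROTEIN_SCORING,
    denominator: Literal["shorter_seq", "alignment_cols"] = "shorter_seq",
) -> AlignmentResult:
    """Optimal global alignment of two sequences with affine gap costs.

    Returns the first optimal alignment in Biopython's deterministic
    enumeration order.  ``identity_pct = 100 * matches / denominator`` where
    the denominator is the shorter input length (default) or the number of
    alignment columns.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    alignment = _aligner(scoring).align(a, b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    matches = sum(x == y and x != "-" for x, y in zip(ga, gb))
    denom = min(len(a), len(b)) if denominator == "shorter_seq" else len(ga)
    return AlignmentResult(
        aligned_a=ga,
        aligned_b=gb,
        matches=matches,
        identity_pct=100.0 * matches / denom,
        score=float(alignment.score),
    )


def global_identity(
    a: str,
    b: str,
    level: Literal["nucleotide", "protein"] = "protein",
    denominator: Literal["shorter_seq", "alignment_cols"] = "shorter_seq",
) -> float:
    """Percent global identity with the level's default scoring."""
    scoring = PROTEIN_SCORING if level == "protein" else NUCLEOTIDE_SCORING
    return global_align(a, b, scoring, denominator).identity_pct


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _prefilter_passes(shared: int, shorter_len: int, k: int,
                      threshold: float) -> bool:
    """Conservative shared-k-mer screen.

    A gapless pair at >= ``threshold`` percent identity has at most
    ``m = shorter * (1 - t/100)`` mismatches, each destroying at most ``k``
    k-mers, so it shares at least ``(shorter - k + 1) - k*m`` k-mers.  A 50%
    safety factor absorbs gapped alignments; pairs below half that bound
    cannot reach the threshold and are skipped without aligning.
    """
    m = shorter_len * (1.0 - threshold / 100.0)
    bound = (shorter_len - k + 1) - k * m
    return shared >= 0.5 * max(bound, 0.0)


def greedy_cluster(
    seqs: Sequence[Record], config: ClusterConfig = ClusterConfig()
) -> list[Cluster]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are processed longest first (ties by id, ascending); each
    sequence joins the first earlier representative with identity >= the
    threshold (inclusive), else founds a new cluster.  The result partitions
    the input.  With ``kmer_prefilter`` enabled, pairs sharing too few
    k-mers (k=11 nucleotide, k=5 protein) to possibly reach the threshold
    are skipped without alignment.
    """
    if not seqs:
        raise ValueError("greedy_cluster requires a nonempty input")
    order = sorted(seqs, key=lambda r: (-len(r.seq), r.id))
    k = 11 if config.level == "nucleotide" else 5
    kmers: dict[str, set[str]] = {}
    if config.kmer_prefilter:
        kmers = {r.id: _kmer_set(r.seq, k) for r in order}
    clusters: list[Cluster] = []
    for rec in order:
        placed = False
        for cl in clusters:
            rep = cl.representative
            if config.kmer_prefilter:
                shared = len(kmers[rec.id] & kmers[rep.id])
                shorter = min(len(rec.seq), len(rep.seq))
                if not _prefilter_passes(shared, shorter, k, config.threshold):
                    continue
            ident = global_identity(
                rep.seq, rec.seq, config.level, config.denominator
            )
            if ident >= config.threshold:
                cl.members.append((rec, ident))
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=rec))
    return clusters


def _overlap_identity(suffix: str, prefix: str) -> float:
    """Ungapped identity of equal-length suffix/prefix windows (percent)."""
    matches = sum(x == y for x, y in zip(suffix, prefix))
    return 100.0 * matches / len(suffix)


def _best_overlap(a: str, b: str, cfg: MergeConfig) -> int | None:
    """Longest suffix(a)/prefix(b) overlap meeting the merge predicate."""
    import numpy as np

    min_len = max(1, int(round(cfg.min_overlap_frac * min(len(a), len(b)))))
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    for L in range(min(len(a), len(b)), min_len - 1, -1):
        matches = int((xa[-L:] == xb[:L]).sum())
        if 100.0 * matches / L >= cfg.min_identity:
            return L
    return None


def _merge_candidates(pool: Sequence[NucleotideRecord],
                      cfg: MergeConfig) -> set[tuple[int, int]] | None:
    """Ordered index pairs worth testing for overlap, via shared 11-mers.

    Returns ``None`` (meaning: test every pair) when contigs are short
    enough that the k-mer screen could be unsound.  A true overlap of
    length >= 100 nt at >= 90 % identity must share well over 10 exact
    11-mers, so pairs sharing fewer are skipped.
    """
    k = 11
    if not pool:
        return None
    # soundness: an overlap of length L at identity p keeps at least
    # (L - k + 1) - k*L*(1-p) exact k-mers; require that bound >= 20 at the
    # smallest overlap the config can demand, else screen nothing.
    min_overlap = min(len(r.seq) for r in pool) * cfg.min_overlap_frac
    p = cfg.min_identity / 100.0
    bound = (min_overlap - k + 1) - k * min_overlap * (1.0 - p)
    if bound < 20:
        return None
    postings: dict[str, list[int]] = {}
    for idx, rec in enumerate(pool):
        for kmer in _kmer_set(rec.seq, k):
            postings.setdefault(kmer, []).append(idx)
    counts: dict[tuple[int, int], int] = {}
    for ids in postings.values():
        if len(ids) < 2 or len(ids) > 50:
            continue
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                counts[(ids[x], ids[y])] = counts.get((ids[x], ids[y]), 0) + 1
    cands = set()
    for (i, j), c in counts.items():
        if c >= 10:
            cands.add((i, j))
            cands.add((j, i))
    return cands


def _merge_pair(a: NucleotideRecord, b: NucleotideRecord, L: int,
                tag: int) -> NucleotideRecord:
    # disagreements in the overlap take the base of the longer contig
    left, right = a.seq[:-L], b.seq[L:]
    ov_a, ov_b = a.seq[-L:], b.seq[:L]
    overlap = ov_a if len(a.seq) >= len(b.seq) else ov_b
    return NucleotideRecord(
        id=f"merge{tag}|{a.id}+{b.id}",
        seq=left + overlap + right,
        description=f"merged from {a.id} and {b.id} (overlap {L} nt)",
    )


def merge_assemblies(
    contigs_a: Sequence[NucleotideRecord],
    contigs_b: Sequence[NucleotideRecord] = (),
    config: MergeConfig = MergeConfig(),
) -> list[NucleotideRecord]:
    """Iteratively merge contigs by suffix-prefix overlap to a fixpoint.

    A pair merges when its best (longest) suffix-prefix overlap spans at
    least ``min_overlap_frac`` of the shorter contig at
    ``min_identity`` percent ungapped identity.  Disagreements in the
    overlap take the base of the longer contig.  Processing order is length
    descending, id ascending; merging repeats until no pair satisfies the
    predicate.
    """
    pool = list(contigs_a) + list(contigs_b)
    tag = 0
    changed = True
    while changed:
        changed = False
        pool.sort(key=lambda r: (-len(r.seq), r.id))
        n = len(pool)
        cands = _merge_candidates(pool, config)
        for i in range(n):
            if changed:
                break
            for j in range(n):
                if i == j or (cands is not None and (i, j) not in cands):
                    continue
                a, b = pool[i], pool[j]
                L = _best_overlap(a.seq, b.seq, config)
                if L is not None:
                    tag += 1
                    merged = _merge_pair(a, b, L, tag)
                    pool = [r for k, r in enumerate(pool) if k not in (i, j)]
                    pool.append(merged)
                    changed = True
                    break
    return pool
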