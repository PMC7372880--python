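"""Six-frame open-reading-frame extraction from transcriptome contigs.

An ORF is a maximal run in one frame from an ATG (or the contig edge, in
which case ``has_start`` is false) to the first in-frame stop codon (or the
contig edge, then ``has_stop`` is false).  Edge-open ORFs are retained and
flagged: they are the raw material for partial gene calls.  Nested ORFs at
internal ATGs are not reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .seqio import CODON_TABLE, NucleotideRecord, ProteinRecord, translate


@dataclass(frozen=True)
class OrfCandidate:
    """A predicted coding region on a contig.

    ``nt_start``/``nt_end`` are 0-based half-open on the forward strand of
    the contig regardless of ``strand``; the span includes the stop codon
    when ``has_stop`` is true.
    """

    contig_id: str
    frame: int
    strand: str
    nt_start: int
    nt_end: int
    protein: ProteinRecord
    has_start: bool
    has_stop: bool

    def __post_init__(self) -> None:
        if (self.nt_end - self.nt_start) % 3 != 0:
            raise ValueError("ORF span must be a whole number of codons")
        if self.has_start and not self.protein.seq.startswith("M"):
            raise ValueError("has_start requires the protein to begin with M")


def _codon(seq: str, i: int) -> str:
    c = seq[i : i + 3]
    return "X" if "N" in c else CODON_TABLE[c]


def _scan_frame(seq: str, frame: int):
    """Yield (codon_start_idx, codon_end_idx, has_start, has_stop) runs."""
    n_codons = (len(seq) - frame) // 3
    if n_codons == 0:
        return
    start = 0  # codon index where current run began
    run_open_at_edge = True
    i = 0
    while i < n_codons:
        aa = _codon(seq, frame + 3 * i)
        if aa == "*":
            yield start, i, run_open_at_edge, True
            start = i + 1
            run_open_at_edge = False
        i += 1
    if start < n_codons:
        yield start, n_codons, run_open_at_edge, False


def find_orfs(
    contig: NucleotideRecord,
    min_aa: int = 100,
    mode: Literal["all", "longest_per_contig"] = "all",
) -> list[OrfCandidate]:
    """Extract ORFs from all six frames of ``contig``.

    Returns ORFs with protein length >= ``min_aa``, sorted by protein length
    descending (ties by forward-strand start, then strand).  Coordinates map
    back to the forward strand for both strands.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    from .seqio import reverse_complement

    results: list[OrfCandidate] = []
    L = len(contig.seq)
    for strand in ("+", "-"):
        s = contig.seq if strand == "+" else reverse_complement(contig.seq)
        for frame in (0, 1, 2):
            for c0, c1, at_edge, stopped in _scan_frame(s, frame):
                # interior runs must begin at their first ATG
                if not at_edge:
                    j = c0
                    while j < c1 and s[frame + 3 * j : frame + 3 * j + 3] != "ATG":
                        j += 1
                    if j == c1:
                        continue
                    c0, has_start = j, True
                else:
                    has_start = s[frame + 3 * c0 : frame + 3 * c0 + 3] == "ATG"
                    if not has_start and not stopped:
                        # a run anchored by neither an ATG nor a stop codon
                        # carries no reading-frame evidence; skip it
                        j = c0
                        while j < c1 and s[frame + 3 * j : frame + 3 * j + 3] != "ATG":
                            j += 1
                        if j == c1:
                            continue
                        c0, has_start = j, True
                n_aa = c1 - c0
                if n_aa < min_aa:
                    continue
                # span on the scanned strand, stop codon included if present
                s_start = frame + 3 * c0
                s_end = frame + 3 * (c1 + (1 if stopped else 0))
                if strand == "+":
                    nt_start, nt_end = s_start, s_end
                else:
                    nt_start, nt_end = L - s_end, L - s_start
                prot = "".join(
                    _codon(s, frame + 3 * k) for k in range(c0, c1)
                )
                results.append(
                    OrfCandidate(
                        contig_id=contig.id,
                        frame=frame,
                        strand=strand,
                        nt_start=nt_start,
                        nt_end=nt_end,
                        protein=ProteinRecord(
                            id=f"{contig.id}|{strand}{frame}:{nt_start}-{nt_end}",
                            seq=prot,
                        ),
                        has_start=has_start,
                        has_stop=stopped,
                    )
                )
    results.sort(key=lambda o: (-len(o.protein.seq), o.nt_start, o.strand))
    if mode == "longest_per_contig":
        return results[:1]
    return results
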