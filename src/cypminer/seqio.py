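"""Sequence and tree input/output plus genetic-code primitives.

Conventions used throughout the package:

* Coordinates are 0-based, half-open, on the forward strand of the input
  contig; strand is stored separately.
* FASTA ids are the first whitespace-delimited token of the header; the
  description is everything after the first whitespace.
* Nucleotide sequences are uppercase over ``ACGTN``; ``N`` translates to
  ``X`` and ``X`` never satisfies a motif position.
* Protein sequences use the 20 standard one-letter codes plus ``X`` and a
  single optional trailing ``*``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import dendropy

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS) | frozenset("X*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Standard genetic code; stop codons map to '*'.
CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    bases = "TCAG"
    residues = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                CODON_TABLE[b1 + b2 + b3] = residues[i]
                i += 1


_build_codon_table()


@dataclass(frozen=True)
class NucleotideRecord:
    """A named nucleotide sequence (a transcriptome contig or transcript)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - NUCLEOTIDE_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal nucleotide character(s) "
                f"{sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence; at most one '*' and only terminal."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal amino-acid character(s) "
                f"{sorted(bad)!r}"
            )
        star = self.seq.find("*")
        if star != -1 and star != len(self.seq) - 1:
            raise ValueError(
                f"record {self.id!r}: '*' allowed only at the final position"
            )

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 0, strand: str = "+") -> str:
    """Translate ``seq`` with the standard genetic code.

    ``strand == '-'`` reverse-complements first and then applies ``frame`` on
    the reverse strand.  Stop codons render ``*``; codons containing ``N``
    render ``X``; trailing 1-2 nt are dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if len(seq) < 3 + frame:
        raise ValueError("sequence shorter than one codon in this frame")
    s = seq if strand == "+" else reverse_complement(seq)
    out = []
    for i in range(frame, len(s) - 2, 3):
        codon = s[i : i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


def _iter_fasta(path: str | os.PathLike) -> Iterable[tuple[str, str, str]]:
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)  # type: ignore[misc]
                parts = line[1:].split(None, 1)
                if not parts:
                    raise ValueError(f"{path}: FASTA header with no id")
                header = (parts[0], parts[1] if len(parts) == 2 else "")
                chunks = []
            elif line.strip():
                if header is None:
                    raise ValueError(f"{path}: sequence before first header")
                chunks.append(line.strip())
        if header is not None:
            yield header, "".join(chunks)  # type: ignore[misc]


def read_fasta(
    path: str | os.PathLike,
    alphabet: Literal["nucleotide", "protein"] = "nucleotide",
) -> list[NucleotideRecord] | list[ProteinRecord]:
    """Read a FASTA file, uppercase-normalized, in file order.

    Duplicate ids, empty sequences and illegal characters are hard errors.
    """
    cls = NucleotideRecord if alphabet == "nucleotide" else ProteinRecord
    records = []
    seen: set[str] = set()
    for (rec_id, desc), seq in _iter_fasta(path):
        if rec_id in seen:
            raise ValueError(f"{path}: duplicate id {rec_id!r}")
        seen.add(rec_id)
        records.append(cls(id=rec_id, seq=seq.upper(), description=desc))
    return records


def write_fasta(
    records: Sequence[NucleotideRecord | ProteinRecord],
    path: str | os.PathLike,
    width: int = 60,
) -> None:
    """Write records as FASTA wrapped at ``width`` columns (default 60)."""
    if width < 1:
        raise ValueError("width must be positive")
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_tsv(rows: Iterable[Sequence], path: str | os.PathLike,
              header: Sequence[str]) -> None:
    """Write rows as a TSV file with a header line."""
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, header)) + "\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
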