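"""Microsatellite (simple sequence repeat) detection in transcripts.

Detection follows the conventions of MISA-style tools: perfect tandem
repeats of 2-6 nt units, with minimum unit counts of six for dinucleotides
and five for tri- through hexanucleotides, and two repeats separated by at
most 100 nt reported together as one compound SSR.  Mononucleotide runs are
not reported, a run reportable at several unit lengths is reported once at
its smallest (primitive) unit, and units containing ``N`` are excluded.
Unit labels are canonicalized to the lexicographically smallest rotation;
reverse-complement folding is deliberately not applied because transcripts
are stranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .seqio import NucleotideRecord


@dataclass(frozen=True)
class SsrConfig:
    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    )
    max_interruption: int = 100

    def __post_init__(self) -> None:
        if not set(self.min_repeats) <= set(range(2, 7)):
            raise ValueError("unit lengths must be within 2..6")
        if any(v < 2 for v in self.min_repeats.values()):
            raise ValueError("minimum unit counts must be >= 2")


@dataclass(frozen=True)
class SsrHit:
    contig_id: str
    unit: str  # canonical rotation
    unit_len: int
    repeats: int
    start: int
    end: int
    kind: str = "simple"  # or "compound"
    members: tuple["SsrHit", ...] = ()


def _canonical_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    """True unless the unit is a whole-number power of a shorter string."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def _simple_hits(seq: str, contig_id: str, config: SsrConfig) -> list[SsrHit]:
    hits: list[SsrHit] = []
    n = len(seq)
    for ul, min_rep in sorted(config.min_repeats.items()):
        i = 0
        while i + ul <= n:
            # extend the period-ul match run starting at i
            j = i
            while j + ul < n and seq[j] == seq[j + ul] and seq[j] != "N":
                j += 1
            run_len = (j - i) + ul if j > i else 0
            if run_len >= ul * min_rep:
                unit = seq[i : i + ul]
                if _is_primitive(unit) and "N" not in unit:
                    repeats = run_len // ul
                    hits.append(
                        SsrHit(
                            contig_id=contig_id,
                            unit=_canonical_rotation(unit),
                            unit_len=ul,
                            repeats=repeats,
                            start=i,
                            end=i + ul * repeats,
                        )
                    )
                i = j + ul  # skip past this run
            else:
                i += 1
    hits.sort(key=lambda h: (h.start, h.unit_len))
    return hits


def find_ssrs(
    contig: NucleotideRecord, config: SsrConfig = SsrConfig()
) -> list[SsrHit]:
    """All maximal perfect tandem repeats meeting the minimum unit counts.

    Simple hits closer than ``max_interruption`` nt are additionally grouped
    into compound hits spanning their members; the returned list contains
    the simple hits in positional order followed by any compound hits.
    """
    simple = _simple_hits(contig.seq, contig.id, config)
    out: list[SsrHit] = list(simple)
    # chain neighboring hits into compounds
    group: list[SsrHit] = []
    compounds: list[SsrHit] = []

    def flush() -> None:
        if len(group) > 1:
            compounds.append(
                SsrHit(
                    contig_id=contig.id,
                    unit="+".join(h.unit for h in group),
                    unit_len=0,
                    repeats=0,
                    start=group[0].start,
                    end=group[-1].end,
                    kind="compound",
                    members=tuple(group),
                )
            )

    for hit in simple:
        if group and hit.start - group[-1].end <= config.max_interruption:
            group.append(hit)
        else:
            flush()
            group = [hit]
    flush()
    return out + compounds


def ssr_summary(hits_by_contig: Mapping[str, Sequence[SsrHit]]) -> dict:
    """Counts by unit length plus the SSR-containing contig tally.

    Reports both counting conventions for compound repeats: simple hits are
    always counted individually (``per_unit_length``), and compound events
    are tallied separately (``n_compound``).
    """
    per_len = {ul: 0 for ul in range(2, 7)}
    contigs_with = []
    n_compound = 0
    for contig_id in sorted(hits_by_contig):
        hits = hits_by_contig[contig_id]
        simple = [h for h in hits if h.kind == "simple"]
        for h in simple:
            per_len[h.unit_len] += 1
        n_compound += sum(1 for h in hits if h.kind == "compound")
        if simple:
            contigs_with.append(contig_id)
    return {
        "per_unit_length": per_len,
        "n_simple": sum(per_len.values()),
        "n_compound": n_compound,
        "n_contigs_with_ssr": len(contigs_with),
        "contigs_with_ssr": contigs_with,
    }
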