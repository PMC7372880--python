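"""Motif-anchored CYP detection, full-length curation and protein properties.

Cytochrome P450 proteins share four hallmark motifs in a fixed N- to
C-terminal order: the I-helix (oxygen activation groove), the K-helix ExxR
salt bridge, the PERF motif, and the heme-binding signature whose invariant
cysteine coordinates the heme iron roughly 50 residues from the C-terminus.
Detection here is deterministic degenerate-pattern scanning over those four
motifs with order constraints; a protein is CYP-like when the heme signature
plus at least two of the other three motifs occur in the canonical order.

Full-length curation applies two criteria: the protein starts with M and is
terminated by a stop codon, and it is at least 400 residues long with the
heme cysteine placed about 50 residues (window 35-65) from the C-terminus.

The scan patterns are the union of the A-type (CYP71-clan) and non-A-type
consensus forms so both groups are detected by one model set:
heme ``FxxGxRxCxG`` (C invariant, <=2 mismatches elsewhere), PERF ``FxPxRx``
(<=1 mismatch), K-helix ``ExxR`` (exact), I-helix ``AGx[DE]T`` (<=1
mismatch).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .orfmine import OrfCandidate
from .seqio import AMINO_ACIDS, ProteinRecord

MOTIF_ORDER = ("I-helix", "ExxR", "PERF", "heme")


@dataclass(frozen=True)
class MotifModel:
    """A degenerate motif pattern.

    ``pattern`` holds one spec per position: ``None`` for a wildcard or a
    frozenset of allowed residues.  Positions listed in ``invariant`` must
    match exactly; the remaining constrained positions may mismatch up to
    ``max_mismatches`` times in total.  ``X`` never satisfies a constrained
    position.
    """

    name: str
    pattern: tuple[frozenset[str] | None, ...]
    invariant: tuple[int, ...] = ()
    max_mismatches: int = 0

    @property
    def width(self) -> int:
        return len(self.pattern)

    @classmethod
    def from_string(cls, name: str, spec: str, invariant: tuple[int, ...] = (),
                    max_mismatches: int = 0) -> "MotifModel":
        """Build from a compact spec: letters fix a residue, ``x`` is a
        wildcard, ``[DE]`` a residue set."""
        pattern: list[frozenset[str] | None] = []
        i = 0
        while i < len(spec):
            c = spec[i]
            if c == "x":
                pattern.append(None)
                i += 1
            elif c == "[":
                j = spec.index("]", i)
                pattern.append(frozenset(spec[i + 1 : j]))
                i = j + 1
            else:
                pattern.append(frozenset(c))
                i += 1
        return cls(name=name, pattern=tuple(pattern), invariant=invariant,
                   max_mismatches=max_mismatches)


def default_models() -> dict[str, MotifModel]:
    """The four hallmark-motif detection models."""
    return {
        "heme": MotifModel.from_string(
            "heme", "FxxGxRxCxG", invariant=(7,), max_mismatches=2
        ),
        "PERF": MotifModel.from_string("PERF", "FxPxRx", max_mismatches=1),
        "ExxR": MotifModel.from_string("ExxR", "ExxR", max_mismatches=0),
        "I-helix": MotifModel.from_string(
            "I-helix", "AGx[DE]T", max_mismatches=1
        ),
    }


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int
    end: int
    matched: str
    mismatches: int


@dataclass(frozen=True)
class CurationConfig:
    min_aa: int = 400
    heme_offset_window: tuple[int, int] = (35, 65)
    detection_min_other_motifs: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.heme_offset_window
        if not lo <= 50 <= hi:
            raise ValueError("heme offset window must contain 50")
        if self.min_aa <= 0:
            raise ValueError("min_aa must be positive")


@dataclass
class CypCall:
    """The curation verdict for one ORF's protein."""

    protein: ProteinRecord
    orf: OrfCandidate | None
    hits: dict[str, list[MotifHit]]
    selected: dict[str, MotifHit]
    cyp_like: bool
    full_length: bool
    failure_reasons: list[str]
    pI: float | None = None
    mw_kda: float | None = None


def scan_motif(protein: ProteinRecord, model: MotifModel) -> list[MotifHit]:
    """All windows matching ``model`` with tolerated mismatches, by start.

    Invariant positions must match exactly; other constrained positions may
    mismatch up to ``model.max_mismatches`` in total; ``X`` never matches a
    constrained position.
    """
    seq = protein.seq
    w = model.width
    if len(seq) < w:
        raise ValueError(
            f"protein {protein.id!r} shorter than motif {model.name!r}"
        )
    hits = []
    inv = set(model.invariant)
    for i in range(len(seq) - w + 1):
        mism = 0
        ok = True
        for j, allowed in enumerate(model.pattern):
            if allowed is None:
                continue
            res = seq[i + j]
            if res in allowed and res != "X":
                continue
            if j in inv:
                ok = False
                break
            mism += 1
            if mism > model.max_mismatches:
                ok = False
                break
        if ok:
            hits.append(MotifHit(model.name, i, i + w, seq[i : i + w], mism))
    return hits


def _best_ordered_combination(
    hits: Mapping[str, list[MotifHit]], min_others: int
) -> dict[str, MotifHit] | None:
    """Best non-overlapping hit combination in the canonical motif order.

    Requires a heme hit plus at least ``min_others`` of the other motifs;
    among valid combinations prefers most motifs, then fewest total
    mismatches, then earliest starts.
    """
    heme_hits = hits.get("heme", [])
    if not heme_hits:
        return None

    def ranked(name: str, cap: int = 12) -> list[MotifHit]:
        pool = sorted(hits[name], key=lambda h: (h.mismatches, h.start))
        return pool[:cap] if len(pool) > cap else pool

    others = [m for m in MOTIF_ORDER[:-1] if hits.get(m)]
    best: tuple | None = None
    best_sel: dict[str, MotifHit] | None = None
    for r in range(len(others), min_others - 1, -1):
        for subset in itertools.combinations(others, r):
            pools = [ranked(m) for m in subset]
            for heme in ranked("heme"):
                for combo in itertools.product(*pools):
                    chain = list(combo) + [heme]
                    if any(
                        chain[k].end > chain[k + 1].start
                        for k in range(len(chain) - 1)
                    ):
                        continue
                    key = (
                        -len(combo),
                        sum(h.mismatches for h in chain),
                        tuple(h.start for h in chain),
                    )
                    if best is None or key < best:
                        best = key
                        best_sel = dict(zip(subset, combo)) | {"heme": heme}
        if best_sel is not None:
            return best_sel
    return None


def heme_cysteine_offset(protein_len: int, heme_hit: MotifHit,
                         model: MotifModel) -> int:
    """Residues from the invariant heme cysteine to the C-terminus.

    Defined as ``len - index(C)`` so a cysteine 50 residues from the end of a
    500-residue protein sits at index 450 and has offset 50.
    """
    c_index = heme_hit.start + model.invariant[0]
    return protein_len - c_index


def call_cyp(
    protein: ProteinRecord,
    orf: OrfCandidate | None,
    models: Mapping[str, MotifModel] | None = None,
    config: CurationConfig = CurationConfig(),
) -> CypCall:
    """Classify one ORF protein as CYP-like and curate full-length status.

    ``cyp_like``: heme hit plus >= ``detection_min_other_motifs`` of
    {I-helix, ExxR, PERF}, in the canonical order.  ``full_length``
    additionally requires an ATG start with leading M, an in-contig stop,
    length >= ``min_aa`` and the heme cysteine offset inside the window.
    ``failure_reasons`` records every violated clause.
    """
    models = models if models is not None else default_models()
    missing = set(MOTIF_ORDER) - set(models)
    if missing:
        raise ValueError(f"models missing motifs: {sorted(missing)}")
    hits = {
        name: (scan_motif(protein, model) if len(protein.seq) >= model.width
               else [])
        for name, model in models.items()
    }
    reasons: list[str] = []
    selected: dict[str, MotifHit] = {}
    if not hits["heme"]:
        reasons.append("no_heme")
        cyp_like = False
    else:
        sel = _best_ordered_combination(
            hits, config.detection_min_other_motifs
        )
        if sel is None:
            reasons.append("bad_order")
            cyp_like = False
        else:
            selected = sel
            cyp_like = True
    full = cyp_like
    if cyp_like:
        if orf is None or not orf.has_start or not protein.seq.startswith("M"):
            reasons.append("no_start")
            full = False
        if orf is None or not orf.has_stop:
            reasons.append("no_stop")
            full = False
        if len(protein.seq) < config.min_aa:
            reasons.append("too_short")
            full = False
        offset = heme_cysteine_offset(
            len(protein.seq), selected["heme"], models["heme"]
        )
        lo, hi = config.heme_offset_window
        if not lo <= offset <= hi:
            reasons.append("heme_offset")
            full = False
    else:
        full = False
    call = CypCall(
        protein=protein,
        orf=orf,
        hits=hits,
        selected=selected,
        cyp_like=cyp_like,
        full_length=full,
        failure_reasons=reasons,
    )
    if full:
        call.pI = isoelectric_point(protein.seq)
        call.mw_kda = molecular_weight(protein.seq)
    return call


# --- physicochemical properties -------------------------------------------

#: Average residue masses (Da), ExPASy convention; peptide mass adds one water.
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.01524

#: Bjellqvist-style pKa values for the ionizable groups.
PKA = {
    "n_term": 7.5, "c_term": 3.55,
    "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    "H": 5.98, "K": 10.0, "R": 12.0,
}
_BASIC = ("H", "K", "R")
_ACIDIC = ("D", "E", "C", "Y")


def molecular_weight(seq: str) -> float:
    """Average molecular weight in kDa (residue masses plus one water)."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(RESIDUE_MASS)
    if bad:
        raise ValueError(f"ambiguous residue(s) {sorted(bad)!r}")
    return (sum(RESIDUE_MASS[c] for c in seq) + WATER_MASS) / 1000.0


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of the peptide at a given pH."""
    counts = {aa: seq.count(aa) for aa in _BASIC + _ACIDIC}
    charge = 1.0 / (1.0 + 10 ** (ph - PKA["n_term"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA["c_term"] - ph))
    for aa in _BASIC:
        charge += counts[aa] / (1.0 + 10 ** (ph - PKA[aa]))
    for aa in _ACIDIC:
        charge -= counts[aa] / (1.0 + 10 ** (PKA[aa] - ph))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """Theoretical pI: the pH of zero net charge, found by bisection."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"ambiguous residue(s) {sorted(bad)!r}")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
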