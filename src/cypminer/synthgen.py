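"""Seeded synthetic transcriptomes with CYP-like statistical structure.

The generator emulates the data regime the mining pipeline is built for:
multi-family CYP complements whose members sit in controlled identity bands
(families diverged below 40 %, subfamily seeds 40-55 % to their family seed,
members >= 55 % to their subfamily seed, allelic variants >= 97 % at the
nucleotide level), orthologous pairs across two species tags at a configured
identity, full-length transcripts with UTRs, 5'- or 3'-truncated partials,
planted conserved motifs in their canonical order, planted microsatellites,
and non-CYP decoy ORFs that can never satisfy the heme-signature detector.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``: identical configs give byte-identical outputs.

What the generator does not emulate: sequencing reads and their errors,
indels (substitution-only divergence), codon-usage bias (synonymous codons
are drawn uniformly), and assembly artifacts such as chimeras.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .cyp_detect import call_cyp, default_models
from .orfmine import find_orfs
from .seqio import AMINO_ACIDS, CODON_TABLE, NucleotideRecord, ProteinRecord, translate
from .ssrfind import SsrConfig, find_ssrs

_AA = np.array(list(AMINO_ACIDS))
_STOPS = ("TAA", "TAG", "TGA")

# inverse codon table, stops excluded
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    if _aa != "*":
        _CODONS_FOR.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class IdentityBands:
    """Target percent identities realizing the nomenclature bands.

    ``subfamily_seed``: identity of a subfamily seed to its family seed
    (inside the family band [40, 55)); ``member``: identity of a member to
    its subfamily seed (inside the subfamily band [55, 97)); ``allele``:
    nucleotide identity of an allelic variant to its source CDS (>= 97).
    """

    subfamily_seed: float = 47.0
    member: float = 65.0
    allele: float = 99.0

    def __post_init__(self) -> None:
        if not 40 <= self.subfamily_seed < 55:
            raise ValueError("subfamily_seed identity must be in [40, 55)")
        if not 55 <= self.member < 97:
            raise ValueError("member identity must be in [55, 97)")
        if not self.allele >= 97:
            raise ValueError("allele identity must be >= 97")


@dataclass(frozen=True)
class SsrPlanting:
    """Plant ``count`` SSRs of ``repeats`` x ``unit`` into one UTR each."""

    unit: str
    repeats: int
    utr: Literal["5p", "3p"]
    count: int


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic two-species transcriptome."""

    seed: int = 0
    n_families: int = 16
    subfamilies_per_family: int = 3
    members_per_subfamily: int = 6
    allelic_rate: float = 0.25
    partial_fraction: float = 0.3
    decoy_count: int = 100
    utr_len_range: tuple[int, int] = (40, 120)
    ssr_plant_spec: tuple[SsrPlanting, ...] = (
        SsrPlanting("AT", 7, "3p", 30),
        SsrPlanting("AAG", 5, "3p", 10),
        SsrPlanting("ACGT", 5, "5p", 5),
        SsrPlanting("AACTG", 5, "3p", 5),
        SsrPlanting("AACGTC", 5, "5p", 5),
    )
    ortholog_pair_identity: float = 90.0
    ortholog_missing_rate: float = 0.2
    a_type_fraction: float = 0.5
    identity_bands: IdentityBands = IdentityBands()
    length_range: tuple[int, int] = (460, 601)

    def __post_init__(self) -> None:
        for name in ("n_families", "subfamilies_per_family",
                     "members_per_subfamily", "decoy_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("allelic_rate", "partial_fraction",
                     "ortholog_missing_rate", "a_type_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


# planted instance layouts; 'x' positions stay backbone, '@' is the cycled
# D/E/A column of the non-A-type I-helix
_A_TYPE_MOTIFS = {
    "I-helix": "AGxDT",
    "ExxR": "ExxR",
    "PERF": "FxPERF",
    "heme": "PFGxGRRxCP",
}
_NON_A_MOTIFS = {
    "I-helix": "AGx@TT",
    "ExxR": "ExxR",
    "PERF": "FxPxRx",
    "heme": "xFxxGxRxCxG",
}

#: rel. index of the invariant heme cysteine inside the planted window
_HEME_C_REL = 8
#: cycle realizing the published "[D/E]" I-helix column of non-A-type CYPs
_DE_CYCLE = ("D", "E", "D", "E", "A")


def make_cyp_scaffold(
    length_aa: int, rng: np.random.Generator, a_type: bool = True
) -> tuple[str, dict[str, tuple[int, int]]]:
    """A random CYP-like protein with the four motifs planted in order.

    Returns the protein string (starting with M) and the planted window
    coordinates per motif.  The invariant heme cysteine lands 46-54 residues
    from the C-terminus.  All non-motif positions are uniform over the 20
    amino acids, which makes the information-content null of an unconstrained
    logo column analytically 0 bits.
    """
    if length_aa < 460:
        raise ValueError("scaffold length must be >= 460 aa")
    motifs = _A_TYPE_MOTIFS if a_type else _NON_A_MOTIFS
    seq = list(rng.choice(_AA, size=length_aa))
    seq[0] = "M"
    offset = int(rng.integers(46, 55))  # heme C this far from the C-terminus
    heme_start = length_aa - offset - _HEME_C_REL
    perf_start = heme_start - len(motifs["PERF"]) - int(rng.integers(12, 25))
    exxr_start = perf_start - len(motifs["ExxR"]) - int(rng.integers(30, 61))
    ihel_start = exxr_start - len(motifs["I-helix"]) - int(rng.integers(40, 81))
    if ihel_start < 10:
        raise ValueError("length too small to place all motifs with spacing")
    coords: dict[str, tuple[int, int]] = {}
    for name, start in (("I-helix", ihel_start), ("ExxR", exxr_start),
                        ("PERF", perf_start), ("heme", heme_start)):
        pat = motifs[name]
        for j, c in enumerate(pat):
            if c == "@":
                seq[start + j] = str(rng.choice(["D", "E"]))
            elif c != "x":
                seq[start + j] = c
        coords[name] = (start, start + len(pat))
    return "".join(seq), coords


def motif_positions(coords: dict[str, tuple[int, int]]) -> set[int]:
    return {i for s, e in coords.values() for i in range(s, e)}


def _break_homopolymer_runs(seq: str, rng: np.random.Generator,
                            protect: set[int], max_run: int = 4) -> str:
    """Cap single-residue runs at ``max_run``.

    Runs of single-codon residues (W, M) longer than four force perfect
    trinucleotide repeats in every possible CDS, which would collide with
    the SSR ground truth; capping all runs keeps the proteins realistic
    and the nucleotide sequences SSR-free by construction.
    """
    out = list(seq)
    i = 0
    while i < len(out):
        j = i
        while j < len(out) and out[j] == out[i]:
            j += 1
        if j - i > max_run:
            for k in range(i + max_run, j, max_run + 1):
                if k in protect:
                    continue
                choices = [a for a in AMINO_ACIDS if a != out[k]]
                out[k] = choices[int(rng.integers(len(choices)))]
        i = j
    return "".join(out)


def mutate_protein(
    seq: str,
    target_identity: float,
    preserve: set[int],
    rng: np.random.Generator,
    tol: float = 1.0,
) -> str:
    """Substitute residues to reach a target global identity.

    Exactly ``round(len * (1 - target/100))`` positions outside ``preserve``
    are changed to a different residue, so the ungapped identity is within
    ``tol`` of the target by construction.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target identity must be in (0, 100]")
    L = len(seq)
    k = round(L * (1.0 - target_identity / 100.0))
    candidates = [i for i in range(L) if i not in preserve]
    if k > len(candidates):
        raise ValueError(
            f"target {target_identity}% infeasible with {len(preserve)} "
            "preserved positions"
        )
    out = list(seq)
    for i in rng.choice(len(candidates), size=k, replace=False):
        pos = candidates[int(i)]
        choices = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """CDS for ``protein`` with uniform synonymous codon choice plus a stop."""
    codons = [
        _CODONS_FOR[aa][int(rng.integers(len(_CODONS_FOR[aa])))]
        for aa in protein
    ]
    return "".join(codons) + _STOPS[int(rng.integers(3))]


def _random_utr(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=length))


@dataclass
class _Locus:
    species: str
    clan: str
    family: str
    subfamily: str
    name: str
    a_type: bool
    protein: str
    coords: dict[str, tuple[int, int]]
    ortholog: str | None = None
    allele_of: str | None = None


@dataclass
class SimResult:
    """Everything `emit_transcriptome` produces."""

    transcripts: list[NucleotideRecord]
    proteins: list[ProteinRecord]
    truth: pd.DataFrame
    panel_proteins: list[ProteinRecord]
    panel_table: pd.DataFrame
    clan_map: dict[str, str]


def _set_protein_position(protein: str, pos: int, residue: str) -> str:
    return protein[:pos] + residue + protein[pos + 1 :]


def _recode_codon(cds: str, aa_pos: int, residue: str,
                  rng: np.random.Generator) -> str:
    codon = _CODONS_FOR[residue][int(rng.integers(len(_CODONS_FOR[residue])))]
    i = 3 * aa_pos
    return cds[:i] + codon + cds[i + 3 :]


def _mutate_cds(cds: str, identity: float, protected_aa: set[int],
                rng: np.random.Generator) -> str:
    """Nucleotide-level substitutions for allelic variants.

    Avoids the stop codon, the start codon and motif codons, and never
    creates an in-frame stop, so the variant stays a valid CYP CDS.
    """
    body_len = len(cds) - 3  # exclude stop codon
    k = round(body_len * (1.0 - identity / 100.0))
    allowed = [
        i for i in range(3, body_len)
        if (i // 3) not in protected_aa
    ]
    out = list(cds)
    chosen = rng.choice(len(allowed), size=min(k, len(allowed)), replace=False)
    for idx in chosen:
        pos = allowed[int(idx)]
        for _ in range(10):
            base = "ACGT"[int(rng.integers(4))]
            if base == out[pos]:
                continue
            old = out[pos]
            out[pos] = base
            c0 = 3 * (pos // 3)
            if CODON_TABLE["".join(out[c0 : c0 + 3])] == "*":
                out[pos] = old
                continue
            break
    return "".join(out)


def _transcript_is_clean(seq: str, planted: list[tuple[str, int, int]],
                         ssr_cfg: SsrConfig) -> bool:
    """True when the only SSRs detected are exactly the planted ones."""
    hits = find_ssrs(NucleotideRecord(id="tmp", seq=seq), ssr_cfg)
    simple = [(h.unit, h.start, h.end) for h in hits if h.kind == "simple"]
    return sorted(simple) == sorted(planted)


def _decoy_is_inert(rec: NucleotideRecord) -> bool:
    models = default_models()
    for orf in find_orfs(rec, min_aa=100):
        if call_cyp(orf.protein, orf, models).cyp_like:
            return False
    return True


def emit_transcriptome(config: SimConfig) -> SimResult:
    """Generate the synthetic two-species transcriptome with ground truth.

    Loci are organized as families x subfamilies x members; every member has
    a home transcript in species ``spA`` and, with probability
    ``1 - ortholog_missing_rate``, an ortholog in ``spB`` at the configured
    identity.  Emitted transcripts acquire allelic variants with probability
    ``allelic_rate`` and are truncated (5' or 3') with probability
    ``partial_fraction``.  SSRs are planted into the UTRs of full-length
    transcripts and re-verified; decoys are rejection-sampled until no ORF
    of theirs is CYP-like and they are SSR-free.
    """
    rng = np.random.default_rng(config.seed)
    bands = config.identity_bands
    n_a = round(config.n_families * config.a_type_fraction)
    non_a_clans = ("CYP72", "CYP85", "CYP86")
    ssr_cfg = SsrConfig()

    # --- protein-level locus construction ---------------------------------
    loci: list[_Locus] = []
    panel_proteins: list[ProteinRecord] = []
    panel_rows: list[dict] = []
    clan_map: dict[str, str] = {}
    for fi in range(config.n_families):
        a_type = fi < n_a
        family = f"CYP9{fi + 1:02d}"
        clan = "CYP71" if a_type else non_a_clans[fi % 3]
        clan_map[family] = clan
        length = int(rng.integers(config.length_range[0],
                                  config.length_range[1] + 1))
        fam_seed, coords = make_cyp_scaffold(length, rng, a_type=a_type)
        keep = motif_positions(coords) | {0}
        fam_seed = _break_homopolymer_runs(fam_seed, rng, keep)
        for si in range(config.subfamilies_per_family):
            sub = f"{family}{chr(ord('A') + si)}"
            sub_seed = _break_homopolymer_runs(
                mutate_protein(fam_seed, bands.subfamily_seed, keep, rng),
                rng, keep,
            )
            panel_proteins.append(
                ProteinRecord(id=f"ref|{sub}1", seq=sub_seed,
                              description=f"reference {sub}")
            )
            panel_rows.append({
                "name": f"{sub}1", "clan": clan, "family": family,
                "subfamily": sub,
            })
            for mi in range(config.members_per_subfamily):
                name = f"{sub}{mi + 2}"
                prot = _break_homopolymer_runs(
                    mutate_protein(sub_seed, bands.member, keep, rng),
                    rng, keep,
                )
                loci.append(_Locus("spA", clan, family, sub, name, a_type,
                                   prot, coords))
                if rng.random() >= config.ortholog_missing_rate:
                    orth = _break_homopolymer_runs(
                        mutate_protein(
                            prot, config.ortholog_pair_identity, keep, rng
                        ),
                        rng, keep,
                    )
                    loci.append(_Locus("spB", clan, family, sub, name, a_type,
                                       orth, coords,
                                       ortholog=f"spA|{name}"))

    # --- transcript-level emission ----------------------------------------
    # Decide partial flags first so the non-A I-helix [D/E] column can be
    # cycled deterministically over the transcripts that end up full length.
    entries: list[dict] = []
    for locus in loci:
        partial = rng.random() < config.partial_fraction
        entries.append({"locus": locus, "partial": partial, "allele": False})
        if not partial and rng.random() < config.allelic_rate:
            entries.append({"locus": locus, "partial": False, "allele": True})

    de_counter = 0
    transcripts: list[NucleotideRecord] = []
    proteins: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    lo_utr, hi_utr = config.utr_len_range

    # assign SSR plantings round-robin over full-length entries
    full_idx = [i for i, e in enumerate(entries) if not e["partial"]]
    plantings: dict[int, SsrPlanting] = {}
    cursor = 0
    for planting in config.ssr_plant_spec:
        for _ in range(planting.count):
            if cursor >= len(full_idx):
                break
            plantings[full_idx[cursor]] = planting
            cursor += 1

    source_cds: dict[str, str] = {}
    for idx, entry in enumerate(entries):
        locus: _Locus = entry["locus"]
        prot = locus.protein
        name = locus.name + ("v" if entry["allele"] else "")
        rec_id = f"{locus.species}|{name}"
        de_letter = ""
        if not locus.a_type:
            # cycle the I-helix [D/E] column across full-length transcripts
            if not entry["partial"]:
                de_letter = _DE_CYCLE[de_counter % len(_DE_CYCLE)]
                de_counter += 1
            else:
                de_letter = str(rng.choice(["D", "E"]))
            de_pos = locus.coords["I-helix"][0] + 3
            prot = _set_protein_position(prot, de_pos, de_letter)

        planting = plantings.get(idx)
        planted: list[tuple[str, int, int]] = []
        for _attempt in range(100):
            # codon choices are part of the rejection loop so accidental
            # tandem repeats inside the CDS can be resampled away
            if entry["allele"]:
                # allelic variants inherit their source transcript's codons
                # so the nucleotide-level identity tracks the allele band
                cds = source_cds[f"{locus.species}|{locus.name}"]
                if not locus.a_type:
                    de_pos = locus.coords["I-helix"][0] + 3
                    cds = _recode_codon(cds, de_pos, de_letter, rng)
                protected = motif_positions(locus.coords) | {0}
                cds = _mutate_cds(cds, bands.allele, protected, rng)
                prot = translate(cds, 0, "+")[:-1]
            else:
                cds = _reverse_translate(prot, rng)
            utr5 = _random_utr(int(rng.integers(lo_utr, hi_utr + 1)), rng)
            utr3 = _random_utr(int(rng.integers(lo_utr, hi_utr + 1)), rng)
            # in-frame stop immediately upstream keeps the ORF anchored at ATG
            utr5 = utr5[:-3] + _STOPS[int(rng.integers(3))]
            planted = []
            if planting is not None and not entry["partial"]:
                unit, reps = planting.unit, planting.repeats
                run = unit * reps
                canon = min(unit[i:] + unit[:i] for i in range(len(unit)))
                pos = 3
                if planting.utr == "5p":
                    if len(utr5) < pos + len(run) + 3:
                        raise ValueError("utr_len_range too small for planting")
                    utr5 = utr5[:pos] + run + utr5[pos + len(run):]
                    planted = [(canon, pos, pos + len(run))]
                else:
                    if len(utr3) < pos + len(run):
                        raise ValueError("utr_len_range too small for planting")
                    utr3 = utr3[:pos] + run + utr3[pos + len(run):]
                    start = len(utr5) + len(cds) + pos
                    planted = [(canon, start, start + len(run))]
            seq = utr5 + cds + utr3
            if entry["partial"]:
                if rng.random() < 0.5:
                    cut = int(len(cds) * rng.uniform(0.2, 0.6))
                    seq = cds[cut:] + utr3
                    mode = "trunc5"
                else:
                    cut = 3 * int(rng.integers(0, 31)) + 3  # stop + <=30 codons
                    seq = utr5 + cds[:-cut]
                    mode = "trunc3"
            else:
                mode = ""
            if _transcript_is_clean(seq, planted, ssr_cfg):
                break
        else:  # pragma: no cover - rejection loop exhausted
            raise RuntimeError(f"could not emit a clean transcript for {rec_id}")
        if not entry["allele"]:
            source_cds[rec_id] = cds

        if mode == "trunc5":
            cds_start, cds_end = 0, len(seq) - len(utr3)
        elif mode == "trunc3":
            cds_start, cds_end = len(utr5), len(seq)
        else:
            cds_start, cds_end = len(utr5), len(utr5) + len(cds)
        transcripts.append(NucleotideRecord(
            id=rec_id, seq=seq,
            description=f"synthetic {locus.family} seed={config.seed}",
        ))
        proteins.append(ProteinRecord(id=rec_id, seq=prot))
        truth_rows.append({
            "id": rec_id,
            "species": locus.species,
            "clan": locus.clan,
            "family": locus.family,
            "subfamily": locus.subfamily,
            "member": name,
            "a_type": locus.a_type,
            "is_allele": entry["allele"],
            "allele_of": f"{locus.species}|{locus.name}" if entry["allele"] else "",
            "ortholog_id": locus.ortholog or "",
            "full_length": not entry["partial"],
            "partial_mode": mode,
            "cds_start": cds_start,
            "cds_end": cds_end,
            "protein_len": len(prot),
            "de_letter": de_letter,
            "motif_coords": ";".join(
                f"{m}:{s}-{e}" for m, (s, e) in sorted(locus.coords.items())
            ),
            "ssr": ";".join(f"{u}:{s}-{e}" for u, s, e in planted),
        })

    # --- decoys ------------------------------------------------------------
    for d in range(config.decoy_count):
        for _attempt in range(100):
            n_codons = int(rng.integers(100, 221))
            prot = "".join(rng.choice(_AA, size=n_codons))
            prot = "M" + prot[1:]
            cds = _reverse_translate(prot, rng)
            utr5 = _random_utr(int(rng.integers(lo_utr, hi_utr + 1)), rng)
            utr3 = _random_utr(int(rng.integers(lo_utr, hi_utr + 1)), rng)
            utr5 = utr5[:-3] + _STOPS[int(rng.integers(3))]
            rec = NucleotideRecord(id=f"decoy|{d:04d}", seq=utr5 + cds + utr3)
            if _decoy_is_inert(rec) and _transcript_is_clean(rec.seq, [], ssr_cfg):
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not emit an inert decoy {d}")
        transcripts.append(rec)

    truth = pd.DataFrame(truth_rows)
    panel_table = pd.DataFrame(panel_rows)
    return SimResult(
        transcripts=transcripts,
        proteins=proteins,
        truth=truth,
        panel_proteins=panel_proteins,
        panel_table=panel_table,
        clan_map=clan_map,
    )
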