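"""Identity-threshold CYP nomenclature against a labelled reference panel.

The standard nomenclature cutoffs are applied inclusively: a query is an
allelic variant of its best reference at >= 97 % amino-acid identity, a new
member of that subfamily at >= 55 %, a new subfamily of that family at
>= 40 %, and a new family below 40 % (where the clan is inherited from the
best hit but flagged low-confidence, since there is no rule for clan
placement below the family cutoff).  A-type CYPs are exactly those of the
CYP71 clan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .redundancy import global_identity
from .seqio import ProteinRecord

A_TYPE_CLAN = "CYP71"
DEFAULT_CUTOFFS = (40.0, 55.0, 97.0)


def load_clan_map() -> dict[str, str]:
    """The shipped family -> clan mapping (editable TSV under data/).

    Seeded from the clan groupings of the bundled five-species count
    table; real analyses can extend or override it.
    """
    from importlib import resources

    out: dict[str, str] = {}
    with resources.files("cypminer.data").joinpath(
        "cyp_family_counts.tsv"
    ).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ci, fi = header.index("clan"), header.index("family")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out[parts[fi]] = parts[ci]
    return out


@dataclass(frozen=True)
class PanelEntry:
    protein: ProteinRecord
    clan: str
    family: str
    subfamily: str
    name: str


@dataclass(frozen=True)
class ReferencePanel:
    entries: tuple[PanelEntry, ...]
    clan_map: Mapping[str, str]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("panel entry names must be unique")
        missing = {e.family for e in self.entries} - set(self.clan_map)
        if missing:
            raise ValueError(f"families missing from clan_map: {sorted(missing)}")


@dataclass(frozen=True)
class NomenclatureCall:
    query_id: str
    best_ref: str
    identity_pct: float
    clan: str
    family: str
    subfamily: str
    status: str  # allelic_variant | new_member | new_subfamily | new_family
    a_type: bool
    low_confidence_clan: bool = False


def assign_nomenclature(
    query: ProteinRecord,
    panel: ReferencePanel,
    cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS,
) -> NomenclatureCall:
    """Classify one full-length CYP protein against the panel.

    The best reference is the panel entry with maximum global identity
    (ties broken by panel order); the three cutoffs partition the identity
    axis with inclusive lower bounds.
    """
    if not panel.entries:
        raise ValueError("reference panel is empty")
    fam_cut, sub_cut, allele_cut = cutoffs
    best: PanelEntry | None = None
    best_ident = -1.0
    for entry in panel.entries:
        ident = global_identity(query.seq, entry.protein.seq, "protein")
        if ident > best_ident:
            best, best_ident = entry, ident
    assert best is not None
    clan = panel.clan_map[best.family]
    low_conf = False
    if best_ident >= allele_cut:
        status, family, subfamily = "allelic_variant", best.family, best.subfamily
    elif best_ident >= sub_cut:
        status, family, subfamily = "new_member", best.family, best.subfamily
    elif best_ident >= fam_cut:
        status, family, subfamily = "new_subfamily", best.family, "new"
    else:
        status, family, subfamily = "new_family", "new", "new"
        low_conf = True
    return NomenclatureCall(
        query_id=query.id,
        best_ref=best.name,
        identity_pct=best_ident,
        clan=clan,
        family=family,
        subfamily=subfamily,
        status=status,
        a_type=clan == A_TYPE_CLAN,
        low_confidence_clan=low_conf,
    )


def tabulate_complement(
    calls_by_species: Mapping[str, Sequence[NomenclatureCall]],
    clan_map: Mapping[str, str] | None = None,
) -> dict:
    """Family x species and clan x species count tables plus per-species
    family tallies (total, A-type, non-A-type).

    Calls with ``family == "new"`` are tabulated under ``new:<clan>`` so
    totals are conserved.  A family absent from the clan map is an error.
    """
    species = sorted(calls_by_species)
    fam_rows: dict[str, dict[str, int]] = {}
    clan_rows: dict[str, dict[str, int]] = {}
    fam_clan: dict[str, str] = {}
    for sp in species:
        for call in calls_by_species[sp]:
            if call.family == "new":
                family = f"new:{call.clan}"
            else:
                family = call.family
                if clan_map is not None and family not in clan_map:
                    raise KeyError(f"family {family!r} not in clan map")
            fam_clan[family] = call.clan
            fam_rows.setdefault(family, {})[sp] = (
                fam_rows.get(family, {}).get(sp, 0) + 1
            )
            clan_rows.setdefault(call.clan, {})[sp] = (
                clan_rows.get(call.clan, {}).get(sp, 0) + 1
            )
    fam_table = (
        pd.DataFrame(fam_rows).T.reindex(columns=species).fillna(0).astype(int)
        .sort_index()
    )
    clan_table = (
        pd.DataFrame(clan_rows).T.reindex(columns=species).fillna(0).astype(int)
        .sort_index()
    )
    summary = {}
    for sp in species:
        nonzero = (
            list(fam_table.index[fam_table[sp] > 0]) if len(fam_table) else []
        )
        n_a = sum(1 for f in nonzero if fam_clan[f] == A_TYPE_CLAN)
        summary[sp] = {
            "n_calls": len(calls_by_species[sp]),
            "n_families": len(nonzero),
            "n_a_type_families": n_a,
            "n_non_a_type_families": len(nonzero) - n_a,
        }
    return {
        "family_table": fam_table,
        "clan_table": clan_table,
        "per_species": summary,
    }
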