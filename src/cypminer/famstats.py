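"""Contingency chi-square comparisons of CYP complements across species.

The module ships a transcribed fixture of the five-species full-length CYP
count matrix (54 families grouped into 9 clans; species codes Jv =
*Jacobaea vulgaris*, Ja = *J. aquatica*, Ha = *Helianthus annuus*, Ls =
*Lactuca sativa*, At = *Arabidopsis thaliana*) and recomputes the published
comparisons from it: Pearson chi-square without continuity correction,
zero-margin rows and columns dropped and recorded, and upper-tail p-values
via the regularized incomplete gamma function.

The fixture guards itself: species totals must match the published
221/157/462/374/244 before any statistic is reported, and each comparison
records its expected degrees of freedom so a transcription slip surfaces
rather than silently shifting a result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaincc

SPECIES = ("Jv", "Ja", "Ha", "Ls", "At")
EXPECTED_TOTALS = {"Jv": 221, "Ja": 157, "Ha": 462, "Ls": 374, "At": 244}
SINGLE_FAMILY_CLANS = ("CYP51", "CYP74", "CYP97", "CYP710", "CYP711")
MULTI_FAMILY_CLANS = ("CYP71", "CYP72", "CYP85", "CYP86")
SIX_LARGEST_FAMILIES = ("CYP71", "CYP706", "CYP76", "CYP72", "CYP82", "CYP93")
A_TYPE_CLAN = "CYP71"

#: published statistics the report checks itself against (statistic, df)
PUBLISHED = {
    "clans_five_species": (42.0, 32),
    "families_five_species": (466.7, 212),
    "single_family_clans_five_species": (11.2, 16),
    "multi_family_clans_five_species": (445.6, 192),
    "clans_jv_vs_ja": (1.6, 8),
    "families_jv_vs_ja": (18.6, 37),
}


@dataclass(frozen=True)
class ContingencyTable:
    """Row-labelled (families or clans) x column-labelled (species) counts."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # integer, non-negative

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ContingencyTable":
        return cls(
            row_labels=tuple(str(i) for i in frame.index),
            col_labels=tuple(str(c) for c in frame.columns),
            counts=frame.to_numpy().astype(np.int64),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    p: float
    dropped_rows: tuple[str, ...] = ()
    dropped_cols: tuple[str, ...] = ()


def chi2_sf(x: float, df: int) -> float:
    """Upper tail of the chi-square distribution (regularized Q(df/2, x/2))."""
    return float(gammaincc(df / 2.0, x / 2.0))


def pearson_chisq(table: ContingencyTable) -> ChisqResult:
    """Pearson chi-square of independence, no continuity correction.

    Rows/columns with zero margins are dropped (and recorded) first;
    fewer than two retained rows or columns is an error.
    """
    counts = np.asarray(table.counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("table grand total must be positive")
    row_keep = counts.sum(axis=1) > 0
    col_keep = counts.sum(axis=0) > 0
    dropped_rows = tuple(
        lbl for lbl, k in zip(table.row_labels, row_keep) if not k
    )
    dropped_cols = tuple(
        lbl for lbl, k in zip(table.col_labels, col_keep) if not k
    )
    O = counts[np.ix_(row_keep, col_keep)]
    if O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("need at least 2 retained rows and columns")
    R = O.sum(axis=1, keepdims=True)
    C = O.sum(axis=0, keepdims=True)
    E = R @ C / O.sum()
    stat = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return ChisqResult(statistic=stat, df=df, p=chi2_sf(stat, df),
                       dropped_rows=dropped_rows, dropped_cols=dropped_cols)


def subset_table(table: ContingencyTable,
                 rows: Sequence[str]) -> ContingencyTable:
    """Row subset with columns intact; unknown labels are an error."""
    unknown = set(rows) - set(table.row_labels)
    if unknown:
        raise KeyError(f"unknown row label(s): {sorted(unknown)}")
    idx = [table.row_labels.index(r) for r in rows]
    return ContingencyTable(
        row_labels=tuple(rows),
        col_labels=table.col_labels,
        counts=np.asarray(table.counts)[idx, :],
    )


def load_family_counts() -> pd.DataFrame:
    """The bundled five-species family count fixture (clan, family, counts)."""
    with resources.files("cypminer.data").joinpath(
        "cyp_family_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def _family_table(frame: pd.DataFrame) -> ContingencyTable:
    return ContingencyTable(
        row_labels=tuple(frame["family"]),
        col_labels=SPECIES,
        counts=frame[list(SPECIES)].to_numpy().astype(np.int64),
    )


def _clan_table(frame: pd.DataFrame) -> ContingencyTable:
    grouped = frame.groupby("clan", sort=False)[list(SPECIES)].sum()
    return ContingencyTable.from_frame(grouped)


def reproduce_published_stats(frame: pd.DataFrame | None = None) -> dict:
    """Recompute every comparison and tally from the fixture, with guards.

    Returns a report dict with the six chi-square comparisons (statistic,
    df, p, and agreement with the published value at 1 decimal), species
    totals, per-species family counts split into A-type (CYP71-clan) and
    non-A-type, and the six-largest-family shares.
    """
    if frame is None:
        frame = load_family_counts()
    totals = {sp: int(frame[sp].sum()) for sp in SPECIES}
    for sp in SPECIES:
        if totals[sp] != EXPECTED_TOTALS[sp]:
            raise ValueError(
                f"fixture guard failed: column {sp} sums to {totals[sp]}, "
                f"expected {EXPECTED_TOTALS[sp]}"
            )
    fam = _family_table(frame)
    clan = _clan_table(frame)
    fam_jvja = ContingencyTable(fam.row_labels, ("Jv", "Ja"),
                                np.asarray(fam.counts)[:, :2])
    clan_jvja = ContingencyTable(clan.row_labels, ("Jv", "Ja"),
                                 np.asarray(clan.counts)[:, :2])
    single = subset_table(clan, SINGLE_FAMILY_CLANS)
    multi_rows = [
        f for f, c in zip(frame["family"], frame["clan"])
        if c in MULTI_FAMILY_CLANS
    ]
    multi = subset_table(fam, multi_rows)

    comparisons = {}
    for name, tbl in (
        ("clans_five_species", clan),
        ("families_five_species", fam),
        ("single_family_clans_five_species", single),
        ("multi_family_clans_five_species", multi),
        ("clans_jv_vs_ja", clan_jvja),
        ("families_jv_vs_ja", fam_jvja),
    ):
        res = pearson_chisq(tbl)
        pub_stat, pub_df = PUBLISHED[name]
        comparisons[name] = {
            "statistic": round(res.statistic, 1),
            "df": res.df,
            "p": res.p,
            "published_statistic": pub_stat,
            "published_df": pub_df,
            "matches_published": (
                round(res.statistic, 1) == pub_stat and res.df == pub_df
            ),
        }

    fam_counts = frame[list(SPECIES)].to_numpy()
    a_mask = (frame["clan"] == A_TYPE_CLAN).to_numpy()
    six_mask = frame["family"].isin(SIX_LARGEST_FAMILIES).to_numpy()
    per_species = {}
    for j, sp in enumerate(SPECIES):
        col = fam_counts[:, j]
        per_species[sp] = {
            "total": totals[sp],
            "n_families": int((col > 0).sum()),
            "n_a_type_families": int(((col > 0) & a_mask).sum()),
            "n_non_a_type_families": int(((col > 0) & ~a_mask).sum()),
            "six_family_share_pct": float(round(
                100.0 * col[six_mask].sum() / totals[sp], 1
            )),
        }
    return {
        "comparisons": comparisons,
        "per_species": per_species,
        "species_totals": totals,
    }
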