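"""Motif window alignments, sequence-logo information content, consensus.

Windows are cut from each protein at its selected motif hit, optionally
extended by asymmetric flanks; the published logos for the A-type and
non-A-type groups use slightly different window frames around the same
detection anchors, captured in :data:`GROUP_WINDOWS`.

Information content per column is the uncorrected logo convention:
``IC = log2(20) - H`` with ``H`` the Shannon entropy of the residue
frequencies (gaps and ``X`` excluded from the denominator); no small-sample
correction is applied by default so the analytic values for pure, uniform
and two-letter columns are exact.  A corrected mode
(Schneider-style ``(s-1)/(2 ln 2 n)`` subtraction) is available behind a
flag.

Consensus notation follows the field's convention: a residue exceeding the
majority fraction prints as itself, a two-residue column as ``[X/Y]``, and
anything less conserved as ``x``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cyp_detect import CypCall
from .seqio import AMINO_ACIDS

LOG2_20 = math.log2(20)

#: (left, right) flank in residues relative to the detection hit, per
#: (motif, group); chosen so the windows match the published logo frames.
GROUP_WINDOWS: dict[tuple[str, str], tuple[int, int]] = {
    ("heme", "A-type"): (1, -1),
    ("heme", "non-A-type"): (1, 0),
    ("I-helix", "A-type"): (0, 0),
    ("I-helix", "non-A-type"): (0, 1),
    ("PERF", "A-type"): (0, 0),
    ("PERF", "non-A-type"): (0, 0),
    ("ExxR", "A-type"): (0, 0),
    ("ExxR", "non-A-type"): (0, 0),
}


@dataclass(frozen=True)
class MotifAlignment:
    motif: str
    group: str  # "A-type" | "non-A-type"
    windows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("alignment needs at least one window")
        widths = {len(w) for w in self.windows}
        if len(widths) != 1:
            raise ValueError("all windows must have equal length")

    @property
    def width(self) -> int:
        return len(self.windows[0])


@dataclass(frozen=True)
class LogoColumn:
    position: int
    frequencies: Mapping[str, float]
    information_bits: float


def build_motif_alignment(
    calls: Iterable[CypCall],
    motif: str,
    group: str,
    group_of: Mapping[str, str] | None = None,
    flank: int = 0,
    left_flank: int | None = None,
    right_flank: int | None = None,
) -> MotifAlignment:
    """Cut equal-length windows at each call's selected motif hit.

    ``group_of`` maps protein id to "A-type"/"non-A-type"; when omitted all
    calls are included.  ``flank`` extends symmetrically; ``left_flank`` /
    ``right_flank`` override it asymmetrically (negative right shrinks the
    window).  Calls lacking the full window are excluded.
    """
    lf = flank if left_flank is None else left_flank
    rf = flank if right_flank is None else right_flank
    windows = []
    for call in calls:
        if group_of is not None and group_of.get(call.protein.id) != group:
            continue
        hit = call.selected.get(motif)
        if hit is None:
            raise ValueError(
                f"call {call.protein.id!r} has no selected {motif!r} hit"
            )
        start, end = hit.start - lf, hit.end + rf
        if start < 0 or end > len(call.protein.seq) or end <= start:
            continue
        windows.append(call.protein.seq[start:end])
    if not windows:
        raise ValueError(f"no windows selected for {motif!r}/{group!r}")
    return MotifAlignment(motif=motif, group=group, windows=tuple(windows))


def information_content(
    alignment: MotifAlignment, small_sample_correction: bool = False
) -> list[LogoColumn]:
    """Per-column residue frequencies and information content in bits."""
    columns = []
    for pos in range(alignment.width):
        counter = Counter(
            w[pos] for w in alignment.windows if w[pos] in AMINO_ACIDS
        )
        n = sum(counter.values())
        if n == 0:
            raise ValueError(f"column {pos}: no countable residues")
        freqs = {aa: c / n for aa, c in sorted(counter.items())}
        entropy = -sum(p * math.log2(p) for p in freqs.values())
        ic = LOG2_20 - entropy
        if small_sample_correction:
            ic -= (len(AMINO_ACIDS) - 1) / (2.0 * math.log(2) * n)
            ic = max(ic, 0.0)
        columns.append(
            LogoColumn(position=pos, frequencies=freqs, information_bits=ic)
        )
    return columns


def consensus_string(
    columns: Sequence[LogoColumn],
    majority: float = 0.5,
    pair_rule: float = 0.8,
) -> str:
    """Call a consensus in the published notation.

    Per column: a residue with frequency exceeding ``majority`` prints as
    itself; otherwise, if the top two residues jointly reach ``pair_rule``
    and each reaches 0.25, they print as ``[X/Y]`` (alphabetical); anything
    else prints as ``x``.
    """
    if not columns:
        raise ValueError("no columns")
    out = []
    for col in columns:
        ranked = sorted(col.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
        if ranked[0][1] > majority:
            out.append(ranked[0][0])
        elif (
            len(ranked) >= 2
            and ranked[0][1] + ranked[1][1] >= pair_rule
            and ranked[1][1] >= 0.25
        ):
            pair = sorted([ranked[0][0], ranked[1][0]])
            out.append(f"[{pair[0]}/{pair[1]}]")
        else:
            out.append("x")
    return "".join(out)


def plot_logo(columns: Sequence[LogoColumn], path: str,
              title: str = "") -> None:  # pragma: no cover - cosmetic
    """Minimal letter-stack logo rendering (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(columns) * 0.6), 3))
    for col in columns:
        bottom = 0.0
        ranked = sorted(col.frequencies.items(), key=lambda kv: kv[1])
        for aa, freq in ranked:
            h = freq * col.information_bits
            if h <= 0:
                continue
            ax.text(col.position + 0.5, bottom + h / 2, aa,
                    ha="center", va="center",
                    fontsize=8 + 10 * freq, family="monospace")
            bottom += h
    ax.set_xlim(0, len(columns))
    ax.set_ylim(0, LOG2_20)
    ax.set_ylabel("bits")
    ax.set_title(title)
    fig.savefig(path, dpi=100)
    plt.close(fig)
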