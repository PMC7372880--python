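"""Distance-based neighbor-joining trees and an ortholog-pairing statistic.

The trees are desk-scale substitutes for likelihood phylogenies: pairwise
p-distances (``1 - identity/100`` from optimal global alignment) feed the
canonical Saitou-Nei neighbor-joining algorithm, which reproduces additive
distance matrices exactly and is deterministic here (ties broken by the
smallest label pair; negative branch estimates clamped to zero and logged).

The pairing statistic operationalizes the observation that closely related
species carry their CYPs "in pairs": the fraction of one species' leaves
whose nearest non-self leaf belongs to the other species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np

from .redundancy import global_identity
from .seqio import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")


def distance_matrix(proteins: Sequence[ProteinRecord]) -> DistanceMatrix:
    """p-distances ``1 - identity/100`` from pairwise global alignment."""
    if len(proteins) < 3:
        raise ValueError("need at least 3 sequences")
    n = len(proteins)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(proteins[i].seq, proteins[j].seq, "protein")
            d[i, j] = d[j, i] = max(0.0, 1.0 - ident / 100.0)
    return DistanceMatrix(labels=tuple(p.id for p in proteins), d=d)


def neighbor_joining(matrix: DistanceMatrix) -> dendropy.Tree:
    """Canonical Saitou-Nei neighbor joining.

    Deterministic: when several pairs minimize the Q criterion the pair
    with the lexicographically smallest (sorted) label pair is joined.
    Negative branch-length estimates are clamped to zero with a log entry.
    Path lengths on the returned tree reproduce additive inputs exactly.
    """
    labels = list(matrix.labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    D = {
        (a, b): float(matrix.d[i, j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
    }
    taxa = dendropy.TaxonNamespace(labels)
    nodes: dict[str, dendropy.Node] = {}
    for lbl in labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lbl)
        nodes[lbl] = node

    def clamp(x: float, a: str, b: str) -> float:
        if x < 0:
            logger.info("clamping negative NJ branch %s-%s (%.3g)", a, b, x)
            return 0.0
        return x

    active = list(labels)
    join_count = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[(a, b)] for b in active if b != a) for a in active}
        best_pair = None
        best_q = None
        for i in range(n):
            for j in range(i + 1, n):
                a, b = active[i], active[j]
                q = (n - 2) * D[(a, b)] - r[a] - r[b]
                key = tuple(sorted((a, b)))
                if (best_q is None or q < best_q - 1e-12
                        or (abs(q - best_q) <= 1e-12 and key < best_pair)):
                    best_q, best_pair = q, key
        a, b = best_pair
        join_count += 1
        u = f"__nj{join_count}"
        la = 0.5 * D[(a, b)] + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = D[(a, b)] - la
        node = dendropy.Node()
        na, nb = nodes.pop(a), nodes.pop(b)
        na.edge.length = clamp(la, a, u)
        nb.edge.length = clamp(lb, b, u)
        node.add_child(na)
        node.add_child(nb)
        nodes[u] = node
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
            D[(u, c)] = D[(c, u)] = duc
        D[(u, u)] = 0.0
        active = [c for c in active if c not in (a, b)] + [u]

    # resolve the final three taxa around an unrooted central node
    a, b, c = active
    la = 0.5 * (D[(a, b)] + D[(a, c)] - D[(b, c)])
    lb = 0.5 * (D[(a, b)] + D[(b, c)] - D[(a, c)])
    lc = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
    center = dendropy.Node()
    for lbl, ln in ((a, la), (b, lb), (c, lc)):
        child = nodes.pop(lbl)
        child.edge.length = clamp(ln, lbl, "center")
        center.add_child(child)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def tree_path_lengths(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths keyed by sorted label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            key = tuple(sorted((taxa[i].label, taxa[j].label)))
            out[key] = pdm.distance(taxa[i], taxa[j])
    return out


def pairing_statistic(
    matrix: DistanceMatrix,
    species_of: Mapping[str, str] | Callable[[str], str],
    a: str,
    b: str,
) -> dict:
    """Fraction of species-``a`` leaves whose nearest non-self leaf is in
    species ``b`` (ties broken by smallest label).  Returns the fraction
    with its numerator and denominator."""
    get = species_of.get if isinstance(species_of, Mapping) else species_of
    species = [get(lbl) for lbl in matrix.labels]
    if a not in species:
        raise ValueError(f"species {a!r} absent from the matrix")
    if b not in species:
        raise ValueError(f"species {b!r} absent from the matrix")
    n_a = 0
    n_paired = 0
    for i, lbl in enumerate(matrix.labels):
        if species[i] != a:
            continue
        n_a += 1
        order = sorted(
            (j for j in range(len(matrix.labels)) if j != i),
            key=lambda j: (matrix.d[i, j], matrix.labels[j]),
        )
        if species[order[0]] == b:
            n_paired += 1
    return {"fraction": n_paired / n_a, "n_paired": n_paired, "n_total": n_a}
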