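"""Patristic distances, cross-species closest-neighbor maps, and
support-aware clade assignment.

Distances treat the tree as unrooted: the patristic distance between two
leaves is the sum of branch lengths on the unique path between them and is
therefore invariant to rooting.  Clade assignment needs a rooting to speak of
"the smallest clade containing the references"; trees are midpoint-rooted by
default with an optional outgroup override.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def patristic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """All-pairs patristic distance matrix over the tree's leaves.

    Returns (leaf labels sorted lexicographically, symmetric matrix in
    substitutions/site).  Requires branch lengths on every edge.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return labels, mat


def patristic_distance(tree: dendropy.Tree, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths on the path between two named leaves."""
    if leaf_a == leaf_b:
        _require_leaf(tree, leaf_a)
        return 0.0
    ta = _require_leaf(tree, leaf_a)
    tb = _require_leaf(tree, leaf_b)
    pdm = tree.phylogenetic_distance_matrix()
    return float(pdm.patristic_distance(ta, tb))


def _require_leaf(tree: dendropy.Tree, label: str) -> dendropy.Taxon:
    taxon = tree.taxon_namespace.get_taxon(label)
    if taxon is None:
        raise KeyError(f"leaf {label!r} not in tree")
    return taxon


@dataclass
class ClosestNeighborTable:
    """Per focal gene: the closest gene of every other species and its distance.

    ``distances``/``neighbors`` are DataFrames indexed by focal gene with one
    column per non-focal species.  ``summary`` adds min/mean/max over species
    and flags the focal gene whose minimum closest distance is globally
    smallest ("most conserved", the deep-ortholog signature).
    """

    focal_species: str
    distances: pd.DataFrame
    neighbors: pd.DataFrame
    summary: pd.DataFrame

    @property
    def most_conserved(self) -> str:
        return self.summary.index[self.summary["most_conserved"]][0]


def closest_neighbor_map(
    tree: dendropy.Tree,
    focal_species: str,
    species_map: Mapping[str, str],
    focal_genes: Iterable[str] | None = None,
) -> ClosestNeighborTable:
    """For each focal-species leaf, the arg-min patristic distance per other species.

    ``species_map`` maps every leaf label to its species.  ``focal_genes``
    optionally restricts the rows (e.g. to helper-clade genes only).  Ties on
    distance break to the lexicographically smallest gene_id (logged).
    """
    labels, mat = patristic_matrix(tree)
    missing = [l for l in labels if l not in species_map]
    if missing:
        raise KeyError(f"leaves absent from species map: {missing[:5]}")
    species = np.array([species_map[l] for l in labels])
    all_species = sorted(set(species))
    if focal_species not in all_species:
        raise KeyError(f"no leaves of focal species {focal_species!r} in tree")
    others = [s for s in all_species if s != focal_species]
    if not others:
        raise ValueError("tree contains only the focal species")

    if focal_genes is None:
        focal_idx = [i for i, s in enumerate(species) if s == focal_species]
    else:
        wanted = set(focal_genes)
        focal_idx = [
            i for i, (l, s) in enumerate(zip(labels, species))
            if s == focal_species and l in wanted
        ]
    focal_labels = [labels[i] for i in focal_idx]

    dist = pd.DataFrame(index=focal_labels, columns=others, dtype=float)
    neigh = pd.DataFrame(index=focal_labels, columns=others, dtype=object)
    for sp in others:
        cols = [i for i, s in enumerate(species) if s == sp]
        col_labels = [labels[i] for i in cols]
        sub = mat[np.ix_(focal_idx, cols)]
        for r, fl in enumerate(focal_labels):
            row = sub[r]
            m = row.min()
            winners = sorted(col_labels[k] for k in np.flatnonzero(row == m))
            if len(winners) > 1:
                logger.info(
                    "tie for closest %s neighbor of %s: %s (keeping %s)",
                    sp, fl, winners, winners[0],
                )
            dist.loc[fl, sp] = m
            neigh.loc[fl, sp] = winners[0]

    summary = pd.DataFrame(
        {
            "min_over_species": dist.min(axis=1),
            "mean_over_species": dist.mean(axis=1),
            "max_over_species": dist.max(axis=1),
        }
    )
    best = summary["min_over_species"].min()
    flag_gene = sorted(summary.index[summary["min_over_species"] == best])[0]
    summary["most_conserved"] = summary.index == flag_gene
    return ClosestNeighborTable(
        focal_species=focal_species,
        distances=dist,
        neighbors=neigh,
        summary=summary,
    )


@dataclass
class CladeAssignment:
    """Result of support-aware clade assignment.

    ``resolved`` is False when no clade on the root path meets the support
    threshold.  ``extra_leaves`` counts leaves swept in beyond the reference
    MRCA while walking toward the root in search of support.
    """

    resolved: bool
    members: frozenset[str] = frozenset()
    support: float | None = None
    threshold: float = 70.0
    reference_leaves: frozenset[str] = frozenset()
    extra_leaves: int = 0

    def __contains__(self, leaf: str) -> bool:
        return leaf in self.members


def _rooted_for_assignment(
    tree: dendropy.Tree, outgroup: Sequence[str] | None
) -> dendropy.Tree:
    clone = tree.clone(depth=1)
    if outgroup:
        mrca = clone.mrca(taxon_labels=list(outgroup))
        clone.reroot_at_edge(mrca.edge, update_bipartitions=False)
    else:
        clone.reroot_at_midpoint(update_bipartitions=False)
    # the root of a rooted representation induces no bipartition: any support
    # value inherited by its edge during rerooting is meaningless there
    clone.seed_node.edge.support = None
    return clone


def assign_clade(
    tree: dendropy.Tree,
    reference_leaves: Sequence[str],
    support_threshold: float = 70.0,
    outgroup: Sequence[str] | None = None,
) -> CladeAssignment:
    """Smallest supported clade containing all reference leaves.

    The tree is midpoint-rooted (or rooted on ``outgroup``); the MRCA of the
    references is located; if its support does not exceed ``support_threshold``
    (strict >, mirroring the bootstrap>70 convention) the walk proceeds toward
    the root until a supported node is found, reporting how many extra leaves
    were swept in.  No supported node on the path -> an unresolved result, not
    an exception.
    """
    refs = list(reference_leaves)
    if not refs:
        raise ValueError("reference_leaves must be non-empty")
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = set(refs) - leaf_labels
    if missing:
        raise KeyError(f"reference leaves not in tree: {sorted(missing)}")

    rooted = _rooted_for_assignment(tree, outgroup)
    node = rooted.mrca(taxon_labels=refs)
    mrca_size = len(node.leaf_nodes())
    while node is not None:
        # support lives on the edge above the node (bipartition property,
        # stable under the rerooting applied above)
        sup = getattr(node.edge, "support", None)
        if sup is not None and sup > support_threshold:
            members = frozenset(l.taxon.label for l in node.leaf_nodes())
            return CladeAssignment(
                resolved=True,
                members=members,
                support=sup,
                threshold=support_threshold,
                reference_leaves=frozenset(refs),
                extra_leaves=len(members) - mrca_size,
            )
        node = node.parent_node
    return CladeAssignment(
        resolved=False,
        threshold=support_threshold,
        reference_leaves=frozenset(refs),
    )


def make_clade_confirmer(
    tree: dendropy.Tree,
    reference_leaves: Sequence[str],
    support_threshold: float = 70.0,
    outgroup: Sequence[str] | None = None,
) -> Callable[[Iterable[str]], set[str]]:
    """Build a confirmation callback for the ortholog search loop.

    Candidates are confirmed iff they fall inside the supported clade that
    contains the reference orthologs on the supplied background tree.  The
    clade is resolved once and reused across rounds (the tree is fixed).
    """
    clade = assign_clade(
        tree, reference_leaves, support_threshold=support_threshold,
        outgroup=outgroup,
    )
    if not clade.resolved:
        logger.warning(
            "reference clade unresolved at support > %s; confirming nothing",
            support_threshold,
        )

    def confirm(candidates: Iterable[str]) -> set[str]:
        if not clade.resolved:
            return set()
        return {c for c in candidates if c in clade.members}

    return confirm
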