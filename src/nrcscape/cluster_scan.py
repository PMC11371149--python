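"""Genetically linked NLR pairs and clusters under the 50 kb rule.

Two genes on the same scaffold are "genetically linked" when the number of
bases strictly between their intervals is below the threshold (default
50,000 bp, strict <).  Overlapping or nested genes get distance 0 and are
always linked; cross-scaffold linkage is never inferred.  Pairs are edges;
clusters are connected components of the pair graph; both are reported but
pair (edge) counts are the primary summary, matching how whole-NLRome
linkage is usually tallied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genome_io import CladeMap, GeneLocus, GeneTable

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_BP = 50_000

PAIR_TYPES = ("HH", "SS", "HS", "other")


@dataclass(frozen=True)
class GenePairRecord:
    """A genetically linked pair, canonically ordered gene_a < gene_b."""

    gene_a: str
    gene_b: str
    species: str
    scaffold: str
    gap_bp: int
    pair_type: str | None = None


@dataclass(frozen=True)
class ClusterRecord:
    """Connected component of the linkage graph (>= 2 members)."""

    cluster_id: str
    species: str
    scaffold: str
    members: tuple[str, ...]
    span_start: int
    span_end: int


def gene_gap(
    a: GeneLocus, b: GeneLocus, measure: str = "gap"
) -> int | None:
    """Genomic distance between two genes; None when on different scaffolds.

    ``measure="gap"`` (default): bases strictly between the intervals, 0 on
    overlap.  ``measure="start"``: absolute difference of start coordinates
    (exposed because the convention of the original distance scripts in this
    field varies).
    """
    if a.scaffold != b.scaffold or (a.species and b.species and a.species != b.species):
        return None
    if measure == "start":
        return abs(a.start - b.start)
    if measure != "gap":
        raise ValueError(f"unknown distance measure {measure!r}")
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    if hi.start <= lo.end:  # overlap or nested
        return 0
    return hi.start - lo.end - 1


def find_linked_pairs(
    table: GeneTable,
    threshold_bp: int = DEFAULT_THRESHOLD_BP,
    measure: str = "gap",
    inclusive: bool = False,
) -> list[GenePairRecord]:
    """All unordered same-scaffold gene pairs with distance below threshold.

    The cutoff is strict (< threshold) by default; ``inclusive=True`` turns it
    into <=.  Implemented as a scaffold-sorted sweep: for a fixed upstream
    gene the gap to later genes is non-decreasing in their start coordinate,
    so the inner scan stops at the first start beyond reach.  Equivalent to
    the O(n^2) all-pairs filter.
    """
    if threshold_bp <= 0:
        raise ValueError("threshold_bp must be positive")

    def passes(gap: int) -> bool:
        return gap <= threshold_bp if inclusive else gap < threshold_bp

    pairs: list[GenePairRecord] = []
    for scaffold, genes in table.by_scaffold().items():
        for i, gi in enumerate(genes):
            # genes are sorted by start, so for fixed gi the distance to gj
            # (either measure) is non-decreasing in gj.start: stop at the
            # first failing gene.
            for gj in genes[i + 1 :]:
                gap = gene_gap(gi, gj, measure=measure)
                if gap is None or not passes(gap):
                    break
                a, b = sorted((gi.gene_id, gj.gene_id))
                pairs.append(
                    GenePairRecord(
                        gene_a=a,
                        gene_b=b,
                        species=gi.species,
                        scaffold=scaffold,
                        gap_bp=gap,
                    )
                )
    pairs.sort(key=lambda p: (p.scaffold, p.gene_a, p.gene_b))
    return pairs


def pairs_to_clusters(
    pairs: Sequence[GenePairRecord], table: GeneTable
) -> list[ClusterRecord]:
    """Connected components of the pair graph; singletons are excluded."""
    graph = nx.Graph()
    for p in pairs:
        graph.add_edge(p.gene_a, p.gene_b)
    clusters: list[ClusterRecord] = []
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for k, comp in enumerate(comps):
        members = tuple(sorted(comp))
        loci = [table.get(m) for m in members]
        species = loci[0].species
        scaffold = loci[0].scaffold
        clusters.append(
            ClusterRecord(
                cluster_id=f"{species or 'na'}.{scaffold}.c{k:03d}",
                species=species,
                scaffold=scaffold,
                members=members,
                span_start=min(l.start for l in loci),
                span_end=max(l.end for l in loci),
            )
        )
    return clusters


def type_pairs(
    pairs: Sequence[GenePairRecord], clades: CladeMap
) -> tuple[list[GenePairRecord], pd.DataFrame]:
    """Label pairs HH/SS/HS/other by clade and tally per species.

    HH: both members helper-clade (NRC_H, incl. NRC0); SS: both sensor-clade
    (NRC_S, incl. NRC0_S); HS: one of each; other: any member outside the NRC
    superclade.  HH + SS + HS therefore partitions the pairs whose members are
    both inside the superclade.
    """
    typed: list[GenePairRecord] = []
    for p in pairs:
        a_h, a_s = clades.is_helper(p.gene_a), clades.is_sensor(p.gene_a)
        b_h, b_s = clades.is_helper(p.gene_b), clades.is_sensor(p.gene_b)
        if a_h and b_h:
            t = "HH"
        elif a_s and b_s:
            t = "SS"
        elif (a_h and b_s) or (a_s and b_h):
            t = "HS"
        else:
            t = "other"
        typed.append(replace(p, pair_type=t))

    rows: dict[str, dict[str, int]] = {}
    for p in typed:
        sp = p.species or "na"
        row = rows.setdefault(sp, {t: 0 for t in PAIR_TYPES})
        row[p.pair_type] += 1
    summary = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    summary = summary.reindex(columns=list(PAIR_TYPES), fill_value=0)
    summary = summary.sort_index()
    summary["total"] = summary.sum(axis=1)
    summary.loc["total"] = summary.sum(axis=0)
    summary.index.name = "species"
    return typed, summary


def conserved_pairs_across_species(
    typed_pairs_by_species: Mapping[str, Sequence[GenePairRecord]],
    group_map: Mapping[str, str],
    pair_type: str = "HS",
) -> pd.DataFrame:
    """Helper-sensor pair classes present in every queried species.

    A pair class is the unordered pair of ortholog-group labels of the two
    members (``group_map``: gene_id -> group).  A class is conserved when at
    least one witnessing pair of the requested type exists in each species of
    the mapping.  Returns one row per conserved class with the witnessing
    pairs per species.
    """
    species = sorted(typed_pairs_by_species)
    if len(species) == 1:
        logger.warning(
            "conserved-pair scan over a single species: every class is "
            "trivially conserved"
        )
    witnesses: dict[tuple[str, str], dict[str, list[str]]] = {}
    for sp in species:
        for p in typed_pairs_by_species[sp]:
            if pair_type is not None and p.pair_type != pair_type:
                continue
            ga = group_map.get(p.gene_a)
            gb = group_map.get(p.gene_b)
            if ga is None or gb is None:
                continue
            cls = tuple(sorted((ga, gb)))
            witnesses.setdefault(cls, {}).setdefault(sp, []).append(
                f"{p.gene_a}--{p.gene_b}"
            )
    rows = []
    for cls in sorted(witnesses):
        per_sp = witnesses[cls]
        if set(per_sp) == set(species):
            rows.append(
                {
                    "class_a": cls[0],
                    "class_b": cls[1],
                    "n_species": len(per_sp),
                    "n_pairs": sum(len(v) for v in per_sp.values()),
                    **{
                        f"pairs_{sp}": ";".join(sorted(per_sp[sp]))
                        for sp in species
                    },
                }
            )
    cols = ["class_a", "class_b", "n_species", "n_pairs"] + [
        f"pairs_{sp}" for sp in species
    ]
    return pd.DataFrame(rows, columns=cols)


def build_cluster_matrix(
    pairs: Sequence[GenePairRecord], tree_leaf_order: Sequence[str]
) -> pd.DataFrame:
    """Symmetric 0/1 linkage matrix over genes in tree-leaf order.

    Genes appearing in pairs but absent from the leaf order are dropped with
    a warning (they fell outside the tree used for visualization).
    """
    order = list(tree_leaf_order)
    idx = {g: i for i, g in enumerate(order)}
    mat = np.zeros((len(order), len(order)), dtype=int)
    dropped = set()
    for p in pairs:
        if p.gene_a not in idx or p.gene_b not in idx:
            dropped.update({p.gene_a, p.gene_b} - set(idx))
            continue
        i, j = idx[p.gene_a], idx[p.gene_b]
        mat[i, j] = mat[j, i] = 1
    if dropped:
        logger.warning(
            "%d genes in pairs but not in tree leaf order: %s",
            len(dropped), sorted(dropped)[:5],
        )
    return pd.DataFrame(mat, index=order, columns=order)


def pairs_to_frame(pairs: Iterable[GenePairRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "species": p.species,
                "scaffold": p.scaffold,
                "gap_bp": p.gap_bp,
                "pair_type": p.pair_type or "",
            }
            for p in pairs
        ],
        columns=["gene_a", "gene_b", "species", "scaffold", "gap_bp", "pair_type"],
    )


def write_itol_connections(
    pairs: Sequence[GenePairRecord], path, color: str = "#1f78b4"
) -> None:
    """Export pairs as an iTOL DATASET_CONNECTION annotation file."""
    with open(path, "w") as fh:
        fh.write("DATASET_CONNECTION\nSEPARATOR COMMA\n")
        fh.write("DATASET_LABEL,gene_clusters\nCOLOR,#ff0000\n")
        fh.write("DRAW_ARROWS,0\nCURVE_ANGLE,0\nDATA\n")
        for p in pairs:
            fh.write(f"{p.gene_a},{p.gene_b},1,{color},normal,{p.gap_bp}\n")
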