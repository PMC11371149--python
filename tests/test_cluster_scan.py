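"""Linkage rule, sweep-vs-brute-force equivalence, pair typing and the
cluster matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrcscape import cluster_scan as cs
from nrcscape.genome_io import CladeMap, GeneLocus, GeneTable


def locus(gid, start, end, scaffold="chr1", species="sp"):
    return GeneLocus(gid, species, scaffold, start, end, "+")


# --- gene_gap ---------------------------------------------------------------

@pytest.mark.parametrize(
    "a, b, expected",
    [
        (locus("a", 100, 500), locus("b", 600, 900), 99),
        (locus("a", 100, 500), locus("b", 400, 900), 0),   # overlap
        (locus("a", 100, 500), locus("b", 200, 300), 0),   # nested
        (locus("a", 100, 500), locus("b", 501, 600), 0),   # adjacent
        (locus("a", 100, 500), locus("b", 502, 600), 1),
        (locus("b", 600, 900), locus("a", 100, 500), 99),  # order-free
    ],
)
def test_gene_gap_interval_arithmetic(a, b, expected):
    assert cs.gene_gap(a, b) == expected


def test_gene_gap_cross_scaffold_unlinked():
    assert cs.gene_gap(locus("a", 1, 10), locus("b", 1, 10, scaffold="chr2")) is None


def test_gene_gap_start_measure():
    assert cs.gene_gap(locus("a", 100, 500), locus("b", 600, 900), measure="start") == 500


# --- find_linked_pairs ------------------------------------------------------

def brute_force_pairs(table, threshold, inclusive=False):
    """Independent O(n^2) oracle with its own arithmetic."""
    out = set()
    recs = list(table)
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            if a.scaffold != b.scaffold:
                continue
            lo, hi = (a, b) if a.start <= b.start else (b, a)
            gap = 0 if hi.start <= lo.end else hi.start - lo.end - 1
            if gap <= threshold if inclusive else gap < threshold:
                out.add(tuple(sorted((a.gene_id, b.gene_id))) + (gap,))
    return out


def random_table(rng, n):
    recs = []
    for k in range(n):
        scaffold = f"chr{rng.integers(1, 6)}"
        start = int(rng.integers(1, 2_000_000))
        length = int(rng.integers(200, 60_000))
        recs.append(locus(f"g{k:03d}", start, start + length - 1, scaffold))
    return GeneTable(recs)


def test_boundary_gap_exactly_at_threshold_not_paired():
    table = GeneTable([locus("a", 1, 1000), locus("b", 51_001, 52_000)])
    assert cs.gene_gap(table.get("a"), table.get("b")) == 50_000
    assert cs.find_linked_pairs(table) == []
    inclusive = cs.find_linked_pairs(table, inclusive=True)
    assert [(p.gene_a, p.gene_b) for p in inclusive] == [("a", "b")]


def test_three_gene_chain_outer_pair_depends_on_middle_span():
    # gaps 10 kb each; outer gap = 10k + 2k + 10k = 22,002 < 50 kb -> 3 pairs
    small = GeneTable([
        locus("a", 1, 1000),
        locus("b", 11_002, 13_001),           # gap a-b = 10,000; len 2 kb
        locus("c", 23_003, 24_000),           # gap b-c = 10,001
    ])
    assert len(cs.find_linked_pairs(small)) == 3
    # middle gene spans 40 kb; outer gap = 10k + 40k + 10k > 50 kb -> 2 pairs
    wide = GeneTable([
        locus("a", 1, 1000),
        locus("b", 11_002, 51_001),
        locus("c", 61_003, 62_000),
    ])
    assert len(cs.find_linked_pairs(wide)) == 2


def test_sweep_equals_brute_force_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(20):
        table = random_table(rng, int(rng.integers(20, 200)))
        got = {(p.gene_a, p.gene_b, p.gap_bp) for p in cs.find_linked_pairs(table)}
        assert got == brute_force_pairs(table, 50_000)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_pair_and_cluster_results_invariant_under_row_order(seed):
    rng = np.random.default_rng(seed)
    table = random_table(rng, 40)
    recs = list(table)
    shuffled = GeneTable(list(rng.permutation(recs)))
    p1 = [(p.gene_a, p.gene_b, p.gap_bp) for p in cs.find_linked_pairs(table)]
    p2 = [(p.gene_a, p.gene_b, p.gap_bp) for p in cs.find_linked_pairs(shuffled)]
    assert p1 == p2
    c1 = {c.members for c in cs.pairs_to_clusters(cs.find_linked_pairs(table), table)}
    c2 = {c.members for c in cs.pairs_to_clusters(cs.find_linked_pairs(shuffled), shuffled)}
    assert c1 == c2


# --- pairs_to_clusters ------------------------------------------------------

def test_transitive_chain_is_one_cluster():
    table = GeneTable([
        locus("a", 1, 1000), locus("b", 2000, 3000), locus("c", 4000, 5000)
    ])
    pairs = [
        cs.GenePairRecord("a", "b", "sp", "chr1", 999),
        cs.GenePairRecord("b", "c", "sp", "chr1", 999),
    ]
    clusters = cs.pairs_to_clusters(pairs, table)
    assert len(clusters) == 1
    assert clusters[0].members == ("a", "b", "c")
    assert (clusters[0].span_start, clusters[0].span_end) == (1, 5000)


def test_no_pairs_no_clusters():
    table = GeneTable([locus("a", 1, 10)])
    assert cs.pairs_to_clusters([], table) == []


def test_component_count_matches_graph_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        table = random_table(rng, 80)
        pairs = cs.find_linked_pairs(table)
        clusters = cs.pairs_to_clusters(pairs, table)
        # oracle: count components by repeated set expansion
        adj = {}
        for p in pairs:
            adj.setdefault(p.gene_a, set()).add(p.gene_b)
            adj.setdefault(p.gene_b, set()).add(p.gene_a)
        seen, n_comp = set(), 0
        for g in sorted(adj):
            if g in seen:
                continue
            n_comp += 1
            stack = [g]
            while stack:
                x = stack.pop()
                if x not in seen:
                    seen.add(x)
                    stack.extend(adj[x] - seen)
        assert len(clusters) == n_comp


# --- type_pairs -------------------------------------------------------------

def test_pair_typing_and_partition():
    clades = CladeMap(labels={
        "h1": "NRC_H", "h2": "NRC0", "s1": "NRC_S", "s2": "NRC0_S", "o1": "OTHER",
    })
    pairs = [
        cs.GenePairRecord("h1", "h2", "sp", "c", 10),
        cs.GenePairRecord("s1", "s2", "sp", "c", 10),
        cs.GenePairRecord("h2", "s2", "sp", "c", 10),
        cs.GenePairRecord("h1", "o1", "sp", "c", 10),
    ]
    typed, summary = cs.type_pairs(pairs, clades)
    assert [p.pair_type for p in typed] == ["HH", "SS", "HS", "other"]
    row = summary.loc["sp"]
    assert (row["HH"], row["SS"], row["HS"], row["other"]) == (1, 1, 1, 1)
    assert row["total"] == 4
    # HH + SS + HS partitions the superclade pairs
    superclade = [p for p in typed
                  if clades.in_superclade(p.gene_a) and clades.in_superclade(p.gene_b)]
    assert row["HH"] + row["SS"] + row["HS"] == len(superclade)


def test_per_species_counts_sum_to_total(default_dataset):
    ds = default_dataset
    all_typed = []
    for sp in ds.species:
        pairs = cs.find_linked_pairs(ds.gene_tables[sp])
        typed, _ = cs.type_pairs(pairs, ds.clade_map)
        all_typed.extend(typed)
    _, summary = cs.type_pairs(all_typed, ds.clade_map)
    body = summary.drop(index="total")
    assert (body.sum(axis=0) == summary.loc["total"]).all()


# --- conserved pairs --------------------------------------------------------

def test_conserved_class_requires_every_species():
    groups = {"h1": "OGH", "s1": "OGS", "h2": "OGH", "s2": "OGS"}
    p1 = cs.GenePairRecord("h1", "s1", "sp1", "c", 10, "HS")
    p2 = cs.GenePairRecord("h2", "s2", "sp2", "c", 10, "HS")
    full = cs.conserved_pairs_across_species({"sp1": [p1], "sp2": [p2]}, groups)
    assert len(full) == 1
    assert (full.iloc[0]["class_a"], full.iloc[0]["class_b"]) == ("OGH", "OGS")
    partial = cs.conserved_pairs_across_species(
        {"sp1": [p1], "sp2": [p2], "sp3": []}, groups
    )
    assert partial.empty


def test_single_species_trivially_conserved_warns(caplog):
    groups = {"h1": "OGH", "s1": "OGS"}
    p1 = cs.GenePairRecord("h1", "s1", "sp1", "c", 10, "HS")
    with caplog.at_level("WARNING"):
        out = cs.conserved_pairs_across_species({"sp1": [p1]}, groups)
    assert len(out) == 1
    assert any("single species" in r.message for r in caplog.records)


def test_planted_conserved_class_found_exactly(default_dataset):
    ds = default_dataset
    groups = dict(zip(ds.truth.genes.gene_id, ds.truth.genes.ortholog_group))
    typed_by_sp = {}
    for sp in ds.species[: ds.config.nrc0_linked_species]:
        pairs = cs.find_linked_pairs(ds.gene_tables[sp])
        typed, _ = cs.type_pairs(pairs, ds.clade_map)
        typed_by_sp[sp] = typed
    out = cs.conserved_pairs_across_species(typed_by_sp, groups)
    assert list(zip(out.class_a, out.class_b)) == [("OG_NRC0", "OG_NRC0S")]


# --- cluster matrix ---------------------------------------------------------

def test_cluster_matrix_properties():
    order = ["a", "b", "c", "d"]
    pairs = [cs.GenePairRecord("a", "b", "sp", "c", 1),
             cs.GenePairRecord("b", "c", "sp", "c", 1)]
    mat = cs.build_cluster_matrix(pairs, order)
    arr = mat.to_numpy()
    assert (arr == arr.T).all()
    assert arr.trace() == 0
    assert arr.sum() == 4  # two symmetric edges
    assert cs.build_cluster_matrix([], order).to_numpy().sum() == 0


def test_cluster_matrix_permutation_conjugation():
    rng = np.random.default_rng(5)
    order = [f"g{i}" for i in range(8)]
    pairs = [cs.GenePairRecord(*sorted(rng.choice(order, 2, replace=False)), "sp", "c", 1)
             for _ in range(6)]
    m1 = cs.build_cluster_matrix(pairs, order).to_numpy()
    perm = list(rng.permutation(8))
    m2 = cs.build_cluster_matrix(pairs, [order[i] for i in perm]).to_numpy()
    p = np.eye(8)[perm]
    assert (m2 == p @ m1 @ p.T).all()


def test_cluster_matrix_drops_unknown_genes_with_warning(caplog):
    pairs = [cs.GenePairRecord("a", "zz", "sp", "c", 1)]
    with caplog.at_level("WARNING"):
        mat = cs.build_cluster_matrix(pairs, ["a", "b"])
    assert mat.to_numpy().sum() == 0
    assert any("not in tree leaf order" in r.message for r in caplog.records)
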