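"""Local alignment against an exhaustive oracle, filter semantics, and the
iterative recruit-confirm loop."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from nrcscape import ortholog_pipeline as op
from nrcscape import phylo_metrics as pm


# --- exhaustive local-alignment oracle for tiny sequences -------------------

BLOSUM62 = substitution_matrices.load("BLOSUM62")
MAX_SUB = float(np.max(BLOSUM62))


def oracle_local_score(q, s, gap_open=12, gap_extend=1):
    """Best local alignment score by explicit path enumeration.

    Explores every alignment path from every start cell with affine gap
    state, pruned only by an admissible bound.  Independent of any DP
    formulation.
    """
    best = 0.0

    def go(i, j, score, last):
        nonlocal best
        if score > best:
            best = score
        # admissible bound: at most min(remaining) more aligned pairs, each
        # worth at most the largest substitution score
        if score + MAX_SUB * min(len(q) - i, len(s) - j) <= best:
            return
        if i < len(q) and j < len(s):
            go(i + 1, j + 1, score + BLOSUM62[q[i], s[j]], "diag")
        if i < len(q):
            go(i + 1, j, score - (gap_extend if last == "qgap" else gap_open), "qgap")
        if j < len(s):
            go(i, j + 1, score - (gap_extend if last == "sgap" else gap_open), "sgap")

    for i in range(len(q)):
        for j in range(len(s)):
            go(i, j, 0.0, None)
    return best


def test_local_align_score_matches_exhaustive_oracle():
    rng = np.random.default_rng(11)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    cases = [("MADA", "QQQQ"), ("MADA", "MADA"), ("WWW", "WAW")]
    cases += [
        (
            "".join(rng.choice(list(aas), size=rng.integers(3, 7))),
            "".join(rng.choice(list(aas), size=rng.integers(3, 7))),
        )
        for _ in range(9)
    ]
    for q, s in cases:
        hit = op.local_align(q, s)
        assert hit.score == pytest.approx(oracle_local_score(q, s)), (q, s)


def test_local_align_identity_and_coverage_definitions():
    hit = op.local_align("MADGEGTR", "MADGEGTR")
    assert hit.percent_identity == 100.0
    assert hit.query_coverage == 100.0
    # identity symmetric, coverage is not (query-length denominators differ)
    a = op.local_align("MADGEGTR", "MADGEGTRINWEPFDW")
    b = op.local_align("MADGEGTRINWEPFDW", "MADGEGTR")
    assert a.percent_identity == pytest.approx(b.percent_identity)
    assert a.query_coverage == pytest.approx(100.0)
    assert b.query_coverage == pytest.approx(50.0)


def test_local_align_rejects_empty_sequences():
    with pytest.raises(ValueError):
        op.local_align("", "MADA")


# --- search_round -----------------------------------------------------------

def test_search_round_self_recruits_and_inclusive_thresholds():
    db = {"q_copy": "MADGEGTRINWEPFDWKQYHR", "junk": "PPPPPPPPPPPPPPPPPPPPP"}
    hits = op.search_round({"q": "MADGEGTRINWEPFDWKQYHR"}, db)
    assert [h.subject_id for h in hits] == ["q_copy"]
    assert hits[0].percent_identity == 100.0


def test_search_round_thresholds_are_inclusive(default_dataset):
    # filters keep a hit sitting exactly at the cutoffs and drop one just below
    ds = default_dataset
    a, b = ds.truth.nrc0_genes[:2]
    hit = op.local_align(ds.sequences[a], ds.sequences[b])
    db = {b: ds.sequences[b]}
    at = op.search_round({a: ds.sequences[a]}, db,
                         min_identity=hit.percent_identity,
                         min_coverage=hit.query_coverage)
    assert [h.subject_id for h in at] == [b]
    above = op.search_round({a: ds.sequences[a]}, db,
                            min_identity=hit.percent_identity + 1e-6,
                            min_coverage=hit.query_coverage)
    assert above == []


def test_recruited_set_equals_brute_force_filter(default_dataset):
    ds = default_dataset
    refs = ds.truth.nrc0_genes
    queries = {refs[0]: ds.sequences[refs[0]]}
    db = dict(ds.sequences.items())
    hits = op.search_round(queries, db)
    got = {h.subject_id for h in hits}
    want = set()
    for sid, seq in db.items():
        h = op.local_align(queries[refs[0]], seq)
        if h.percent_identity >= 40 and h.query_coverage >= 95:
            want.add(sid)
    assert got == want
    assert set(refs) <= got  # the planted ortholog group passes the filters


# --- iterate_search ---------------------------------------------------------

def chain_family():
    """A -> B -> C identity chain: C is <40% to A but >=40% to B."""
    rng = np.random.default_rng(19)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    n = 100
    a = rng.integers(0, 20, n)

    def mutate(seq, frac):
        out = seq.copy()
        k = int(frac * n)
        pos = rng.choice(n, size=k, replace=False)
        r = rng.integers(0, 19, k)
        out[pos] = r + (r >= out[pos])
        return out

    b = mutate(a, 0.45)      # A-B ~55% identity
    c = mutate(b, 0.45)      # B-C ~55%, A-C ~ 0.55^2 ~ 30%
    return {k: "".join(aas[v]) for k, v in {"A": a, "B": b, "C": c}.items()}


def test_chain_recruitment_across_rounds():
    fam = chain_family()
    a_c = op.local_align(fam["A"], fam["C"])
    assert a_c.percent_identity < 40  # construction holds
    result = op.iterate_search({"A": fam["A"]}, fam, min_coverage=90)
    assert result.members == {"A", "B", "C"}
    assert result.provenance["B"][0] == 1
    assert result.provenance["C"][0] == 2
    assert result.converged


def test_no_recruitment_returns_seeds_only():
    db = {"A": "MADGEGTRINWEPFDWKQYHR", "far": "PLPLPLPLPLPLPLPLPLPLP"}
    result = op.iterate_search({"A": db["A"]}, db)
    assert result.members == {"A"}
    assert result.converged


def test_ortholog_set_monotone_over_rounds():
    fam = chain_family()
    sets = []
    for rounds in [1, 2, 3]:
        r = op.iterate_search({"A": fam["A"]}, fam, min_coverage=90,
                              max_rounds=rounds)
        sets.append(set(r.members))
    assert sets[0] <= sets[1] <= sets[2]


def test_result_invariant_under_input_order():
    fam = chain_family()
    forward = op.iterate_search({"A": fam["A"]}, fam, min_coverage=90)
    reordered = dict(reversed(list(fam.items())))
    backward = op.iterate_search({"A": fam["A"]}, reordered, min_coverage=90)
    assert forward.members == backward.members
    assert forward.provenance == backward.provenance


def test_confirmation_quarantines_but_reports(default_dataset, default_tree):
    ds = default_dataset
    refs = ds.truth.nrc0_genes
    seeds = {refs[0]: ds.sequences[refs[0]]}
    # confirm nothing: every candidate must end up quarantined, none accepted
    result = op.iterate_search(seeds, ds.sequences, confirm=lambda c: set())
    assert result.members == set()
    assert refs[0] in result.quarantined


def test_planted_orthologs_recovered_with_perfect_precision_recall(
    default_dataset, default_tree
):
    ds = default_dataset
    refs = ds.truth.nrc0_genes
    seeds = {g: ds.sequences[g] for g in refs if g.startswith("sp01")}
    confirm = pm.make_clade_confirmer(default_tree, refs[:2], 70)
    result = op.iterate_search(seeds, ds.sequences, confirm=confirm)
    assert result.members == set(refs)
    audit = op.audit_filters(result.members, dict(ds.sequences.items()))
    assert all(audit.values())


# --- extract_linked_sensors -------------------------------------------------

def test_linked_sensor_extraction_matches_truth(default_dataset):
    ds = default_dataset
    per, summary = op.extract_linked_sensors(
        ds.truth.nrc0_genes, ds.gene_tables, ds.clade_map
    )
    # every ortholog with coordinates is listed, even with zero sensors
    assert set(per["ortholog"]) == set(ds.truth.nrc0_genes)
    truth_pairs = ds.truth.pairs
    for _, row in per.iterrows():
        want = set()
        for _, p in truth_pairs[truth_pairs.species == row.species].iterrows():
            if p.gene_a == row.ortholog and ds.clade_map.is_sensor(p.gene_b):
                want.add(p.gene_b)
            if p.gene_b == row.ortholog and ds.clade_map.is_sensor(p.gene_a):
                want.add(p.gene_a)
        got = set(row.linked_sensors.split(";")) if row.linked_sensors else set()
        assert got == want
    assert summary.loc["total", "n_orthologs"] == len(ds.truth.nrc0_genes)


def test_ortholog_without_neighbors_listed_with_zero(default_dataset):
    ds = default_dataset
    # a lineage-specific helper far from sensors: take one with no truth pair
    paired = set(ds.truth.pairs.gene_a) | set(ds.truth.pairs.gene_b)
    lonely = [g for g in ds.clade_map.genes_with_label("NRC_H")
              if g not in paired][:1]
    per, _ = op.extract_linked_sensors(lonely, ds.gene_tables, ds.clade_map)
    assert len(per) == 1
    assert per.iloc[0]["n_linked_sensors"] == 0
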