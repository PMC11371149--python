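"""Iterative ortholog discovery: local alignment, identity/coverage
filtering, and the recruit-confirm fixed-point loop.

The search stands in for an iterated BLASTP protocol at desk scale: exact
Smith-Waterman local alignment (BLOSUM62, affine gaps, BLAST-convention
open 11 / extend 1) replaces heuristic seeding, and candidates pass when
percent identity >= 40 and query coverage >= 95 (both inclusive) for at
least one query.  E-values are not used; the filters are on identity and
coverage only.  Accepted candidates become the next round's queries until a
round recruits nothing new.  A clade-confirmation callback (usually built by
:func:`nrcscape.phylo_metrics.make_clade_confirmer`) gates acceptance;
candidates that fail confirmation are quarantined and reported, not
silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .cluster_scan import DEFAULT_THRESHOLD_BP, find_linked_pairs
from .genome_io import CladeMap, GeneTable, SequenceSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 40.0
DEFAULT_MIN_COVERAGE = 95.0


@dataclass(frozen=True)
class Scoring:
    """Local-alignment scoring: substitution matrix + affine gaps.

    Gap costs follow the BLAST convention: a gap of length k costs
    ``gap_open + k * gap_extend`` (default 11 + k).
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def aligner(self) -> PairwiseAligner:
        aln = PairwiseAligner(
            mode="local",
            substitution_matrix=substitution_matrices.load(self.matrix),
            # biopython charges open_gap_score for the first gapped column and
            # extend for each further one: open+(k-1)*ext == 11+k requires
            # open = gap_open + gap_extend.
            open_gap_score=-(self.gap_open + self.gap_extend),
            extend_gap_score=-self.gap_extend,
        )
        return aln


@dataclass(frozen=True)
class SearchHit:
    """One query-subject local alignment with BLAST-style statistics.

    ``percent_identity`` is identities over alignment columns (gapped columns
    included); ``query_coverage`` is the aligned query span over the query
    length, both on the 0-100 scale and computed from the same alignment.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    query_coverage: float
    score: float


def local_align(
    query: str,
    subject: str,
    scoring: Scoring = Scoring(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> SearchHit:
    """Optimal Smith-Waterman local alignment of two protein sequences."""
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    aligner = scoring.aligner()
    alignments = aligner.align(query, subject)
    if len(alignments) == 0 or alignments.score <= 0:
        return SearchHit(query_id, subject_id, 0.0, 0.0, 0.0)
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    qblocks = aln.aligned[0]
    span = int(qblocks[-1][1] - qblocks[0][0]) if len(qblocks) else 0
    coverage = 100.0 * span / len(query)
    return SearchHit(query_id, subject_id, identity, coverage, float(aln.score))


def search_round(
    queries: Mapping[str, str],
    database: Mapping[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    scoring: Scoring = Scoring(),
) -> list[SearchHit]:
    """All database sequences hit by >= 1 query passing both filters (>=).

    Returns the passing hits sorted by (subject, query); a subject recruited
    by several queries keeps every passing hit for provenance.
    """
    hits: list[SearchHit] = []
    for qid in sorted(queries):
        qseq = queries[qid]
        for sid in sorted(database):
            hit = local_align(
                qseq, database[sid], scoring=scoring,
                query_id=qid, subject_id=sid,
            )
            if hit.percent_identity >= min_identity and hit.query_coverage >= min_coverage:
                hits.append(hit)
    hits.sort(key=lambda h: (h.subject_id, h.query_id))
    return hits


@dataclass
class OrthologSet:
    """Accepted orthologs with per-round recruitment provenance.

    ``provenance[gene] = (round, recruiting query)``; seeds are round 0.
    ``quarantined`` holds candidates that passed the similarity filters but
    failed clade confirmation in some round.
    """

    members: set[str] = field(default_factory=set)
    provenance: dict[str, tuple[int, str]] = field(default_factory=dict)
    quarantined: set[str] = field(default_factory=set)
    rounds_run: int = 0
    converged: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "round": self.provenance[g][0],
             "recruited_by": self.provenance[g][1]}
            for g in sorted(self.members)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "round", "recruited_by"])


def iterate_search(
    seeds: Mapping[str, str],
    database: SequenceSet | Mapping[str, str],
    confirm: Callable[[Iterable[str]], set[str]] | None = None,
    max_rounds: int = 10,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    scoring: Scoring = Scoring(),
) -> OrthologSet:
    """Fixed-point iterated search: recruit, confirm, re-query.

    Seeds present in the database are confirmed members from round 0 (external
    seed sequences recruit but are not themselves reported as members).  Each
    round queries with the previous round's new members; recruitment stops
    when a round confirms nothing new or ``max_rounds`` is hit (logged).  The
    result is independent of seed/database ordering: all iteration is over
    sorted ids.
    """
    db = dict(database.items()) if hasattr(database, "items") else dict(database)
    result = OrthologSet()

    seed_members = sorted(set(seeds) & set(db))
    candidates0 = seed_members
    if confirm is not None:
        confirmed0 = confirm(candidates0)
        result.quarantined |= set(candidates0) - confirmed0
        candidates0 = sorted(confirmed0)
    for g in candidates0:
        result.members.add(g)
        result.provenance[g] = (0, "seed")

    queries: dict[str, str] = dict(sorted(seeds.items()))
    for rnd in range(1, max_rounds + 1):
        if not queries:
            result.converged = True
            break
        remaining = {
            sid: s for sid, s in db.items()
            if sid not in result.members and sid not in queries
        }
        hits = search_round(
            queries, remaining,
            min_identity=min_identity, min_coverage=min_coverage,
            scoring=scoring,
        )
        recruited: dict[str, str] = {}
        for h in hits:
            recruited.setdefault(h.subject_id, h.query_id)
        candidates = sorted(set(recruited) - result.members - result.quarantined)
        if confirm is not None:
            confirmed = confirm(candidates)
            newly_quarantined = set(candidates) - confirmed
            if newly_quarantined:
                logger.info(
                    "round %d: %d candidates failed clade confirmation: %s",
                    rnd, len(newly_quarantined), sorted(newly_quarantined)[:5],
                )
            result.quarantined |= newly_quarantined
            candidates = sorted(confirmed)
        result.rounds_run = rnd
        if not candidates:
            result.converged = True
            break
        for g in candidates:
            result.members.add(g)
            result.provenance[g] = (rnd, recruited[g])
        queries = {g: db[g] for g in candidates}
    else:
        logger.warning("iterate_search stopped at max_rounds=%d", max_rounds)
    if result.rounds_run == 0:
        result.converged = True
    return result


def extract_linked_sensors(
    orthologs: Iterable[str],
    gene_tables: Mapping[str, GeneTable],
    clades: CladeMap,
    threshold_bp: int = DEFAULT_THRESHOLD_BP,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sensor-clade NLRs genetically linked (< threshold) to each ortholog.

    Every ortholog that has genomic coordinates is listed, including those
    with zero linked sensors.  Returns (per-ortholog table, per-species
    summary with the headline counts: orthologs, linked orthologs, distinct
    linked sensors).
    """
    ortho = sorted(set(orthologs))
    rows = []
    for species in sorted(gene_tables):
        table = gene_tables[species]
        pairs = find_linked_pairs(table, threshold_bp=threshold_bp)
        partners: dict[str, set[str]] = {}
        for p in pairs:
            partners.setdefault(p.gene_a, set()).add(p.gene_b)
            partners.setdefault(p.gene_b, set()).add(p.gene_a)
        for g in ortho:
            if g not in table:
                continue
            sensors = sorted(
                x for x in partners.get(g, ()) if clades.is_sensor(x)
            )
            rows.append(
                {
                    "ortholog": g,
                    "species": species,
                    "scaffold": table.get(g).scaffold,
                    "n_linked_sensors": len(sensors),
                    "linked_sensors": ";".join(sensors),
                }
            )
    per_ortholog = pd.DataFrame(
        rows,
        columns=["ortholog", "species", "scaffold", "n_linked_sensors",
                 "linked_sensors"],
    )
    if per_ortholog.empty:
        summary = pd.DataFrame(
            columns=["n_orthologs", "n_linked_orthologs", "n_linked_sensors"]
        )
    else:
        def summarize(df: pd.DataFrame) -> pd.Series:
            sensors = {
                s for cell in df["linked_sensors"] if cell for s in cell.split(";")
            }
            return pd.Series(
                {
                    "n_orthologs": len(df),
                    "n_linked_orthologs": int((df["n_linked_sensors"] > 0).sum()),
                    "n_linked_sensors": len(sensors),
                }
            )

        summary = per_ortholog.groupby("species").apply(summarize, include_groups=False)
        summary.loc["total"] = summarize(per_ortholog)
    return per_ortholog, summary


def audit_filters(
    members: Iterable[str],
    database: Mapping[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    scoring: Scoring = Scoring(),
) -> dict[str, bool]:
    """Filter-soundness audit: each member re-passes against some other member."""
    members = sorted(set(members))
    out: dict[str, bool] = {}
    for g in members:
        ok = False
        for other in members:
            if other == g:
                continue
            hit = local_align(
                database[other], database[g], scoring=scoring,
                query_id=other, subject_id=g,
            )
            if hit.percent_identity >= min_identity and hit.query_coverage >= min_coverage:
                ok = True
                break
        out[g] = ok if len(members) > 1 else True
    return out
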