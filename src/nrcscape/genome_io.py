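"""Readers, writers and canonical in-memory tables for the pipeline's formats.

Everything downstream works on four containers defined here: :class:`GeneTable`
(gene coordinates from GFF3), :class:`SequenceSet` (amino-acid sequences from
FASTA, plain or aligned), :class:`CladeMap` (gene -> phylogenetic class), and
dendropy trees read from Newick.  Coordinates are 1-based inclusive throughout,
as in GFF3; no half-open conversion happens anywhere so the 50 kb linkage rule
stays unambiguous.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_PLAIN_ALPHABET = set(AMINO_ACIDS + "X*")
_ALIGNED_ALPHABET = _PLAIN_ALPHABET | {"-", "."}

#: Clade labels understood by the pipeline.  NRC0 is a subclade of the helper
#: clade and NRC0_S of the sensor clade, so a gene labeled NRC0 also counts as
#: a helper in all downstream summaries (and NRC0_S as a sensor).
CLADE_LABELS = frozenset(
    {"NRC_H", "NRC_S", "NRC0", "NRC0_S", "ADR1", "NRG1", "OTHER"}
)
HELPER_LABELS = frozenset({"NRC_H", "NRC0"})
SENSOR_LABELS = frozenset({"NRC_S", "NRC0_S"})
SUPERCLADE_LABELS = HELPER_LABELS | SENSOR_LABELS

#: Default transcript-suffix pattern stripped when matching gene identifiers
#: between GFF3, FASTA and tree leaves (annotations mix gene and protein
#: accessions such as "itf14g00240.t1" vs "itf14g00240").
DEFAULT_ID_SUFFIX = r"(?:\.t\d+|\.\d+)+$"


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_id(identifier: str, suffix_pattern: str = DEFAULT_ID_SUFFIX) -> str:
    """Strip a configurable transcript/protein suffix from an identifier."""
    return re.sub(suffix_pattern, "", identifier)


@dataclass(frozen=True)
class GeneLocus:
    """A gene's genomic placement: species, scaffold, 1-based inclusive interval."""

    gene_id: str
    species: str
    scaffold: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in {"+", "-", "unknown"}:
            object.__setattr__(
                self, "strand", "unknown"
            )  # '.' and '?' in GFF3 both mean unknown

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GeneTable:
    """Ordered collection of :class:`GeneLocus`, sorted by (scaffold, start).

    gene_id is unique within a table; duplicates raise at construction.
    """

    def __init__(
        self, records: Iterable[GeneLocus], provenance: str = ""
    ) -> None:
        records = sorted(records, key=lambda g: (g.scaffold, g.start, g.gene_id))
        seen: dict[str, GeneLocus] = {}
        for rec in records:
            if rec.gene_id in seen:
                raise ParseError(f"duplicate gene_id {rec.gene_id!r} in gene table")
            seen[rec.gene_id] = rec
        self.records: list[GeneLocus] = records
        self._by_id = seen
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneLocus]:
        return iter(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def get(self, gene_id: str) -> GeneLocus:
        return self._by_id[gene_id]

    def by_scaffold(self) -> dict[str, list[GeneLocus]]:
        out: dict[str, list[GeneLocus]] = {}
        for rec in self.records:
            out.setdefault(rec.scaffold, []).append(rec)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "species": g.species,
                    "scaffold": g.scaffold,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                }
                for g in self.records
            ],
            columns=["gene_id", "species", "scaffold", "start", "end", "strand"],
        )


@dataclass
class CladeMap:
    """Assignment of gene ids to phylogenetic classes.

    ``labels`` maps gene_id -> label in :data:`CLADE_LABELS`.  Optional
    per-gene domain-architecture flags (has_CC, has_NBARC, has_LRR) are
    carried through from upstream NLR annotation but never computed here.
    """

    labels: dict[str, str]
    domains: dict[str, dict[str, bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - CLADE_LABELS
        if bad:
            raise ValueError(f"unknown clade labels: {sorted(bad)}")

    def label(self, gene_id: str) -> str:
        return self.labels.get(gene_id, "OTHER")

    def is_helper(self, gene_id: str) -> bool:
        return self.label(gene_id) in HELPER_LABELS

    def is_sensor(self, gene_id: str) -> bool:
        return self.label(gene_id) in SENSOR_LABELS

    def in_superclade(self, gene_id: str) -> bool:
        return self.label(gene_id) in SUPERCLADE_LABELS

    def genes_with_label(self, *labels: str) -> list[str]:
        return sorted(g for g, lab in self.labels.items() if lab in labels)


class SequenceSet:
    """id -> amino-acid sequence with alphabet validation.

    Plain sets allow the 20 amino acids plus X and ``*``; aligned sets
    additionally allow gap characters and require equal lengths.
    """

    def __init__(
        self, sequences: Mapping[str, str], aligned: bool = False
    ) -> None:
        alphabet = _ALIGNED_ALPHABET if aligned else _PLAIN_ALPHABET
        clean: dict[str, str] = {}
        for sid, seq in sequences.items():
            seq = "".join(seq.split()).upper().replace(".", "-")
            if not seq:
                raise ParseError(f"sequence {sid!r} is empty")
            bad = set(seq) - alphabet
            if bad:
                raise ParseError(
                    f"sequence {sid!r} contains invalid characters {sorted(bad)}"
                )
            clean[sid] = seq
        if aligned:
            lengths = {len(s) for s in clean.values()}
            if len(lengths) > 1:
                raise ParseError(
                    f"aligned sequences have unequal lengths: {sorted(lengths)}"
                )
        self.sequences = clean
        self.aligned = aligned

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def __contains__(self, sid: str) -> bool:
        return sid in self.sequences

    def __getitem__(self, sid: str) -> str:
        return self.sequences[sid]

    def items(self):
        return self.sequences.items()

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        return SequenceSet(
            {i: self.sequences[i] for i in ids}, aligned=self.aligned
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_gff3(
    path: str | Path,
    feature_type: str = "gene",
    id_attribute: str = "ID",
    species: str = "",
) -> GeneTable:
    """Read gene coordinates from a GFF3 file into a :class:`GeneTable`.

    Keeps rows whose feature type equals ``feature_type`` (annotations vary in
    whether gene or mRNA rows carry the stable identifier; "gene" is the
    default and configurable).  Coordinates are taken verbatim: GFF3 is
    1-based inclusive and so is everything downstream.  Kept/skipped counts
    are logged and sum to the number of feature rows.
    """
    path = Path(path)
    records: list[GeneLocus] = []
    n_features = 0
    n_kept = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):  # trailing FASTA section
                break
            if line.count("\t") != 8:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated columns, "
                    f"got {line.count(chr(9)) + 1}"
                )
            n_features += 1
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # pragma: no cover - gffutils detail
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            if feat.featuretype != feature_type:
                continue
            if id_attribute not in feat.attributes:
                raise ParseError(
                    f"{path.name}:{lineno}: feature lacks attribute "
                    f"{id_attribute!r}: {line}"
                )
            strand = feat.strand if feat.strand in {"+", "-"} else "unknown"
            records.append(
                GeneLocus(
                    gene_id=feat.attributes[id_attribute][0],
                    species=species,
                    scaffold=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=strand,
                )
            )
            n_kept += 1
    if n_features == 0:
        logger.warning("%s: no feature rows found (empty GeneTable)", path.name)
    logger.info(
        "%s: kept %d/%d features of type %r (skipped %d)",
        path.name, n_kept, n_features, feature_type, n_features - n_kept,
    )
    return GeneTable(records, provenance=f"{path}::{species}")


def _normalize_supports(tree: dendropy.Tree) -> None:
    """Interpret numeric internal-node labels as bootstrap support.

    Stores the value as ``node.support`` (float, percent scale).  If every
    numeric label lies in [0, 1] the values are read as fractions and
    rescaled to percent (both dialects occur in RAxML-family output); the
    rescale is logged.
    """
    supports: list[tuple[dendropy.Node, float]] = []
    for node in tree.preorder_node_iter():
        node.support = None
        node.edge.support = None
        if node.is_leaf() or node.label is None:
            continue
        try:
            supports.append((node, float(node.label)))
        except ValueError:
            logger.info("non-numeric internal label %r kept as-is", node.label)
    if supports and all(0.0 <= v <= 1.0 for _, v in supports):
        logger.info("internal labels in [0,1]: interpreting as fractional support")
        supports = [(n, v * 100.0) for n, v in supports]
    for node, val in supports:
        node.support = val
        # support describes the bipartition induced by the edge above the
        # node; keeping it on the edge keeps it attached to the right clade
        # under rerooting
        node.edge.support = val


def read_newick(
    path: str | Path, allow_missing_lengths: bool = False
) -> dendropy.Tree:
    """Read a single-tree Newick file.

    Numeric internal-node labels become bootstrap support on ``node.support``
    (percent scale, see :func:`_normalize_supports`).  Leaf names are
    preserved byte-exact (no underscore/space munging).  Missing branch
    lengths raise unless ``allow_missing_lengths`` substitutes 0.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ParseError(f"duplicate leaf names in tree: {exc}") from exc
    except Exception as exc:
        raise ParseError(f"malformed Newick in {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ParseError(f"duplicate leaf names in tree: {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            if allow_missing_lengths:
                node.edge.length = 0.0
            else:
                raise ParseError(
                    "tree has branches without lengths "
                    "(pass allow_missing_lengths=True to default them to 0)"
                )
    _normalize_supports(tree)
    return tree


def tree_from_string(newick: str, **kwargs) -> dendropy.Tree:
    """Parse a Newick string with the same contracts as :func:`read_newick`."""
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".nwk", delete=False) as fh:
        fh.write(newick)
        name = fh.name
    try:
        return read_newick(name, **kwargs)
    finally:
        Path(name).unlink(missing_ok=True)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree with supports restored as internal-node labels."""
    clone = tree.clone(depth=1)
    for node in clone.preorder_node_iter():
        sup = getattr(node, "support", None)
        if not node.is_leaf() and sup is not None:
            node.label = format(sup, "g")
    clone.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )


def read_fasta(path: str | Path, aligned: bool = False) -> SequenceSet:
    """Read FASTA; id = header token before first whitespace; uppercased.

    Duplicate ids raise.  Internal whitespace in sequence lines is stripped.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        logger.warning("%s: no FASTA records found", path)
    return SequenceSet(seqs, aligned=aligned)


def write_fasta(seqs: SequenceSet | Mapping[str, str], path: str | Path) -> None:
    items = seqs.items() if hasattr(seqs, "items") else seqs
    with open(path, "w") as fh:
        for sid, seq in items:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with a header row; byte-stable given equal input."""
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_clade_map(path: str | Path) -> CladeMap:
    """Read a two-column (gene_id, clade) TSV, extra columns treated as domain flags."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "clade"} <= set(df.columns):
        raise ParseError(f"{path}: clade map needs 'gene_id' and 'clade' columns")
    labels = dict(zip(df["gene_id"], df["clade"]))
    domains: dict[str, dict[str, bool]] = {}
    flag_cols = [c for c in df.columns if c.startswith("has_")]
    if flag_cols:
        for _, row in df.iterrows():
            domains[row["gene_id"]] = {
                c: str(row[c]).lower() in {"1", "true", "yes"} for c in flag_cols
            }
    return CladeMap(labels=labels, domains=domains)
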