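"""Synthetic genomes, trees and sequences with planted ground truth.

The generator emulates the input structure of a helper-sensor NLR
phylogenomics study at desk scale: per-species NLR complements with a helper
(NRC-H) clade, a sensor (NRC-S) clade and an outgroup clade on one gene tree;
a deep-conserved helper ortholog group ("NRC0-like") shared by a subset of
species and genetically adjacent to a sensor partner; lineage-specific
paralog groups for everything else; genomic coordinates with a controllable
fraction of genes in tandem clusters (linked gaps uniform below the 50 kb
threshold, unlinked gaps uniform between 50 kb and 5 Mb); MADA-like motifs
planted at the N termini of helpers at rate ``p_mada_helper`` (default 0.9,
echoing the ~90% detection rate among real deep-conserved helpers) and the
degenerate MAHA pattern in sensors at rate ``p_maha_sensor``.

Sequences evolve by a per-site substitution process with a uniform exchange
kernel: along a branch of length b each site substitutes with probability
1 - exp(-b), to a uniformly chosen different residue.  This controls pairwise
identity levels - which is all the downstream pipeline consumes - without
full empirical-matrix likelihood machinery.  Within-ortholog-group identity
stays far above the 40% recruitment threshold and between-group identity far
below it under the default divergences.

Randomness is split into one stream per species plus a backbone stream, all
derived from the master seed, so adding a species never changes the data of
existing species.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome_io import (
    AMINO_ACIDS,
    CladeMap,
    GeneLocus,
    GeneTable,
    SequenceSet,
    tree_from_string,
    write_fasta,
    write_tsv,
)

logger = logging.getLogger(__name__)

#: Synthetic MADA-like N-terminal consensus planted in helper genes.  The
#: length and alpha1-helix flavor follow the field's MADA definition but the
#: letters are this generator's own model, not an external HMM.
MADA_CONSENSUS = "MADGEGTRINWEPFDWKQYHR"

#: Degenerate sensor N-terminal pattern (x = any residue), as reported for
#: NRC0-linked sensors, plus a short conserved sensor-clade context block the
#: generator plants right after it (sensor N termini are conserved beyond the
#: degenerate positions; the block also keeps the planted helper and sensor
#: signals from overlapping anywhere but the initiator M-A).
MAHA_TEMPLATE = "MAHAAVVSLxQKLxx"
SENSOR_CONTEXT = "SLEDNA"


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic dataset.

    All outputs are a deterministic function of this object.  Divergences are
    branch lengths in expected substitutions/site of the uniform-kernel
    process; gaps are in bp on 1-based inclusive coordinates.
    """

    seed: int = 0
    n_species: int = 6
    #: first ``nrc0_n_species`` species carry the deep-conserved helper group
    nrc0_n_species: int = 4
    #: first ``nrc0_linked_species`` species also carry the linked sensor
    nrc0_linked_species: int = 4
    helper_groups_per_species: tuple[int, int] = (1, 2)
    helper_paralogs: tuple[int, int] = (1, 2)
    sensor_groups_per_species: tuple[int, int] = (2, 3)
    sensor_paralogs: tuple[int, int] = (1, 3)
    other_genes_per_species: int = 4
    protein_length: int = 140
    clade_divergence: float = 1.2
    group_divergence: float = 0.7
    leaf_divergence: tuple[float, float] = (0.05, 0.12)
    planted_support: tuple[float, float] = (85.0, 100.0)
    background_support: tuple[float, float] = (10.0, 100.0)
    threshold_bp: int = 50_000
    cluster_fraction: float = 0.3
    cluster_size: tuple[int, int] = (2, 3)
    linked_gap_bp: tuple[int, int] = (0, 50_000)  # half-open upper bound
    unlinked_gap_bp: tuple[int, int] = (50_000, 5_000_000)
    gene_length_bp: tuple[int, int] = (1_500, 4_500)
    n_scaffolds: int = 5
    p_mada_helper: float = 0.9
    p_maha_sensor: float = 1.0
    motif_noise: float = 0.1
    #: elevated-substitution interval planted in the deep-conserved groups
    #: (1-based inclusive reference positions) and its rate multiplier
    vr_interval: tuple[int, int] = (61, 90)
    vr_multiplier: float = 6.0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not (0 <= self.nrc0_linked_species <= self.nrc0_n_species <= self.n_species):
            raise ValueError(
                "need 0 <= nrc0_linked_species <= nrc0_n_species <= n_species"
            )
        for p, name in [(self.p_mada_helper, "p_mada_helper"),
                        (self.p_maha_sensor, "p_maha_sensor"),
                        (self.motif_noise, "motif_noise"),
                        (self.cluster_fraction, "cluster_fraction")]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for v, name in [(self.clade_divergence, "clade_divergence"),
                        (self.group_divergence, "group_divergence"),
                        (self.vr_multiplier, "vr_multiplier")]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.linked_gap_bp[1] > self.threshold_bp:
            raise ValueError("linked gaps must stay below the linkage threshold")
        if self.unlinked_gap_bp[0] < self.threshold_bp:
            raise ValueError("unlinked gaps must start at/above the threshold")
        if self.protein_length < len(MADA_CONSENSUS) + 10:
            raise ValueError("protein_length too short for motif planting")
        if not (1 <= self.vr_interval[0] <= self.vr_interval[1] <= self.protein_length):
            raise ValueError("vr_interval outside the protein")

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]


@dataclass
class TruthTable:
    """Planted ground truth, consistent with the emitted files by construction.

    ``genes``: one row per gene (species, clade, ortholog group, planted
    motif, cluster id, coordinates).  ``pairs``: every genetically linked
    pair under the strict threshold, typed from the planted clade labels and
    computed by an O(n^2) scan over the final coordinates (independent of
    the pipeline's sweep).  ``node_supports``: planted support class per
    labeled tree node.
    """

    genes: pd.DataFrame
    pairs: pd.DataFrame
    nrc0_group: str = "OG_NRC0"
    nrc0s_group: str = "OG_NRC0S"

    @property
    def nrc0_genes(self) -> list[str]:
        return sorted(self.genes.loc[self.genes["ortholog_group"] == self.nrc0_group, "gene_id"])

    @property
    def nrc0s_genes(self) -> list[str]:
        return sorted(self.genes.loc[self.genes["ortholog_group"] == self.nrc0s_group, "gene_id"])

    def genes_of_clade(self, *clades: str) -> list[str]:
        return sorted(self.genes.loc[self.genes["clade"].isin(clades), "gene_id"])

    def cluster_of(self) -> dict[str, str]:
        return dict(zip(self.genes["gene_id"], self.genes["cluster_id"]))


# --- internal tree scaffolding ---------------------------------------------

@dataclass
class _Node:
    children: list = field(default_factory=list)
    length: float = 0.0
    support: float | None = None
    name: str | None = None  # leaves only

    def newick(self) -> str:
        if self.name is not None:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        sup = "" if self.support is None else format(int(round(self.support)), "d")
        return f"({inner}){sup}:{self.length:.6f}"


@dataclass
class _Gene:
    gene_id: str
    species: str
    clade: str  # clade label for the CladeMap
    group: str  # ortholog-group label
    seq: np.ndarray
    motif: str = ""  # "", "MADA", "MAHA"


def _evolve(
    seq: np.ndarray,
    branch_length: float,
    rng: np.random.Generator,
    site_multiplier: np.ndarray | None = None,
) -> np.ndarray:
    """Per-site substitution along a branch; uniform exchange kernel."""
    bl = np.full(seq.shape, float(branch_length))
    if site_multiplier is not None:
        bl = bl * site_multiplier
    p = 1.0 - np.exp(-bl)
    mask = rng.random(seq.shape) < p
    out = seq.copy()
    if mask.any():
        r = rng.integers(0, 19, mask.sum())
        out[mask] = r + (r >= seq[mask])  # uniform over the 19 other residues
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in seq)


def _plant_mada(seq: np.ndarray, rng: np.random.Generator, noise: float) -> np.ndarray:
    out = seq.copy()
    motif = np.array([AMINO_ACIDS.index(a) for a in MADA_CONSENSUS])
    mutate = rng.random(len(motif)) < noise
    mutate[0] = False  # the initiator methionine stays
    if mutate.any():
        r = rng.integers(0, 19, mutate.sum())
        motif[mutate] = r + (r >= motif[mutate])
    out[: len(motif)] = motif
    return out


def _plant_maha(seq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    motif = np.array(
        [rng.integers(0, 20) if a == "x" else AMINO_ACIDS.index(a)
         for a in MAHA_TEMPLATE + SENSOR_CONTEXT]
    )
    out[: len(motif)] = motif
    return out


@dataclass
class SimulatedDataset:
    """Everything :func:`simulate` produces, in memory."""

    config: SimConfig
    species: list[str]
    sequences: SequenceSet
    gene_tables: dict[str, GeneTable]
    newick: str
    clade_map: CladeMap
    species_map: dict[str, str]
    truth: TruthTable
    perturbations: list[str] = field(default_factory=list)

    @property
    def tree(self):
        return tree_from_string(self.newick)

    def proteome(self, species: str) -> SequenceSet:
        ids = sorted(g for g, sp in self.species_map.items() if sp == species)
        return self.sequences.subset(ids)

    def alignment(self, ids: Iterable[str]) -> SequenceSet:
        """Equal-length ungapped sequences double as an alignment (no indels)."""
        return SequenceSet(
            {i: self.sequences[i] for i in sorted(ids)}, aligned=True
        )

    def write(self, outdir: str | Path) -> None:
        """Emit the exact formats the readers consume; deterministic bytes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in self.species:
            write_fasta(self.proteome(sp), outdir / f"{sp}.proteome.faa")
            with open(outdir / f"{sp}.genes.gff3", "w") as fh:
                fh.write("##gff-version 3\n")
                for g in self.gene_tables[sp]:
                    fh.write(
                        f"{g.scaffold}\t{__name__}\tgene\t{g.start}\t{g.end}"
                        f"\t.\t{g.strand if g.strand != 'unknown' else '.'}\t.\t"
                        f"ID={g.gene_id}\n"
                    )
        write_fasta(self.sequences, outdir / "all_proteins.faa")
        with open(outdir / "gene_tree.nwk", "w") as fh:
            fh.write(self.newick + "\n")
        write_tsv(
            pd.DataFrame(
                sorted(self.species_map.items()), columns=["gene_id", "species"]
            ),
            outdir / "species_map.tsv",
        )
        write_tsv(
            pd.DataFrame(
                sorted(self.clade_map.labels.items()), columns=["gene_id", "clade"]
            ),
            outdir / "clades.tsv",
        )
        write_tsv(self.truth.genes, outdir / "truth_genes.tsv")
        write_tsv(self.truth.pairs, outdir / "truth_pairs.tsv")
        with open(outdir / "sim_config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _species_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, 1000 + index])


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    return float(rng.uniform(bounds[0], bounds[1]))


def simulate(config: SimConfig = SimConfig()) -> SimulatedDataset:
    """Generate one dataset: sequences, tree, coordinates, clade map, truth."""
    config.validate()
    L = config.protein_length
    backbone = np.random.default_rng([config.seed, 0])

    root = backbone.integers(0, 20, L)
    helper_anc = _evolve(root, config.clade_divergence, backbone)
    sensor_anc = _evolve(root, config.clade_divergence, backbone)
    other_anc = _evolve(root, config.clade_divergence, backbone)
    nrc0_anc = _evolve(helper_anc, config.group_divergence, backbone)
    nrc0s_anc = _evolve(sensor_anc, config.group_divergence, backbone)

    vr_mult = np.ones(L)
    vr_mult[config.vr_interval[0] - 1 : config.vr_interval[1]] = config.vr_multiplier

    helper_clade = _Node(length=config.clade_divergence,
                         support=_uniform(backbone, config.planted_support))
    sensor_clade = _Node(length=config.clade_divergence,
                         support=_uniform(backbone, config.planted_support))
    other_clade = _Node(length=config.clade_divergence,
                        support=_uniform(backbone, config.planted_support))
    nrc0_node = _Node(length=config.group_divergence,
                      support=_uniform(backbone, config.planted_support))
    nrc0s_node = _Node(length=config.group_divergence,
                       support=_uniform(backbone, config.planted_support))

    genes: list[_Gene] = []

    for i, sp in enumerate(config.species_names):
        rng = _species_rng(config.seed, i)
        serial = 0

        def new_id() -> str:
            nonlocal serial
            serial += 1
            return f"{sp}_g{serial:03d}"

        # deep-conserved helper ortholog (+ linked sensor partner)
        if i < config.nrc0_n_species:
            bl = _uniform(rng, config.leaf_divergence)
            seq = _evolve(nrc0_anc, bl, rng, site_multiplier=vr_mult)
            gid = new_id()
            genes.append(_Gene(gid, sp, "NRC0", "OG_NRC0", seq))
            nrc0_node.children.append(_Node(name=gid, length=bl))
        if i < config.nrc0_linked_species:
            bl = _uniform(rng, config.leaf_divergence)
            seq = _evolve(nrc0s_anc, bl, rng, site_multiplier=vr_mult)
            gid = new_id()
            genes.append(_Gene(gid, sp, "NRC0_S", "OG_NRC0S", seq))
            nrc0s_node.children.append(_Node(name=gid, length=bl))

        def lineage_groups(
            clade_label: str, clade_node: _Node, ancestor: np.ndarray,
            group_bounds: tuple[int, int], paralog_bounds: tuple[int, int],
            tag: str,
        ) -> None:
            n_groups = int(rng.integers(group_bounds[0], group_bounds[1] + 1))
            for j in range(n_groups):
                group = f"OG_{sp}_{tag}{j + 1}"
                anc = _evolve(ancestor, config.group_divergence, rng)
                n_par = int(rng.integers(paralog_bounds[0], paralog_bounds[1] + 1))
                leaves = []
                for _ in range(n_par):
                    bl = _uniform(rng, config.leaf_divergence)
                    seq = _evolve(anc, bl, rng)
                    gid = new_id()
                    genes.append(_Gene(gid, sp, clade_label, group, seq))
                    leaves.append(_Node(name=gid, length=bl))
                if n_par == 1:
                    leaves[0].length += config.group_divergence
                    clade_node.children.append(leaves[0])
                else:
                    clade_node.children.append(
                        _Node(
                            children=leaves,
                            length=config.group_divergence,
                            support=_uniform(rng, config.background_support),
                        )
                    )

        lineage_groups("NRC_H", helper_clade, helper_anc,
                       config.helper_groups_per_species,
                       config.helper_paralogs, "H")
        lineage_groups("NRC_S", sensor_clade, sensor_anc,
                       config.sensor_groups_per_species,
                       config.sensor_paralogs, "S")
        for j in range(config.other_genes_per_species):
            bl = config.group_divergence + _uniform(rng, config.leaf_divergence)
            seq = _evolve(other_anc, bl, rng)
            gid = new_id()
            genes.append(_Gene(gid, sp, "OTHER", f"OG_{sp}_O{j + 1}", seq))
            other_clade.children.append(_Node(name=gid, length=bl))

        # motif planting, per species stream
        for g in genes:
            if g.species != sp or g.motif:
                continue
            if g.clade in ("NRC0", "NRC_H"):
                if rng.random() < config.p_mada_helper:
                    g.seq = _plant_mada(g.seq, rng, config.motif_noise)
                    g.motif = "MADA"
            elif g.clade in ("NRC0_S", "NRC_S"):
                if rng.random() < config.p_maha_sensor:
                    g.seq = _plant_maha(g.seq, rng)
                    g.motif = "MAHA"

    if nrc0_node.children:
        helper_clade.children.insert(0, nrc0_node)
    if nrc0s_node.children:
        sensor_clade.children.insert(0, nrc0s_node)
    tree_root = _Node(children=[helper_clade, sensor_clade, other_clade])
    newick = tree_root.newick().rsplit(":", 1)[0] + ";"

    gene_tables = {
        sp: _place_genes(
            [g for g in genes if g.species == sp], sp,
            np.random.default_rng([config.seed, 2000 + i]),
            config,
        )
        for i, sp in enumerate(config.species_names)
    }

    truth = _build_truth(genes, gene_tables, config)
    sequences = SequenceSet({g.gene_id: _decode(g.seq) for g in genes})
    clade_map = CladeMap(labels={g.gene_id: g.clade for g in genes})
    species_map = {g.gene_id: g.species for g in genes}
    return SimulatedDataset(
        config=config,
        species=config.species_names,
        sequences=sequences,
        gene_tables=gene_tables,
        newick=newick,
        clade_map=clade_map,
        species_map=species_map,
        truth=truth,
    )


def _place_genes(
    genes: list[_Gene], species: str, rng: np.random.Generator, config: SimConfig
) -> GeneTable:
    """Place one species' genes on scaffolds as tandem-cluster and singleton units."""
    clustering = config.cluster_fraction > 0
    tandem_prob = min(1.0, 2.0 * config.cluster_fraction)
    absorb_prob = 0.4 * config.cluster_fraction

    planted_ids = {
        g.gene_id for g in genes if g.group in ("OG_NRC0", "OG_NRC0S")
    }
    units: list[list[str]] = []
    singletons: list[str] = []
    if planted_ids:
        unit = sorted(planted_ids)
        if len(unit) == 2 and rng.random() < 0.5:
            unit = unit[::-1]
        if clustering and len(unit) > 1:
            units.append(unit)
        else:
            singletons.extend(unit)
    # paralog groups become tandem arrays with probability ~2*cluster_fraction;
    # split groups and single-copy genes are placed as dispersed singletons
    by_group: dict[str, list[str]] = {}
    for g in genes:
        if g.gene_id not in planted_ids:
            by_group.setdefault(g.group, []).append(g.gene_id)
    for group in sorted(by_group):
        members = sorted(by_group[group])
        if clustering and len(members) > 1 and rng.random() < tandem_prob:
            units.append(list(rng.permutation(members)))
        else:
            singletons.extend(members)
    # a tandem array occasionally absorbs an unrelated neighbor, producing
    # the rarer mixed-clade linked pairs
    singletons = list(rng.permutation(singletons))
    for unit in units:
        if singletons and rng.random() < absorb_prob:
            unit.append(singletons.pop())
    for gid in singletons:
        units.append([gid])

    per_scaffold: dict[str, list[list[str]]] = {}
    for unit in units:
        scaf = f"{species}_scaf{int(rng.integers(0, config.n_scaffolds)) + 1}"
        per_scaffold.setdefault(scaf, []).append(unit)

    loci: list[GeneLocus] = []
    for scaf in sorted(per_scaffold):
        cursor = int(rng.integers(1, 10_000))
        first_unit = True
        for unit in per_scaffold[scaf]:
            # cursor sits at the first free base after the previous gene, so
            # advancing it by g bases leaves an inter-interval gap of exactly g
            if not first_unit:
                cursor += int(rng.integers(*config.unlinked_gap_bp))
            first_unit = False
            for k, gid in enumerate(unit):
                if k > 0:
                    cursor += int(rng.integers(*config.linked_gap_bp))
                length = int(rng.integers(*config.gene_length_bp))
                strand = "+" if rng.random() < 0.5 else "-"
                loci.append(
                    GeneLocus(
                        gene_id=gid, species=species, scaffold=scaf,
                        start=cursor, end=cursor + length - 1, strand=strand,
                    )
                )
                cursor = cursor + length - 1 + 1  # next free base
    return GeneTable(loci, provenance=f"simulated::{species}")


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


_HELPERS = {"NRC0", "NRC_H"}
_SENSORS = {"NRC0_S", "NRC_S"}


def _build_truth(
    genes: list[_Gene], gene_tables: Mapping[str, GeneTable], config: SimConfig
) -> TruthTable:
    by_id = {g.gene_id: g for g in genes}
    pair_rows = []
    cluster_of: dict[str, str] = {}
    for sp in sorted(gene_tables):
        table = gene_tables[sp]
        recs = list(table)
        dsu = _DSU([r.gene_id for r in recs])
        # O(n^2) scan, arithmetic written out independently of the sweep
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                if a.scaffold != b.scaffold:
                    continue
                lo, hi = (a, b) if a.start <= b.start else (b, a)
                gap = 0 if hi.start <= lo.end else hi.start - lo.end - 1
                if gap < config.threshold_bp:
                    ga, gb = sorted((a.gene_id, b.gene_id))
                    ca, cb = by_id[ga].clade, by_id[gb].clade
                    if ca in _HELPERS and cb in _HELPERS:
                        ptype = "HH"
                    elif ca in _SENSORS and cb in _SENSORS:
                        ptype = "SS"
                    elif {ca, cb} & _HELPERS and {ca, cb} & _SENSORS:
                        ptype = "HS"
                    else:
                        ptype = "other"
                    pair_rows.append(
                        {"gene_a": ga, "gene_b": gb, "species": sp,
                         "scaffold": a.scaffold, "gap_bp": gap,
                         "pair_type": ptype}
                    )
                    dsu.union(ga, gb)
        comps: dict[str, list[str]] = {}
        for r in recs:
            comps.setdefault(dsu.find(r.gene_id), []).append(r.gene_id)
        k = 0
        for root in sorted(comps, key=lambda r: sorted(comps[r])[0]):
            members = comps[root]
            if len(members) < 2:
                continue
            cid = f"{sp}.truthc{k:03d}"
            k += 1
            for m in members:
                cluster_of[m] = cid

    gene_rows = []
    for sp in sorted(gene_tables):
        for rec in gene_tables[sp]:
            g = by_id[rec.gene_id]
            gene_rows.append(
                {
                    "gene_id": g.gene_id, "species": sp,
                    "scaffold": rec.scaffold, "start": rec.start,
                    "end": rec.end, "strand": rec.strand,
                    "clade": g.clade, "ortholog_group": g.group,
                    "motif_planted": g.motif,
                    "cluster_id": cluster_of.get(g.gene_id, ""),
                }
            )
    genes_df = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "species", "scaffold", "start", "end", "strand",
                 "clade", "ortholog_group", "motif_planted", "cluster_id"],
    ).sort_values(["species", "scaffold", "start"], kind="stable").reset_index(drop=True)
    pairs_df = pd.DataFrame(
        pair_rows,
        columns=["gene_a", "gene_b", "species", "scaffold", "gap_bp", "pair_type"],
    ).sort_values(["species", "gene_a", "gene_b"], kind="stable").reset_index(drop=True)
    return TruthTable(genes=genes_df, pairs=pairs_df)


def mada_seed_alignment(
    n: int = 30, seed: int = 0, noise: float = 0.1
) -> SequenceSet:
    """Sample a seed alignment of MADA-like motifs for profile building.

    Draws ``n`` motif instances from the same planting model the generator
    uses, so a profile built from this seed matches the planted signal.
    """
    rng = np.random.default_rng([seed, 77])
    Lm = len(MADA_CONSENSUS)
    seqs = {}
    for i in range(n):
        seq = _plant_mada(np.zeros(Lm, dtype=int), rng, noise)
        seqs[f"mada_seed_{i + 1:02d}"] = _decode(seq[:Lm])
    return SequenceSet(seqs, aligned=True)


def perturb(
    dataset: SimulatedDataset,
    drop_species: Iterable[str] = (),
    support_floor: float | None = None,
    shuffle_n_termini: bool = False,
    n_terminal_window: int = 30,
    seed: int = 0,
) -> SimulatedDataset:
    """Controlled corruptions for robustness tests; every change is logged.

    ``drop_species`` removes those species' gene tables (coordinates lost,
    sequences kept, emulating a missing annotation).  ``support_floor`` caps
    every node support at the given value, collapsing confidence (0 makes
    every clade call unresolved at the usual threshold).
    ``shuffle_n_termini`` permutes the first ``n_terminal_window`` residues
    of every sequence, destroying planted motifs while preserving
    composition.
    """
    rng = np.random.default_rng([seed, 4242])
    log: list[str] = list(dataset.perturbations)

    gene_tables = dict(dataset.gene_tables)
    for sp in drop_species:
        if sp in gene_tables:
            del gene_tables[sp]
            log.append(f"dropped gene table for {sp}")

    newick = dataset.newick
    if support_floor is not None:
        tree = dataset.tree
        for node in tree.preorder_node_iter():
            sup = getattr(node, "support", None)
            if sup is not None:
                node.support = min(sup, support_floor)
                node.label = format(node.support, "g")
        newick = tree.as_string(schema="newick", unquoted_underscores=True).strip()
        if newick.startswith("[&R] ") or newick.startswith("[&U] "):
            newick = newick[5:]
        log.append(f"capped node supports at {support_floor}")

    sequences = dataset.sequences
    if shuffle_n_termini:
        shuffled = {}
        for sid in sorted(sequences):
            seq = sequences[sid]
            head = list(seq[:n_terminal_window])
            rng.shuffle(head)
            shuffled[sid] = "".join(head) + seq[n_terminal_window:]
        sequences = SequenceSet(shuffled)
        log.append(f"shuffled first {n_terminal_window} residues of every sequence")

    return replace(
        dataset,
        gene_tables=gene_tables,
        newick=newick,
        sequences=sequences,
        perturbations=log,
    )
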