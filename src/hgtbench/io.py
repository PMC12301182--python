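"""Readers and writers for the artifact's file formats.

Formats: newick species trees, gene-order TSV, gain-event TSV, FASTA
(per-taxon gene sequences), presence/absence TSV. All TSVs are UTF-8 with a
header row; missing donors are written as "." (empty also accepted on read).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    GainEvent,
    Gene,
    GenomeAnnotation,
    InferenceSet,
    PresenceAbsenceMatrix,
    SpeciesTree,
    TreeNode,
)

__all__ = [
    "read_species_tree",
    "write_species_tree",
    "read_gene_orders",
    "write_gene_orders",
    "read_gain_events",
    "write_gain_events",
    "presence_absence_from_orders",
    "read_gene_fastas",
    "write_gene_fastas",
]

GAIN_EVENT_COLUMNS = [
    "method",
    "stringency",
    "family_id",
    "recipient_branch",
    "donor_branch",
    "confidence",
]

GENE_ORDER_COLUMNS = ["taxon", "chromosome", "position", "gene_id", "family_id"]


def _from_dendropy(dtree: dendropy.Tree) -> SpeciesTree:
    def convert(dnode, parent: Optional[TreeNode]) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
        else:
            label = dnode.label or ""
        node = TreeNode(
            label=label,
            length=float(dnode.edge.length) if dnode.edge.length is not None else 0.0,
        )
        if parent is not None:
            parent.add_child(node)
        for child in dnode.child_nodes():
            convert(child, node)
        return node

    root = convert(dtree.seed_node, None)

    # Auto-label unlabeled internal nodes with their preorder index ("N0"
    # for the root, then preorder). Deterministic across reads.
    taken = set()
    stack, order = [root], []
    while stack:
        n = stack.pop()
        order.append(n)
        taken.update([n.label] if n.label else [])
        stack.extend(reversed(n.children))
    for i, n in enumerate(order):
        if not n.label:
            label = f"N{i}"
            while label in taken:
                label = "N" + label
            n.label = label
            taken.add(label)
    return SpeciesTree(root)


def read_species_tree(path: str | os.PathLike) -> SpeciesTree:
    """Read one rooted newick tree; a trifurcating root is accepted and
    treated as a rooted multifurcation."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise ValueError(f"duplicate leaf labels in newick file: {e}") from e
    tree = _from_dendropy(dtree)
    leaves = tree.leaf_labels
    if len(leaves) != len(set(leaves)):
        dupes = sorted({l for l in leaves if leaves.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    return tree


def write_species_tree(tree: SpeciesTree, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.newick() + "\n")


def read_gene_orders(path: str | os.PathLike) -> list[GenomeAnnotation]:
    """Read a gene-order TSV into per-taxon annotations.

    Required columns: taxon, chromosome, position, gene_id, family_id;
    optional: strand. Unknown columns are tolerated and ignored. Positions
    per (taxon, chromosome) must form a gapless 0..n-1 sequence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_ORDER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene-order TSV missing columns: {missing}")
    df["position"] = df["position"].astype(int)
    has_strand = "strand" in df.columns
    annotations = []
    for taxon, tgroup in df.groupby("taxon", sort=True):
        chromosomes = []
        for chrom, cgroup in tgroup.groupby("chromosome", sort=True):
            cgroup = cgroup.sort_values("position")
            positions = cgroup["position"].tolist()
            if positions != list(range(len(positions))):
                raise ValueError(
                    f"positions on ({taxon}, {chrom}) are not a gapless "
                    f"0..{len(positions) - 1} sequence"
                )
            genes = [
                Gene(
                    gene_id=row.gene_id,
                    family=row.family_id,
                    strand=(row.strand if has_strand and pd.notna(row.strand) else None),
                )
                for row in cgroup.itertuples()
            ]
            chromosomes.append((chrom, genes))
        annotations.append(GenomeAnnotation(taxon=taxon, chromosomes=chromosomes))
    return annotations


def write_gene_orders(
    annotations: Sequence[GenomeAnnotation], path: str | os.PathLike
) -> None:
    rows = []
    for ann in annotations:
        for chrom, genes in ann.chromosomes:
            for pos, g in enumerate(genes):
                rows.append(
                    {
                        "taxon": ann.taxon,
                        "chromosome": chrom,
                        "position": pos,
                        "gene_id": g.gene_id,
                        "family_id": g.family,
                        "strand": g.strand if g.strand is not None else ".",
                    }
                )
    pd.DataFrame(rows, columns=GENE_ORDER_COLUMNS + ["strand"]).to_csv(
        path, sep="\t", index=False
    )


def read_gain_events(
    path: str | os.PathLike, tree: Optional[SpeciesTree] = None
) -> InferenceSet:
    """Read a gain-event TSV into an InferenceSet.

    Donor "." or empty means absent. Branch ids are validated against
    ``tree`` when one is given.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GAIN_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gain-event TSV missing columns: {missing}")
    methods = sorted(set(df["method"])) if len(df) else []
    if len(methods) > 1:
        raise ValueError(f"gain-event TSV mixes methods: {methods}")
    method = methods[0] if methods else "unknown"
    levels: dict[float, list[GainEvent]] = {}
    for row in df.itertuples():
        donor = None if row.donor_branch in (".", "") else row.donor_branch
        ev = GainEvent(
            family=row.family_id,
            recipient=row.recipient_branch,
            donor=donor,
            confidence=float(row.confidence),
        )
        levels.setdefault(float(row.stringency), []).append(ev)
    iset = InferenceSet(method=method, levels=levels)
    if tree is not None:
        iset.validate_against(tree)
    return iset


def write_gain_events(iset: InferenceSet, path: str | os.PathLike) -> None:
    rows = []
    for stringency, events in iset.levels.items():
        for ev in events:
            rows.append(
                {
                    "method": iset.method,
                    "stringency": stringency,
                    "family_id": ev.family,
                    "recipient_branch": ev.recipient,
                    "donor_branch": ev.donor if ev.donor is not None else ".",
                    "confidence": ev.confidence,
                }
            )
    pd.DataFrame(rows, columns=GAIN_EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def presence_absence_from_orders(
    annotations: Sequence[GenomeAnnotation],
) -> PresenceAbsenceMatrix:
    """Family x taxon copy-number matrix from ordered gene lists."""
    return PresenceAbsenceMatrix.from_annotations(annotations)


def read_gene_fastas(directory: str | os.PathLike) -> dict[str, dict[str, str]]:
    """Read per-taxon FASTA files ``<taxon>.fasta`` from a directory into
    {taxon: {gene_id: sequence}}."""
    out: dict[str, dict[str, str]] = {}
    for name in sorted(os.listdir(directory)):
        if not name.endswith((".fasta", ".fa", ".fna")):
            continue
        taxon = name.rsplit(".", 1)[0]
        records = SeqIO.parse(os.path.join(directory, name), "fasta")
        out[taxon] = {rec.id: str(rec.seq).upper() for rec in records}
    return out


def write_gene_fastas(
    sequences: Mapping[str, Mapping[str, str]], directory: str | os.PathLike
) -> None:
    os.makedirs(directory, exist_ok=True)
    for taxon, genes in sequences.items():
        records = [
            SeqRecord(Seq(seq), id=gene_id, description="")
            for gene_id, seq in genes.items()
        ]
        SeqIO.write(records, os.path.join(directory, f"{taxon}.fasta"), "fasta")
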