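"""Shared domain types.

The frame of reference for every analysis is a rooted species tree whose
branches are named by their child node. Gene content lives in per-taxon
ordered gene lists (one per chromosome); inferred horizontal acquisitions are
(family, recipient branch) events, optionally carrying a donor branch and a
confidence. An inference method exposes its events as an
:class:`InferenceSet`: a sweep of event collections indexed by a
method-specific stringency value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeNode",
    "SpeciesTree",
    "Gene",
    "GenomeAnnotation",
    "GainEvent",
    "InferenceSet",
    "PresenceAbsenceMatrix",
]


@dataclass
class TreeNode:
    label: str
    length: float = 0.0
    parent: Optional["TreeNode"] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child


class SpeciesTree:
    """Rooted (possibly multifurcating) tree with uniquely labeled nodes.

    A *branch* is identified by the label of its child node; the root has no
    branch, so no gain event can be assigned to the root's (non-existent)
    stem except by the explicit root-charging convention of the parsimony
    module, which uses the root label itself.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [n.label for n in self.preorder()]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate node labels in tree: {dupes}")
        for node in self.preorder():
            if node.is_leaf and not node.label:
                raise ValueError("empty leaf label")
            if node.length < 0:
                raise ValueError(f"negative branch length at {node.label!r}")
        self._by_label = {n.label: n for n in self.preorder()}

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def node(self, label: str) -> TreeNode:
        return self._by_label[label]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    @property
    def branches(self) -> list[str]:
        """Branch ids = labels of all non-root nodes."""
        return [n.label for n in self.preorder() if n is not self.root]

    def path_to_root(self, label: str) -> list[str]:
        """Labels from ``label`` up to (and including) the root."""
        node = self.node(label)
        path = []
        while node is not None:
            path.append(node.label)
            node = node.parent
        return path

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.label
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.label
            if node is self.root:
                return core
            return f"{core}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({len(self.leaf_labels)} leaves)"


@dataclass(frozen=True)
class Gene:
    gene_id: str
    family: str
    strand: Optional[str] = None


@dataclass
class GenomeAnnotation:
    """Ordered gene lists of one taxon, grouped by chromosome.

    Gene positions are the 0-based indices of the ordered lists: consecutive
    and gapless. "Intervening genes" between positions p < q is q - p - 1.
    Chromosomes are linear (no wraparound neighbors).
    """

    taxon: str
    chromosomes: list[tuple[str, list[Gene]]]

    def __post_init__(self) -> None:
        chrom_ids = [c for c, _ in self.chromosomes]
        if len(chrom_ids) != len(set(chrom_ids)):
            raise ValueError(f"duplicate chromosome ids for taxon {self.taxon!r}")
        seen: set[str] = set()
        for _, genes in self.chromosomes:
            for g in genes:
                if g.gene_id in seen:
                    raise ValueError(
                        f"duplicate gene id {g.gene_id!r} in taxon {self.taxon!r}"
                    )
                seen.add(g.gene_id)

    @property
    def n_genes(self) -> int:
        return sum(len(genes) for _, genes in self.chromosomes)

    def families(self) -> set[str]:
        return {g.family for _, genes in self.chromosomes for g in genes}

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, genes in self.chromosomes:
            for g in genes:
                counts[g.family] = counts.get(g.family, 0) + 1
        return counts


@dataclass(frozen=True)
class GainEvent:
    """One inferred acquisition of a gene family on a recipient branch."""

    family: str
    recipient: str
    donor: Optional[str] = None
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.donor is not None and self.donor == self.recipient:
            raise ValueError(
                f"donor equals recipient ({self.recipient!r}) for family {self.family!r}"
            )


class InferenceSet:
    """One method's gain events, sweepable by stringency.

    ``levels`` maps stringency value -> list of GainEvents. For
    threshold-on-confidence methods the collections are nested
    (non-increasing as stringency increases); for parameter sweeps (e.g. the
    gain/loss penalty ratio) each level is an independent run.
    """

    def __init__(
        self,
        method: str,
        levels: dict[float, list[GainEvent]],
        axis: str = "threshold",
    ):
        if axis not in ("threshold", "parameter"):
            raise ValueError(f"unknown stringency axis {axis!r}")
        self.method = method
        self.axis = axis
        self.levels = dict(sorted(levels.items()))

    @property
    def stringencies(self) -> list[float]:
        return list(self.levels.keys())

    def events(self, stringency: float) -> list[GainEvent]:
        return self.levels[stringency]

    def validate_against(self, tree: SpeciesTree) -> None:
        for s, events in self.levels.items():
            for ev in events:
                if ev.recipient not in tree:
                    raise ValueError(
                        f"recipient branch {ev.recipient!r} not in tree "
                        f"(method {self.method!r}, stringency {s})"
                    )
                if ev.donor is not None and ev.donor not in tree:
                    raise ValueError(
                        f"donor branch {ev.donor!r} not in tree "
                        f"(method {self.method!r}, stringency {s})"
                    )

    def __repr__(self) -> str:  # pragma: no cover
        sizes = {s: len(e) for s, e in self.levels.items()}
        return f"InferenceSet({self.method!r}, levels={sizes})"


class PresenceAbsenceMatrix:
    """Family x taxon copy-number matrix with a derived binary view."""

    def __init__(self, counts: pd.DataFrame):
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        self.counts = counts.astype(int)

    @classmethod
    def from_annotations(
        cls, annotations: Sequence[GenomeAnnotation]
    ) -> "PresenceAbsenceMatrix":
        if not annotations:
            raise ValueError("no annotations")
        data = {a.taxon: a.family_counts() for a in annotations}
        df = pd.DataFrame(data).fillna(0).astype(int)
        return cls(df.sort_index())

    @property
    def binary(self) -> pd.DataFrame:
        return (self.counts > 0).astype(int)

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def presence_vector(self, family: str) -> dict[str, int]:
        row = self.counts.loc[family]
        return {t: int(v > 0) for t, v in row.items()}

    @property
    def total_genes(self) -> int:
        return int(np.asarray(self.counts.values).sum())
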