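"""Synthetic genome evolution with segmental horizontal transfer.

The generator produces the data structure the downstream analyses assume: a
rooted species tree, per-genome ordered gene lists, nucleotide sequences,
and a ground-truth log of every transfer event. The key feature is
*segmental* HGT — one event moves a contiguous run of genes from a donor
genome into a contiguous block of the recipient — so that genes gained in
the same event start out as genomic neighbors and remain so unless
rearrangements separate them.

There is no substitution model and no amelioration: sequences only carry an
order-0 compositional signal (a GC offset for horizontally acquired genes),
which is what the parametric detector consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import GainEvent, Gene, GenomeAnnotation, InferenceSet, SpeciesTree, TreeNode

__all__ = [
    "EvolutionParams",
    "TransferEvent",
    "TruthLog",
    "simulate_species_tree",
    "evolve_genomes",
    "truth_inference",
    "corrupt_inference",
    "simulate_sequences",
]


@dataclass
class EvolutionParams:
    """Knobs of the genome-evolution generator.

    root_size
        Number of gene families in the root genome (single chromosome).
        Default 1200: comfortably above the evaluator's >=1,000-gene
        chromosome filter even after per-branch losses shrink the leaves.
    p_loss
        Per-branch, per-gene independent loss probability.
    hgt_rate
        Poisson rate of HGT events per unit branch length (tree depth is
        normalized to 1 by :func:`simulate_species_tree`).
    p_seg
        Success probability of the geometric transferred-segment length
        (support >= 1); mean segment length = 1 / p_seg.
    rearr_rate
        Poisson rate of translocations per unit branch length; each excises
        a geometric-length segment and reinserts it elsewhere.
    p_novel
        Probability that a transferred segment consists of brand-new
        families absent from every other genome (taxon-restricted influx).
    seed
        Seed of the single random stream driving the whole simulation.
    """

    root_size: int = 1200
    p_loss: float = 0.01
    hgt_rate: float = 8.0
    p_seg: float = 0.4
    rearr_rate: float = 0.5
    p_novel: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_loss", "p_seg", "p_novel"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_seg == 0.0:
            raise ValueError("p_seg must be positive (geometric support >= 1)")
        if self.hgt_rate < 0 or self.rearr_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.root_size < 1:
            raise ValueError("root_size must be >= 1")

    @property
    def mean_segment_length(self) -> float:
        return 1.0 / self.p_seg

    @property
    def single_gene_fraction(self) -> float:
        """Fraction of transfers carrying exactly one gene."""
        return self.p_seg


@dataclass(frozen=True)
class TransferEvent:
    event_id: int
    donor: str
    recipient: str
    segment: tuple[str, ...]  # ordered family ids, contiguous in the donor


@dataclass
class TruthLog:
    """Complete simulator ground truth."""

    transfers: list[TransferEvent] = field(default_factory=list)
    losses: list[tuple[str, str]] = field(default_factory=list)  # (family, branch)

    def gains_by_branch(self) -> dict[str, list[tuple[str, int]]]:
        """branch -> [(family, event_id), ...] for every gained family."""
        out: dict[str, list[tuple[str, int]]] = {}
        for ev in self.transfers:
            for fam in ev.segment:
                out.setdefault(ev.recipient, []).append((fam, ev.event_id))
        return out

    @property
    def total_gains(self) -> int:
        return sum(len(ev.segment) for ev in self.transfers)


def simulate_species_tree(n_taxa: int, seed: int = 0) -> SpeciesTree:
    """Yule (pure-birth) tree with ``n_taxa`` leaves, total depth 1.

    Each extant lineage splits at rate 1; after the last split one more
    waiting time is appended so terminal branches have positive length. The
    tree is ultrametric and its root-to-leaf depth is normalized to 1.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode(label="", length=0.0)
    # active lineages: (node, birth_time)
    a = root.add_child(TreeNode(""))
    b = root.add_child(TreeNode(""))
    active: list[tuple[TreeNode, float]] = [(a, 0.0), (b, 0.0)]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, birth = active.pop(i)
        node.length = t - birth
        c1 = node.add_child(TreeNode(""))
        c2 = node.add_child(TreeNode(""))
        active.extend([(c1, t), (c2, t)])
    t += rng.exponential(1.0 / len(active))
    for node, birth in active:
        node.length = t - birth
    _scale_tree(root, 1.0 / t)  # normalize depth to 1
    _label(root, n_taxa)
    return SpeciesTree(root)


def _scale_tree(root: TreeNode, factor: float) -> None:
    stack = [root]
    while stack:
        n = stack.pop()
        n.length *= factor
        stack.extend(n.children)


def _label(root: TreeNode, n_taxa: int) -> None:
    width = max(2, len(str(n_taxa)))
    stack, order = [root], []
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(reversed(n.children))
    leaf_i = 0
    for i, n in enumerate(order):
        if n.is_leaf:
            leaf_i += 1
            n.label = f"T{leaf_i:0{width}d}"
        else:
            n.label = f"N{i}"


def _geometric_length(rng: np.random.Generator, p: float) -> int:
    return int(rng.geometric(p))


def evolve_genomes(
    tree: SpeciesTree, params: EvolutionParams
) -> tuple[list[GenomeAnnotation], TruthLog]:
    """Evolve gene orders down the tree; return leaf annotations + truth.

    Root genome: one chromosome of ``root_size`` genes, families
    F0001..F{G}. Along each branch, in order: (1) independent per-gene loss,
    (2) Poisson(hgt_rate x length) segmental transfers, (3)
    Poisson(rearr_rate x length) translocations. The donor of a transfer is
    drawn uniformly among branches off the recipient's root path; its genome
    is read from the nearest already-evolved node on the donor's root path
    (the simulation is one preorder pass, so donors are not
    time-consistent — the evaluation never consults donor timing).
    """
    rng = np.random.default_rng(params.seed)
    G = params.root_size
    width = len(str(G))
    root_genome = [f"F{i + 1:0{width}d}" for i in range(G)]
    genomes: dict[str, list[str]] = {tree.root.label: root_genome}
    log = TruthLog()
    novel_counter = 0
    event_counter = 0
    branch_ids = tree.branches

    def donor_genome(donor_label: str) -> list[str]:
        node = tree.node(donor_label)
        while node is not None and node.label not in genomes:
            node = node.parent
        assert node is not None  # root genome always present
        return genomes[node.label]

    for node in tree.preorder():
        if node is tree.root:
            continue
        genome = list(genomes[node.parent.label])
        L = node.length
        # 1. losses
        if params.p_loss > 0 and genome:
            keep = rng.random(len(genome)) >= params.p_loss
            for fam, k in zip(genome, keep):
                if not k:
                    log.losses.append((fam, node.label))
            genome = [fam for fam, k in zip(genome, keep) if k]
        if not genome:
            raise RuntimeError(f"empty genome at branch {node.label!r}")
        # 2. segmental HGT
        own_path = set(tree.path_to_root(node.label))
        eligible = [b for b in branch_ids if b not in own_path]
        n_hgt = int(rng.poisson(params.hgt_rate * L))
        for _ in range(n_hgt):
            donor = eligible[int(rng.integers(len(eligible)))]
            src = donor_genome(donor)
            start = int(rng.integers(len(src)))
            seg_len = min(_geometric_length(rng, params.p_seg), len(src) - start)
            segment = list(src[start : start + seg_len])
            if rng.random() < params.p_novel:
                novel = []
                for _ in segment:
                    novel_counter += 1
                    novel.append(f"FN{novel_counter:05d}")
                segment = novel
            pos = int(rng.integers(len(genome) + 1))
            genome[pos:pos] = segment
            log.transfers.append(
                TransferEvent(
                    event_id=event_counter,
                    donor=donor,
                    recipient=node.label,
                    segment=tuple(segment),
                )
            )
            event_counter += 1
        # 3. rearrangements (translocations)
        n_rearr = int(rng.poisson(params.rearr_rate * L))
        for _ in range(n_rearr):
            if len(genome) < 2:
                break
            start = int(rng.integers(len(genome)))
            seg_len = min(_geometric_length(rng, params.p_seg), len(genome) - start)
            segment = genome[start : start + seg_len]
            rest = genome[:start] + genome[start + seg_len :]
            pos = int(rng.integers(len(rest) + 1))
            rest[pos:pos] = segment
            genome = rest
        genomes[node.label] = genome

    annotations = []
    for leaf in tree.leaves:
        genome = genomes[leaf.label]
        genes = [
            Gene(gene_id=f"{leaf.label}|g{i:05d}", family=fam)
            for i, fam in enumerate(genome)
        ]
        annotations.append(
            GenomeAnnotation(taxon=leaf.label, chromosomes=[("chr1", genes)])
        )
    return annotations, log


def truth_inference(log: TruthLog) -> InferenceSet:
    """Ground-truth gains as a single-stringency inference set."""
    events = []
    seen = set()
    for ev in log.transfers:
        for fam in ev.segment:
            key = (fam, ev.recipient, ev.donor)
            if key in seen:
                continue
            seen.add(key)
            events.append(
                GainEvent(family=fam, recipient=ev.recipient, donor=ev.donor, confidence=1.0)
            )
    return InferenceSet(method="truth", levels={1.0: events})


def corrupt_inference(
    truth: InferenceSet,
    fpr: float,
    fnr: float,
    tree: SpeciesTree,
    families: Sequence[str],
    seed: int = 0,
) -> InferenceSet:
    """Degrade a truth set with false negatives and false positives.

    Each true event is dropped with probability ``fnr``. False events are
    added as uniform random (family, terminal branch) pairs not present in
    the truth; their count is fpr / (1 - fpr) times the retained-truth
    count, so ``fpr`` is the expected fraction of false events in the
    output. Confidences are Beta(8, 2) for true and Beta(2, 8) for false
    events, so thresholding on confidence enacts a stringency sweep;
    stringency levels are the deciles of the pooled confidences.
    """
    if not (0.0 <= fpr < 1.0 and 0.0 <= fnr < 1.0):
        raise ValueError("fpr and fnr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    true_events = [ev for evs in truth.levels.values() for ev in evs]
    retained = [ev for ev in true_events if rng.random() >= fnr]
    n_false = int(round(fpr / (1.0 - fpr) * len(retained)))
    truth_keys = {(ev.family, ev.recipient) for ev in true_events}
    leaf_labels = tree.leaf_labels
    families = list(families)
    false_events: list[GainEvent] = []
    used = set(truth_keys)
    while len(false_events) < n_false:
        fam = families[int(rng.integers(len(families)))]
        rec = leaf_labels[int(rng.integers(len(leaf_labels)))]
        if (fam, rec) in used:
            continue
        used.add((fam, rec))
        false_events.append(GainEvent(family=fam, recipient=rec, donor=None))
    scored = [
        GainEvent(ev.family, ev.recipient, ev.donor, confidence=float(rng.beta(8, 2)))
        for ev in retained
    ] + [
        GainEvent(ev.family, ev.recipient, ev.donor, confidence=float(rng.beta(2, 8)))
        for ev in false_events
    ]
    confs = np.array([ev.confidence for ev in scored])
    thresholds = np.quantile(confs, np.arange(10) / 10.0) if len(scored) else [0.0]
    levels = {
        float(th): [ev for ev in scored if ev.confidence >= th] for th in thresholds
    }
    return InferenceSet(method=f"corrupt(fpr={fpr},fnr={fnr})", levels=levels)


def simulate_sequences(
    annotations: Sequence[GenomeAnnotation],
    log: TruthLog,
    k_order: int = 0,
    shift: float = 0.3,
    gene_len: int = 500,
    seed: int = 0,
) -> dict[str, dict[str, str]]:
    """Order-0 nucleotide sequences with a compositional HGT signal.

    Each taxon gets a genome-specific GC content drawn uniform in
    [0.35, 0.65]; native genes are sampled i.i.d. from it. Genes whose
    family was gained on the taxon's terminal branch (per the truth log) are
    sampled from a composition whose GC is displaced by +/- ``shift``
    (sign drawn per transfer event, clamped to [0.05, 0.95]).

    Returns {taxon: {gene_id: sequence}}.
    """
    if not 0.0 <= shift <= 0.5:
        raise ValueError("shift must be in [0, 0.5]")
    if gene_len < 100:
        raise ValueError("gene_len must be >= 100")
    if k_order != 0:
        warnings.warn("only order-0 composition is implemented; ignoring k_order")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))

    # family -> signed shift for families gained on terminal branches
    gains = log.gains_by_branch()
    event_sign: dict[int, int] = {}
    out: dict[str, dict[str, str]] = {}
    for ann in sorted(annotations, key=lambda a: a.taxon):
        gc = float(rng.uniform(0.35, 0.65))
        transferred_gc: dict[str, float] = {}
        for fam, event_id in gains.get(ann.taxon, []):
            if event_id not in event_sign:
                event_sign[event_id] = 1 if rng.random() < 0.5 else -1
            g2 = min(max(gc + event_sign[event_id] * shift, 0.05), 0.95)
            transferred_gc[fam] = g2
        seqs: dict[str, str] = {}
        for _, genes in ann.chromosomes:
            for gene in genes:
                g = transferred_gc.get(gene.family, gc)
                p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
                idx = rng.choice(4, size=gene_len, p=p)
                seqs[gene.gene_id] = "".join(alphabet[idx])
        out[ann.taxon] = seqs
    return out
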