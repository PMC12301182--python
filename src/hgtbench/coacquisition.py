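"""Co-acquisition and co-transfer statistics against a chromosome-size null.

Two genes from different families inferred to be gained on the same terminal
branch are a *co-acquisition*; if both events also name the same donor
branch they are a *co-transfer*. Genes separated by at most t intervening
genes on the same chromosome (default t = 1) are *neighbors*. A method whose
co-acquisitions are enriched for neighbors — far above the analytic
expectation for randomly placed genes — is inferring transfers more
reliably, because genes moved on one DNA fragment start out adjacent in the
recipient genome.

Small-number guards from the study design: chromosomes with fewer than 1,000
genes are excluded, and any stringency level with fewer than 20
co-acquisition pairs is excluded from comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import GainEvent, GenomeAnnotation, InferenceSet, SpeciesTree

__all__ = [
    "CoAcquisitionPair",
    "CoAcquisitionTable",
    "EvalRow",
    "enumerate_coacquisitions",
    "percent_neighbors",
    "expected_neighbor_percent",
    "cotransfer_stats",
    "stringency_sweep",
    "plot_sweep",
]

MIN_CHROMOSOME_GENES = 1000
MIN_PAIRS = 20


@dataclass(frozen=True)
class CoAcquisitionPair:
    taxon: str
    chromosome: str
    gene_a: str
    gene_b: str
    family_a: str
    family_b: str
    intervening: int
    cotransfer: Optional[bool]  # True / False / None = unknown


@dataclass
class CoAcquisitionTable:
    """All co-acquired gene pairs at one stringency, plus the per-chromosome
    tallies (c_i pairs, g_i genes) that feed the null model."""

    stringency: float
    t: int
    pairs: list[CoAcquisitionPair]
    chromosome_tallies: dict[tuple[str, str], tuple[int, int]]  # (taxon, chrom) -> (c_i, g_i)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_chromosomes(self) -> int:
        """Chromosomes carrying at least one co-acquisition."""
        return sum(1 for c, _ in self.chromosome_tallies.values() if c > 0)


@dataclass
class EvalRow:
    method: str
    stringency: float
    n_coacquisitions: int
    pct_neighbors: Optional[float]
    expected_pct: Optional[float]
    pct_cotransfers: Optional[float]
    pct_neighbor_cotransfers: Optional[float]
    excluded: bool
    reason: str = ""


def _pair_cotransfer(
    donors_a: set[str], has_unknown_a: bool, donors_b: set[str], has_unknown_b: bool
) -> Optional[bool]:
    # unknown if either family's gain carries no donor; yes if the donor
    # sets intersect; no otherwise
    if has_unknown_a or has_unknown_b or not donors_a or not donors_b:
        return None
    return bool(donors_a & donors_b)


def enumerate_coacquisitions(
    events: Iterable[GainEvent],
    annotations: Sequence[GenomeAnnotation],
    tree: SpeciesTree,
    t: int = 1,
    stringency: float = 0.0,
    min_chromosome_genes: int = MIN_CHROMOSOME_GENES,
) -> CoAcquisitionTable:
    """Enumerate same-branch, same-chromosome, cross-family gene pairs.

    Only gains on terminal branches are considered (positions exist only in
    extant genomes). Each gained family is expanded to all of its member
    genes in the recipient's annotation; all unordered cross-family pairs on
    the same chromosome count, except on chromosomes with fewer than
    ``min_chromosome_genes`` genes.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    leaf_set = set(tree.leaf_labels)
    ann_by_taxon = {a.taxon: a for a in annotations}

    # per taxon: family -> (donor set, saw-donorless-event flag)
    per_taxon: dict[str, dict[str, tuple[set[str], bool]]] = {}
    for ev in events:
        if ev.recipient not in leaf_set:
            continue
        if ev.recipient not in ann_by_taxon:
            continue  # taxon absent from annotations: skip its events
        donors, unknown = per_taxon.setdefault(ev.recipient, {}).setdefault(
            ev.family, (set(), False)
        )
        if ev.donor is None:
            per_taxon[ev.recipient][ev.family] = (donors, True)
        else:
            donors.add(ev.donor)

    pairs: list[CoAcquisitionPair] = []
    tallies: dict[tuple[str, str], tuple[int, int]] = {}
    for taxon in sorted(per_taxon):
        families = per_taxon[taxon]
        ann = ann_by_taxon[taxon]
        for chrom, genes in ann.chromosomes:
            if len(genes) < min_chromosome_genes:
                continue
            members = [
                (pos, g) for pos, g in enumerate(genes) if g.family in families
            ]
            chrom_pairs = 0
            for i in range(len(members)):
                pos_a, gene_a = members[i]
                donors_a, unk_a = families[gene_a.family]
                for j in range(i + 1, len(members)):
                    pos_b, gene_b = members[j]
                    if gene_a.family == gene_b.family:
                        continue
                    donors_b, unk_b = families[gene_b.family]
                    pairs.append(
                        CoAcquisitionPair(
                            taxon=taxon,
                            chromosome=chrom,
                            gene_a=gene_a.gene_id,
                            gene_b=gene_b.gene_id,
                            family_a=gene_a.family,
                            family_b=gene_b.family,
                            intervening=pos_b - pos_a - 1,
                            cotransfer=_pair_cotransfer(donors_a, unk_a, donors_b, unk_b),
                        )
                    )
                    chrom_pairs += 1
            if chrom_pairs > 0:
                tallies[(taxon, chrom)] = (chrom_pairs, len(genes))
    return CoAcquisitionTable(
        stringency=stringency, t=t, pairs=pairs, chromosome_tallies=tallies
    )


def percent_neighbors(table: CoAcquisitionTable) -> float:
    """Observed percentage of co-acquired pairs that are neighbors."""
    if not table.pairs:
        raise ValueError("empty co-acquisition table: percentage undefined")
    n_neigh = sum(1 for p in table.pairs if p.intervening <= table.t)
    return 100.0 * n_neigh / len(table.pairs)


def expected_neighbor_percent(table: CoAcquisitionTable) -> float:
    """Analytic null expectation for the neighbor percentage.

    For a gene placed at random among the g_i positions of chromosome i, the
    probability that a second independently placed gene lands within t + 1
    positions on either side is 2(t+1)/g_i (approximating for boundary
    genes). The expectation aggregates per-chromosome as
    100 * 2 * sum_i (t+1) c_i / g_i / sum_i c_i, which for a single
    chromosome reduces to 100 * 2(t+1)/g.
    """
    tallies = table.chromosome_tallies
    total_c = sum(c for c, _ in tallies.values())
    if total_c < 1:
        raise ValueError("no co-acquisitions: expectation undefined")
    if any(g == 0 for _, g in tallies.values()):
        raise ValueError("chromosome with zero genes")
    t = table.t
    num = 2.0 * sum((t + 1) * c / g for c, g in tallies.values())
    return 100.0 * num / total_c


def cotransfer_stats(table: CoAcquisitionTable) -> tuple[float, float]:
    """(percent co-transfers, percent neighboring co-transfers), both among
    all co-acquisitions.

    Raises if no pair carries donor information (implicit and parametric
    methods provide no donors).
    """
    if not table.pairs:
        raise ValueError("empty co-acquisition table")
    known = [p for p in table.pairs if p.cotransfer is not None]
    if not known:
        raise ValueError("method provides no donors")
    n = len(table.pairs)
    n_yes = sum(1 for p in table.pairs if p.cotransfer)
    n_yes_neigh = sum(
        1 for p in table.pairs if p.cotransfer and p.intervening <= table.t
    )
    return 100.0 * n_yes / n, 100.0 * n_yes_neigh / n


def stringency_sweep(
    iset: InferenceSet,
    annotations: Sequence[GenomeAnnotation],
    tree: SpeciesTree,
    t: int = 1,
    min_chromosome_genes: int = MIN_CHROMOSOME_GENES,
    min_pairs: int = MIN_PAIRS,
) -> list[EvalRow]:
    """One evaluation row per stringency level of an inference set.

    Levels with fewer than ``min_pairs`` co-acquisitions are marked excluded
    (reason "min-pairs"); empty levels are excluded with reason "no-pairs".
    The co-acquisition count is the cross-method comparability axis.
    """
    rows = []
    for s in iset.stringencies:
        table = enumerate_coacquisitions(
            iset.events(s),
            annotations,
            tree,
            t=t,
            stringency=s,
            min_chromosome_genes=min_chromosome_genes,
        )
        n = table.n_pairs
        if n == 0:
            rows.append(
                EvalRow(iset.method, s, 0, None, None, None, None, True, "no-pairs")
            )
            continue
        pct = percent_neighbors(table)
        exp = expected_neighbor_percent(table)
        try:
            pct_ct, pct_nct = cotransfer_stats(table)
        except ValueError:
            pct_ct = pct_nct = None
        excluded = n < min_pairs
        rows.append(
            EvalRow(
                method=iset.method,
                stringency=s,
                n_coacquisitions=n,
                pct_neighbors=pct,
                expected_pct=exp,
                pct_cotransfers=pct_ct,
                pct_neighbor_cotransfers=pct_nct,
                excluded=excluded,
                reason="min-pairs" if excluded else "",
            )
        )
    return rows


def plot_sweep(rows: Sequence[EvalRow], ax=None, label: Optional[str] = None):
    """Percent neighboring co-acquisitions vs number of co-acquisitions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    kept = [r for r in rows if not r.excluded]
    xs = [r.n_coacquisitions for r in kept]
    ys = [r.pct_neighbors for r in kept]
    ax.plot(xs, ys, "o-", label=label or (kept[0].method if kept else None))
    ax.set_xscale("log")
    ax.set_xlabel("co-acquisitions")
    ax.set_ylabel("% neighboring co-acquisitions")
    if label or kept:
        ax.legend()
    return ax
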