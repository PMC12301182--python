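"""End-to-end benchmark experiments on synthetic data.

Each function runs one self-contained study through the package API —
simulate, infer, evaluate — and returns plain dictionaries of the measured
quantities. They back both the acceptance checks and the command-line
reproduction script; problem sizes are desk-scale (tens of taxa, ~10^3-gene
genomes, 10-20 replicate seeds).
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
from scipy.stats import binomtest

from . import simulate, wagner, wn
from .coacquisition import (
    CoAcquisitionPair,
    CoAcquisitionTable,
    cotransfer_stats,
    enumerate_coacquisitions,
    expected_neighbor_percent,
    percent_neighbors,
)
from .compare import DistanceMatrix, max_overlap_coefficient, upgma
from .model import GainEvent, Gene, GenomeAnnotation, InferenceSet, TreeNode, SpeciesTree

__all__ = [
    "cotransfer_worked_example",
    "null_model_grid",
    "parsimony_oracle",
    "fpr_discrimination",
    "wn_detection_experiment",
    "comparison_checks",
]


def cotransfer_worked_example(
    n_pairs: int = 1000, pct_cotransfers: float = 13.0, pct_neighbor_ct: float = 0.2
) -> dict:
    """Conditional neighbor percentage among co-transfers.

    Builds a co-acquisition table in which the given percentages of pairs
    are co-transfers and neighboring co-transfers (both relative to all
    co-acquisitions, the denominators of the evaluation), then derives the
    fraction of co-transferred pairs that are neighbors.
    """
    n_ct = round(n_pairs * pct_cotransfers / 100.0)
    n_nct = round(n_pairs * pct_neighbor_ct / 100.0)
    pairs = []
    for i in range(n_pairs):
        is_ct = i < n_ct
        is_neighbor = i < n_nct  # neighboring co-transfers are co-transfers
        pairs.append(
            CoAcquisitionPair(
                taxon="X",
                chromosome="c",
                gene_a=f"a{i}",
                gene_b=f"b{i}",
                family_a=f"Fa{i}",
                family_b=f"Fb{i}",
                intervening=0 if is_neighbor else 5,
                cotransfer=is_ct,
            )
        )
    table = CoAcquisitionTable(0.0, 1, pairs, {("X", "c"): (n_pairs, 2000)})
    pct_ct, pct_nct = cotransfer_stats(table)
    conditional = 100.0 * pct_nct / pct_ct
    return {
        "pct_cotransfers": pct_ct,
        "pct_neighbor_cotransfers": pct_nct,
        "conditional_pct_neighbors_among_cotransfers": conditional,
    }


def null_model_grid(
    seed: int = 0,
    replicates: int = 100_000,
    gs: Sequence[int] = (1000, 2000),
    cs: Sequence[int] = (10, 50),
    ts: Sequence[int] = (0, 1, 2),
) -> list[dict]:
    """Monte-Carlo oracle for the analytic null expectation.

    For each (g, c, t): place c genes independently and uniformly on a
    g-gene chromosome and measure the fraction of gene pairs that are
    neighbors (<= t intervening genes), using circular distance — the
    boundary approximation the analytic formula makes. Returns the formula
    value, the Monte-Carlo mean, its standard error, and the z-score of the
    discrepancy (all percentages).
    """
    rng = np.random.default_rng(seed)
    out = []
    chunk = 5000
    for g, c in itertools.product(gs, cs):
        iu, ju = np.triu_indices(c, k=1)
        n_pairs = len(iu)
        fractions = {t: [] for t in ts}
        done = 0
        while done < replicates:
            m = min(chunk, replicates - done)
            pos = rng.integers(0, g, size=(m, c), dtype=np.int32)
            d = (pos[:, iu] - pos[:, ju]) % g
            for t in ts:
                near = ((d >= 1) & (d <= t + 1)) | (d >= g - (t + 1))
                fractions[t].append(near.sum(axis=1) / n_pairs)
            done += m
        for t in ts:
            frac = np.concatenate(fractions[t])
            table = CoAcquisitionTable(0.0, t, [], {("x", "c"): (c, g)})
            formula = expected_neighbor_percent(table)
            mc = 100.0 * float(frac.mean())
            se = 100.0 * float(frac.std(ddof=1) / np.sqrt(len(frac)))
            out.append(
                {
                    "g": g,
                    "c": c,
                    "t": t,
                    "formula_pct": formula,
                    "mc_pct": mc,
                    "se_pct": se,
                    "z": (mc - formula) / se if se > 0 else 0.0,
                }
            )
    return out


def _enumerate_min_cost(tree: SpeciesTree, presence: dict[str, int], r: float) -> float:
    """Exhaustive minimum parsimony cost over all internal labelings
    (loss 1, gain r, root presence charged one stem gain)."""
    internal = [n for n in tree.preorder() if not n.is_leaf]
    best = float("inf")
    for bits in range(2 ** len(internal)):
        state = {n.label: (bits >> i) & 1 for i, n in enumerate(internal)}
        for leaf in tree.leaves:
            state[leaf.label] = 1 if presence[leaf.label] else 0
        cost = r * state[tree.root.label]
        for node in tree.preorder():
            if node is tree.root:
                continue
            sp, sc = state[node.parent.label], state[node.label]
            if sp == 0 and sc == 1:
                cost += r
            elif sp == 1 and sc == 0:
                cost += 1.0
        if cost < best:
            best = cost
    return best


def parsimony_oracle(
    seed: int = 0,
    n_instances: int = 1000,
    ratios: Sequence[float] = (1, 2, 4, 7),
    max_leaves: int = 6,
) -> dict:
    """Dynamic program vs exhaustive enumeration on random small instances.

    Returns the fraction of (instance, ratio) cells where the DP minimum
    cost equals the brute-force minimum, and the fraction of instances whose
    per-family gain count is non-increasing in the penalty ratio.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    monotone = 0
    total = 0
    for _ in range(n_instances):
        n = int(rng.integers(3, max_leaves + 1))
        tree = simulate.simulate_species_tree(n, seed=int(rng.integers(2**31)))
        presence = {l: int(rng.integers(2)) for l in tree.leaf_labels}
        if not any(presence.values()):
            presence[tree.leaf_labels[0]] = 1
        prev_gains = None
        inst_monotone = True
        for r in ratios:
            gains, losses = wagner.infer_family_gains(
                tree, presence, wagner.ParsimonyConfig(gain_loss_ratio=r)
            )
            dp_cost = r * len(gains) + len(losses)
            if abs(dp_cost - _enumerate_min_cost(tree, presence, r)) < 1e-9:
                agree += 1
            total += 1
            if prev_gains is not None and len(gains) > prev_gains:
                inst_monotone = False
            prev_gains = len(gains)
        monotone += inst_monotone
    return {
        "agreement_fraction": agree / total,
        "monotone_fraction": monotone / n_instances,
        "n_instances": n_instances,
    }


def fpr_discrimination(
    seed: int = 0,
    n_seeds: int = 10,
    n_taxa: int = 30,
    fprs: Sequence[float] = (0.0, 0.2, 0.5),
    t: int = 1,
) -> dict:
    """Percent neighboring co-acquisitions vs the false-positive rate.

    Per replicate seed: simulate genome evolution, corrupt the ground-truth
    gain set at each false-positive rate, and evaluate the percentage of
    neighboring co-acquisitions of the full (lowest-stringency) event set.
    Adjacent rates are compared by a paired sign test.
    """
    per_fpr: dict[float, list[float]] = {f: [] for f in fprs}
    for i in range(n_seeds):
        rep_seed = seed * 1009 % 2**20 + 17 * i
        tree = simulate.simulate_species_tree(n_taxa, seed=rep_seed)
        params = simulate.EvolutionParams(seed=rep_seed)
        annotations, log = simulate.evolve_genomes(tree, params)
        truth = simulate.truth_inference(log)
        families = sorted(
            {g.family for a in annotations for _, gs in a.chromosomes for g in gs}
        )
        for fpr in fprs:
            c = simulate.corrupt_inference(
                truth, fpr, 0.0, tree, families, seed=rep_seed + 1
            )
            events = c.events(min(c.stringencies))
            table = enumerate_coacquisitions(events, annotations, tree, t=t)
            per_fpr[fpr].append(percent_neighbors(table))
    means = {f: float(np.mean(v)) for f, v in per_fpr.items()}
    comparisons = []
    ordered = sorted(fprs)
    for lo, hi in zip(ordered, ordered[1:]):
        wins = sum(a > b for a, b in zip(per_fpr[lo], per_fpr[hi]))
        p = binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue
        comparisons.append({"lower_fpr": lo, "higher_fpr": hi, "wins": wins, "p": p})
    return {"means": means, "per_seed": per_fpr, "comparisons": comparisons}


def _implant_setup(n_genes: int, implant_fraction: float, segment: int = 5):
    """Single-taxon annotation plus a truth log marking terminal gains."""
    taxon = "T01"
    genes = [Gene(f"{taxon}|g{i:05d}", f"F{i + 1:05d}") for i in range(n_genes)]
    ann = GenomeAnnotation(taxon, [("chr1", genes)])
    n_implant = round(n_genes * implant_fraction)
    transfers = []
    fams = [g.family for g in genes]
    for e, start in enumerate(range(0, n_implant, segment)):
        seg = tuple(fams[start : min(start + segment, n_implant)])
        transfers.append(simulate.TransferEvent(e, "DONOR", taxon, seg))
    log = simulate.TruthLog(transfers=transfers)
    implanted = {f for ev in transfers for f in ev.segment}
    return ann, log, implanted


def wn_detection_experiment(
    seed: int = 0,
    shift: float = 0.3,
    n_seeds: int = 10,
    n_genes: int = 1000,
    implant_fraction: float = 0.05,
    k: int = 4,
    gene_len: int = 500,
    s_eval: float = 4.0,
) -> dict:
    """Recall and flagged fraction of the typicality detector.

    Per seed: implant ``implant_fraction`` of a 1,000-gene genome as
    terminal-branch acquisitions with GC displaced by ``shift``, generate
    sequences, run the detector sweep, and measure (at stringency
    ``s_eval``) the recall of implanted families and the flagged fraction.
    Also verifies the flag sets shrink monotonically over the sweep.
    """
    config = wn.WnConfig(k=k)
    recalls, flagged_fracs = [], []
    monotone = True
    for i in range(n_seeds):
        rep_seed = seed * 907 % 2**20 + 13 * i
        ann, log, implanted = _implant_setup(n_genes, implant_fraction)
        seqs = simulate.simulate_sequences(
            [ann], log, shift=shift, gene_len=gene_len, seed=rep_seed
        )
        iset = wn.wn_inference_set(seqs, [ann], config)
        sizes = [len(iset.events(s)) for s in iset.stringencies]
        if sizes != sorted(sizes, reverse=True):
            monotone = False
        flagged = {e.family for e in iset.events(s_eval)}
        recalls.append(len(flagged & implanted) / len(implanted))
        flagged_fracs.append(len(iset.events(s_eval)) / n_genes)
    return {
        "mean_recall": float(np.mean(recalls)),
        "mean_flagged_fraction": float(np.mean(flagged_fracs)),
        "monotone": monotone,
        "per_seed_recall": recalls,
    }


def comparison_checks(seed: int = 0) -> dict:
    """Sanity checks of the method-comparison layer on constructed sets."""
    rng = np.random.default_rng(seed)
    universe = [(f"F{i}", "A") for i in range(20)]

    def iset(name, levels):
        return InferenceSet(
            name, {s: [GainEvent(f, r) for f, r in keys] for s, keys in levels.items()}
        )

    nested = iset("nested1", {1.0: universe[:4], 2.0: universe[:9]})
    superset = iset("nested2", {1.0: universe, 2.0: universe[:12]})
    max_oc_nested = max_overlap_coefficient(nested, superset)

    l1 = {
        float(s): [universe[i] for i in rng.choice(20, size=int(rng.integers(3, 12)), replace=False)]
        for s in range(3)
    }
    l2 = {
        float(s): [universe[i] for i in rng.choice(20, size=int(rng.integers(3, 12)), replace=False)]
        for s in range(3)
    }
    brute = max(
        len(set(a) & set(b)) / min(len(set(a)), len(set(b)))
        for a in l1.values()
        for b in l2.values()
    )
    max_oc_random = max_overlap_coefficient(iset("r1", l1), iset("r2", l2))

    matrix = DistanceMatrix(
        methods=["A", "B", "C"],
        values=np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]]),
    )
    newick = upgma(matrix)
    return {
        "max_oc_nested": max_oc_nested,
        "max_oc_random": max_oc_random,
        "max_oc_bruteforce": brute,
        "upgma_newick": newick,
    }
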