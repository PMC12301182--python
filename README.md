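# hgtbench

Benchmarking horizontal gene transfer (HGT) inference by the
genomic-neighborhood signal of co-acquired genes.

## The problem

Methods that infer HGT — from gene-tree/species-tree reconciliation, from
gene-family presence/absence (phyletic) patterns, or from sequence
composition — are hard to validate: there is no fossil record of past
transfers, and simulations tend to embed the same assumptions as the methods
they test. This package implements an assumption-light benchmark built on one
biological fact: transfers often move a *segment* of DNA carrying several
neighboring genes, and those genes start out (and frequently remain) neighbors
in the recipient genome. A method whose inferred acquisitions are enriched for
genomic neighbors, far beyond what random gene placement predicts, is making
more reliable calls.

It is intended for researchers developing or choosing HGT inference methods,
and provides:

- a **genome-evolution simulator** (Yule species tree; per-branch gene loss;
  Poisson segmental HGT with geometric segment lengths, optional novel-family
  influx; translocations) with a complete ground-truth transfer log;
- two in-repo inference methods: **asymmetric Wagner parsimony** on
  presence/absence profiles (Sankoff DP; stringency = gain/loss penalty
  ratio) and the parametric **Wn detector** (oligonucleotide typicality,
  Savitzky–Golay smoothing of the rank curve, MAD-multiple thresholds,
  stringency = MAD multiple 4–13);
- the **co-acquisition evaluator** with its analytic null model; and
- a **method-comparison layer** (maximum Overlap Coefficient over stringency
  pairs, UPGMA dendrogram).

External tools' inferences can be evaluated too: convert them to the
gain-event TSV dialect (`method, stringency, family_id, recipient_branch,
donor_branch, confidence`).

## The statistic

Two genes from different families gained on the same terminal branch of the
species tree are a *co-acquisition*; if both events name the same donor
branch they are a *co-transfer*; genes on the same chromosome separated by at
most *t* intervening genes (default *t* = 1) are *neighbors*. The headline
measure is the percentage of co-acquisitions that are neighbors, compared at
equal co-acquisition counts across methods, against the random-placement
expectation

$$ E[\text{fraction of neighbors}] = \frac{2\sum_i (t+1)\,c_i/g_i}{\sum_i c_i}, $$

where $c_i$ and $g_i$ are the co-acquisition pairs and the gene count of
chromosome $i$ (for a single chromosome this reduces to $2(t+1)/g$, e.g.
0.4 % for $g = 1000$, $t = 1$). Chromosomes with fewer than 1,000 genes and
stringency levels with fewer than 20 pairs are excluded to limit
small-number effects.

## Worked example

Simulate 30 genomes, corrupt the ground truth with 30 % false positives and
10 % false negatives, and sweep the confidence threshold:

```python
import hgtbench as hb

tree = hb.simulate_species_tree(30, seed=1)
annotations, log = hb.evolve_genomes(tree, hb.EvolutionParams(seed=1))
truth = hb.truth_inference(log)
families = sorted({g.family for a in annotations
                   for _, gs in a.chromosomes for g in gs})
noisy = hb.corrupt_inference(truth, fpr=0.3, fnr=0.1, tree=tree,
                             families=families, seed=1)

rows = hb.stringency_sweep(truth, annotations, tree, t=1)
rows += hb.stringency_sweep(noisy, annotations, tree, t=1)[:3]
for r in rows:
    print(f"{r.method.split('(')[0]:6s} s={r.stringency:.3f} "
          f"pairs={r.n_coacquisitions:4d} %neigh={r.pct_neighbors:6.2f} "
          f"expected={r.expected_pct:.3f}")
```

prints (abridged):

```
truth  s=1.000 pairs=1952 %neigh= 12.86 expected=0.342
corrupt s=0.007 pairs=2407 %neigh=  8.81 expected=0.343
corrupt s=0.142 pairs=2112 %neigh= 10.04 expected=0.343
corrupt s=0.267 pairs=1857 %neigh= 11.42 expected=0.343
```

The ground truth has 12.9 % neighboring co-acquisitions — ~38× the 0.34 %
random expectation — while the corrupted set starts at 8.8 % and climbs back
toward the truth as the confidence threshold removes low-confidence (mostly
false) events: exactly the discrimination the benchmark is designed to
detect. At the very strictest levels the percentage becomes unstable (tens of
pairs), which is why the < 20-pair exclusion exists.

The same pipeline is available from the shell:

```bash
hgtbench simulate --n-taxa 30 --seed 1 --out-dir sim/
hgtbench infer-mp --tree sim/tree.nwk --orders sim/orders.tsv --ratios 1,4,7 --out mp.tsv
hgtbench infer-wn --fasta-dir sim/fasta --orders sim/orders.tsv --k 4 --out wn.tsv
hgtbench evaluate --events mp.tsv --orders sim/orders.tsv --tree sim/tree.nwk --out eval.tsv
hgtbench compare --events sim/truth_events.tsv --events mp.tsv --events wn.tsv \
    --out dist.tsv --newick dendro.nwk
```

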