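import numpy as np
import pytest

import hgtbench as hb
from hgtbench.compare import event_keys


def test_yule_two_taxa_is_cherry():
    tree = hb.simulate_species_tree(2, seed=0)
    assert len(tree.leaf_labels) == 2
    assert len(tree.root.children) == 2
    assert all(c.is_leaf for c in tree.root.children)


def test_yule_determinism_and_depth():
    t1 = hb.simulate_species_tree(50, seed=7)
    t2 = hb.simulate_species_tree(50, seed=7)
    assert t1.newick() == t2.newick()
    assert len(t1.leaf_labels) == 50
    # ultrametric, depth normalized to 1
    depths = []
    for leaf in t1.leaves:
        node, d = leaf, 0.0
        while node.parent is not None:
            d += node.length
            node = node.parent
        depths.append(d)
    assert np.allclose(depths, 1.0)


def test_yule_rejects_single_taxon():
    with pytest.raises(ValueError):
        hb.simulate_species_tree(1)


def test_evolution_noop_keeps_root_order():
    tree = hb.simulate_species_tree(6, seed=3)
    params = hb.EvolutionParams(
        root_size=50, p_loss=0.0, hgt_rate=0.0, rearr_rate=0.0, seed=3
    )
    annotations, log = hb.evolve_genomes(tree, params)
    root_fams = [f"F{i + 1:02d}" for i in range(50)]
    for ann in annotations:
        assert [g.family for g in ann.chromosomes[0][1]] == root_fams
    assert log.total_gains == 0 and not log.losses


def test_evolution_determinism_and_conservation():
    tree = hb.simulate_species_tree(10, seed=5)
    params = hb.EvolutionParams(root_size=200, seed=5)
    ann1, log1 = hb.evolve_genomes(tree, params)
    ann2, log2 = hb.evolve_genomes(tree, params)
    assert log1 == log2
    for a, b in zip(ann1, ann2):
        assert [g.family for g in a.chromosomes[0][1]] == [
            g.family for g in b.chromosomes[0][1]
        ]
    # per-leaf conservation: size = root - losses + gains along root path
    gains_by_branch = {}
    for ev in log1.transfers:
        gains_by_branch[ev.recipient] = gains_by_branch.get(ev.recipient, 0) + len(
            ev.segment
        )
    losses_by_branch = {}
    for _, br in log1.losses:
        losses_by_branch[br] = losses_by_branch.get(br, 0) + 1
    for ann in ann1:
        path = tree.path_to_root(ann.taxon)[:-1]  # exclude root
        expect = 200
        for br in path:
            expect += gains_by_branch.get(br, 0) - losses_by_branch.get(br, 0)
        assert ann.n_genes == expect
    assert log1.total_gains == sum(len(ev.segment) for ev in log1.transfers)


def test_terminal_segments_contiguous_without_rearrangement():
    tree = hb.simulate_species_tree(8, seed=9)
    params = hb.EvolutionParams(
        root_size=300, p_loss=0.0, hgt_rate=6.0, rearr_rate=0.0, p_novel=1.0, seed=9
    )
    annotations, log = hb.evolve_genomes(tree, params)
    by_taxon = {a.taxon: a for a in annotations}
    checked = 0
    for ev in log.transfers:
        if ev.recipient not in by_taxon or len(ev.segment) < 2:
            continue
        order = [g.family for g in by_taxon[ev.recipient].chromosomes[0][1]]
        start = order.index(ev.segment[0])
        assert tuple(order[start : start + len(ev.segment)]) == ev.segment
        checked += 1
    assert checked > 0


def test_empty_genome_raises_with_branch_id():
    tree = hb.simulate_species_tree(4, seed=1)
    params = hb.EvolutionParams(root_size=5, p_loss=1.0, hgt_rate=0.0, seed=1)
    with pytest.raises(RuntimeError, match="empty genome at branch"):
        hb.evolve_genomes(tree, params)


def test_truth_inference_structure():
    assert hb.truth_inference(hb.TruthLog()).events(1.0) == []
    log = hb.TruthLog(
        transfers=[hb.TransferEvent(0, "D", "R", ("F1", "F2", "F3"))]
    )
    events = hb.truth_inference(log).events(1.0)
    assert len(events) == 3
    assert {(e.donor, e.recipient) for e in events} == {("D", "R")}


def test_truth_round_trip_tsv(tmp_path, sim_bundle):
    _, _, _, truth = sim_bundle
    p = tmp_path / "truth.tsv"
    hb.write_gain_events(truth, p)
    back = hb.read_gain_events(p)
    assert back.levels == truth.levels


def test_corrupt_identity_and_false_count(sim_bundle):
    tree, _, _, truth = sim_bundle
    families = sorted({ev.family for ev in truth.events(1.0)})
    clean = hb.corrupt_inference(truth, fpr=0.0, fnr=0.0, tree=tree, families=families, seed=2)
    lowest = clean.events(min(clean.stringencies))
    assert event_keys(lowest) == event_keys(truth.events(1.0))
    half = hb.corrupt_inference(truth, fpr=0.5, fnr=0.0, tree=tree, families=families, seed=2)
    all_events = half.events(min(half.stringencies))
    n_true = len(truth.events(1.0))
    assert len(all_events) == 2 * n_true  # added-false count equals retained-truth count


def test_corrupt_threshold_sweep_raises_precision(sim_bundle):
    """Confidence thresholds enact a stringency sweep: over seeds, mean
    precision at the strictest decile exceeds mean precision at the loosest."""
    tree, _, _, truth = sim_bundle
    families = sorted({ev.family for ev in truth.events(1.0)})
    truth_keys = event_keys(truth.events(1.0))
    loose, strict = [], []
    for seed in range(20):
        c = hb.corrupt_inference(truth, fpr=0.4, fnr=0.1, tree=tree, families=families, seed=seed)
        lo, hi = min(c.stringencies), max(c.stringencies)
        for s, acc in ((lo, loose), (hi, strict)):
            evs = c.events(s)
            keys = [(e.family, e.recipient) for e in evs]
            acc.append(sum(1 for k in keys if k in truth_keys) / len(keys))
    assert np.mean(strict) > np.mean(loose)


def test_sequences_alphabet_length_and_gc_shift():
    genes = [hb.Gene(f"g{i:04d}", f"F{i:04d}") for i in range(300)]
    ann = hb.GenomeAnnotation("TX", [("chr1", genes)])
    seg = tuple(f"F{i:04d}" for i in range(60))  # first 60 genes transferred
    log = hb.TruthLog(transfers=[hb.TransferEvent(0, "DON", "TX", seg)])
    seqs = hb.simulate_sequences([ann], log, shift=0.3, gene_len=120, seed=4)["TX"]
    assert set(len(s) for s in seqs.values()) == {120}
    assert set("".join(seqs.values())) <= set("ACGT")

    def gc(s):
        return (s.count("G") + s.count("C")) / len(s)

    native = np.mean([gc(seqs[f"g{i:04d}"]) for i in range(60, 300)])
    transferred = np.mean([gc(seqs[f"g{i:04d}"]) for i in range(60)])
    assert abs(abs(transferred - native) - 0.3) < 0.02

    # shift=0: transferred and native genes identically distributed
    seqs0 = hb.simulate_sequences([ann], log, shift=0.0, gene_len=120, seed=4)["TX"]
    native0 = np.mean([gc(seqs0[f"g{i:04d}"]) for i in range(60, 300)])
    transferred0 = np.mean([gc(seqs0[f"g{i:04d}"]) for i in range(60)])
    assert abs(transferred0 - native0) < 0.02
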