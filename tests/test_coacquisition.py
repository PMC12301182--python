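import numpy as np
import pytest

import hgtbench as hb
from hgtbench.coacquisition import (
    CoAcquisitionPair,
    CoAcquisitionTable,
    cotransfer_stats,
    enumerate_coacquisitions,
    expected_neighbor_percent,
    percent_neighbors,
    stringency_sweep,
)


def _annotation(taxon, n_genes, gained_positions, chrom="chr1"):
    """Annotation with families GAINED_<pos> at the given positions and
    unique filler families elsewhere."""
    genes = []
    for i in range(n_genes):
        fam = f"GAINED_{i}" if i in gained_positions else f"BG_{taxon}_{i}"
        genes.append(hb.Gene(f"{taxon}|g{i}", fam))
    return hb.GenomeAnnotation(taxon, [(chrom, genes)])


def _events(taxon, positions, donors=None):
    donors = donors or {}
    return [
        hb.GainEvent(f"GAINED_{p}", taxon, donor=donors.get(p)) for p in positions
    ]


@pytest.fixture()
def leaf_tree():
    root = hb.TreeNode("R")
    for lbl in ("X", "Y", "DON1", "DON2"):
        root.add_child(hb.TreeNode(lbl, 1.0))
    return hb.SpeciesTree(root)


def test_adjacent_pair_on_large_chromosome(leaf_tree):
    ann = _annotation("X", 1200, {3, 4})
    table = enumerate_coacquisitions(_events("X", [3, 4]), [ann], leaf_tree, t=1)
    assert table.n_pairs == 1
    assert table.pairs[0].intervening == 0
    assert percent_neighbors(table) == 100.0
    assert table.chromosome_tallies == {("X", "chr1"): (1, 1200)}


def test_small_chromosome_excluded(leaf_tree):
    ann = _annotation("X", 800, {3, 4})
    table = enumerate_coacquisitions(_events("X", [3, 4]), [ann], leaf_tree, t=1)
    assert table.n_pairs == 0


def test_cross_chromosome_pairs_excluded(leaf_tree):
    genes_a = [hb.Gene("X|a0", "GAINED_0")] + [
        hb.Gene(f"X|a{i}", f"BGA_{i}") for i in range(1, 1100)
    ]
    genes_b = [hb.Gene("X|b0", "GAINED_1")] + [
        hb.Gene(f"X|b{i}", f"BGB_{i}") for i in range(1, 1100)
    ]
    ann = hb.GenomeAnnotation("X", [("c1", genes_a), ("c2", genes_b)])
    events = [hb.GainEvent("GAINED_0", "X"), hb.GainEvent("GAINED_1", "X")]
    table = enumerate_coacquisitions(events, [ann], leaf_tree, t=1)
    assert table.n_pairs == 0


def test_internal_branch_gains_ignored(leaf_tree):
    ann = _annotation("X", 1200, {3, 4})
    events = _events("X", [3]) + [hb.GainEvent("GAINED_4", "R")]
    table = enumerate_coacquisitions(events, [ann], leaf_tree, t=1)
    assert table.n_pairs == 0


def test_percent_neighbors_arithmetic(leaf_tree):
    ann = _annotation("X", 1500, {0, 2, 10})
    # pairs: (0,2) intervening 1; (0,10) intervening 9; (2,10) intervening 7
    table = enumerate_coacquisitions(_events("X", [0, 2, 10]), [ann], leaf_tree, t=1)
    assert table.n_pairs == 3
    assert percent_neighbors(table) == pytest.approx(100.0 / 3)
    with pytest.raises(ValueError, match="undefined"):
        percent_neighbors(
            CoAcquisitionTable(0.0, 1, [], {})
        )


@pytest.mark.parametrize(
    "tallies,t,expected",
    [
        ({("x", "c"): (10, 1000)}, 1, 0.4),
        ({("x", "c"): (10, 1000)}, 0, 0.2),
        ({("x", "c1"): (10, 1000), ("x", "c2"): (30, 2000)}, 1, 0.25),
    ],
)
def test_expected_neighbor_percent_formula(tallies, t, expected):
    table = CoAcquisitionTable(0.0, t, [], tallies)
    assert expected_neighbor_percent(table) == pytest.approx(expected)


def test_expected_neighbor_percent_matches_monte_carlo():
    """Random-placement oracle for one (g, c, t) cell; the acceptance suite
    covers the full grid. Genes are placed independently and uniformly with
    circular distance — the boundary approximation the formula makes."""
    g, c, t = 1000, 10, 1
    rng = np.random.default_rng(123)
    reps = 20000
    pos = rng.integers(0, g, size=(reps, c))
    iu, ju = np.triu_indices(c, k=1)
    d = (pos[:, iu] - pos[:, ju]) % g
    neigh = ((d >= 1) & (d <= t + 1)) | (d >= g - (t + 1))
    frac = neigh.mean(axis=1)
    se = frac.std(ddof=1) / np.sqrt(reps)
    table = CoAcquisitionTable(0.0, t, [], {("x", "c"): (c, g)})
    expected = expected_neighbor_percent(table) / 100.0
    assert abs(frac.mean() - expected) < 3 * se + 1e-12


def _pair(intervening, cotransfer):
    return CoAcquisitionPair(
        "X", "c", "a", "b", "F1", "F2", intervening, cotransfer
    )


def test_cotransfer_stats():
    table = CoAcquisitionTable(0.0, 1, [_pair(0, True), _pair(3, False)], {})
    assert cotransfer_stats(table) == (50.0, 50.0)
    table = CoAcquisitionTable(0.0, 1, [_pair(4, True)], {})
    assert cotransfer_stats(table) == (100.0, 0.0)
    donorless = CoAcquisitionTable(0.0, 1, [_pair(0, None)], {})
    with pytest.raises(ValueError, match="no donors"):
        cotransfer_stats(donorless)


def test_donor_flags_from_events(leaf_tree):
    ann = _annotation("X", 1100, {0, 1, 5})
    events = _events("X", [0, 1, 5], donors={0: "DON1", 1: "DON1", 5: "DON2"})
    table = enumerate_coacquisitions(events, [ann], leaf_tree, t=1)
    flags = {
        frozenset((p.family_a, p.family_b)): p.cotransfer for p in table.pairs
    }
    assert flags[frozenset(("GAINED_0", "GAINED_1"))] is True
    assert flags[frozenset(("GAINED_0", "GAINED_5"))] is False


def test_stringency_sweep_exclusions_and_monotone_counts(leaf_tree):
    ann = _annotation("X", 1200, set(range(12)))
    all_events = _events("X", range(12))
    levels = {
        1.0: all_events,  # 66 pairs
        2.0: all_events[:3],  # 3 pairs -> excluded
        3.0: [],  # no pairs
    }
    iset = hb.InferenceSet("m", levels)
    rows = stringency_sweep(iset, [ann], leaf_tree, t=1)
    by_s = {r.stringency: r for r in rows}
    assert not by_s[1.0].excluded and by_s[1.0].n_coacquisitions == 66
    assert by_s[2.0].excluded and by_s[2.0].reason == "min-pairs"
    assert by_s[3.0].excluded and by_s[3.0].reason == "no-pairs"
    counts = [by_s[s].n_coacquisitions for s in (1.0, 2.0, 3.0)]
    assert counts == sorted(counts, reverse=True)


def test_truth_beats_null_expectation(sim_bundle):
    """Ground-truth gains from a segmental-transfer simulation are far more
    often neighbors than the random-placement expectation."""
    tree, annotations, _, truth = sim_bundle
    table = enumerate_coacquisitions(truth.events(1.0), annotations, tree, t=1)
    assert table.n_pairs >= 20
    assert percent_neighbors(table) > 5 * expected_neighbor_percent(table)


def test_wagner_stringency_improves_neighbor_fraction():
    """Raising the gain/loss penalty ratio prunes poorly supported gains, so
    the surviving inferences are enriched for true segmental transfers."""
    tree = hb.simulate_species_tree(20, seed=21)
    params = hb.EvolutionParams(
        root_size=1500, p_loss=0.03, hgt_rate=8.0, p_seg=0.4,
        rearr_rate=0.2, p_novel=0.6, seed=21,
    )
    annotations, log = hb.evolve_genomes(tree, params)
    matrix = hb.presence_absence_from_orders(annotations)
    iset = hb.sweep_ratios(tree, matrix, hb.ParsimonyConfig(ratio_sweep=[1, 7]))
    rows = {r.stringency: r for r in stringency_sweep(iset, annotations, tree, t=1)}
    assert not rows[1.0].excluded and not rows[7.0].excluded
    assert rows[7.0].pct_neighbors > rows[1.0].pct_neighbors
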