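import numpy as np
import pytest

import hgtbench as hb


@pytest.fixture(scope="session")
def small_tree():
    """((A,B)N1,(C,D)N2)R; unit branch lengths."""
    root = hb.TreeNode("R")
    n1 = root.add_child(hb.TreeNode("N1", 1.0))
    n2 = root.add_child(hb.TreeNode("N2", 1.0))
    for lbl, parent in (("A", n1), ("B", n1), ("C", n2), ("D", n2)):
        parent.add_child(hb.TreeNode(lbl, 1.0))
    return hb.SpeciesTree(root)


@pytest.fixture(scope="session")
def sim_bundle():
    """One standard simulation shared across tests: tree, annotations,
    truth log, truth inference set."""
    tree = hb.simulate_species_tree(30, seed=11)
    params = hb.EvolutionParams(seed=11)
    annotations, log = hb.evolve_genomes(tree, params)
    truth = hb.truth_inference(log)
    return tree, annotations, log, truth


def random_tree_and_presence(rng: np.random.Generator, max_leaves: int = 6):
    """Random small tree plus a random non-empty presence vector."""
    n = int(rng.integers(3, max_leaves + 1))
    tree = hb.simulate_species_tree(n, seed=int(rng.integers(2**31)))
    leaves = tree.leaf_labels
    while True:
        presence = {l: int(rng.integers(2)) for l in leaves}
        if any(presence.values()):
            return tree, presence


def brute_force_min_cost(tree, presence, r):
    """Exhaustive minimum over all internal-node state labelings.

    Cost convention matches the parsimony module: loss 1, gain r, and a
    family present at the root is charged one stem gain (r).
    """
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
            s_p, s_c = state[node.parent.label], state[node.label]
            if s_p == 0 and s_c == 1:
                cost += r
            elif s_p == 1 and s_c == 0:
                cost += 1.0
        best = min(best, cost)
    return best
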