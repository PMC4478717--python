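import numpy as np
import pytest

import mitorisk as mr


@pytest.fixture(scope="session")
def curated():
    """Miniature mtDNA-like reference tree + full-resolution panel."""
    return mr.curated_tree()


@pytest.fixture()
def chain():
    """RSRS -> T -> T1 -> T1a chain with a 3-locus panel."""
    panel = mr.LocusPanel(
        [
            mr.Locus(100, "G", "A"),
            mr.Locus(200, "T", "C"),
            mr.Locus(300, "C", "T"),
        ]
    )
    tree = mr.ReferenceTree.from_edge_table(
        [
            ("RSRS", "T", "G100A"),
            ("T", "T1", "T200C"),
            ("T1", "T1a", "C300T"),
        ],
        panel=panel,
    )
    return tree, panel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


# ---------------------------------------------------------------------------
# independent oracles


def oracle_node_state(tree, node, panel):
    """Naive replay: intersect the root-path substitution list with the panel."""
    state = {l.position: l.ref_allele for l in panel}
    for member in tree.root_path(node)[1:]:
        for m in tree.edge_mutations[member]:
            if m.position in state:
                state[m.position] = m.to_allele
    return tuple(state[p] for p in panel.positions)


def oracle_mrca(tree, nodes):
    """Deepest node present on every member's root path."""
    paths = [tree.root_path(n) for n in nodes]
    common = set(paths[0]).intersection(*map(set, paths[1:]))
    return max(common, key=lambda n: tree.depth[n])


def oracle_fitch_score(children, root, leaf_states):
    """Brute-force minimum change count over all internal labelings."""
    from itertools import product

    internal = [n for n in children if children[n]]
    fixed = {n: s for n, s in leaf_states.items()}
    best = None
    for combo in product([0, 1], repeat=len(internal)):
        lab = dict(fixed)
        lab.update(dict(zip(internal, combo)))
        changes = sum(
            lab[p] != lab[c] for p in children for c in children[p]
        )
        best = changes if best is None else min(best, changes)
    return best
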