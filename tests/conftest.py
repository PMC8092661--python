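import numpy as np
import pytest

from piturn.evolution import CharacterMatrix, read_tree
from piturn.helix import (assign_helix_types, compute_hbonds_ks,
                          place_backbone_hydrogens)
from piturn.synthetic import HelixSpec, make_ideal_helix, make_toy_dimer


@pytest.fixture(scope="session")
def composite_helix():
    """alpha(8) + pi(6) + alpha(8) backbone with hydrogens placed."""
    s = make_ideal_helix(HelixSpec([("alpha", 8), ("pi", 6), ("alpha", 8)]))
    place_backbone_hydrogens(s)
    return s


@pytest.fixture(scope="session")
def composite_assignment(composite_helix):
    hbonds = compute_hbonds_ks(composite_helix)
    return assign_helix_types(composite_helix, hbonds), hbonds


@pytest.fixture()
def bridged_dimer():
    return make_toy_dimer(20, 20.0, [(5, 5, 2.8)])


@pytest.fixture(scope="session")
def five_tip_tree():
    return read_tree("(((A:0.3,B:0.5):0.4,C:0.8):0.2,(D:0.6,E:0.9):0.5);")


@pytest.fixture(scope="session")
def five_tip_chars():
    return CharacterMatrix({"A": 0, "B": 0, "C": 1, "D": 1, "E": 0}, ("0", "1"))


def enumeration_loglik(tree, chars, model):
    """Brute-force likelihood: sum over all internal-node state labelings."""
    import itertools

    from piturn.evolution import transition_matrix

    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf()]
    k = model.k
    P = {n.index: transition_matrix(model, n.length)
         for n in nodes if n is not tree.root}
    total = 0.0
    for labeling in itertools.product(range(k), repeat=len(internals)):
        states = {n.index: s for n, s in zip(internals, labeling)}
        for tip in tree.tips():
            states[tip.index] = chars.states[tip.label]
        lik = model.prior[states[tree.root.index]]
        for node in nodes:
            if node is tree.root:
                continue
            parent = tree.parent(node)
            s_tip = states[node.index]
            if s_tip is None:  # missing tip: marginalize
                lik *= 1.0
            else:
                lik *= P[node.index][states[parent.index], s_tip]
        total += lik
    return float(np.log(total))


def enumeration_marginals(tree, chars, model):
    """Brute-force node posteriors by enumerating all labelings."""
    import itertools

    from piturn.evolution import transition_matrix

    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf()]
    k = model.k
    P = {n.index: transition_matrix(model, n.length)
         for n in nodes if n is not tree.root}
    weights = {n.index: np.zeros(k) for n in internals}
    for labeling in itertools.product(range(k), repeat=len(internals)):
        states = {n.index: s for n, s in zip(internals, labeling)}
        for tip in tree.tips():
            states[tip.index] = chars.states[tip.label]
        lik = model.prior[states[tree.root.index]]
        for node in nodes:
            if node is tree.root:
                continue
            s_tip = states[node.index]
            if s_tip is not None:
                lik *= P[node.index][states[tree.parent(node).index], s_tip]
        for n in internals:
            weights[n.index][states[n.index]] += lik
    return {i: w / w.sum() for i, w in weights.items()}


def enumeration_parsimony(tree, chars):
    """Exhaustive minimum-change count over all internal labelings."""
    import itertools

    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf()]
    observed = sorted({s for s in chars.states.values() if s is not None})
    best = None
    for labeling in itertools.product(observed, repeat=len(internals)):
        states = {n.index: s for n, s in zip(internals, labeling)}
        for tip in tree.tips():
            states[tip.index] = chars.states[tip.label]
        changes = 0
        for node in nodes:
            if node is tree.root or states[node.index] is None:
                continue
            if states[node.index] != states[tree.parent(node).index]:
                changes += 1
        best = changes if best is None else min(best, changes)
    return best
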