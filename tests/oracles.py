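"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation paths they check:
the forward oracle enumerates every state path explicitly; the Sankoff
oracle enumerates every ancestral labeling.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from symgras.seqio import AMINO_ACIDS

_AAI = {a: i for i, a in enumerate(AMINO_ACIDS)}


def brute_force_forward(hmm, residues: str) -> float:
    """Forward log-odds bit score by explicit enumeration of all paths.

    Paths are triples (entry point i, core state path consuming residues
    i..j-1, exit point j); flank residues emit background and cost zero
    bits, matching the glocal scoring semantics.
    """
    m = hmm.n_match
    xs = [_AAI[c] for c in residues]
    L = len(xs)
    bg = hmm.background
    t = hmm.transitions

    def lo_match(k: int, x: int) -> float:
        return hmm.match_emissions[k, x] / bg[x]

    def lo_insert(k: int, x: int) -> float:
        return hmm.insert_emissions[k, x] / bg[x]

    path_odds: list[float] = []

    def extend(k: int, state: str, pos: int, j: int, odds: float) -> None:
        if k == m - 1 and state in "MD":
            if pos == j:
                path_odds.append(odds)
            return
        key = {"M": "M", "I": "I", "D": "D"}[state]
        # to insert of current node
        if k < m - 1 and pos < j:
            extend(k, "I", pos + 1, j, odds * t[key + "I"][k] * lo_insert(k, xs[pos]))
        # to next match
        if k + 1 < m and pos < j:
            extend(k + 1, "M", pos + 1, j, odds * t[key + "M"][k] * lo_match(k + 1, xs[pos]))
        # to next delete
        if k + 1 < m:
            extend(k + 1, "D", pos, j, odds * t[key + "D"][k])

    for i in range(L + 1):
        for j in range(i, L + 1):
            if i < j:
                extend(0, "M", i + 1, j, t["BM"] * lo_match(0, xs[i]))
            extend(0, "D", i, j, t["BD"])
    total = sum(path_odds)
    return math.log2(total) if total > 0 else -math.inf


def brute_force_sankoff(tree, leaf_counts: dict[str, int], n_states: int,
                        dollo: bool = True) -> int:
    """Minimum total |parent-child| cost over all ancestral labelings.

    ``leaf_counts`` maps leaf label -> observed copy number. Regain from
    zero is forbidden on every branch when ``dollo`` is set.
    """
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    idx = {id(n): i for i, n in enumerate(internals)}
    edges = []  # (parent kind, parent index-or-state, child kind, ...)
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            if child.is_leaf():
                edges.append((idx[id(node)], leaf_counts[child.taxon.label]))
            else:
                edges.append((idx[id(node)], None, idx[id(child)]))

    states = np.array(
        list(itertools.product(range(n_states), repeat=len(internals))),
        dtype=np.int16,
    )
    cost = np.zeros(len(states), dtype=float)
    for edge in edges:
        if len(edge) == 2:
            p, leaf_state = edge
            a = states[:, p]
            b = np.full_like(a, leaf_state)
        else:
            p, _, c = edge
            a, b = states[:, p], states[:, c]
        step = np.abs(a - b).astype(float)
        if dollo:
            step[(a == 0) & (b > 0)] = math.inf
        cost += step
    best = cost.min()
    assert math.isfinite(best)
    return int(best)
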