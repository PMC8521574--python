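"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (explicit
loops, scipy.linalg.expm, literal set algebra) so it shares no code path
with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

# -- genetic code, rebuilt by hand from the standard-code codon table ------

_BASES = "ACGT"
_CODE = {}
_STANDARD = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product("TCAG", repeat=3)):
    _CODE[_a + _b + _c] = _STANDARD[_i]
SENSE_CODONS = sorted(c for c, aa in _CODE.items() if aa != "*")


def brute_unscaled_q(kappa, omega, pi):
    """GY94 rate matrix by direct double loop (no shared code)."""
    n = len(SENSE_CODONS)
    Q = np.zeros((n, n))
    transitions = {frozenset("AG"), frozenset("CT")}
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(ci, cj) if x != y]
            if len(diffs) != 1:
                continue
            rate = pi[j]
            if frozenset(diffs[0]) in transitions:
                rate *= kappa
            if _CODE[ci] != _CODE[cj]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def brute_class_generator(kappa, omega, pi):
    """Effective generator of one omega class under the package's units:
    the unscaled GY94 matrix divided by the NEUTRAL mean rate."""
    Q = brute_unscaled_q(kappa, omega, pi)
    Q1 = brute_unscaled_q(kappa, 1.0, pi)
    neutral_rate = -float(np.dot(pi, np.diag(Q1)))
    return Q / neutral_rate


def enumeration_site_loglike(tree, leaf_state, kappa, omega_bg, omega_fg, pi, focal):
    """Site log-likelihood by exhaustive summation over all internal-state
    assignments (einsum contraction over one 61-axis per internal node),
    with transition matrices from scipy expm.

    ``tree`` is an evosig PhyloTree (topology/lengths only are used);
    ``leaf_state`` maps leaf name -> codon index or -1 for a gap.
    """
    Q_bg = brute_class_generator(kappa, omega_bg, pi)
    Q_fg = brute_class_generator(kappa, omega_fg, pi)
    n = len(SENSE_CODONS)

    operands = []
    subscripts = []
    axis_of = {}
    next_axis = [0]

    def axis(node):
        if id(node) not in axis_of:
            axis_of[id(node)] = chr(ord("a") + next_axis[0])
            next_axis[0] += 1
        return axis_of[id(node)]

    root = tree._tree.seed_node
    operands.append(np.asarray(pi))
    subscripts.append(axis(root))
    for node in tree._tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        is_fg = node.is_leaf() and node.taxon.label == focal
        P = expm((Q_fg if is_fg else Q_bg) * t)
        pax = axis(node.parent_node)
        if node.is_leaf():
            obs = leaf_state[node.taxon.label]
            vec = P.sum(axis=1) if obs < 0 else P[:, obs]
            operands.append(vec)
            subscripts.append(pax)
        else:
            operands.append(P)
            subscripts.append(pax + axis(node))
    expr = ",".join(subscripts) + "->"
    return float(np.log(np.einsum(expr, *operands)))


def literal_enumeration_loglike(tree, leaf_state, kappa, omega, pi):
    """The same quantity by a literal python loop over every internal-state
    assignment (feasible only for trees with <= 2 internal nodes)."""
    Q = brute_class_generator(kappa, omega, pi)
    nodes = list(tree._tree.preorder_node_iter())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    P = {}
    for nd in nodes:
        if nd.parent_node is not None:
            P[id(nd)] = expm(Q * (nd.edge.length or 0.0))
    n = len(SENSE_CODONS)
    total = 0.0
    for assign in itertools.product(range(n), repeat=len(internals)):
        state = {id(nd): s for nd, s in zip(internals, assign)}
        term = pi[state[id(tree._tree.seed_node)]]
        for nd in nodes:
            if nd.parent_node is None:
                continue
            sp = state[id(nd.parent_node)]
            if nd.is_leaf():
                obs = leaf_state[nd.taxon.label]
                term *= 1.0 if obs < 0 else P[id(nd)][sp, obs]
            else:
                term *= P[id(nd)][sp, state[id(nd)]]
        total += term
    return float(np.log(total))


# -- simple combinatorial oracles ------------------------------------------


def brute_gap_mask(matrix, flank):
    """For every column, scan +-flank for any gap or X in any row."""
    n_taxa, n_cols = matrix.shape
    bad = [
        any(matrix[t][c] in "-X" for t in range(n_taxa)) for c in range(n_cols)
    ]
    mask = []
    for c in range(n_cols):
        lo = max(0, c - flank)
        hi = min(n_cols - 1, c + flank)
        mask.append(any(bad[k] for k in range(lo, hi + 1)))
    return np.array(mask)


def brute_bh(pvalues):
    """Benjamini-Hochberg step-up by the textbook formula."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return np.array(q)


def brute_root_to_tip(tree):
    """Climb parent pointers from every leaf, summing edge lengths."""
    out = {}
    for leaf in tree._tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = d
    return out


def brute_msa_summary(rows):
    """Set-algebra counts from (unique, divergent, selected) boolean rows."""
    U = {i for i, r in enumerate(rows) if r[0]}
    D = {i for i, r in enumerate(rows) if r[1]}
    P = {i for i, r in enumerate(rows) if r[2]}
    venn = {
        "U": len(U - D - P),
        "D": len(D - U - P),
        "P": len(P - U - D),
        "UD": len((U & D) - P),
        "UP": len((U & P) - D),
        "DP": len((D & P) - U),
        "UDP": len(U & D & P),
    }
    msa = len((U & D) | (U & P) | (D & P))
    return {
        "unique_sub_impact": len(U),
        "divergent": len(D),
        "positively_selected": len(P),
        "msa": msa,
        "venn": venn,
    }
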