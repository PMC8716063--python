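"""Shared tree builders and independent brute-force oracles for the tests.

The oracles deliberately avoid the package's own vectorised/DP code paths:
genotypes are recomputed by explicit parent walks, elementary symmetric
polynomials by subset enumeration, and set probabilities by enumerating all
subsets, so that agreement is a genuine cross-check.
"""
from __future__ import annotations

import itertools

import numpy as np

from clonex.trees import ClonalTree


def linear_tree(pid: str, genes, tree_id: str = "t0") -> ClonalTree:
    """Chain tree, one gene per clone: every pair co-occurs (r = 0)."""
    genes = list(genes)
    clones = [f"c{i}" for i in range(len(genes))]
    parent = {c: (clones[i - 1] if i else None) for i, c in enumerate(clones)}
    branch = {c: frozenset([g]) for c, g in zip(clones, genes)}
    return ClonalTree(pid, tree_id, parent, branch)


def star_tree(pid: str, genes, tree_id: str = "t0") -> ClonalTree:
    """Empty root with one child per gene: every pair exclusive (r = 1)."""
    genes = list(genes)
    clones = ["c0"] + [f"c{i + 1}" for i in range(len(genes))]
    parent = {"c0": None, **{c: "c0" for c in clones[1:]}}
    branch = {"c0": frozenset()}
    for c, g in zip(clones[1:], genes):
        branch[c] = frozenset([g])
    return ClonalTree(pid, tree_id, parent, branch)


def cherry_tree(pid: str, root_genes, left_genes, right_genes,
                tree_id: str = "t0") -> ClonalTree:
    """Root with two children; an informative topology when genes split."""
    return ClonalTree(pid, tree_id,
                      {"c0": None, "c1": "c0", "c2": "c0"},
                      {"c0": frozenset(root_genes),
                       "c1": frozenset(left_genes),
                       "c2": frozenset(right_genes)})


def random_tree(rng: np.random.Generator, n_clones: int, genes,
                pid: str = "rt", tree_id: str = "t0") -> ClonalTree:
    """Random parent-vector tree with genes scattered over branches."""
    clones = [f"c{i}" for i in range(n_clones)]
    parent = {"c0": None}
    for i in range(1, n_clones):
        parent[clones[i]] = clones[int(rng.integers(i))]
    branch: dict[str, set] = {c: set() for c in clones}
    for g in genes:
        branch[clones[int(rng.integers(n_clones))]].add(g)
    return ClonalTree(pid, tree_id, parent,
                      {c: frozenset(s) for c, s in branch.items()})


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_genotype(tree: ClonalTree, clone: str) -> frozenset:
    """Genotype of a clone by an explicit walk to the root."""
    genes: set = set()
    node = clone
    while node is not None:
        genes |= tree.branch_genes[node]
        node = tree.parent[node]
    return frozenset(genes)


def brute_pair_exclusive(tree: ClonalTree, j: str, k: str) -> bool:
    return not any(j in g and k in g
                   for g in (brute_genotype(tree, c) for c in tree.clones))


def brute_background_rate(tree: ClonalTree) -> float:
    genes = sorted(tree.genes)
    pairs = list(itertools.combinations(genes, 2))
    excl = sum(brute_pair_exclusive(tree, j, k) for j, k in pairs)
    return excl / len(pairs)


def brute_esp(weights, k: int) -> float:
    return float(sum(np.prod([weights[i] for i in sub])
                     for sub in itertools.combinations(range(len(weights)), k)))


def brute_set_prob(s, w, wp=None) -> float:
    """Probability of set s under product-of-weights sampling."""
    wp = w if wp is None else wp
    k = len(s)
    num = np.prod([wp[i] for i in s])
    z = brute_esp(wp, k)
    return float(num / z)


def brute_null_m(n_t: int, w, r) -> np.ndarray:
    """Null distribution of the exclusive count m by full enumeration."""
    n = len(w)
    pm = np.zeros(n_t + 1)
    z = 0.0
    for sub in itertools.combinations(range(n), n_t):
        pw = np.prod([w[i] for i in sub])
        z += pw
        for outs in itertools.product([0, 1], repeat=n_t):
            pr = np.prod([r[i] if o else 1.0 - r[i]
                          for i, o in zip(sub, outs)])
            pm[sum(outs)] += pw * pr
    return pm / z
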