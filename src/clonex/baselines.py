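"""Naive clone-level exclusivity tests that ignore phylogeny.

Each clone of each tumour contributes one unit to a 2x2 contingency table
cross-classifying presence of the two genes (presence meaning inherited or
newly mutated).  Treating clones as independent observations ignores their
phylogenetic dependency, which inflates the type-I error of the standard
independence tests; these baselines exist to demonstrate that confounding.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .trees import PatientSample, clone_genotypes

__all__ = ["clone_table", "fisher_p", "g_test_p", "log_or_z"]


def clone_table(cohort: Sequence[PatientSample], gene_j: str, gene_k: str,
                tree_index: int = 0) -> np.ndarray:
    """Pooled 2x2 clone table for a gene pair.

    Layout: rows = gene_j present/absent, columns = gene_k present/absent,
    so ``t[0, 0]`` counts clones carrying both genes.  Patients with several
    trees contribute the tree at ``tree_index`` (default: the first), and
    only patients whose chosen tree contains both genes are pooled.
    """
    table = np.zeros((2, 2), dtype=int)
    found = False
    for p in cohort:
        if tree_index >= len(p.trees):
            continue
        tree = p.trees[tree_index]
        if gene_j not in tree.genes or gene_k not in tree.genes:
            continue
        found = True
        gm = clone_genotypes(tree)
        rj = gm.gene_row(gene_j)
        rk = gm.gene_row(gene_k)
        table[0, 0] += int(np.sum(rj & rk))
        table[0, 1] += int(np.sum(rj & ~rk))
        table[1, 0] += int(np.sum(~rj & rk))
        table[1, 1] += int(np.sum(~rj & ~rk))
    if not found:
        raise ValueError(f"pair ({gene_j}, {gene_k}) occurs in no patient tree")
    return table


def _degenerate(table: np.ndarray) -> bool:
    t = np.asarray(table)
    return bool((t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any())


def fisher_p(table: np.ndarray) -> float:
    """Two-sided Fisher's exact test p-value."""
    if _degenerate(table):
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def g_test_p(table: np.ndarray) -> float:
    """Two-sided G-test (likelihood-ratio chi-squared, 1 df, no Williams
    correction)."""
    if _degenerate(table):
        return 1.0
    res = stats.chi2_contingency(table, correction=False,
                                 lambda_="log-likelihood")
    return float(res.pvalue)


def log_or_z(table: np.ndarray):
    """Log odds ratio test with the normal approximation.

    Applies the Haldane-Anscombe +0.5 correction to every cell when any cell
    is zero.  Returns ``(z, p)``; negative z indicates clonal exclusivity
    (off-diagonal excess), positive z co-occurrence.
    """
    t = np.asarray(table, dtype=float)
    if t.sum() == 0:
        return 0.0, 1.0
    if (t == 0).any():
        t = t + 0.5
    lor = np.log(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    se = np.sqrt(np.sum(1.0 / t))
    z = float(lor / se)
    return z, float(2.0 * stats.norm.sf(abs(z)))
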