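"""Synthetic-data generation and simulation studies.

Study conditions
----------------
Background exclusivity rates are drawn from Beta(2, 3), which matches the
mean (0.4) and spread of rates observed in real single-cell AML cohorts.
Effects are planted as a logit shift Delta of those rates (negative Delta =
exclusivity enrichment).  For the comparison with naive clone-level tests,
tumours are emulated as uniformly sampled random binary trees with 10 inner
branches carrying 20 uniformly placed mutations (10 clonal genotypes per
tree), collated into sets of 10 trees and repeated 400 times.

The module also provides a full synthetic-cohort generator emitting the
clone-per-row TSV schema, used both as the test-fixture factory and for
parameter-recovery experiments.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import clone_table, fisher_p, g_test_p, log_or_z
from .combined import p_combined_exact
from .occurrence import CohortWeights, occurrence_test
from .placement import (ShiftParams, SmoothingParams, chisq_pvalues_batch,
                        exact_pvalues_batch, mc_pvalues_batch, shift_rate)
from .trees import (ClonalTree, PatientSample, background_rate,
                    pair_relation, write_cohort, EXCLUSIVE)

__all__ = [
    "SimulationSpec",
    "sample_rates",
    "simulate_outcomes",
    "random_binary_tree",
    "run_calibration",
    "run_power",
    "run_naive_comparison",
    "synth_cohort",
    "sample_weighted_set",
    "rejection_rate",
]

_EPS = 1e-12

PLACEMENT_TESTS = ("placement_chisq", "placement_exact", "placement_mc")
COHORT_TESTS = ("occurrence", "combined")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the simulation studies (see module docstring).

    ``n`` is the number of patient samples carrying the simulated gene pair,
    ``delta`` the planted logit-shift effect (0 = null), ``reps`` the number
    of replicates, and the ``tree_*`` fields configure the random-binary-tree
    null of the naive-test comparison.
    """

    beta_a: float = 2.0
    beta_b: float = 3.0
    n: int = 10
    delta: float = 0.0
    reps: int = 1000
    alpha: float = 0.05
    inner_branches: int = 10
    mutations: int = 20
    trees_per_set: int = 10
    sets: int = 400
    nu: float = 10.0
    mc_samples: int = 1000
    seed: int = 0

    def __post_init__(self):
        if min(self.n, self.reps, self.inner_branches, self.mutations,
               self.trees_per_set, self.sets, self.mc_samples) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def sample_rates(spec: SimulationSpec,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """n i.i.d. Beta(beta_a, beta_b) background rates, clipped into (0, 1)."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    return np.clip(rng.beta(spec.beta_a, spec.beta_b, size=spec.n),
                   _EPS, 1.0 - _EPS)


def simulate_outcomes(rates: np.ndarray, delta: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Binary exclusivity outcomes O_i ~ Bernoulli(shift_rate(r_i, delta))."""
    shifted = shift_rate(np.asarray(rates, dtype=float), delta)
    return (rng.random(shifted.shape) < shifted).astype(float)


# ---------------------------------------------------------------------------
# random trees
# ---------------------------------------------------------------------------

def random_binary_tree(inner_branches: int, mutations: int,
                       rng: np.random.Generator,
                       patient_id: str = "sim",
                       tree_id: str = "t0") -> ClonalTree:
    """Uniform random binary tree with one clone per inner branch.

    A leaf-labelled binary tree is grown by Remy-style uniform edge
    insertion (each step splits a uniformly chosen edge, counting the
    virtual edge above the root); its ``inner_branches`` internal nodes
    become the clones, and each of the ``mutations`` labels is assigned
    uniformly at random (with replacement) to one internal branch.
    """
    if inner_branches < 1:
        raise ValueError("inner_branches must be >= 1")
    parent: dict[int, int | None] = {0: None}
    internal: set[int] = set()
    next_id = 1
    nodes = [0]
    for _ in range(inner_branches):
        v = nodes[rng.integers(len(nodes))]
        u = next_id
        leaf = next_id + 1
        next_id += 2
        parent[u] = parent[v]
        parent[v] = u
        parent[leaf] = u
        internal.add(u)
        nodes.extend([u, leaf])
    internal_list = sorted(internal)
    label = {node: f"c{i}" for i, node in enumerate(internal_list)}

    def internal_parent(node: int) -> str | None:
        p = parent[node]
        while p is not None and p not in internal:
            p = parent[p]
        return label[p] if p is not None else None

    clone_parent = {label[v]: internal_parent(v) for v in internal_list}
    assign = rng.integers(len(internal_list), size=mutations)
    branch_genes: dict[str, set[str]] = {label[v]: set() for v in internal_list}
    for g, b in enumerate(assign):
        branch_genes[label[internal_list[b]]].add(f"g{g}")
    return ClonalTree(patient_id, tree_id, clone_parent,
                      {c: frozenset(gs) for c, gs in branch_genes.items()})


# ---------------------------------------------------------------------------
# weighted subset sampling (Fisher non-central hypergeometric null)
# ---------------------------------------------------------------------------

def sample_weighted_set(w: np.ndarray, k: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw a k-subset with probability proportional to the product of its
    weights, by sequential conditionals on suffix elementary symmetric
    polynomials."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if not 0 <= k <= n:
        raise ValueError("k out of range")
    scale = w.max(initial=0.0)
    if scale <= 0:
        raise ValueError("need at least one positive weight")
    ws = w / scale
    # suffix[i, j] = e_j(ws[i:])
    suffix = np.zeros((n + 1, k + 1))
    suffix[n, 0] = 1.0
    for i in range(n - 1, -1, -1):
        suffix[i, 0] = 1.0
        suffix[i, 1:] = suffix[i + 1, 1:] + ws[i] * suffix[i + 1, :-1]
    chosen = []
    need = k
    for i in range(n):
        if need == 0:
            break
        p_take = ws[i] * suffix[i + 1, need - 1] / suffix[i, need]
        if rng.random() < p_take:
            chosen.append(i)
            need -= 1
    return np.array(chosen, dtype=int)


def _null_cohort_weights(rng: np.random.Generator, n_patients: int = 40,
                         linear_frac: float = 0.65, star_frac: float = 0.04,
                         beta_a: float = 2.0, beta_b: float = 3.0) -> CohortWeights:
    """Synthetic cohort composition mirroring a mostly-linear AML-like cohort:
    about two thirds linear trees (r = 0), a few star trees (r = 1), the rest
    branched with Beta rates; w drawn as C(g, 2) for g in 2..6 genes."""
    kinds = rng.random(n_patients)
    r = np.where(kinds < linear_frac, 0.0,
                 np.where(kinds < linear_frac + star_frac, 1.0,
                          np.clip(rng.beta(beta_a, beta_b, n_patients),
                                  _EPS, 1 - _EPS)))
    g = rng.integers(2, 7, size=n_patients)
    w = (g * (g - 1) // 2).astype(float)
    return CohortWeights(tuple(f"p{i}" for i in range(n_patients)), w, r)


# ---------------------------------------------------------------------------
# studies
# ---------------------------------------------------------------------------

def run_calibration(spec: SimulationSpec, test: str) -> pd.DataFrame:
    """Null p-values for one test variant; tidy frame (test, n, delta, rep, p).

    Placement variants draw rates from the Beta null and outcomes at those
    rates.  The occurrence/combined variants draw a fresh synthetic cohort
    per replicate, select the carrier set by Fisher-weighted sampling and
    place the pair uniformly (outcomes Bernoulli(r_i)).
    """
    rng = np.random.default_rng(spec.seed)
    params = ShiftParams()
    if test in PLACEMENT_TESTS:
        rates = np.clip(rng.beta(spec.beta_a, spec.beta_b,
                                 size=(spec.reps, spec.n)), _EPS, 1 - _EPS)
        outcomes = (rng.random(rates.shape) < rates).astype(float)
        if test == "placement_chisq":
            p = chisq_pvalues_batch(rates, outcomes, params)
        elif test == "placement_exact":
            p = exact_pvalues_batch(rates, outcomes, params)
        else:
            smooth = SmoothingParams(nu=spec.nu, n_samples=spec.mc_samples)
            p = mc_pvalues_batch(rates, outcomes, params, smooth, rng)
    elif test in COHORT_TESTS:
        p = np.empty(spec.reps)
        for rep in range(spec.reps):
            cohort = _null_cohort_weights(rng, beta_a=spec.beta_a,
                                          beta_b=spec.beta_b)
            s = sample_weighted_set(cohort.w, spec.n, rng)
            if test == "occurrence":
                p[rep] = occurrence_test(s, cohort, params).p
            else:
                m = int(np.sum(rng.random(spec.n) < cohort.r[s]))
                p[rep] = p_combined_exact(m, spec.n, cohort, params)
    else:
        raise ValueError(f"unknown test identifier {test!r}")
    return pd.DataFrame({"test": test, "n": spec.n, "delta": 0.0,
                         "rep": np.arange(spec.reps), "p": p})


def rejection_rate(pvalues, alpha: float = 0.05) -> float:
    return float(np.mean(np.asarray(pvalues) <= alpha))


def run_power(spec: SimulationSpec, deltas=(-4.0, -3.0, -2.0),
              ns=(4, 8, 10)) -> pd.DataFrame:
    """Power of the exact placement test on a (delta, n) grid.

    Each cell runs ``spec.reps`` replicates with Beta-distributed rates and
    outcomes drawn at the logit-shifted rates; power is the fraction of
    exact p-values at or below ``spec.alpha``.
    """
    rng = np.random.default_rng(spec.seed)
    params = ShiftParams()
    rows = []
    for n in ns:
        for delta in deltas:
            rates = np.clip(rng.beta(spec.beta_a, spec.beta_b,
                                     size=(spec.reps, n)), _EPS, 1 - _EPS)
            shifted = shift_rate(rates, delta)
            outcomes = (rng.random(rates.shape) < shifted).astype(float)
            p = exact_pvalues_batch(rates, outcomes, params)
            rows.append({"delta": delta, "n": n, "reps": spec.reps,
                         "power": rejection_rate(p, spec.alpha)})
    return pd.DataFrame(rows)


def run_naive_comparison(spec: SimulationSpec) -> pd.DataFrame:
    """Naive clone-level tests vs placement variants on the random-tree null.

    For each of ``spec.sets`` sets of ``spec.trees_per_set`` random binary
    trees, the designated mutation pair (g0, g1; mutations are exchangeable)
    is scored with the pooled-clone contingency tests and with the placement
    test variants on the informative trees.  Returns a tidy frame
    (rep, test, p).
    """
    rng = np.random.default_rng(spec.seed)
    params = ShiftParams()
    rows = []
    mc_queue: list[tuple[int, np.ndarray, np.ndarray]] = []
    for rep in range(spec.sets):
        trees = [random_binary_tree(spec.inner_branches, spec.mutations,
                                    rng, patient_id=f"p{rep}_{t}")
                 for t in range(spec.trees_per_set)]
        patients = [PatientSample.from_trees(t.patient_id, [t]) for t in trees]
        table = clone_table(patients, "g0", "g1")
        z, p_lor = log_or_z(table)
        rows.append({"rep": rep, "test": "fisher", "p": fisher_p(table)})
        rows.append({"rep": rep, "test": "g_test", "p": g_test_p(table)})
        rows.append({"rep": rep, "test": "log_or", "p": p_lor})
        rates, outs = [], []
        for t in trees:
            r = background_rate(t)
            if _EPS < r < 1.0 - _EPS:
                rates.append(r)
                outs.append(float(pair_relation(t, "g0", "g1") == EXCLUSIVE))
        if rates:
            rates_arr = np.array(rates)[None, :]
            outs_arr = np.array(outs)[None, :]
            p_chi = chisq_pvalues_batch(rates_arr, outs_arr, params)[0]
            rows.append({"rep": rep, "test": "placement_chisq", "p": p_chi})
            if len(rates) <= params.exact_max_n:
                p_ex = exact_pvalues_batch(rates_arr, outs_arr, params)[0]
            else:
                p_ex = p_chi
            rows.append({"rep": rep, "test": "placement_exact", "p": p_ex})
            mc_queue.append((rep, rates_arr, outs_arr))
    smooth = SmoothingParams(nu=spec.nu, n_samples=spec.mc_samples)
    for rep, rates_arr, outs_arr in mc_queue:
        p_mc = mc_pvalues_batch(rates_arr, outs_arr, params, smooth, rng)[0]
        rows.append({"rep": rep, "test": "placement_mc", "p": p_mc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic cohorts with planted effects
# ---------------------------------------------------------------------------

def _linear_tree(pid: str, genes: list[str], rng) -> ClonalTree:
    k = int(rng.integers(2, 5))
    clones = [f"c{i}" for i in range(k)]
    parent = {c: (clones[i - 1] if i else None) for i, c in enumerate(clones)}
    branch: dict[str, set[str]] = {c: set() for c in clones}
    for g in genes:
        branch[clones[rng.integers(k)]].add(g)
    return ClonalTree(pid, "t0", parent, {c: frozenset(s) for c, s in branch.items()})


def _star_tree(pid: str, genes: list[str], rng) -> ClonalTree:
    clones = ["c0"] + [f"c{i + 1}" for i in range(len(genes))]
    parent = {"c0": None, **{c: "c0" for c in clones[1:]}}
    branch = {"c0": frozenset()}
    for c, g in zip(clones[1:], genes):
        branch[c] = frozenset([g])
    return ClonalTree(pid, "t0", parent, branch)


def _branched_tree(pid: str, genes: list[str], rng,
                   inner_lo: int = 3, inner_hi: int = 6,
                   max_tries: int = 50) -> ClonalTree:
    """Random binary-shaped tree carrying the given genes, retried until its
    background rate is informative (strictly between 0 and 1)."""
    for _ in range(max_tries):
        k = int(rng.integers(inner_lo, inner_hi + 1))
        base = random_binary_tree(k, len(genes), rng, patient_id=pid)
        relabel = dict(zip(sorted(base.genes, key=lambda g: int(g[1:])), genes))
        branch = {c: frozenset(relabel[g] for g in gs)
                  for c, gs in base.branch_genes.items()}
        tree = ClonalTree(pid, "t0", dict(base.parent), branch)
        if len(tree.genes) >= 2 and _EPS < background_rate(tree) < 1 - _EPS:
            return tree
    raise RuntimeError("failed to draw an informative branched tree")


def _comparability(tree: ClonalTree):
    """Ordered clone pairs split into comparable (incl. identical) and
    incomparable, based on ancestry."""
    clones = tree.clones
    anc: dict[str, set[str]] = {}
    for c in clones:
        path = set()
        node = c
        while node is not None:
            path.add(node)
            node = tree.parent[node]
        anc[c] = path
    comparable, incomparable = [], []
    for a in clones:
        for b in clones:
            if a in anc[b] or b in anc[a]:
                comparable.append((a, b))
            else:
                incomparable.append((a, b))
    return comparable, incomparable


def _plant_pair(tree: ClonalTree, pair: tuple[str, str], delta: float,
                rng) -> tuple[ClonalTree, int]:
    """Place the pair's genes on branches so the pair is exclusive with
    probability shift_rate(r, delta), r being the tree's background rate."""
    r = background_rate(tree)
    exclusive = int(rng.random() < shift_rate(r, delta))
    comparable, incomparable = _comparability(tree)
    options = incomparable if exclusive else comparable
    if not options:
        raise RuntimeError("tree lacks the required branch configuration")
    b1, b2 = options[rng.integers(len(options))]
    branch = {c: set(gs) for c, gs in tree.branch_genes.items()}
    branch[b1].add(pair[0])
    branch[b2].add(pair[1])
    return ClonalTree(tree.patient_id, tree.tree_id, dict(tree.parent),
                      {c: frozenset(s) for c, s in branch.items()},
                      tree.clone_freq), exclusive


def synth_cohort(path, *, n_pair_patients: int = 10, delta: float = -3.0,
                 n_linear: int = 14, n_star: int = 3, n_branched_extra: int = 3,
                 gene_pool: int = 10, genes_per_patient: tuple[int, int] = (4, 7),
                 pair: tuple[str, str] = ("GP1", "GP2"), seed: int = 0) -> dict:
    """Write a synthetic cohort TSV with a planted gene pair; returns truth.

    The cohort mixes linear, star and branched topologies (mirroring the
    mostly-linear composition of real AML cohorts).  The planted pair occurs
    in ``n_pair_patients`` informative branched patients and is clonally
    exclusive in each with probability shift_rate(r, delta).  A ground-truth
    sidecar (same path + ``.truth.json``) records the planted outcomes.
    """
    rng = np.random.default_rng(seed)
    pool = [f"B{i:02d}" for i in range(gene_pool)]
    lo, hi = genes_per_patient
    patients: list[PatientSample] = []
    truth_outcomes: dict[str, int] = {}
    pid_counter = 0

    def background_genes():
        k = int(rng.integers(lo, hi + 1))
        return list(rng.choice(pool, size=k, replace=False))

    for _ in range(n_pair_patients):
        pid = f"p{pid_counter:03d}"
        pid_counter += 1
        tree = _branched_tree(pid, background_genes(), rng)
        tree, exclusive = _plant_pair(tree, pair, delta, rng)
        truth_outcomes[pid] = exclusive
        patients.append(PatientSample.from_trees(pid, [tree]))
    for _ in range(n_branched_extra):
        pid = f"p{pid_counter:03d}"
        pid_counter += 1
        tree = _branched_tree(pid, background_genes(), rng)
        patients.append(PatientSample.from_trees(pid, [tree]))
    for _ in range(n_linear):
        pid = f"p{pid_counter:03d}"
        pid_counter += 1
        tree = _linear_tree(pid, background_genes(), rng)
        patients.append(PatientSample.from_trees(pid, [tree]))
    for _ in range(n_star):
        pid = f"p{pid_counter:03d}"
        pid_counter += 1
        tree = _star_tree(pid, background_genes(), rng)
        patients.append(PatientSample.from_trees(pid, [tree]))

    write_cohort(patients, path)
    truth = {"pair": list(pair), "delta": delta,
             "outcomes": truth_outcomes,
             "n_pair_patients": n_pair_patients, "seed": seed}
    Path(str(path) + ".truth.json").write_text(json.dumps(truth, indent=2))
    return truth
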