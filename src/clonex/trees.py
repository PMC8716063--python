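"""Clone-tree data model.

A tumour's evolutionary history is represented as a rooted clone hierarchy:
each clone is a node, and the branch entering a clone carries the set of
genes newly mutated in that clone.  A clone's genotype is the union of the
branch gene sets along its root-to-clone path (mutations are inherited).

A gene pair is *clonally exclusive* in a tree when no clone's genotype
carries both genes, i.e. the mutations sit on incomparable branches; the
complement (same branch, or ancestor/descendant branches) is *clonal
co-occurrence*.  The per-patient background exclusivity rate r is the
fraction of unordered gene pairs in the tree that are clonally exclusive,
averaged over the patient's (posterior sample of) trees.  Linear trees have
r = 0 and star trees with one gene per branch have r = 1; both are
uninformative for the placement test.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ClonalTree",
    "CloneGenotypeMatrix",
    "PatientSample",
    "GenePairObservation",
    "CohortParseError",
    "clone_genotypes",
    "pair_relation",
    "background_rate",
    "collect_pair",
    "read_cohort",
    "write_cohort",
    "map_to_pathways",
    "CO_OCCURRING",
    "EXCLUSIVE",
]

ROOT_SENTINEL = "-"
CO_OCCURRING = "co-occurring"
EXCLUSIVE = "exclusive"
_RATE_TOL = 1e-12  # tolerance for classifying r as exactly 0 or 1


class CohortParseError(ValueError):
    """Raised for malformed cohort files; the message names the input line."""


@dataclass(frozen=True, eq=False)
class ClonalTree:
    """Rooted clone hierarchy with per-branch mutated gene sets.

    ``parent`` maps every clone to its parent clone (``None`` for the single
    root).  ``branch_genes`` maps a clone to the genes newly mutated on the
    branch entering it; a gene may legitimately appear on several branches
    (parallel evolution).  ``clone_freq`` optionally gives clone fractions.
    """

    patient_id: str
    tree_id: str
    parent: Mapping[str, str | None]
    branch_genes: Mapping[str, frozenset[str]]
    clone_freq: Mapping[str, float] | None = None

    def __post_init__(self):
        clones = set(self.parent)
        roots = [c for c, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree {self.patient_id}/{self.tree_id}: "
                             f"expected exactly one root, found {len(roots)}")
        for c, p in self.parent.items():
            if p is not None and p not in clones:
                raise ValueError(f"tree {self.patient_id}/{self.tree_id}: "
                                 f"clone {c!r} has unknown parent {p!r}")
        # acyclic + connected: every clone must reach the root
        for c in clones:
            seen = set()
            node = c
            while node is not None:
                if node in seen:
                    raise ValueError(f"tree {self.patient_id}/{self.tree_id}: "
                                     f"cycle through clone {node!r}")
                seen.add(node)
                node = self.parent[node]
        extra = set(self.branch_genes) - clones
        if extra:
            raise ValueError(f"branch_genes refer to unknown clones: {sorted(extra)}")
        if self.clone_freq is not None:
            total = sum(self.clone_freq.values())
            if total > 1.0 + 1e-6:
                raise ValueError(f"clone frequencies sum to {total:.4f} > 1")
        object.__setattr__(self, "branch_genes",
                           {c: frozenset(self.branch_genes.get(c, ())) for c in clones})

    @property
    def root(self) -> str:
        return next(c for c, p in self.parent.items() if p is None)

    @property
    def clones(self) -> tuple[str, ...]:
        return tuple(sorted(self.parent))

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.branch_genes.values():
            out |= gs
        return frozenset(out)

    def children(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in self.parent}
        for c, p in self.parent.items():
            if p is not None:
                out[p].append(c)
        return out


@dataclass(frozen=True, eq=False)
class CloneGenotypeMatrix:
    """Binary genes-by-clones matrix; entry 1 iff the clone's root-to-clone
    path carries the gene.  Monotone along any lineage by construction."""

    genes: tuple[str, ...]
    clones: tuple[str, ...]
    matrix: np.ndarray  # shape (len(genes), len(clones)), dtype bool

    def carries(self, gene: str, clone: str) -> bool:
        return bool(self.matrix[self.genes.index(gene), self.clones.index(clone)])

    def gene_row(self, gene: str) -> np.ndarray:
        return self.matrix[self.genes.index(gene)]


def clone_genotypes(tree: ClonalTree) -> CloneGenotypeMatrix:
    """Derive the clone-genotype matrix: clones inherit ancestral mutations."""
    genes = tuple(sorted(tree.genes))
    gene_idx = {g: i for i, g in enumerate(genes)}
    clones = tree.clones
    clone_idx = {c: i for i, c in enumerate(clones)}
    mat = np.zeros((len(genes), len(clones)), dtype=bool)
    children = tree.children()
    # BFS from the root accumulating genotypes
    stack = [tree.root]
    while stack:
        c = stack.pop()
        ci = clone_idx[c]
        p = tree.parent[c]
        if p is not None:
            mat[:, ci] = mat[:, clone_idx[p]]
        for g in tree.branch_genes[c]:
            mat[gene_idx[g], ci] = True
        stack.extend(children[c])
    return CloneGenotypeMatrix(genes, clones, mat)


def pair_relation(tree: ClonalTree, gene_j: str, gene_k: str) -> str:
    """Classify a gene pair as clonally exclusive or co-occurring in a tree.

    Exclusive iff no clone's genotype carries both genes; this covers the
    same-branch and ancestor/descendant cases as co-occurrence and tolerates
    genes assigned to multiple branches.
    """
    gm = clone_genotypes(tree)
    for g in (gene_j, gene_k):
        if g not in gm.genes:
            raise KeyError(f"gene {g!r} absent from tree "
                           f"{tree.patient_id}/{tree.tree_id}")
    both = gm.gene_row(gene_j) & gm.gene_row(gene_k)
    return EXCLUSIVE if not both.any() else CO_OCCURRING


def background_rate(tree: ClonalTree) -> float:
    """Fraction of unordered gene pairs that are clonally exclusive."""
    gm = clone_genotypes(tree)
    g = len(gm.genes)
    if g < 2:
        raise ValueError(f"tree {tree.patient_id}/{tree.tree_id} has fewer "
                         "than two genes; background rate undefined")
    co_carrier = (gm.matrix.astype(np.int32) @ gm.matrix.T.astype(np.int32)) > 0
    n_pairs = g * (g - 1) // 2
    n_co = int(np.triu(co_carrier, k=1).sum())
    return 1.0 - n_co / n_pairs


@dataclass(frozen=True, eq=False)
class PatientSample:
    """A patient's tree sample(s) plus derived summaries.

    r is the background exclusivity rate averaged over the patient's trees
    (trees with fewer than two genes are skipped); w = C(|genes|, 2) is the
    number of unordered gene pairs the patient possesses, used as the
    weighted-sampling weight of the occurrence test.
    """

    patient_id: str
    trees: tuple[ClonalTree, ...]
    genes: frozenset[str]
    r: float
    w: int

    @classmethod
    def from_trees(cls, patient_id: str,
                   trees: Sequence[ClonalTree]) -> "PatientSample":
        if not trees:
            raise ValueError(f"patient {patient_id!r} has no trees")
        for t in trees:
            if t.patient_id != patient_id:
                raise ValueError("trees must share patient_id")
        genes: set[str] = set()
        for t in trees:
            genes |= t.genes
        rates = [background_rate(t) for t in trees if len(t.genes) >= 2]
        r = float(np.mean(rates)) if rates else 0.0
        return cls(patient_id, tuple(trees), frozenset(genes), r,
                   comb(len(genes), 2))

    @property
    def is_informative(self) -> bool:
        return _RATE_TOL < self.r < 1.0 - _RATE_TOL


@dataclass(frozen=True, eq=False)
class GenePairObservation:
    """Cohort-level summary for one gene pair.

    n_t patients carry both genes in at least one tree; of these, n_l have
    purely linear topologies (r = 0), n_s purely star topologies (r = 1) and
    n = n_t - n_l - n_s are informative.  n_cx informative patients show the
    pair as clonally exclusive (posterior fractions binarised at 0.5), and
    m = n_cx + n_s is the exclusive count including star trees, used by the
    combined test.  ``rates``/``outcomes`` hold the informative patients'
    data for the placement test.
    """

    gene_j: str
    gene_k: str
    patients: tuple[str, ...]
    o_frac: tuple[float, ...]
    n_t: int
    n: int
    n_l: int
    n_s: int
    n_cx: int
    m: int
    informative_patients: tuple[str, ...]
    rates: np.ndarray
    outcomes: np.ndarray
    outcomes_frac: np.ndarray

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_j, self.gene_k)


def collect_pair(cohort: Sequence[PatientSample], gene_j: str, gene_k: str,
                 binarize_threshold: float = 0.5) -> GenePairObservation:
    """Collect per-patient exclusivity data for one gene pair over a cohort.

    For each patient, O is the fraction of trees containing both genes in
    which the pair is clonally exclusive (trees lacking one of the genes do
    not enter the denominator).  Patients are classified as linear/star/
    informative by their averaged background rate r.
    """
    pids: list[str] = []
    o_frac: list[float] = []
    n_l = n_s = n_cx = 0
    inf_pids: list[str] = []
    inf_rates: list[float] = []
    inf_out: list[float] = []
    inf_frac: list[float] = []
    for p in cohort:
        with_both = [t for t in p.trees
                     if gene_j in t.genes and gene_k in t.genes]
        if not with_both:
            continue
        o = float(np.mean([pair_relation(t, gene_j, gene_k) == EXCLUSIVE
                           for t in with_both]))
        pids.append(p.patient_id)
        o_frac.append(o)
        if p.r <= _RATE_TOL:
            n_l += 1
        elif p.r >= 1.0 - _RATE_TOL:
            n_s += 1
        else:
            outcome = 1.0 if o >= binarize_threshold else 0.0
            n_cx += int(outcome)
            inf_pids.append(p.patient_id)
            inf_rates.append(p.r)
            inf_out.append(outcome)
            inf_frac.append(o)
    n_t = len(pids)
    n = n_t - n_l - n_s
    return GenePairObservation(
        gene_j=gene_j, gene_k=gene_k, patients=tuple(pids),
        o_frac=tuple(o_frac), n_t=n_t, n=n, n_l=n_l, n_s=n_s, n_cx=n_cx,
        m=n_cx + n_s, informative_patients=tuple(inf_pids),
        rates=np.asarray(inf_rates, dtype=float),
        outcomes=np.asarray(inf_out, dtype=float),
        outcomes_frac=np.asarray(inf_frac, dtype=float))


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("patient_id", "tree_id", "clone_id", "parent_id", "genes")


def read_cohort(path, min_clone_freq: float = 0.0) -> list[PatientSample]:
    """Read a cohort from the clone-per-row TSV schema.

    Columns: patient_id, tree_id, clone_id, parent_id ('-' for the root),
    genes (semicolon-separated, empty allowed) and optionally freq.  Clones
    with frequency below ``min_clone_freq`` are merged into their parent
    (their branch genes re-attached) before any computation, so filtering
    never changes a tree's gene content.
    """
    groups: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or any(
                c not in reader.fieldnames for c in _REQUIRED_COLS):
            raise CohortParseError(
                f"header must contain columns {_REQUIRED_COLS}, "
                f"got {reader.fieldnames}")
        has_freq = "freq" in reader.fieldnames
        for ln, row in enumerate(reader, start=2):
            try:
                pid = row["patient_id"].strip()
                tid = row["tree_id"].strip()
                cid = row["clone_id"].strip()
                par = row["parent_id"].strip()
                genes = frozenset(g for g in row["genes"].split(";")
                                  if g.strip()) if row["genes"] else frozenset()
            except (KeyError, AttributeError) as exc:
                raise CohortParseError(f"line {ln}: malformed row") from exc
            if not pid or not tid or not cid:
                raise CohortParseError(f"line {ln}: empty identifier")
            key = (pid, tid)
            if key not in groups:
                groups[key] = {"parent": {}, "genes": {}, "freq": {}, "lines": {}}
                order.append(key)
            tree = groups[key]
            if cid in tree["parent"]:
                raise CohortParseError(f"line {ln}: duplicate clone {cid!r} "
                                       f"in tree {pid}/{tid}")
            tree["parent"][cid] = None if par == ROOT_SENTINEL else par
            tree["genes"][cid] = genes
            tree["lines"][cid] = ln
            if has_freq and row.get("freq", "").strip():
                try:
                    tree["freq"][cid] = float(row["freq"])
                except ValueError as exc:
                    raise CohortParseError(
                        f"line {ln}: invalid frequency {row['freq']!r}") from exc

    trees_by_patient: dict[str, list[ClonalTree]] = {}
    patient_order: list[str] = []
    for (pid, tid) in order:
        raw = groups[(pid, tid)]
        for cid, par in raw["parent"].items():
            if par is not None and par not in raw["parent"]:
                raise CohortParseError(
                    f"line {raw['lines'][cid]}: clone {cid!r} has unknown "
                    f"parent {par!r} in tree {pid}/{tid}")
        roots = [c for c, p in raw["parent"].items() if p is None]
        if len(roots) != 1:
            some = raw["lines"][roots[0]] if roots else min(raw["lines"].values())
            raise CohortParseError(f"line {some}: tree {pid}/{tid} has "
                                   f"{len(roots)} roots (expected 1)")
        for cid in raw["parent"]:
            seen = set()
            node = cid
            while node is not None:
                if node in seen:
                    raise CohortParseError(
                        f"line {raw['lines'][cid]}: cycle in parent mapping "
                        f"of tree {pid}/{tid}")
                seen.add(node)
                node = raw["parent"][node]
        freq = raw["freq"] if raw["freq"] else None
        tree = ClonalTree(pid, tid, dict(raw["parent"]), dict(raw["genes"]), freq)
        tree = _filter_clones(tree, min_clone_freq)
        if pid not in trees_by_patient:
            trees_by_patient[pid] = []
            patient_order.append(pid)
        trees_by_patient[pid].append(tree)
    return [PatientSample.from_trees(pid, trees_by_patient[pid])
            for pid in patient_order]


def _filter_clones(tree: ClonalTree, min_clone_freq: float) -> ClonalTree:
    """Merge clones below the frequency threshold into their parents.

    The removed clone's branch genes are re-attached to the parent and its
    frequency mass added there; its children are re-parented.  The root is
    never removed.  Clones without a recorded frequency are kept.
    """
    if min_clone_freq <= 0.0 or tree.clone_freq is None:
        return tree
    parent = dict(tree.parent)
    genes = {c: set(gs) for c, gs in tree.branch_genes.items()}
    freq = dict(tree.clone_freq)
    while True:
        low = sorted(c for c in parent
                     if parent[c] is not None
                     and c in freq and freq[c] < min_clone_freq)
        if not low:
            break
        c = low[0]
        p = parent[c]
        genes.setdefault(p, set()).update(genes.get(c, set()))
        if p in freq:
            freq[p] = freq.get(p, 0.0) + freq.pop(c)
        else:
            freq.pop(c)
        for other in list(parent):
            if parent[other] == c:
                parent[other] = p
        del parent[c]
        genes.pop(c, None)
    return ClonalTree(tree.patient_id, tree.tree_id, parent,
                      {c: frozenset(gs) for c, gs in genes.items()},
                      freq if freq else None)


def write_cohort(cohort: Iterable[PatientSample], path) -> None:
    """Write a cohort back to the clone-per-row TSV schema."""
    any_freq = any(t.clone_freq is not None
                   for p in cohort for t in p.trees)
    cols = list(_REQUIRED_COLS) + (["freq"] if any_freq else [])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for p in cohort:
            for t in p.trees:
                for cid in t.clones:
                    row = [t.patient_id, t.tree_id, cid,
                           t.parent[cid] if t.parent[cid] is not None else ROOT_SENTINEL,
                           ";".join(sorted(t.branch_genes[cid]))]
                    if any_freq:
                        f = (t.clone_freq or {}).get(cid)
                        row.append("" if f is None else f"{f:.6g}")
                    writer.writerow(row)


def read_pathway_map(path) -> dict[str, str]:
    """Read a two-column gene-to-pathway TSV mapping."""
    mapping: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "gene" not in reader.fieldnames \
                or "pathway" not in reader.fieldnames:
            raise CohortParseError("pathway map needs columns gene, pathway")
        for row in reader:
            mapping[row["gene"].strip()] = row["pathway"].strip()
    return mapping


def map_to_pathways(cohort: Sequence[PatientSample],
                    mapping: Mapping[str, str],
                    on_unmapped: str = "error") -> list[PatientSample]:
    """Relabel genes by pathway; duplicate pathway labels on one branch
    collapse to a single marker (set semantics).

    ``on_unmapped`` is either "error" (raise, listing the offending genes) or
    "drop" (remove unmapped genes; per-patient summaries are recomputed).
    """
    if on_unmapped not in ("error", "drop"):
        raise ValueError("on_unmapped must be 'error' or 'drop'")
    missing: set[str] = set()
    for p in cohort:
        missing |= p.genes - set(mapping)
    if missing and on_unmapped == "error":
        raise KeyError(f"genes without pathway mapping: {sorted(missing)}")
    out: list[PatientSample] = []
    for p in cohort:
        new_trees = []
        for t in p.trees:
            bg = {c: frozenset(mapping[g] for g in gs if g in mapping)
                  for c, gs in t.branch_genes.items()}
            new_trees.append(ClonalTree(t.patient_id, t.tree_id,
                                        dict(t.parent), bg, t.clone_freq))
        out.append(PatientSample.from_trees(p.patient_id, new_trees))
    return out


def all_pairs(genes: Iterable[str]):
    """Unordered gene pairs in sorted order."""
    return combinations(sorted(genes), 2)
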