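import math

import numpy as np
import pytest
from helpers import (brute_background_rate, brute_genotype, cherry_tree,
                     linear_tree, random_tree, star_tree)

from clonex.trees import (CO_OCCURRING, EXCLUSIVE, ClonalTree,
                          CohortParseError, PatientSample, background_rate,
                          clone_genotypes, collect_pair, map_to_pathways,
                          pair_relation, read_cohort, write_cohort)


class TestCloneGenotypes:
    def test_linear_inheritance(self):
        gm = clone_genotypes(linear_tree("p", ["A", "B"]))
        assert gm.carries("A", "c1") and gm.carries("B", "c1")
        assert gm.carries("A", "c0") and not gm.carries("B", "c0")

    def test_star_no_shared_clone(self):
        gm = clone_genotypes(star_tree("p", ["A", "B", "C"]))
        assert gm.matrix.sum() == 3  # each gene in exactly one clone

    def test_multi_gene_branch_inherits_root(self):
        # clone c2 inherits the root gene and carries its own two genes
        t = cherry_tree("p", ["A"], ["B"], ["D", "H"])
        gm = clone_genotypes(t)
        assert {g for g in gm.genes if gm.carries(g, "c2")} == {"A", "D", "H"}

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_along_lineages(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tree(rng, int(rng.integers(2, 9)),
                        [f"g{i}" for i in range(int(rng.integers(2, 10)))])
        for c in t.clones:
            p = t.parent[c]
            if p is not None:
                assert brute_genotype(t, p) <= brute_genotype(t, c)


class TestPairRelation:
    def test_same_branch_cooccurs(self):
        t = cherry_tree("p", [], ["A", "B"], ["C"])
        assert pair_relation(t, "A", "B") == CO_OCCURRING

    def test_ancestor_descendant_cooccurs(self):
        t = linear_tree("p", ["A", "B"])
        assert pair_relation(t, "A", "B") == CO_OCCURRING

    def test_siblings_exclusive(self):
        t = cherry_tree("p", ["C"], ["A"], ["B"])
        assert pair_relation(t, "A", "B") == EXCLUSIVE

    def test_absent_gene_raises(self):
        with pytest.raises(KeyError):
            pair_relation(linear_tree("p", ["A", "B"]), "A", "Z")

    def test_parallel_evolution_tolerated(self):
        # same gene on two sibling branches: pair with either neighbour
        t = ClonalTree("p", "t0", {"c0": None, "c1": "c0", "c2": "c0"},
                       {"c0": frozenset(), "c1": frozenset({"A", "B"}),
                        "c2": frozenset({"A"})})
        assert pair_relation(t, "A", "B") == CO_OCCURRING


class TestBackgroundRate:
    def test_linear_zero(self):
        assert background_rate(linear_tree("p", list("ABCD"))) == 0.0

    def test_star_one(self):
        assert background_rate(star_tree("p", list("ABC"))) == 1.0

    def test_cherry_one_third(self):
        assert background_rate(cherry_tree("p", ["C"], ["A"], ["B"])) \
            == pytest.approx(1 / 3)

    def test_single_gene_raises(self):
        with pytest.raises(ValueError):
            background_rate(linear_tree("p", ["A"]))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = random_tree(rng, int(rng.integers(2, 9)),
                        [f"g{i}" for i in range(int(rng.integers(2, 12)))])
        assert background_rate(t) == pytest.approx(brute_background_rate(t))


class TestPatientSample:
    def test_weight_is_pair_count(self):
        p = PatientSample.from_trees("p", [linear_tree("p", list("ABCD"))])
        assert p.w == math.comb(4, 2)
        assert p.r == 0.0 and not p.is_informative

    def test_rate_averaged_over_trees(self):
        trees = [linear_tree("p", ["A", "B"], "t0"),
                 star_tree("p", ["A", "B"], "t1")]
        p = PatientSample.from_trees("p", trees)
        assert p.r == pytest.approx(0.5)
        assert p.is_informative


class TestCollectPair:
    def test_published_count_shape(self, mixed_cohort):
        obs = collect_pair(mixed_cohort, "FLT3", "NRAS")
        assert (obs.n_t, obs.n, obs.n_cx, obs.n_l, obs.n_s) == (15, 8, 7, 3, 4)
        assert obs.n_t == obs.n + obs.n_l + obs.n_s
        assert obs.m == obs.n_cx + obs.n_s == 11
        assert 0 <= obs.n_cx <= obs.n and 0 <= obs.m <= obs.n_t

    def test_absent_pair_all_zero(self, mixed_cohort):
        obs = collect_pair(mixed_cohort, "FLT3", "ZZZ")
        assert obs.n_t == obs.n == obs.n_l == obs.n_s == obs.m == 0

    def test_posterior_fraction(self):
        trees = [cherry_tree("p", [], ["A", "B"], ["C"], "t0"),   # co-occ
                 cherry_tree("p", [], ["A"], ["B", "C"], "t1")]   # exclusive
        cohort = [PatientSample.from_trees("p", trees)]
        obs = collect_pair(cohort, "A", "B")
        assert obs.o_frac == (0.5,)

    def test_denominator_counts_trees_with_both_genes(self):
        # second tree lacks gene B, so it does not dilute O
        trees = [cherry_tree("p", [], ["A"], ["B"], "t0"),
                 cherry_tree("p", [], ["A"], ["C"], "t1")]
        cohort = [PatientSample.from_trees("p", trees)]
        obs = collect_pair(cohort, "A", "B")
        assert obs.o_frac == (1.0,)


COHORT_TSV = """patient_id\ttree_id\tclone_id\tparent_id\tgenes\tfreq
P1\tt0\tc0\t-\tTP53\t0.5
P1\tt0\tc1\tc0\tKRAS;NRAS\t0.5
P2\tt0\tc0\t-\t\t0.4
P2\tt0\tc1\tc0\tFLT3\t0.3
P2\tt0\tc2\tc0\tNPM1\t0.3
"""


class TestReadCohort:
    def test_toy_roundtrip(self, tmp_path):
        path = tmp_path / "cohort.tsv"
        path.write_text(COHORT_TSV)
        cohort = read_cohort(path)
        assert len(cohort) == 2
        by_id = {p.patient_id: p for p in cohort}
        assert by_id["P1"].genes == {"TP53", "KRAS", "NRAS"}
        assert by_id["P2"].genes == {"FLT3", "NPM1"}
        out = tmp_path / "again.tsv"
        write_cohort(cohort, out)
        cohort2 = read_cohort(out)
        assert {p.patient_id: p.genes for p in cohort2} == \
            {p.patient_id: p.genes for p in cohort}

    def test_low_frequency_clone_merged_into_parent(self, tmp_path):
        rows = ["patient_id\ttree_id\tclone_id\tparent_id\tgenes\tfreq",
                "P\tt0\tc0\t-\tA\t0.6",
                "P\tt0\tc1\tc0\tB\t0.395",
                "P\tt0\tc2\tc1\tC\t0.005"]
        path = tmp_path / "c.tsv"
        path.write_text("\n".join(rows) + "\n")
        (p,) = read_cohort(path, min_clone_freq=0.01)
        tree = p.trees[0]
        assert set(tree.clones) == {"c0", "c1"}
        assert p.genes == {"A", "B", "C"}  # filtering preserves gene content
        # gene C re-attached to c1: genotype of c1 now carries A, B, C
        assert brute_genotype(tree, "c1") == {"A", "B", "C"}

    def test_cycle_raises_with_line(self, tmp_path):
        rows = ["patient_id\ttree_id\tclone_id\tparent_id\tgenes",
                "P\tt0\tc0\t-\tA",
                "P\tt0\tc1\tc2\tB",
                "P\tt0\tc2\tc1\tC"]
        path = tmp_path / "c.tsv"
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(CohortParseError, match="line"):
            read_cohort(path)

    def test_unknown_parent_raises(self, tmp_path):
        rows = ["patient_id\ttree_id\tclone_id\tparent_id\tgenes",
                "P\tt0\tc0\t-\tA",
                "P\tt0\tc1\tc9\tB"]
        path = tmp_path / "c.tsv"
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(CohortParseError, match="unknown parent"):
            read_cohort(path)

    def test_two_roots_raise(self, tmp_path):
        rows = ["patient_id\ttree_id\tclone_id\tparent_id\tgenes",
                "P\tt0\tc0\t-\tA",
                "P\tt0\tc1\t-\tB"]
        path = tmp_path / "c.tsv"
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(CohortParseError, match="roots"):
            read_cohort(path)


class TestMapToPathways:
    def test_same_branch_collapse(self):
        t = cherry_tree("p", ["TP53"], ["KRAS", "NRAS"], ["FLT3"])
        cohort = [PatientSample.from_trees("p", [t])]
        mapping = {"KRAS": "RAS", "NRAS": "RAS", "TP53": "TP53", "FLT3": "RTK"}
        (mapped,) = map_to_pathways(cohort, mapping)
        assert mapped.genes == {"RAS", "TP53", "RTK"}
        assert mapped.trees[0].branch_genes["c1"] == {"RAS"}

    def test_identity_mapping_is_noop(self):
        t = cherry_tree("p", ["A"], ["B"], ["C"])
        cohort = [PatientSample.from_trees("p", [t])]
        (mapped,) = map_to_pathways(cohort, {g: g for g in "ABC"})
        assert mapped.genes == cohort[0].genes
        assert mapped.r == cohort[0].r and mapped.w == cohort[0].w

    def test_unmapped_gene_errors_or_drops(self):
        t = cherry_tree("p", ["A"], ["B"], ["C"])
        cohort = [PatientSample.from_trees("p", [t])]
        with pytest.raises(KeyError, match="C"):
            map_to_pathways(cohort, {"A": "pA", "B": "pB"})
        (dropped,) = map_to_pathways(cohort, {"A": "pA", "B": "pB"},
                                     on_unmapped="drop")
        assert dropped.genes == {"pA", "pB"}
        assert dropped.w == 1  # pair count recomputed
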