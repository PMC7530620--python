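"""Distances, neighbor joining, bootstrap supports, and split comparison."""

import numpy as np
import pytest

from ohnoscope import (
    DataError,
    DistanceMatrix,
    DistanceParams,
    bootstrap_support,
    distance_matrix,
    nj_tree,
    pairwise_distance,
    partition_trees,
    read_newick,
    split_distance,
)
from ohnoscope.phylo import supports


class TestDistances:
    @pytest.mark.parametrize("model", ["p", "poisson", "gamma"])
    def test_identical_sequences_are_distance_zero(self, model):
        s = "ACDEFGHIKL" * 10
        assert pairwise_distance(s, s, DistanceParams(model=model)) == 0.0

    def test_gamma_closed_form(self):
        # p = 0.25, alpha = 0.77
        a = "A" * 75 + "C" * 25
        b = "A" * 75 + "G" * 25
        expect = 0.77 * (0.75 ** (-1 / 0.77) - 1)
        got = pairwise_distance(a, b, DistanceParams(model="gamma", alpha=0.77))
        assert got == pytest.approx(expect, abs=1e-12)
        assert got == pytest.approx(0.3488, abs=5e-4)

    def test_pairwise_deletion_excludes_gapped_sites(self):
        assert pairwise_distance("A-AA", "AAAA", DistanceParams(model="p")) == 0.0

    def test_all_gap_overlap_rejected(self):
        with pytest.raises(DataError, match="comparable"):
            pairwise_distance("A--", "-AA")

    def test_saturation_guard(self):
        with pytest.raises(DataError, match="saturated"):
            pairwise_distance("A" * 4 + "C" * 96, "A" * 100,
                              DistanceParams(model="gamma"))

    def test_correction_ordering_on_p_grid(self):
        # gamma(0.77) >= poisson >= p for p in (0, 0.95)
        for p100 in range(1, 95):
            n = p100
            a = "A" * 100
            b = "C" * n + "A" * (100 - n)
            d_p = pairwise_distance(a, b, DistanceParams(model="p"))
            d_poi = pairwise_distance(a, b, DistanceParams(model="poisson"))
            d_gam = pairwise_distance(a, b, DistanceParams(model="gamma"))
            assert d_gam >= d_poi >= d_p

    def test_coverage_filter_drops_gappy_columns(self):
        seqs = {f"t{i}": ("AC" if i else "A-") + "DDDD" for i in range(25)}
        dm = distance_matrix(seqs, DistanceParams(model="p",
                                                  deletion="coverage95"))
        # gappy column 2 removed for everyone -> all identical
        assert np.all(dm.matrix == 0)


def _random_additive(n, rng):
    items = [f"T{i}:{rng.uniform(0.1, 1.0):.6f}" for i in range(n)]
    while len(items) > 2:
        a = items.pop(int(rng.integers(len(items))))
        b = items.pop(int(rng.integers(len(items))))
        items.append(f"({a},{b}):{rng.uniform(0.1, 1.0):.6f}")
    tree = read_newick(f"({items[0]},{items[1]});")
    labels = sorted(tree.leaf_labels)
    D = np.zeros((n, n))
    pdm = tree.tree.phylogenetic_distance_matrix()
    tn = tree.tree.taxon_namespace
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                D[i, j] = D[j, i] = pdm.patristic_distance(
                    tn.get_taxon(a), tn.get_taxon(b)
                )
    return tree, DistanceMatrix(labels, D)


class TestNeighborJoining:
    def test_two_taxa_edge_length(self):
        dm = DistanceMatrix(["X", "Y"], np.array([[0.0, 3.5], [3.5, 0.0]]))
        t = nj_tree(dm)
        assert t.path_distance("X", "Y") == pytest.approx(3.5)

    def test_three_point_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        t = nj_tree(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in t.tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_recovers_additive_six_taxon_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            true_tree, dm = _random_additive(6, rng)
            est = nj_tree(dm)
            assert est.bipartitions() == true_tree.bipartitions()
            pdm = est.tree.phylogenetic_distance_matrix()
            tn = est.tree.taxon_namespace
            for i, a in enumerate(dm.labels):
                for j, b in enumerate(dm.labels):
                    if i < j:
                        d = pdm.patristic_distance(tn.get_taxon(a),
                                                   tn.get_taxon(b))
                        assert d == pytest.approx(dm.matrix[i, j], abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(DataError, match="symmetric"):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestBootstrap:
    def test_same_seed_same_supports(self, conversion_result):
        r = conversion_result
        aln = {
            g.gene_id: r.proteome[g.gene_id]
            for tbl in r.gene_tables.values()
            for g in tbl
            if g.family_id == "MRF"
        }
        t1 = bootstrap_support(aln, n_replicates=50, seed=5)
        t2 = bootstrap_support(aln, n_replicates=50, seed=5)
        assert supports(t1) == supports(t2)
        assert all(0 <= v <= 100 for v in supports(t1).values())

    def test_fully_congruent_split_supported_100(self):
        # two column patterns only: constant, and one supporting AB|CD
        aln = {
            "A": "A" * 400 + "C" * 100,
            "B": "A" * 400 + "C" * 100,
            "C": "A" * 400 + "G" * 100,
            "D": "A" * 400 + "G" * 100,
        }
        t = bootstrap_support(aln, n_replicates=100,
                              params=DistanceParams(model="p"), seed=2)
        assert supports(t) == {frozenset({"C", "D"}): 100.0}

    def test_fewer_than_four_taxa_has_no_supports(self):
        aln = {"A": "ACDE" * 20, "B": "ACDF" * 20, "C": "ACEF" * 20}
        t = bootstrap_support(aln, n_replicates=20,
                              params=DistanceParams(model="p"), seed=1)
        assert supports(t) == {}

    def test_supports_invariant_to_leaf_order(self):
        rng = np.random.default_rng(3)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        template = rng.choice(list(aas), 80)
        base = {}
        for i in range(5):
            s = template.copy()
            pos = rng.choice(80, size=12, replace=False)
            s[pos] = rng.choice(list(aas), 12)
            base[f"t{i}"] = "".join(s)
        shuffled = {k: base[k] for k in reversed(list(base))}
        p = DistanceParams(model="p")
        assert supports(bootstrap_support(base, 50, p, seed=4)) == supports(
            bootstrap_support(shuffled, 50, p, seed=4)
        )


class TestPartitions:
    def test_single_full_partition_matches_whole_alignment(self, conversion_result):
        r = conversion_result
        aln = {
            g.gene_id: r.proteome[g.gene_id]
            for tbl in r.gene_tables.values()
            for g in tbl
            if g.family_id == "MRF"
        }
        L = len(next(iter(aln.values())))
        (t_part,) = partition_trees(aln, [(0, L)], n_replicates=20, seed=1)
        t_whole = bootstrap_support(aln, n_replicates=20, seed=1)
        assert t_part.bipartitions() == t_whole.bipartitions()

    def test_empty_or_overlapping_ranges_rejected(self):
        aln = {"A": "ACDE" * 20, "B": "ACDF" * 20}
        with pytest.raises(DataError):
            partition_trees(aln, [(10, 10)])
        with pytest.raises(DataError, match="disjoint"):
            partition_trees(aln, [(0, 40), (30, 60)])

    def test_conversion_preset_discordance(self, conversion_result):
        """First-exon conversion pairs paralogs by species; the rest of the
        protein keeps each gene monophyletic."""
        r = conversion_result
        aln = {
            g.gene_id: r.proteome[g.gene_id]
            for tbl in r.gene_tables.values()
            for g in tbl
            if g.family_id == "MRF"
        }
        exon1, exon23 = partition_trees(aln, [(0, 60), (60, 200)],
                                        n_replicates=100, seed=1)
        species = ["Bfloridae", "Blanceolatum", "Bbelcheri"]
        for sp in species:
            assert exon1.has_split({f"{sp}_MRF2a", f"{sp}_MRF2b"})
        for gene in ["MRF1", "MRF2a", "MRF2b", "MRF3", "MRF4"]:
            assert exon23.has_split({f"{sp}_{gene}" for sp in species})
        assert split_distance(exon1, exon23) > 0
        # two-gene split strongly supported away from the converted exon
        sup = supports(exon23)
        leaves = frozenset(aln)
        clade = frozenset({f"{sp}_MRF2a" for sp in species})
        if min(leaves) in clade:
            clade = leaves - clade
        assert sup.get(clade, 0) >= 95


class TestSplitDistance:
    def test_identical_trees(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert split_distance(t, read_newick(t.to_newick())) == 0

    def test_four_taxon_swap(self):
        a = read_newick("((A,B),(C,D));")
        b = read_newick("((A,C),(B,D));")
        assert split_distance(a, b) == 2

    def test_symmetric_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            ta, _ = _random_additive(7, rng)
            tb, _ = _random_additive(7, rng)
            assert split_distance(ta, tb) == split_distance(tb, ta)

    def test_leaf_set_mismatch_rejected(self):
        a = read_newick("((A,B),(C,D));")
        b = read_newick("((A,B),(C,E));")
        with pytest.raises(DataError):
            split_distance(a, b)
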