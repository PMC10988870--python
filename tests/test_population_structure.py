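"""F_ST distances, neighbor joining, PCA, LD decay."""

import numpy as np
import pandas as pd
import pytest

import ovisweep as ov
from ovisweep.genotype_io import from_haplotypes
from ovisweep.population_structure import (DistanceMatrix, ld_decay, nj_tree,
                                           pairwise_fst_matrix, pca)


def bn_dataset(seed, F=0.1, n=50, m=2000):
    cfg = ov.SimulationConfig(mode="balding_nichols", seed=seed,
                              n_diploids=n, n_sites=m, F=F)
    return ov.simulate_balding_nichols(cfg)


class TestPairwiseFst:
    def test_identical_populations_zero(self):
        g, assign, _ = bn_dataset(1, n=20, m=500)
        # duplicate pop1's genotypes as a third population
        import copy
        rows = [g.samples.index(s) for s in assign.samples_of("pop1")]
        g2 = ov.GenotypeMatrix(
            sites=list(g.sites),
            samples=list(g.samples) + [f"dup_{i}" for i in range(len(rows))],
            dosage=np.vstack([g.dosage, g.dosage[rows]]),
            alleles=np.vstack([g.alleles, g.alleles[rows]]),
            phased=np.vstack([g.phased, g.phased[rows]]))
        a = ov.PopulationAssignment(
            {**assign.assignment,
             **{f"dup_{i}": "dup" for i in range(len(rows))}})
        dm = pairwise_fst_matrix(g2, a)
        i, j = dm.labels.index("pop1"), dm.labels.index("dup")
        assert dm.values[i, j] == 0.0  # <= 0 before clamping

    def test_fixed_differences_give_one(self):
        from conftest import matrix_from_dosage

        n = 10
        dosage = np.vstack([np.full((n, 50), 2), np.zeros((n, 50))])
        g = matrix_from_dosage(dosage)
        a = ov.PopulationAssignment(
            {f"s{i}": ("p1" if i < n else "p2") for i in range(2 * n)})
        dm = pairwise_fst_matrix(g, a)
        assert dm.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_parameter_recovery(self):
        g, assign, _ = bn_dataset(11, F=0.1)
        dm = pairwise_fst_matrix(g, assign)
        assert 0.08 <= dm.values[0, 1] <= 0.12

    def test_label_permutation_equivariance(self):
        g, assign, _ = bn_dataset(3, n=20, m=400)
        swapped = ov.PopulationAssignment(
            {s: {"pop1": "b", "pop2": "a"}[p]
             for s, p in assign.assignment.items()})
        dm1 = pairwise_fst_matrix(g, assign)
        dm2 = pairwise_fst_matrix(g, swapped)
        assert dm1.values[0, 1] == pytest.approx(dm2.values[0, 1])

    def test_small_population_rejected(self):
        g, assign, _ = bn_dataset(4, n=10, m=100)
        a = ov.PopulationAssignment(
            {s: ("solo" if i == 0 else p)
             for i, (s, p) in enumerate(assign.assignment.items())})
        with pytest.raises(ValueError, match="< 2 samples"):
            pairwise_fst_matrix(g, a)


class TestNjTree:
    def test_three_point_formulas(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0.0]]))
        tree = nj_tree(dm)
        d = tree.leaf_path_lengths()
        lengths = dict(zip((c.label for c, _ in tree.children),
                           (ln for _, ln in tree.children)))
        assert lengths == pytest.approx({"A": 0.0, "B": 2.0, "C": 4.0})
        assert d.loc["A", "B"] == pytest.approx(2.0)

    def test_additive_four_taxon_topology_and_lengths(self):
        labels = ["A", "B", "C", "D"]
        m = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 3],
                      [6, 7, 3, 0.0]])
        tree = nj_tree(DistanceMatrix(labels, m))
        d = tree.leaf_path_lengths()
        assert np.allclose(d.loc[labels, labels].to_numpy(), m, atol=1e-12)
        nwk = tree.newick()
        assert ("(A:1,B:2)" in nwk) or ("(B:2,A:1)" in nwk)

    def test_path_lengths_recover_additive_matrix(self, rng):
        """On any additive (tree-generated) matrix, NJ reproduces all
        pairwise path lengths to machine precision."""
        for _ in range(10):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            # random additive matrix from a random binary tree: leaves
            # carry their distances to every taxon below them; joining
            # two subtrees with fresh positive edges fixes all
            # cross-subtree distances
            m = np.zeros((n, n))
            clusters = [[i] for i in range(n)]
            depth = {i: 0.0 for i in range(n)}  # taxon -> dist to its root
            while len(clusters) > 1:
                i, j = sorted(rng.choice(len(clusters), 2, replace=False))
                e1, e2 = rng.uniform(0.1, 2.0, size=2)
                for a in clusters[i]:
                    for b in clusters[j]:
                        m[a, b] = m[b, a] = depth[a] + e1 + depth[b] + e2
                for a in clusters[i]:
                    depth[a] += e1
                for b in clusters[j]:
                    depth[b] += e2
                clusters[i] = clusters[i] + clusters[j]
                del clusters[j]
            tree = nj_tree(DistanceMatrix(labels, m))
            d = tree.leaf_path_lengths().loc[labels, labels].to_numpy()
            assert np.allclose(d, m, atol=1e-9)

    def test_cross_check_against_skbio(self):
        """Independent NJ implementation (scikit-bio) recovers the same
        pairwise path lengths on an additive matrix."""
        import skbio

        labels = ["A", "B", "C", "D"]
        m = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 3],
                      [6, 7, 3, 0.0]])
        sk = skbio.tree.nj(skbio.DistanceMatrix(m, labels))
        mine = nj_tree(DistanceMatrix(labels, m)).leaf_path_lengths()
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert mine.loc[a, b] == pytest.approx(
                    sk.find(a).distance(sk.find(b)), abs=1e-9)

    def test_rejects_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.0]])))


class TestPca:
    def test_duplicated_patterns_separate_on_pc1(self, rng):
        from conftest import matrix_from_dosage

        base1 = rng.integers(0, 3, size=60)
        base2 = rng.integers(0, 3, size=60)
        dosage = np.vstack([np.tile(base1, (5, 1)),
                            np.tile(base2, (5, 1))])
        g = matrix_from_dosage(dosage)
        res = pca(g, k=3)
        pc1 = res.coords[:, 0]
        assert np.std(pc1[:5]) == pytest.approx(0.0, abs=1e-9)
        assert np.std(pc1[5:]) == pytest.approx(0.0, abs=1e-9)
        assert abs(pc1[0] - pc1[5]) > 1e-6

    def test_site_order_invariance(self, rng):
        g, _, _ = bn_dataset(5, n=15, m=300)
        perm = rng.permutation(g.n_sites)
        # permuting sites breaks position ordering; rebuild positions
        g2 = ov.GenotypeMatrix(
            sites=[ov.VariantSite("1", j + 1, None, "A", ("T",))
                   for j in range(g.n_sites)],
            samples=list(g.samples),
            dosage=g.dosage[:, perm], alleles=g.alleles[:, perm],
            phased=g.phased[:, perm])
        r1 = pca(g, k=2)
        r2 = pca(g2, k=2)
        assert np.allclose(np.abs(r1.coords), np.abs(r2.coords), atol=1e-8)

    def test_components_diagonalize_covariance(self):
        g, _, _ = bn_dataset(6, n=25, m=800)
        res = pca(g, k=5)
        gram = res.coords.T @ res.coords
        assert np.allclose(gram, np.diag(res.eigenvalues), atol=1e-8)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_separates_bn_populations(self):
        for seed in range(10):
            g, assign, _ = bn_dataset(100 + seed, F=0.1)
            res = pca(g, k=2)
            pc1 = res.coords[:, 0]
            a = pc1[:50]
            b = pc1[50:]
            assert max(a.min(), b.min()) > min(a.max(), b.max()) \
                or a.max() < b.min() or b.max() < a.min()

    def test_k_too_large_rejected(self):
        g, _, _ = bn_dataset(7, n=5, m=50)
        with pytest.raises(ValueError):
            pca(g, k=11)


class TestLdDecay:
    def _haplo(self, seed, recomb):
        cfg = ov.SimulationConfig(mode="forward_wf", seed=seed,
                                  n_diploids=50, chrom_length=1_000_000,
                                  mu_per_hap=0.5, recomb_rate=recomb,
                                  burnin=150, split_time=10, sample_size=20)
        return ov.simulate_forward_two_pop(cfg)

    def test_curve_structure_and_pair_conservation(self):
        h, assign, _ = self._haplo(1, 1e-6)
        curves = ld_decay(h, assign, max_dist=200_000, bin_width=5_000)
        for pop, c in curves.items():
            ok = c.n_pairs > 0
            assert ((c.mean_r2[ok] >= 0) & (c.mean_r2[ok] <= 1)).all()
            # conservation: total pairs = eligible defined pairs
            rows = h.sample_haplotype_rows(assign.samples_of(pop))
            hap = h.haplotypes[rows]
            pos = h.positions
            k = hap.sum(axis=0)
            poly = (k > 0) & (k < len(rows))
            iu, ju = np.triu_indices(h.n_sites, k=1)
            eligible = ((pos[ju] - pos[iu]) <= 200_000) \
                & poly[iu] & poly[ju]
            assert c.n_pairs.sum() == eligible.sum()

    def test_more_recombination_shortens_half_decay(self):
        wins = 0
        for seed in range(5):
            h1, a1, _ = self._haplo(20 + seed, 2e-7)
            h2, a2, _ = self._haplo(20 + seed, 2e-6)
            d1 = ld_decay(h1, a1, max_dist=300_000, bin_width=2_000)
            d2 = ld_decay(h2, a2, max_dist=300_000, bin_width=2_000)
            hd1 = d1["pop1"].half_decay_distance
            hd2 = d2["pop1"].half_decay_distance
            if hd2 < hd1:
                wins += 1
        assert wins == 5

    def test_two_sites_single_pair(self):
        sites = [ov.VariantSite("1", 100, None, "A", ("T",)),
                 ov.VariantSite("1", 1600, None, "C", ("G",))]
        hap = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=np.uint8)
        h = ov.HaplotypeMatrix(sites=sites, samples=["x", "y"],
                               haplotypes=hap)
        a = ov.PopulationAssignment({"x": "p", "y": "p"})
        curves = ld_decay(h, a, max_dist=10_000, bin_width=1_000)
        assert curves["p"].n_pairs.sum() == 1

    def test_too_few_haplotypes_rejected(self):
        sites = [ov.VariantSite("1", 100, None, "A", ("T",))]
        h = ov.HaplotypeMatrix(sites=sites, samples=["x"],
                               haplotypes=np.array([[0], [1]],
                                                   dtype=np.uint8))
        a = ov.PopulationAssignment({"x": "p"})
        with pytest.raises(ValueError, match="< 4 haplotypes"):
            ld_decay(h, a)
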