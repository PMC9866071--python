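import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skbio import TreeNode

from clonalsig.genio import HaplotypeSet
from clonalsig.sexsignal import (HaploSplit, incompatibility_matrix,
                                 hamming_matrix, meselson_test, nj_tree,
                                 normalized_rf, phi_test, split_haplotypes,
                                 _perm_moments)

import oracles


def hapset(haps, samples=None):
    haps = np.asarray(haps, dtype=np.uint8)
    n, _, S = haps.shape
    sites = pd.DataFrame({"contig": "c1", "pos": np.arange(1, S + 1),
                          "ref": "A", "alt": "T"})
    return HaplotypeSet(samples=samples or [f"s{i}" for i in range(n)],
                        sites=sites, haps=haps)


class TestSplitHaplotypes:
    def test_reference_identical_haplotype_is_A(self):
        hap = hapset([[[0, 0, 0, 0, 0], [1, 1, 1, 1, 1]]])
        sp = split_haplotypes(hap)
        assert sp.table["dist_a"].iloc[0] == 0
        assert sp.table["dist_b"].iloc[0] == 5
        assert np.array_equal(sp.A[0], np.zeros(5))

    def test_tie_goes_to_first_haplotype(self):
        hap = hapset([[[1, 0], [0, 1]]])
        sp = split_haplotypes(hap)
        assert sp.table["a_is_hap0"].iloc[0]
        assert np.array_equal(sp.A[0], [1, 0])

    @given(st.integers(0, 2 ** 31 - 1))
    def test_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, size=(5, 2, 12)).astype(np.uint8)
        hap = hapset(haps)
        swapped = hapset(haps[:, ::-1, :])
        a, b = split_haplotypes(hap), split_haplotypes(swapped)
        # labels may flip on exact ties, but the A/B sets are unchanged
        ties = haps.sum(axis=2)[:, 0] == haps.sum(axis=2)[:, 1]
        assert np.array_equal(a.A[~ties], b.A[~ties])
        assert np.array_equal(a.B[~ties], b.B[~ties])

    def test_hybrid_fixture_matches_founder_pool_truth(self):
        """In a hybrid-origin founding generation, haplotype A labels agree
        with the founder pool closer to the reference."""
        from clonalsig.synthpop import SimConfig, simulate
        cfg = SimConfig(seed=4, founder_mode="hybrid", clonality=1.0,
                        generations=0, n_groups=1, pops_per_group=(1,),
                        individuals_per_pop=12, genome_length=100_000,
                        n_contigs=4, founder_diversity=0.001,
                        founder_divergence=0.004, cds_fraction=0)
        _, hap, _, _, truth = simulate(cfg)
        sp = split_haplotypes(hap)
        # pool B carries the alternate allele at every divergence site, so
        # pool A is reference-proximal
        agree = 0
        for i, s in enumerate(hap.samples):
            k = 0 if sp.table["a_is_hap0"].iloc[i] else 1
            agree += truth.founder_pool_of_haplotype[f"{s}_{k}"] == "A"
        assert agree >= 11  # at most one tie-induced disagreement


class TestNjTree:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float)
        t = nj_tree(D, ids=list("abc"))
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(4.0)

    def test_additive_four_taxon_recovers_topology(self):
        # tree ((a,b),(c,d)) with internal branch 2
        D = np.array([[0, 2, 7, 7], [2, 0, 7, 7],
                      [7, 7, 0, 2], [7, 7, 2, 0]], dtype=float)
        t = nj_tree(D, ids=list("abcd"))
        oracle = TreeNode.read([oracles.nj_textbook(D, list("abcd"))])
        assert normalized_rf(t, oracle) == 0.0

    def test_matches_independent_textbook_nj_on_random_matrix(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, size=(8, 30))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        ids = list("abcdefgh")
        t = nj_tree(D, ids=ids)
        oracle = TreeNode.read([oracles.nj_textbook(D, ids)])
        assert normalized_rf(t, oracle) == 0.0

    def test_nonfinite_distances_fail(self):
        with pytest.raises(ValueError, match="finite"):
            nj_tree(np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]]),
                    ids=list("abc"))


class TestRfDistance:
    def trees(self):
        rng = np.random.default_rng(2)
        out = []
        for _ in range(4):
            X = rng.uniform(size=(6, 10))
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            out.append(nj_tree(D, ids=list("abcdef")))
        return out

    def test_metric_properties(self):
        ts = self.trees()
        for t in ts:
            assert normalized_rf(t, t) == 0.0
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                dij = normalized_rf(ts[i], ts[j])
                assert dij == normalized_rf(ts[j], ts[i])
                assert 0.0 <= dij <= 1.0
        for i, j, k in [(0, 1, 2), (1, 2, 3), (0, 2, 3)]:
            assert (normalized_rf(ts[i], ts[k]) <=
                    normalized_rf(ts[i], ts[j]) +
                    normalized_rf(ts[j], ts[k]) + 1e-12)


class TestMeselson:
    def test_relabelled_copy_is_mirrored(self):
        rng = np.random.default_rng(0)
        A = rng.integers(0, 2, size=(6, 40)).astype(np.uint8)
        sp = HaploSplit(samples=[f"s{i}" for i in range(6)], A=A, B=A.copy(),
                        table=pd.DataFrame())
        pair = meselson_test(sp)
        assert pair.rf_normalized == 0.0 and pair.mirrored

    def test_fewer_than_four_leaves_errors(self):
        A = np.zeros((3, 5), dtype=np.uint8)
        sp = HaploSplit(samples=list("abc"), A=A, B=A, table=pd.DataFrame())
        with pytest.raises(ValueError, match="4"):
            meselson_test(sp)


class TestPhi:
    def tree_like_alignment(self):
        # nested clades: sites fully compatible with one genealogy
        n = 8
        aln = np.zeros((n, 12), dtype=np.uint8)
        clades = [range(0, 4), range(4, 8), range(0, 2), range(2, 4),
                  range(4, 6), range(6, 8)]
        for j, cl in enumerate(clades * 2):
            aln[list(cl), j] = 1
        return aln

    def test_single_genealogy_gives_zero_phi_p_one(self):
        res = phi_test(self.tree_like_alignment(), window=10, n_perm=50)
        assert res.phi == 0.0
        assert res.p_permutation == 1.0
        assert res.p_normal == 1.0

    def test_four_gamete_pair_is_incompatible(self):
        aln = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 2, dtype=np.uint8)
        X = incompatibility_matrix(aln)
        assert X[0, 1] == 1.0
        aln2 = np.array([[0, 0], [0, 1], [1, 1], [1, 1]] * 2, dtype=np.uint8)
        assert incompatibility_matrix(aln2)[0, 1] == 0.0

    def test_too_few_informative_sites_flagged(self):
        aln = np.zeros((5, 4), dtype=np.uint8)
        aln[0, 0] = 1  # singleton: not informative
        res = phi_test(aln)
        assert res.status.startswith("not applicable")
        assert res.p_permutation == 1.0

    def test_analytic_moments_match_empirical_permutation(self):
        """The closed-form permutation mean/variance agree with brute-force
        sampling of site orderings."""
        rng = np.random.default_rng(3)
        S, w = 12, 4
        X = (rng.uniform(size=(S, S)) < 0.3).astype(float)
        X = np.triu(X, 1)
        X = X + X.T
        W = np.zeros((S, S))
        for d in range(1, w + 1):
            i = np.arange(S - d)
            W[i, i + d] = W[i + d, i] = 1.0
        mean, var = _perm_moments(W, X)
        ts = []
        for _ in range(4000):
            s = rng.permutation(S)
            ts.append((W * X[np.ix_(s, s)]).sum())
        ts = np.array(ts)
        assert mean == pytest.approx(ts.mean(), rel=0.02)
        assert var == pytest.approx(ts.var(), rel=0.15)

    def test_power_increases_with_recombination_rate(self):
        """PHI p-values fall as the simulated recombination rate rises."""
        from clonalsig.synthpop import SimConfig, simulate
        ps = []
        for rec in (0.0, 5e-7, 5e-6):
            vals = []
            for seed in range(3):
                cfg = SimConfig(seed=seed, founder_mode="panmictic",
                                clonality=0.0, rec_rate=rec, n_groups=1,
                                pops_per_group=(1,), individuals_per_pop=25,
                                genome_length=80_000, n_contigs=1,
                                founder_diversity=0.008, generations=10,
                                cds_fraction=0)
                _, hap, *_ = simulate(cfg)
                vals.append(phi_test(hap, n_perm=100,
                                     seed=seed).p_normal)
            ps.append(np.mean(vals))
        assert ps[0] >= ps[1] >= ps[2] or (ps[1] < 0.05 and ps[2] < 0.05)
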