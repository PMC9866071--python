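import numpy as np
import pandas as pd
import pytest

from clonalsig.genio import PopulationHierarchy
from clonalsig.structure import (amova, amova_coefficients, amova_components,
                                 fst_outlier_scan, geographic_distance_matrix,
                                 ibs_distance, mantel_ibd,
                                 mds_genotypic_groups, pairwise_fst, wc_fst)
from clonalsig.synthpop import expand_clones

import oracles
from conftest import make_matrix

TABLE_SS = [166030.43, 396979.34, 255202.00, 1452238.00]
DESIGN_3_5_4 = {"g1": {f"p{i}": 5 for i in range(3)},
                "g2": {f"q{i}": 5 for i in range(5)},
                "g3": {f"r{i}": 5 for i in range(4)}}


def two_pop_hierarchy(samples, split):
    pop_of = {s: ("p1" if i < split else "p2") for i, s in enumerate(samples)}
    return PopulationHierarchy(pop_of=pop_of, group_of={"p1": "g", "p2": "g"})


class TestWcFst:
    def test_fixed_difference_gives_theta_one(self):
        g = make_matrix([[0] * 4, [0] * 4, [0] * 4,
                         [2] * 4, [2] * 4, [2] * 4])
        h = two_pop_hierarchy(g.samples, 3)
        res = wc_fst(g, h)
        assert res.theta_multilocus == pytest.approx(1.0)
        assert res.per_site["theta"].to_numpy() == pytest.approx(np.ones(4))

    def test_identical_genotype_counts_give_near_zero(self):
        # two pops of 30 with identical genotype count vectors at every site
        block = np.array([[0, 1, 2, 1], [1, 0, 1, 2], [2, 2, 0, 0]],
                         dtype=np.int8)
        pop = np.repeat(block, 10, axis=0)
        g = make_matrix(np.vstack([pop, pop]))
        h = two_pop_hierarchy(g.samples, 30)
        assert abs(wc_fst(g, h).theta_multilocus) < 0.05

    def test_matches_direct_formula_transcription(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, size=(6, 25)).astype(np.int8)
        g = make_matrix(dosage)
        h = two_pop_hierarchy(g.samples, 3)
        res = wc_fst(g, h)
        direct = oracles.wc_direct(dosage, [[0, 1, 2], [3, 4, 5]])
        for k, name in enumerate(("a", "b", "c")):
            got = res.per_site[name].to_numpy()
            ok = np.isfinite(direct[k])
            assert got[ok] == pytest.approx(direct[k][ok], abs=1e-10)

    def test_multilocus_is_ratio_of_averages(self):
        dosage = np.array([[0, 0], [0, 1], [2, 1], [2, 2]], dtype=np.int8)
        g = make_matrix(dosage)
        h = two_pop_hierarchy(g.samples, 2)
        res = wc_fst(g, h)
        per = res.per_site
        roa = per["a"].sum() / (per["a"] + per["b"] + per["c"]).sum()
        aor = np.nanmean(per["theta"])
        assert res.theta_multilocus == pytest.approx(roa)
        assert abs(roa - aor) > 1e-6  # the two disagree on this toy


class TestAmovaComponents:
    def test_reproduces_published_worked_example(self):
        """Printed sums of squares with the 3/5/4-population, 5-diploid
        design reproduce the published variance components, percentages,
        and fixation indices within 0.01."""
        tab = amova_components(TABLE_SS, DESIGN_3_5_4)
        assert tab["variance_component"].to_numpy() == pytest.approx(
            [993.35, 3879.21, -9443.63, 24203.97], abs=0.01)
        assert tab["percentage"].to_numpy() == pytest.approx(
            [5.06, 19.76, -48.10, 123.28], abs=0.01)
        assert tab["fixation_index"].to_numpy() == pytest.approx(
            [0.05, 0.21, -0.64, -0.23], abs=0.01)

    def test_equal_mean_squares_give_residual_only(self):
        C = amova_coefficients(DESIGN_3_5_4)
        df = np.array([2, 9, 48, 60])
        m = 7.5
        ss = C @ np.array([0.0, 0.0, 0.0, m])
        tab = amova_components(ss, DESIGN_3_5_4)
        assert tab["variance_component"].to_numpy() == pytest.approx(
            [0, 0, 0, m], abs=1e-9)
        assert ss == pytest.approx(df * (C[:, 3] / df) * m)

    def test_algebraic_inverse_roundtrip(self):
        rng = np.random.default_rng(0)
        C = amova_coefficients(DESIGN_3_5_4)
        for _ in range(5):
            ss = rng.uniform(10, 1e6, size=4)
            sigma = amova_components(ss, DESIGN_3_5_4)[
                "variance_component"].to_numpy()
            assert np.abs(C @ sigma - ss).max() < 1e-9

    def test_singular_design_fails(self):
        with pytest.raises(ValueError, match="singular"):
            amova_components([1, 2, 3, 4], {"g1": {"p1": 5}})


class TestAmova:
    def test_ss_matches_double_loop_oracle(self, hybrid_sim):
        g, hap, _, h, _ = hybrid_sim
        sub = hap.take_sites(np.arange(0, hap.n_sites, 25))
        tab = amova(sub, h, n_perm=0)
        copy_ind = np.repeat(np.arange(sub.n_samples), 2)
        pops = {p: i for i, p in enumerate(h.populations())}
        grps = {x: i for i, x in enumerate(h.groups())}
        copy_pop = np.repeat([pops[h.pop_of[s]] for s in sub.samples], 2)
        copy_grp = np.repeat(
            [grps[h.group_of[h.pop_of[s]]] for s in sub.samples], 2)
        expect = oracles.amova_ss_double_loop(sub.alignment(), copy_ind,
                                              copy_pop, copy_grp)
        assert tab["sum_of_squares"].to_numpy() == pytest.approx(expect)

    def test_identical_individuals_reported_empty_with_warning(self, caplog):
        import logging

        from clonalsig.genio import HaplotypeSet
        sites = pd.DataFrame({"contig": ["c1"] * 2, "pos": [1, 2],
                              "ref": ["A", "A"], "alt": ["T", "T"]})
        haps = np.ones((8, 2, 2), dtype=np.uint8)
        hap = HaplotypeSet(samples=[f"s{i}" for i in range(8)], sites=sites,
                           haps=haps)
        pop_of = {f"s{i}": f"p{i // 2}" for i in range(8)}
        h = PopulationHierarchy(pop_of=pop_of,
                                group_of={"p0": "g1", "p1": "g1",
                                          "p2": "g2", "p3": "g2"})
        with caplog.at_level(logging.WARNING):
            tab = amova(hap, h, n_perm=0)
        assert "identical" in caplog.text
        assert (tab["variance_component"] == 0).all()
        assert tab["percentage"].isna().all()

    def test_structured_fixture_has_significant_group_level(self, hybrid_sim):
        g, hap, _, h, _ = hybrid_sim
        sub = hap.take_sites(np.arange(0, hap.n_sites, 10))
        tab = amova(sub, h, n_perm=49, seed=1)
        assert tab.loc[0, "p_value"] <= 0.05
        # the clonal-hybrid pattern: negative among-individual component,
        # dominant within-individual component
        assert tab.loc[2, "variance_component"] < 0
        assert tab.loc[3, "percentage"] > 100


class TestMantel:
    def test_identical_matrices_give_r_one(self):
        coords = {"a": (30, 100), "b": (31, 101), "c": (33, 99),
                  "d": (28, 103), "e": (29, 97), "f": (32, 104)}
        geo = geographic_distance_matrix(coords, list(coords))
        fst = geo / (geo + 1)  # linearises back to geo exactly
        r, p = mantel_ibd(fst, coords, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_three_by_three_closed_form(self):
        coords = {"a": (30, 100), "b": (30, 101), "c": (31, 100)}
        fst = pd.DataFrame([[0, .1, .2], [.1, 0, .3], [.2, .3, 0]],
                           index=list("abc"), columns=list("abc"))
        r, _ = mantel_ibd(fst, coords, n_perm=9, seed=0)
        gen = np.array([.1 / .9, .2 / .8, .3 / .7])
        geo = geographic_distance_matrix(coords, list("abc")).to_numpy()
        geo = geo[np.triu_indices(3, 1)]
        expect = np.corrcoef(gen, geo)[0, 1]
        assert r == pytest.approx(expect)

    def test_fst_of_one_requires_cap(self):
        coords = {"a": (30, 100), "b": (31, 101), "c": (33, 99)}
        fst = pd.DataFrame([[0, 1.0, .2], [1.0, 0, .3], [.2, .3, 0]],
                           index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError, match="cap"):
            mantel_ibd(fst, coords, n_perm=9)
        r, _ = mantel_ibd(fst, coords, n_perm=9, cap=0.999)
        assert np.isfinite(r)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(5)
        coords = {f"p{i}": (30 + rng.uniform(-3, 3), 100 + rng.uniform(-3, 3))
                  for i in range(8)}
        ps = []
        for rep in range(20):
            M = rng.uniform(0.0, 0.5, size=(8, 8))
            fst = pd.DataFrame((M + M.T) / 2, index=list(coords),
                               columns=list(coords))
            np.fill_diagonal(fst.values, 0)
            ps.append(mantel_ibd(fst, coords, n_perm=99, seed=rep)[1])
        ps = np.array(ps)
        assert 0.15 < (ps < 0.5).mean() < 0.85  # not degenerate
        assert ps.min() > 1 / 100


class TestGenotypicGroups:
    def test_identical_individuals_share_group(self, hybrid_sim):
        _, hap, *_ = hybrid_sim
        # pick a sample genuinely distinct from sample 0 (the mostly clonal
        # fixture contains clone mates with identical genotypes)
        far = int(np.argmax(
            np.abs(hap.haps.sum(1) - hap.haps.sum(1)[0]).sum(1)))
        base = expand_clones(hap, {hap.samples[0]: ["a1", "a2"],
                                   hap.samples[far]: ["b1"]})
        g = base.to_genotype_matrix()
        h = PopulationHierarchy(pop_of={"a1": "p1", "a2": "p1", "b1": "p1"},
                                group_of={"p1": "g1"})
        out = mds_genotypic_groups(g, h, epsilon=0.01)
        by = dict(zip(out["individual"], out["genotypic_group"]))
        assert by["a1"] == by["a2"] != by["b1"]
        assert ibs_distance(g)[0, 1] == 0.0

    def test_mds_exact_for_three_equidistant_points(self):
        g = make_matrix([[0, 0, 2, 2], [2, 2, 0, 0], [0, 2, 0, 2]])
        h = PopulationHierarchy(pop_of={s: "p1" for s in g.samples},
                                group_of={"p1": "g1"})
        out = mds_genotypic_groups(g, h, dims=2, epsilon=0.001)
        D = ibs_distance(g)
        xy = out.sort_values("individual")[["mds1", "mds2"]].to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                got = np.linalg.norm(xy[i] - xy[j])
                assert got == pytest.approx(D[i, j], rel=1e-6)

    def test_recovers_planted_clone_lineages(self):
        """24 planted clone lineages (2 per population) are recovered as
        exactly 24 genotypic groups at a suitable epsilon."""
        from clonalsig.synthpop import SimConfig, simulate
        cfg = SimConfig(seed=9, founder_mode="hybrid", clonality=1.0,
                        generations=0, n_groups=1, pops_per_group=(1,),
                        individuals_per_pop=24, genome_length=100_000,
                        n_contigs=5, founder_diversity=0.004,
                        founder_divergence=0.003, cds_fraction=0.1)
        _, hap, genome, _, _ = simulate(cfg)
        plan, pop_of = {}, {}
        for k in range(24):
            src = hap.samples[k]
            names = [f"l{k:02d}_c{j}" for j in range(2 + k % 2)]
            plan[src] = names
            for nm in names:
                pop_of[nm] = f"pp{k // 2}"
        clones = expand_clones(hap, plan, seed=1, noise_mutations=3.0,
                               genome=genome)
        g = clones.to_genotype_matrix()
        h = PopulationHierarchy(pop_of=pop_of,
                                group_of={f"pp{i}": "g1" for i in range(12)})
        out = mds_genotypic_groups(g, h, epsilon=0.01)
        assert out.attrs["n_groups"] == 24
        reps = out.loc[out["representative"], "individual"]
        assert len(reps) == 24

    def test_epsilon_must_be_positive(self, hybrid_sim):
        g, _, _, h, _ = hybrid_sim
        with pytest.raises(ValueError, match="epsilon"):
            mds_genotypic_groups(g, h, epsilon=0.0)


class TestOutlierScan:
    def test_single_population_errors(self):
        g = make_matrix([[0, 1], [1, 2]])
        h = PopulationHierarchy(pop_of={s: "p1" for s in g.samples},
                                group_of={"p1": "g1"})
        with pytest.raises(ValueError, match="populations"):
            fst_outlier_scan(g, h)

    def test_null_p_distribution_roughly_uniform(self, panmictic_sim):
        g, _, _, h, _ = panmictic_sim
        scan = fst_outlier_scan(g, h, n_perm=100, seed=3)
        p = scan["p"].to_numpy()
        assert 0.4 < p.mean() < 0.6
        assert scan["outlier"].sum() == 0

    def test_low_n_perm_warns(self, panmictic_sim, caplog):
        import logging
        g, _, _, h, _ = panmictic_sim
        with caplog.at_level(logging.WARNING):
            fst_outlier_scan(g.take_sites(np.arange(50)), h, n_perm=20)
        assert "n_perm" in caplog.text

    def test_q_monotone_in_p_rank(self, panmictic_sim):
        g, _, _, h, _ = panmictic_sim
        scan = fst_outlier_scan(g, h, n_perm=100, seed=3)
        s = scan.sort_values("p")
        assert (np.diff(s["q"].to_numpy()) >= -1e-12).all()


def test_pairwise_fst_symmetric_nonnegative_diag_zero(hybrid_sim):
    g, _, _, h, _ = hybrid_sim
    m = pairwise_fst(g, h, level="groups")
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 0.0)
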