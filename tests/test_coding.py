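import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonalsig.coding import (classify_degeneracy, enrichment,
                              map_outliers_to_genes, pi0_pi4,
                              premature_stop_screen)
from clonalsig.genio import AnnotatedGenome, HaplotypeSet
from clonalsig.synthpop import inject_premature_stop

import oracles
from conftest import make_matrix


def plus_gene(coding, gene_id="g1", contig="c1"):
    return AnnotatedGenome(
        seqs={contig: coding},
        cds=pd.DataFrame([{"gene_id": gene_id, "contig": contig, "start": 0,
                           "end": len(coding), "strand": "+", "frame": 0}]))


class TestClassifyDegeneracy:
    def test_known_codons(self):
        genome = plus_gene("GGAATGTGGTAA")  # Gly, Met, Trp, stop
        tab = classify_degeneracy(genome).table
        by = {(r.pos, r.codon): r.fold for r in tab.itertuples()}
        assert by[(3, "GGA")] == 4          # third position of Gly codon
        assert all(by[(p, "ATG")] == 0 for p in (4, 5, 6))
        assert all(by[(p, "TGG")] == 0 for p in (7, 8, 9))
        assert not any(r.pos > 9 for r in tab.itertuples())  # stop excluded

    def test_counts_match_exhaustive_code_table(self, hybrid_sim):
        _, _, genome, _, _ = hybrid_sim
        tab = classify_degeneracy(genome).table
        oracle = oracles.degeneracy_enumerate()
        sample = tab.sample(n=300, random_state=0)
        for r in sample.itertuples():
            assert oracle[(r.codon, r.codon_pos)] == r.fold

    def test_strand_invariance(self):
        """A minus-strand gene classifies identically to its sense-strand
        equivalent."""
        coding = "ATGGGACCTTGCAAATAA"
        rc = str(__import__("Bio.Seq", fromlist=["Seq"]).Seq(coding)
                 .reverse_complement())
        gplus = plus_gene(coding)
        gminus = AnnotatedGenome(
            seqs={"c1": rc},
            cds=pd.DataFrame([{"gene_id": "g1", "contig": "c1", "start": 0,
                               "end": len(rc), "strand": "-", "frame": 0}]))
        tplus = classify_degeneracy(gplus).table
        tminus = classify_degeneracy(gminus).table
        assert list(tplus["fold"]) == list(tminus["fold"])
        assert list(tplus["codon"]) == list(tminus["codon"])


class TestPi0Pi4:
    def degmap(self):
        from clonalsig.coding import DegeneracyMap
        return DegeneracyMap(pd.DataFrame({
            "contig": "c1",
            "pos": np.concatenate([np.arange(100, 200), np.arange(300, 400)]),
            "gene_id": "g", "codon": "NNN", "codon_pos": 0,
            "fold": [0] * 100 + [4] * 100}))

    def test_identical_representatives_undefined_ratio(self, caplog):
        import logging
        g = make_matrix(np.zeros((3, 10), dtype=np.int8), start=100, step=1)
        with caplog.at_level(logging.WARNING):
            out = pi0_pi4(g, ["s1", "s2"], self.degmap())
        assert out["pi0"] == out["pi4"] == 0.0
        assert np.isnan(out["ratio"])

    def test_single_fourfold_difference(self):
        """Two representatives differing (homozygously) at one 4-fold site
        of 100: pi4 = 0.01, pi0 = 0, ratio 0."""
        sites = pd.DataFrame({
            "contig": "c1",
            "pos": np.concatenate([np.arange(100, 200), np.arange(300, 400)]),
            "ref": "A", "alt": "T"})
        dosage = np.zeros((2, 200), dtype=np.int8)
        dosage[1, 150] = 2  # a 4-fold site
        from clonalsig.genio import GenotypeMatrix
        g = GenotypeMatrix(samples=["r1", "r2"], sites=sites, dosage=dosage)
        out = pi0_pi4(g, ["r1", "r2"], self.degmap())
        assert out["pi4"] == pytest.approx(0.01)
        assert out["pi0"] == 0.0 and out["ratio"] == 0.0

    def test_neutral_simulation_ratio_near_one(self, hybrid_sim):
        """Without selection the 0-fold and 4-fold classes have the same
        diversity, so the ratio is ~1 within sampling error."""
        from clonalsig.structure import mds_genotypic_groups
        g, _, genome, h, _ = hybrid_sim
        gg = mds_genotypic_groups(g, h, epsilon=0.03)
        reps = sorted(gg.loc[gg["representative"], "individual"])
        deg = classify_degeneracy(genome)
        out = pi0_pi4(g, reps, deg)
        assert 0.6 < out["ratio"] < 1.6


class TestOutlierGeneMapping:
    def test_interval_join(self):
        genome = plus_gene("ATG" + "GGA" * 30 + "TAA")
        scan = pd.DataFrame({"contig": ["c1", "c1"], "pos": [10, 5000],
                             "outlier": [True, True]})
        out = map_outliers_to_genes(scan, genome)
        d = dict(zip(out["gene_id"], out["n_outliers"]))
        assert d == {"g1": 1, "(unassigned)": 1}

    def test_planted_outliers_map_to_their_genes(self, panmictic_sim):
        from clonalsig.structure import fst_outlier_scan
        from clonalsig.synthpop import plant_differentiated_sites
        g, _, genome, h, _ = panmictic_sim
        # plant inside known CDS sites
        cds_mask = np.zeros(g.n_sites, dtype=bool)
        deg = classify_degeneracy(genome).table
        key = set(zip(deg["contig"], deg["pos"]))
        for i, (c, p) in enumerate(zip(g.sites["contig"], g.sites["pos"])):
            cds_mask[i] = (c, p) in key
        cds_idx = np.flatnonzero(cds_mask)[:6]
        d = g.dosage.copy()
        hi = np.array([h.pop_of[s] in {"pop01", "pop02"} for s in g.samples])
        d[np.ix_(hi, cds_idx)] = 2
        d[np.ix_(~hi, cds_idx)] = 0
        from clonalsig.genio import GenotypeMatrix
        g2 = GenotypeMatrix(samples=list(g.samples), sites=g.sites.copy(),
                            dosage=d)
        scan = fst_outlier_scan(g2, h, n_perm=150, seed=4)
        out = map_outliers_to_genes(scan, genome)
        expect = set()
        for i in cds_idx:
            c, p = g.sites["contig"].iloc[i], g.sites["pos"].iloc[i]
            expect.update(deg.loc[(deg["contig"] == c) & (deg["pos"] == p),
                                  "gene_id"])
        assert set(out["gene_id"]) - {"(unassigned)"} == expect


class TestEnrichment:
    def annotation(self):
        rows = [("gene%03d" % i, "T1") for i in range(100)]
        rows += [("gene%03d" % i, "T2") for i in range(1000)]
        return pd.DataFrame(rows, columns=["gene", "term"])

    def test_equal_proportions_give_statistic_zero(self):
        ann = pd.DataFrame({"gene": [f"g{i}" for i in range(100)],
                            "term": ["T"] * 50 + ["U"] * 50})
        study = [f"g{i}" for i in range(45, 55)]  # 5 in T, 5 in U
        out = enrichment(study, ann)
        assert out["statistic"].to_numpy() == pytest.approx([0.0, 0.0])
        assert out["p"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_matches_textbook_two_by_two(self):
        """Study 10-in-term of 20 vs background 100 of 1000 equals the
        direct chi-squared formula evaluation."""
        study = ["gene%03d" % i for i in range(10)] + \
                ["gene%03d" % i for i in range(500, 510)]
        out = enrichment(study, self.annotation())
        row = out[out["term"] == "T1"].iloc[0]
        stat = oracles.chi2_2x2(10, 10, 90, 890)
        assert row["statistic"] == pytest.approx(stat)
        assert row["p"] == pytest.approx(stats.chi2.sf(stat, 1))

    def test_low_expected_count_falls_back_to_hypergeometric(self):
        ann = pd.DataFrame({"gene": [f"g{i}" for i in range(50)],
                            "term": ["rare"] * 1 + ["common"] * 49})
        out = enrichment(["g0", "g1"], ann)
        row = out[out["term"] == "rare"].iloc[0]
        assert "hypergeometric" in row["method"]
        assert row["p"] == pytest.approx(
            stats.hypergeom.sf(0, 50, 1, 2))

    def test_empty_study_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            enrichment([], self.annotation())


class TestPrematureStopScreen:
    def test_planted_stop_flags_planted_carriers_exactly(self, hybrid_sim):
        """Flags after planting = flags before planting + exactly the
        planted (gene, individual) carriers (random simulated alleles can
        create stops on their own, so the comparison is relative)."""
        _, hap, genome, _, _ = hybrid_sim
        genes = genome.genes()
        before = premature_stop_screen(hap, genome, genes[:2])
        pre = {(r.gene_id, r.individual, r.haplotype)
               for r in before[before["kind"] == "premature_stop"].itertuples()}
        carriers = {genes[0]: [hap.samples[2]],
                    genes[1]: [hap.samples[0], hap.samples[7]]}
        hap2 = hap
        for gene, who in carriers.items():
            hap2 = inject_premature_stop(genome, hap2, gene, who)
        out = premature_stop_screen(hap2, genome, genes[:2])
        flagged = out[out["kind"] == "premature_stop"]
        got = {(r.gene_id, r.individual, r.haplotype)
               for r in flagged.itertuples()}
        want = pre | {(g, w, 0) for g, who in carriers.items() for w in who}
        assert got == want  # precision = recall = 1 on the planted set

    def test_synonymous_snp_not_flagged(self):
        genome = plus_gene("ATGGGAGGATAA")
        # GGA -> GGG at codon 2 third position: synonymous
        hap = HaplotypeSet(
            samples=["i1"],
            sites=pd.DataFrame({"contig": ["c1"], "pos": [6], "ref": ["A"],
                                "alt": ["G"]}),
            haps=np.array([[[1], [0]]], dtype=np.uint8))
        out = premature_stop_screen(hap, genome)
        assert out.empty

    def test_terminal_stop_loss_reported_separately(self):
        genome = plus_gene("ATGGGATAA")
        # TAA -> CAA: terminal stop lost, no internal stop
        hap = HaplotypeSet(
            samples=["i1"],
            sites=pd.DataFrame({"contig": ["c1"], "pos": [7], "ref": ["T"],
                                "alt": ["C"]}),
            haps=np.array([[[1], [0]]], dtype=np.uint8))
        out = premature_stop_screen(hap, genome)
        assert list(out["kind"]) == ["stop_loss"]
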