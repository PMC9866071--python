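"""Coding-sequence analyses: codon-degeneracy classification, pi0/pi4 over
genotypic-group representatives, outlier-to-gene mapping, chi-squared term
enrichment, and the premature-stop screen.

pi0/pi4 (piN/piS) compares nucleotide diversity at 0-fold degenerate sites
(every change nonsynonymous) against 4-fold degenerate sites (every change
synonymous); an elevated ratio indicates reduced efficacy of purifying
selection, as expected when linkage is genome-wide.  Diversity in each class
is normalised by the total number of sites of that class in the analysed
coding sequence, not just the segregating ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from intervaltree import IntervalTree
from scipy import stats

from .genio import AnnotatedGenome, GenotypeMatrix, HaplotypeSet

log = logging.getLogger(__name__)

_CODE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODE[_stop] = "*"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class DegeneracyMap:
    """Per-CDS-site degeneracy classes (0-, 2-, 3- or 4-fold)."""

    table: pd.DataFrame  # contig, pos (1-based), gene_id, codon, codon_pos, fold

    def class_counts(self) -> pd.Series:
        return self.table["fold"].value_counts().sort_index()


def _fold(codon: str, offset: int) -> int | None:
    """Degeneracy class of one codon position under the standard code."""
    if any(b not in "ACGT" for b in codon):
        return None
    aa = _CODE[codon]
    if aa == "*":
        return None
    syn = sum(1 for b in "ACGT" if b != codon[offset]
              and _CODE[codon[:offset] + b + codon[offset + 1:]] == aa)
    return {0: 0, 1: 2, 2: 3, 3: 4}[syn]


def classify_degeneracy(genome: AnnotatedGenome) -> DegeneracyMap:
    """Classify every CDS site by substituting all three alternatives in its
    codon; codons containing N (or stop codons) leave their sites unclassified.
    """
    rows = []
    for gene in genome.genes():
        coding = genome.coding_sequence(gene)
        index = genome.cds_site_index(gene)
        usable = len(coding) - len(coding) % 3
        for ci in range(usable // 3):
            codon = coding[3 * ci: 3 * ci + 3]
            for off in range(3):
                fold = _fold(codon, off)
                if fold is None:
                    continue
                contig, gpos, _ = index[3 * ci + off]
                rows.append({"contig": contig, "pos": gpos + 1, "gene_id": gene,
                             "codon": codon, "codon_pos": off, "fold": fold})
    return DegeneracyMap(pd.DataFrame(
        rows, columns=["contig", "pos", "gene_id", "codon", "codon_pos", "fold"]))


def pi0_pi4(g: GenotypeMatrix, representatives: list,
            degeneracy: DegeneracyMap) -> dict:
    """Nucleotide diversity at 0-fold and 4-fold sites over one representative
    per genotypic group, and their ratio.

    Per-class pi = (sum of per-site pairwise diversity at segregating sites of
    the class) / (total number of CDS sites of the class), mirroring a
    concatenated-coding-sequence computation.
    """
    if len(representatives) < 2:
        raise ValueError("pi0/pi4 needs >= 2 genotypic-group representatives")
    sub = g.take_samples(representatives)
    key = sub.sites.assign(_idx=np.arange(sub.n_sites)).merge(
        degeneracy.table[["contig", "pos", "fold"]], on=["contig", "pos"],
        how="inner")
    totals = degeneracy.table["fold"].value_counts()
    out = {}
    for fold in (0, 4):
        n_class = int(totals.get(fold, 0))
        if n_class == 0:
            raise ValueError(f"no {fold}-fold sites in the annotation")
        idx = key.loc[key["fold"] == fold, "_idx"].to_numpy()
        if len(idx) == 0:
            out[f"pi{fold}"] = 0.0
            continue
        # mean pairwise difference between representatives: at a site the
        # expected difference between one allele drawn from each individual
        # is p_i + p_j - 2 p_i p_j with p = dosage / 2
        d = sub.dosage[:, idx].astype(float)
        ok = d >= 0
        p = np.where(ok, d / 2.0, np.nan)
        k = p.shape[0]
        tot = np.zeros(len(idx))
        npairs = np.zeros(len(idx))
        for i in range(k):
            for j in range(i + 1, k):
                both = ok[i] & ok[j]
                tot[both] += (p[i] + p[j] - 2 * p[i] * p[j])[both]
                npairs[both] += 1
        persite = np.where(npairs > 0, tot / np.maximum(npairs, 1), 0.0)
        out[f"pi{fold}"] = float(persite.sum() / n_class)
    if out["pi4"] == 0:
        log.warning("pi4 = 0: pi0/pi4 ratio undefined")
        out["ratio"] = np.nan
    else:
        out["ratio"] = out["pi0"] / out["pi4"]
    return out


def map_outliers_to_genes(scan: pd.DataFrame, genome: AnnotatedGenome) -> pd.DataFrame:
    """Join flagged outlier sites against gene CDS spans.

    Returns one row per gene with its outlier-site count; sites between genes
    are collected in the ``(unassigned)`` bucket.
    """
    trees = {}
    for r in genome.cds.itertuples():
        trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end, r.gene_id)
    hits = {}
    flagged = scan[scan["outlier"]] if "outlier" in scan.columns else scan
    for r in flagged.itertuples():
        found = trees.get(r.contig, IntervalTree())[r.pos - 1]
        if found:
            for iv in found:
                hits[iv.data] = hits.get(iv.data, 0) + 1
        else:
            hits["(unassigned)"] = hits.get("(unassigned)", 0) + 1
    return (pd.DataFrame([{"gene_id": k, "n_outliers": v} for k, v in hits.items()])
            .sort_values(["n_outliers", "gene_id"], ascending=[False, True])
            .reset_index(drop=True)
            if hits else pd.DataFrame(columns=["gene_id", "n_outliers"]))


def enrichment(study_genes: list, annotation: pd.DataFrame,
               universe_size: int | None = None) -> pd.DataFrame:
    """Per-term 2x2 chi-squared enrichment of a study gene set.

    ``annotation`` is a two-column table (gene, term); the background universe
    defaults to all annotated genes.  When any expected cell count is below 1
    the chi-squared approximation is unreliable and the hypergeometric
    (Fisher one-tail) p is reported instead, with a note in ``method``.
    """
    study = set(study_genes)
    if not study:
        raise ValueError("empty study gene set")
    gene_col, term_col = annotation.columns[:2]
    universe = set(annotation[gene_col])
    Nu = universe_size if universe_size is not None else len(universe)
    n = len(study & universe)
    rows = []
    for term, sub in annotation.groupby(term_col):
        term_genes = set(sub[gene_col])
        K = len(term_genes)
        k = len(study & term_genes)
        table = np.array([[k, n - k], [K - k, Nu - n - (K - k)]], dtype=float)
        expected = stats.contingency.expected_freq(table + 0.0) \
            if table.sum() else np.ones((2, 2))
        hyper_p = float(stats.hypergeom.sf(k - 1, Nu, K, n))
        if (expected < 1).any():
            stat, p, method = np.nan, hyper_p, "hypergeometric (low expected count)"
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            method = "chi-squared"
        rows.append({"term": term, "study_count": k, "background_count": K,
                     "statistic": stat, "p": p, "p_hypergeom": hyper_p,
                     "method": method})
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


def premature_stop_screen(hap: HaplotypeSet, genome: AnnotatedGenome,
                          genes: list | None = None) -> pd.DataFrame:
    """Translate every haplotype of every gene and flag internal stop codons.

    A stop strictly before the annotated terminal codon is flagged as
    ``premature_stop`` with its codon index (0-based) and causal site; loss
    of the terminal stop alone is reported separately as ``stop_loss``.
    """
    genes = genes if genes is not None else genome.genes()
    site_lookup = {(c, p): i for i, (c, p) in
                   enumerate(zip(hap.sites["contig"], hap.sites["pos"] - 1))}
    rows = []
    for gene in genes:
        coding = genome.coding_sequence(gene)
        index = genome.cds_site_index(gene)
        strand = genome.gene_rows(gene)["strand"].iloc[0]
        n_codons = len(coding) // 3
        snp_here = [(cpos, site_lookup[(c, p)])
                    for (c, p, cpos) in index if (c, p) in site_lookup]
        if not snp_here:
            continue
        ref_aa = str(Seq(coding[:3 * n_codons]).translate())
        for i, sample in enumerate(hap.samples):
            for k in (0, 1):
                carried = [(cpos, si) for cpos, si in snp_here
                           if hap.haps[i, k, si] == 1]
                if not carried:
                    continue
                seq = list(coding)
                for cpos, si in carried:
                    alt = hap.sites["alt"].iloc[si]
                    seq[cpos] = alt if strand == "+" else _COMP[alt]
                aa = str(Seq("".join(seq[:3 * n_codons])).translate())
                internal = aa[:-1].find("*")
                if internal >= 0:
                    causal = [si for cpos, si in carried
                              if cpos // 3 == internal]
                    rows.append({"gene_id": gene, "individual": sample,
                                 "haplotype": k, "kind": "premature_stop",
                                 "codon_index": internal,
                                 "causal_site": int(causal[0]) if causal else -1})
                elif ref_aa.endswith("*") and not aa.endswith("*"):
                    rows.append({"gene_id": gene, "individual": sample,
                                 "haplotype": k, "kind": "stop_loss",
                                 "codon_index": n_codons - 1,
                                 "causal_site": -1})
    return pd.DataFrame(rows, columns=["gene_id", "individual", "haplotype",
                                       "kind", "codon_index", "causal_site"])
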