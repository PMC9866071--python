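"""Core genotype data model and file I/O.

Holds the in-memory containers shared by every analysis stage
(:class:`GenotypeMatrix`, :class:`HaplotypeSet`, :class:`PopulationHierarchy`,
:class:`AnnotatedGenome`) together with readers/writers for VCF, FASTA, GFF3
and the tab-separated population/coordinate tables, plus the genotype-level
site filters (biallelic SNPs only, no missing genotypes, polymorphic).

Coordinates are 0-based half-open internally; conversion to/from the 1-based
conventions of VCF and GFF3 happens only at the I/O boundary.
"""

from __future__ import annotations

import gzip
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

MISSING = -1

SITE_COLUMNS = ["contig", "pos", "ref", "alt"]


class GenioError(ValueError):
    """Raised for malformed inputs or violated data-model invariants."""


def _open_text(path, mode="rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a sample set.

    Parameters
    ----------
    samples : list of str
        Sample identifiers, one per matrix row.
    sites : pandas.DataFrame
        One row per site with columns ``contig, pos, ref, alt``; ``pos`` is
        1-based (VCF convention for display; all arithmetic is positional).
        Positions must be strictly increasing within each contig.
    dosage : ndarray of int8, shape (n_samples, n_sites)
        Alternate-allele dosage 0/1/2, ``-1`` for missing.
    phased : ndarray of bool, shape (n_samples,)
        Whether every non-missing genotype of the sample was phased.
    """

    samples: list
    sites: pd.DataFrame
    dosage: np.ndarray
    phased: np.ndarray | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise GenioError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if self.phased is None:
            self.phased = np.zeros(len(self.samples), dtype=bool)
        self.sites = self.sites.reset_index(drop=True)
        bad = (self.dosage < -1) | (self.dosage > 2)
        if bad.any():
            raise GenioError("dosage values must be in {0,1,2} or -1 (missing)")
        for contig, sub in self.sites.groupby("contig", sort=False):
            p = sub["pos"].to_numpy()
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise GenioError(f"positions not strictly increasing on {contig}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def allele_freq(self) -> np.ndarray:
        """Whole-sample alternate-allele frequency per site (missing skipped)."""
        d = self.dosage
        obs = d >= 0
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(d > 0, d, 0).sum(axis=0) / np.maximum(2 * n, 1)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index].copy(),
            phased=self.phased.copy(),
        )

    def take_samples(self, which) -> "GenotypeMatrix":
        if all(isinstance(w, str) for w in which):
            idx = [self.samples.index(w) for w in which]
        else:
            idx = list(which)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=self.sites.copy(),
            dosage=self.dosage[idx].copy(),
            phased=self.phased[idx].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.sites[SITE_COLUMNS].equals(other.sites[SITE_COLUMNS])
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass
class HaplotypeSet:
    """Phased haplotypes: two 0/1 allele strings per individual over a site list.

    ``haps[i, k, s]`` is the allele (0=ref, 1=alt) of haplotype ``k`` of
    individual ``i`` at site ``s``. The haplotype pair always sums to the
    dosage, so a :class:`GenotypeMatrix` can be derived at any time.
    """

    samples: list
    sites: pd.DataFrame
    haps: np.ndarray  # (n_samples, 2, n_sites) uint8

    def __post_init__(self):
        self.haps = np.asarray(self.haps, dtype=np.uint8)
        if self.haps.shape != (len(self.samples), 2, len(self.sites)):
            raise GenioError("haps shape does not match samples x 2 x sites")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def to_genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.copy(),
            dosage=self.haps.sum(axis=1).astype(np.int8),
            phased=np.ones(len(self.samples), dtype=bool),
        )

    def alignment(self) -> np.ndarray:
        """All 2N haplotypes as a (2N, S) array, individual-major order."""
        return self.haps.reshape(-1, self.n_sites)

    def hap_labels(self) -> list:
        return [f"{s}_{k}" for s in self.samples for k in (0, 1)]

    def take_sites(self, index) -> "HaplotypeSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypeSet(
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
            haps=self.haps[:, :, index].copy(),
        )


@dataclass
class PopulationHierarchy:
    """Three-level sampling design: individuals in populations in groups."""

    pop_of: dict            # individual -> population
    group_of: dict          # population -> group
    coords: dict = field(default_factory=dict)  # population -> (lat, lon)

    def populations(self) -> list:
        seen = []
        for p in self.pop_of.values():
            if p not in seen:
                seen.append(p)
        return seen

    def groups(self) -> list:
        seen = []
        for p in self.populations():
            g = self.group_of[p]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in_pop(self, pop) -> list:
        return [s for s, p in self.pop_of.items() if p == pop]

    def pops_in_group(self, group) -> list:
        return [p for p in self.populations() if self.group_of[p] == group]

    def samples_in_group(self, group) -> list:
        return [s for s, p in self.pop_of.items() if self.group_of[p] == group]

    def group_of_sample(self, sample):
        return self.group_of[self.pop_of[sample]]

    def validate(self, samples: Sequence[str]) -> None:
        missing = [s for s in samples if s not in self.pop_of]
        if missing:
            raise GenioError(f"samples absent from population table: {missing}")
        for p in self.populations():
            if p not in self.group_of:
                raise GenioError(f"population {p!r} has no group assignment")


@dataclass
class AnnotatedGenome:
    """Reference contig sequences plus CDS annotation.

    ``cds`` has one row per CDS segment with columns
    ``gene_id, contig, start, end, strand, frame`` where ``start/end`` are
    0-based half-open and ``frame`` is the number of bases to skip before the
    first complete codon.
    """

    seqs: dict                       # contig -> str
    cds: pd.DataFrame

    def genes(self) -> list:
        return list(dict.fromkeys(self.cds["gene_id"]))

    def gene_rows(self, gene_id) -> pd.DataFrame:
        rows = self.cds[self.cds["gene_id"] == gene_id]
        if rows.empty:
            raise GenioError(f"unknown gene {gene_id!r}")
        return rows.sort_values("start")

    def coding_sequence(self, gene_id) -> str:
        """Spliced, strand-oriented coding sequence of a gene."""
        rows = self.gene_rows(gene_id)
        strand = rows["strand"].iloc[0]
        parts = [self.seqs[r.contig][r.start:r.end] for r in rows.itertuples()]
        seq = "".join(parts)
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        frame = int(rows["frame"].iloc[0] if strand == "+" else rows["frame"].iloc[-1])
        return seq[frame:]

    def cds_site_index(self, gene_id) -> list:
        """(contig, genomic 0-based pos, index within coding sequence) per base.

        The index is in coding-strand orientation and already accounts for the
        frame offset; bases trimmed by the frame are omitted.
        """
        rows = self.gene_rows(gene_id)
        strand = rows["strand"].iloc[0]
        coords = []
        for r in rows.itertuples():
            coords.extend((r.contig, p) for p in range(r.start, r.end))
        if strand == "-":
            coords = coords[::-1]
        frame = int(rows["frame"].iloc[0] if strand == "+" else rows["frame"].iloc[-1])
        coords = coords[frame:]
        return [(c, p, i) for i, (c, p) in enumerate(coords)]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records and indels are excluded (their counts are logged,
    mirroring the biallelic-SNP-only input contract); missing genotypes map
    to the missing marker.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path), gts012=False)
    samples = list(vcf.samples)
    contigs, poss, refs, alts = [], [], [], []
    rows = []
    phased_all = np.ones(len(samples), dtype=bool)
    n_multi = n_indel = 0
    for i, rec in enumerate(vcf):
        try:
            if len(rec.ALT) != 1:
                n_multi += 1
                continue
            if not rec.is_snp:
                n_indel += 1
                continue
            gts = rec.genotypes  # [a0, a1, phased] per sample
            dos = np.empty(len(samples), dtype=np.int8)
            for j, g in enumerate(gts):
                a0, a1 = g[0], g[1]
                if a0 < 0 or a1 < 0:
                    dos[j] = MISSING
                else:
                    dos[j] = a0 + a1
                    phased_all[j] &= bool(g[2])
            rows.append(dos)
            contigs.append(rec.CHROM)
            poss.append(rec.POS)
            refs.append(rec.REF)
            alts.append(rec.ALT[0])
        except Exception as exc:  # pragma: no cover - defensive
            raise GenioError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc
    if n_multi or n_indel:
        log.info("read_vcf %s: excluded %d multi-allelic and %d non-SNP records",
                 path, n_multi, n_indel)
    sites = pd.DataFrame({"contig": contigs, "pos": poss, "ref": refs, "alt": alts})
    dosage = (np.vstack(rows).T if rows
              else np.empty((len(samples), 0), dtype=np.int8))
    g = GenotypeMatrix(samples=samples, sites=sites, dosage=dosage,
                       phased=phased_all)
    g.excluded = {"multiallelic": n_multi, "non_snp": n_indel}
    return g


def read_phased_haplotypes(path) -> HaplotypeSet:
    """Read a fully phased VCF into a :class:`HaplotypeSet`.

    Every genotype must be phased and called; use :func:`read_vcf` +
    :func:`filter_sites` for matrices with missing data.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path), gts012=False)
    samples = list(vcf.samples)
    contigs, poss, refs, alts, cols = [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            continue
        col = np.empty((len(samples), 2), dtype=np.uint8)
        for j, gt in enumerate(rec.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[2]
            if a0 < 0 or a1 < 0 or not phased:
                raise GenioError(
                    f"{path} {rec.CHROM}:{rec.POS} sample {samples[j]}: "
                    "unphased or missing genotype")
            col[j] = (a0, a1)
        cols.append(col)
        contigs.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    sites = pd.DataFrame({"contig": contigs, "pos": poss,
                          "ref": refs, "alt": alts})
    haps = (np.stack(cols, axis=2) if cols
            else np.empty((len(samples), 2, 0), dtype=np.uint8))
    return HaplotypeSet(samples=samples, sites=sites, haps=haps)


def write_vcf(obj, path) -> None:
    """Write a :class:`HaplotypeSet` (phased ``a|b``) or :class:`GenotypeMatrix`.

    An empty site list still produces a valid header-only VCF (with a warning).
    """
    if isinstance(obj, HaplotypeSet):
        samples, sites = obj.samples, obj.sites
        haps = obj.haps
        def gt(i, s):
            return f"{haps[i, 0, s]}|{haps[i, 1, s]}"
    else:
        samples, sites = obj.samples, obj.sites
        dos = obj.dosage
        codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        def gt(i, s):
            return codes[int(dos[i, s])]
    if len(sites) == 0:
        log.warning("write_vcf %s: no polymorphic sites, writing header only", path)
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in dict.fromkeys(sites["contig"]):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for s, row in enumerate(sites.itertuples()):
            cols = [row.contig, str(row.pos), ".", row.ref, row.alt,
                    ".", "PASS", ".", "GT"]
            cols += [gt(i, s) for i in range(len(samples))]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

class FilterResult(NamedTuple):
    matrix: GenotypeMatrix
    n_input: int
    n_removed_missing: int
    n_removed_monomorphic: int

    @property
    def n_retained(self) -> int:
        return self.matrix.n_sites


def filter_sites(g: GenotypeMatrix, require_complete: bool = True,
                 require_polymorphic: bool = True) -> FilterResult:
    """Apply the final genotype-level site filters.

    With both flags on (the default), a retained site has a genotype call in
    every sample and both alleles observed — the complete-data polymorphic
    matrix that all downstream statistics assume. Idempotent.
    """
    keep = np.ones(g.n_sites, dtype=bool)
    n_missing = n_mono = 0
    if require_complete:
        complete = ~(g.missing_mask().any(axis=0))
        n_missing = int((~complete & keep).sum())
        keep &= complete
    if require_polymorphic:
        d = np.where(g.dosage >= 0, g.dosage, 0)
        obs = (g.dosage >= 0).sum(axis=0)
        alt = d.sum(axis=0)
        poly = (alt > 0) & (alt < 2 * obs) & (obs > 0)
        n_mono = int((~poly & keep).sum())
        keep &= poly
    out = g.take_sites(keep)
    log.info("filter_sites: %d -> %d sites (%d missing-genotype, %d monomorphic removed)",
             g.n_sites, out.n_sites, n_missing, n_mono)
    if out.n_sites == 0:
        log.warning("filter_sites: no sites retained")
    return FilterResult(out, g.n_sites, n_missing, n_mono)


# ---------------------------------------------------------------------------
# FASTA / GFF3 / tables
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict, path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gff_cds(path, seqs: dict) -> AnnotatedGenome:
    """Read CDS features from GFF3 (1-based inclusive) into an AnnotatedGenome.

    Genes whose spliced CDS length is not a multiple of 3 after the frame
    adjustment are flagged and excluded from coding analyses.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise GenioError(f"{path}:{lineno}: expected 9 GFF columns, got {len(f)}")
            if f[2] != "CDS":
                continue
            contig, start, end, strand, frame = f[0], int(f[3]), int(f[4]), f[6], f[7]
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gene = attrs.get("Parent") or attrs.get("gene_id") or attrs.get("ID")
            if gene is None:
                raise GenioError(f"{path}:{lineno}: CDS without Parent/gene_id/ID")
            if contig not in seqs:
                raise GenioError(f"{path}:{lineno}: unknown contig {contig!r}")
            if not (1 <= start <= end <= len(seqs[contig])):
                raise GenioError(f"{path}:{lineno}: CDS outside contig bounds")
            rows.append({"gene_id": gene, "contig": contig,
                         "start": start - 1, "end": end, "strand": strand,
                         "frame": 0 if frame == "." else int(frame)})
    cds = pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end",
                                      "strand", "frame"])
    genome = AnnotatedGenome(seqs=seqs, cds=cds)
    bad = []
    for gene in genome.genes():
        if len(genome.coding_sequence(gene)) % 3 != 0:
            bad.append(gene)
    if bad:
        log.warning("read_gff_cds: excluding %d genes with CDS length not "
                    "divisible by 3: %s", len(bad), bad)
        genome = AnnotatedGenome(seqs=seqs,
                                 cds=cds[~cds["gene_id"].isin(bad)].reset_index(drop=True))
        genome.flagged_genes = bad
    return genome


def write_gff_cds(genome: AnnotatedGenome, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for r in genome.cds.itertuples():
            attrs = f"ID=cds_{r.gene_id};Parent={r.gene_id}"
            fh.write("\t".join([r.contig, "clonalsig", "CDS", str(r.start + 1),
                                str(r.end), ".", r.strand, str(r.frame), attrs]) + "\n")


def read_tables(pop_path, coord_path=None,
                samples: Iterable[str] | None = None) -> PopulationHierarchy:
    """Read the individual/population/group table and optional coordinates."""
    tab = pd.read_csv(pop_path, sep="\t")
    need = {"individual", "population", "group"}
    if not need.issubset(tab.columns):
        raise GenioError(f"population table must have columns {sorted(need)}")
    pop_of = dict(zip(tab["individual"], tab["population"]))
    group_of = dict(zip(tab["population"], tab["group"]))
    coords = {}
    if coord_path is not None:
        ct = pd.read_csv(coord_path, sep="\t")
        if not {"population", "lat", "lon"}.issubset(ct.columns):
            raise GenioError("coordinates table must have columns population, lat, lon")
        coords = {r.population: (float(r.lat), float(r.lon)) for r in ct.itertuples()}
    h = PopulationHierarchy(pop_of=pop_of, group_of=group_of, coords=coords)
    if samples is not None:
        h.validate(list(samples))
    return h


def write_tables(h: PopulationHierarchy, pop_path, coord_path=None) -> None:
    pd.DataFrame(
        {"individual": list(h.pop_of), "population": list(h.pop_of.values()),
         "group": [h.group_of[p] for p in h.pop_of.values()]}
    ).to_csv(pop_path, sep="\t", index=False)
    if coord_path is not None:
        pd.DataFrame(
            [{"population": p, "lat": c[0], "lon": c[1]} for p, c in h.coords.items()]
        ).to_csv(coord_path, sep="\t", index=False)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    with _open_text(path, "wt") as fh:
        json.dump(obj, fh, indent=1, default=default)
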