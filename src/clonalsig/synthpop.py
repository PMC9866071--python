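"""Forward-in-time simulator of partially clonal diploid populations.

Simulates discrete Wright–Fisher generations for a hierarchically structured
set of populations (groups -> populations -> diploid individuals).  Each
offspring is produced clonally (both haplotypes copied from one parent) with
probability ``clonality``, otherwise sexually from two distinct parents, each
transmitting a recombinant gamete (Poisson crossovers per contig, uniform
breakpoints; recombination never crosses contig boundaries).  Mutation follows
an infinite-sites approximation on the finite base-pair grid: each new
mutation takes a previously unused position, so every site stays biallelic.

Founder modes
-------------
``panmictic``
    Founder haplotypes are drawn (without replacement) from a single
    neutral-coalescent pool, so generation 0 is at Hardy–Weinberg proportions.
``hybrid``
    Two diverged founder pools; every founder individual receives one
    haplotype from each pool, emulating an asexual lineage founded by
    interspecific hybridisation (fixed inter-pool differences at rate
    ``founder_divergence`` per bp, plus within-pool coalescent variation).
``meselson``
    The whole metapopulation descends from a single homozygous founder
    individual; under strict clonality the two haplotypes of the lineage then
    diverge independently (the Meselson effect).

The genome carries a reference sequence with non-overlapping CDS genes
(stop-free internal codons, terminal stop), so codon-degeneracy and
premature-stop analyses can run on the fixtures with known truth.

Selection is not simulated; coding-site statistics on these fixtures validate
the computation, not an evolutionary recovery.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genio
from .genio import (AnnotatedGenome, GenotypeMatrix, HaplotypeSet,
                    PopulationHierarchy)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SimulationError(ValueError):
    """Raised for degenerate configurations or empty simulation output."""


@dataclass
class SimConfig:
    """Parameters of one simulation run.

    Defaults mirror the sampling design of the motivating study system —
    60 diploid individuals in 12 populations nested in 3 groups (3/5/4
    populations of 5 individuals) — on a genome scaled down to keep a full
    run in the seconds range; rates are per bp per generation.
    """

    n_groups: int = 3
    pops_per_group: tuple = (3, 5, 4)
    individuals_per_pop: int = 5
    genome_length: int = 500_000
    n_contigs: int = 20
    mu: float = 1e-7
    rec_rate: float = 1e-7
    clonality: float = 0.99
    generations: int = 40
    founder_mode: str = "hybrid"
    founder_divergence: float = 0.005
    founder_diversity: float = 0.002
    cds_fraction: float = 0.2
    gene_length: int = 300
    pop_split_gen: int | None = None   # generations before present; default generations // 2
    migration_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_groups < 1:
            raise SimulationError("n_groups must be >= 1")
        if len(self.pops_per_group) != self.n_groups:
            raise SimulationError("pops_per_group length must equal n_groups")
        if self.individuals_per_pop < 1:
            raise SimulationError("individuals_per_pop must be >= 1")
        if self.n_contigs < 1 or self.genome_length < self.n_contigs:
            raise SimulationError("genome_length must be >= n_contigs >= 1")
        for name in ("mu", "rec_rate", "founder_divergence", "founder_diversity",
                     "migration_rate", "cds_fraction"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not 0.0 <= self.clonality <= 1.0:
            raise SimulationError("clonality must be in [0, 1]")
        if self.generations < 0:
            raise SimulationError("generations must be >= 0")
        if self.founder_mode not in ("panmictic", "hybrid", "meselson"):
            raise SimulationError(f"unknown founder_mode {self.founder_mode!r}")
        if self.gene_length % 3 != 0 or self.gene_length < 9:
            raise SimulationError("gene_length must be a multiple of 3 and >= 9")


@dataclass
class SimTruth:
    """Ground-truth metadata emitted alongside the simulated data."""

    founder_pool_of_haplotype: dict      # "sample_k" -> "A" | "B" | "M" (recombined)
    clone_lineage: dict                  # sample -> founder lineage id
    reproduction_log: list               # per generation: {"clonal": n, "sexual": n}
    degeneracy: pd.DataFrame             # per CDS site: contig, pos, gene_id, fold
    true_phase: HaplotypeSet | None = None
    config: SimConfig | None = None


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _random_codon(rng) -> str:
    while True:
        codon = "".join(rng.choice(_BASES, 3))
        if codon not in _STOPS:
            return codon


def _build_genome(rng, cfg: SimConfig) -> AnnotatedGenome:
    contig_len = cfg.genome_length // cfg.n_contigs
    seqs, rows = {}, []
    genes_per_contig = int(cfg.cds_fraction * contig_len / cfg.gene_length)
    gene_no = 0
    for ci in range(cfg.n_contigs):
        name = f"contig{ci + 1:03d}"
        seq = rng.choice(_BASES, contig_len)
        if genes_per_contig > 0:
            spacing = contig_len // genes_per_contig
            for gi in range(genes_per_contig):
                start = gi * spacing + (spacing - cfg.gene_length) // 2
                if start < 0 or start + cfg.gene_length > contig_len:
                    continue
                gene_no += 1
                gene_id = f"gene{gene_no:04d}"
                strand = "+" if gene_no % 2 else "-"
                n_codons = cfg.gene_length // 3
                coding = "".join(_random_codon(rng) for _ in range(n_codons - 1))
                coding += ["TAA", "TAG", "TGA"][int(rng.integers(3))]
                if strand == "-":
                    placed = "".join(_COMP[b] for b in reversed(coding))
                else:
                    placed = coding
                seq[start:start + cfg.gene_length] = list(placed)
                rows.append({"gene_id": gene_id, "contig": name, "start": start,
                             "end": start + cfg.gene_length, "strand": strand,
                             "frame": 0})
        seqs[name] = "".join(seq)
    cds = pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end",
                                      "strand", "frame"])
    return AnnotatedGenome(seqs=seqs, cds=cds)


# ---------------------------------------------------------------------------
# founder pools: neutral coalescent haplotypes
# ---------------------------------------------------------------------------

def _coalescent_mutations(rng, n_hap: int, n_mut: int) -> np.ndarray:
    """(n_hap, n_mut) 0/1 matrix: mutations dropped on a Kingman genealogy."""
    if n_mut == 0 or n_hap < 2:
        return np.zeros((n_hap, max(n_mut, 0)), dtype=np.uint8)
    lineages = [frozenset([i]) for i in range(n_hap)]
    start = {l: 0.0 for l in lineages}
    t = 0.0
    branches, lengths = [], []
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        for l in (a, b):
            branches.append(l)
            lengths.append(t - start[l])
        merged = a | b
        lineages = [l for l in lineages if l is not a and l is not b] + [merged]
        start[merged] = t
    lengths = np.array(lengths)
    picks = rng.choice(len(branches), size=n_mut, p=lengths / lengths.sum())
    out = np.zeros((n_hap, n_mut), dtype=np.uint8)
    for m, bi in enumerate(picks):
        out[list(branches[bi]), m] = 1
    return out


def _founder_pool(rng, n_hap, contig_len, diversity) -> tuple:
    """Haplotype pool for one contig: (matrix, positions within contig)."""
    a_n = sum(1.0 / i for i in range(1, n_hap)) if n_hap > 1 else 0.0
    n_mut = rng.poisson(diversity * contig_len * a_n)
    n_mut = min(n_mut, contig_len)
    pos = rng.choice(contig_len, size=n_mut, replace=False)
    return _coalescent_mutations(rng, n_hap, n_mut), pos


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def _names(cfg: SimConfig):
    groups, pops, samples, pop_of, group_of = [], [], [], {}, {}
    pop_no = 0
    for gi in range(cfg.n_groups):
        gname = f"grp{gi + 1}"
        groups.append(gname)
        for _ in range(cfg.pops_per_group[gi]):
            pop_no += 1
            pname = f"pop{pop_no:02d}"
            pops.append(pname)
            group_of[pname] = gname
            for k in range(cfg.individuals_per_pop):
                sname = f"{pname}_i{k + 1}"
                samples.append(sname)
                pop_of[sname] = pname
    return groups, pops, samples, pop_of, group_of


def _coords(rng, cfg: SimConfig, pops, group_of) -> dict:
    centers = {}
    for gi, g in enumerate(dict.fromkeys(group_of.values())):
        centers[g] = (28.0 + 3.0 * gi, 98.0 + 3.0 * gi)
    out = {}
    for p in pops:
        lat0, lon0 = centers[group_of[p]]
        out[p] = (lat0 + rng.uniform(-0.8, 0.8), lon0 + rng.uniform(-0.8, 0.8))
    return out


def simulate(cfg: SimConfig):
    """Run the forward simulation.

    Returns ``(GenotypeMatrix, HaplotypeSet, AnnotatedGenome,
    PopulationHierarchy, SimTruth)``.  Only sites polymorphic in the final
    sample are emitted, sorted by contig and position; the run is
    deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome = _build_genome(rng, cfg)
    contig_len = cfg.genome_length // cfg.n_contigs
    contig_names = list(genome.seqs)

    groups, pops, samples, pop_of, group_of = _names(cfg)
    n_ind = len(samples)
    n_hap = 2 * n_ind

    # deme partitions: one deme per group early, one per population late
    pop_index = {p: i for i, p in enumerate(pops)}
    group_index = {g: i for i, g in enumerate(groups)}
    deme_pop = np.array([pop_index[pop_of[s]] for s in samples])
    deme_group = np.array([group_index[group_of[pop_of[s]]] for s in samples])
    split = cfg.generations // 2 if cfg.pop_split_gen is None else cfg.pop_split_gen

    # --- founders -----------------------------------------------------------
    site_contig, site_pos, columns = [], [], []
    used = set()
    pool_label = np.full(n_hap, "M", dtype="<U1")
    if cfg.founder_mode == "panmictic":
        for ci in range(cfg.n_contigs):
            mat, pos = _founder_pool(rng, n_hap, contig_len, cfg.founder_diversity)
            order = rng.permutation(n_hap)
            columns.append(mat[order])
            site_contig.extend([ci] * len(pos))
            site_pos.extend(pos.tolist())
            used.update((ci, int(p)) for p in pos)
        pool_label[:] = "M"
    elif cfg.founder_mode == "hybrid":
        for ci in range(cfg.n_contigs):
            block_cols = []
            matA, posA = _founder_pool(rng, n_ind, contig_len, cfg.founder_diversity)
            matB, posB = _founder_pool(rng, n_ind, contig_len, cfg.founder_diversity)
            # within-pool variation
            for mat, pos, which in ((matA, posA, 0), (matB, posB, 1)):
                pos = np.array([p for p in pos if (ci, int(p)) not in used],
                               dtype=int)[:mat.shape[1]]
                mat = mat[:, :len(pos)]
                full = np.zeros((n_hap, mat.shape[1]), dtype=np.uint8)
                full[which::2] = mat[rng.permutation(n_ind)]
                block_cols.append(full)
                site_contig.extend([ci] * len(pos))
                site_pos.extend(pos.tolist())
                used.update((ci, int(p)) for p in pos)
            # fixed inter-pool divergence: pool B carries the alternate allele
            n_div = min(rng.poisson(cfg.founder_divergence * contig_len), contig_len)
            free = [p for p in rng.permutation(contig_len)[:3 * n_div]
                    if (ci, int(p)) not in used][:n_div]
            div = np.zeros((n_hap, len(free)), dtype=np.uint8)
            div[1::2] = 1
            block_cols.append(div)
            site_contig.extend([ci] * len(free))
            site_pos.extend(int(p) for p in free)
            used.update((ci, int(p)) for p in free)
            columns.extend(block_cols)
        pool_label[0::2] = "A"
        pool_label[1::2] = "B"
    else:  # meselson: a single homozygous founder individual, cloned
        pool_label[0::2] = "A"
        pool_label[1::2] = "B"

    S = len(site_pos)
    H = (np.concatenate(columns, axis=1) if columns
         else np.zeros((n_hap, 0), dtype=np.uint8))
    site_contig = np.array(site_contig, dtype=np.int64)
    site_pos = np.array(site_pos, dtype=np.int64)

    lineage = np.arange(n_ind) if cfg.founder_mode != "meselson" else np.zeros(n_ind, int)
    rep_log = []

    # --- generations --------------------------------------------------------
    mean_mut = 2 * n_ind * cfg.mu * cfg.genome_length
    for gen in range(cfg.generations):
        demes = deme_group if gen < cfg.generations - split else deme_pop
        members = {d: np.flatnonzero(demes == d) for d in np.unique(demes)}
        newH = np.empty_like(H)
        new_label = np.empty_like(pool_label)
        new_lineage = np.empty_like(lineage)
        per_contig = [np.flatnonzero(site_contig == ci) for ci in range(cfg.n_contigs)]
        n_clonal = 0
        for i in range(n_ind):
            cand = members[demes[i]]
            if cfg.migration_rate > 0 and rng.random() < cfg.migration_rate:
                other = rng.integers(len(members))
                cand = members[list(members)[other]]
            if rng.random() < cfg.clonality:
                p = int(cand[rng.integers(len(cand))])
                newH[2 * i] = H[2 * p]
                newH[2 * i + 1] = H[2 * p + 1]
                new_label[2 * i] = pool_label[2 * p]
                new_label[2 * i + 1] = pool_label[2 * p + 1]
                new_lineage[i] = lineage[p]
                n_clonal += 1
            else:
                if len(cand) < 2:
                    pa = pb = int(cand[0])
                else:
                    pa, pb = (int(x) for x in rng.choice(cand, 2, replace=False))
                for k, par in ((0, pa), (1, pb)):
                    gam, lab = _gamete(H, pool_label, par, per_contig, site_pos,
                                       contig_len, cfg.rec_rate, rng)
                    newH[2 * i + k] = gam
                    new_label[2 * i + k] = lab
                new_lineage[i] = n_ind + gen * n_ind + i  # fresh lineage id
        H, pool_label, lineage = newH, new_label, new_lineage
        rep_log.append({"clonal": n_clonal, "sexual": n_ind - n_clonal})
        # new mutations, infinite-sites on the bp grid
        n_mut = rng.poisson(mean_mut)
        if n_mut:
            add_c, add_p, add_row = [], [], []
            for _ in range(n_mut):
                for _try in range(50):
                    ci = int(rng.integers(cfg.n_contigs))
                    p = int(rng.integers(contig_len))
                    if (ci, p) not in used:
                        used.add((ci, p))
                        add_c.append(ci)
                        add_p.append(p)
                        add_row.append(int(rng.integers(n_hap)))
                        break
            if add_c:
                block = np.zeros((n_hap, len(add_c)), dtype=np.uint8)
                block[add_row, np.arange(len(add_c))] = 1
                H = np.concatenate([H, block], axis=1)
                site_contig = np.concatenate([site_contig, add_c])
                site_pos = np.concatenate([site_pos, add_p])

    # --- finalize -----------------------------------------------------------
    counts = H.sum(axis=0)
    keep = (counts > 0) & (counts < n_hap)
    H, site_contig, site_pos = H[:, keep], site_contig[keep], site_pos[keep]
    if H.shape[1] == 0:
        raise SimulationError(
            "simulation produced 0 polymorphic sites; increase mu, generations "
            "or founder_diversity")
    order = np.lexsort((site_pos, site_contig))
    H, site_contig, site_pos = H[:, order], site_contig[order], site_pos[order]

    refs = np.array([genome.seqs[contig_names[c]][p]
                     for c, p in zip(site_contig, site_pos)])
    alts = np.array([_BASES[(list("ACGT").index(r) + 1 + int(k)) % 4]
                     for r, k in zip(refs, rng.integers(0, 3, size=len(refs)))])
    sites = pd.DataFrame({
        "contig": [contig_names[c] for c in site_contig],
        "pos": site_pos + 1, "ref": refs, "alt": alts})

    hap = HaplotypeSet(samples=samples, sites=sites,
                       haps=H.reshape(n_ind, 2, -1))
    g = hap.to_genotype_matrix()
    hierarchy = PopulationHierarchy(
        pop_of=pop_of, group_of=group_of,
        coords=_coords(rng, cfg, pops, group_of))

    from .coding import classify_degeneracy
    truth = SimTruth(
        founder_pool_of_haplotype={f"{s}_{k}": pool_label[2 * i + k]
                                   for i, s in enumerate(samples) for k in (0, 1)},
        clone_lineage={s: int(lineage[i]) for i, s in enumerate(samples)},
        reproduction_log=rep_log,
        degeneracy=classify_degeneracy(genome).table,
        true_phase=hap, config=cfg)
    return g, hap, genome, hierarchy, truth


def _gamete(H, pool_label, parent, per_contig, site_pos, contig_len, rec_rate, rng):
    """One recombinant gamete from a diploid parent; contigs assort freely."""
    r0, r1 = 2 * parent, 2 * parent + 1
    out = np.empty(H.shape[1], dtype=np.uint8)
    labels = set()
    for idx in per_contig:
        k = rng.poisson(rec_rate * contig_len)
        start = int(rng.integers(2))
        if k == 0 or len(idx) == 0:
            src = r0 if start == 0 else r1
            out[idx] = H[src, idx]
            labels.add(pool_label[src])
        else:
            bps = np.sort(rng.integers(0, contig_len, size=k))
            seg = (np.searchsorted(bps, site_pos[idx], side="right") + start) % 2
            out[idx] = np.where(seg == 0, H[r0, idx], H[r1, idx])
            labels.update((pool_label[r0], pool_label[r1]))
    lab = labels.pop() if len(labels) == 1 else "M"
    return out, lab


# ---------------------------------------------------------------------------
# fixture helpers
# ---------------------------------------------------------------------------

def write_fixture(out_dir, g: GenotypeMatrix, hap: HaplotypeSet | None,
                  genome: AnnotatedGenome, hierarchy: PopulationHierarchy,
                  truth: SimTruth | None = None) -> dict:
    """Write a simulated data set to disk in the standard formats.

    Emits phased VCF (from the haplotypes when available), reference FASTA,
    GFF3 CDS annotation, population and coordinate tables, and a JSON truth
    sidecar. Returns the path map.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "sim.vcf"),
        "fasta": os.path.join(out_dir, "reference.fa"),
        "gff": os.path.join(out_dir, "annotation.gff3"),
        "pops": os.path.join(out_dir, "populations.tsv"),
        "coords": os.path.join(out_dir, "coordinates.tsv"),
    }
    genio.write_vcf(hap if hap is not None else g, paths["vcf"])
    genio.write_fasta(genome.seqs, paths["fasta"])
    genio.write_gff_cds(genome, paths["gff"])
    genio.write_tables(hierarchy, paths["pops"], paths["coords"])
    if truth is not None:
        paths["truth"] = os.path.join(out_dir, "truth.json")
        genio.write_json(
            {"founder_pool_of_haplotype": truth.founder_pool_of_haplotype,
             "clone_lineage": truth.clone_lineage,
             "reproduction_log": truth.reproduction_log,
             "config": dataclasses.asdict(truth.config) if truth.config else None},
            paths["truth"])
    return paths


def inject_premature_stop(genome: AnnotatedGenome, hap: HaplotypeSet,
                          gene_id: str, carriers: list) -> HaplotypeSet:
    """Add one SNP that converts an internal codon of ``gene_id`` to a stop.

    The alternate allele is placed on haplotype 0 of every carrier
    individual; everyone else keeps the reference allele.  Fails explicitly
    if no internal codon can reach a stop by a single substitution, or if
    ``carriers`` is empty.
    """
    if not carriers:
        raise SimulationError("carrier set must not be empty")
    unknown = [c for c in carriers if c not in hap.samples]
    if unknown:
        raise SimulationError(f"unknown carrier individuals: {unknown}")
    coding = genome.coding_sequence(gene_id)
    site_index = genome.cds_site_index(gene_id)
    strand = genome.gene_rows(gene_id)["strand"].iloc[0]
    n_codons = len(coding) // 3
    if n_codons < 3:
        raise SimulationError(f"gene {gene_id} has fewer than 2 internal codons")
    taken = set(zip(hap.sites["contig"], hap.sites["pos"] - 1))
    for codon_i in range(n_codons - 1):          # exclude the terminal codon
        codon = coding[3 * codon_i: 3 * codon_i + 3]
        for off in range(3):
            for alt in "ACGT":
                if alt == codon[off]:
                    continue
                mutated = codon[:off] + alt + codon[off + 1:]
                if mutated in _STOPS:
                    contig, gpos, _ = site_index[3 * codon_i + off]
                    if (contig, gpos) in taken:
                        continue
                    ref_base = genome.seqs[contig][gpos]
                    alt_base = alt if strand == "+" else _COMP[alt]
                    return _insert_site(hap, contig, gpos, ref_base, alt_base,
                                        carriers)
    raise SimulationError(f"gene {gene_id} has no SNV-reachable internal stop codon")


def _insert_site(hap: HaplotypeSet, contig, gpos0, ref, alt, carriers):
    sites = hap.sites
    new_row = pd.DataFrame([{"contig": contig, "pos": gpos0 + 1,
                             "ref": ref, "alt": alt}])
    key = pd.concat([sites, new_row], ignore_index=True)
    order = np.lexsort((key["pos"].to_numpy(), key["contig"].to_numpy()))
    new_sites = key.iloc[order].reset_index(drop=True)
    col = np.zeros((hap.n_samples, 2, 1), dtype=np.uint8)
    for c in carriers:
        col[hap.samples.index(c), 0, 0] = 1
    haps = np.concatenate([hap.haps, col], axis=2)[:, :, order]
    return HaplotypeSet(samples=list(hap.samples), sites=new_sites, haps=haps)


def expand_clones(hap: HaplotypeSet, plan: dict, seed: int = 0,
                  noise_mutations: float = 0.0,
                  genome: AnnotatedGenome | None = None) -> HaplotypeSet:
    """Expand individuals into clone-mate copies (for planted-lineage fixtures).

    ``plan`` maps a source sample to the list of names of its clonal copies.
    Each copy optionally receives ``Poisson(noise_mutations)`` private
    mutations at fresh positions (requires ``genome`` for reference alleles).
    """
    rng = np.random.default_rng(seed)
    names, rows = [], []
    extra = []  # (copy_index, contig, pos0, ref, alt)
    used = set(zip(hap.sites["contig"], hap.sites["pos"] - 1))
    for src, copies in plan.items():
        si = hap.samples.index(src)
        for name in copies:
            names.append(name)
            rows.append(hap.haps[si].copy())
            if noise_mutations > 0:
                if genome is None:
                    raise SimulationError("noise mutations require a genome")
                contigs = list(genome.seqs)
                for _ in range(rng.poisson(noise_mutations)):
                    for _try in range(100):
                        c = contigs[rng.integers(len(contigs))]
                        p = int(rng.integers(len(genome.seqs[c])))
                        if (c, p) not in used:
                            used.add((c, p))
                            ref = genome.seqs[c][p]
                            alt = _BASES[(list("ACGT").index(ref) + 1) % 4]
                            extra.append((len(names) - 1, c, p, ref, alt))
                            break
    haps = np.stack(rows)
    sites = hap.sites.copy()
    if extra:
        add = pd.DataFrame([{"contig": c, "pos": p + 1, "ref": r, "alt": a}
                            for (_, c, p, r, a) in extra])
        block = np.zeros((len(names), 2, len(extra)), dtype=np.uint8)
        for j, (i, *_rest) in enumerate(extra):
            block[i, int(rng.integers(2)), j] = 1
        sites = pd.concat([sites, add], ignore_index=True)
        haps = np.concatenate([haps, block], axis=2)
        order = np.lexsort((sites["pos"].to_numpy(), sites["contig"].to_numpy()))
        sites = sites.iloc[order].reset_index(drop=True)
        haps = haps[:, :, order]
    return HaplotypeSet(samples=names, sites=sites, haps=haps)


def plant_differentiated_sites(g: GenotypeMatrix, h: PopulationHierarchy,
                               n_sites: int, high_pops: list,
                               seed: int = 0):
    """Overwrite ``n_sites`` random sites with fixed differences between
    ``high_pops`` and the remaining populations; returns (matrix, site indices).
    """
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(g.n_sites, size=n_sites, replace=False))
    d = g.dosage.copy()
    hi = np.array([h.pop_of[s] in set(high_pops) for s in g.samples])
    d[np.ix_(hi, idx)] = 2
    d[np.ix_(~hi, idx)] = 0
    out = GenotypeMatrix(samples=list(g.samples), sites=g.sites.copy(),
                         dosage=d, phased=g.phased.copy())
    return out, idx
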