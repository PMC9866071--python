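# Methods

`clonalsig` implements the population-genomic signature battery used to ask
whether a putatively strictly asexual diploid plant — the motivating system
is *Kingdonia uniflora*, a monotypic alpine herb that propagates by rhizome
rupture — is an ancient clonal lineage, a recent hybrid, or a cryptic
sexual. Every statistic is driven by a forward simulator so that each stage
can be validated against planted truth without the original resequencing
data.

## The discrimination logic

Three hypotheses leave distinct fingerprints in a multi-sample SNP matrix:

| signal | long-term clonality (Meselson effect) | hybrid origin + clonality | sexual reproduction |
|---|---|---|---|
| per-individual F_IS = 1 − H_obs/H_exp | strongly negative | strongly negative | ≈ 0 |
| heterozygote sharing across populations | high, post-divergence | high, pre-divergence | ≈ HWE |
| haplotype A/B NJ trees | mirrored (RF ≈ 0) | discordant | discordant |
| LD decay with distance | flat | flat | decaying |
| PHI recombination test | n.s. | n.s. (unless rare sex) | significant |
| π0/π4 | elevated | elevated | ~0.2–0.35 |

The package computes every row of this table; the `analysis/` scripts walk
through them on a three-scenario fixture panel.

## Forward simulator (`synthpop`)

Discrete Wright–Fisher generations over a metapopulation whose deme
partition follows the study's sampling design (default 3 groups of 3/5/4
populations, 5 diploids each, 60 individuals). Each offspring is clonal
with probability `clonality` (both haplotypes copied from one parent) and
sexual otherwise (two distinct parents, each transmitting a gamete with
Poisson(`rec_rate` × contig length) crossovers at uniform breakpoints;
contigs assort freely and recombination never crosses them). Mutation is
infinite-sites on the bp grid (collisions resampled), keeping all sites
biallelic. Groups descend from a common founder sample; populations split
from their group deme `pop_split_gen` generations before the present
(default `generations/2`), with no subsequent migration unless
`migration_rate > 0`.

Founder standing variation comes from a per-contig Kingman-coalescent pool
sampler (random topology with exponential waiting times, mutations placed
proportional to branch length), scaled so the pool's pairwise diversity per
bp ≈ `founder_diversity`. Founder modes:

- `panmictic` — haplotypes drawn without replacement from one pool;
  generation 0 is at Hardy–Weinberg proportions.
- `hybrid` — two independent pools plus fixed inter-pool differences at
  rate `founder_divergence` per bp; every founder receives one haplotype
  from each pool (asexuality founded by interspecific hybridisation).
- `meselson` — the whole metapopulation starts as copies of a single
  homozygous individual; under strict clonality its two haplotypes then
  diverge independently along the shared clone pedigree.

The genome carries a reference sequence with non-overlapping 300-bp CDS
genes (stop-free internal codons, terminal stop, alternating strands) at
density `cds_fraction`, so degeneracy classes and premature stops are fully
known. Truth metadata records founder-pool labels per haplotype (clonal
copying preserves them; any recombined gamete becomes "mixed"), clone
lineage ids, the clonal/sexual birth log, and the degeneracy map.

Defaults emulate the study design; the genome (500 kb, 20 contigs; test
fixtures 60–700 kb) is deliberately scaled so a full run takes seconds —
statistics, not genome size, are the object under test. `clonality = 0.99`
reflects a plant that reproduces by rhizome fragmentation with at most rare,
cryptic sex. Selection is never simulated: π0/π4 on fixtures validates the
computation (ratio ≈ 1 under neutrality), not an evolutionary recovery.

Two properties of the simulator worth knowing before interpreting fixtures:

- **Tiny demes coalesce fast.** With 2N gene copies, k lineages coalesce at
  rate k(k−1)/(4N) per generation; a 5-diploid population loses most of its
  lineage diversity within a few generations. This produces realistic
  clone-mate structure (and strong drift differentiation) but means
  "panmictic control" fixtures should use a single unsplit deme
  (`pop_split_gen=0`), otherwise the Wahlund effect dominates F_IS.
- **Post-founding clonality makes haplotype trees concordant.** Once a
  hybrid population reproduces clonally, both haplotypes of a lineage travel
  through the same pedigree, so A- and B-trees converge on the clone
  genealogy. The hybrid-origin discordance signal lives in the independent
  founder-pool genealogies and is sharpest at founding; the mirrored-tree
  (Meselson) signal requires deep, well-separated clonal branches.

## Statistics

**F_IS (`diversity.individual_fis`).** H_exp at a site is 2p(1−p) with p
the whole-sample alternate-allele frequency (a per-population option
exists); per-individual means over non-missing sites; F_IS = 1 −
H_obs/H_exp. The plug-in H_exp carries a small finite-sample bias
(E[F_IS] ≈ −1/(2n−1) under HWE), which is part of the definition as used
with standard VCF tooling and is well inside the acceptance bands.

**π (`diversity.nucleotide_diversity`).** Per site 2p(1−p)·2n/(2n−1) — the
unbiased mean pairwise difference among gene copies — averaged over sites;
also summed per contig. Equals the all-pairs Hamming oracle exactly on
complete data.

**Heterozygote-sharing SFS (`diversity.het_sharing_sfs`).** Per site, the
folded minor-allele count and the number of heterozygous individuals in the
scored subset. Expected class counts under HWE treat individuals as
exchangeable and sites as independent: Σ_sites Binom(N, 2p(1−p)).pmf(k).
p is estimated from the *full* matrix even when a subset is scored; using
the subset's own p̂ inflates the expectation of the extreme classes
(conditioning bias). The observed/expected ratio of the all-heterozygous
class is the headline number: ≈ 1 under panmixia (only when aggregated over
replicates — the all-het event is rare and linked sites fire together, so
single-replicate ratios are overdispersed), and orders of magnitude above 1
under clonal/hybrid heterozygosity excess.

**Weir–Cockerham F_ST (`structure.wc_fst`).** Per-site variance components
a/b/c for diploids with observed heterozygote counts, transcribed from the
1984 estimator; multi-locus θ is the ratio of averages Σa/Σ(a+b+c) (never
the average of ratios). Pairwise matrices restrict the sample to each pair.
Note the estimator's small-sample behaviour: two demes with *identical*
genotype counts give θ < 0 of order −1/(n̄−1), not 0.

**AMOVA (`structure.amova`).** Distances are allele-difference counts
between the 2N phased gene copies (the within-individual level requires
copies). SS decompose by nesting (total/within-group/within-population/
within-individual); variance components solve the expected-mean-square
system with unequal-size coefficients, exposed separately as
`amova_components` so the published worked example is testable from its
printed sums of squares alone. Negative components are reported as
computed. Permutation p-values per level: populations among groups;
individuals among populations within groups; gene copies among individuals
within populations; gene copies among all individuals (lower tail for the
within-individual component, which shrinks under structure).

**Mantel IBD (`structure.mantel_ibd`).** F_ST/(1−F_ST) against great-circle
distance (mean-radius sphere, 6371.0088 km); Pearson r on upper triangles;
upper-tail permutation p with the (count+1)/(n_perm+1) correction. With m
labels only m! distinct permutations exist, so small designs cannot reach
small p.

**Genotypic groups (`structure.mds_genotypic_groups`).** IBS distance
(mean per-site |dosage_i − dosage_j|/2), classical scaling (PCoA) for
display, and single-linkage clusters within each population at threshold
`epsilon` (default 0.03: clone mates differ by a handful of somatic
mutations, i.e. IBS ≲ 0.005 on typical fixtures, while distinct genotypes
sit an order of magnitude higher; the default lives in the gap). One
representative per group (lowest sample id, for determinism) feeds π0/π4.

**Outlier scan (`structure.fst_outlier_scan`).** Per-site θ against a null
built by permuting individuals among populations (sizes preserved), pooled
across sites and permutations; upper-tail p with +1 correction;
Benjamini–Hochberg q; flag at q < 0.01. The permutation null tests
exchangeability of individuals, so it is calibrated for detecting planted
differentiation on an otherwise unstructured background; on genuinely
structured data it flags genome-wide differentiation wholesale — a
deliberate, documented substitution for a Bayesian F_ST-outlier model with
the same downstream contract (per-site flags).

**LD decay (`linkage.ld_decay`).** r² is the squared Pearson correlation of
dosage vectors (composite LD; no phase needed), pairs restricted to the same
contig and binned as (start, end] up to 300 kb / 1 Mb; a haplotype-based
variant exists for phased data. Zero-variance sites are skipped; sparse
missingness is mean-imputed within the scope before correlation.

**Haplotype split and Meselson test (`sexsignal`).** Haplotype A is the
copy with fewer non-reference alleles (ties: first stored copy), B the
other. NJ (Saitou–Nei, via scikit-bio, negative branches clamped) on
within-A and within-B Hamming matrices; concordance is the normalized
unweighted Robinson–Foulds distance on topologies; "mirrored" iff RF ≤ 0.1
— an explicit operationalisation of the verbal "topologies match", always
reported alongside the distance itself.

**PHI test (`sexsignal.phi_test`).** For biallelic SNPs, the pairwise
incompatibility score reduces to the four-gamete indicator. Φ_w is the mean
incompatibility over parsimony-informative site pairs within `window`
(default 100) informative sites of each other. Recombination makes nearby
pairs more compatible than the genome-wide average, so significance is the
*lower* tail: permutation p over random site orderings (+1 corrected) and an
analytic normal approximation using the exact permutation mean/variance of
the generalized Mantel statistic (verified against empirical moments in the
tests). Degenerate regimes are handled explicitly: < 2 informative sites
returns a "not applicable" status, and when the window spans most of the
alignment the statistic loses contrast (tests size fixtures so S ≫ window).

**Coding analyses (`coding`).** Degeneracy of every CDS position by
substituting all three alternatives under the standard code (0/2/3/4-fold;
stop codons and N-containing codons unclassified); strand-invariant. π0/π4
uses one representative per genotypic group, mean between-representative
allele mismatch per site (p_i + p_j − 2p_ip_j), summed over segregating
sites of a class and divided by the total class-site count of the
concatenated CDS; 2- and 3-fold sites enter neither. Outlier sites join
gene spans via interval trees. Enrichment is a per-term 2×2 chi-squared
(no continuity correction) against a user-supplied gene→term table, with an
automatic hypergeometric fallback when any expected cell < 1. The stop
screen substitutes each haplotype's alleles into the CDS, translates, and
flags stops strictly before the terminal codon (terminal stop loss is
reported separately); random mutations do create spontaneous premature
stops, so planted-truth comparisons are made relative to the pre-existing
flag set.

## Pipeline and determinism

`clonalsig.pipeline.run_pipeline` executes io → diversity/structure/linkage
→ coding/sexsignal from a YAML config (exactly one of an input-file block
or a simulate block; unknown keys rejected; effective config echoed). One
top-level seed fans out through named `SeedSequence` substreams per stage,
so toggling a stage never shifts another stage's draws; identical configs
give identical summary JSON. The `clonalsig` CLI exposes `simulate`,
`validate`, `run`, and per-stage subcommands.

## What the fixtures do and do not show

Passing the battery on simulations shows the estimators recover the
signatures their theory predicts under the stated models. The simulator
omits, among other things: selection (so π0/π4 elevation is never
*generated*, only measured), gene conversion, mitotic recombination,
genotyping error and missingness structure, reference bias, and realistic
demography (split times and sizes are signal-clarity choices, not
inferences). Real-data values reported for this system (e.g. 114,746 SNPs,
mean F_IS −0.26, Mantel r 0.468, π0/π4 0.55) depend on terabyte-scale raw
sequencing data and are therefore represented here by the property checks
in `tests/test_acceptance.py`, plus the exact reproduction of the published
AMOVA worked example, which `scripts/acceptance.py` recomputes from the
printed sums of squares and the sampling design.

Problem sizes used by the test suite and analysis scripts (60–700 kb
genomes, 8–60 individuals, 10–80 generations, 99–999 permutations) are the
package's own choices for seconds-scale reproducibility; every stochastic
assertion was frozen against its stated seed set before being recorded
here.
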