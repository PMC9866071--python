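"""Hierarchical population structure: Weir–Cockerham F_ST, four-level AMOVA,
Mantel isolation-by-distance, IBS-MDS genotypic grouping, and a
permutation-null F_ST-outlier scan.

The AMOVA decomposes squared haplotype distances (allele-difference counts
between the 2N phased gene copies) into among-group, among-population,
among-individual and within-individual components; variance components are
solved from the expected-mean-square system with unequal-size coefficients,
and negative components are reported as computed, never truncated.

The outlier scan replaces a Bayesian reversible-jump F_ST model with a
permutation null: per-site Weir–Cockerham theta is compared against theta
values from permutations of individuals among populations, pooled across
sites, with Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .genio import GenotypeMatrix, HaplotypeSet, PopulationHierarchy

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    per_site: pd.DataFrame      # columns a, b, c, theta
    theta_multilocus: float
    level: str


def wc_fst(g: GenotypeMatrix, h: PopulationHierarchy,
           level: str = "populations") -> FstResult:
    """Per-site Weir–Cockerham variance components a, b, c and theta.

    The multi-locus estimate is the ratio of averages, sum(a)/sum(a+b+c).
    Sites where fewer than two units carry genotype calls are skipped (NaN).
    """
    units = h.populations() if level == "populations" else h.groups()
    if len(units) < 2:
        raise ValueError(f"wc_fst needs >= 2 {level}")
    members = (h.samples_in_pop if level == "populations" else h.samples_in_group)
    idx = [[g.samples.index(s) for s in members(u)] for u in units]
    a, b, c = _wc_components(g.dosage, idx)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    ok = np.isfinite(a)
    multi = float(np.nansum(a[ok]) / np.nansum(denom[ok])) if ok.any() else np.nan
    per_site = g.sites.copy()
    per_site["a"], per_site["b"], per_site["c"], per_site["theta"] = a, b, c, theta
    return FstResult(per_site=per_site, theta_multilocus=multi, level=level)


def _wc_components(dosage: np.ndarray, unit_rows: list):
    """Vectorised W&C 1984 a, b, c per site for diploid data with observed
    heterozygote counts; ``unit_rows`` lists sample-row indices per unit."""
    S = dosage.shape[1]
    ni, pi, hi = [], [], []
    for rows in unit_rows:
        d = dosage[rows]
        obs = d >= 0
        n = obs.sum(0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(d > 0, d, 0).sum(0) / np.maximum(2 * n, 1)
            het = np.where(obs, d == 1, False).sum(0) / np.maximum(n, 1)
        ni.append(n); pi.append(p); hi.append(het)
    ni, pi, hi = (np.array(x) for x in (ni, pi, hi))

    present = ni > 0
    r = present.sum(0).astype(float)
    nsum = ni.sum(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = nsum / r
        nc = (nsum - (ni ** 2).sum(0) / nsum) / (r - 1)
        pbar = (ni * pi).sum(0) / nsum
        s2 = (ni * (pi - pbar) ** 2).sum(0) / ((r - 1) * nbar)
        hbar = (ni * hi).sum(0) / nsum
        pq = pbar * (1 - pbar)
        a = (nbar / nc) * (s2 - (pq - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pq - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = (r < 2) | (nbar <= 1)
    for x in (a, b, c):
        x[bad] = np.nan
    assert a.shape == (S,)
    return a, b, c


def pairwise_fst(g: GenotypeMatrix, h: PopulationHierarchy,
                 level: str = "populations") -> pd.DataFrame:
    """Multi-locus W&C theta for every pair of units, by restricting the sample."""
    units = h.populations() if level == "populations" else h.groups()
    members = (h.samples_in_pop if level == "populations" else h.samples_in_group)
    out = pd.DataFrame(0.0, index=units, columns=units)
    for i, u in enumerate(units):
        for v in units[i + 1:]:
            sub = g.take_samples(members(u) + members(v))
            subh = PopulationHierarchy(
                pop_of={s: u for s in members(u)} | {s: v for s in members(v)},
                group_of={u: u, v: v})
            t = wc_fst(sub, subh, level="populations").theta_multilocus
            out.loc[u, v] = out.loc[v, u] = t
    return out


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _copy_distances(hap: HaplotypeSet) -> np.ndarray:
    """Allele-difference counts between all 2N gene copies (used as squared
    distances in the AMOVA decomposition)."""
    A = hap.alignment().astype(np.int32)
    rs = A.sum(1)
    cross = A @ A.T
    return rs[:, None] + rs[None, :] - 2 * cross


def _ss_decomposition(D: np.ndarray, copy_ind, copy_pop, copy_grp) -> np.ndarray:
    """SS vector (among groups, among pops within groups, among individuals
    within pops, within individuals) from squared copy distances."""
    def ssw(mask):
        n = int(mask.sum())
        return float(D[np.ix_(mask, mask)].sum()) / (2.0 * n)
    total = ssw(np.ones(len(D), bool))
    wg = sum(ssw(copy_grp == x) for x in np.unique(copy_grp))
    wp = sum(ssw(copy_pop == x) for x in np.unique(copy_pop))
    wi = sum(ssw(copy_ind == x) for x in np.unique(copy_ind))
    return np.array([total - wg, wg - wp, wp - wi, wi])


def _design_arrays(samples, h: PopulationHierarchy):
    copy_ind = np.repeat(np.arange(len(samples)), 2)
    pops = {p: i for i, p in enumerate(h.populations())}
    grps = {g: i for i, g in enumerate(h.groups())}
    copy_pop = np.repeat([pops[h.pop_of[s]] for s in samples], 2)
    copy_grp = np.repeat([grps[h.group_of[h.pop_of[s]]] for s in samples], 2)
    return copy_ind, copy_pop, copy_grp


def amova_coefficients(design: dict) -> np.ndarray:
    """Coefficient matrix C with E[SS_l] = sum_k C[l, k] * sigma2_k for the
    four-level nested design.

    ``design`` maps group -> {population -> number of diploid individuals}.
    Copies per individual is fixed at 2 (diploid gene copies).
    """
    Ng = {g: 2 * sum(pops.values()) for g, pops in design.items()}
    Np = {(g, p): 2 * n for g, pops in design.items() for p, n in pops.items()}
    NT = sum(Ng.values())
    G = len(design)
    P = len(Np)
    N = NT // 2
    c_g = sum(v * v for v in Ng.values()) / NT
    c_pg = sum(Np[(g, p)] ** 2 / Ng[g] for (g, p) in Np)
    c_p = sum(v * v for v in Np.values()) / NT
    c_ig = sum(sum(4 for _ in range(pops[p])) / Ng[g]
               for g, pops in design.items() for p in pops)
    c_i = 4 * N / NT
    c_ip = sum(4 * n / Np[(g, p)] for (g, p), n in
               (((g, p), pops[p]) for g, pops in design.items() for p in pops))
    return np.array([
        [NT - c_g, c_pg - c_p, c_ig - c_i, G - 1],
        [0.0, NT - c_pg, c_ip - c_ig, P - G],
        [0.0, 0.0, NT - c_ip, N - P],
        [0.0, 0.0, 0.0, NT - N]])


def amova_components(ss, design: dict) -> pd.DataFrame:
    """Solve the expected-mean-square system for the variance components.

    Returns the full AMOVA table (df, SS, variance component, percentage of
    total, fixation index) for the four levels: among groups (Phi_CT), among
    populations within groups (Phi_SC), among individuals within populations
    (Phi_IS), within individuals (Phi_IT).  Negative components are kept.
    """
    ss = np.asarray(ss, dtype=float)
    if ss.shape != (4,):
        raise ValueError("expected 4 sums of squares")
    C = amova_coefficients(design)
    if abs(np.linalg.det(C)) < 1e-12:
        raise ValueError("singular design (need >= 2 groups, populations, "
                         "individuals)")
    sigma = np.linalg.solve(C, ss)
    tot = sigma.sum()
    G = len(design)
    P = sum(len(p) for p in design.values())
    N = sum(n for p in design.values() for n in p.values())
    df = np.array([G - 1, P - G, N - P, N])
    pct = 100 * sigma / tot if tot != 0 else np.full(4, np.nan)
    phi = np.array([
        sigma[0] / tot,
        sigma[1] / sigma[1:].sum(),
        sigma[2] / sigma[2:].sum(),
        (tot - sigma[3]) / tot]) if tot != 0 else np.full(4, np.nan)
    return pd.DataFrame({
        "source": ["among_groups", "among_populations_within_groups",
                   "among_individuals_within_populations", "within_individuals"],
        "df": df, "sum_of_squares": ss, "variance_component": sigma,
        "percentage": pct,
        "fixation_index": phi,
        "fixation_index_name": ["Phi_CT", "Phi_SC", "Phi_IS", "Phi_IT"]})


def amova(hap: HaplotypeSet, h: PopulationHierarchy, n_perm: int = 99,
          seed: int = 0) -> pd.DataFrame:
    """Four-level AMOVA on phased gene copies, with permutation p-values.

    Distances are allele-difference counts between the 2N haplotype copies.
    Permutation schemes per tested level: whole populations among groups
    (among-groups), individuals among populations within groups
    (among-populations), gene copies among individuals within populations
    (among-individuals), and gene copies among all individuals
    (within-individuals).
    """
    h.validate(hap.samples)
    D = _copy_distances(hap)
    copy_ind, copy_pop, copy_grp = _design_arrays(hap.samples, h)
    design = {g: {p: len(h.samples_in_pop(p)) for p in h.pops_in_group(g)}
              for g in h.groups()}
    ss = _ss_decomposition(D, copy_ind, copy_pop, copy_grp)
    if np.allclose(ss, 0):
        log.warning("amova: all individuals identical; components undefined")
        tab = amova_components(np.zeros(4), design)
        tab["variance_component"] = 0.0
        tab["percentage"] = np.nan
        tab["fixation_index"] = np.nan
        tab["p_value"] = np.nan
        return tab
    tab = amova_components(ss, design)
    if n_perm > 0:
        tab["p_value"] = _amova_pvalues(D, hap.samples, h, design,
                                        tab["variance_component"].to_numpy(),
                                        n_perm, seed)
    return tab


def _amova_pvalues(D, samples, h, design, sigma_obs, n_perm, seed):
    rng = np.random.default_rng(seed)
    C = amova_coefficients(design)
    copy_ind, copy_pop, copy_grp = _design_arrays(samples, h)
    n = len(samples)
    pops = {p: i for i, p in enumerate(h.populations())}
    grps = {g: i for i, g in enumerate(h.groups())}
    pop_grp = np.array([grps[h.group_of[p]] for p in h.populations()])
    ind_pop = np.array([pops[h.pop_of[s]] for s in samples])

    hits = np.zeros(4)
    for _ in range(n_perm):
        # level 1: permute populations among groups (pop sizes preserved)
        pg = pop_grp[rng.permutation(len(pop_grp))]
        cg1 = np.repeat(pg[ind_pop], 2)
        s1 = np.linalg.solve(C, _ss_decomposition(D, copy_ind, copy_pop, cg1))
        hits[0] += s1[0] >= sigma_obs[0]
        # level 2: permute individuals among populations within groups
        ip = ind_pop.copy()
        for gi in range(len(grps)):
            rows = np.flatnonzero(np.array([grps[h.group_of[h.pop_of[s]]]
                                            for s in samples]) == gi)
            ip[rows] = ind_pop[rows][rng.permutation(len(rows))]
        cp2 = np.repeat(ip, 2)
        s2 = np.linalg.solve(C, _ss_decomposition(D, copy_ind, cp2, copy_grp))
        hits[1] += s2[1] >= sigma_obs[1]
        # level 3: permute gene copies among individuals within populations
        ci3 = copy_ind.copy()
        for pi in range(len(pops)):
            rows = np.flatnonzero(copy_pop == pi)
            ci3[rows] = copy_ind[rows][rng.permutation(len(rows))]
        s3 = np.linalg.solve(C, _ss_decomposition(D, ci3, copy_pop, copy_grp))
        hits[2] += s3[2] >= sigma_obs[2]
        # level 4: permute gene copies among all individuals
        ci4 = copy_ind[rng.permutation(2 * n)]
        s4 = np.linalg.solve(C, _ss_decomposition(D, ci4, copy_pop, copy_grp))
        hits[3] += s4[3] <= sigma_obs[3]
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Mantel isolation by distance
# ---------------------------------------------------------------------------

def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance on the mean-radius sphere, in kilometres."""
    f1, f2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    d = math.sin((f2 - f1) / 2) ** 2 + math.cos(f1) * math.cos(f2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(d))


def geographic_distance_matrix(coords: dict, order: list) -> pd.DataFrame:
    out = pd.DataFrame(0.0, index=order, columns=order)
    for i, u in enumerate(order):
        for v in order[i + 1:]:
            d = great_circle_km(*coords[u], *coords[v])
            out.loc[u, v] = out.loc[v, u] = d
    return out


def mantel_ibd(fst: pd.DataFrame, coords: dict, n_perm: int = 9999,
               seed: int = 0, cap: float | None = None):
    """Mantel test of linearised F_ST/(1-F_ST) against great-circle distance.

    Returns ``(r, p)``; ``p`` is the upper-tail permutation probability with
    the (count+1)/(n_perm+1) correction. An F_ST entry of 1 makes the
    linearised distance infinite — pass ``cap`` (e.g. 0.999) to clip.
    """
    order = list(fst.index)
    F = fst.to_numpy(dtype=float)
    if not np.allclose(F, F.T):
        raise ValueError("F_ST matrix must be symmetric")
    if (F >= 1).any():
        if cap is None:
            raise ValueError("F_ST = 1 gives infinite linearised distance; "
                             "pass cap= (e.g. 0.999) to proceed")
        F = np.minimum(F, cap)
    gen = F / (1 - F)
    geo = geographic_distance_matrix(coords, order).to_numpy()
    iu = np.triu_indices(len(order), k=1)
    x, y = gen[iu], geo[iu]
    r_obs = _pearson(x, y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(order))
        count += _pearson(gen[np.ix_(perm, perm)][iu], y) >= r_obs
    return float(r_obs), float((count + 1) / (n_perm + 1))


def _pearson(x, y):
    x = x - x.mean(); y = y - y.mean()
    den = math.sqrt((x * x).sum() * (y * y).sum())
    return float((x * y).sum() / den) if den > 0 else 0.0


# ---------------------------------------------------------------------------
# IBS-MDS genotypic groups
# ---------------------------------------------------------------------------

def ibs_distance(g: GenotypeMatrix) -> np.ndarray:
    """Allele-sharing distance: mean per-site |dosage_i - dosage_j| / 2,
    over sites genotyped in both individuals."""
    d = g.dosage.astype(float)
    miss = d < 0
    D = np.zeros((g.n_samples, g.n_samples))
    for i in range(g.n_samples):
        diff = np.abs(d[i] - d) / 2.0
        both = ~(miss[i] | miss)
        diff[~both] = 0.0
        with np.errstate(invalid="ignore"):
            D[i] = diff.sum(1) / np.maximum(both.sum(1), 1)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2


def mds_genotypic_groups(g: GenotypeMatrix, h: PopulationHierarchy,
                         dims: int = 2, epsilon: float = 0.01) -> pd.DataFrame:
    """Classical-scaling coordinates plus within-population genotypic groups.

    Genotypic groups are single-linkage clusters of the IBS distance within
    each population at threshold ``epsilon`` (putative clone mates); the
    representative of each group is its lexicographically smallest sample id.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if g.n_samples < 2:
        raise ValueError("need >= 2 individuals")
    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa

    D = ibs_distance(g)
    ndim = min(dims, g.n_samples - 1)
    ord_res = pcoa(DistanceMatrix(D, ids=g.samples),
                   number_of_dimensions=ndim)
    coords = ord_res.samples.to_numpy()[:, :ndim]

    rows = []
    group_no = 0
    for pop in h.populations():
        members = sorted(s for s in g.samples if h.pop_of[s] == pop)
        mi = [g.samples.index(s) for s in members]
        if len(mi) == 1:
            labels = np.array([1])
        else:
            sub = D[np.ix_(mi, mi)]
            Z = linkage(squareform(sub, checks=False), method="single")
            labels = fcluster(Z, t=epsilon, criterion="distance")
        for lab in sorted(set(labels)):
            group_no += 1
            grp = sorted(members[k] for k in range(len(members))
                         if labels[k] == lab)
            for s in grp:
                i = g.samples.index(s)
                rows.append({"individual": s, "population": pop,
                             "genotypic_group": f"gg{group_no:03d}",
                             "representative": s == grp[0],
                             **{f"mds{d + 1}": coords[i, d] for d in range(ndim)}})
    out = pd.DataFrame(rows)
    out.attrs["n_groups"] = group_no
    return out


# ---------------------------------------------------------------------------
# F_ST outlier scan
# ---------------------------------------------------------------------------

def fst_outlier_scan(g: GenotypeMatrix, h: PopulationHierarchy,
                     n_perm: int = 200, q_threshold: float = 0.01,
                     seed: int = 0) -> pd.DataFrame:
    """Permutation-null per-site F_ST outlier scan with BH FDR.

    The null distribution of per-site theta is built by permuting individuals
    among populations (sizes preserved) and pooling theta across sites and
    permutations; per-site p is the upper-tail frequency with the +1
    correction, q the Benjamini–Hochberg value, and sites with
    ``q < q_threshold`` are flagged.
    """
    if len(h.populations()) < 2:
        raise ValueError("outlier scan needs >= 2 populations")
    if n_perm < 100:
        log.warning("fst_outlier_scan: n_perm=%d gives coarse p resolution", n_perm)
    res = wc_fst(g, h, level="populations")
    theta = res.per_site["theta"].to_numpy()

    rng = np.random.default_rng(seed)
    pops = [h.pop_of[s] for s in g.samples]
    null = []
    for _ in range(n_perm):
        perm = rng.permutation(len(pops))
        pop_of = {g.samples[i]: pops[perm[i]] for i in range(len(pops))}
        hp = PopulationHierarchy(pop_of=pop_of, group_of=dict(h.group_of))
        t = wc_fst(g, hp, level="populations").per_site["theta"].to_numpy()
        null.append(t[np.isfinite(t)])
    pool = np.sort(np.concatenate(null))
    M = len(pool)
    # upper-tail count via binary search on the sorted pool
    ge = M - np.searchsorted(pool, np.nan_to_num(theta, nan=-np.inf), side="left")
    p = (ge + 1) / (M + 1)
    p[~np.isfinite(theta)] = 1.0
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = g.sites.copy()
    out["theta"] = theta
    out["p"] = p
    out["q"] = q
    out["outlier"] = q < q_threshold
    return out
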