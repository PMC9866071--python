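"""Discriminators between long-term clonality and hybrid origin / cryptic sex.

Two ideas from the asexuality literature:

* **Haplotype-tree concordance (Meselson test).**  Under long-term strict
  clonality the two haplotypes of every individual diverge in parallel along
  the same clonal genealogy, so a tree built from each individual's
  reference-proximal haplotype (A) should mirror the tree from the diverged
  haplotype (B).  A hybrid origin gives high heterozygosity without mirrored
  trees, because the two haplotype sets trace back to different parental
  gene pools.  Concordance is scored by the normalized Robinson–Foulds
  distance between neighbor-joining trees.

* **PHI (pairwise homoplasy index) recombination test.**  For biallelic
  sites the refined incompatibility score reduces to the four-gamete
  indicator: two sites are incompatible with a single non-recombining
  genealogy iff all four haplotype combinations occur.  Phi_w is the mean
  incompatibility over informative site pairs within a window of w
  informative sites; recombination makes nearby pairs more compatible than
  distant ones, so a Phi_w below its site-permutation expectation signals
  recombination (lower-tail p, by permutation and by a normal approximation
  from the exact permutation moments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .genio import HaplotypeSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# haplotype A/B split
# ---------------------------------------------------------------------------

@dataclass
class HaploSplit:
    """Per individual: haplotype A (closer to the reference) and B (more
    diverged), with their distances to the reference allele string."""

    samples: list
    A: np.ndarray            # (n, S) alleles of the reference-proximal haplotype
    B: np.ndarray
    table: pd.DataFrame      # individual, dist_a, dist_b, a_is_hap0


def split_haplotypes(hap: HaplotypeSet) -> HaploSplit:
    """Label each individual's haplotypes A/B by distance to the reference.

    Distance is the count of non-reference alleles; on ties the first stored
    haplotype is labelled A.  Swapping the stored pair of every individual
    leaves the labelling invariant.
    """
    counts = hap.haps.sum(axis=2)          # (n, 2)
    a_is_0 = counts[:, 0] <= counts[:, 1]
    A = np.where(a_is_0[:, None], hap.haps[:, 0, :], hap.haps[:, 1, :])
    B = np.where(a_is_0[:, None], hap.haps[:, 1, :], hap.haps[:, 0, :])
    table = pd.DataFrame({
        "individual": hap.samples,
        "dist_a": np.minimum(counts[:, 0], counts[:, 1]),
        "dist_b": np.maximum(counts[:, 0], counts[:, 1]),
        "a_is_hap0": a_is_0})
    return HaploSplit(samples=list(hap.samples), A=A.astype(np.uint8),
                      B=B.astype(np.uint8), table=table)


# ---------------------------------------------------------------------------
# neighbor joining + Robinson-Foulds
# ---------------------------------------------------------------------------

def nj_tree(dm: np.ndarray | DistanceMatrix, ids: list | None = None) -> TreeNode:
    """Saitou–Nei neighbor joining; negative branch lengths are clamped to 0."""
    if not isinstance(dm, DistanceMatrix):
        dm = np.asarray(dm, dtype=float)
        if not np.isfinite(dm).all():
            raise ValueError("distance matrix contains non-finite entries")
        dm = DistanceMatrix(dm, ids=ids)
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    tree = _skbio_nj(dm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        log.info("nj_tree: clamped %d negative branch lengths to 0", clamped)
    return tree


def hamming_matrix(X: np.ndarray) -> np.ndarray:
    X = X.astype(np.int32)
    rs = X.sum(1)
    return (rs[:, None] + rs[None, :] - 2 * (X @ X.T)).astype(float)


def normalized_rf(t1: TreeNode, t2: TreeNode) -> float:
    """Unweighted Robinson–Foulds distance on topologies, normalized to [0, 1]
    by the total number of internal bipartitions in the two trees."""
    n = len(list(t1.tips()))
    if n < 4 or len(list(t2.tips())) != n:
        raise ValueError("RF needs two trees with the same >= 4 leaves")
    def bip(tree):
        leaves = frozenset(l.name for l in tree.tips())
        out = set()
        for node in tree.non_tips(include_self=False):
            side = frozenset(l.name for l in node.tips())
            if 1 < len(side) < n - 1:
                out.add(min(side, leaves - side, key=sorted))
        return out
    b1, b2 = bip(t1), bip(t2)
    denom = len(b1) + len(b2)
    return len(b1 ^ b2) / denom if denom else 0.0


@dataclass
class TreePair:
    tree_a: TreeNode
    tree_b: TreeNode
    rf_normalized: float
    mirrored: bool
    threshold: float


def meselson_test(split: HaploSplit, rf_threshold: float = 0.1) -> TreePair:
    """Neighbor-joining trees of the A- and B-haplotype sets and their
    topological concordance.

    ``mirrored`` is True iff the normalized RF distance is at or below
    ``rf_threshold`` (an operational cutoff for the verbal "topologies
    match" criterion; report the distance itself alongside).
    """
    if len(split.samples) < 4:
        raise ValueError("Meselson test needs >= 4 individuals")
    ta = nj_tree(hamming_matrix(split.A), ids=split.samples)
    tb = nj_tree(hamming_matrix(split.B), ids=split.samples)
    rf = normalized_rf(ta, tb)
    return TreePair(tree_a=ta, tree_b=tb, rf_normalized=rf,
                    mirrored=rf <= rf_threshold, threshold=rf_threshold)


# ---------------------------------------------------------------------------
# PHI test
# ---------------------------------------------------------------------------

@dataclass
class PhiResult:
    phi: float
    p_permutation: float
    p_normal: float
    n_informative: int
    n_sequences: int
    status: str = "ok"


def _informative(aln: np.ndarray) -> np.ndarray:
    counts = aln.sum(0)
    n = aln.shape[0]
    return (counts >= 2) & (counts <= n - 2)


def incompatibility_matrix(aln: np.ndarray) -> np.ndarray:
    """Four-gamete incompatibility for every pair of biallelic columns."""
    A = aln.astype(np.int32)
    nA = 1 - A
    c11 = A.T @ A
    c10 = A.T @ nA
    c01 = nA.T @ A
    c00 = nA.T @ nA
    X = ((c11 > 0) & (c10 > 0) & (c01 > 0) & (c00 > 0)).astype(np.float64)
    np.fill_diagonal(X, 0.0)
    return X


def _perm_moments(W: np.ndarray, X: np.ndarray):
    """Exact mean and variance of T = sum_{i != j} W_ij X_{s(i) s(j)} under a
    uniform random permutation s (both matrices symmetric, zero diagonal)."""
    n = len(W)
    def parts(M):
        m1 = M.sum()
        m2 = (M * M).sum()
        m3 = (M.sum(1) ** 2).sum() - m2
        m4 = m1 ** 2 - 2 * m2 - 4 * m3
        return m1, m2, m3, m4
    w1, w2, w3, w4 = parts(W)
    x1, x2, x3, x4 = parts(X)
    f2 = n * (n - 1)
    f3 = f2 * (n - 2)
    f4 = f3 * (n - 3)
    mean = w1 * x1 / f2
    second = 2 * w2 * x2 / f2 + 4 * w3 * x3 / f3 + (w4 * x4 / f4 if n > 3 else 0.0)
    return mean, max(second - mean ** 2, 0.0)


def phi_test(aln_or_hap, window: int = 100, n_perm: int = 1000,
             seed: int = 0) -> PhiResult:
    """PHI recombination test on a binary haplotype alignment.

    ``window`` is measured in informative-site count.  The permutation p is
    the lower-tail probability that a random site ordering gives a windowed
    mean incompatibility at or below the observed one (+1 corrected); the
    analytic p uses a normal approximation with the exact permutation
    mean/variance of the statistic.
    """
    if isinstance(aln_or_hap, HaplotypeSet):
        aln = aln_or_hap.alignment()
    else:
        aln = np.asarray(aln_or_hap)
    if aln.shape[0] < 4:
        raise ValueError("PHI needs >= 4 sequences")
    keep = _informative(aln)
    S = int(keep.sum())
    if S < 2:
        return PhiResult(phi=np.nan, p_permutation=1.0, p_normal=1.0,
                         n_informative=S, n_sequences=aln.shape[0],
                         status="not applicable: < 2 informative sites")
    aln = aln[:, keep]
    X = incompatibility_matrix(aln)
    w = min(window, S - 1)
    # windowed pair sum over site order 0..S-1
    offsets = np.arange(1, w + 1)
    idx = np.arange(S)

    def pair_sum(order):
        t = 0.0
        for d in offsets:
            t += X[order[:-d], order[d:]].sum()
        return t

    n_pairs = sum(S - d for d in offsets)
    t_obs = pair_sum(idx)
    phi = t_obs / n_pairs

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += pair_sum(rng.permutation(S)) <= t_obs
    p_perm = (count + 1) / (n_perm + 1)

    W = np.zeros((S, S))
    iu = np.arange(S)
    for d in offsets:
        W[iu[:-d], iu[d:]] = 1.0
        W[iu[d:], iu[:-d]] = 1.0
    mean, var = _perm_moments(W, X)
    if var <= 0:
        p_norm = 1.0 if 2 * t_obs >= mean else 0.0
    else:
        p_norm = float(stats.norm.cdf((2 * t_obs - mean) / np.sqrt(var)))
    return PhiResult(phi=float(phi), p_permutation=float(p_perm),
                     p_normal=p_norm, n_informative=S,
                     n_sequences=aln.shape[0])


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
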