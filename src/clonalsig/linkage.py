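"""Pairwise r^2 and distance-binned linkage-disequilibrium decay per contig.

r^2 is the squared Pearson correlation of genotype dosage vectors (composite
LD), which needs no phase information; a haplotype-based option is available
when phased haplotypes are supplied.  Pairs are restricted to the same contig
and to a maximum physical distance, then averaged in non-overlapping distance
bins.  Under frequent recombination mean r^2 falls off with distance; under
clonal propagation the curve stays near-flat genome-wide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, HaplotypeSet, PopulationHierarchy


def ld_decay(g: GenotypeMatrix, h: PopulationHierarchy | None = None,
             scope: str | None = None, max_dist: int = 300_000,
             bin_width: int = 1_000) -> pd.DataFrame:
    """Binned mean r^2 versus physical distance.

    ``scope`` restricts the sample to one group (or population) from the
    hierarchy; ``None`` uses all samples.  Zero-variance sites within the
    scope are skipped.  Returns one row per distance bin: ``bin_start``
    (exclusive), ``bin_end`` (inclusive), ``mean_r2``, ``n_pairs``.
    """
    sub = g
    if scope is not None:
        if h is None:
            raise ValueError("scope requires a hierarchy")
        members = (h.samples_in_group(scope) if scope in h.groups()
                   else h.samples_in_pop(scope))
        sub = g.take_samples(members)
    edges = np.arange(0, max_dist + bin_width, bin_width)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for contig, sidx in sub.sites.groupby("contig", sort=False).indices.items():
        _accumulate_contig(sub.dosage[:, sidx].astype(float),
                           sub.sites["pos"].to_numpy()[sidx],
                           max_dist, edges, sums, counts)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "mean_r2": mean, "n_pairs": counts})


def _accumulate_contig(d, pos, max_dist, edges, sums, counts):
    miss = d < 0
    if miss.any():
        # complete-data pairs only would be quadratic; mean-impute missing
        col_mean = np.where(miss, np.nan, d)
        col_mean = np.nanmean(col_mean, axis=0)
        d = np.where(miss, col_mean[None, :], d)
    sd = d.std(axis=0)
    keep = sd > 0
    d, pos = d[:, keep], pos[keep]
    S = d.shape[1]
    if S < 2:
        return
    z = (d - d.mean(0)) / d.std(0)
    n = d.shape[0]
    R = (z.T @ z) / n
    r2 = np.clip(R ** 2, 0.0, 1.0)
    iu, ju = np.triu_indices(S, k=1)
    dist = pos[ju] - pos[iu]
    ok = (dist > 0) & (dist <= max_dist)
    # bins are (start, end]
    which = np.searchsorted(edges, dist[ok], side="left") - 1
    np.add.at(sums, which, r2[iu[ok], ju[ok]])
    np.add.at(counts, which, 1)


def pair_r2(g: GenotypeMatrix, i: int, j: int) -> float:
    """r^2 between two site indices (dosage correlation)."""
    x, y = g.dosage[:, i].astype(float), g.dosage[:, j].astype(float)
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def ld_decay_haplotype(hap: HaplotypeSet, max_dist: int = 300_000,
                       bin_width: int = 1_000) -> pd.DataFrame:
    """Haplotype-based r^2 decay (correlation of 0/1 alleles over 2N copies)."""
    g = GenotypeMatrix(samples=hap.hap_labels(), sites=hap.sites.copy(),
                       dosage=hap.alignment().astype(np.int8))
    return ld_decay(g, max_dist=max_dist, bin_width=bin_width)


def summarize_ld(decay: pd.DataFrame, near: int = 25_000,
                 far_from: int | None = None) -> dict:
    """Mean r^2 over the near window (<= ``near`` bp) and the farthest window
    (pairs beyond ``far_from``, default: last 10% of the binned range)."""
    if far_from is None:
        far_from = int(decay["bin_end"].max() * 0.9)
    def wmean(mask):
        w = decay.loc[mask, "n_pairs"].to_numpy()
        v = decay.loc[mask, "mean_r2"].to_numpy()
        ok = w > 0
        return float((v[ok] * w[ok]).sum() / w[ok].sum()) if w[ok].sum() else np.nan
    return {"near_mean_r2": wmean(decay["bin_end"] <= near),
            "far_mean_r2": wmean(decay["bin_start"] >= far_from)}
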