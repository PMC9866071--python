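"""Heterozygosity, per-individual F_IS, nucleotide diversity, and the
heterozygote-sharing site-frequency spectrum with Hardy–Weinberg expectations.

Negative per-individual F_IS = 1 - Hobs/Hexp marks an excess of observed
heterozygosity over the random-mating expectation — the classic signature of
clonal reproduction, where the two haplotypes of a lineage diverge without
segregation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix, PopulationHierarchy

log = logging.getLogger(__name__)


def individual_fis(g: GenotypeMatrix, h: PopulationHierarchy | None = None,
                   per_population_freq: bool = False) -> pd.DataFrame:
    """Per-individual observed/expected heterozygosity and F_IS.

    ``Hexp`` at a site is ``2 p (1 - p)`` with ``p`` the whole-sample
    alternate-allele frequency (optionally the individual's own population
    frequency with ``per_population_freq``); per-individual values are means
    over that individual's non-missing sites.
    """
    if g.n_samples < 2:
        raise ValueError("individual F_IS needs at least 2 individuals")
    if g.n_sites == 0:
        raise ValueError("individual F_IS needs polymorphic sites")
    if per_population_freq:
        if h is None:
            raise ValueError("per_population_freq requires a hierarchy")
        pexp = np.empty((g.n_samples, g.n_sites))
        for pop in h.populations():
            rows = [i for i, s in enumerate(g.samples) if h.pop_of[s] == pop]
            sub = g.dosage[rows]
            obs = sub >= 0
            p = np.where(sub > 0, sub, 0).sum(0) / np.maximum(2 * obs.sum(0), 1)
            pexp[rows] = 2 * p * (1 - p)
    else:
        p = g.allele_freq()
        pexp = np.broadcast_to(2 * p * (1 - p), (g.n_samples, g.n_sites))

    rows = []
    for i, s in enumerate(g.samples):
        ok = g.dosage[i] >= 0
        if not ok.any():
            log.warning("individual %s has no usable sites; F_IS is NaN", s)
            rows.append({"individual": s, "n_sites": 0, "hobs": np.nan,
                         "hexp": np.nan, "fis": np.nan})
            continue
        hobs = float((g.dosage[i][ok] == 1).mean())
        hexp = float(pexp[i][ok].mean())
        fis = 1.0 - hobs / hexp if hexp > 0 else np.nan
        rows.append({"individual": s, "n_sites": int(ok.sum()),
                     "hobs": hobs, "hexp": hexp, "fis": fis})
    return pd.DataFrame(rows)


def nucleotide_diversity(g: GenotypeMatrix, h: PopulationHierarchy | None = None,
                         by: str = "group") -> pd.DataFrame:
    """Unbiased per-site nucleotide diversity π, per group (or population).

    Per site, ``pi = 2 p (1 - p) * 2n / (2n - 1)`` — the mean pairwise
    difference among the ``2n`` gene copies — averaged over sites.  A
    per-contig sum is also reported via :func:`nucleotide_diversity_contigs`.
    """
    scopes = {"all": list(g.samples)}
    if h is not None:
        units = h.groups() if by == "group" else h.populations()
        getter = h.samples_in_group if by == "group" else h.samples_in_pop
        scopes = {u: getter(u) for u in units}
    rows = []
    for name, members in scopes.items():
        sub = g.take_samples(members)
        rows.append({by if h is not None else "scope": name,
                     "n": sub.n_samples, "pi": _pi_per_site(sub).mean()
                     if sub.n_sites else 0.0})
    return pd.DataFrame(rows)


def _pi_per_site(g: GenotypeMatrix) -> np.ndarray:
    d = g.dosage
    obs = d >= 0
    n2 = 2 * obs.sum(0)
    if (n2 < 2).any():
        raise ValueError("nucleotide diversity needs >= 1 genotyped diploid "
                         "(2 gene copies) per site")
    p = np.where(d > 0, d, 0).sum(0) / n2
    return 2 * p * (1 - p) * n2 / (n2 - 1)


def nucleotide_diversity_contigs(g: GenotypeMatrix) -> pd.DataFrame:
    """Sum of per-site π per contig (whole sample)."""
    pi = _pi_per_site(g)
    out = (pd.DataFrame({"contig": g.sites["contig"], "pi": pi})
           .groupby("contig", sort=False)["pi"].agg(["sum", "size"])
           .reset_index())
    return out.rename(columns={"sum": "pi_sum", "size": "n_sites"})


def het_sharing_sfs(g: GenotypeMatrix, individuals: list | None = None) -> pd.DataFrame:
    """Heterozygote-sharing spectrum with HWE expectations.

    For each site the minor-allele count (folded, 0..N copies of 2N) and the
    number of heterozygous individuals are recorded.  The expected number of
    sites with exactly ``k`` heterozygotes under Hardy–Weinberg equilibrium
    treats individuals as exchangeable and sites as independent:
    ``sum over sites of Binomial(N, 2 p (1-p)).pmf(k)``, with ``p`` the
    site's sample allele frequency.  The ``excess`` column is observed /
    expected per heterozygote-count class — values far above 1 in the
    all-heterozygous class are the clonal/hybrid signature.
    """
    sub = g if individuals is None else g.take_samples(individuals)
    if sub.n_samples < 2:
        raise ValueError("SFS needs >= 2 individuals")
    d = sub.dosage
    if (d < 0).any() or (g.dosage < 0).any():
        raise ValueError("SFS expects a complete-data matrix (no missing)")
    N = sub.n_samples
    alt = d.sum(0)
    mac = np.minimum(alt, 2 * N - alt)
    nhet = (d == 1).sum(0)
    # allele frequency from the full matrix: when a subset is scored, the
    # remaining samples still inform p, reducing the plug-in bias of the
    # HWE expectation
    p = g.allele_freq()
    phet = 2 * p * (1 - p)

    het_classes = np.arange(N + 1)
    observed = np.bincount(nhet, minlength=N + 1).astype(float)
    expected = stats.binom.pmf(het_classes[None, :], N, phet[:, None]).sum(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        excess = np.where(expected > 0, observed / expected, np.nan)
    spectrum = pd.DataFrame({"n_het": het_classes, "observed": observed,
                             "expected": expected, "excess": excess})
    spectrum.attrs["n_individuals"] = N
    spectrum.attrs["site_classes"] = pd.DataFrame(
        {"minor_allele_count": np.arange(N + 1),
         "n_sites": np.bincount(mac, minlength=N + 1)})
    return spectrum
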