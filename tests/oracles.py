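"""Independent brute-force oracles used to cross-check the library.

Everything here is written as plain loops from first principles, independent
of the vectorised implementations under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Seq import Seq


def wc_direct(dosage, unit_rows):
    """Scalar transcription of the Weir & Cockerham (1984) a, b, c per site."""
    S = dosage.shape[1]
    out = np.full((3, S), np.nan)
    for s in range(S):
        ns, ps, hs = [], [], []
        for rows in unit_rows:
            vals = [dosage[i, s] for i in rows if dosage[i, s] >= 0]
            if not vals:
                continue
            n = len(vals)
            ns.append(n)
            ps.append(sum(vals) / (2 * n))
            hs.append(sum(1 for v in vals if v == 1) / n)
        r = len(ns)
        if r < 2:
            continue
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
        pq = pbar * (1 - pbar)
        a = (nbar / nc) * (s2 - (pq - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pq - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        out[:, s] = (a, b, c)
    return out


def amova_ss_double_loop(alignment, copy_ind, copy_pop, copy_grp):
    """AMOVA sums of squares by explicit O(n^2) pair loops over gene copies."""
    n = alignment.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = sum(int(a != b) for a, b in zip(alignment[i], alignment[j]))

    def ssw(labels):
        total = 0.0
        for lab in set(labels):
            rows = [i for i in range(n) if labels[i] == lab]
            acc = 0.0
            for i in rows:
                for j in rows:
                    if i < j:
                        acc += D[i, j]
            total += acc / len(rows)
        return total

    sst = ssw([0] * n)
    ssg = ssw(list(copy_grp))
    ssp = ssw(list(copy_pop))
    ssi = ssw(list(copy_ind))
    return np.array([sst - ssg, ssg - ssp, ssp - ssi, ssi])


def pi_allpairs(dosage):
    """Mean pairwise Hamming difference per site over all 2n gene copies."""
    copies = []
    for row in dosage:
        assert all(d >= 0 for d in row)
        copies.append([1 if d >= 1 else 0 for d in row])
        copies.append([1 if d == 2 else 0 for d in row])
    n = len(copies)
    S = len(copies[0])
    acc = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            acc += sum(int(a != b) for a, b in zip(copies[i], copies[j]))
    return acc / (n * (n - 1) / 2) / S


def nj_textbook(D, ids):
    """Plain Saitou–Nei neighbor joining, returning a newick string."""
    D = [list(map(float, row)) for row in D]
    nodes = [f"{i}" for i in ids]
    while len(nodes) > 3:
        n = len(nodes)
        r = [sum(D[i]) for i in range(n)]
        best, bi, bj = None, None, None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i][j] - r[i] - r[j]
                if best is None or q < best - 1e-12:
                    best, bi, bj = q, i, j
        d_iu = 0.5 * D[bi][bj] + (r[bi] - r[bj]) / (2 * (n - 2))
        d_ju = D[bi][bj] - d_iu
        newnode = f"({nodes[bi]}:{d_iu:.6f},{nodes[bj]}:{d_ju:.6f})"
        newdist = [0.5 * (D[bi][k] + D[bj][k] - D[bi][bj])
                   for k in range(n) if k not in (bi, bj)]
        keep = [k for k in range(n) if k not in (bi, bj)]
        D = [[D[a][b] for b in keep] + [newdist[ai]]
             for ai, a in enumerate(keep)]
        D.append(newdist + [0.0])
        nodes = [nodes[k] for k in keep] + [newnode]
    if len(nodes) == 3:
        d01, d02, d12 = D[0][1], D[0][2], D[1][2]
        b0 = (d01 + d02 - d12) / 2
        b1 = (d01 + d12 - d02) / 2
        b2 = (d02 + d12 - d01) / 2
        return (f"({nodes[0]}:{b0:.6f},{nodes[1]}:{b1:.6f},"
                f"{nodes[2]}:{b2:.6f});")
    return f"({nodes[0]}:{D[0][1] / 2:.6f},{nodes[1]}:{D[0][1] / 2:.6f});"


def degeneracy_enumerate():
    """fold class for every (codon, position) by exhaustive enumeration,
    translating with Biopython's Seq.translate (independent of the codon
    table mapping used in the library)."""
    table = {}
    for codon in map("".join, itertools.product("ACGT", repeat=3)):
        aa = str(Seq(codon).translate())
        if aa == "*":
            continue
        for pos in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if str(Seq(alt).translate()) == aa:
                    syn += 1
            table[(codon, pos)] = {0: 0, 1: 2, 2: 3, 3: 4}[syn]
    return table


def chi2_2x2(a, b, c, d):
    """Textbook Pearson chi-squared for a 2x2 table, no continuity correction."""
    n = a + b + c + d
    exp = [[(a + b) * (a + c) / n, (a + b) * (b + d) / n],
           [(c + d) * (a + c) / n, (c + d) * (b + d) / n]]
    obs = [[a, b], [c, d]]
    stat = sum((obs[i][j] - exp[i][j]) ** 2 / exp[i][j]
               for i in range(2) for j in range(2))
    return stat


def fis_direct(dosage):
    """Per-individual F_IS from first principles (complete data)."""
    n, S = dosage.shape
    p = [sum(dosage[i, s] for i in range(n)) / (2 * n) for s in range(S)]
    out = []
    for i in range(n):
        hobs = sum(1 for s in range(S) if dosage[i, s] == 1) / S
        hexp = sum(2 * p[s] * (1 - p[s]) for s in range(S)) / S
        out.append(1 - hobs / hexp)
    return out
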