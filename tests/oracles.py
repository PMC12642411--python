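"""Independent brute-force oracles used only by the test suite.

Each function here is deliberately written in a different style from the
library implementation it checks (naive loops, textbook formulas), so the
two routes are independent.
"""

import re
from itertools import combinations
from math import comb, log10, sqrt

import numpy as np

VALID = set("ACGT")


def brute_segregating_sites(seqs):
    n_cols = len(seqs[0])
    count = 0
    for j in range(n_cols):
        col = [s[j] for s in seqs]
        if any(c not in VALID for c in col):
            continue
        if len(set(col)) >= 2:
            count += 1
    return count


def brute_pi(seqs):
    n_cols = len(seqs[0])
    usable = [
        j for j in range(n_cols) if all(s[j] in VALID for s in seqs)
    ]
    total = 0
    for a, b in combinations(seqs, 2):
        total += sum(1 for j in usable if a[j] != b[j])
    return total / (comb(len(seqs), 2) * len(usable))


def brute_tajimas_d(seqs):
    """Textbook Tajima (1989) evaluation via explicit pairwise differences."""
    n = len(seqs)
    usable = [j for j in range(len(seqs[0])) if all(s[j] in VALID for s in seqs)]
    s = sum(1 for j in usable if len({q[j] for q in seqs}) >= 2)
    if s == 0:
        return None
    k_hat = (
        sum(
            sum(1 for j in usable if a[j] != b[j])
            for a, b in combinations(seqs, 2)
        )
        / comb(n, 2)
    )
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k_hat - s / a1) / sqrt(e1 * s + e2 * s * (s - 1))


def brute_ehh(seqs, core_index, core_allele):
    """Pairwise enumeration of identity from the core through each position."""
    carriers = [s for s in seqs if s[core_index] == core_allele]
    n = len(carriers)
    pairs = list(combinations(range(n), 2))
    out = {}
    for x in range(len(seqs[0])):
        lo, hi = min(core_index, x), max(core_index, x)
        same = sum(
            1
            for i, j in pairs
            if carriers[i][lo : hi + 1] == carriers[j][lo : hi + 1]
        )
        out[x] = same / len(pairs)
    return out


def brute_r2(seqs, i, j):
    """r^2 from the full 2x2 haplotype contingency table."""
    ai = sorted({s[i] for s in seqs})
    aj = sorted({s[j] for s in seqs})
    table = np.zeros((2, 2))
    for s in seqs:
        table[ai.index(s[i]), aj.index(s[j])] += 1
    n = table.sum()
    p_a = table[0].sum() / n
    p_b = table[:, 0].sum() / n
    p_ab = table[0, 0] / n
    d = p_ab - p_a * p_b
    return d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))


_RC = str.maketrans("ACGT", "TGCA")


def brute_orfs(seq, min_aa):
    """Regex-based six-frame ORF scan: first ATG after each stop/break to the
    next in-frame stop, forward-strand coordinates."""
    n = len(seq)
    results = set()
    for strand, s in (("+", seq), ("-", seq.translate(_RC)[::-1])):
        for frame in range(3):
            codons = [s[p : p + 3] for p in range(frame, n - 2, 3)]
            blocks = "".join(
                "X" if any(c not in VALID for c in cod)
                else ("*" if cod in ("TAA", "TAG", "TGA") else ("M" if cod == "ATG" else "."))
                for cod in codons
            )
            for m in re.finditer(r"M[M.]*\*", blocks):
                a = frame + 3 * m.start()
                b = frame + 3 * m.end()
                if b - a >= 3 * (min_aa + 1):
                    span = (a, b) if strand == "+" else (n - b, n - a)
                    results.add((span, strand, frame))
    return results


def brute_chi2_2x2(table):
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    expected = np.outer(row, col) / n
    return float(((table - expected) ** 2 / expected).sum())


def brute_peak_region(positions, pvals, delta=2.0):
    pairs = sorted(zip(positions, pvals))
    peak_p = min(p for _, p in pairs)
    cutoff = -log10(peak_p) - delta
    inside = [pos for pos, p in pairs if -log10(p) >= cutoff]
    return min(inside), max(inside)


def brute_block_methylation(scores, block, threshold):
    disc = [1 if s >= threshold else 0 for s in scores]
    counts = [sum(disc[i : i + block]) for i in range(0, len(disc), block)]
    means = [
        sum(disc[i : i + block]) / len(disc[i : i + block])
        for i in range(0, len(disc), block)
    ]
    return counts, means
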