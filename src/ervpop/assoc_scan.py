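"""Case-control allele-frequency association scan with a permutation-derived
genome-wide significance threshold and peak-region definition.

The per-site test compares allele counts between cases and controls in a 2x2
chi-square without continuity correction, substituting the exact conditional
(Fisher) test whenever any expected cell is below 5. Genome-wide significance
uses the max-statistic method: the phenotype labels are permuted, the minimum
p-value across sites is recorded per permutation, and the empirical
alpha-quantile of those minima is the threshold, so the family-wise error
rate is controlled at alpha without distributional assumptions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "site_test",
    "scan",
    "permutation_threshold",
    "peak_region",
    "ScanResult",
]

logger = logging.getLogger(__name__)


def _allele_table(case_gt: np.ndarray, control_gt: np.ndarray) -> np.ndarray:
    """2x2 allele-count table [[case_alt, case_ref], [ctrl_alt, ctrl_ref]]
    from genotype count triples (n0, n1, n2)."""
    c0, c1, c2 = case_gt
    k0, k1, k2 = control_gt
    case_alt = c1 + 2 * c2
    case_ref = 2 * c0 + c1
    ctrl_alt = k1 + 2 * k2
    ctrl_ref = 2 * k0 + k1
    return np.array([[case_alt, case_ref], [ctrl_alt, ctrl_ref]], dtype=float)


def site_test(
    case_genotype_counts: tuple[int, int, int] | np.ndarray,
    control_genotype_counts: tuple[int, int, int] | np.ndarray,
) -> tuple[float, float]:
    """Allele-frequency test at one biallelic site.

    Returns (statistic, p). Chi-square on the 2x2 allele table without
    continuity correction; the exact conditional test is substituted when any
    expected cell is < 5. A monomorphic site returns p = 1 by convention.
    """
    table = _allele_table(np.asarray(case_genotype_counts), np.asarray(control_genotype_counts))
    if table.sum(axis=1).min() <= 0:
        raise ValueError("both groups must contribute alleles")
    col_tot = table.sum(axis=0)
    if col_tot.min() == 0:
        logger.info("monomorphic site: p = 1 by convention")
        return 0.0, 1.0
    row_tot = table.sum(axis=1)
    n = table.sum()
    expected = np.outer(row_tot, col_tot) / n
    if expected.min() < 5:
        _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
        return float("nan"), float(p)
    chi2 = float((n * (table[0, 0] * table[1, 1] - table[0, 1] * table[1, 0]) ** 2)
                 / (row_tot[0] * row_tot[1] * col_tot[0] * col_tot[1]))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(genotypes: np.ndarray, mask: np.ndarray) -> np.ndarray:
    sub = genotypes[mask]
    return np.stack([(sub == g).sum(axis=0) for g in (0, 1, 2)])


def scan(genotypes: np.ndarray, phenotypes: np.ndarray,
         positions: np.ndarray | None = None) -> pd.DataFrame:
    """Per-site association test over a genotype matrix (individuals x sites).

    Vectorised chi-square with the exact-test substitution applied to the
    (margin-determined) sites whose expected counts fall below 5.
    """
    genotypes = np.asarray(genotypes)
    phenotypes = np.asarray(phenotypes).astype(bool)
    n_sites = genotypes.shape[1]
    if positions is None:
        positions = np.arange(n_sites)
    stat, p, needs_exact = _chi2_vector(genotypes, phenotypes)
    for j in np.nonzero(needs_exact)[0]:
        stat_j, p_j = site_test(
            tuple(_genotype_counts(genotypes[:, [j]], phenotypes)[:, 0]),
            tuple(_genotype_counts(genotypes[:, [j]], ~phenotypes)[:, 0]),
        )
        stat[j], p[j] = stat_j, p_j
    return pd.DataFrame({"position": positions, "statistic": stat, "p": p})


def _chi2_vector(
    genotypes: np.ndarray, phenotypes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised 2x2 allele-count chi-square across sites.

    Also returns the mask of sites whose expected cells fall below 5; those
    margins do not depend on how labels are assigned, only on group sizes,
    so the mask is permutation-invariant.
    """
    y = phenotypes.astype(np.float64)
    n_case = y.sum()
    n_ctrl = y.size - n_case
    alt_case = y @ genotypes
    alt_tot = genotypes.sum(axis=0).astype(np.float64)
    alt_ctrl = alt_tot - alt_case
    tot_case = 2.0 * n_case
    tot_ctrl = 2.0 * n_ctrl
    n = tot_case + tot_ctrl
    ref_tot = n - alt_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        num = n * (alt_case * (tot_ctrl - alt_ctrl) - (tot_case - alt_case) * alt_ctrl) ** 2
        den = tot_case * tot_ctrl * alt_tot * ref_tot
        chi2 = num / den
    mono = (alt_tot == 0) | (ref_tot == 0)
    chi2[mono] = 0.0
    p = stats.chi2.sf(chi2, df=1)
    p[mono] = 1.0
    expected_min = np.minimum(alt_tot, ref_tot) * min(tot_case, tot_ctrl) / n
    needs_exact = (expected_min < 5) & ~mono
    return chi2, p, needs_exact


def _exact_p_lookup(
    alt_tot: int, tot_case: int, tot_ctrl: int
) -> np.ndarray:
    """Two-sided Fisher p for every possible case alt-allele count given the
    fixed margins; used to evaluate exact sites across many permutations."""
    lo = max(0, alt_tot - tot_ctrl)
    hi = min(alt_tot, tot_case)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, tot_case + tot_ctrl, alt_tot, tot_case)
    out = np.zeros(tot_case + 1)
    for a, pa in zip(support, pmf):
        out[a] = pmf[pmf <= pa * (1 + 1e-7)].sum()
    return np.minimum(out, 1.0)


def permutation_threshold(
    genotypes: np.ndarray,
    phenotypes: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide p-value threshold by the max-statistic permutation method.

    For each of ``n_perm`` random relabelings of the phenotypes the minimum
    p-value across all sites is recorded; the threshold is the empirical
    alpha-quantile of those minima (the k-th smallest with
    k = floor(alpha*(n_perm+1)), so a site with p strictly below it is
    genome-wide significant at level alpha).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    k = min(int(np.floor(alpha * (n_perm + 1))), n_perm)
    if k < 1:
        raise ValueError("alpha too small for the number of permutations")
    genotypes = np.asarray(genotypes, dtype=np.float64)
    phenotypes = np.asarray(phenotypes).astype(bool)
    rng = np.random.default_rng(seed)
    n, m = genotypes.shape
    n_case = int(phenotypes.sum())
    tot_case, tot_ctrl = 2 * n_case, 2 * (n - n_case)
    alt_tot = genotypes.sum(axis=0)
    # permuted case alt-allele counts for all sites at once
    perm_y = np.zeros((n_perm, n))
    for r in range(n_perm):
        perm_y[r, rng.choice(n, size=n_case, replace=False)] = 1.0
    alt_case = perm_y @ genotypes  # (n_perm, m)
    ref_tot = tot_case + tot_ctrl - alt_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_ctrl = alt_tot - alt_case
        num = (tot_case + tot_ctrl) * (
            alt_case * (tot_ctrl - alt_ctrl) - (tot_case - alt_case) * alt_ctrl
        ) ** 2
        den = tot_case * tot_ctrl * alt_tot * ref_tot
        chi2 = num / den
    mono = (alt_tot == 0) | (ref_tot == 0)
    chi2[:, mono] = 0.0
    p = stats.chi2.sf(chi2, df=1)
    p[:, mono] = 1.0
    # exact-test substitution: margins are permutation-invariant, so the
    # affected sites are fixed and their p-values can be looked up by count
    _, _, needs_exact = _chi2_vector(genotypes, phenotypes)
    for j in np.nonzero(needs_exact)[0]:
        lookup = _exact_p_lookup(int(alt_tot[j]), tot_case, tot_ctrl)
        p[:, j] = lookup[alt_case[:, j].astype(int)]
    minima = p.min(axis=1)
    return float(np.sort(minima)[k - 1])


@dataclass
class ScanResult:
    """A completed association scan."""

    table: pd.DataFrame
    threshold: float
    significant: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.table["p"].to_numpy()
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p-values must lie in (0, 1]")


def run_scan(
    genotypes: np.ndarray,
    phenotypes: np.ndarray,
    positions: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ScanResult:
    """Scan plus permutation threshold plus the significant-site table."""
    table = scan(genotypes, phenotypes, positions)
    threshold = permutation_threshold(genotypes, phenotypes, n_perm, alpha, seed)
    significant = table[table["p"] < threshold].reset_index(drop=True)
    return ScanResult(table=table, threshold=threshold, significant=significant)


def peak_region(
    positions: np.ndarray | list[int],
    p_values: np.ndarray | list[float],
    delta: float = 2.0,
) -> tuple[int, int, int]:
    """Peak-anchored association region.

    The peak is the site with minimum p (leftmost on ties); the region spans
    from the leftmost to the rightmost site whose -log10(p) is within
    ``delta`` units of the peak's. Returns (start_position, end_position,
    peak_index). A single site yields a zero-length interval at that site.
    """
    positions = np.asarray(positions)
    p_values = np.asarray(p_values, dtype=float)
    if positions.size == 0:
        raise ValueError("need at least one site")
    order = np.argsort(positions, kind="stable")
    positions, p_values = positions[order], p_values[order]
    peak_idx = int(np.argmin(p_values))
    logp = -np.log10(p_values)
    inside = logp >= logp[peak_idx] - delta
    idx = np.nonzero(inside)[0]
    return int(positions[idx[0]]), int(positions[idx[-1]]), peak_idx
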