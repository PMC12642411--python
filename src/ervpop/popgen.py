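"""Windowed diversity statistics and haplotype-class contrasts.

All statistics operate on aligned haplotype sequences of equal length.
Columns containing gaps ('-') or non-ACGT characters are excluded from S,
pi, and Tajima's D by default, the conservative convention for statistics
computed from whole-assembly alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, sqrt

import numpy as np
import pandas as pd

from .core import HaplotypeSet

__all__ = [
    "segregating_sites",
    "nucleotide_diversity",
    "tajimas_d",
    "sliding_window_stats",
    "ehh",
    "EhhCurve",
    "ld_r2",
    "window_quantile_flags",
    "carrier_stats",
]

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _as_matrix(alignment: list[str] | np.ndarray) -> np.ndarray:
    if isinstance(alignment, np.ndarray):
        return alignment
    arr = np.vstack(
        [np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in alignment]
    )
    return arr


def _valid_columns(mat: np.ndarray, skip_gap_columns: bool = True) -> np.ndarray:
    """Mask of columns usable for the statistics (all-ACGT by default)."""
    ok = np.isin(mat, _ACGT)
    if skip_gap_columns:
        return ok.all(axis=0)
    # with gaps allowed, a column is usable if >=2 haplotypes have ACGT states
    return ok.sum(axis=0) >= 2


def _allele_counts(mat: np.ndarray) -> np.ndarray:
    """Counts of A/C/G/T per column, shape (4, n_cols)."""
    return np.stack([(mat == b).sum(axis=0) for b in _ACGT])


def segregating_sites(
    alignment: list[str] | np.ndarray, skip_gap_columns: bool = True
) -> int:
    """Number of columns with at least two distinct valid states."""
    mat = _as_matrix(alignment)
    if mat.shape[0] < 2:
        raise ValueError("need at least two haplotypes")
    valid = _valid_columns(mat, skip_gap_columns)
    counts = _allele_counts(mat[:, valid])
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def nucleotide_diversity(
    alignment: list[str] | np.ndarray, skip_gap_columns: bool = True
) -> float:
    """Mean pairwise difference per comparable site over all haplotype pairs."""
    mat = _as_matrix(alignment)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two haplotypes")
    valid = _valid_columns(mat, skip_gap_columns)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no comparable sites in alignment")
    counts = _allele_counts(mat[:, valid])
    pairs_total = comb(n, 2)
    same = (counts * (counts - 1) // 2).sum(axis=0)
    pi_cols = 1.0 - same / pairs_total
    return float(pi_cols.sum() / n_valid)


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(
    alignment: list[str] | np.ndarray, skip_gap_columns: bool = True
) -> float | None:
    """Tajima's D; ``None`` (undefined, distinct from 0.0) when S = 0.

    D = (pi_total - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the canonical
    constants derived from the sample size.
    """
    mat = _as_matrix(alignment)
    n = mat.shape[0]
    if n < 4:
        raise ValueError("Tajima's D requires at least 4 haplotypes")
    valid = _valid_columns(mat, skip_gap_columns)
    counts = _allele_counts(mat[:, valid])
    seg = (counts > 0).sum(axis=0) >= 2
    s = int(seg.sum())
    if s == 0:
        return None
    pairs_total = comb(n, 2)
    same = (counts * (counts - 1) // 2).sum(axis=0)
    pi_total = float((1.0 - same / pairs_total).sum())
    a1 = sum(1.0 / i for i in range(1, n))
    e1, e2 = _tajima_constants(n)
    return (pi_total - s / a1) / sqrt(e1 * s + e2 * s * (s - 1))


def sliding_window_stats(
    hapset: HaplotypeSet,
    window: int = 5000,
    step: int | None = None,
    match_sample_sizes: bool = False,
    n_subsamples: int = 1,
    seed: int = 0,
    skip_gap_columns: bool = True,
) -> pd.DataFrame:
    """Per-class, per-window S, pi, and Tajima's D.

    Windows tile [0, L) half-open; by default they are non-overlapping
    (step = window). With ``match_sample_sizes`` the larger class is randomly
    subsampled (seeded) to the smaller class's size before computing the
    statistics; ``n_subsamples`` > 1 averages over repeated draws.
    """
    if step is None:
        step = window
    classes = hapset.by_class()
    if any(len(v) == 0 for v in classes.values()) or not classes:
        raise ValueError("every class must be non-empty")
    rng = np.random.default_rng(seed)
    length = hapset.length
    min_size = min(len(v) for v in classes.values())
    rows = []
    for label, seqs in classes.items():
        mat = _as_matrix(seqs)
        if match_sample_sizes and mat.shape[0] > min_size:
            draws = [
                rng.choice(mat.shape[0], size=min_size, replace=False)
                for _ in range(n_subsamples)
            ]
            mats = [mat[d] for d in draws]
        else:
            mats = [mat]
        for start in range(0, length, step):
            end = min(start + window, length)
            svals, pivals, dvals = [], [], []
            for m in mats:
                sub = m[:, start:end]
                svals.append(segregating_sites(sub, skip_gap_columns))
                pivals.append(nucleotide_diversity(sub, skip_gap_columns))
                if m.shape[0] >= 4:
                    d = tajimas_d(sub, skip_gap_columns)
                    if d is not None:
                        dvals.append(d)
            rows.append(
                {
                    "seq_name": hapset.seq_name,
                    "start": start,
                    "end": end,
                    "class_label": label,
                    "n_haplotypes": mats[0].shape[0],
                    "S": float(np.mean(svals)),
                    "pi": float(np.mean(pivals)),
                    "tajima_d": float(np.mean(dvals)) if dvals else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class EhhCurve:
    """Extended haplotype homozygosity outward from a core site."""

    core_index: int
    core_allele: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        core = self.values[self.positions == self.core_index]
        if core.size and not np.isclose(core[0], 1.0):
            raise ValueError("EHH must equal 1 at the core")


def ehh(
    alignment: list[str] | np.ndarray, core_index: int, core_allele: str
) -> EhhCurve:
    """EHH(x): fraction of core-carrying haplotype pairs identical at every
    site from the core through x, computed outward in both directions."""
    mat = _as_matrix(alignment)
    carriers = mat[mat[:, core_index] == ord(core_allele)]
    n_core = carriers.shape[0]
    if n_core < 2:
        raise ValueError("need >=2 haplotypes carrying the core allele")
    pairs_total = comb(n_core, 2)
    length = mat.shape[1]

    def _half(indices: range) -> tuple[list[int], list[float]]:
        # refine a partition of carriers column by column; EHH is the
        # probability two carriers fall in the same block
        groups = [np.arange(n_core)]
        pos_out, val_out = [], []
        for x in indices:
            new_groups = []
            for g in groups:
                col = carriers[g, x]
                for allele in np.unique(col):
                    new_groups.append(g[col == allele])
            groups = new_groups
            same = sum(comb(len(g), 2) for g in groups)
            pos_out.append(x)
            val_out.append(same / pairs_total)
        return pos_out, val_out

    left_pos, left_val = _half(range(core_index - 1, -1, -1))
    right_pos, right_val = _half(range(core_index + 1, length))
    positions = np.array(left_pos[::-1] + [core_index] + right_pos)
    values = np.array(left_val[::-1] + [1.0] + right_val)
    if np.any(np.diff(values[positions >= core_index]) > 1e-12):
        raise AssertionError("EHH increased away from the core")
    if np.any(np.diff(values[positions <= core_index][::-1]) > 1e-12):
        raise AssertionError("EHH increased away from the core")
    return EhhCurve(
        core_index=core_index,
        core_allele=core_allele,
        positions=positions,
        values=values,
    )


def ld_r2(
    alignment: list[str] | np.ndarray, site_pairs: list[tuple[int, int]]
) -> np.ndarray:
    """r-squared between pairs of biallelic sites from haplotype counts."""
    mat = _as_matrix(alignment)
    n = mat.shape[0]
    out = np.empty(len(site_pairs))
    for k, (i, j) in enumerate(site_pairs):
        for col in (i, j):
            if len(np.unique(mat[:, col])) != 2:
                raise ValueError(f"site {col} is not biallelic")
        ref_i = np.unique(mat[:, i])[0]
        ref_j = np.unique(mat[:, j])[0]
        a = mat[:, i] == ref_i
        b = mat[:, j] == ref_j
        p_a = a.mean()
        p_b = b.mean()
        p_ab = (a & b).mean()
        denom = p_a * (1 - p_a) * p_b * (1 - p_b)
        out[k] = (p_ab - p_a * p_b) ** 2 / denom
    return out


def window_quantile_flags(
    values: np.ndarray | list[float], q: float = 0.95
) -> tuple[np.ndarray, dict[str, float]]:
    """Flag windows whose statistic is >= the empirical q-quantile.

    Returns the boolean flags and a summary with the mean and the quantile
    value of the distribution across windows. Flagging uses >= so a constant
    statistic flags every window (documented tie rule).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 20:
        raise ValueError("need at least 20 windows for quantile flagging")
    quantile = float(np.quantile(values, q))
    flags = values >= quantile
    return flags, {"mean": float(values.mean()), "quantile": quantile, "q": q}


def carrier_stats(n_case: int, n_total: int) -> tuple[float, float]:
    """Trait prevalence and its binomial standard error, as percentages.

    Both are rounded to one decimal, e.g. 66 carriers among 260 sampled
    individuals gives (25.4, 2.7).
    """
    if not 0 <= n_case <= n_total or n_total <= 0:
        raise ValueError("need 0 <= n_case <= n_total and n_total > 0")
    p = n_case / n_total
    se = sqrt(p * (1 - p) / n_total)
    return round(100 * p, 1), round(100 * se, 1)
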