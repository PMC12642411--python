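"""Detection and description of full-length LTR-retroelement insertions.

A full-length element is recognised by its paired long terminal repeats:
two near-identical same-strand repeats at the element's ends, found by exact
k-mer seeding and ungapped X-drop extension. The short host duplication left
at the integration site (target-site duplication, TSD) and the long open
reading frames of the internal region complete the anatomy. Presence/absence
of catalogued elements across assembled haplotypes is scored by locating the
flanking anchor sequences and measuring the distance between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .core import ErvElement, HaplotypeSet, Span

__all__ = [
    "LtrPair",
    "find_ltr_pair",
    "find_tsd",
    "scan_orfs",
    "annotate_element",
    "is_complete_element",
    "AnchorCatalogEntry",
    "catalog_from_truth",
    "PresenceAbsenceMatrix",
    "presence_absence",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_STOPS = ("TAA", "TAG", "TGA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class LtrPair:
    """A candidate pair of terminal repeats within a window."""

    ltr5: Span
    ltr3: Span
    identity: float


def _seed_offsets(seq: str, k: int, min_sep: int) -> dict[int, list[int]]:
    """Positions of exact k-mer matches grouped by diagonal offset."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    offsets: dict[int, list[int]] = {}
    for positions in index.values():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                d = positions[b] - positions[a]
                if d >= min_sep:
                    offsets.setdefault(d, []).append(positions[a])
    return offsets


def _exact_extend(seq: str, start: int, end: int, offset: int) -> Span:
    """Grow a span on diagonal ``offset`` while both copies match exactly."""
    n = len(seq)
    while end + offset < n and seq[end] == seq[end + offset]:
        end += 1
    while start > 0 and seq[start - 1] == seq[start - 1 + offset]:
        start -= 1
    return start, end


def _xdrop_extend(
    seq: str,
    start: int,
    end: int,
    offset: int,
    match_score: float,
    mismatch_score: float,
    xdrop: float,
) -> Span:
    """Best-scoring ungapped extension with an X-drop stopping rule."""
    n = len(seq)
    best, cur, best_end = 0.0, 0.0, end
    j = end
    while j + offset < n:
        cur += match_score if seq[j] == seq[j + offset] else mismatch_score
        if cur > best:
            best, best_end = cur, j + 1
        if best - cur > xdrop:
            break
        j += 1
    best, cur, best_start = 0.0, 0.0, start
    j = start - 1
    while j >= 0:
        cur += match_score if seq[j] == seq[j + offset] else mismatch_score
        if cur > best:
            best, best_start = cur, j
        if best - cur > xdrop:
            break
        j -= 1
    return best_start, best_end


def _extend(seq: str, start: int, end: int, offset: int) -> Span:
    """Repeat-boundary estimation on one diagonal.

    The seeded core is first grown by exact matching. A provisional tolerant
    extension estimates the column mismatch rate over its interior; when that
    rate is zero the exact-run boundaries are final (identical repeat copies
    end at their first mismatch), otherwise the boundaries are re-derived
    with a log-likelihood score whose mismatch penalty reflects the observed
    divergence, so light within-pair divergence is crossed while random flank
    sequence is not.
    """
    start, end = _exact_extend(seq, start, end, offset)
    prov_s, prov_e = _xdrop_extend(seq, start, end, offset, 1.0, -1.0, 12.0)
    interior = range(prov_s + 12, prov_e - 12)
    n_cols = len(interior)
    mismatches = sum(1 for p in interior if seq[p] != seq[p + offset])
    if n_cols <= 0 or mismatches == 0:
        return start, end
    m = min(max(mismatches / n_cols, 0.005), 0.25)
    match_score = np.log(4.0 * (1.0 - m))
    mismatch_score = np.log(4.0 * m / 3.0)
    return _xdrop_extend(seq, start, end, offset, match_score, mismatch_score, 18.0)


def find_ltr_pair(
    window_seq: str,
    min_ltr_len: int = 100,
    max_ltr_len: int = 3000,
    min_identity: float = 0.8,
    k: int = 15,
) -> LtrPair | None:
    """Highest-scoring pair of same-strand terminal repeats, or None.

    Exact k-mer seeds shared between two positions define candidate diagonal
    offsets; dense seed runs are extended ungapped with an X-drop rule, and
    the two copies' identity is scored by edit distance. Absence of any pair
    with identity >= ``min_identity`` is a valid result (None).
    """
    seq = window_seq.upper()
    if len(seq) < 2 * min_ltr_len:
        raise ValueError("window shorter than two minimum-length LTRs")
    offsets = _seed_offsets(seq, k, min_sep=min_ltr_len)
    best: LtrPair | None = None
    best_score = 0.0
    # strongest offsets first: more seeds = more plausible repeat
    ranked = sorted(offsets.items(), key=lambda kv: len(kv[1]), reverse=True)[:10]
    for offset, seeds in ranked:
        seeds = sorted(seeds)
        # cluster seeds into dense runs (gap <= 100 bp between seed starts)
        runs: list[list[int]] = [[seeds[0]]]
        for s in seeds[1:]:
            if s - runs[-1][-1] <= 100:
                runs[-1].append(s)
            else:
                runs.append([s])
        run = max(runs, key=len)
        start, end = _extend(seq, run[0], run[-1] + k, offset)
        if end - start > max_ltr_len:
            # keep the densest max_ltr_len stretch anchored on the seed run
            mid = (run[0] + run[-1] + k) // 2
            start = max(start, mid - max_ltr_len // 2)
            end = min(end, start + max_ltr_len)
        length = end - start
        if length < min_ltr_len:
            continue
        copy5 = seq[start:end]
        copy3 = seq[start + offset : end + offset]
        dist = edlib.align(copy5, copy3, task="distance")["editDistance"]
        identity = 1.0 - dist / max(len(copy5), len(copy3))
        score = length * identity
        if identity >= min_identity and score > best_score:
            best_score = score
            best = LtrPair(
                ltr5=(start, end),
                ltr3=(start + offset, end + offset),
                identity=identity,
            )
    return best


def find_tsd(
    genome_seq: str, element_span: Span, min_len: int = 4, max_len: int = 8
) -> str | None:
    """Longest exact duplication anchored at the element boundaries.

    Compares the ``max_len`` bases immediately 5' of the element with the
    ``max_len`` bases immediately 3' of it; the longest shared word that is a
    suffix of the left flank and a prefix of the right flank, if at least
    ``min_len`` long, is the target-site duplication.
    """
    start, end = element_span
    if start < max_len or end + max_len > len(genome_seq):
        raise ValueError("element needs >= max_len bases of flank on both sides")
    left = genome_seq[start - max_len : start]
    right = genome_seq[end : end + max_len]
    for length in range(max_len, min_len - 1, -1):
        if left[-length:] == right[:length]:
            return right[:length]
    return None


def scan_orfs(seq: str, min_aa: int = 100) -> list[tuple[Span, str, int]]:
    """Open reading frames on both strands, three frames each.

    An ORF runs from the first ATG after the previous stop (or frame break)
    to the next in-frame stop, with total length >= 3*(min_aa+1) nucleotides
    including the stop. Ambiguous bases break ORFs. Coordinates are on the
    forward strand (0-based half-open); entries are (span, strand, frame),
    reported longest-first.
    """
    seq = seq.upper()
    n = len(seq)
    found: list[tuple[Span, str, int]] = []
    min_nt = 3 * (min_aa + 1)
    for strand in "+-":
        s = seq if strand == "+" else _revcomp(seq)
        for frame in range(3):
            start: int | None = None
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if any(c not in "ACGT" for c in codon):
                    start = None  # ambiguity breaks the ORF
                    continue
                if codon in _STOPS:
                    if start is not None and pos + 3 - start >= min_nt:
                        if strand == "+":
                            span = (start, pos + 3)
                        else:
                            span = (n - (pos + 3), n - start)
                        found.append((span, strand, frame))
                    start = None
                elif codon == "ATG" and start is None:
                    start = pos
    found.sort(key=lambda t: (-(t[0][1] - t[0][0]), t[0][0]))
    return found


def annotate_element(
    seq: str,
    seq_name: str = "query",
    min_ltr_len: int = 100,
    max_ltr_len: int = 3000,
    min_identity: float = 0.8,
    min_aa: int = 100,
    tsd_min_len: int = 4,
    tsd_max_len: int = 8,
) -> ErvElement | None:
    """Full annotation of the best candidate element in a window: LTR pair,
    TSD (when flanks allow), and internal ORFs."""
    pair = find_ltr_pair(seq, min_ltr_len, max_ltr_len, min_identity)
    if pair is None:
        return None
    start, end = pair.ltr5[0], pair.ltr3[1]
    tsd = None
    if start >= tsd_max_len and end + tsd_max_len <= len(seq):
        tsd = find_tsd(seq, (start, end), tsd_min_len, tsd_max_len)
    internal = (pair.ltr5[1], pair.ltr3[0])
    orfs_local = scan_orfs(seq[internal[0] : internal[1]], min_aa=min_aa)
    orfs = [
        ((internal[0] + a, internal[0] + b), strand, frame)
        for (a, b), strand, frame in orfs_local
    ]
    return ErvElement(
        seq_name=seq_name,
        start=start,
        end=end,
        ltr5=pair.ltr5,
        ltr3=pair.ltr3,
        internal=internal,
        tsd=tsd,
        orfs=orfs,
        ltr_identity=pair.identity,
    )


def is_complete_element(
    element: ErvElement,
    min_identity: float = 0.8,
    min_orf_coverage: float = 0.5,
    min_aa: int = 100,
) -> bool:
    """Operational definition of a complete element: both LTRs detected at
    identity >= ``min_identity`` and ORFs of >= ``min_aa`` covering at least
    ``min_orf_coverage`` of the internal region. Monotone: raising either
    threshold never adds complete elements."""
    if element.ltr_identity < min_identity:
        return False
    internal_len = element.internal[1] - element.internal[0]
    if internal_len <= 0:
        return False
    covered = np.zeros(internal_len, dtype=bool)
    for (a, b), _strand, _frame in element.orfs:
        if b - a >= 3 * (min_aa + 1):
            lo = max(a, element.internal[0]) - element.internal[0]
            hi = min(b, element.internal[1]) - element.internal[0]
            if hi > lo:
                covered[lo:hi] = True
    return covered.mean() >= min_orf_coverage


# ---------------------------------------------------------------------------
# presence/absence across haplotypes


@dataclass
class AnchorCatalogEntry:
    """Flanking anchors and expected geometry of one catalogued locus."""

    locus: str
    left_anchor: str
    right_anchor: str
    element_length: int
    tsd_len: int


def catalog_from_truth(
    locus: str, genome_seq: str, element: ErvElement, anchor_len: int = 500
) -> AnchorCatalogEntry:
    """Build a catalog entry from a planted genome: anchors are taken just
    outside the target-site duplications."""
    tsd_len = len(element.tsd) if element.tsd else 0
    left_end = element.start - tsd_len
    right_start = element.end + tsd_len
    if left_end < anchor_len or right_start + anchor_len > len(genome_seq):
        raise ValueError("not enough flank for the requested anchor length")
    return AnchorCatalogEntry(
        locus=locus,
        left_anchor=genome_seq[left_end - anchor_len : left_end],
        right_anchor=genome_seq[right_start : right_start + anchor_len],
        element_length=element.length,
        tsd_len=tsd_len,
    )


@dataclass
class PresenceAbsenceMatrix:
    """Loci x haplotypes calls in {present, absent, unresolved} with a
    per-locus fixed/polymorphic classification."""

    matrix: pd.DataFrame
    locus_call: pd.Series

    def __post_init__(self) -> None:
        has_present = (self.matrix == "present").any(axis=1)
        if not has_present.all():
            missing = list(self.matrix.index[~has_present])
            raise ValueError(f"loci with no present call: {missing}")


def _locate_anchor(
    hap_seq: str, anchor: str, min_identity: float
) -> tuple[Span | None, str | None]:
    """Best infix hit of an anchor in a haplotype. Returns (span, reason);
    span is None with a reason when unresolved (weak or multi-mapping)."""
    res = edlib.align(anchor, hap_seq, mode="HW", task="locations")
    dist = res["editDistance"]
    identity = 1.0 - dist / len(anchor)
    if identity < min_identity:
        return None, "no_hit"
    locs = res["locations"]
    starts = sorted({s for s, _ in locs})
    # well-separated equally good hits mean the anchor multi-maps
    if starts[-1] - starts[0] > len(anchor):
        return None, "multi_mapping"
    s, e = locs[0]
    return (s, e + 1), None


def presence_absence(
    haplotypes: dict[str, str] | HaplotypeSet,
    catalog: list[AnchorCatalogEntry],
    min_anchor_identity: float = 0.9,
    length_tolerance: float = 0.1,
) -> PresenceAbsenceMatrix:
    """Score each catalogued locus in each haplotype.

    Both flanking anchors are located; the locus is present when the
    inter-anchor distance matches the element length (within
    ``length_tolerance`` of it, plus both TSD copies), absent when it matches
    the empty site (one target-site copy, within a TSD-length tolerance), and
    unresolved otherwise. Haplotypes here need not be aligned, so a plain
    name -> sequence mapping is accepted alongside a ``HaplotypeSet``.
    """
    if isinstance(haplotypes, HaplotypeSet):
        haplotypes = dict(zip(haplotypes.names, haplotypes.seqs))
    calls = pd.DataFrame(
        index=[c.locus for c in catalog], columns=list(haplotypes), dtype=object
    )
    for entry in catalog:
        occupied = entry.element_length + 2 * entry.tsd_len
        empty = entry.tsd_len
        for name, seq in haplotypes.items():
            left, why_l = _locate_anchor(seq, entry.left_anchor, min_anchor_identity)
            right, why_r = _locate_anchor(seq, entry.right_anchor, min_anchor_identity)
            if left is None or right is None:
                calls.loc[entry.locus, name] = "unresolved"
                continue
            gap = right[0] - left[1]
            if abs(gap - occupied) <= length_tolerance * entry.element_length:
                calls.loc[entry.locus, name] = "present"
            elif abs(gap - empty) <= entry.tsd_len + 2:
                calls.loc[entry.locus, name] = "absent"
            else:
                calls.loc[entry.locus, name] = "unresolved"
    def _classify(row: pd.Series) -> str:
        values = set(row)
        if "present" in values and "absent" in values:
            return "polymorphic"
        resolvable = [v for v in row if v != "unresolved"]
        if resolvable and all(v == "present" for v in resolvable):
            return "fixed"
        return "unresolved"

    locus_call = calls.apply(_classify, axis=1)
    return PresenceAbsenceMatrix(matrix=calls, locus_call=locus_call)
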