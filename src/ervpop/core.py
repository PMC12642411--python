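"""Shared domain types for the ERV insertion-polymorphism pipeline.

Coordinates are 0-based half-open throughout the library; writers that emit
1-based formats (GFF3, VCF) convert at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

Span = tuple[int, int]


@dataclass(frozen=True)
class Epoch:
    """One piecewise-constant demographic epoch.

    Times are in generations before present; ``end`` may be ``None`` for an
    open-ended terminal epoch. ``n_diploid`` is the diploid population size.
    """

    start: int
    end: int | None
    n_diploid: int

    def __post_init__(self) -> None:
        if self.n_diploid < 2:
            raise ValueError("diploid population size must be >= 2")
        if self.end is not None and self.end <= self.start:
            raise ValueError("epoch end must exceed start")


@dataclass(frozen=True)
class Demography:
    """Piecewise-constant diploid population sizes over time.

    Epochs are ordered from the present backwards and must tile the time axis
    from 0 without gaps or overlaps.
    """

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("at least one epoch required")
        if self.epochs[0].start != 0:
            raise ValueError("first epoch must start at 0 generations before present")
        for prev, cur in zip(self.epochs, self.epochs[1:]):
            if prev.end is None:
                raise ValueError("only the terminal epoch may be open-ended")
            if cur.start != prev.end:
                raise ValueError("epochs must be contiguous")

    @classmethod
    def constant(cls, n_diploid: int) -> "Demography":
        return cls((Epoch(0, None, n_diploid),))

    @property
    def t_max(self) -> float:
        last = self.epochs[-1]
        return np.inf if last.end is None else last.end

    def size_at(self, t: int) -> int:
        """Diploid size at ``t`` generations before present."""
        if t < 0:
            raise ValueError("time must be non-negative")
        for ep in self.epochs:
            if ep.end is None or t < ep.end:
                if t >= ep.start:
                    return ep.n_diploid
        raise ValueError(f"time {t} not covered by demography")

    def size_array(self, t_max: int) -> np.ndarray:
        """Vector of diploid sizes for t = 0..t_max inclusive."""
        out = np.empty(t_max + 1, dtype=np.int64)
        for ep in self.epochs:
            lo = ep.start
            hi = t_max + 1 if ep.end is None else min(ep.end, t_max + 1)
            if lo <= t_max:
                out[lo:hi] = ep.n_diploid
        if self.t_max < t_max + 1:
            raise ValueError("demography does not cover requested time span")
        return out

    def to_json(self) -> str:
        return json.dumps(
            {"epochs": [[e.start, e.end, e.n_diploid] for e in self.epochs]}
        )

    @classmethod
    def from_json(cls, text: str) -> "Demography":
        data = json.loads(text)
        return cls(tuple(Epoch(s, e, n) for s, e, n in data["epochs"]))


@dataclass(frozen=True)
class ErvConstruct:
    """Blueprint of a full-length LTR retroelement used for planting.

    The single ``ltr_seq`` is duplicated verbatim at both ends at creation, so
    the 5' and 3' copies start identical. ORF spans are relative to
    ``internal_seq`` and must be codon-sized.
    """

    ltr_seq: str
    internal_seq: str
    orf_layout: tuple[tuple[int, int, str], ...] = ()
    tsd_len: int = 6

    def __post_init__(self) -> None:
        if not self.ltr_seq or not self.internal_seq:
            raise ValueError("LTR and internal sequences must be non-empty")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")
        for start, end, strand in self.orf_layout:
            if not (0 <= start < end <= len(self.internal_seq)):
                raise ValueError("ORF span outside internal sequence")
            if (end - start) % 3 != 0:
                raise ValueError("ORF span length must be divisible by 3")
            if strand not in "+-":
                raise ValueError("ORF strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return 2 * len(self.ltr_seq) + len(self.internal_seq)


@dataclass
class ErvElement:
    """Coordinates and anatomy of one insertion on a named sequence."""

    seq_name: str
    start: int
    end: int
    ltr5: Span
    ltr3: Span
    internal: Span
    tsd: str | None = None
    orfs: list[tuple[Span, str, int]] = field(default_factory=list)
    ltr_identity: float = 1.0

    def __post_init__(self) -> None:
        if not (self.start <= self.ltr5[0] < self.ltr5[1] <= self.internal[0]):
            raise ValueError("5' LTR must precede internal region within element")
        if not (self.internal[0] <= self.internal[1] <= self.ltr3[0]):
            raise ValueError("internal region must precede 3' LTR")
        if not (self.ltr3[0] < self.ltr3[1] <= self.end):
            raise ValueError("3' LTR must lie within element")
        if not 0.0 <= self.ltr_identity <= 1.0:
            raise ValueError("ltr_identity must be in [0,1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HaplotypeSet:
    """Aligned haplotype sequences with per-haplotype class labels."""

    names: list[str]
    seqs: list[str]
    labels: dict[str, str]
    seq_name: str = "region"

    def __post_init__(self) -> None:
        if len(self.names) != len(self.seqs):
            raise ValueError("names and seqs must have equal length")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("haplotypes must be aligned to equal length")
        missing = [n for n in self.names if n not in self.labels]
        if missing:
            raise ValueError(f"labels missing for haplotypes: {missing}")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def by_class(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name, seq in zip(self.names, self.seqs):
            out.setdefault(self.labels[name], []).append(seq)
        return out

    def subset(self, names: list[str]) -> "HaplotypeSet":
        idx = {n: i for i, n in enumerate(self.names)}
        return HaplotypeSet(
            names=list(names),
            seqs=[self.seqs[idx[n]] for n in names],
            labels={n: self.labels[n] for n in names},
            seq_name=self.seq_name,
        )


@dataclass
class PopulationTruth:
    """Ground truth for one simulated insertion history."""

    insertion_time: int
    survived: bool
    allele_frequency: float
    carrier_flags: list[bool]
    mutation_positions: np.ndarray
    ltr_pairs: list[tuple[str, str]]
    final_copies: int


@dataclass
class MethylationTrack:
    """Ordered CpG positions with methylation scores in [0,1]."""

    seq_name: str
    positions: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.positions.shape != self.scores.shape:
            raise ValueError("positions and scores must align")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("CpG positions must be strictly increasing")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0,1]")

    def __len__(self) -> int:
        return int(self.positions.size)
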