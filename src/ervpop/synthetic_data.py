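"""Generators for every input the pipeline consumes, with known ground truth.

Four families of inputs are produced:

* genomes with a planted full-length LTR retroelement (paired identical LTRs,
  a target-site duplication, internal ORFs);
* population haplotype samples in which the insertion arose as a single copy
  ``T`` generations ago and drifted under a piecewise-constant demography;
* case/control genotype matrices with one dominant, fully penetrant causal
  locus;
* CpG methylation tracks with a hypomethylated dip at the LTRs.

All randomness flows from one integer seed per operation.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import truncnorm

from .core import (
    Demography,
    ErvConstruct,
    ErvElement,
    HaplotypeSet,
    MethylationTrack,
    PopulationTruth,
)
from .wright_fisher import (
    carrier_genealogy,
    drop_mutations,
    final_allele_counts,
    kingman_tree,
    surviving_trajectories,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# distinct stream keys so the same integer seed, passed to different
# operations, never yields overlapping random streams
_STREAM_CONSTRUCT = 1
_STREAM_GENOME = 2
_STREAM_LTR_PAIRS = 3
_STREAM_POPULATION = 4
_STREAM_CASE_CONTROL = 5
_STREAM_METHYLATION = 6


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random nucleotide sequence."""
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-site substitutions at the given rate (to a different base)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(idx + rng.integers(1, 4, size=hit.size)) % 4]
    return arr.tobytes().decode()


def _derived_bases(
    ancestral: np.ndarray, positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One derived base per mutation, guaranteed to differ from the ancestral."""
    idx = np.searchsorted(_BASES, ancestral[positions])
    return _BASES[(idx + rng.integers(1, 4, size=positions.size)) % 4]


# ---------------------------------------------------------------------------
# planted genomes


def make_erv_genome(
    genome_length: int,
    construct: ErvConstruct,
    position: int,
    seed: int,
    target_site: str | None = None,
) -> tuple[str, ErvElement]:
    """Plant a full-length element into a random background genome.

    The ``tsd_len`` bases at the target site are duplicated so they flank the
    element on both sides (the hallmark of retroviral integration). Returns
    the new sequence and an exact truth record of all coordinates (0-based
    half-open). Total output length is
    ``genome_length + 2*|ltr| + |internal| + tsd_len``.
    """
    tsd_len = construct.tsd_len
    if not 0 <= position <= genome_length - tsd_len:
        raise ValueError("position (plus TSD) out of range for genome length")
    if tsd_len > genome_length:
        raise ValueError("tsd_len exceeds genome length")
    rng = np.random.default_rng([_STREAM_GENOME, seed])
    background = random_sequence(genome_length, rng)
    if target_site is not None:
        if len(target_site) != tsd_len:
            raise ValueError("target_site length must equal tsd_len")
        background = (
            background[:position] + target_site + background[position + tsd_len :]
        )
    tsd = background[position : position + tsd_len]
    element_seq = construct.ltr_seq + construct.internal_seq + construct.ltr_seq
    seq = (
        background[:position]
        + tsd
        + element_seq
        + tsd
        + background[position + tsd_len :]
    )
    el_start = position + tsd_len
    ltr_len = len(construct.ltr_seq)
    internal_start = el_start + ltr_len
    internal_end = internal_start + len(construct.internal_seq)
    el_end = internal_end + ltr_len
    orfs = [
        ((internal_start + s, internal_start + e), strand, (internal_start + s) % 3)
        for s, e, strand in construct.orf_layout
    ]
    truth = ErvElement(
        seq_name="synthetic_genome",
        start=el_start,
        end=el_end,
        ltr5=(el_start, internal_start),
        ltr3=(internal_end, el_end),
        internal=(internal_start, internal_end),
        tsd=tsd if tsd_len > 0 else None,
        orfs=orfs,
        ltr_identity=1.0,
    )
    return seq, truth


def _atg_free(seq: str) -> str:
    """Remove every ATG trinucleotide (any frame) by recoding its G."""
    while "ATG" in seq:
        i = seq.index("ATG")
        seq = seq[: i + 2] + "C" + seq[i + 3 :]
    return seq


def default_construct(
    rng: np.random.Generator | int = 0,
    ltr_len: int = 600,
    internal_len: int = 9000,
    n_orfs: int = 3,
    orf_aa: int = 600,
    tsd_len: int = 6,
    target_site: str = "TAGTTA",
) -> ErvConstruct:
    """A realistic full-length element: ~10 kb with LTRs and long ORFs.

    ORFs are planted as ATG + non-stop codons + TAA; the spacers between them
    are kept ATG-free so each planted ORF's first in-frame start codon is the
    planted one, making the scanner's truth exact. The internal sequence's
    terminal bases are chosen to differ from the target-site bases so the
    maximal exact terminal repeat equals the planted LTR pair.
    """
    rng = np.random.default_rng([_STREAM_CONSTRUCT, rng]) if isinstance(rng, int) else rng
    ltr = random_sequence(ltr_len, rng)
    # codons avoiding stops and start codons on the forward strand
    stops = {"TAA", "TAG", "TGA"}
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    safe = [c for c in codons if c not in stops and c != "ATG"]
    pieces: list[str] = []
    layout: list[tuple[int, int, str]] = []
    gap = max(30, (internal_len - n_orfs * 3 * (orf_aa + 2)) // (n_orfs + 1))
    cursor = 0
    for _ in range(n_orfs):
        spacer = _atg_free(random_sequence(gap, rng))
        pieces.append(spacer)
        cursor += gap
        orf = "ATG" + "".join(rng.choice(safe) for _ in range(orf_aa)) + "TAA"
        start = cursor
        pieces.append(orf)
        cursor += len(orf)
        layout.append((start, cursor, "+"))
    tail = internal_len - cursor
    if tail > 0:
        pieces.append(_atg_free(random_sequence(tail, rng)))
    internal = list("".join(pieces))
    # keep the LTR boundaries sharp: the base just inside each LTR must not
    # chance-extend the terminal repeat into the TSD copies
    if tsd_len > 0:
        forbidden_first, forbidden_last = target_site[0], target_site[-1]
        if internal[0] == forbidden_first:
            internal[0] = "C" if forbidden_first != "C" else "G"
        if internal[-1] == forbidden_last:
            internal[-1] = "C" if forbidden_last != "C" else "G"
    return ErvConstruct(
        ltr_seq=ltr,
        internal_seq="".join(internal),
        orf_layout=tuple(layout),
        tsd_len=tsd_len,
    )


# ---------------------------------------------------------------------------
# population samples with a dated insertion


def neutral_alignment(
    n: int,
    length: int,
    theta_site: float,
    rng: np.random.Generator,
    ancestral: str | None = None,
) -> list[str]:
    """Neutral Kingman-coalescent alignment with per-site theta.

    Expected pairwise per-site diversity equals ``theta_site`` (infinite
    sites). Used both for background haplotype diversity and as a neutral
    null for Tajima's D calibration.
    """
    if ancestral is None:
        ancestral = random_sequence(length, rng)
    arr0 = np.frombuffer(ancestral.encode(), dtype=np.uint8)
    if n == 1:
        return [ancestral]
    tree = kingman_tree(n, rng)
    positions, carriers = drop_mutations(tree, theta_site / 2.0, length, rng)
    seqs = np.tile(arr0, (n, 1))
    derived = _derived_bases(arr0, positions, rng)
    for pos, tips, base in zip(positions, carriers, derived):
        seqs[tips, pos] = base
    return [row.tobytes().decode() for row in seqs]


def simulate_ltr_pairs(
    t_insertion: int,
    mu: float,
    ltr_length: int,
    n_elements: int,
    seed: int,
) -> list[tuple[str, str]]:
    """Independent elements of age ``t_insertion`` with diverged LTR copies.

    Both LTR copies of each element start identical and accumulate
    substitutions independently at ``mu`` per site per generation, so the
    expected per-site distance between copies is ``2 * mu * t_insertion``.
    """
    rng = np.random.default_rng([_STREAM_LTR_PAIRS, seed])
    ancestral = random_sequence(ltr_length, rng)
    arr0 = np.frombuffer(ancestral.encode(), dtype=np.uint8)
    lam = mu * t_insertion * ltr_length
    counts = rng.poisson(lam, size=(n_elements, 2))
    out: list[tuple[str, str]] = []
    for k5, k3 in counts:
        pair = []
        for k in (k5, k3):
            if k == 0:
                pair.append(ancestral)
                continue
            arr = arr0.copy()
            pos = rng.choice(ltr_length, size=min(int(k), ltr_length), replace=False)
            arr[pos] = _derived_bases(arr0, pos, rng)
            pair.append(arr.tobytes().decode())
        out.append((pair[0], pair[1]))
    return out


def simulate_population(
    demography: Demography,
    t_insertion: int,
    mu: float,
    flank_length: int,
    ltr_length: int,
    n_sample: int,
    seed: int,
    background_pi: float = 0.002,
    n_carriers: int | None = None,
    condition_on_survival: bool = False,
    max_raw: int | None = None,
) -> tuple[HaplotypeSet, PopulationTruth]:
    """Sample haplotypes from a population where an insertion arose ``T``
    generations ago as a single copy.

    The allele's copy count follows a forward Wright-Fisher trajectory. The
    sampled carrier haplotypes coalesce inside the carrier class conditional
    on that trajectory and accumulate infinite-sites flanking mutations at
    rate ``mu`` per site per generation; each carrier's two LTR copies diverge
    by independent per-site mutation along the same genealogy. Non-carrier
    haplotypes are drawn from a neutral background with per-site diversity
    ``background_pi``; the founding carrier haplotype is one background draw.

    If the allele is lost before the present and no conditioning was
    requested, a carrier-free sample is returned with ``truth.survived`` set
    to False (loss is a status, not an exception, so establishment
    conditioning stays possible downstream).
    """
    if t_insertion > demography.t_max:
        raise ValueError("insertion time outside demography")
    rng = np.random.default_rng([_STREAM_POPULATION, seed])
    two_n0 = 2 * demography.size_at(0)
    if n_sample > two_n0:
        raise ValueError("cannot sample more haplotypes than 2N at present")
    if n_carriers is not None and n_carriers > n_sample:
        raise ValueError("n_carriers cannot exceed n_sample")

    min_final = n_carriers if n_carriers is not None else 1
    if condition_on_survival or n_carriers is not None:
        traj = surviving_trajectories(
            demography, t_insertion, 1, rng, min_final=min_final, max_raw=max_raw
        )[0]
        survived = True
    else:
        sizes = demography.size_array(t_insertion)
        traj = np.zeros(t_insertion + 1, dtype=np.int64)
        traj[t_insertion] = 1
        c = 1
        for t in range(t_insertion, 0, -1):
            c = int(rng.binomial(2 * sizes[t - 1], c / (2.0 * sizes[t])))
            traj[t - 1] = c
            if c == 0:
                break
        survived = traj[0] > 0

    copies = int(traj[0])
    if n_carriers is None:
        n_car = (
            int(rng.hypergeometric(copies, two_n0 - copies, n_sample))
            if survived
            else 0
        )
    else:
        n_car = n_carriers
    n_bg = n_sample - n_car

    # background pool: non-carriers plus one founder haplotype
    bg = neutral_alignment(n_bg + 1, flank_length, background_pi, rng)
    founder = bg[-1]
    founder_arr = np.frombuffer(founder.encode(), dtype=np.uint8)

    names: list[str] = []
    seqs: list[str] = []
    labels: dict[str, str] = {}
    carrier_flags: list[bool] = []
    ltr_pairs: list[tuple[str, str]] = []
    positions = np.empty(0, dtype=np.int64)

    if n_car > 0:
        tree = carrier_genealogy(traj, n_car, rng)
        positions, carriers = drop_mutations(tree, mu, flank_length, rng)
        car_seqs = np.tile(founder_arr, (n_car, 1))
        derived = _derived_bases(founder_arr, positions, rng)
        for pos, tips, base in zip(positions, carriers, derived):
            car_seqs[tips, pos] = base
        # LTR copies diverge independently along the same genealogy
        ltr_anc = random_sequence(ltr_length, rng)
        ltr_anc_arr = np.frombuffer(ltr_anc.encode(), dtype=np.uint8)
        copy_seqs = []
        for _copy in range(2):
            pos_c, car_c = drop_mutations(tree, mu, ltr_length, rng)
            mats = np.tile(ltr_anc_arr, (n_car, 1))
            dv = _derived_bases(ltr_anc_arr, pos_c, rng)
            for pos, tips, base in zip(pos_c, car_c, dv):
                mats[tips, pos] = base
            copy_seqs.append(mats)
        for i in range(n_car):
            name = f"carrier_{i}"
            names.append(name)
            seqs.append(car_seqs[i].tobytes().decode())
            labels[name] = "carrier"
            carrier_flags.append(True)
            ltr_pairs.append(
                (copy_seqs[0][i].tobytes().decode(), copy_seqs[1][i].tobytes().decode())
            )
    for j in range(n_bg):
        name = f"noncarrier_{j}"
        names.append(name)
        seqs.append(bg[j])
        labels[name] = "non-carrier"
        carrier_flags.append(False)

    hapset = HaplotypeSet(names=names, seqs=seqs, labels=labels, seq_name="flank")
    truth = PopulationTruth(
        insertion_time=t_insertion,
        survived=bool(survived),
        allele_frequency=copies / two_n0,
        carrier_flags=carrier_flags,
        mutation_positions=positions,
        ltr_pairs=ltr_pairs,
        final_copies=copies,
    )
    return hapset, truth


def allele_frequency_replicates(
    demography: Demography,
    t_insertion: int,
    n_replicates: int,
    seed: int,
) -> np.ndarray:
    """Final allele frequencies of unconditioned single-copy insertions."""
    rng = np.random.default_rng(seed)
    counts = final_allele_counts(demography, t_insertion, n_replicates, rng)
    return counts / (2.0 * demography.size_at(0))


# ---------------------------------------------------------------------------
# case/control genotypes


def make_case_control(
    n_individuals: int,
    n_sites: int,
    causal_index: int | None,
    carrier_allele_freq: float,
    seed: int,
    penetrance: float = 1.0,
    null_prevalence: float = 0.254,
    freq_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Hardy-Weinberg genotype matrix with one dominant causal locus.

    Genotypes are alt-allele counts in {0,1,2}. The phenotype is 1 with
    probability ``penetrance`` for individuals carrying at least one causal
    alt allele (dominant), 0 otherwise. With ``causal_index=None`` the
    phenotype is drawn independently of all genotypes at ``null_prevalence``
    (a pure null dataset for type-I calibration).
    """
    if not 0.0 <= carrier_allele_freq <= 1.0:
        raise ValueError("carrier_allele_freq must be in [0,1]")
    if causal_index is not None and not 0 <= causal_index < n_sites:
        raise ValueError("causal_index out of range")
    rng = np.random.default_rng([_STREAM_CASE_CONTROL, seed])
    freqs = rng.uniform(*freq_range, size=n_sites)
    if causal_index is not None:
        freqs[causal_index] = carrier_allele_freq
    genotypes = rng.binomial(2, freqs, size=(n_individuals, n_sites)).astype(np.int8)
    if causal_index is None:
        phenotypes = rng.binomial(1, null_prevalence, size=n_individuals).astype(np.int8)
    else:
        carrier = genotypes[:, causal_index] >= 1
        phenotypes = np.where(
            carrier, rng.binomial(1, penetrance, size=n_individuals), 0
        ).astype(np.int8)
    return genotypes, phenotypes


# ---------------------------------------------------------------------------
# methylation tracks


def make_methylation_track(
    n_cpg: int,
    element: ErvElement,
    seed: int,
    body_level: float = 0.9,
    ltr_level: float = 0.2,
    background_level: float = 0.8,
    noise_sd: float = 0.1,
    pad: int | None = None,
) -> tuple[MethylationTrack, np.ndarray]:
    """CpG track spanning the element with a hypomethylated dip at the LTRs.

    CpGs are placed uniformly at random (without replacement) across the
    element plus flanking padding; each score is drawn from a normal
    truncated to [0,1] around its region's level. Returns the track and the
    per-CpG truth labels ('ltr', 'body', 'background').
    """
    for level in (body_level, ltr_level, background_level):
        if not 0.0 <= level <= 1.0:
            raise ValueError("methylation levels must be in [0,1]")
    rng = np.random.default_rng([_STREAM_METHYLATION, seed])
    if pad is None:
        pad = max(1000, element.length // 2)
    span_start = max(0, element.start - pad)
    span_end = element.end + pad
    positions = np.sort(
        rng.choice(span_end - span_start, size=n_cpg, replace=False) + span_start
    )
    labels = np.full(n_cpg, "background", dtype=object)
    in_ltr = (
        (positions >= element.ltr5[0]) & (positions < element.ltr5[1])
    ) | ((positions >= element.ltr3[0]) & (positions < element.ltr3[1]))
    in_body = (positions >= element.internal[0]) & (positions < element.internal[1])
    labels[in_ltr] = "ltr"
    labels[in_body] = "body"
    level_map = {"ltr": ltr_level, "body": body_level, "background": background_level}
    scores = np.empty(n_cpg)
    for lab, level in level_map.items():
        mask = labels == lab
        if not mask.any():
            continue
        if noise_sd == 0:
            scores[mask] = level
        else:
            a, b = (0.0 - level) / noise_sd, (1.0 - level) / noise_sd
            scores[mask] = truncnorm.rvs(
                a, b, loc=level, scale=noise_sd, size=int(mask.sum()), random_state=rng
            )
    track = MethylationTrack(
        seq_name=element.seq_name, positions=positions, scores=scores
    )
    return track, labels.astype(str)
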