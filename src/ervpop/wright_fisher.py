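"""Forward Wright-Fisher allele trajectories and trajectory-conditioned
genealogies.

A new insertion is modelled as a single chromosome copy arising ``T``
generations before present in a diploid population whose size follows a
piecewise-constant demography. Copy counts evolve by binomial resampling
(neutral drift). Sampled carrier haplotypes coalesce inside the carrier class
at rate C(k,2)/(copies at that generation), with all surviving lineages forced
to the founding copy at the insertion time; this is the exact genealogy of the
carrier class under the model and far cheaper than tracking every haplotype
forward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Demography

__all__ = [
    "final_allele_counts",
    "surviving_trajectories",
    "CoalescentTree",
    "carrier_genealogy",
    "drop_mutations",
    "kingman_tree",
]


def _step(counts: np.ndarray, n_prev: int, n_next: int, rng: np.random.Generator) -> np.ndarray:
    """One generation of binomial resampling for an array of trajectories."""
    return rng.binomial(2 * n_next, counts / (2.0 * n_prev))


def final_allele_counts(
    demography: Demography,
    t_insertion: int,
    n_replicates: int,
    rng: np.random.Generator,
    init_copies: int = 1,
) -> np.ndarray:
    """Unconditioned forward trajectories; returns copy counts at present.

    Lost replicates are reported as zeros, so establishment conditioning and
    the martingale property E[p_final] = p_0 are both checkable downstream.
    """
    sizes = demography.size_array(t_insertion)
    counts = np.full(n_replicates, init_copies, dtype=np.int64)
    alive = np.arange(n_replicates)
    out = np.zeros(n_replicates, dtype=np.int64)
    for t in range(t_insertion, 0, -1):
        counts = _step(counts, sizes[t], sizes[t - 1], rng)
        keep = counts > 0
        counts = counts[keep]
        alive = alive[keep]
        if alive.size == 0:
            return out
    out[alive] = counts
    return out


def surviving_trajectories(
    demography: Demography,
    t_insertion: int,
    n_needed: int,
    rng: np.random.Generator,
    min_final: int = 1,
    batch: int = 50_000,
    max_raw: int | None = None,
) -> np.ndarray:
    """Full copy-count trajectories conditioned on survival to present.

    Returns an array of shape (n_needed, t_insertion + 1) whose column ``t``
    holds the copy count ``t`` generations before present (column
    ``t_insertion`` is the founding single copy). Conditioning is by rejection:
    batches of unconditioned forward simulations are run with lost
    trajectories compacted away each generation, which makes the expected cost
    per raw replicate logarithmic in ``t_insertion``.

    Raises ``RuntimeError`` if ``max_raw`` raw replicates are exhausted before
    ``n_needed`` survivors (with final copies >= ``min_final``) are collected.
    """
    if t_insertion == 0 and min_final > 1:
        raise ValueError(
            "an insertion arising at the present is a single copy; cannot "
            f"condition on {min_final} final copies"
        )
    sizes = demography.size_array(t_insertion)
    collected: list[np.ndarray] = []
    n_collected = 0
    raw_used = 0
    while n_collected < n_needed:
        if max_raw is not None and raw_used >= max_raw:
            raise RuntimeError(
                f"exhausted {raw_used} raw replicates with only "
                f"{n_collected}/{n_needed} surviving trajectories"
            )
        this_batch = batch if max_raw is None else min(batch, max_raw - raw_used)
        raw_used += this_batch
        idx = np.arange(this_batch)
        counts = np.ones(this_batch, dtype=np.int64)
        # history[t] = (alive original indices, their counts) at time t before present
        history: dict[int, tuple[np.ndarray, np.ndarray]] = {
            t_insertion: (idx, counts)
        }
        for t in range(t_insertion, 0, -1):
            counts = _step(counts, sizes[t], sizes[t - 1], rng)
            keep = counts > 0
            idx = idx[keep]
            counts = counts[keep]
            history[t - 1] = (idx, counts)
            if idx.size == 0:
                break
        if idx.size == 0:
            continue
        surv = idx[counts >= min_final]
        if surv.size == 0:
            continue
        traj = np.empty((surv.size, t_insertion + 1), dtype=np.int64)
        for t, (idx_t, counts_t) in history.items():
            pos = np.searchsorted(idx_t, surv)
            traj[:, t] = counts_t[pos]
        collected.append(traj)
        n_collected += surv.size
    return np.concatenate(collected, axis=0)[:n_needed]


@dataclass
class CoalescentTree:
    """Genealogy of sampled carrier haplotypes back to the founding copy.

    Tips are nodes ``0..n-1`` at time 0; internal nodes follow. ``node_time``
    is in generations before present. ``children[v]`` lists direct children of
    internal node ``v`` (empty for tips). The root sits at the insertion time
    (the founding copy); its "branch" has zero length.
    """

    n_tips: int
    node_time: np.ndarray
    children: list[list[int]]
    parent: np.ndarray

    def branch_lengths(self) -> np.ndarray:
        lens = np.zeros(len(self.node_time))
        root = len(self.node_time) - 1
        for v in range(root):
            lens[v] = self.node_time[self.parent[v]] - self.node_time[v]
        return lens

    def tips_below(self) -> list[np.ndarray]:
        """For each node, the sorted array of tip indices it subtends."""
        out: list[np.ndarray] = [np.array([v]) for v in range(self.n_tips)]
        for v in range(self.n_tips, len(self.node_time)):
            out.append(np.sort(np.concatenate([out[c] for c in self.children[v]])))
        return out


def carrier_genealogy(
    trajectory: np.ndarray,
    n_tips: int,
    rng: np.random.Generator,
) -> CoalescentTree:
    """Coalescent of ``n_tips`` carrier lineages conditioned on a trajectory.

    ``trajectory[t]`` is the carrier copy count ``t`` generations before
    present. Pairs coalesce at per-generation rate C(k,2)/copies(t); waiting
    times are drawn by inverting the cumulative hazard, so the cost is
    O(events * log T) rather than O(T). Any lineages left at the insertion
    time are joined to the founding copy there (forced multifurcation).
    """
    t_insertion = trajectory.shape[0] - 1
    if n_tips < 1:
        raise ValueError("need at least one sampled carrier")
    if trajectory[0] < n_tips:
        raise ValueError("cannot sample more carriers than present-day copies")
    # per-pair hazard accumulated crossing generation t -> t+1
    unit = 1.0 / trajectory[:-1]
    cum = np.concatenate([[0.0], np.cumsum(unit)])  # cum[t]: hazard from 0 to t

    node_time = [0.0] * n_tips
    children: list[list[int]] = [[] for _ in range(n_tips)]
    active = list(range(n_tips))
    t_cur = 0
    while len(active) > 1:
        k = len(active)
        pairs = k * (k - 1) / 2.0
        target = cum[t_cur] + rng.exponential() / pairs
        t_ev = int(np.searchsorted(cum, target, side="left"))
        if t_ev > t_insertion:
            break
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        new = len(node_time)
        node_time.append(float(t_ev))
        children.append([a, b])
        active = [x for x in active if x not in (a, b)] + [new]
        t_cur = t_ev
    # root = founding copy at the insertion time
    root = len(node_time)
    node_time.append(float(t_insertion))
    children.append(list(active))
    parent = np.full(root + 1, -1, dtype=np.int64)
    for v, kids in enumerate(children):
        for c in kids:
            parent[c] = v
    return CoalescentTree(
        n_tips=n_tips,
        node_time=np.asarray(node_time),
        children=children,
        parent=parent,
    )


def drop_mutations(
    tree: CoalescentTree,
    rate_per_site: float,
    seq_length: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Poisson infinite-sites mutations on a genealogy.

    Each branch of length L generations receives Poisson(rate * seq_length * L)
    mutations at distinct uniform positions. Returns (positions, tip index
    arrays), one entry per mutation; a mutation's carriers are the tips below
    its branch. Mutations on the root's stem do not exist (the founder defines
    the ancestral state).
    """
    lens = tree.branch_lengths()
    tipsets = tree.tips_below()
    n_mut = rng.poisson(rate_per_site * seq_length * lens)
    total = int(n_mut.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), []
    if total > seq_length:
        raise ValueError("more mutations than sites; infinite-sites violated")
    positions = rng.choice(seq_length, size=total, replace=False)
    carriers: list[np.ndarray] = []
    k = 0
    out_pos = np.empty(total, dtype=np.int64)
    for v in range(len(lens)):
        for _ in range(int(n_mut[v])):
            out_pos[k] = positions[k]
            carriers.append(tipsets[v])
            k += 1
    return out_pos, carriers


def kingman_tree(n_tips: int, rng: np.random.Generator) -> CoalescentTree:
    """Standard neutral Kingman coalescent in coalescent time units.

    Used for background (non-carrier) diversity and neutral-null simulation;
    node times are in units of 2N generations, so mutation dropping should use
    theta/2 per unit time per site.
    """
    node_time = [0.0] * n_tips
    children: list[list[int]] = [[] for _ in range(n_tips)]
    active = list(range(n_tips))
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(scale=2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        new = len(node_time)
        node_time.append(t)
        children.append([a, b])
        active = [x for x in active if x not in (a, b)] + [new]
    parent = np.full(len(node_time), -1, dtype=np.int64)
    for v, kids in enumerate(children):
        for c in kids:
            parent[c] = v
    return CoalescentTree(
        n_tips=n_tips,
        node_time=np.asarray(node_time),
        children=children,
        parent=parent,
    )
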