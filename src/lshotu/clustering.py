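"""Greedy, seed-based OTU assignment under the LSH filter, iterated and merged.

One iteration draws a fresh randomized hash function, then greedily covers
the read pool: pick an unassigned seed, open a new OTU, sweep the remaining
pool once and pull in every read whose hash key is within the mismatch
budget of the seed's key, remove the assigned reads, repeat until the pool
is empty. Iterating ``l`` times with independent hash functions and merging
by a union operation (reads co-clustered in *any* iteration end up in the
same final OTU, transitively) suppresses the false negatives a single
random index draw can produce.

Reproducibility: iteration ``t`` uses the generator seeded by
``(master_seed, t)``; within an iteration the generator is consumed first
by the index draw, then by the pool shuffle (random seeding mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .lsh import (
    HashFunctionSpec,
    allowed_mismatches,
    extract_key,
    mismatches_exceed,
    sample_indices,
    window_mismatch_budget,
)
from .seq_io import SampleSet

SeedingMode = Literal["random", "input_order"]
BudgetMode = Literal["divergence", "symbol_fraction"]


@dataclass
class ClusteringParams:
    """Parameters of the iterated LSH clustering.

    ``p`` is interpreted according to ``budget_mode``:

    - ``"divergence"`` (default): the target pairwise nucleotide divergence
      (the distance cutoff d); the per-iteration symbol budget is the
      binomial-quantile calibration of
      :func:`~lshotu.lsh.window_mismatch_budget` at level ``alpha``.
    - ``"symbol_fraction"``: the literal fraction of sampled symbols allowed
      to differ; budget ``floor(p * k)``.

    Defaults k=30, w=3 follow the tool's standard operating point for 16S
    reads; l=4 iterations is this package's default.
    """

    k: int = 30
    w: int = 3
    l: int = 4
    p: float = 0.05
    seed: int = 0
    seeding_mode: SeedingMode = "random"
    budget_mode: BudgetMode = "divergence"
    alpha: float = 0.05

    def mismatch_budget(self) -> int:
        if self.budget_mode == "divergence":
            return window_mismatch_budget(self.k, self.w, self.p, self.alpha)
        if self.budget_mode == "symbol_fraction":
            return allowed_mismatches(self.k, self.p)
        raise ValueError(f"unknown budget_mode {self.budget_mode!r}")


@dataclass
class OTUAssignment:
    """A total partition of sequence ids into OTU labels.

    ``labels`` preserves input order; labels are ``OTU_<i>`` numbered in
    order of cluster creation. ``sample_ids`` optionally records the sample
    each read came from (for joint clusterings across samples).
    """

    labels: dict[str, str]
    sample_ids: dict[str, str] | None = None

    @property
    def num_otus(self) -> int:
        return len(set(self.labels.values()))

    def members(self) -> dict[str, list[str]]:
        """OTU label -> member ids, labels in order of first appearance."""
        out: dict[str, list[str]] = {}
        for seq_id, otu in self.labels.items():
            out.setdefault(otu, []).append(seq_id)
        return out

    def sizes(self) -> list[int]:
        return [len(m) for m in self.members().values()]

    def partition(self) -> frozenset[frozenset[str]]:
        """Label-free view of the partition, for equality up to relabeling."""
        return frozenset(frozenset(m) for m in self.members().values())


def iteration_rng(master_seed: int, t: int) -> np.random.Generator:
    """The deterministic generator stream for iteration ``t`` of a run."""
    return np.random.default_rng([master_seed, t])


def _relabel(groups: list[list[str]], order: list[str]) -> dict[str, str]:
    """Assign OTU_<i> labels to groups ordered by first member in ``order``."""
    rank = {seq_id: i for i, seq_id in enumerate(order)}
    groups = sorted(groups, key=lambda g: min(rank[x] for x in g))
    labels: dict[str, str] = {}
    by_id: dict[str, str] = {}
    for i, g in enumerate(groups):
        for x in g:
            by_id[x] = f"OTU_{i}"
    for seq_id in order:
        labels[seq_id] = by_id[seq_id]
    return labels


def assign_single_iteration(
    sample: SampleSet,
    spec: HashFunctionSpec,
    p: float,
    rng: np.random.Generator | None = None,
    seeding_mode: SeedingMode = "random",
    max_mismatches: int | None = None,
) -> OTUAssignment:
    """One greedy covering pass of the pool under a fixed hash function.

    ``max_mismatches`` overrides the default symbol budget
    ``floor(p * k)``; the clustering front-end passes the calibrated
    budget here. Reads, once assigned, are removed from the pool.
    """
    if len(sample) == 0:
        raise ValueError("no sequences")
    budget = (
        max_mismatches
        if max_mismatches is not None
        else allowed_mismatches(spec.k, p)
    )
    keys = [extract_key(r, spec) for r in sample]
    if seeding_mode == "random":
        if rng is None:
            raise ValueError("random seeding mode requires a generator")
        order = [int(i) for i in rng.permutation(len(sample))]
    elif seeding_mode == "input_order":
        order = list(range(len(sample)))
    else:
        raise ValueError(f"unknown seeding_mode {seeding_mode!r}")

    group_of = [-1] * len(sample)
    pool = order
    otu = 0
    while pool:
        seed = pool[0]
        seed_key = keys[seed]
        group_of[seed] = otu
        rest: list[int] = []
        for y in pool[1:]:
            if mismatches_exceed(seed_key, keys[y], budget):
                rest.append(y)
            else:
                group_of[y] = otu
        otu += 1
        pool = rest

    groups: list[list[str]] = [[] for _ in range(otu)]
    for i, g in enumerate(group_of):
        groups[g].append(sample[i].id)
    return OTUAssignment(labels=_relabel(groups, sample.ids()))


class _DisjointSet:
    """Union-find over sequence ids (path halving, union by size)."""

    def __init__(self, ids: list[str]):
        self.parent = {x: x for x in ids}
        self.size = {x: 1 for x in ids}

    def find(self, x: str) -> str:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def union_merge(assignments: list[OTUAssignment]) -> OTUAssignment:
    """Merge per-iteration partitions: transitive closure of co-membership.

    Two reads share a final OTU iff they are connected in the graph whose
    edges join reads co-clustered in at least one iteration (disjoint-set
    union over per-iteration groups). The merged OTU count is therefore
    never larger than any single iteration's.
    """
    if not assignments:
        raise ValueError("no assignments to merge")
    ids = list(assignments[0].labels)
    id_set = set(ids)
    for a in assignments[1:]:
        if set(a.labels) != id_set:
            raise ValueError("assignment mismatch: iterations cover different ids")
    dsu = _DisjointSet(ids)
    for a in assignments:
        for group in a.members().values():
            first = group[0]
            for other in group[1:]:
                dsu.union(first, other)
    comps: dict[str, list[str]] = {}
    for x in ids:
        comps.setdefault(dsu.find(x), []).append(x)
    return OTUAssignment(
        labels=_relabel(list(comps.values()), ids),
        sample_ids=assignments[0].sample_ids,
    )


def cluster(
    sample: SampleSet,
    params: ClusteringParams,
    return_details: bool = False,
):
    """Run the full iterated clustering: l hash draws, l greedy passes, union.

    The effective length is the shortest read in the sample, so every read
    supports every sampled window. Fully reproducible given ``params`` and
    the input order.

    With ``return_details=True`` returns
    ``(merged, per_iteration_assignments, specs)``.
    """
    if len(sample) == 0:
        raise ValueError("no sequences")
    if params.l < 1:
        raise ValueError("iteration count l must be >= 1")
    n_eff = sample.min_length()
    budget = params.mismatch_budget()
    per_iter: list[OTUAssignment] = []
    specs: list[HashFunctionSpec] = []
    for t in range(params.l):
        rng = iteration_rng(params.seed, t)
        spec = sample_indices(n_eff, params.k, params.w, rng)
        spec = replace(spec, seed=params.seed)
        specs.append(spec)
        per_iter.append(
            assign_single_iteration(
                sample,
                spec,
                p=params.p,
                rng=rng,
                seeding_mode=params.seeding_mode,
                max_mismatches=budget,
            )
        )
    merged = union_merge(per_iter)
    if return_details:
        return merged, per_iter, specs
    return merged
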