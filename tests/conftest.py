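"""Shared fixtures and the independent brute-force clustering oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import binom

from lshotu import ClusteringParams, SampleSet, SequenceRecord


def make_sample(seqs: list[str], sample_id: str = "s") -> SampleSet:
    return SampleSet(sample_id, [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)])


def random_sample(
    rng: np.random.Generator, n: int, length: int, sample_id: str = "s"
) -> SampleSet:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = [
        bases[rng.integers(0, 4, size=length)].tobytes().decode() for _ in range(n)
    ]
    return make_sample(seqs, sample_id)


def greedy_oracle(sample: SampleSet, params: ClusteringParams) -> frozenset[frozenset[str]]:
    """Literal re-implementation of the iterated greedy clustering.

    No hash-key structures: window comparisons are done directly on the
    sequence strings, pools are plain lists, the union step is a
    breadth-first connected-components pass. Shares the generator stream
    of the package implementation (index draw first, then shuffle).
    """
    n = len(sample)
    n_eff = min(len(r.seq) for r in sample)
    half = params.w // 2
    if params.budget_mode == "divergence":
        q = 1.0 - (1.0 - params.p) ** params.w
        budget = int(binom.ppf(1.0 - params.alpha, params.k, q))
    else:
        budget = int(np.floor(params.p * params.k))

    def differing_windows(sx: str, sy: str, centers: list[int]) -> int:
        count = 0
        for c in centers:
            a = sx[c - half : c + half + 1]
            b = sy[c - half : c + half + 1]
            if a != b or "N" in a:
                count += 1
        return count

    co_clustered: list[list[list[int]]] = []
    for t in range(params.l):
        rng = np.random.default_rng([params.seed, t])
        centers = sorted(
            int(c)
            for c in rng.choice(
                np.arange(half, n_eff - half), size=params.k, replace=False
            )
        )
        if params.seeding_mode == "random":
            order = [int(i) for i in rng.permutation(n)]
        else:
            order = list(range(n))
        remaining = list(order)
        groups: list[list[int]] = []
        while remaining:
            sx = remaining[0]
            members = [sx] + [
                y
                for y in remaining[1:]
                if differing_windows(sample[sx].seq, sample[y].seq, centers) <= budget
            ]
            groups.append(members)
            member_set = set(members)
            remaining = [y for y in remaining if y not in member_set]
        co_clustered.append(groups)

    # union step: connected components over per-iteration co-membership
    adjacency: dict[int, set[int]] = {i: set() for i in range(n)}
    for groups in co_clustered:
        for g in groups:
            for x in g:
                adjacency[x].update(g)
    seen: set[int] = set()
    parts: list[frozenset[str]] = []
    for i in range(n):
        if i in seen:
            continue
        comp, frontier = {i}, [i]
        while frontier:
            x = frontier.pop()
            for y in adjacency[x]:
                if y not in comp:
                    comp.add(y)
                    frontier.append(y)
        seen |= comp
        parts.append(frozenset(sample[j].id for j in comp))
    return frozenset(parts)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
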