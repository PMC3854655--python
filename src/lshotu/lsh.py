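"""The randomized, w-mer-enriched locality-sensitive hash and its filter.

A hash function is defined by ``k`` positions sampled uniformly at random
(without replacement) from a sequence of effective length ``n_eff``. Each
sampled position is the *center* of a gapless window of odd width ``w``;
the hash key of a read is the ordered tuple of its ``k`` window substrings
(w-mers). Two reads pass the similarity filter when at most a budgeted
number of their w-mer symbols differ — a symbol either matches exactly or
counts as one mismatch; partial credit within a window is never given.

For reads ``x`` and ``y`` differing at no more than ``m`` of ``n``
positions, the probability (over an independent uniform draw of each of
the ``k`` indices, ``w = 1``) that their keys are identical is at least
``(1 - m/n)**k``; :func:`collision_probability_lower_bound` evaluates this
bound and :func:`empirical_collision_probability` estimates the collision
frequency by Monte Carlo under the same index model.

Ambiguity handling: an ``N`` at a sampled window mismatches everything,
including another ``N`` — ambiguity never creates a collision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .seq_io import SequenceRecord


@dataclass(frozen=True)
class HashFunctionSpec:
    """One iteration's randomized hash definition.

    ``indices`` are the k distinct window centers (0-based, ascending);
    each full window must fit inside ``[0, n_eff)``.
    """

    k: int
    w: int
    indices: tuple[int, ...]
    n_eff: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.w < 1 or self.w % 2 == 0:
            raise ValueError("w must be an odd positive integer")
        if len(self.indices) != self.k or len(set(self.indices)) != self.k:
            raise ValueError("indices must be k distinct positions")
        if self.k * self.w > self.n_eff:
            raise ValueError("k * w exceeds effective sequence length")
        half = self.w // 2
        for c in self.indices:
            if c - half < 0 or c + half > self.n_eff - 1:
                raise ValueError(f"window at center {c} does not fit in n_eff={self.n_eff}")


@dataclass(frozen=True)
class HashKey:
    """A read's hash value: k w-mer symbols, in sampled-index order."""

    symbols: tuple[str, ...]
    w: int
    owner: str = ""


def sample_indices(
    n_eff: int, k: int, w: int, rng: np.random.Generator
) -> HashFunctionSpec:
    """Draw k distinct window centers uniformly from the admissible range.

    Admissible centers are those whose full w-window fits in ``n_eff``,
    i.e. ``n_eff - w + 1`` positions. Returned sorted ascending;
    reproducible given the generator state.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError("w must be an odd positive integer")
    if n_eff < w:
        raise ValueError("effective length shorter than window width")
    half = w // 2
    admissible = n_eff - w + 1
    if k > admissible:
        raise ValueError(
            f"k too large for read length: k={k} > {admissible} admissible centers"
        )
    if k * w > n_eff:
        raise ValueError(f"k too large for read length: k*w={k * w} > n_eff={n_eff}")
    centers = rng.choice(np.arange(half, n_eff - half), size=k, replace=False)
    return HashFunctionSpec(k, w, tuple(sorted(int(c) for c in centers)), n_eff)


def extract_key(record: SequenceRecord, spec: HashFunctionSpec) -> HashKey:
    """Extract a read's hash key: the w-mer centered at every sampled index."""
    if len(record.seq) < spec.n_eff:
        raise ValueError(
            f"sequence too short: '{record.id}' has length {len(record.seq)} "
            f"< n_eff={spec.n_eff}"
        )
    half = spec.w // 2
    seq = record.seq
    return HashKey(
        symbols=tuple(seq[c - half : c + half + 1] for c in spec.indices),
        w=spec.w,
        owner=record.id,
    )


def allowed_mismatches(k: int, p: float) -> int:
    """Maximum number of sampled symbols permitted to differ: ``floor(p * k)``.

    ``p`` is the allowable mismatch fraction over the k sampled symbols
    (e.g. k=64, p=0.10 -> 6). ``p = 0`` demands exact symbol-wise identity.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"mismatch fraction p={p} outside [0, 1]")
    return math.floor(p * k)


def mismatch_count(a: HashKey, b: HashKey) -> int:
    """Number of sampled windows whose w-mers differ (whole-symbol equality).

    An ``N`` anywhere in a symbol forces a mismatch at that window.
    """
    if len(a.symbols) != len(b.symbols) or a.w != b.w:
        raise ValueError("incompatible keys: different k or w")
    return sum(1 for x, y in zip(a.symbols, b.symbols) if x != y or "N" in x)


def mismatches_exceed(a: HashKey, b: HashKey, budget: int) -> bool:
    """Early-exit test: does the symbol mismatch count exceed ``budget``?"""
    if len(a.symbols) != len(b.symbols) or a.w != b.w:
        raise ValueError("incompatible keys: different k or w")
    n = 0
    for x, y in zip(a.symbols, b.symbols):
        if x != y or "N" in x:
            n += 1
            if n > budget:
                return True
    return False


def is_similar(a: HashKey, b: HashKey, p: float) -> bool:
    """True iff the keys differ in at most ``floor(p * k)`` symbols."""
    return mismatch_count(a, b) <= allowed_mismatches(len(a.symbols), p)


def window_mismatch_budget(k: int, w: int, p: float, alpha: float = 0.05) -> int:
    """Symbol-mismatch budget calibrated to a target nucleotide divergence.

    Interprets ``p`` as the maximum pairwise nucleotide divergence (the
    distance cutoff ``d``) that the filter should still accept. A w-wide
    window straddling a pair at divergence ``p`` differs with probability
    ``q = 1 - (1 - p)**w`` (independent-mismatch approximation), so the
    number of differing windows among the k sampled is ~ Binomial(k, q).
    The budget is the ``(1 - alpha)`` quantile of that distribution: the
    per-comparison false-negative rate for pairs exactly at the cutoff is
    bounded by ``alpha`` (and shrinks further with repeated iterations).
    ``p = 0`` yields budget 0 (exact match required).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"divergence p={p} outside [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    q = 1.0 - (1.0 - p) ** w
    return int(binom.ppf(1.0 - alpha, k, q))


def collision_probability_lower_bound(n: int, k: int, p_mismatch: int) -> float:
    """Lower bound ``(1 - m/n)**k`` on the hash collision probability.

    Holds for two length-``n`` strings differing at no more than
    ``p_mismatch`` positions, over independent uniform draws of the k
    indices (w = 1).
    """
    if not 0 <= p_mismatch <= n:
        raise ValueError("p_mismatch outside [0, n]")
    if not 1 <= k <= n:
        raise ValueError("k outside [1, n]")
    return (1.0 - p_mismatch / n) ** k


def empirical_collision_probability(
    n: int, k: int, m: int, draws: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo collision frequency for strings with exactly ``m`` mismatches.

    Draws the k indices i.i.d. uniform on ``[0, n)`` (the probability model
    of the bound) and counts the fraction of draws avoiding all m mismatched
    positions. Note the clustering hash itself samples indices *without*
    replacement, under which the exact collision probability is the slightly
    smaller hypergeometric product ``prod_j (n-m-j)/(n-j)``.
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    if not 0 <= m <= n:
        raise ValueError("m outside [0, n]")
    idx = rng.integers(0, n, size=(draws, k))
    # w.l.o.g. the m mismatched positions are 0..m-1
    return float((idx >= m).all(axis=1).mean())
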