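"""Synthetic amplicon data with known species-of-origin labels.

Emulates a marker-gene benchmark: a panel of species-specific reference
sequences with a guaranteed minimum pairwise divergence, and full-length
reads copied from those references with bounded substitution error.
"Up to x% error" means each read carries an independently drawn number of
substitutions, uniform on [0, floor(x * length)], at uniform positions,
each substituted to a different base — a per-read maximum, not a per-base
rate. No indels, chimeras or abundance skew are modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .clustering import OTUAssignment
from .seq_io import SampleSet, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulatedDataset:
    """References, reads and read -> reference truth labels."""

    references: list[SequenceRecord]
    reads: SampleSet
    truth: dict[str, str]
    error_rate: float


class RecoveryScore(NamedTuple):
    num_otus: int
    purity: float


def _hamming_fraction(a: np.ndarray, b: np.ndarray) -> float:
    return float((a != b).mean())


def generate_references(
    num_species: int,
    length: int,
    min_divergence: float,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> list[SequenceRecord]:
    """Uniform-random reference panel with pairwise divergence >= threshold.

    Rejection sampling: candidates closer than ``min_divergence`` (hamming
    fraction) to any accepted reference are redrawn, up to ``max_tries``
    per slot.
    """
    if num_species < 1 or length < 1:
        raise ValueError("num_species and length must be >= 1")
    if not 0.0 <= min_divergence <= 1.0:
        raise ValueError("min_divergence outside [0, 1]")
    accepted: list[np.ndarray] = []
    while len(accepted) < num_species:
        for _ in range(max_tries):
            cand = _BASES[rng.integers(0, 4, size=length)]
            if all(_hamming_fraction(cand, r) >= min_divergence for r in accepted):
                accepted.append(cand)
                break
        else:
            raise ValueError(
                f"divergence unsatisfiable: no candidate at >= {min_divergence} "
                f"after {max_tries} tries"
            )
    width = len(str(num_species - 1))
    return [
        SequenceRecord(f"ref_{i:0{width}d}", arr.tobytes().decode())
        for i, arr in enumerate(accepted)
    ]


def simulate_reads(
    references: list[SequenceRecord],
    reads_per_ref: int,
    error_rate: float,
    rng: np.random.Generator,
    sample_id: str = "simulated",
) -> SimulatedDataset:
    """Full-length reads with up to ``error_rate`` substitution error.

    Each read draws its substitution count uniform on
    ``[0, floor(error_rate * length)]``; positions are uniform without
    replacement and every substitution changes the base.
    """
    if reads_per_ref < 1:
        raise ValueError("reads_per_ref must be >= 1")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate outside [0, 1)")
    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    rwidth = len(str(reads_per_ref - 1))
    for ref in references:
        arr = np.frombuffer(ref.seq.encode(), dtype=np.uint8)
        max_subs = math.floor(error_rate * len(arr))
        for j in range(reads_per_ref):
            read = arr.copy()
            n_subs = int(rng.integers(0, max_subs + 1))
            if n_subs:
                pos = rng.choice(len(arr), size=n_subs, replace=False)
                for p in pos:
                    choices = _BASES[_BASES != read[p]]
                    read[p] = choices[rng.integers(0, len(choices))]
            read_id = f"{ref.id}_r{j:0{rwidth}d}"
            records.append(SequenceRecord(read_id, read.tobytes().decode()))
            truth[read_id] = ref.id
    return SimulatedDataset(
        references=references,
        reads=SampleSet(sample_id, records),
        truth=truth,
        error_rate=error_rate,
    )


def recovery_score(assignment: OTUAssignment, truth: dict[str, str]) -> RecoveryScore:
    """Cluster count plus majority-label purity against the truth labels.

    Purity is the fraction of reads whose OTU's majority species-of-origin
    matches their own; over-splitting is pure by construction, so purity
    must be read together with the OTU count.
    """
    if set(assignment.labels) != set(truth):
        raise ValueError("assignment and truth cover different read ids")
    correct = 0
    for members in assignment.members().values():
        counts: dict[str, int] = {}
        for read_id in members:
            counts[truth[read_id]] = counts.get(truth[read_id], 0) + 1
        majority = max(sorted(counts), key=counts.get)
        correct += counts[majority]
    return RecoveryScore(assignment.num_otus, correct / len(truth))
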