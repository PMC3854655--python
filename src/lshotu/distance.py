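"""Exact pairwise distances and post-hoc validation of the distance cutoff.

The clustering stage never computes alignments; this module measures,
after the fact, whether the reads inside each OTU actually satisfy a
distance cutoff d — the maximum intra-OTU pairwise distance is reported
per OTU and globally, under either a global-alignment (Needleman-Wunsch)
distance or a k-mer profile distance.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import edlib
import numpy as np

from .clustering import OTUAssignment
from .seq_io import SampleSet, SequenceRecord

Metric = Literal["nw", "kmer"]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _seq(x: SequenceRecord | str) -> str:
    return x.seq if isinstance(x, SequenceRecord) else x


def nw_alignment_stats(a: SequenceRecord | str, b: SequenceRecord | str) -> tuple[int, int]:
    """Unit-cost global alignment: ``(edit_distance, aligned_columns)``.

    Match 0, mismatch 1, gap 1, no end-gap discount. Columns count every
    alignment position (matches + mismatches + gap columns) of the optimal
    alignment found.
    """
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        raise ValueError("empty sequence")
    # co-optimal alignments can differ in gap-column count; fix the argument
    # order so ties resolve identically for (a, b) and (b, a)
    if (len(sb), sb) < (len(sa), sa):
        sa, sb = sb, sa
    res = edlib.align(sa, sb, mode="NW", task="path")
    columns = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    return res["editDistance"], columns


def nw_distance(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Normalized global-alignment distance in [0, 1].

    ``(mismatches + gap columns) / alignment length`` of a unit-cost
    Needleman-Wunsch alignment; 0 iff the sequences are identical.
    """
    edit, columns = nw_alignment_stats(a, b)
    return edit / columns


def kmer_distance(
    a: SequenceRecord | str, b: SequenceRecord | str, kmer_size: int = 6
) -> float:
    """Profile distance over shared k-mer counts, in [0, 1].

    ``1 - sum_kmer min(count_a, count_b) / (min(len_a, len_b) - k + 1)``;
    0 for identical sequences, 1 when no k-mer is shared.
    """
    sa, sb = _seq(a), _seq(b)
    if len(sa) < kmer_size or len(sb) < kmer_size:
        raise ValueError(f"sequence shorter than kmer_size={kmer_size}")
    ca = Counter(sa[i : i + kmer_size] for i in range(len(sa) - kmer_size + 1))
    cb = Counter(sb[i : i + kmer_size] for i in range(len(sb) - kmer_size + 1))
    shared = sum(min(n, cb[kmer]) for kmer, n in ca.items() if kmer in cb)
    denom = min(len(sa), len(sb)) - kmer_size + 1
    return 1.0 - shared / denom


@dataclass
class DistanceReport:
    """Per-OTU maximum pairwise distances against a target cutoff."""

    metric: str
    cutoff: float
    per_otu_max: dict[str, float]
    global_max: float
    satisfied: bool
    sampled: bool = False
    otu_sizes: dict[str, int] = field(default_factory=dict)


def validate_cutoff(
    assignment: OTUAssignment,
    sample: SampleSet,
    metric: Metric = "nw",
    cutoff: float = 0.05,
    kmer_size: int = 6,
    max_pairs: int | None = None,
    rng: np.random.Generator | None = None,
) -> DistanceReport:
    """Report the maximum intra-OTU pairwise distance for every OTU.

    All within-OTU pairs are measured; singleton OTUs contribute 0. When
    ``max_pairs`` is given, OTUs with more pairs than that are subsampled
    uniformly, the reported maxima become lower bounds, and the report is
    flagged ``sampled``.
    """
    if metric == "nw":
        dist = nw_distance
    elif metric == "kmer":
        def dist(x, y):  # noqa: ANN001 - local closure
            return kmer_distance(x, y, kmer_size)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    by_id = {r.id: r for r in sample}
    missing = [r.id for r in sample if r.id not in assignment.labels]
    if missing:
        raise ValueError(f"assignment does not cover sample: missing {missing[:3]}")

    per_otu_max: dict[str, float] = {}
    otu_sizes: dict[str, int] = {}
    sampled = False
    for otu, ids in assignment.members().items():
        ids = [x for x in ids if x in by_id]
        if not ids:
            continue
        otu_sizes[otu] = len(ids)
        pairs = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
        if max_pairs is not None and len(pairs) > max_pairs:
            if rng is None:
                rng = np.random.default_rng(0)
            pick = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[int(i)] for i in pick]
            sampled = True
        best = 0.0
        for i, j in pairs:
            d = dist(by_id[ids[i]], by_id[ids[j]])
            if d > best:
                best = d
        per_otu_max[otu] = best
    global_max = max(per_otu_max.values(), default=0.0)
    return DistanceReport(
        metric=metric,
        cutoff=cutoff,
        per_otu_max=per_otu_max,
        global_max=global_max,
        satisfied=global_max <= cutoff,
        sampled=sampled,
        otu_sizes=otu_sizes,
    )


def write_distance_report(report: DistanceReport, path: str | Path) -> None:
    """Emit the report as TSV with a summary header comment."""
    with open(path, "w", newline="\n") as fh:
        fh.write(
            f"# metric={report.metric}\tcutoff={report.cutoff}\t"
            f"global_max={report.global_max:.6f}\tsatisfied={report.satisfied}\t"
            f"sampled={report.sampled}\n"
        )
        fh.write("otu_id\tsize\tmax_distance\n")
        for otu, mx in report.per_otu_max.items():
            fh.write(f"{otu}\t{report.otu_sizes.get(otu, 0)}\t{mx:.6f}\n")
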