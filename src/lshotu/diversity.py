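"""Species richness and diversity estimators from an OTU assignment.

All estimators consume only the abundance histogram of OTU sizes
(n_i = number of OTUs containing exactly i reads), which is a sufficient
statistic for every quantity here:

- Chao1:  S_obs + n1 (n1 - 1) / (2 (n2 + 1)), with n1 the singleton and
  n2 the doubleton count; the +1 keeps the estimate finite when no
  doubletons are observed.
- Shannon H': - sum_i (n_i / N) ln (n_i / N) over OTUs, in nats.
- ACE: splits OTUs at an "abund" threshold (default 10) into rare and
  abundant, estimates the sample coverage of the rare fraction as
  C = 1 - n1 / N_rare, and corrects S_rare / C by a coefficient of
  variation term gamma^2.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .clustering import OTUAssignment


@dataclass(frozen=True)
class OTUSizeProfile:
    """Abundance histogram: size -> number of OTUs of that size."""

    size_counts: dict[int, int]
    s_obs: int
    n: int

    def __post_init__(self) -> None:
        if any(i < 1 or c < 0 for i, c in self.size_counts.items()):
            raise ValueError("invalid size histogram")
        if sum(self.size_counts.values()) != self.s_obs:
            raise ValueError("size_counts do not sum to S_obs")
        if sum(i * c for i, c in self.size_counts.items()) != self.n:
            raise ValueError("size_counts do not account for N sequences")

    @classmethod
    def from_sizes(cls, sizes: list[int]) -> "OTUSizeProfile":
        counts = dict(Counter(sizes))
        return cls(counts, len(sizes), sum(sizes))


@dataclass(frozen=True)
class AceComponents:
    """All intermediates of the ACE estimate, exposed for audit."""

    abund: int
    s_rare: int
    s_abund: int
    n_rare: int
    c_ace: float
    gamma_sq: float
    s_ace: float


def size_profile(
    assignment: OTUAssignment, sample_id: str | None = None
) -> OTUSizeProfile:
    """Histogram of OTU sizes; optionally restricted to one sample's reads."""
    if not assignment.labels:
        raise ValueError("empty assignment")
    if sample_id is None:
        sizes = assignment.sizes()
    else:
        sids = assignment.sample_ids or {}
        counts = Counter(
            otu for sid, otu in assignment.labels.items() if sids.get(sid) == sample_id
        )
        if not counts:
            raise ValueError(f"no reads for sample '{sample_id}'")
        sizes = list(counts.values())
    return OTUSizeProfile.from_sizes(sizes)


def chao1(profile: OTUSizeProfile) -> float:
    """Chao1 richness estimate; always >= S_obs, finite even with n2 = 0."""
    n1 = profile.size_counts.get(1, 0)
    n2 = profile.size_counts.get(2, 0)
    return profile.s_obs + n1 * (n1 - 1) / (2 * (n2 + 1))


def shannon(profile: OTUSizeProfile) -> float:
    """Shannon diversity H' of the OTU size distribution, in nats."""
    n = profile.n
    h = 0.0
    for size, count in profile.size_counts.items():
        frac = size / n
        h -= count * frac * math.log(frac)
    return h


def ace(profile: OTUSizeProfile, abund: int = 10) -> AceComponents:
    """Abundance-based Coverage Estimator with its components.

    Raises when coverage is zero (every rare OTU a singleton), the known
    singularity of the estimator. With no rare OTUs at all the estimate
    degenerates to S_abund with no correction term.
    """
    if abund < 1:
        raise ValueError("abund threshold must be >= 1")
    rare = {i: c for i, c in profile.size_counts.items() if i <= abund}
    s_rare = sum(rare.values())
    s_abund = profile.s_obs - s_rare
    n_rare = sum(i * c for i, c in rare.items())
    n1 = profile.size_counts.get(1, 0)
    if n_rare == 0:
        return AceComponents(abund, 0, s_abund, 0, 1.0, 0.0, float(s_abund))
    c_ace = 1.0 - n1 / n_rare
    if c_ace == 0.0:
        raise ValueError("ACE undefined: coverage zero (all rare OTUs are singletons)")
    if n_rare > 1:
        ssq = sum(i * (i - 1) * c for i, c in rare.items())
        gamma_sq = max((s_rare / c_ace) * ssq / (n_rare * (n_rare - 1)) - 1.0, 0.0)
    else:
        gamma_sq = 0.0
    s_ace = s_abund + s_rare / c_ace + (n1 / c_ace) * gamma_sq
    return AceComponents(abund, s_rare, s_abund, n_rare, c_ace, gamma_sq, s_ace)


def diversity_summary(assignment: OTUAssignment, abund: int = 10) -> pd.DataFrame:
    """One row of richness metrics per sample in the assignment.

    Columns: ``sample_id, reads, otus, chao1, shannon, ace`` (ACE is NaN
    where undefined).
    """
    sids = assignment.sample_ids or {}
    samples = sorted(set(sids.values())) if sids else ["sample"]
    rows = []
    for sample_id in samples:
        prof = size_profile(assignment, sample_id if sids else None)
        try:
            s_ace = ace(prof, abund).s_ace
        except ValueError:
            s_ace = float("nan")
        rows.append(
            {
                "sample_id": sample_id,
                "reads": prof.n,
                "otus": prof.s_obs,
                "chao1": chao1(prof),
                "shannon": shannon(prof),
                "ace": s_ace,
            }
        )
    return pd.DataFrame(rows)
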