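"""Protein-level aggregation of filtered PSMs, replicate averaging and QC.

Per run, each protein gets a spectral count (SpC: number of accepted PSMs)
and a cumulative Score (sum of its per-PSM scores).  Proteins whose Score
does not exceed the consensus threshold (default 10, strict) are dropped.
Technical replicates of a condition are then averaged with zero imputation
for replicate-absent proteins, which preserves exclusivity semantics: a
protein never seen in a condition averages to exactly 0 there.

Run-to-run repeatability is summarised by an ordinary least-squares fit of
one replicate's SpC values on the other's over the union of identified
proteins; slope and R-squared near 1 indicate reproducible runs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .psm import PSMRecord

__all__ = [
    "ProteinQuant",
    "ConditionProfile",
    "RepeatabilityReport",
    "InsufficientDataError",
    "aggregate_proteins",
    "average_replicates",
    "repeatability",
    "profile_to_frame",
    "quants_to_frame",
]


class InsufficientDataError(ValueError):
    """Not enough data points for the requested statistic."""


@dataclass(frozen=True)
class ProteinQuant:
    """One protein's quantification in one run."""

    accession: str
    spc: int
    score: float
    run_id: str


@dataclass
class ConditionProfile:
    """Replicate-averaged Score/SpC per protein for one condition.

    ``n_replicates`` is the number of runs averaged; ``presence_counts``
    records in how many of them each protein was identified.
    """

    condition: str
    n_replicates: int
    scores: dict[str, float] = field(default_factory=dict)
    spcs: dict[str, float] = field(default_factory=dict)
    presence_counts: dict[str, int] = field(default_factory=dict)

    def accessions(self) -> list[str]:
        return sorted(self.scores)

    def score(self, accession: str) -> float:
        return self.scores.get(accession, 0.0)

    def spc(self, accession: str) -> float:
        return self.spcs.get(accession, 0.0)

    def presence(self, accession: str) -> int:
        return self.presence_counts.get(accession, 0)


@dataclass(frozen=True)
class RepeatabilityReport:
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")


def aggregate_proteins(
    psms: Iterable[PSMRecord], run_id: str, min_consensus_score: float = 10.0
) -> list[ProteinQuant]:
    """Aggregate already-filtered PSMs into per-protein SpC and Score.

    SpC is the number of PSMs assigned to the accession, Score the sum of
    their per-PSM scores.  Proteins with Score <= ``min_consensus_score``
    are removed (the protein-level consensus filter; pass 0 to disable,
    e.g. for repeatability QC on everything identified).
    """
    spc: dict[str, int] = defaultdict(int)
    score: dict[str, float] = defaultdict(float)
    for p in psms:
        spc[p.accession] += 1
        score[p.accession] += p.psm_score
    return [
        ProteinQuant(accession=acc, spc=spc[acc], score=score[acc], run_id=run_id)
        for acc in sorted(spc)
        if score[acc] > min_consensus_score
    ]


def average_replicates(
    replicate_quants: Sequence[Sequence[ProteinQuant]], condition: str
) -> ConditionProfile:
    """Average technical replicates of one condition into a profile.

    A protein absent from a replicate contributes 0 to its average (rather
    than being averaged over present replicates only), so averages compare
    like with like across proteins and a condition-absent protein averages
    to exactly 0.  Presence counts are kept so callers can later demand
    identification in every replicate.
    """
    if len(replicate_quants) == 0:
        raise ValueError("need at least one replicate quantification list")
    n = len(replicate_quants)
    score_sum: dict[str, float] = defaultdict(float)
    spc_sum: dict[str, float] = defaultdict(float)
    presence: dict[str, int] = defaultdict(int)
    for quants in replicate_quants:
        for q in quants:
            score_sum[q.accession] += q.score
            spc_sum[q.accession] += q.spc
            presence[q.accession] += 1
    return ConditionProfile(
        condition=condition,
        n_replicates=n,
        scores={a: s / n for a, s in score_sum.items()},
        spcs={a: s / n for a, s in spc_sum.items()},
        presence_counts=dict(presence),
    )


def repeatability(
    rep1: Sequence[ProteinQuant], rep2: Sequence[ProteinQuant]
) -> RepeatabilityReport:
    """OLS fit of replicate-2 SpC on replicate-1 SpC (union, absent -> 0).

    Raises :class:`InsufficientDataError` below 3 points.
    """
    s1 = {q.accession: q.spc for q in rep1}
    s2 = {q.accession: q.spc for q in rep2}
    union = sorted(set(s1) | set(s2))
    if len(union) < 3:
        raise InsufficientDataError(
            f"repeatability needs >= 3 proteins, got {len(union)}"
        )
    x = [float(s1.get(a, 0)) for a in union]
    y = [float(s2.get(a, 0)) for a in union]
    fit = stats.linregress(x, y)
    return RepeatabilityReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_points=len(union),
    )


def quants_to_frame(quants: Sequence[ProteinQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        [q.__dict__ for q in quants], columns=["accession", "spc", "score", "run_id"]
    )


def profile_to_frame(profile: ConditionProfile) -> pd.DataFrame:
    """Condition profile as a tidy table (one row per protein)."""
    rows = [
        {
            "accession": acc,
            "avg_score": profile.scores[acc],
            "avg_spc": profile.spcs[acc],
            "n_replicates_present": profile.presence_counts.get(acc, 0),
        }
        for acc in profile.accessions()
    ]
    return pd.DataFrame(
        rows, columns=["accession", "avg_score", "avg_spc", "n_replicates_present"]
    )
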