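"""DAve/DCI label-free differential analysis between two condition profiles.

Two proteomes quantified by spectral counting are compared protein by
protein through a pair of statistics computed from the replicate-averaged
SEQUEST Score values X and Y of each protein:

* ``DAve`` (Differential Average), the relative difference
  ``(X - Y) / ((X + Y) * 0.5)``.  It is scale-free and bounded in
  ``[-2, +2]``; the bounds are attained exactly when the protein is
  *exclusive*, i.e. detected in only one of the two conditions.
* ``DCI`` (Differential Confidence Index), ``(X + Y) * (X - Y) / 2``.
  It carries the same sign as DAve but grows with total abundance, so it
  expresses how much identification evidence backs the difference.

A protein is called up-represented in X when ``DAve >= +0.4`` and
``DCI >= +400`` jointly, and up-represented in Y for the mirrored negative
thresholds; everything else is "unchanged".  The joint gate means an
exclusive protein (``|DAve| = 2``) is still not called unless its Score is
large enough: at the default thresholds the nonzero Score must reach
``sqrt(2 * 400) ~ 28.3``.

Downstream helpers compare differential lists across comparisons (strict
overlap of called proteins, or relaxed sign-concordance over everything
called in at least one list) and lay DAve values out as a clamped,
colour-binned matrix for heat-map style reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .quant import ConditionProfile

__all__ = [
    "DiffThresholds",
    "DifferentialRecord",
    "compute_dave",
    "compute_dci",
    "compare_conditions",
    "overlap_analysis",
    "OverlapResult",
    "heatmap_matrix",
    "dave_bin",
    "differential_to_frame",
]

Call = Literal["up_in_X", "up_in_Y", "unchanged"]


class UndefinedStatisticError(ValueError):
    """Raised when DAve is requested for a protein absent from both samples."""


@dataclass(frozen=True)
class DiffThresholds:
    """Joint DAve/DCI calling thresholds (defaults: 0.4 and 400)."""

    dave_min: float = 0.4
    dci_min: float = 400.0

    def __post_init__(self) -> None:
        if self.dave_min <= 0 or self.dci_min <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class DifferentialRecord:
    """One protein's differential outcome between two conditions."""

    accession: str
    score_x: float
    score_y: float
    dave: float
    dci: float
    call: Call
    exclusive: bool


def compute_dave(x: float, y: float) -> float:
    """Differential Average of two nonnegative Score values.

    ``DAve = (X - Y) / ((X + Y) * 0.5)``, i.e. the difference relative to
    the mean of the two scores.  Bounded in ``[-2, +2]``; equals +2 iff
    ``y == 0`` and -2 iff ``x == 0``.

    Raises
    ------
    UndefinedStatisticError
        If both scores are zero (the protein was seen in neither sample).
    ValueError
        If either score is negative.
    """
    if x < 0 or y < 0:
        raise ValueError(f"scores must be nonnegative, got ({x}, {y})")
    if x == 0 and y == 0:
        raise UndefinedStatisticError("DAve undefined for a protein absent from both samples")
    return (x - y) / ((x + y) * 0.5)


def compute_dci(x: float, y: float) -> float:
    """Differential Confidence Index ``(X + Y) * (X - Y) / 2``.

    Shares its sign with DAve but scales with total abundance
    (``compute_dci(c*x, c*y) == c**2 * compute_dci(x, y)``), so at a fixed
    abundance ratio better-supported proteins score higher.  Defined (as 0)
    even when both scores are 0.
    """
    if x < 0 or y < 0:
        raise ValueError(f"scores must be nonnegative, got ({x}, {y})")
    return (x + y) * (x - y) / 2.0


def _classify(dave: float, dci: float, thresholds: DiffThresholds) -> Call:
    if dave >= thresholds.dave_min and dci >= thresholds.dci_min:
        return "up_in_X"
    if dave <= -thresholds.dave_min and dci <= -thresholds.dci_min:
        return "up_in_Y"
    return "unchanged"


def compare_conditions(
    profile_x: ConditionProfile,
    profile_y: ConditionProfile,
    thresholds: DiffThresholds = DiffThresholds(),
    min_presence: int = 1,
) -> list[DifferentialRecord]:
    """Run the DAve/DCI comparison over the union of two condition profiles.

    Every accession present (nonzero averaged Score) in at least one of the
    two profiles yields one :class:`DifferentialRecord`; proteins with zero
    Score in both are skipped, since the relative statistic is undefined for
    them.  The ``exclusive`` flag marks proteins whose Score is zero in
    exactly one condition.

    Parameters
    ----------
    min_presence:
        Require a protein to have been identified in at least this many
        replicates of a condition for its average to count as "present";
        averages below that support are zeroed before comparison.  The
        default (1) keeps every identification; 2 reproduces a strict
        "identified in both technical replicates" reading.
    """
    records: list[DifferentialRecord] = []
    accessions = sorted(set(profile_x.accessions()) | set(profile_y.accessions()))
    for acc in accessions:
        x = profile_x.score(acc) if profile_x.presence(acc) >= min_presence else 0.0
        y = profile_y.score(acc) if profile_y.presence(acc) >= min_presence else 0.0
        if x == 0.0 and y == 0.0:
            continue
        dave = compute_dave(x, y)
        dci = compute_dci(x, y)
        records.append(
            DifferentialRecord(
                accession=acc,
                score_x=x,
                score_y=y,
                dave=dave,
                dci=dci,
                call=_classify(dave, dci, thresholds),
                exclusive=(x == 0.0) != (y == 0.0),
            )
        )
    return records


class OverlapResult(NamedTuple):
    """Agreement between two differential lists.

    ``n_shared`` counts agreeing proteins, ``n_total`` is the denominator
    the fraction is taken over (the first list's called set in strict mode;
    the union of called proteins in relaxed mode).
    """

    n_shared: int
    n_total: int
    fraction: float


def _called(records: Iterable[DifferentialRecord]) -> set[str]:
    return {r.accession for r in records if r.call != "unchanged"}


def overlap_analysis(
    list_a: Sequence[DifferentialRecord],
    list_b: Sequence[DifferentialRecord],
    mode: Literal["strict", "relaxed"] = "strict",
) -> OverlapResult:
    """Cross-comparison agreement between two differential lists.

    ``strict`` counts proteins called differential (non-"unchanged") in both
    lists, as a fraction of those called in ``list_a``.  ``relaxed`` takes
    every protein called in at least one list and counts those whose DAve
    values carry the same (nonzero) sign in both lists, irrespective of the
    thresholds — the paper-style "same pattern" reading that also credits
    sub-threshold trends.
    """
    called_a, called_b = _called(list_a), _called(list_b)
    if mode == "strict":
        shared = called_a & called_b
        n_a = len(called_a)
        return OverlapResult(len(shared), n_a, len(shared) / n_a if n_a else 0.0)
    if mode != "relaxed":
        raise ValueError(f"unknown mode {mode!r}")
    dave_a = {r.accession: r.dave for r in list_a}
    dave_b = {r.accession: r.dave for r in list_b}
    union = called_a | called_b
    concordant = sum(
        1
        for acc in union
        if acc in dave_a
        and acc in dave_b
        and np.sign(dave_a[acc]) == np.sign(dave_b[acc])
        and np.sign(dave_a[acc]) != 0
    )
    n = len(union)
    return OverlapResult(concordant, n, concordant / n if n else 0.0)


def dave_bin(dave: float, dave_min: float = 0.4, n_bins_per_side: int = 8) -> int:
    """Assign a DAve value to a signed colour bin.

    Bin 0 is the neutral (white) band ``|DAve| < dave_min``; positive bins
    1..n split ``[dave_min, 2]`` linearly up to dark red, negative bins
    mirror them toward dark blue.  Values are clamped to ``[-2, 2]`` first.
    """
    d = float(np.clip(dave, -2.0, 2.0))
    if abs(d) < dave_min:
        return 0
    width = (2.0 - dave_min) / n_bins_per_side
    k = min(int((abs(d) - dave_min) // width) + 1, n_bins_per_side)
    return k if d > 0 else -k


def heatmap_matrix(
    comparisons: Mapping[str, Sequence[DifferentialRecord]],
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """DAve matrix (proteins x comparisons) for heat-map reporting.

    Rows are proteins ordered by annotation group then accession, columns
    are comparison names.  Cells hold DAve clamped to ``[-2, 2]``; a protein
    absent from a comparison is ``NaN`` (distinct from a measured 0).  When
    ``groups`` is given, proteins annotated there but appearing in no
    comparison are dropped with a warning, and a ``group`` column is
    prepended.
    """
    dave_by_comp = {
        name: {r.accession: float(np.clip(r.dave, -2.0, 2.0)) for r in recs}
        for name, recs in comparisons.items()
    }
    seen: set[str] = set()
    for m in dave_by_comp.values():
        seen.update(m)
    if groups is not None:
        missing = sorted(set(groups) - seen)
        if missing:
            warnings.warn(
                f"{len(missing)} annotated protein(s) appear in no comparison "
                f"and were dropped: {', '.join(missing[:5])}"
                + ("..." if len(missing) > 5 else "")
            )
        rows = sorted(seen, key=lambda a: (groups.get(a, "~unannotated"), a))
    else:
        rows = sorted(seen)
    mat = pd.DataFrame(
        {name: [dave_by_comp[name].get(acc, np.nan) for acc in rows] for name in comparisons},
        index=pd.Index(rows, name="accession"),
    )
    if groups is not None:
        mat.insert(0, "group", [groups.get(acc, "") for acc in rows])
    return mat


def differential_to_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """Differential list as a tidy DataFrame (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "accession": r.accession,
                "score_x": r.score_x,
                "score_y": r.score_y,
                "dave": r.dave,
                "dci": r.dci,
                "call": r.call,
                "exclusive": r.exclusive,
            }
            for r in records
        ],
        columns=["accession", "score_x", "score_y", "dave", "dci", "call", "exclusive"],
    )
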