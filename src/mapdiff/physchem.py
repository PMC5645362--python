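"""Theoretical molecular weight and isoelectric point; 2D virtual maps.

Identified proteins can be laid out on a virtual 2D map — theoretical
average molecular weight (MW) against theoretical isoelectric point (pI) —
mimicking a 2D gel.  MW is the sum of average residue masses plus one
water; pI is the pH at which the Henderson–Hasselbalch net charge

    Q(pH) = sum_basic 1 / (1 + 10**(pH - pKa))
          - sum_acidic 1 / (1 + 10**(pKa - pH))

crosses zero (basic groups: N-terminus, K, R, H; acidic: C-terminus, D, E,
C, Y), found by bisection on [0, 14].  The pKa set defaults to the
EMBOSS-style values pinned in :data:`EMBOSS_PKA`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio.SeqRecord import SeqRecord

from .quant import ConditionProfile

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "EMBOSS_PKA",
    "PhyschemPoint",
    "compute_mw",
    "net_charge",
    "compute_pi",
    "build_virtual_map",
    "points_to_frame",
]

#: Average (isotope-abundance-weighted) residue masses in Da.
AVERAGE_RESIDUE_MASS: Mapping[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MASS = 18.0153

#: EMBOSS-style pKa values for the ionizable groups.
EMBOSS_PKA: Mapping[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,          # basic side chains
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,  # acidic side chains
}

_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")

UnknownPolicy = Literal["strict", "skip-residue"]


@dataclass(frozen=True)
class PhyschemPoint:
    """One protein's coordinates on the virtual 2D map."""

    accession: str
    mw: float
    pi: float
    abundance_proxy: float

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if not 0 < self.pi < 14:
            raise ValueError("pi must lie strictly inside (0, 14)")


def _clean(sequence: str, unknown: UnknownPolicy) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = [c for c in seq if c not in AVERAGE_RESIDUE_MASS]
    if bad:
        if unknown == "strict":
            raise ValueError(f"unknown residue(s): {sorted(set(bad))}")
        seq = "".join(c for c in seq if c in AVERAGE_RESIDUE_MASS)
        if not seq:
            raise ValueError("sequence contains no standard residues")
    return seq


def compute_mw(sequence: str, unknown: UnknownPolicy = "strict") -> float:
    """Average molecular weight in Da: residue masses plus one water.

    ``unknown`` governs non-standard letters (B, Z, X, U...): ``strict``
    raises, ``skip-residue`` drops them from the sum.
    """
    seq = _clean(sequence, unknown)
    return sum(AVERAGE_RESIDUE_MASS[c] for c in seq) + WATER_MASS


def net_charge(
    sequence: str, ph: float, pka: Mapping[str, float] = EMBOSS_PKA,
    unknown: UnknownPolicy = "strict",
) -> float:
    """Net protein charge at the given pH under the configured pKa set."""
    seq = _clean(sequence, unknown)
    counts = Counter(seq)
    q = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    q -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in _BASIC:
        q += counts[aa] / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in _ACIDIC:
        q -= counts[aa] / (1.0 + 10.0 ** (pka[aa] - ph))
    return q


def compute_pi(
    sequence: str, pka: Mapping[str, float] = EMBOSS_PKA,
    tol: float = 1e-4, unknown: UnknownPolicy = "strict",
) -> float:
    """Isoelectric point by bisection of the net charge on [0, 14].

    Q(pH) is strictly decreasing, positive at pH 0 and negative at pH 14
    (the termini alone guarantee a sign change), so bisection converges;
    iteration stops once ``|Q| < tol``.
    """
    seq = _clean(sequence, unknown)
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid, pka)
        if abs(q) < tol:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def build_virtual_map(
    profile: ConditionProfile,
    fasta_records: Iterable[SeqRecord],
    abundance: Literal["score", "spc"] = "score",
    unknown: UnknownPolicy = "strict",
) -> tuple[list[PhyschemPoint], list[str]]:
    """Map a condition profile onto (MW, pI) coordinates.

    Returns the points plus the accessions skipped because they were absent
    from the FASTA database (each also emits a log-style warning via the
    returned list; nothing is fatal).  Point size metadata comes from the
    averaged Score (default) or SpC.
    """
    seqs = {r.id.split()[0]: str(r.seq) for r in fasta_records}
    points: list[PhyschemPoint] = []
    skipped: list[str] = []
    for acc in profile.accessions():
        seq = seqs.get(acc)
        if seq is None:
            skipped.append(acc)
            continue
        proxy = profile.score(acc) if abundance == "score" else profile.spc(acc)
        points.append(
            PhyschemPoint(
                accession=acc,
                mw=compute_mw(seq, unknown),
                pi=compute_pi(seq, unknown=unknown),
                abundance_proxy=proxy,
            )
        )
    return points, skipped


def points_to_frame(points: Sequence[PhyschemPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"accession": p.accession, "mw_da": p.mw, "pi": p.pi,
             "abundance_proxy": p.abundance_proxy}
            for p in points
        ],
        columns=["accession", "mw_da", "pi", "abundance_proxy"],
    )
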