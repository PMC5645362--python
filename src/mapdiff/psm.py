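"""PSM table IO and SEQUEST-style quality filtering.

A peptide-spectrum match (PSM) row carries the search-engine evidence for
one fragmentation spectrum: the matched peptide, its precursor charge, the
SEQUEST cross-correlation (Xcorr), a peptide probability (smaller is more
confident) and a per-PSM score that later sums into the protein Score.

Filtering keeps a PSM iff its peptide probability is at most 1e-3 and its
Xcorr reaches the charge-specific minimum (1.5 / 2.0 / 2.5 / 3.0 for charge
1+ / 2+ / 3+ / 4+; higher charges use the 4+ threshold).  Both boundaries
are inclusive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PSMRecord",
    "FilterConfig",
    "PSMFormatError",
    "PSM_COLUMNS",
    "read_psm_table",
    "write_psm_table",
    "filter_psms",
]

PSM_COLUMNS = (
    "accession",
    "peptide",
    "charge",
    "xcorr",
    "peptide_probability",
    "psm_score",
    "run_id",
)

DEFAULT_XCORR_MIN = {1: 1.5, 2: 2.0, 3: 2.5, 4: 3.0}


class PSMFormatError(ValueError):
    """A PSM table violated the expected tab-separated dialect."""


@dataclass(frozen=True)
class PSMRecord:
    accession: str
    peptide: str
    charge: int
    xcorr: float
    peptide_probability: float
    psm_score: float
    run_id: str = ""

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.xcorr < 0:
            raise ValueError(f"xcorr must be nonnegative, got {self.xcorr}")
        if not 0 < self.peptide_probability <= 1:
            raise ValueError(
                f"peptide_probability must be in (0, 1], got {self.peptide_probability}"
            )


@dataclass(frozen=True)
class FilterConfig:
    """PSM acceptance thresholds.

    ``min_consensus_score`` is carried here for convenience but applied at
    the protein level (see :func:`mapdiff.quant.aggregate_proteins`).
    """

    max_peptide_probability: float = 1e-3
    min_xcorr_by_charge: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_XCORR_MIN)
    )
    min_consensus_score: float = 10.0

    def __post_init__(self) -> None:
        if self.max_peptide_probability <= 0:
            raise ValueError("max_peptide_probability must be positive")
        if any(v <= 0 for v in self.min_xcorr_by_charge.values()):
            raise ValueError("Xcorr thresholds must be positive")
        if not {1, 2, 3, 4} <= set(self.min_xcorr_by_charge):
            raise ValueError("min_xcorr_by_charge must cover charges 1..4")

    def xcorr_threshold(self, charge: int) -> float:
        """Charge-specific Xcorr minimum; charges above 4 use the 4+ value."""
        return self.min_xcorr_by_charge[min(charge, max(self.min_xcorr_by_charge))]


def _parse_charge(value: object, line_no: int) -> int:
    # tolerate the common "2+" spelling
    s = str(value).strip().rstrip("+")
    try:
        return int(s)
    except ValueError:
        raise PSMFormatError(f"line {line_no}: unparsable charge {value!r}") from None


def read_psm_table(path: str | os.PathLike) -> list[PSMRecord]:
    """Read a tab-separated PSM table into records.

    The header must contain every column in :data:`PSM_COLUMNS` except that
    ``run_id`` may be omitted (it then defaults to the file's stem).
    Malformed numeric fields raise :class:`PSMFormatError` with the 1-based
    data line number.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise PSMFormatError(f"{path}: empty PSM table") from None
    required = [c for c in PSM_COLUMNS if c != "run_id"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise PSMFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "run_id" not in frame.columns:
        frame["run_id"] = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    records: list[PSMRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        r = row._asdict()
        try:
            records.append(
                PSMRecord(
                    accession=str(r["accession"]),
                    peptide=str(r["peptide"]),
                    charge=_parse_charge(r["charge"], i),
                    xcorr=float(r["xcorr"]),
                    peptide_probability=float(r["peptide_probability"]),
                    psm_score=float(r["psm_score"]),
                    run_id=str(r["run_id"]),
                )
            )
        except PSMFormatError:
            raise
        except (TypeError, ValueError) as exc:
            raise PSMFormatError(f"{path}, line {i}: {exc}") from None
    return records


def write_psm_table(psms: Iterable[PSMRecord], path: str | os.PathLike) -> None:
    """Write records as a tab-separated table with the standard header."""
    pd.DataFrame([r.__dict__ for r in psms], columns=list(PSM_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def filter_psms(
    psms: Sequence[PSMRecord], config: FilterConfig = FilterConfig()
) -> list[PSMRecord]:
    """Apply the probability and charge-conditional Xcorr filters.

    Keeps a PSM iff ``peptide_probability <= max_peptide_probability`` and
    ``xcorr >= min_xcorr_by_charge[min(charge, 4)]`` (both inclusive).
    Order is preserved and the input is untouched.
    """
    return [
        p
        for p in psms
        if p.peptide_probability <= config.max_peptide_probability
        and p.xcorr >= config.xcorr_threshold(p.charge)
    ]
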