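"""Re-check published differential counts from a per-sample Score table.

Given a table of replicate-averaged protein Scores (first column the
protein accession, one further numeric column per sample/condition), this
rebuilds condition profiles, reruns the DAve/DCI comparison for requested
sample pairs and reports differential counts, up/down/exclusive breakdowns
and strict/relaxed overlaps — everything needed to verify printed summary
numbers against the underlying supplementary data of a study.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd

from .differential import DiffThresholds, compare_conditions, overlap_analysis
from .quant import ConditionProfile

__all__ = ["load_score_table", "recheck_comparisons"]


def load_score_table(path: str | os.PathLike) -> dict[str, ConditionProfile]:
    """Read an accession x sample Score matrix into condition profiles.

    Accepts tab/comma-separated text or xlsx (by extension).  Empty cells
    count as Score 0 (protein not identified in that sample).
    """
    p = os.fspath(path)
    if p.endswith((".xlsx", ".xls")):
        frame = pd.read_excel(p)
    else:
        frame = pd.read_csv(p, sep="\t" if p.endswith((".tsv", ".txt")) else ",")
    acc_col = frame.columns[0]
    profiles: dict[str, ConditionProfile] = {}
    for col in frame.columns[1:]:
        scores = {
            str(a): float(v)
            for a, v in zip(frame[acc_col], pd.to_numeric(frame[col], errors="coerce").fillna(0.0))
            if float(v) > 0
        }
        profiles[str(col)] = ConditionProfile(
            condition=str(col),
            n_replicates=1,
            scores=scores,
            spcs=dict(scores),
            presence_counts={a: 1 for a in scores},
        )
    return profiles


def recheck_comparisons(
    profiles: Mapping[str, ConditionProfile],
    comparisons: Sequence[tuple[str, str]],
    overlaps: Sequence[tuple[str, str]] = (),
    thresholds: DiffThresholds = DiffThresholds(),
) -> dict:
    """Recompute differential counts and overlaps for named sample pairs.

    ``comparisons`` lists (sample_x, sample_y) column pairs; ``overlaps``
    lists pairs of comparison names (``"X_vs_Y"``) whose differential lists
    to intersect.  Returns a plain dict ready for printing or YAML dumping.
    """
    report: dict = {"comparisons": {}, "overlaps": {}}
    lists = {}
    for x, y in comparisons:
        if x not in profiles or y not in profiles:
            raise KeyError(f"comparison ({x}, {y}) names a missing sample column")
        records = compare_conditions(profiles[x], profiles[y], thresholds)
        name = f"{x}_vs_{y}"
        lists[name] = records
        up = [r for r in records if r.call == "up_in_X"]
        down = [r for r in records if r.call == "up_in_Y"]
        report["comparisons"][name] = {
            "n_compared": len(records),
            "n_differential": len(up) + len(down),
            "n_up_in_x": len(up),
            "n_up_in_y": len(down),
            "n_up_in_x_exclusive": sum(r.exclusive for r in up),
            "n_up_in_y_exclusive": sum(r.exclusive for r in down),
        }
    diff_union: set[str] = set()
    for name, records in lists.items():
        diff_union.update(r.accession for r in records if r.call != "unchanged")
    report["n_distinct_differential"] = len(diff_union)
    for a, b in overlaps:
        strict = overlap_analysis(lists[a], lists[b], "strict")
        relaxed = overlap_analysis(lists[a], lists[b], "relaxed")
        report["overlaps"][f"{a}|{b}"] = {
            "strict_shared": strict.n_shared,
            "strict_of": strict.n_total,
            "strict_fraction": strict.fraction,
            "relaxed_concordant": relaxed.n_shared,
            "relaxed_of": relaxed.n_total,
            "relaxed_fraction": relaxed.fraction,
        }
    return report
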