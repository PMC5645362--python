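"""End-to-end orchestration: filter -> quantify -> compare -> report.

Wires the stages into the full label-free workflow and writes every
artefact (per-run protein tables, condition profiles, differential lists,
repeatability QC, the MW/pI virtual-map table, the DAve heat matrix and a
run manifest) as tab-separated text under one output directory.  Outputs
are deterministic given identical inputs and configuration.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import yaml
from Bio import SeqIO

from .differential import (
    DiffThresholds,
    DifferentialRecord,
    compare_conditions,
    differential_to_frame,
    heatmap_matrix,
)
from .physchem import build_virtual_map, points_to_frame
from .psm import FilterConfig, filter_psms, read_psm_table
from .quant import (
    ConditionProfile,
    RepeatabilityReport,
    aggregate_proteins,
    average_replicates,
    profile_to_frame,
    quants_to_frame,
    repeatability,
)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "build_profiles"]

log = logging.getLogger("mapdiff")

#: Documented reading of the two differential statistics, recorded in every
#: run manifest so results stay self-describing.
FORMULA_READINGS = {
    "dave": "(X - Y) / ((X + Y) * 0.5), bounded in [-2, +2]",
    "dci": "(X + Y) * (X - Y) / 2",
}


@dataclass
class RunConfig:
    """Everything one pipeline invocation needs.

    ``condition_tables`` maps each condition label to its replicate PSM
    table paths; ``comparisons`` lists (condition_x, condition_y) pairs.
    An empty comparison list means all pairwise combinations in order.
    """

    condition_tables: Mapping[str, Sequence[str]]
    fasta: str | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    thresholds: DiffThresholds = field(default_factory=DiffThresholds)
    comparisons: Sequence[tuple[str, str]] = ()
    min_presence: int = 1
    groups: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.condition_tables:
            raise ValueError("at least one condition is required")
        for x, y in self.comparisons:
            for c in (x, y):
                if c not in self.condition_tables:
                    raise ValueError(f"comparison references undefined condition {c!r}")

    def comparison_pairs(self) -> list[tuple[str, str]]:
        if self.comparisons:
            return list(self.comparisons)
        return list(combinations(self.condition_tables, 2))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        fc = raw.get("filter", {})
        filter_config = FilterConfig(
            max_peptide_probability=float(fc.get("max_peptide_probability", 1e-3)),
            min_xcorr_by_charge={
                int(k): float(v)
                for k, v in fc.get(
                    "min_xcorr_by_charge", {1: 1.5, 2: 2.0, 3: 2.5, 4: 3.0}
                ).items()
            },
            min_consensus_score=float(fc.get("min_consensus_score", 10.0)),
        )
        th = raw.get("thresholds", {})
        thresholds = DiffThresholds(
            dave_min=float(th.get("dave_min", 0.4)),
            dci_min=float(th.get("dci_min", 400.0)),
        )
        return cls(
            condition_tables={
                str(c): [str(p) for p in paths]
                for c, paths in raw["conditions"].items()
            },
            fasta=raw.get("fasta"),
            filter_config=filter_config,
            thresholds=thresholds,
            comparisons=[tuple(pair) for pair in raw.get("comparisons", [])],
            min_presence=int(raw.get("min_presence", 1)),
            groups=raw.get("groups"),
        )


@dataclass
class RunResult:
    profiles: dict[str, ConditionProfile]
    differentials: dict[str, list[DifferentialRecord]]
    qc: dict[str, RepeatabilityReport]
    counts: dict[str, dict[str, int]]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_profiles(
    config: RunConfig,
) -> tuple[dict[str, ConditionProfile], dict[str, RepeatabilityReport], dict[str, dict[str, int]], dict[str, list]]:
    """Read, filter and aggregate every run; average into condition profiles.

    Returns (profiles, per-condition repeatability QC, per-run row counts,
    per-condition consensus-filtered quant lists).  QC regresses the first
    two replicates' SpC with the consensus filter disabled, so borderline
    identifications do not masquerade as irreproducibility.
    """
    profiles: dict[str, ConditionProfile] = {}
    qc: dict[str, RepeatabilityReport] = {}
    counts: dict[str, dict[str, int]] = {}
    quants_by_condition: dict[str, list] = {}
    for cond, paths in config.condition_tables.items():
        rep_quants = []
        rep_quants_unfiltered = []
        for path in paths:
            psms = read_psm_table(path)
            kept = filter_psms(psms, config.filter_config)
            run_id = os.path.splitext(os.path.basename(path))[0]
            quants = aggregate_proteins(
                kept, run_id, config.filter_config.min_consensus_score
            )
            counts[run_id] = {
                "input_psms": len(psms),
                "kept_psms": len(kept),
                "proteins_pre_consensus": len({p.accession for p in kept}),
                "proteins_post_consensus": len(quants),
            }
            log.info(
                "%s: %d PSMs in, %d kept, %d proteins (%d after consensus filter)",
                run_id, len(psms), len(kept),
                counts[run_id]["proteins_pre_consensus"], len(quants),
            )
            rep_quants.append(quants)
            rep_quants_unfiltered.append(aggregate_proteins(kept, run_id, 0.0))
        profiles[cond] = average_replicates(rep_quants, cond)
        quants_by_condition[cond] = rep_quants
        if len(rep_quants_unfiltered) >= 2:
            qc[cond] = repeatability(rep_quants_unfiltered[0], rep_quants_unfiltered[1])
            log.info(
                "%s repeatability: slope %.3f, R^2 %.3f over %d proteins",
                cond, qc[cond].slope, qc[cond].r_squared, qc[cond].n_points,
            )
    return profiles, qc, counts, quants_by_condition


def run_pipeline(config: RunConfig, out_dir: str | os.PathLike | None = None) -> RunResult:
    """Execute the full workflow; optionally write all artefacts to disk."""
    profiles, qc, counts, quants_by_condition = build_profiles(config)

    differentials: dict[str, list[DifferentialRecord]] = {}
    for x, y in config.comparison_pairs():
        name = f"{x}_vs_{y}"
        records = compare_conditions(
            profiles[x], profiles[y], config.thresholds, config.min_presence
        )
        n_diff = sum(1 for r in records if r.call != "unchanged")
        log.info("%s: %d proteins compared, %d differential", name, len(records), n_diff)
        differentials[name] = records

    result = RunResult(profiles=profiles, differentials=differentials, qc=qc, counts=counts)
    if out_dir is None:
        return result

    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    for cond, profile in profiles.items():
        profile_to_frame(profile).to_csv(
            os.path.join(out, f"profile_{cond}.tsv"), sep="\t", index=False
        )
        for quants in quants_by_condition[cond]:
            if quants:
                quants_to_frame(quants).to_csv(
                    os.path.join(out, f"proteins_{quants[0].run_id}.tsv"),
                    sep="\t", index=False,
                )
    for name, records in differentials.items():
        differential_to_frame(records).to_csv(
            os.path.join(out, f"differential_{name}.tsv"), sep="\t", index=False
        )
    if differentials:
        heatmap_matrix(differentials, config.groups).to_csv(
            os.path.join(out, "dave_matrix.tsv"), sep="\t", na_rep="NA"
        )
    if config.fasta:
        fasta_records = list(SeqIO.parse(config.fasta, "fasta"))
        for cond, profile in profiles.items():
            points, skipped = build_virtual_map(profile, fasta_records)
            if skipped:
                log.warning("virtual map %s: %d accession(s) missing from FASTA", cond, len(skipped))
            points_to_frame(points).to_csv(
                os.path.join(out, f"virtual_map_{cond}.tsv"), sep="\t", index=False
            )

    manifest = {
        "filter": {
            "max_peptide_probability": config.filter_config.max_peptide_probability,
            "min_xcorr_by_charge": dict(config.filter_config.min_xcorr_by_charge),
            "min_consensus_score": config.filter_config.min_consensus_score,
        },
        "thresholds": {
            "dave_min": config.thresholds.dave_min,
            "dci_min": config.thresholds.dci_min,
        },
        "min_presence": config.min_presence,
        "formula_readings": FORMULA_READINGS,
        "inputs": {
            cond: {os.path.basename(p): _sha256(p) for p in paths}
            for cond, paths in config.condition_tables.items()
        },
        "row_counts": counts,
        "qc": {
            cond: {"slope": r.slope, "intercept": r.intercept,
                   "r_squared": r.r_squared, "n_points": r.n_points}
            for cond, r in qc.items()
        },
        "differential_counts": {
            name: sum(1 for r in records if r.call != "unchanged")
            for name, records in differentials.items()
        },
    }
    with open(os.path.join(out, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return result
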