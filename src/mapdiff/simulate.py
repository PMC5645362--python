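"""Synthetic multi-condition PSM tables with known ground truth.

Emulates a shotgun (MudPIT-style) label-free experiment: several biological
conditions, each acquired in technical replicates, producing one PSM table
per run.  The generative model is deliberately minimal:

* per-protein baseline abundance ``lambda_i`` drawn from a lognormal law
  (or pinned to a nominal value for spike-in proteins),
* per run, the protein's spectral count is Poisson with rate
  ``lambda_i * f_{i,c}`` where ``f_{i,c}`` is the condition fold change
  (0 for condition-exclusive absences),
* each accepted-quality PSM gets a charge from a categorical law, an Xcorr
  above the charge-specific acceptance minimum, a peptide probability below
  1e-3, and a per-PSM score from a Gamma law (protein Score is then the sum
  over its PSMs, roughly proportional to SpC),
* a configurable fraction of additional low-quality PSMs is injected that
  fails at least one acceptance filter, so the filtering stage has real
  work to do.

Everything is driven by one integer seed; identical design and seed yield
byte-identical tables and truth.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .psm import DEFAULT_XCORR_MIN, PSMRecord

__all__ = [
    "AA_FREQUENCIES",
    "SimDesign",
    "SyntheticTruth",
    "log_mean_for_mean_rate",
    "generate_proteome",
    "generate_psm_tables",
    "spike_in_design",
    "write_fasta",
    "write_psm_tables",
]

#: Swiss-Prot-like amino-acid background frequencies used for synthetic sequences.
AA_FREQUENCIES: Mapping[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

_AAS = np.array(list(AA_FREQUENCIES))
_AA_P = np.array(list(AA_FREQUENCIES.values()))
_AA_P = _AA_P / _AA_P.sum()


def log_mean_for_mean_rate(mean_rate: float, log_sd: float) -> float:
    """Lognormal ``mu`` giving the requested arithmetic-mean rate."""
    return math.log(mean_rate) - log_sd**2 / 2.0


@dataclass(frozen=True)
class SimDesign:
    """Design of one synthetic multi-condition experiment.

    ``baseline_log_mean``/``baseline_log_sd`` parameterise the lognormal
    law of per-protein Poisson rates (defaults give a mean SpC of 40 per
    run with a ~0.8-log spread).  ``fold_change_map`` maps accessions to
    per-condition abundance ratios, ``exclusive_map`` lists conditions in
    which a protein is entirely absent, and ``abundance_map`` pins selected
    proteins (spike-ins) to a fixed nominal rate instead of a lognormal
    draw.  ``noise_fraction`` is the fraction of table rows that are
    low-quality PSMs destined to fail at least one acceptance filter.
    """

    n_proteins: int
    conditions: tuple[str, ...] = ("A", "B", "C", "D")
    n_replicates_per_condition: int = 2
    baseline_log_mean: float = log_mean_for_mean_rate(40.0, 0.8)
    baseline_log_sd: float = 0.8
    fold_change_map: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    exclusive_map: Mapping[str, frozenset[str]] = field(default_factory=dict)
    abundance_map: Mapping[str, float] = field(default_factory=dict)
    noise_fraction: float = 0.1
    seed: int = 0
    charge_frequencies: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.60, 3: 0.30, 4: 0.05}
    )
    psm_score_mean: float = 0.6
    psm_score_shape: float = 8.0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if len(self.conditions) < 1 or len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be nonempty and unique")
        if self.n_replicates_per_condition < 1:
            raise ValueError("need at least one replicate per condition")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError("noise_fraction must lie in [0, 1)")
        for acc, per_cond in self.fold_change_map.items():
            for cond, f in per_cond.items():
                if cond not in self.conditions:
                    raise ValueError(f"fold change for unknown condition {cond!r} ({acc})")
                if f <= 0:
                    raise ValueError(f"fold change must be positive ({acc}, {cond}: {f})")
        for acc, conds in self.exclusive_map.items():
            if not set(conds) <= set(self.conditions):
                raise ValueError(f"exclusive_map for {acc} names unknown conditions")
        if self.psm_score_mean <= 0 or self.psm_score_shape <= 0:
            raise ValueError("per-PSM score law parameters must be positive")

    def run_ids(self) -> list[tuple[str, int, str]]:
        """(condition, replicate index, run_id) triples in generation order."""
        return [
            (c, r, f"{c}_r{r}")
            for c in self.conditions
            for r in range(1, self.n_replicates_per_condition + 1)
        ]


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the tables.

    ``rates`` holds each protein's true Poisson rate per condition (0 marks
    a designed absence); ``realized_spc`` the total quality-PSM count it
    actually received per condition across replicates.
    """

    rates: dict[str, dict[str, float]]
    realized_spc: dict[str, dict[str, int]]

    def status(self, accession: str, cond_x: str, cond_y: str) -> str:
        """True differential status of one protein for a pairwise comparison.

        Returns ``up_in_X``/``up_in_Y``/``unchanged``/``exclusive``
        (``absent`` if the protein exists in neither condition).  Exclusive
        means a rate of exactly 0 in one condition and > 0 in the other.
        """
        rx, ry = self.rates[accession][cond_x], self.rates[accession][cond_y]
        if rx == 0 and ry == 0:
            return "absent"
        if (rx == 0) != (ry == 0):
            return "exclusive"
        if rx > ry:
            return "up_in_X"
        if rx < ry:
            return "up_in_Y"
        return "unchanged"

    def changed_set(self, cond_x: str, cond_y: str) -> set[str]:
        """Accessions whose true rates differ between the two conditions."""
        return {
            a for a in self.rates
            if self.status(a, cond_x, cond_y) in ("up_in_X", "up_in_Y", "exclusive")
        }

    def exclusive_set(self, cond_x: str, cond_y: str) -> set[str]:
        return {a for a in self.rates if self.status(a, cond_x, cond_y) == "exclusive"}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for acc in sorted(self.rates):
            for cond in self.rates[acc]:
                rows.append(
                    {
                        "accession": acc,
                        "condition": cond,
                        "true_rate": self.rates[acc][cond],
                        "realized_spc": self.realized_spc[acc][cond],
                    }
                )
        return pd.DataFrame(rows, columns=["accession", "condition", "true_rate", "realized_spc"])


def generate_proteome(
    n_proteins: int,
    seed: int,
    mean_length: float = 350.0,
    length_log_sd: float = 0.35,
    fixed_length: int | None = None,
    accession_prefix: str = "SYN",
) -> list[SeqRecord]:
    """Random protein database over the 20 standard amino acids.

    Lengths follow a lognormal law around ``mean_length`` (floored at 30
    residues) unless ``fixed_length`` pins them; residues are i.i.d. from
    :data:`AA_FREQUENCIES`.  Deterministic under the seed.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_proteins)))
    records = []
    for i in range(n_proteins):
        if fixed_length is not None:
            length = int(fixed_length)
        else:
            mu = log_mean_for_mean_rate(mean_length, length_log_sd)
            length = max(30, int(round(rng.lognormal(mu, length_log_sd))))
        seq = "".join(rng.choice(_AAS, size=length, p=_AA_P))
        acc = f"{accession_prefix}{i + 1:0{width}d}"
        records.append(SeqRecord(Seq(seq), id=acc, description=f"synthetic protein {i + 1}"))
    return records


def _random_peptide(rng: np.random.Generator, sequence: str) -> str:
    # tryptic-like length window; short parents yield the whole chain
    length = int(rng.integers(7, 26))
    if len(sequence) <= length:
        return sequence
    start = int(rng.integers(0, len(sequence) - length + 1))
    return sequence[start : start + length]


def _clean_psm(
    rng: np.random.Generator, design: SimDesign, acc: str, seq: str, run_id: str
) -> PSMRecord:
    charges = np.array(list(design.charge_frequencies))
    probs = np.array(list(design.charge_frequencies.values()), dtype=float)
    z = int(rng.choice(charges, p=probs / probs.sum()))
    xcorr = DEFAULT_XCORR_MIN[min(z, 4)] + rng.gamma(2.0, 0.5)
    return PSMRecord(
        accession=acc,
        peptide=_random_peptide(rng, seq),
        charge=z,
        xcorr=round(float(xcorr), 4),
        peptide_probability=float(f"{10.0 ** -rng.uniform(3.05, 7.0):.3e}"),
        psm_score=round(float(rng.gamma(design.psm_score_shape,
                                        design.psm_score_mean / design.psm_score_shape)), 4),
        run_id=run_id,
    )


def _noise_psm(
    rng: np.random.Generator, design: SimDesign, accessions: Sequence[str],
    seqs: Mapping[str, str], run_id: str,
) -> PSMRecord:
    acc = str(rng.choice(np.asarray(accessions)))
    charges = np.array(list(design.charge_frequencies))
    probs = np.array(list(design.charge_frequencies.values()), dtype=float)
    z = int(rng.choice(charges, p=probs / probs.sum()))
    thr = DEFAULT_XCORR_MIN[min(z, 4)]
    mode = rng.choice(np.array(["xcorr", "prob", "both"]))
    if mode in ("xcorr", "both"):
        xcorr = float(rng.uniform(0.2, thr - 0.05))
    else:
        xcorr = thr + float(rng.gamma(2.0, 0.5))
    if mode in ("prob", "both"):
        prob = float(rng.uniform(2e-3, 5e-2))
    else:
        prob = 10.0 ** -float(rng.uniform(3.05, 7.0))
    return PSMRecord(
        accession=acc,
        peptide=_random_peptide(rng, seqs[acc]),
        charge=z,
        xcorr=round(xcorr, 4),
        peptide_probability=float(f"{prob:.3e}"),
        psm_score=round(float(rng.gamma(design.psm_score_shape,
                                        design.psm_score_mean / design.psm_score_shape)), 4),
        run_id=run_id,
    )


def generate_psm_tables(
    design: SimDesign, proteome: Sequence[SeqRecord]
) -> tuple[dict[str, list[PSMRecord]], SyntheticTruth]:
    """Generate one PSM table per condition x replicate, plus ground truth.

    Raises ``ValueError`` if ``fold_change_map``, ``exclusive_map`` or
    ``abundance_map`` reference accessions missing from the proteome.
    """
    seqs = {r.id.split()[0]: str(r.seq) for r in proteome}
    accessions = sorted(seqs)
    for name, mapping in (
        ("fold_change_map", design.fold_change_map),
        ("exclusive_map", design.exclusive_map),
        ("abundance_map", design.abundance_map),
    ):
        unknown = set(mapping) - set(accessions)
        if unknown:
            raise ValueError(f"{name} references unknown accession(s): {sorted(unknown)[:5]}")

    rng = np.random.default_rng(design.seed)
    baselines = {
        acc: design.abundance_map.get(
            acc, float(rng.lognormal(design.baseline_log_mean, design.baseline_log_sd))
        )
        for acc in accessions
    }
    rates = {
        acc: {
            cond: (
                0.0
                if cond in design.exclusive_map.get(acc, frozenset())
                else baselines[acc] * design.fold_change_map.get(acc, {}).get(cond, 1.0)
            )
            for cond in design.conditions
        }
        for acc in accessions
    }

    tables: dict[str, list[PSMRecord]] = {}
    realized = {acc: {cond: 0 for cond in design.conditions} for acc in accessions}
    for cond, _rep, run_id in design.run_ids():
        clean: list[PSMRecord] = []
        # a protein designed absent from this condition produces no spectra
        # at all, so noise PSMs draw from the present proteins only
        present = [acc for acc in accessions if rates[acc][cond] > 0]
        for acc in accessions:
            count = int(rng.poisson(rates[acc][cond]))
            realized[acc][cond] += count
            clean.extend(_clean_psm(rng, design, acc, seqs[acc], run_id) for _ in range(count))
        n_noise = int(round(design.noise_fraction / (1.0 - design.noise_fraction) * len(clean)))
        rows = clean + [
            _noise_psm(rng, design, present, seqs, run_id) for _ in range(n_noise)
        ]
        order = rng.permutation(len(rows))
        tables[run_id] = [rows[i] for i in order]
    return tables, SyntheticTruth(rates=rates, realized_spc=realized)


def spike_in_design(
    n_proteins: int = 1000,
    n_spiked: int = 30,
    fold: float = 4.0,
    spike_rate: float = 40.0,
    conditions: tuple[str, str] = ("A", "B"),
    spiked_condition: str | None = None,
    seed: int = 0,
    **kwargs,
) -> SimDesign:
    """Two-condition spike-in benchmark design.

    The first ``n_spiked`` accessions are placed at a fixed nominal rate
    (``spike_rate`` expected PSMs per run) and increased ``fold``-fold in
    the spiked condition (default: the first); all remaining proteins share
    the lognormal baseline between conditions.
    """
    if not 1 <= n_spiked <= n_proteins:
        raise ValueError("need 1 <= n_spiked <= n_proteins")
    width = max(5, len(str(n_proteins)))
    spiked = [f"SYN{i + 1:0{width}d}" for i in range(n_spiked)]
    target = spiked_condition or conditions[0]
    if target not in conditions:
        raise ValueError(f"spiked_condition {target!r} not among conditions")
    return SimDesign(
        n_proteins=n_proteins,
        conditions=conditions,
        fold_change_map={acc: {target: fold} for acc in spiked},
        abundance_map={acc: spike_rate for acc in spiked},
        seed=seed,
        **kwargs,
    )


def write_fasta(records: Sequence[SeqRecord], path: str | os.PathLike) -> None:
    """Standard 60-column-wrapped FASTA."""
    SeqIO.write(records, os.fspath(path), "fasta")


def write_psm_tables(
    tables: Mapping[str, Sequence[PSMRecord]], out_dir: str | os.PathLike
) -> dict[str, str]:
    """One TSV per run under ``out_dir``; returns run_id -> path."""
    from .psm import write_psm_table

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for run_id in sorted(tables):
        path = os.path.join(os.fspath(out_dir), f"{run_id}.psms.tsv")
        write_psm_table(tables[run_id], path)
        paths[run_id] = path
    return paths
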