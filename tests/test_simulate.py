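"""Synthetic proteome and PSM-table generator: determinism and calibration."""

import io

import numpy as np
import pytest
from Bio import SeqIO

from mapdiff.psm import filter_psms
from mapdiff.simulate import (
    AA_FREQUENCIES,
    SimDesign,
    generate_proteome,
    generate_psm_tables,
    log_mean_for_mean_rate,
    spike_in_design,
    write_fasta,
)


def fasta_bytes(records) -> bytes:
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue().encode()


class TestGenerateProteome:
    def test_fixed_length_single_record(self):
        (rec,) = generate_proteome(1, seed=7, fixed_length=10)
        assert len(rec.seq) == 10

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            generate_proteome(0, seed=1)

    def test_deterministic_fasta_bytes(self):
        a = fasta_bytes(generate_proteome(100, seed=1, fixed_length=50))
        b = fasta_bytes(generate_proteome(100, seed=1, fixed_length=50))
        assert a == b

    def test_unique_accessions(self):
        records = generate_proteome(200, seed=2, fixed_length=40)
        assert len({r.id for r in records}) == 200

    def test_amino_acid_frequencies_within_three_sd(self):
        records = generate_proteome(100, seed=1, fixed_length=300)
        pooled = "".join(str(r.seq) for r in records)
        n = len(pooled)
        for aa, p in AA_FREQUENCIES.items():
            observed = pooled.count(aa) / n
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(observed - p) <= 3 * sd, f"{aa}: {observed} vs {p}"

    def test_wrapped_fasta_output(self, tmp_path):
        path = tmp_path / "db.fasta"
        write_fasta(generate_proteome(3, seed=9, fixed_length=150), path)
        lines = path.read_text().splitlines()
        assert max(len(ln) for ln in lines if not ln.startswith(">")) == 60


class TestGeneratePSMTables:
    def test_designed_absence_yields_zero_psms(self, small_experiment):
        design, tables, truth = small_experiment
        excluded = next(iter(design.exclusive_map))
        for r in (1, 2):
            assert all(p.accession != excluded for p in tables[f"B_r{r}"])
        assert truth.status(excluded, "A", "B") == "exclusive"

    def test_noise_free_tables_survive_filters_intact(self, small_proteome):
        design = SimDesign(n_proteins=20, conditions=("A",), noise_fraction=0.0, seed=13)
        tables, _ = generate_psm_tables(design, small_proteome)
        for rows in tables.values():
            assert filter_psms(rows) == rows

    def test_noise_psms_all_fail_a_filter(self, small_experiment):
        # every injected low-quality PSM must be caught: kept fraction
        # matches 1 - noise_fraction exactly because clean PSMs always pass
        design, tables, _ = small_experiment
        for rows in tables.values():
            kept = filter_psms(rows)
            n_noise = round(design.noise_fraction / (1 - design.noise_fraction) * len(kept))
            assert len(rows) - len(kept) == n_noise

    def test_unknown_accession_rejected(self, small_proteome):
        design = SimDesign(n_proteins=20, conditions=("A",),
                           fold_change_map={"NOPE": {"A": 2.0}}, seed=1)
        with pytest.raises(ValueError, match="NOPE"):
            generate_psm_tables(design, small_proteome)

    def test_deterministic_tables_and_truth(self, small_proteome):
        design = SimDesign(n_proteins=20, conditions=("A", "B"), seed=21)
        t1, truth1 = generate_psm_tables(design, small_proteome)
        t2, truth2 = generate_psm_tables(design, small_proteome)
        assert t1 == t2
        assert truth1.rates == truth2.rates and truth1.realized_spc == truth2.realized_spc

    def test_mean_spc_calibration(self):
        # fold change 1 everywhere at mean rate 20: the average per-protein
        # SpC per run should sit within 5% of the design mean
        design = SimDesign(
            n_proteins=1000, conditions=("A",),
            baseline_log_mean=log_mean_for_mean_rate(20.0, 0.8), seed=11,
            noise_fraction=0.0,
        )
        proteome = generate_proteome(1000, seed=11, fixed_length=50)
        tables, truth = generate_psm_tables(design, proteome)
        n_runs = len(tables)
        mean_spc = np.mean(
            [truth.realized_spc[acc]["A"] / n_runs for acc in truth.realized_spc]
        )
        assert mean_spc == pytest.approx(20.0, rel=0.05)

    def test_realized_counts_match_emitted_tables(self, small_experiment):
        design, tables, truth = small_experiment
        kept = {rid: filter_psms(rows) for rid, rows in tables.items()}
        for acc in truth.realized_spc:
            for cond in design.conditions:
                emitted = sum(
                    sum(1 for p in kept[f"{cond}_r{r}"] if p.accession == acc)
                    for r in (1, 2)
                )
                assert emitted == truth.realized_spc[acc][cond]


class TestDesignValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_proteins": 0},
        {"n_proteins": 5, "conditions": ()},
        {"n_proteins": 5, "conditions": ("A", "A")},
        {"n_proteins": 5, "n_replicates_per_condition": 0},
        {"n_proteins": 5, "noise_fraction": 1.0},
        {"n_proteins": 5, "fold_change_map": {"P": {"A": -1.0}}},
        {"n_proteins": 5, "fold_change_map": {"P": {"Z": 2.0}}},
        {"n_proteins": 5, "exclusive_map": {"P": frozenset({"Z"})}},
    ])
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimDesign(**kwargs)

    def test_spike_in_design_shape(self):
        design = spike_in_design(n_proteins=50, n_spiked=4, fold=4.0, spike_rate=40.0, seed=3)
        assert len(design.abundance_map) == 4
        assert all(per == {"A": 4.0} for per in design.fold_change_map.values())

    def test_truth_status_classification(self):
        from mapdiff.simulate import SyntheticTruth

        truth = SyntheticTruth(
            rates={"P": {"A": 8.0, "B": 2.0}, "Q": {"A": 0.0, "B": 5.0},
                   "R": {"A": 3.0, "B": 3.0}, "S": {"A": 0.0, "B": 0.0}},
            realized_spc={a: {"A": 0, "B": 0} for a in "PQRS"},
        )
        assert truth.status("P", "A", "B") == "up_in_X"
        assert truth.status("P", "B", "A") == "up_in_Y"
        assert truth.status("Q", "A", "B") == "exclusive"
        assert truth.status("R", "A", "B") == "unchanged"
        assert truth.status("S", "A", "B") == "absent"
        assert truth.changed_set("A", "B") == {"P", "Q"}
        assert truth.exclusive_set("A", "B") == {"Q"}
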