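"""Spike-in benchmark: call differential proteins with DAve/DCI.

Simulates 300 proteins in two conditions (duplicate runs each); 10 of them
are spiked 4-fold into condition A at a nominal 40 spectra per run.  The
pipeline averages replicate Scores per condition and calls a protein
up-represented when DAve = (X-Y)/((X+Y)*0.5) >= 0.4 AND
DCI = (X+Y)(X-Y)/2 >= 400 (mirrored for down).  The joint gate keeps
low-evidence proteins out even when their ratio is extreme.
"""

from mapdiff import (
    aggregate_proteins,
    average_replicates,
    compare_conditions,
    filter_psms,
    generate_proteome,
    generate_psm_tables,
    spike_in_design,
)

design = spike_in_design(n_proteins=300, n_spiked=10, fold=4.0, spike_rate=40.0, seed=7)
proteome = generate_proteome(300, seed=7, fixed_length=100)
tables, truth = generate_psm_tables(design, proteome)

profiles = {}
for cond in design.conditions:
    quants = [
        aggregate_proteins(filter_psms(tables[f"{cond}_r{r}"]), f"{cond}_r{r}", 10.0)
        for r in (1, 2)
    ]
    profiles[cond] = average_replicates(quants, cond)

records = compare_conditions(profiles["A"], profiles["B"])
called = [r for r in records if r.call != "unchanged"]
spiked = truth.changed_set("A", "B")

print(f"{len(records)} proteins compared, {len(called)} called differential")
tp = sum(1 for r in called if r.accession in spiked)
print(f"true spiked proteins recovered: {tp}/{len(spiked)}; "
      f"false calls: {len(called) - tp}")
print("\naccession     Score(A)  Score(B)   DAve     DCI    call")
for r in sorted(called, key=lambda r: -r.dci)[:6]:
    mark = "*" if r.accession in spiked else " "
    print(f"{mark}{r.accession}  {r.score_x:8.1f}  {r.score_y:8.1f}  {r.dave:+.2f}  {r.dci:7.0f}  {r.call}")
print("\n(*) = truly spiked. DAve ~ +1.2 is the 4-fold signature:")
print("2*(4-1)/(4+1) = 1.2; DCI grows with abundance, so well-measured")
print("proteins dominate the top of the list.")
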