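# Methods

## Scope and model

`mapdiff` implements threshold-based label-free differential analysis for
spectral-counting proteomics. It deliberately contains no probabilistic
test: the calling rule is a pair of deterministic statistics with fixed
thresholds, which is how this family of workflows operates in practice.
Everything upstream of the PSM table (acquisition, the spectrum-to-peptide
database search) and everything requiring external annotation services is
out of scope; functional grouping is taken from a user-supplied
accession → group table.

## The differential statistics

For a protein with replicate-averaged Scores X and Y in two conditions:

* `DAve = (X − Y) / ((X + Y) · 0.5)`. Scale-free (`DAve(cX, cY) = DAve(X, Y)`),
  antisymmetric, bounded in [−2, +2] with the bounds attained exactly iff
  one Score is 0. These printed formulas circulate in a typographically
  ambiguous form; the reading used here is fixed by the stated range
  [−2, +2] and by exclusive proteins sitting at exactly ±2 — the
  left-to-right reading `(X − Y)/(X + Y) · 0.5` would bound the statistic
  at ±0.5 and is therefore not what the range implies. Each run manifest
  records the reading in force.
* `DCI = (X + Y)(X − Y) / 2`. Same sign as DAve, scales as c² under joint
  rescaling, so at a fixed abundance ratio it grows with total evidence.
  The alternative literal reading `(X + Y)/(X − Y)/2` diverges as X → Y and
  cannot support a fixed ±400 working threshold, which again fixes the
  product form.

Calling is joint and sign-consistent: up in X iff `DAve ≥ dave_min` and
`DCI ≥ dci_min` (defaults 0.4 and 400), mirrored for down. Consequences
worth knowing:

* an exclusive protein (Y = 0, DAve = 2) is called only when
  `X ≥ sqrt(2 · dci_min)` ≈ 28.3 at defaults;
* at the DAve boundary the DCI condition reduces to
  `X + Y ≥ sqrt(dci_min / (dave_min/4))` ≈ 63.2, so DCI acts as a
  minimum-evidence gate for low-Score proteins and is inactive for
  well-measured ones.

Proteins with zero averaged Score in both conditions are excluded rather
than assigned DAve 0: the statistic is a ratio of observed evidence and is
undefined without any.

## Filtering and aggregation

PSMs are kept iff peptide probability ≤ 1e-3 (smaller is better for
SEQUEST-style probabilities) and Xcorr ≥ {1+: 1.5, 2+: 2.0, 3+: 2.5,
4+: 3.0}; both comparisons are inclusive, and charges above 4 use the 4+
threshold (clamping is the least-surprise rule for a table that stops at
quadruply charged ions). Per run, SpC is the number of kept PSMs per
accession and Score the sum of their per-PSM scores; the consensus filter
removes proteins with Score ≤ 10 (strict, per "higher than").

Replicate averaging imputes 0 for a protein absent from a replicate. The
alternative (averaging over present replicates only) would both inflate
single-replicate identifications and break the exclusivity semantics that
make |DAve| = 2 meaningful. A presence count is kept so callers can demand
identification in every technical replicate (`min_presence=2`); the default
includes single-replicate identifications with zero imputation, since
dropping them silently discards real exclusives.

Repeatability QC regresses one replicate's SpC on the other's (ordinary
least squares with intercept, union of accessions, absent → 0) and reports
slope and R². The pipeline computes QC on aggregates **without** the
consensus filter: the filter zeroes borderline proteins in one replicate
but not the other, which injects artificial discordance into a plot whose
purpose is to measure run-to-run repeatability of the measurement itself.

## Overlap between comparisons

Strict overlap counts proteins called differential in both lists, reported
over the first list's called set (and the reverse is available by swapping
arguments). Relaxed concordance takes every protein called in at least one
list and counts those whose DAve values carry the same nonzero sign in
both, crediting sub-threshold trends; a protein absent from one list
entirely cannot be concordant but stays in the denominator.

## Theoretical MW and pI

MW is the sum of average (isotope-weighted) residue masses plus one water
(18.0153 Da); average rather than monoisotopic masses because virtual 2D
maps mimic gel migration, which follows average mass. The residue table is
cross-checked in the test suite against an independent mass library.

pI is the root of the Henderson–Hasselbalch net-charge curve (basic groups:
N-terminus, K, R, H; acidic: C-terminus, D, E, C, Y) found by bisection on
[0, 14], stopping at |Q| < 1e-4. The pKa set is an EMBOSS-style table
pinned in `EMBOSS_PKA`; any published set would do, but reproducibility
requires pinning one, and the choice is configurable per call. Q is
strictly decreasing and changes sign inside (0, 14) (the termini alone
guarantee it), so the root exists and is unique. Note that for strongly
acid- or base-rich sequences the root can fall slightly outside the span of
the involved pKa values (several partially ionized acidic groups can
outweigh the single N-terminal charge below pH 3.6); the tests therefore
verify the root property itself rather than a pKa-interval heuristic.
Unknown residues (B, Z, X, U) follow a policy flag: `strict` (default,
error) or `skip-residue`.

## The synthetic-data generator

The generator emulates the study design the pipeline targets — several
conditions, duplicate technical runs each — with the following laws, chosen
once as defaults and documented here because no published values exist for
them:

* **Abundance**: per-protein Poisson rate λᵢ ~ lognormal with mean 40 SpC
  per run and log-sd 0.8. The mean matches a mid-abundance proteome slice;
  the spread is wide enough that between-protein variance dominates Poisson
  noise (giving replicate-scatter R² ≈ 0.9–0.95, the regime a competent
  MudPIT replicate pair shows) without burying most proteins below the
  consensus filter.
* **Counts**: SpC ~ Poisson(λᵢ · f_{i,c}); fold changes f multiply the
  rate, exclusive absences set it to 0. Over-dispersion is not modelled
  (see limitations).
* **Per-PSM score**: Gamma(shape 8, mean 0.6); protein Score is the sum
  over kept PSMs, hence roughly proportional to SpC. The scale is a
  benchmark design choice: it places protein Scores in the 10–10² range
  where the DCI = 400 threshold is an *active* abundance gate (combined
  Scores below ≈ 63 cannot be called), so simulations exercise both halves
  of the joint rule rather than reducing it to a DAve cut.
* **Spike-ins**: benchmark spike-ins are placed at a fixed nominal rate
  (40 SpC) rather than drawn from the abundance law — the standard design
  for defined-concentration spike-in experiments, and the only way the
  benchmark measures sensitivity at a stated abundance instead of at
  whatever abundances a particular seed happens to draw.
* **PSM quality**: charge ~ {1+: 5%, 2+: 60%, 3+: 30%, 4+: 5%} (a typical
  tryptic ESI distribution); accepted-quality PSMs draw Xcorr as the
  charge threshold plus Gamma(2, 0.5) and probability as 10^−U(3.05, 7), so
  they always pass the filters. Injected noise PSMs (default 10% of rows)
  fail the Xcorr threshold, the probability threshold, or both, and are
  drawn only from proteins present in that condition. Peptides are
  tryptic-length (7–25) substrings of the parent sequence; shared peptides
  across proteins are not generated.
* **Proteome**: i.i.d. residues at Swiss-Prot-like frequencies, lognormal
  lengths around 350 aa.

Because clean PSMs always pass and noise PSMs never do, filtering recovers
exactly the Poisson counts — which is what makes the generator's truth
tables exact. What the generator does **not** emulate: between-run
biological variance and batch effects, over-dispersed counts, shared
peptides / protein-inference ambiguity, saturation of spectral counts for
very abundant proteins, and any dependence of detectability on protein
length or hydrophobicity. Passing the synthetic benchmark therefore
demonstrates correct mechanics and calibrated behaviour under the stated
noise model, not performance on real biological replicates.

## Problem sizes and numerical choices

The shipped benchmark is 1000 proteins × 2 conditions × 2 runs (≈ 180k
PSM rows, a few seconds to generate and analyse), with 30 proteins spiked
4-fold; sensitivity and false-call fraction are measured against the truth
table at default thresholds. Examples use 200–300 proteins for instant
turnaround. Bisection for pI uses ≤ 200 iterations with a 1e-4 charge
tolerance (≈ 1e-3 pH accuracy, tested against a 0.001-step grid scan).
Filter boundaries are inclusive on both statistics; ties at the consensus
threshold are removed ("higher than 10"). All tabular outputs are
tab-separated text; the run manifest (YAML) records thresholds, formula
readings, per-stage row counts and SHA-256 checksums of the inputs, which
is sufficient to reproduce a run bit for bit.

## Known limitations

No FDR control or rescoring (threshold-based by design); no
length-normalised indices (NSAF) — Score averaging assumes comparable
acquisition depth between the runs being compared; protein inference is
taken as given by the upstream search; the MW/pI map ignores
post-translational modifications and uses one fixed pKa table.
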