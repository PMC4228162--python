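# Methods

This note documents the procedures implemented in `trflptools`, the
parameters that matter, the numerical choices made where the procedure
descriptions left room, and what the synthetic-data generator does and does
not emulate.

## Data model

A peak is a (size, height, area) triple: size in bases, height and area in
fluorescence units. Presence rows in the on-disk block layout are
authoritative — a value of 0 and a blank cell are equivalent to "absent",
and a presence of 1 with a blank size cell is a format error rather than a
guess. All sizes are kept at full precision internally; reported sizes are
rounded to two decimals with decimal-aware round-half-away-from-zero,
because binary round-half-to-even would print 166.565 as 166.56 and
disagree with the convention used in fragment-analysis reports. Every chain
step appends one JSON-lines record (timestamp, operation, parameter
snapshot, input and output identifiers) to a run history, so an analysis is
reconstructible after the fact.

## Preparation

Peaks survive when `height >= PDT` and `size_min <= size <= size_max`. The
threshold comparison is non-strict and the range is closed at both ends:
detection thresholds conventionally admit equality, and "50 to 1020 bases"
is read as a closed interval. Filtering judges height only (the parameter
is a *height* detection threshold); a surviving peak keeps its area.
Preparation is idempotent and monotone in PDT.

## Total-fluorescence normalization (TFN)

TF is the sum of a profile's heights (or areas); TF<sub>min</sub> is the
minimum over the profiles being normalized, computed once at entry. Each
profile with TF > TF<sub>min</sub> is multiplied by TF<sub>min</sub>/TF —
heights and areas by the same factor, so the two signals stay proportional
— after which peaks whose chosen signal falls below the minimum allowed
value are removed and the iteration repeats on the remainder. The minimum
allowed value is the detection threshold for height-based TFN, and the
minimum observed peak area for area-based TFN (dataset-wide, or within the
replicate group for the local-threshold variant; in both cases the
replicate-wise entry points normalize each group to its own
TF<sub>min</sub>, while the whole-dataset entry point uses the global one).

Termination: the loop stops when |TF − TF<sub>min</sub>| ≤ 10⁻⁶ ·
TF<sub>min</sub> or when TF ≤ TF<sub>min</sub>. A profile that undershoots
after a removal is never scaled back up — only profiles with TF *above*
TF<sub>min</sub> are multiplied — which makes the per-profile TF sequence
monotone non-increasing and guarantees termination. A consequence is that a
period-2 cycle around TF<sub>min</sub> (a peak hopping in and out at the
threshold) cannot arise under these semantics; the resolution rule for such
a cycle — the per-peak arithmetic mean of the two states, with a peak
present in only one state contributing half its value and kept — is
nevertheless implemented as a separate, directly tested state-averaging
step, so the behaviour is defined if the termination rule is ever relaxed.

## Fixed percentage threshold (FPT)

Relative abundances are computed once on the input profile; peaks strictly
below the threshold fraction are removed and survivors keep their raw
values (conversion to relative abundance is a deliberate later step, so FPT
composes with any downstream normalization). The threshold is a fraction:
0.01 means 1 % of total signal. A peak exactly at the threshold is kept.
Because removals only increase the survivors' shares, FPT is idempotent.

## Moving-average alignment

Parameters: Y, the seed range, and Z, the mean-extension range, both in
bases (defaults 1 and 0.5). Binning is greedy from short to long: the
globally shortest unassigned fragment seeds a bin; every unassigned
fragment strictly less than Y bases longer than the seed joins, at most one
per profile with the shortest winning; then any unassigned fragment from an
unrepresented profile strictly less than Z bases longer than the bin's mean
is added — one at a time in ascending size order, the mean recomputed after
each addition, members never expelled — until nothing qualifies. Both
comparisons are strict; the strict and non-strict readings coincide on all
published worked examples. Output bins partition the input (every fragment
in exactly one bin, at most one per profile per bin) and the procedure is
deterministic, with ties broken by profile order.

**Ambiguity correction.** The greedy pass can pair a fragment with the
wrong neighbour when it lies between two near-coincident fragments of other
profiles. A fragment is flagged when it is strictly within Y of both a
shorter and a longer fragment of other profiles; each flagged fragment is
re-assigned to the bin holding its nearest neighbour by absolute size
difference, unless its profile is already represented there (including when
that bin is its current one). Correction is single-pass — flags are
computed on the input alignment — which reproduces both published worked
examples; fragment counts are preserved, only assignments change. Emptied
bins are dropped and bins re-ordered by mean size.

**Bin checking.** For consensus alignments no automatic correction is
applied (that judgement is left to the analyst); instead each bin gets
count/min/max/mean statistics and an ambiguity flag: a pair of adjacent
bins is flagged — both bins — when the next bin's shortest fragment is
strictly less than Y bases longer than the current bin's longest. Flagged
bins may still be correct; the flag marks where a pairwise or subset
analysis could bin differently.

## Systematic size-calling shifts

For each profile pair in scope (replicate pairs, or all pairs for
consensus profiles), the size differences over bins where both are present
are examined — ambiguous bins excluded on request. A systematic shift is
declared only when *all* differences share one sign; a single tie or mixed
sign yields "no shift". One shared bin suffices for a declaration (the
minimum is not specified by the procedure's rule; this is the literal
reading). The direction matrix is antisymmetric with zero diagonal.

**Reference re-sizing.** Every bin containing a fragment from all profiles
is tested as a reference: per profile, each fragment's relative size is its
size minus that profile's size in the candidate bin, and the candidate's
score is the sum over bins of the sample standard deviation (n−1
denominator) of relative sizes, single-member bins contributing 0. The
lowest score wins; scores within a 10⁻⁹ relative tolerance are treated as
tied (exact float equality would make the mathematically tied case
order-dependent) and the tie breaks to the smallest mean size for
determinism. New sizes anchor the reference at the mean of its original
sizes, so a constant per-profile offset is absorbed exactly. Re-alignment
of the new sizes uses size data only; each fragment keeps its original size
as its identity, and the comparison between original and re-aligned binning
counts fragments whose set of co-binned companions changed — bins are
matched by member sets, not positions, so insertions or deletions of bins
do not desynchronize the comparison. Applying any correction to the
original alignment remains a manual decision; the package reports the
comparison.

## Consensus profiles

Per sample and bin, a consensus fragment is emitted when the bin holds
fragments from at least X of the sample's replicates (1 ≤ X ≤ replicate
count). Its size is the mean of the member sizes; height and area are the
mean or the sum over the replicates *in which it is present* — not
zero-filled over all replicates, since with X below the replicate count an
absent observation is missing data, not an observed zero. With X = 1 and
the sum rule, total signal is conserved. Consensus profiles take the sample
name (the `<sample>.<replicate>` suffix stripped where that convention is
used).

## Community metrics

Relative abundance divides each fragment's height (or area) by the
profile's total. Bray-Curtis evaluates Σ|x_i−y_i| / Σ(x_i+y_i) literally —
the denominator is not assumed to be 2, so un-normalized inputs are
handled. Jaccard counts occupied bins: shared over union. Shannon is
−Σ x_i log₁₀ x_i over positive abundances; the base-10 logarithm is a
deliberate convention and values differ from natural-log implementations by
the factor ln 10. Shannon values depend strongly on the detection
threshold, normalization and consensus rule applied upstream, so they are
comparable only within one identically treated dataset.

## Synthetic data

The generator draws, per profile, each true fragment's observed size as
`true size + N(0, jitter_sd) + profile offset` and its height as
`mean height × lognormal(0, σ)` (σ = 0.5 by default), applies per-fragment
dropout, and adds uniform noise peaks below the usual detection threshold
(heights 10–49). Areas are `height × (2 + 0.06 × size)` — a width factor
growing linearly with size, emulating peak broadening at long migration
times; the coefficients are a fixture choice. The default design
(`example_spec`) is duplicate loadings with ~30 fragments spaced ≥ 3 bases
over 50–1020 bases, jitter SD 0.1 bases and median height ~500 units,
matching the scale of real duplicate fingerprint datasets analysed with
Y = 1, Z = 0.5 and PDT 50. One RNG stream per call; the same seed gives
byte-identical output. If adjacent true fragments lie closer than four
jitter SDs the generator warns that bins may merge.

Not emulated: electrophoresis physics, size-calling nonlinearity (offsets
are constant per profile, while real size-calling error can drift with
fragment length), overlapping-peak area distortion, and between-run
baseline differences. Tests passing on synthetic data therefore demonstrate
algorithmic correctness under the stated noise model, not robustness to
every artefact of real capillary data.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run on the published worked
examples (2–6 profiles), the six-profile example peak table, and synthetic
datasets of 4–16 profiles with 8–30 fragments — sizes at which every
procedure's expected outcome can be verified by hand or by construction.
One end-to-end check targets the 76-profile activated-sludge reference
dataset; that dataset is not redistributable with the package, and the
check documents the path where a local copy should be placed.

## Known limitations

* Alignment is greedy and order-dependent by design (it reproduces the
  established moving-average procedure, including its known failure mode,
  which the correction step addresses); it is not a globally optimal
  clustering.
* Ambiguity correction is single-pass; a move never triggers re-evaluation
  of other fragments' flags.
* TFN assumes at least one peak per profile and positive totals; profiles
  emptied by aggressive thresholds raise errors rather than propagating
  silently.
* The shift test's "all differences share a sign" rule is sensitive to a
  single discordant bin and declares shifts from as little as one shared
  bin; with few shared bins it is a weak signal and the per-pair report
  should be inspected.
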