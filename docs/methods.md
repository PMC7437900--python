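# Methods

## Model and scope

`barcodepci` evaluates distance-based species identification on an
*already aligned* barcode reference library. It consumes a multiple
sequence alignment (FASTA) plus a sample metadata table, or
alternatively a precomputed square distance matrix; it does not perform
alignment, fetch repository records, or build phylogenies. The
identification model is deliberately the simplest one in field use:
each query returns the set of its nearest neighbors under p-distance,
interpreted as a list of equally likely species; identification is
*unanimous* when every neighbor carries the query's species label.

## p-distance and exact tie handling

The p-distance between two aligned sequences is the fraction of
comparable columns that mismatch, where a column is comparable only if
both sequences show an unambiguous nucleotide (A, C, G or T). Gaps and
every IUPAC ambiguity code are excluded from numerator and denominator
alike — no partial-match scoring. A pair with zero comparable columns
has no defined distance; the package raises a named error identifying
the pair rather than imputing a value, because a silently imputed
distance could enter and corrupt nearest-neighbor sets.

Distances are stored as integer pairs (mismatches, comparable sites)
and every comparison — nearest-neighbor minimization, tie detection,
the barcode-gap inequality — is performed on exact rationals by integer
cross-multiplication. Ties at the minimum distance are common (replicate
sequences are retained on purpose) and define the conspecific fraction
*f*σ, so detecting them by floating-point equality would be fragile:
1/3 and 2/6 must tie exactly. Floats appear only in output tables,
written with 12 significant digits so they round-trip.

Distance matrices re-read from TSV reconstruct exact rationals from the
decimal strings; equal printed values therefore still tie exactly,
though per-pair comparable-site counts are not recoverable from a plain
matrix.

## The four PCIs

Per species (≥ 2 samples), leave-one-out: each sample is queried
against the full dataset minus itself, singletons of other species
included as decoys. `p_F,s` is the mean conspecific fraction, `p_A,s`
the mean unanimity indicator, `p_U,s` their minimum, and `p_B,s` the
strict barcode-gap indicator (max intraspecies distance < min
interspecies distance; equality means no gap). The ordering
`0 ≤ p_B,s ≤ p_U,s ≤ p_A,s ≤ p_F,s ≤ 1` is a theorem and is enforced as
a runtime invariant of the result type as well as a property test.

One boundary case is not covered by the definitions: a (sub)dataset
containing samples of only one species has no interspecies distance,
so the gap inequality compares against a minimum over an empty set. We
take that minimum as +∞, i.e. the gap holds vacuously and `p_B,s` = 1.
This keeps the PCI ordering intact (all four PCIs are then 1, since
every neighbor is conspecific) and lets resampling operate on
single-species subsets instead of discarding them.

Dataset-level PCIs are *unweighted* means over non-singleton species —
taxonomic normalization, so that a species with 20 samples counts no
more than one with 2. Singletons are excluded from the averages and
reported as two separate counts: all singletons, and singletons whose
sequence is unique in the dataset (those are unidentifiable by nearest
neighbors regardless of pipeline quality). Standard errors use the
unbiased sample variance, `sqrt(Σ(p_i − p̄)²/(N−1))/√N`, applied
uniformly — including to the binary-valued `p_B`/`p_U` species scores,
with no binomial shortcut. With a single non-singleton species the SEM
is reported as 0 by convention.

## Taxonomic unanimity test

Given a partition of the samples into two groups (e.g. expert-annotated
vs not), each non-singleton species contributes a 2×2 table: A/C
in-group unanimous/non-unanimous, B/D out-group. Under the null that
unanimity is independent of group, conditioned on all margins, A is
hypergeometric with mean `E_s = (A+C)(A+B)/N` and variance
`σ_s² = (A+C)(B+D)(A+B)(C+D)/(N²(N−1))`. The statistic
`X = Σ_s (A_s − E_s)` is approximately normal with variance
`σ² = Σ_s σ_s²` (species treated as independent), giving an upper-tail
one-sided p for "group 1 is more unanimous". Unanimity is always
computed on the *combined* dataset — both groups together supply the
neighbors. Species with any zero margin have `σ_s² = 0` and contribute
nothing to X or σ², but their tables are retained in the output for
scrutiny (they are exactly where a curator looks for suspect records).
If every table is degenerate the test raises rather than emitting a
0/0.

Because the margins fix `E_s` and the `A_s` are integers, X moves on a
unit lattice; a continuity correction of `0.5/σ` is therefore applied
toward zero (never past it) and the corrected Z is reported in the
"uncorrected minus correction" form, alongside both p-values. The
correction formula is an interpretation — the convention is documented
here precisely because reasonable alternatives exist — and the
uncorrected Z is always available. Under label permutation the
uncorrected Z is the statistic with mean 0 and unit variance; the
calibration test checks both that and the nominal 5% rejection rate of
the uncorrected p.

No multiple-testing correction is applied by default; a Bonferroni
helper is provided for the per-species Fisher p-values.

## Pipeline comparisons

Two pipelines scored on the same species set are compared pairwise on
any one of the four species PCIs. Zero differences are dropped and
their count reported — the number of species where the pipelines
actually disagree is itself informative. The Wilcoxon signed-rank test
uses an exact null distribution for up to 25 nonzero differences,
computed by convolution over doubled midranks (which handles tied
magnitudes, unlike the common exact implementations); above 25 it
defers to the normal approximation with tie correction
(`scipy.stats.wilcoxon`). The sign test is the exact binomial test on
sign counts; it discards magnitudes entirely and is therefore immune to
sampling biases that distort them. With no nonzero differences both
report p = 1 and flag the degeneracy.

## Resampling

For each target size, samples are drawn uniformly without replacement;
the four dataset-level PCIs are recomputed over species that remain
non-singleton *in the resample*, with neighbors drawn only within the
resample, and distances sliced from the precomputed matrix (no
realignment — alignment reuse does not materially change
identifications). A replicate with no non-singleton species is redrawn,
with the redraw count reported. The default is 1000 replicates per
size; results carry the seed. Sample SDs of identical replicate values
are forced to exactly 0 (at the full dataset size every draw is the
whole dataset, and `np.std`'s rounding must not blur that).

## Synthetic data

The generator emulates the structure of a curated fungal ITS reference
set: several species with a configurable range of samples each (the
default range 1–6 produces natural singletons), exact replicate
sequences, ambiguity codes and gap characters injected at configurable
rates, and a misannotation rate that relabels samples to another
species. Sequences evolve by per-site substitution from a common
ancestor: centroids mutate at `inter_divergence/2` per lineage and
samples at `intra_divergence/2` from their centroid, so expected
pairwise divergences approximate the configured targets (coincident
substitutions make attained values slightly smaller; defaults of 0.02
within and 0.25 between species reflect typical congeneric ITS
variation). A rejection step prevents *accidental* identical sequences
across species — cross-species duplicates appear only via the explicit
misannotation knob, keeping expected PCIs controllable. The generator
is seed-deterministic to the byte.

What it does not model: indel dynamics, rate heterogeneity along the
sequence, alignment error, chimeras, or intragenomic ITS variation.
Passing tests on generated data therefore demonstrate the correctness
of the *scoring machinery*, not that any particular real library has
high PCIs.

The deterministic misannotation fixture is the minimal alignment (9
samples × 10 columns) realizing the neighbor topology of the worked
example: any alignment with the same distance structure yields
identical PCIs. An independent oracle (`oracle_species_pci`) recomputes
species PCIs by naive exhaustive enumeration in pure Python, sharing no
code with the production path, and must agree exactly — rational
arithmetic on both sides makes "exactly" meaningful.

## Problem sizes and numerical choices

The test suite exercises ~600 generated datasets of 2–7 species × 1–6
samples and sequence lengths 30–200, a 71-species dataset for the
1/n perturbation bound, a 45-species dataset (~230 samples, ≥ 20
informative species) with 2000 label permutations for the unanimity
calibration, and resampling at up to a few hundred samples — sizes
chosen so the whole suite completes in well under a minute while every
check is still at full strength (the oracle comparisons and inequality
checks are exact, not approximate, so scale adds nothing to them).
Distance matrices are built with one-hot integer matrix products;
counts are far below 2⁵³ so float matmuls remain exact before the cast
back to integers.

## Known limitations

- PCIs are only computed at species rank; genus- or family-level
  generalizations are straightforward but not implemented.
- The unanimity test's normality is asymptotic in the number of
  informative species; with a handful of tables the continuity-corrected
  p is a rough guide and the per-species Fisher tests are preferable.
- Replicate sequences must already be present in the input alignment;
  the package does not re-expand deduplicated alignments.
- Model-based distances (K2P, etc.) are out of scope; identifications
  are rarely sensitive to the choice.
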