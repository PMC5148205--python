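# Methods

This note records the models and procedures implemented in prophagekit, the
parameters that matter, the design choices that were genuinely open, and what
the synthetic data generator does and does not emulate.

## Coordinates and sequence conventions

All user-facing coordinates are 1-based inclusive, the GenBank convention, so
positions printed by the package can be compared directly with annotation and
with published tables. BED export converts to 0-based half-open. Sequences are
uppercase DNA over {A, C, G, T, N}; `N` is accepted on input but never
participates in repeat matches or motif hits — an ambiguous base is treated as
matching nothing, which can only split or shorten reported repeats, never
fabricate one.

## Attachment-site discovery

An integrated P4-like element is delimited by two same-strand copies of an
exact core (attL and attR). The search is anchored: one window around the
anchor gene's 3′ end (by default from the anchor's start to the integrase
gene's start) and one window downstream. `find_direct_repeats` indexes all
k-mers of the left window with k = `min_core_len` and extends each seed match
maximally in both directions; matches are restricted to, and maximal within,
the windows. The output is every maximal exact match of length ≥
`min_core_len` with one copy per window, ordered by (core length descending,
attL start, attR start); `locate_prophage` takes the first candidate whose
attL overlaps or abuts the anchor and whose span is within `max_span`.

Defaults: `min_core_len = 15`, flank alignment width `w = 30`,
`max_span = 100 kb`. A genuine tmRNA-anchored core is typically ~20–30 nt and
the elements tens of kb, so the defaults contain the real case with margin
while a 15 nt exact repeat between two specific windows is rare enough
(~4⁻¹⁵ per position pair) to keep noise near zero. Inverted repeats are
deliberately ignored: integration by a tyrosine recombinase produces direct
copies.

Equivalence with a brute-force oracle (diagonal enumeration of all maximal
match runs) is asserted in the test suite over hundreds of random instances,
including low-entropy alphabets and embedded `N`s.

## Excision model

With the AttSitePair invariant (the two copies are exactly equal), every
crossover point inside the core yields the same products, so the crossover
policy (`keep_attL_copy`, `keep_attR_copy`, `midpoint_crossover`, default
midpoint) only labels which copy is notionally written at the junction;
`unique_outcome` is reported accordingly. The excised chromosome is
`seq[..attL) + core + (attR..]`; the circle is the removed interval closed
with the complementary core copy, serialised with its origin at the attP core
start so outputs are byte-stable. `integrate` is the exact inverse and is used
for round-trip testing.

The mutational consequence on the anchor gene is computed by global pairwise
alignment (Biopython `PairwiseAligner`) of the original gene against the
post-excision window starting at the gene's original start and extending 10 nt
past its original end. Gap opening costs more than a mismatch (−6 vs −3,
match +2) so a single indel is only reported when it genuinely shortens the
edit script, and end gaps on the post-excision window are free so edits
outside the gene are not reported. Indels are right-normalised within
homopolymer runs: deleting any T of a TT run is the same molecule, and the 3′
position is reported, matching how terminal tmRNA deletions are conventionally
given. On genes much shorter than ~20 nt a terminal deletion followed by
coincidentally matching context can be reported as a substitution — an
inherent ambiguity of minimal edit scripts, not an implementation artifact.

## Acceptor-stem check

No structure prediction is attempted. The stem layout — an ordered list of
(i, j) pairing positions within the gene — is an input, because the biological
claim ("the variant lacks the terminal G·U wobble pair") is about a *fixed*
layout re-evaluated on the variant sequence. `check_stem` classifies each pair
as Watson–Crick, wobble (G·U/U·G, both included by default), or unpaired; a
variant shorter than the layout is flagged truncated with the out-of-range
pairs unpaired. `compare_stem` never re-annotates the variant: a deletion
upstream of the 3′ arm shifts every downstream base under the layout, which is
exactly the mechanism by which a single-nucleotide deletion breaks the stem.
The acceptor-stem coordinates of a real gene must come from external
annotation; the synthetic generator emits its own layout in the truth record.

## Excision-frequency estimation

**qPCR.** Calibration points (known prophage-free fraction f, ΔCq =
Cq_junction − Cq_reference) are fitted by ordinary least squares as
ΔCq = m·log₁₀f + b; amplification efficiency E = 10^(−1/m). The fit requires
≥ 3 distinct fractions spanning ≥ 2 decades. Replicate Cq values are averaged
*before* inversion (standard calibration practice, and it makes results
deterministic in the replicate order); sample fractions
f = 10^((ΔCq−b)/m) are clamped to [0, 1] with an explicit flag rather than
silently, since Cq noise can invert above 1. The efficiency default is 2
(perfect doubling, slope −log₂10 ≈ −3.3219) and is configurable.

**Junction reads.** A read counts for a junction iff it contains, exactly and
on either strand, that junction's discriminating window — the shared core ±
`min_overhang` (default 10) nt of flank. Reads matching both windows count for
neither. Matching is exact by design: the package's scope is synthetic and
high-identity data, and embedding a mismatch-tolerant aligner would change the
estimator's error model. The frequency k_attB/(k_attB+k_attL) carries a Wilson
95% interval, which unlike the Wald interval remains calibrated at the
10⁻⁶–10⁻² fractions of interest.

Fold changes between conditions are plain ratios, with a zero baseline
reported as infinite with a flag. Relative expression uses the
efficiency-corrected ΔΔCq form E^(−ΔΔCq).

## Population variant calling

For each non-reference allele (single-base substitutions and single-base
deletions) with count k at depth n, the p-value is the one-sided binomial tail
P(X ≥ k | n, ε); Benjamini–Hochberg correction is applied across **all tested
alleles genome-wide** (standard FDR semantics — per-site families would be
anti-conservative at genome scale). Calls require adjusted p < α, frequency ≥
`min_freq`, and depth ≥ `min_depth`. Defaults ε = 0.001, min_freq = 0.01,
min_depth = 100, α = 0.05: the error rate is a typical post-filter Illumina
substitution rate, and the frequency floor matches the 1–24% window in which
population mutations were reported. Effects are classified by in-frame codon
translation on the coding strand (CDS), any change in an RNA feature is
`rna_gene`, and a CDS whose length is not a multiple of 3 is refused rather
than guessed. A single-base deletion in a CDS is a frameshift and is counted
as nonsynonymous. The classifier is tested against an oracle that translates
the entire mutated CDS.

The packaged survey (`data/cold_shift_mutations.tsv`) transcribes the
published whole-genome deep-sequencing mutation table for cold-grown
*S. oneidensis* (10 mutations at population frequencies 0.01–0.24); effects
are derived at load time from the reported residue changes, not stored. Its
gene-relative DNA positions and absolute genome positions are carried verbatim
and not reconciled, which would require the annotated genome.

## Motif scan

Exact scanning only (no PWM): the reported H-NS site 5′-GATAATG-3′ is a fixed
word, overlaps allowed, `N` never matches. The default promoter window is
300 nt upstream of the annotated start codon on the coding strand — published
analyses of this motif state its 5′→3′ polarity but no window, so the window
is this package's convention and is configurable; hit counts on real promoters
should be read as exploratory.

## Synthetic data generator

The generator emulates the study's experimental designs so every stage runs
without downloads:

* **Genome.** 50 kb i.i.d. background carrying a 362 nt anchor tmRNA gene
  whose 3′ region contains the attL copy of a 26 nt core; the element (default
  5 kb span, configurable to the real 36 kb with 30 interior CDS) ends in the
  attR copy. The attL copy's tail carries one extra T immediately after the
  core (gene position 349 by default) that the attR copy lacks, so excision
  deletes exactly that base — the geometry of the motivating locus, scaled
  down. A 7-pair acceptor stem is written into the gene with the outermost
  pair G·U. Backgrounds are resampled until the planted core is the unique
  ≥ 15 nt repeat between the search windows, and divergence is forced at both
  repeat boundaries so the planted core *is* the maximal match; the truth
  record stores the maximal-repeat coordinates.
* **Reads.** Single-end, uniform start, either strand; each read comes from
  the excised genome with probability p (default 0.03, the cold-condition
  excision fraction) and carries i.i.d. base errors (default 10⁻³). No
  paired ends, quality models, or coverage bias.
* **qPCR.** Cq_junction = Cq₀ − log_E(fraction) + N(0, sd), reference Cq₀ +
  noise; mixing series 1/10 … 1/10⁶, E = 2, sd = 0.1 cycles, 3 replicates.
* **Pileups.** Depth ~ Poisson(mean), planted alt ~ Binomial(depth, f), errors
  spread uniformly over non-reference bases. `survey_mutation_panel` plants a
  panel with the published frequencies and effect classes (verified by
  translation at planting time).
* **Colony screen.** Binomial(n, p) draws, default (200, 0.01).

Randomness: one stream per generator, derived from (master seed, fixed label)
via `SeedSequence`, so adding a generator never perturbs another and all
outputs are byte-reproducible under a fixed seed.

What passing tests on synthetic data do **not** show: robustness to alignment
artifacts, strand bias, indel-rich repeats, or degraded base quality — real
pileups and reads carry structure the i.i.d. generator deliberately omits.

## Numerical and testing choices

* Demonstrations that call the planted survey panel use a detection threshold
  of 0.005 — half the smallest planted frequency — the usual power-margin
  choice when the expected range is known; the caller's *default* stays 0.01.
* Single-replicate checks that a 95% interval covers the truth are statistical
  coin flips by construction; end-to-end tests therefore assert recovery
  within 4 binomial standard deviations, and interval *coverage* is asserted
  where it belongs, over 1,000 replicates (93–97% band).
* Problem sizes in the test suite and acceptance script (genomes 12–100 kb,
  10⁵ error sites at depth 500, 10³–1.5×10⁶ reads, 10⁵ colony-screen
  replicates) are chosen so every brute-force oracle remains exact and the
  whole suite runs in well under a minute on one CPU.
* Checks that depend on the real MR-1 accession are realised on the generator
  configured to the published geometry (26 nt core, 36 kb span, 30 interior
  genes, deletion at 349); the same functions accept a user-supplied GenBank
  file for the real chromosome.

## Known limitations

* One replicon per run; no multi-contig assemblies.
* Direct repeats only; elements integrated by serine recombinases with
  inverted sites are out of scope.
* Exact-match read counting understates frequencies when per-base error is
  high (a read with any error in the 46 nt window is dropped — symmetric
  between junctions, so the ratio stays unbiased, but the informative count
  shrinks).
* The variant caller models substitutions and single-base deletions only, with
  no strand-bias or mapping-quality terms.
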