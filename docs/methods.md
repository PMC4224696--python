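# Methods

## Coordinate conventions

Mutations are 1-based with `pos` the first affected base, matching how
positions are printed in the literature (chr5:1,295,228). All BED-derived
intervals are 0-based half-open; conversions happen only inside query
helpers, and a property test pins the convention: interval (s, e)
contains exactly the 1-based positions s+1..e. Deletions are anchored at
the first deleted base, insertions at the base after which the sequence
is inserted; VCF-style anchored alleles are trimmed to this minimal form
on input. Chromosome names gain a `chr` prefix when missing and are
never stripped, since ENCODE / Epigenome Atlas peak files use `chr`.

## Chromatin context

DHS membership is plain interval intersection (any affected base counts
for deletions; the anchor base for insertions; book-ended ties resolve
to the smallest start). Histone marks are sought in the flanking annulus
150–500 bp either side of an anchor: the DHS peak center (floor midpoint
for odd lengths — a deterministic tie-break) when the mutation is in a
DHS, else the mutation position. "Within ±150–500 bp of a peak" is
implemented as peak-interval-overlaps-annulus with any ≥ 1 bp overlap
counting, not peak-center-in-annulus: broad-peak calls are routinely
wider than the 351 bp windows, and center-based matching would miss
obviously flanking peaks. A peak lying entirely inside the ±150 core
does not count — it is not *flanking*. The 150/500 bounds are
configuration keys (`flank_inner`, `flank_outer`); a degenerate annulus
(inner ≥ outer) is treated as empty and always yields a false flag.

## Motif scanning

Scores are log-likelihood ratios in bits against a uniform ¼ background
with no pseudocounts: a zero-frequency base gives −∞ and the placement
simply cannot qualify, with no epsilon smoothing. Bases outside
{A, C, G, T} likewise force −∞ for any covering placement —
conservative and deterministic. The hit criterion is conjunctive:
score > 5 bits (the classic PSSM-search default) and an exact match at
every matrix position where one base exceeds 80% frequency (both
thresholds configurable; both comparisons strict). The order of the two
checks is immaterial.

Both strands are scanned, the minus strand via the reverse complement of
the covered window; detecting ETS sites on minus-strand genes requires
it. Reported TF sets are strand-agnostic and name-deduplicated, so
duplicate matrix versions collapse to one name.

For indels the wild-type and mutant windows differ in length and are
scanned independently; differencing at TF-name level (created =
mutant-specific, removed = wild-type-specific) absorbs the coordinate
shift. For substitutions this implies a useful invariant, which is
property-tested: a TF whose placements never cover the mutated base
appears in neither set.

The database filter keeps motifs whose taxon tag is in
{mammals, vertebrates} and whose site count (maximum column sum of the
count matrix) is strictly greater than 20.

One note on monotonicity: raising the score cutoff can only shrink the
reported TF set, but raising the conserved-position threshold *weakens*
the stringency filter (fewer positions exceed it, so fewer exact-match
constraints apply). The filter is disabled entirely at threshold 1.0,
which is what the strict-shrinkage checks compare against.

## Gene assignment

Enhancer–TSS associations take priority: a mutation inside an associated
enhancer maps to the associated gene, and to every such gene when
several enhancers overlap it (the output table is keyed by
mutation–gene pairs). Otherwise the nearest TSS on the same chromosome
within 1 Mbp wins — the printed proximity rule is used directly rather
than a full basal-plus-extension regulatory-domain model, whose server
internals are not reproducible offline. Equidistant TSSs tie-break
lexicographically by symbol (the upstream convention is unstated; this
is the package's deterministic choice). Distances are signed in the
gene's orientation, measured from the mutation anchor base; this
convention reproduces the published TERT distances (−66/−88 with the
TSS derived from one pair). Promoter/enhancer transcript predictions are
extended ±500 bp before point-overlap testing, because the predictions
locate transcripts, not the elements themselves.

## Conservation

Substitutions report the track score at the mutated base, multi-base
substitutions and deletions the mean over affected bases, insertions
nothing. The background value is the mean over covered bases within
±20 bp (mutated base included — whether to include it is unstated; the
1/41 weight is immaterial in practice). Track gaps are excluded from
means, never zero-filled, since zero-filling would bias conservation
downward in sparsely covered regions.

## Differential expression

With a single mutant sample per DHS (the typical case), a two-group
test is undefined; the per-sample reading is a one-sample t-test of the
non-mutant expression values against the mutant value as hypothesized
mean: t = (mean(non) − mutant)/(sd(non)/√n), df = n − 1, two-sided.
Fold change is the mutant value over the non-mutant median. Flagged
normal samples join the non-mutant side (they carry no mutations by
construction). Degenerate cases: zero non-mutant variance gives p = 1
when the mutant equals the common value and p = 0 otherwise, with a
degeneracy flag; fewer than 3 non-mutant values give no p. Bonferroni
correction multiplies by the number of DHS-associated (mutation, gene)
records in the run, capped at 1; records sharing a DHS are corrected as
separate tests. The correction implemented is the family-wise one, as
stated procedurally in the source description of the method, and the
output column is named `adj_p_value`.

## Bootstrap enrichment

Replicates sample without replacement from a finite mutation catalogue,
so replicate overlap counts are hypergeometric; the calibration tests
compare the empirical mean and sd with k·p and
√(k·p·(1−p)·(N−k)/(N−1)) at 3 standard errors. Significance of the
observed overlap is a two-sided one-sample t-test of the replicates
against it; an empirical rank p (add-one corrected) is emitted alongside
because the t-test's normality assumption is poor in the extreme tails.
A fixed seed yields a bit-identical replicate vector.

## Synthetic cohort

The generator emulates the demonstration cohort: 17 tumour samples plus
3 normals, a 100 kb single-chromosome genome, an expression shift of
8 non-mutant standard deviations for planted true positives (large
enough that the analytic one-sample-t power is ≈ 1, so planted-truth
recovery is deterministic), conservation 0.95 at planted functional
bases and 0.30 at the conservation-negative control. Planted sites
embed an 8-bp fully conserved ETS-like consensus with one broken base
(creation) or intact (removal); flanks are re-drawn until neither window
carries an unintended consensus on either strand, so the motif ground
truth is exact. The motif library also carries a partially conserved, a
uniform, a non-mammalian and an under-sampled matrix to exercise the
database filter. The generator does not emulate mutational signatures,
realistic peak-width distributions, read-count noise or linked
mutations — passing tests validate the pipeline's logic, not
performance on real tumour genomes.

Problem sizes in the test-suite and acceptance runs (100 kb genome,
33-mutation cohort, 10,000-mutation bootstrap universe, 1,000 replicates
or simulation draws) were chosen as the smallest scales at which every
statistical check has negligible Monte-Carlo error.

## Known limitations

* Motif scanning is exhaustive per window (fine for ±20 bp windows; not
  intended for genome-wide scans).
* The conservation track is held as a per-base map, suitable for
  kilobase–megabase tracks, not whole-genome bigWigs.
* "Non-coding" status is delegated to a user-supplied coding-region
  mask; without one, all mutations are processed.
* No signal-level (read pileup) chromatin analysis; peak calls only.
* TF expression is not consulted when reporting created/removed motifs.
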