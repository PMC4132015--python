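# Methods

This note records the models, conventions and design choices behind
`spinqc`, in the order the pipeline runs.

## Read preparation

Reads are modelled as (id-stem, sequence, Phred+33 qualities, mate).
Only offset-33 FASTQ is supported; offset-64 encodings predate the
platforms this pipeline targets and are out of scope.

**Quality trimming** removes the *maximal 3′ suffix in which every base
is below* `min_q` (default Q35). This is deliberately not a
sliding-window or per-base filter: internal low-quality bases are kept,
matching a rule phrased as trimming "bases of the 3′ ends". The
operation is idempotent — after one pass the terminal base is at or
above the threshold.

**Poly-A/T trimming** removes a terminal homopolymer run of A or of T
whose length strictly exceeds `max_homopolymer` (default 10; a run of
exactly 10 stays). Both ends are handled, symmetrically for A and T —
without strand information a 5′ T-run and a 3′ A-run are equally likely
to be tail artefacts. Runs must be exact homopolymers (no mismatches).
Stripping repeats to a fixpoint so that removing one run cannot leave
another over-long run exposed; this makes the operation idempotent,
which a strict single pass per end would not be. Note the *composition*
quality-trim → poly-A-trim is still not idempotent in general (removing
an A-tail can expose low-quality bases), which is why the pipeline fixes
the order — quality first, then poly-A — and the tests assert
idempotence per operation, not for the composition.

Reads emptied by trimming are dropped (`min_len_keep` = 1 bp), and
**pair repair** then separates id-stems present in both mate files
(emitted interleaved, mate-1 order) from singletons. Read conservation
holds exactly: 2·pairs + singles = input reads.

**Random splitting** assigns each pair uniformly to one of *k* parts.
**Random subsetting** ranks pairs by a single seeded permutation and
keeps the first round(fraction·n); subsets drawn from one seed are
therefore *nested* (10% ⊆ 20% ⊆ …), which makes saturation curves
monotone by construction. Nestedness is a design choice of this package:
independent draws per fraction would add sampling noise to the curve
without adding information.

## Assembly merging and locus accounting

The rescue filter keeps fragments *strictly* longer than 110 bp
("longer than" is read as exclusive). Merging is a pure union with id
collisions resolved by prefixing rescued ids, so transcript count and
total base pairs are conserved — the bookkeeping identity
primary + rescued = merged holds exactly.

Locus ids follow the Oases grammar
`Locus_<i>_Transcript_<j>/<k>_Confidence_<c>` (trailing fields ignored).
Ids that do not parse become singleton loci rather than being dropped,
preserving the partition invariant (locus sizes sum to the transcript
count). The mean transcripts-per-locus is computed over *all* loci,
including degenerate mega-loci; no denominator adjustment is attempted
because any published figure computed with a different convention cannot
be reconstructed from totals alone.

## Assembly statistics

**NXX** is the length-weighted statistic used by assembly tools: sort
lengths descending and report the first length at which the cumulative
base count reaches X% of the assembly. A count-based quantile ("X% of
sequences are this long or longer") is a different statistic that
sometimes appears in prose descriptions; this package implements only
the length-weighted form, and the property suite pins it to a
brute-force cumulative-sum oracle on 1,000 random instances.

**GC content** is pooled — (G+C)/(A+C+G+T) over all bases together, not
a mean of per-transcript fractions — because a single assembly-wide
figure is the quantity being reported. Ambiguity codes are excluded from
numerator and denominator alike.

**ORF screen.** An ORF is a maximal stop-free codon run (stop-to-stop)
in any of the six frames, reported at ≥ `min_aa` residues (default 100)
with no start-codon requirement and the standard genetic code only. This
is the simplest defensible coding-potential screen; it intentionally
performs no hexamer/codon-usage scoring and is not a gene predictor.
Coordinates are reported 0-based half-open on the forward strand for
every frame; the longest run per transcript is flagged primary, ties
broken forward-strand-first then lowest start, so output is
deterministic. External interval output (BED) inherits these
conventions; BLAST tabular input keeps its native 1-based inclusive
coordinates and is converted only where consumed.

## Orthology

Best hits are selected per query among hits passing the e-value cutoff,
ranked by higher bitscore, then lower e-value, then lexicographically
smallest subject id. The third key matters: without it, tied hits would
make results depend on input order.

Classification keys entirely on reciprocity: ortholog iff the forward
best hit's gene has the transcript as its own best reverse hit. A
forward-hit gene *absent* from the reverse table is classed paralog, not
no-call — a missing reverse hit is still a failure of reciprocity. Each
reference gene is the ortholog partner of at most one transcript by
construction. Because "orthologs including paralogs" can be counted per
gene or per transcript call, both tallies are reported
(`OrthologCounts`).

Default e-value cutoffs follow common practice for this kind of
annotation: 1e-5 for the gene-prediction (RBH) route and 1e-10 where
raw search storage is concerned; both are plain parameters.

**OHR** uses the single best HSP: subject-residue span (|send − sstart| + 1)
divided by the reference protein length, clamped into (0, 1]. HSPs are
not merged — the ratio is meant to measure one contiguous homologous
block, and merging would inflate completeness for fragmented alignments.
Since 12-column BLAST output carries neither subject lengths nor
taxonomy, both come from a sidecar table (accession, length, taxon) or
the reference FASTA. The span convention is in subject (protein)
residues; a nucleotide-side convention divided by three would give the
same ratio up to edge effects.

Pathway presence marks a component present when its query gene appears
in the supplied hit set; the previously-known percentage is taken over
*present* components. Percentages are reported at 2 decimals, with an
overall row pooled across pathways.

## Expression

Coverage is mapped reads divided by transcript length (reads/bp), with
counts consumed exactly as an idxstats-style table provides them:
multi-mapping reads counted at every position they map to. Both Pearson
and Spearman length–count coefficients are reported, since at
transcriptome scale normality of counts cannot be meaningfully
established and the rank statistic is the robust complement.

Library-size correction is a single multiplicative factor
smaller_total/larger_total, reported at six decimals and applied to the
*larger* library's counts. Corrected counts remain real-valued; the
exclusive-presence threshold (≥ 1000 by default) is compared against the
corrected value for the scaled library and the raw value for the other.
"Zero reads on the other side" always means a raw count of exactly 0 —
scaling can neither create nor destroy zeros. The two exclusive sets are
disjoint by construction and shrink monotonically as the threshold
rises. No count-model differential test is attempted: with a single
library per condition there is no dispersion to estimate, so the method
detects presence/absence, not fold change.

Saturation curves take per-subset analysis results at strictly
increasing fractions and flag the first point whose unique-hit increment
over the previous point falls below a relative tolerance (default 1%).
With nested subsets the unique-hit series is non-decreasing, so the
plateau is well-defined.

## Synthetic data

The generators are pure functions of (parameters, seed): identical
inputs give byte-identical outputs, which the CLI determinism test
checks file-by-file.

The default study design is a 50-gene proteome (100–300 aa, taxon labels
drawn from a four-taxon palette), 250 loci × 2 isoforms = 500
transcripts, and ~20k read pairs — sized so the full pipeline runs end
to end in seconds while every stage has non-trivial input. Core loci
carry one full back-translated protein (the planted ortholog, a
bijection gene → transcript); further isoforms are truncated copies and
extra loci are diverged copies (15% residue substitution by default), so
every non-ortholog coding transcript is a planted paralog whose
simulated hits score strictly below the true ortholog's. Back-translation
draws a synonymous codon per residue from the rng stream; every coding
region is bracketed by in-frame stops, so its coordinates are exactly
recoverable by the stop-to-stop ORF scan.

Reads are 101 bp pairs from a 250 bp insert. A configurable fraction of
reads (30% by default) gets a linear 3′ quality decline from Q40 to Q20
over the last 15 bases, and 10% get their 3′ end replaced by an 11–15
base A-run — both chosen to engage the Q35 / >10-base trimming rules.
With both rates at zero, trimming is the identity on the output, which
anchors the trimming tests. Transcripts shorter than the insert are
skipped with a warning.

Counts follow a negative-binomial model around planted means (the
standard RNA-seq overdispersion family); dispersion defaults to 0, where
counts equal rounded means, because recovery guarantees
(precision = recall = 1 for exclusive calls) are stated at zero noise.
Planted exclusive transcripts have mean zero in the silent library and
at least 1500 expected reads in the other — above the 1000-read
threshold even after worst-case library-size correction. Default library
totals mirror a two-lane embryonic/post-embryonic design
(331,060,788 / 292,205,142 reads, factor 0.882633), and the
29/918 exclusive split used in the acceptance run mirrors the same
study's call counts as a fixture shape.

What the generators do *not* emulate: platform-specific error profiles
(no homopolymer errors, no quality-dependent miscalls by default),
alignment ambiguity (BLAST tables are consistent with the planted truth
by construction), chimeric or fused transcripts, and biological
correlation structure in counts. Passing tests therefore demonstrate
that the *computations* are correct and internally consistent, not that
the upstream assemblers or aligners they post-process would behave well
on real data.

## Numerical conventions

Percentages are rounded with Python's `round` at the precision each
report uses (1 or 2 decimals, or nearest integer where a headline figure
is integral); the correction factor is reported at 6 decimals and
applied as reported. Degenerate inputs fail loudly: empty length lists,
zero-variance correlations, all-ambiguous GC pools, zero library totals
and missing sidecar accessions all raise with a message naming the
offending quantity. Every stochastic routine takes an explicit seed;
derived seeds stay below 2^31.
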