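# Methods

## Event model

A gene is a set of transcript isoforms, each an ordered chain of
non-overlapping exons on one chromosome and strand (1-based inclusive
coordinates, as in GTF). Events are enumerated *pairwise*: every unordered
pair of distinct isoform structures is compared and each local difference is
matched against one of five templates. Pairwise local-difference enumeration
(rather than splice-graph bubbles) matches the event-level granularity of
the downstream test, where each event is quantified and tested on its own.

* **RI** — one isoform has consecutive exons [a,b], [c,d]; the other has the
  single exon [a,d]. Both outer boundaries must match exactly. The retained
  intron is [b+1, c−1].
* **SE** — one isoform joins exons ending at b and starting at e directly;
  the other carries ≥ 1 complete exons between the same boundaries. A skip
  of k ≥ 2 consecutive exons is one event (one junction difference defines
  one event).
* **A5/A3** — two introns, one per isoform, share exactly one boundary. The
  exon carrying the variable boundary must share its distal edge between the
  isoforms; the label (donor vs acceptor side) is assigned relative to the
  strand.
* **MXE** — both isoforms insert exactly one middle exon between identical
  flanking boundaries; the middle exons are disjoint and neither isoform
  contains the other's.

Exonic differences inside the common span that no template explains are
emitted as type `complex` and excluded from five-class statistics. This is a
deliberate consequence of strict template matching: when two events share a
flanking exon (e.g. a donor shift immediately upstream of a skipped exon),
the combined pairwise difference has no unambiguous single-event reading.

**Canonical inclusion form.** RI: the retained intron; SE: the
exon-containing chain; A5/A3: the longer exon; MXE: the longer middle exon,
ties broken toward the leftmost. This makes Ψ orientation (and the sign of
ΔΨ) a deterministic function of the event, independent of transcript input
order.

**Event identity.** `gene:etype:chrom:strand:anchors:inclusion|exclusion` —
a pure function of the event's coordinates, used as the join key across
samples and conditions.

## Read counting

A read is a chain of aligned blocks; block gaps imply splice junctions
(recorded as the flanking exonic base pair). For an event, a read counts
toward a form when it carries one of that form's junctions, or — for
RI/SE/MXE — at least `min_overlap = 8` bases of overlap with a
form-specific exonic interval (for RI, a block crossing an exon–intron
boundary also counts as retention evidence). A5/A3 events are decided by the
two competing junctions only. Reads consistent with both forms or with
neither are ignored; a read can never count toward both forms. The 8-base
minimum guards against alignment-edge noise and is configurable. Counts are
raw read counts, not normalised by the number of informative positions; an
optional helper exposes per-form informative-position counts for users who
want that normalisation.

## PSI posterior and Bayes factor

With a Beta(a, b) prior (uniform a = b = 1 by default, since no prior
information about Ψ is assumed), the posterior after i inclusion and e
exclusion reads is Beta(a+i, b+e); we report its mean and the 2.5%/97.5%
quantiles. With no reads the prior itself is returned.

Differential splicing is scored on replicate-summed counts per condition
(pooling is the testing unit; replicates serve only the filters). The Bayes
factor compares M1 (Ψ₁, Ψ₂ independent uniform) against M0 (one shared
uniform Ψ):

    log BF = ln B(i₁+1, e₁+1) + ln B(i₂+1, e₂+1) − ln B(i₁+i₂+1, e₁+e₂+1)

evaluated with log-Beta functions for numerical stability. With zero reads
in both conditions BF = 1 is returned with a warning. The closed form was
validated against Simpson-quadrature integration of the three marginal
likelihoods: relative error < 10⁻⁵ % over all count pairs with
per-condition totals ≤ 50.

## Filters and significance

* **Reads filter:** every replicate of both conditions needs ≥ 20
  isoform-specific reads; the bound is inclusive, and a missing replicate
  record counts as zero (fails, logged).
* **Consistency filter:** max within-condition pairwise |ΔΨ| (over
  replicate posterior means, maximised over conditions) must be *strictly*
  smaller than the min between-condition pairwise |ΔΨ|. The
  pairwise-max/min formalisation is the most conservative reading of
  "within-condition differences smaller than between-condition
  differences"; both aggregates are returned so alternative readings can be
  audited. With single replicates the within term is 0.
* **Significance:** both filters pass and BF ≥ 5, threshold inclusive.

No multiple-testing correction is applied to Bayes-factor calls. Gene-level
sets are the union of genes owning ≥ 1 significant event. Reciprocal events
between two comparisons are those significant in both with strictly opposite
ΔΨ signs.

## Ortholog filtering and overlap

Tabular (outfmt-6-style) protein alignments are kept when percent identity
≥ 40 and the aligned subject span (|send − sstart| + 1 over the subject
protein length) is ≥ 0.75; per query the best survivor is chosen by bit
score, then e-value, then lexicographic subject id. Subject-span coverage is
used (rather than alignment length, which counts gaps) because the rule asks
how much of the subject protein the alignment includes. Genotype overlap
is |translated(A) ∩ B| / |A| — the denominator is the first argument's set
size, and it is reported alongside the shared gene list so the convention is
explicit.

## Enrichment statistics

* **Chi-square:** Pearson, df = 1, no Yates correction by default (flag
  available); a zero marginal returns (statistic 0, p 1) with a warning.
  The per-event-type distribution test compares differential events against
  the *total* catalog by default, accepting that the differential set is a
  subset of the total; a disjoint `differential_vs_rest` mode is available.
* **Term enrichment:** upper-tail hypergeometric P(X ≥ k) —
  overrepresentation only — against a caller-supplied reference universe,
  with BH step-up q-values over the tested terms. A helper builds the
  recommended universe: intron-containing genes with ≥ 1 read, minus an
  exclusion list (e.g. organellar genes). Annotation propagation to
  ancestor terms along an acyclic child→parent edge list is on by default;
  cycles are an error. The q column is clamped to q ≥ p to guard against
  floating-point rounding in the step-up.
* **Pfaffl ratio:** E_t^ΔCt_t / E_ref^ΔCt_ref with efficiencies validated to
  (1, 2]; ΔCt is control − treatment, and the reference amplicon is a region
  present in all isoforms of the gene.

## Synthetic data

The generator emulates the study design the analysis assumes: two
conditions × two biological replicates (configurable), one planted event per
event gene, genes on alternating strands, 10 kb spacing on one chromosome.
Defaults: 100 genes, 10 events per class, base Ψ ~ Uniform(0.2, 0.8), 20%
of events shifted by ΔΨ = 0.3 (direction random where feasible), mean depth
100 informative reads per event and replicate (Poisson with floor 1,
inclusion Binomial(n, Ψ)), 10% of genes labelled splicing-related, 20 terms
of 15 genes each, read length 100. An enrichment factor > 1 plants shifts
preferentially into splicing-labelled genes for testing the enrichment
statistics.

Reads are simulated at the block level only: junction reads with 50-base
flanks, or fully intronic body reads for RI inclusion. Each stage draws from
its own generator seeded with (stage index, seed) so stages are
reproducible in isolation; the read simulator reuses the count-stage stream,
making count-level and read-level simulation exactly consistent at a seed.

What this does *not* emulate — and therefore what passing tests do not
establish about real data: sequence-level errors and mapping ambiguity,
paired-end fragment-length information, overlapping events within one gene
region (an overlap-free layout keeps ground truth unambiguous), expression
heterogeneity between genes beyond per-event depth, and annotation
incompleteness (events absent from the supplied GTF are invisible to the
detector by construction).

## Validation sizes and observed behaviour

The test suite checks detection against an independent brute-force
classifier on 500 random genes (≤ 6 exons, ≤ 4 transcripts, both strands)
and under coordinate mirroring (which must swap A5↔A3 when the strand is
kept, and preserve all labels when it is flipped); Bayes factors against
quadrature for all totals ≤ 50; null calibration on 3 × 1000 events at
depth 100 (observed significant fraction ≈ 0.2–0.3%, well under 5% — the
filter stack plus BF ≥ 5 is conservative); and power on 1000 events with
200 planted ΔΨ = 0.3 shifts at depth 200 (observed recovery 100%, false
positives ≤ 0.5%, pooled-Ψ mean absolute error ≈ 0.018). PSI accuracy is
asserted as mean |error| ≤ 0.05 with ≥ 90% of per-event estimates within
±0.05: at pooled depth ≈ 400 the binomial standard error is ≈ 0.025, so a
small tail of individual estimates beyond 0.05 is expected behaviour, not
failure.

## Known limitations

Annotation-guided only (no de-novo junction discovery); events with more
than two forms are not modelled; `complex` regions are catalogued but not
quantified or tested; BAM ingestion is limited to block-level TSV input
(convert with any aligner post-processor); the distribution-shift test's
default differential-vs-total comparison double-counts the differential
subset, exactly as the headline analyses it mirrors do — use
`differential_vs_rest` for disjoint strata.
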