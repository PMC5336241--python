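# spliceshift

Differential alternative-splicing analysis from transcript annotations and
junction-level read support: event detection, PSI quantification, filtered
Bayes-factor testing, and downstream enrichment statistics — with a
ground-truthed synthetic-data generator so the whole pipeline is testable
end to end without any sequencing download.

It is aimed at transcriptomics analyses of the kind used to study
temperature-responsive splicing in plants (e.g. *Arabidopsis* ambient
temperature shifts): two conditions, a small number of biological replicates,
and event-level rather than isoform-level quantification.

## What it computes

**Events.** From a GTF of transcript isoforms, every local structural
difference between two isoforms of a gene is classified into the five classic
classes: retained intron (RI), skipped exon (SE), alternative 5′ donor (A5),
alternative 3′ acceptor (A3), and mutually exclusive exons (MXE). A5/A3 are
strand-relative. Differences matching none of the five definitions are kept
as `complex` and excluded from five-class statistics.

**PSI.** For an event with *i* inclusion-specific and *e* exclusion-specific
reads in a sample, the inclusion fraction Ψ (percent spliced in) has the
conjugate posterior

    Ψ | i, e  ~  Beta(a + i, b + e),    Beta(1, 1) prior by default,

summarised by its mean and central 95% credible interval. A read is
*isoform-specific* when it is consistent with exactly one of the event's two
forms (a form-specific splice junction, or ≥ 8 bases of form-specific body
overlap for RI/SE/MXE).

**Differential test.** Replicate counts are summed per condition ("pooled
samples") and scored with the two-sample binomial Bayes factor

    BF = B(i₁+1, e₁+1) · B(i₂+1, e₂+1) / B(i₁+i₂+1, e₁+e₂+1),

the marginal-likelihood ratio of independent vs shared Ψ under uniform
priors, computed in log space. An event is called significant when

1. every replicate of both conditions has ≥ 20 isoform-specific reads,
2. the largest within-condition |ΔΨ| among replicates is strictly smaller
   than the smallest between-condition |ΔΨ|, and
3. BF ≥ 5 (inclusive).

**Downstream.** Reciprocal events between two comparisons (significant in
both, opposite ΔΨ sign); best-hit ortholog filtering of tabular protein
alignments (identity ≥ 40%, subject coverage ≥ 75%) and cross-genotype gene
overlap; Pearson chi-square tests of event-type distribution shifts and of
splicing-related-gene enrichment; hypergeometric term (GO-style) enrichment
with Benjamini–Hochberg correction against a custom intron-containing,
expressed reference universe; and Pfaffl qPCR validation ratios
E_t^ΔCt_t / E_ref^ΔCt_ref.

## Worked example

Simulate a small two-condition, two-replicate study (80 genes, 50 planted
events, ten per class, 20% of them with a true ΔΨ of 0.3), then detect and
test:

```sh
$ splice-shift simulate --seed 4 --outdir demo --n-genes 80
wrote synthetic dataset (80 genes, 50 events) to demo
$ splice-shift detect --gtf demo/genome.gtf --out demo/events.tsv
50 events: RI=10, SE=10, A5=10, A3=10, MXE=10, complex=0
$ splice-shift diff --counts demo/counts.tsv --out demo/calls.tsv
10/50 events significant
```

Detection recovers exactly the 50 planted events. The 10 significant calls
are exactly the 10 events simulated with a true PSI shift (no false
positives at this depth); `calls.tsv` holds, per event, the pooled Bayes
factor, ΔΨ = Ψ(condition 2) − Ψ(condition 1), and the two filter outcomes,
e.g.:

```
event_id                                        bf            delta_psi  significant
G00006:RI:chr1:-:50100-50201:50101-50200|.      4.51e+06      -0.289     True
G00012:SE:chr1:-:110100-110401:110201-110300|.  3.16e+09      -0.228     True
```

(true Ψ for G00006 was 0.633 vs 0.333 — the estimate −0.289 is within
0.01 of the planted −0.300).

The same stages are available as library functions
(`spliceshift.detect_events`, `psi_posterior`, `bayes_factor`,
`call_differential`, `term_enrichment`, ...), and `splice-shift run
--config run.yaml` executes the whole pipeline with provenance-stamped,
byte-reproducible outputs.

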