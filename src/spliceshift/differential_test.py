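"""Replicate filters, pooled Bayes-factor calls, ortholog and overlap ops.

Differential splicing between two conditions is called per event with:

1. *Reads filter* — every replicate of both conditions must carry at least
   ``min_reads`` isoform-specific reads (inclusion + exclusion).
2. *Consistency filter* — the largest within-condition pairwise |dPsi| among
   replicates must be strictly smaller than the smallest between-condition
   pairwise |dPsi|.
3. *Bayes factor* — computed on replicate-summed (pooled) counts per
   condition; the call is significant when both filters pass and
   BF >= ``bf_threshold`` (inclusive).

Gene-level sets (for overlap and enrichment work) are the union of genes
owning at least one significant event.  Cross-genotype comparison first maps
gene identifiers through a best-hit ortholog table derived from tabular
protein alignments filtered on percent identity and subject coverage.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .psi_quant import EventCounts, bayes_factor, pool_counts, psi_posterior

log = logging.getLogger(__name__)

DEFAULT_MIN_READS = 20
DEFAULT_BF_THRESHOLD = 5.0
DEFAULT_MIN_IDENTITY = 40.0
DEFAULT_MIN_COVERAGE = 0.75


@dataclass(frozen=True)
class DifferentialCall:
    """Outcome of the filtered, pooled differential-splicing test for one event."""

    event_id: str
    gene_id: str
    bf: float
    delta_psi: float
    passed_reads_filter: bool
    passed_consistency_filter: bool
    significant: bool

    def __post_init__(self) -> None:
        if self.significant and not (
            self.passed_reads_filter and self.passed_consistency_filter
        ):
            raise ValueError("significant call with a failed filter")


@dataclass(frozen=True)
class OrthologPair:
    """Best protein-level match of a query gene in the other genotype/species."""

    query_gene: str
    subject_gene: str
    pct_identity: float
    subject_coverage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"identity out of range: {self.pct_identity}")
        if not (0.0 <= self.subject_coverage <= 1.0):
            raise ValueError(f"coverage out of range: {self.subject_coverage}")


def reads_filter(
    counts_by_condition: Mapping[str, Sequence[EventCounts | None]],
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[bool, dict[str, list[int]]]:
    """Require >= min_reads isoform-specific reads in every replicate.

    A missing replicate record (None) counts as zero reads and fails the
    filter.  Returns the decision and the per-replicate totals per condition.
    """
    totals: dict[str, list[int]] = {}
    for cond, reps in counts_by_condition.items():
        if not reps:
            raise ValueError(f"condition {cond!r} has no replicates")
        row = []
        for i, c in enumerate(reps):
            if c is None:
                log.warning("condition %s replicate %d: missing counts, "
                            "treated as 0 reads", cond, i + 1)
                row.append(0)
            else:
                row.append(c.total)
        totals[cond] = row
    passed = all(t >= min_reads for row in totals.values() for t in row)
    return passed, totals


def consistency_filter(
    psi_by_condition: Mapping[str, Sequence[float]],
) -> tuple[bool, float, float]:
    """Within-condition PSI spread must be strictly below between-condition spread.

    within_max: the largest pairwise |dPsi| among replicates of one condition,
    maximised over conditions (0 when every condition has a single replicate).
    between_min: the smallest |dPsi| over all cross-condition replicate pairs.
    """
    conds = list(psi_by_condition)
    if len(conds) != 2:
        raise ValueError("consistency filter expects exactly two conditions")
    within = [
        abs(x - y)
        for reps in psi_by_condition.values()
        for x, y in itertools.combinations(reps, 2)
    ]
    within_max = max(within, default=0.0)
    between = [
        abs(x - y)
        for x in psi_by_condition[conds[0]]
        for y in psi_by_condition[conds[1]]
    ]
    if not between:
        raise ValueError("each condition needs at least one replicate PSI")
    between_min = min(between)
    return within_max < between_min, within_max, between_min


def call_differential(
    counts_by_condition: Mapping[str, Sequence[EventCounts]],
    gene_id: str = "",
    bf_threshold: float = DEFAULT_BF_THRESHOLD,
    min_reads: int = DEFAULT_MIN_READS,
) -> DifferentialCall:
    """Filtered pooled Bayes-factor call for one event.

    ``counts_by_condition`` maps the two condition names (iteration order
    defines condition 1 and 2) to per-replicate counts.  delta_psi is the
    pooled posterior-mean PSI of condition 2 minus condition 1.
    """
    conds = list(counts_by_condition)
    if len(conds) != 2:
        raise ValueError("differential call expects exactly two conditions")
    event_ids = {c.event_id for reps in counts_by_condition.values()
                 for c in reps if c is not None}
    if len(event_ids) != 1:
        raise ValueError(f"counts from zero or several events: {sorted(event_ids)}")
    event_id = event_ids.pop()

    passed_reads, _ = reads_filter(counts_by_condition, min_reads)
    psi_reps = {
        cond: [psi_posterior(c).mean for c in reps if c is not None]
        for cond, reps in counts_by_condition.items()
    }
    passed_consistency, _, _ = consistency_filter(psi_reps)

    pooled = {
        cond: pool_counts([c for c in reps if c is not None],
                          sample_id=f"{cond}_pooled")
        for cond, reps in counts_by_condition.items()
    }
    bf = bayes_factor(pooled[conds[0]], pooled[conds[1]])
    delta = (psi_posterior(pooled[conds[1]]).mean
             - psi_posterior(pooled[conds[0]]).mean)
    return DifferentialCall(
        event_id=event_id,
        gene_id=gene_id,
        bf=bf,
        delta_psi=delta,
        passed_reads_filter=passed_reads,
        passed_consistency_filter=passed_consistency,
        significant=passed_reads and passed_consistency and bf >= bf_threshold,
    )


CALL_COLUMNS = ["event_id", "gene_id", "bf", "delta_psi",
                "passed_reads_filter", "passed_consistency_filter",
                "significant"]


def calls_to_table(calls: Iterable[DifferentialCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{k: getattr(c, k) for k in CALL_COLUMNS} for c in calls],
        columns=CALL_COLUMNS,
    )


def find_reciprocal(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Events significant in both call tables with opposite dPsi signs.

    Symmetric in its arguments; events with dPsi = 0 never qualify.
    """
    sig_a = calls_a[calls_a["significant"]].set_index("event_id")
    sig_b = calls_b[calls_b["significant"]].set_index("event_id")
    shared = sig_a.index.intersection(sig_b.index)
    rows = []
    for event_id in sorted(shared):
        da = float(sig_a.loc[event_id, "delta_psi"])
        db = float(sig_b.loc[event_id, "delta_psi"])
        if da * db < 0:
            rows.append({
                "event_id": event_id,
                "gene_id": sig_a.loc[event_id, "gene_id"],
                "delta_psi_a": da,
                "delta_psi_b": db,
            })
    return pd.DataFrame(
        rows, columns=["event_id", "gene_id", "delta_psi_a", "delta_psi_b"]
    )


#: outfmt-6 style tabular alignment columns
ALIGNMENT_COLUMNS = [
    "query", "subject", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def filter_orthologs(
    alignments: pd.DataFrame,
    subject_lengths: Mapping[str, int],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> dict[str, OrthologPair]:
    """Best surviving subject per query after identity and coverage filters.

    A record survives when pct_identity >= min_identity and the aligned
    subject span, |send - sstart| + 1 over the subject protein length, is
    >= min_coverage.  Among survivors of one query the best subject is chosen
    by bit score, then lowest e-value, then lexicographic subject id.
    """
    missing = [c for c in ALIGNMENT_COLUMNS if c not in alignments.columns]
    if missing:
        raise ValueError(f"alignment table lacks columns: {missing}")
    best: dict[str, tuple] = {}
    for rec in alignments.itertuples(index=False):
        slen = subject_lengths.get(rec.subject, 0)
        if slen <= 0:
            warnings.warn(
                f"subject {rec.subject} has no positive length; record skipped"
            )
            continue
        coverage = (abs(int(rec.send) - int(rec.sstart)) + 1) / slen
        if float(rec.pct_identity) < min_identity or coverage < min_coverage:
            continue
        # higher bitscore wins; ties -> lower e-value, then lexicographic id
        key = (-float(rec.bitscore), float(rec.evalue), str(rec.subject))
        pair = OrthologPair(str(rec.query), str(rec.subject),
                            float(rec.pct_identity), min(coverage, 1.0))
        if rec.query not in best or key < best[rec.query][0]:
            best[rec.query] = (key, pair)
    return {q: pair for q, (_, pair) in sorted(best.items())}


def genotype_overlap(
    calls_a: Iterable[str],
    calls_b: Iterable[str],
    ortholog_map: Mapping[str, OrthologPair] | None = None,
) -> tuple[float, list[str]]:
    """Fraction of the first gene set recovered in the second.

    With an ortholog map, genes of the first set are translated to their best
    subject before intersection.  The denominator is the size of the first
    (untranslated) set; an empty first set yields NaN and an empty list.
    """
    set_a = set(calls_a)
    set_b = set(calls_b)
    if not set_a:
        return math.nan, []
    if ortholog_map is None:
        translated = set_a
    else:
        translated = {ortholog_map[g].subject_gene
                      for g in set_a if g in ortholog_map}
    shared = sorted(translated & set_b)
    return len(shared) / len(set_a), shared


def gene_level_calls(calls: pd.DataFrame) -> set[str]:
    """Genes owning at least one significant event."""
    return set(calls.loc[calls["significant"], "gene_id"])
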