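"""Isoform-specific read counting, PSI posteriors and Bayes factors.

The inclusion fraction Psi of an event is modelled with a beta-binomial:
given i inclusion-specific and e exclusion-specific reads and a Beta(a, b)
prior, Psi | data ~ Beta(a + i, b + e).  Differential splicing between two
pooled conditions is scored with the Bayes factor of the two-sample binomial
model comparison

    M1: Psi1, Psi2 ~ iid Uniform(0, 1)    (conditions differ)
    M0: Psi1 = Psi2 ~ Uniform(0, 1)       (shared inclusion fraction)

which has the closed form

    BF = B(i1+1, e1+1) * B(i2+1, e2+1) / B(i1+i2+1, e1+e2+1)

with B the Beta function, evaluated in log space.

A read is *isoform-specific* for an event when it is consistent with exactly
one of the event's two forms: a junction read matching one form's splice
junction, or (for RI/SE/MXE) a read with at least ``min_overlap`` bases of
body evidence inside a form-specific exonic interval.  Reads compatible with
both forms, or with neither, are ignored.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import special, stats

from .event_detection import SpliceEvent
from .gene_models import Interval

DEFAULT_MIN_OVERLAP = 8


@dataclass(frozen=True)
class ReadSupport:
    """One aligned read: sorted non-overlapping blocks; gaps imply junctions."""

    read_id: str
    blocks: tuple[Interval, ...]

    def __post_init__(self) -> None:
        for (s, e) in self.blocks:
            if s > e:
                raise ValueError(f"read {self.read_id}: block start > end")
        for (_, e1), (s2, _) in itertools.pairwise(self.blocks):
            if s2 <= e1:
                raise ValueError(
                    f"read {self.read_id}: blocks overlap or are unsorted"
                )

    @property
    def junctions(self) -> tuple[Interval, ...]:
        """(last exonic base, next exonic base) for every block gap."""
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in itertools.pairwise(self.blocks)
        )


@dataclass(frozen=True)
class EventCounts:
    """Isoform-specific read counts for one event in one sample."""

    event_id: str
    sample_id: str
    inclusion: int
    exclusion: int

    def __post_init__(self) -> None:
        if self.inclusion < 0 or self.exclusion < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.inclusion + self.exclusion


@dataclass(frozen=True)
class PsiPosterior:
    event_id: str
    sample_id: str
    mean: float
    ci_low: float
    ci_high: float
    n_specific: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.mean <= self.ci_high <= 1.0):
            raise ValueError(f"inconsistent posterior summary: {self}")


def _overlap_len(block: Interval, iv: Interval) -> int:
    return max(0, min(block[1], iv[1]) - max(block[0], iv[0]) + 1)


def _supports(event: SpliceEvent, read: ReadSupport, inclusion: bool,
              min_overlap: int) -> bool:
    juncs = (event.inclusion_junctions() if inclusion
             else event.exclusion_junctions())
    if set(read.junctions) & set(juncs):
        return True
    bodies = event.inclusion_bodies() if inclusion else event.exclusion_bodies()
    for body in bodies:
        for block in read.blocks:
            if _overlap_len(block, body) >= min_overlap:
                return True
    if event.etype == "RI" and inclusion:
        # a block running across an exon-intron boundary is retention evidence
        for block in read.blocks:
            if block[0] <= event.anchor_left and block[1] > event.anchor_left:
                return True
            if block[0] < event.anchor_right and block[1] >= event.anchor_right:
                return True
    return False


def classify_read(event: SpliceEvent, read: ReadSupport,
                  min_overlap: int = DEFAULT_MIN_OVERLAP) -> str | None:
    """'inclusion', 'exclusion', or None if the read is not isoform-specific."""
    inc = _supports(event, read, True, min_overlap)
    exc = _supports(event, read, False, min_overlap)
    if inc and not exc:
        return "inclusion"
    if exc and not inc:
        return "exclusion"
    return None


def assign_reads(event: SpliceEvent, reads: Iterable[ReadSupport],
                 sample_id: str = "",
                 min_overlap: int = DEFAULT_MIN_OVERLAP) -> EventCounts:
    """Count isoform-specific reads for one event; ambiguous reads are ignored."""
    inc = exc = 0
    for read in reads:
        side = classify_read(event, read, min_overlap)
        if side == "inclusion":
            inc += 1
        elif side == "exclusion":
            exc += 1
    return EventCounts(event.event_id, sample_id, inc, exc)


def informative_positions(event: SpliceEvent, inclusion: bool) -> int:
    """Number of distinct informative features of a form (junctions + body bases).

    Used by the optional length-normalisation of counts; raw counts are the
    default unit everywhere.
    """
    juncs = (event.inclusion_junctions() if inclusion
             else event.exclusion_junctions())
    bodies = event.inclusion_bodies() if inclusion else event.exclusion_bodies()
    return len(juncs) + sum(e - s + 1 for s, e in bodies)


def psi_posterior(counts: EventCounts, prior_a: float = 1.0,
                  prior_b: float = 1.0) -> PsiPosterior:
    """Beta posterior summary of the inclusion fraction Psi for one sample."""
    if prior_a <= 0 or prior_b <= 0:
        raise ValueError("Beta prior parameters must be positive")
    a = prior_a + counts.inclusion
    b = prior_b + counts.exclusion
    dist = stats.beta(a, b)
    return PsiPosterior(
        event_id=counts.event_id,
        sample_id=counts.sample_id,
        mean=a / (a + b),
        ci_low=float(dist.ppf(0.025)),
        ci_high=float(dist.ppf(0.975)),
        n_specific=counts.total,
    )


def _as_counts(c) -> tuple[int, int]:
    if isinstance(c, EventCounts):
        return c.inclusion, c.exclusion
    i, e = c
    return int(i), int(e)


def log_bayes_factor(c1, c2) -> float:
    """log BF for different-vs-shared Psi between two pooled count pairs."""
    i1, e1 = _as_counts(c1)
    i2, e2 = _as_counts(c2)
    if min(i1, e1, i2, e2) < 0:
        raise ValueError("counts must be non-negative")
    if i1 + e1 + i2 + e2 == 0:
        warnings.warn("Bayes factor requested with zero reads in both "
                      "conditions; returning BF = 1 (no evidence)")
        return 0.0
    return float(
        special.betaln(i1 + 1, e1 + 1)
        + special.betaln(i2 + 1, e2 + 1)
        - special.betaln(i1 + i2 + 1, e1 + e2 + 1)
    )


def bayes_factor(c1, c2) -> float:
    """Bayes factor of independent vs shared inclusion fraction (closed form)."""
    return float(np.exp(log_bayes_factor(c1, c2)))


def pool_counts(counts: Sequence[EventCounts], sample_id: str = "pooled") -> EventCounts:
    """Sum replicate counts within a condition (pooled-sample testing unit)."""
    if not counts:
        raise ValueError("cannot pool an empty replicate list")
    event_ids = {c.event_id for c in counts}
    if len(event_ids) > 1:
        raise ValueError(f"pooling counts from different events: {sorted(event_ids)}")
    return EventCounts(
        counts[0].event_id, sample_id,
        sum(c.inclusion for c in counts),
        sum(c.exclusion for c in counts),
    )
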