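"""Enumeration of local alternative-splicing events from transcript pairs.

Five classic event classes are recognised by comparing the exon chains of two
isoforms of the same gene:

* ``RI``  — retained intron: one isoform splices an intron that the other
  keeps inside a single exon with identical outer boundaries.
* ``SE``  — skipped exon(s): one isoform joins two exons directly that the
  other separates by one or more complete exons (a multi-exon skip is one
  event).
* ``A5`` / ``A3`` — alternative 5' donor / 3' acceptor site: two introns share
  one splice boundary and differ at the other; the label is strand-relative
  (the donor is the 5' end of the intron in transcription direction).
* ``MXE`` — mutually exclusive exons: both isoforms insert exactly one middle
  exon between the same flanking boundaries, the two middle exons are
  disjoint, and neither isoform carries the other's exon.

Local differences that match none of the five templates are reported with
type ``complex`` and excluded from five-class statistics.

Each event stores its two local forms.  The *inclusion* form is canonical:
the retained intron for RI, the exon-containing chain for SE, the longer exon
for A5/A3, and for MXE the longer (tie: leftmost) middle exon — so PSI always
has a deterministic orientation regardless of transcript input order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .gene_models import GeneModel, Interval, Transcript, introns_of

EVENT_TYPES = ("RI", "SE", "A5", "A3", "MXE")
COMPLEX = "complex"
_TYPE_ORDER = {t: i for i, t in enumerate((*EVENT_TYPES, COMPLEX))}


@dataclass(frozen=True)
class SpliceEvent:
    """One local splicing difference between two isoform forms.

    ``anchor_left`` and ``anchor_right`` are the shared splice-relevant
    coordinates bounding the variable region; ``inclusion_exons`` /
    ``exclusion_exons`` are the exonic intervals of each form strictly inside
    the region (for RI the inclusion "exon" is the retained intron itself).
    """

    gene_id: str
    chrom: str
    strand: str
    etype: str
    anchor_left: int
    anchor_right: int
    inclusion_exons: tuple[Interval, ...]
    exclusion_exons: tuple[Interval, ...]

    @property
    def event_id(self) -> str:
        def fmt(xs: tuple[Interval, ...]) -> str:
            return ",".join(f"{s}-{e}" for s, e in xs) or "."

        return (
            f"{self.gene_id}:{self.etype}:{self.chrom}:{self.strand}:"
            f"{self.anchor_left}-{self.anchor_right}:"
            f"{fmt(self.inclusion_exons)}|{fmt(self.exclusion_exons)}"
        )

    @property
    def signature(self) -> tuple:
        """Gene-free structural identity (used for deduplication and tests)."""
        return (
            self.etype,
            self.anchor_left,
            self.anchor_right,
            self.inclusion_exons,
            self.exclusion_exons,
        )

    def _junctions(self, form: tuple[Interval, ...]) -> tuple[Interval, ...]:
        chain: list[Interval] = [(self.anchor_left, self.anchor_left)]
        chain += list(form)
        chain.append((self.anchor_right, self.anchor_right))
        juncs = []
        for (_, e1), (s2, _) in itertools.pairwise(chain):
            if s2 > e1 + 1:
                juncs.append((e1, s2))
        return tuple(juncs)

    def inclusion_junctions(self) -> tuple[Interval, ...]:
        """Splice junctions (last exonic base, next exonic base) of the inclusion form."""
        return self._junctions(self.inclusion_exons)

    def exclusion_junctions(self) -> tuple[Interval, ...]:
        return self._junctions(self.exclusion_exons)

    def inclusion_bodies(self) -> tuple[Interval, ...]:
        """Intervals where body (non-junction) read overlap supports inclusion."""
        if self.etype in ("RI", "SE", "MXE", COMPLEX):
            return self.inclusion_exons
        return ()  # A5/A3 are decided by the competing junctions only

    def exclusion_bodies(self) -> tuple[Interval, ...]:
        if self.etype in ("MXE", COMPLEX):
            return self.exclusion_exons
        return ()


def _ri_events(spliced: Transcript, retaining: Transcript,
               gene_id: str) -> list[SpliceEvent]:
    """Retained introns: `spliced` has the intron, `retaining` a single exon."""
    retained_exons = set(retaining.exon_chain)
    out = []
    chain = spliced.exon_chain
    for (a, b), (c, d) in itertools.pairwise(chain):
        if (a, d) in retained_exons:
            out.append(SpliceEvent(
                gene_id, spliced.chrom, spliced.strand, "RI",
                anchor_left=b, anchor_right=c,
                inclusion_exons=((b + 1, c - 1),),
                exclusion_exons=(),
            ))
    return out


def _se_events(skipping: Transcript, including: Transcript,
               gene_id: str) -> list[SpliceEvent]:
    """Skipped exons: `skipping` has junction b->e, `including` exon(s) between."""
    end_index = {e: i for i, (s, e) in enumerate(including.exon_chain)}
    start_index = {s: i for i, (s, e) in enumerate(including.exon_chain)}
    out = []
    for (_, b), (e, _) in itertools.pairwise(skipping.exon_chain):
        i = end_index.get(b)
        j = start_index.get(e)
        if i is None or j is None or j < i + 2:
            continue
        skipped = including.exon_chain[i + 1:j]
        out.append(SpliceEvent(
            gene_id, skipping.chrom, skipping.strand, "SE",
            anchor_left=b, anchor_right=e,
            inclusion_exons=skipped,
            exclusion_exons=(),
        ))
    return out


def _alt_site_events(tx_a: Transcript, tx_b: Transcript,
                     gene_id: str) -> list[SpliceEvent]:
    """Alternative donor/acceptor events from intron pairs sharing one boundary."""
    strand = tx_a.strand

    def maps(t: Transcript):
        by_end = {e: (s, e) for s, e in t.exon_chain}
        by_start = {s: (s, e) for s, e in t.exon_chain}
        return by_end, by_start

    a_by_end, a_by_start = maps(tx_a)
    b_by_end, b_by_start = maps(tx_b)
    out = []
    for s1, e1 in introns_of(tx_a):
        for s2, e2 in introns_of(tx_b):
            if (s1, e1) == (s2, e2):
                continue
            if s1 == s2 and e1 != e2:
                # acceptor-side (genomic right) variation; require the two
                # variable downstream exons to share their distal end
                d1 = a_by_start.get(e1 + 1)
                d2 = b_by_start.get(e2 + 1)
                if d1 is None or d2 is None or d1[1] != d2[1]:
                    continue
                g = d1[1]
                etype = "A3" if strand == "+" else "A5"
                lo, hi = min(e1, e2), max(e1, e2)
                out.append(SpliceEvent(
                    gene_id, tx_a.chrom, strand, etype,
                    anchor_left=s1 - 1, anchor_right=g,
                    inclusion_exons=((lo + 1, g),),   # longer exon
                    exclusion_exons=((hi + 1, g),),
                ))
            elif e1 == e2 and s1 != s2:
                # donor-side (genomic left) variation; variable upstream exons
                # must share their distal start
                u1 = a_by_end.get(s1 - 1)
                u2 = b_by_end.get(s2 - 1)
                if u1 is None or u2 is None or u1[0] != u2[0]:
                    continue
                h = u1[0]
                etype = "A5" if strand == "+" else "A3"
                lo, hi = min(s1, s2), max(s1, s2)
                out.append(SpliceEvent(
                    gene_id, tx_a.chrom, strand, etype,
                    anchor_left=h, anchor_right=e1 + 1,
                    inclusion_exons=((h, hi - 1),),   # longer exon
                    exclusion_exons=((h, lo - 1),),
                ))
    return out


def _mxe_events(tx_a: Transcript, tx_b: Transcript,
                gene_id: str) -> list[SpliceEvent]:
    a_chain, b_chain = tx_a.exon_chain, tx_b.exon_chain
    a_set, b_set = set(a_chain), set(b_chain)
    # consecutive triples keyed by flanking boundaries (end of left flank,
    # start of right flank)
    def triples(chain):
        out = {}
        for (s0, e0), mid, (s2, e2) in zip(chain, chain[1:], chain[2:]):
            out.setdefault((e0, s2), []).append(mid)
        return out

    ta, tb = triples(a_chain), triples(b_chain)
    out = []
    for key in set(ta) & set(tb):
        b_end, e_start = key
        for m1 in ta[key]:
            for m2 in tb[key]:
                if m1 == m2:
                    continue
                if m1[1] >= m2[0] and m2[1] >= m1[0]:
                    continue  # overlapping middle exons
                if m1 in b_set or m2 in a_set:
                    continue  # not mutually exclusive
                # canonical inclusion: longer exon, tie -> leftmost
                len1 = m1[1] - m1[0]
                len2 = m2[1] - m2[0]
                inc, exc = (m1, m2) if (len1, -m1[0]) > (len2, -m2[0]) else (m2, m1)
                out.append(SpliceEvent(
                    gene_id, tx_a.chrom, tx_a.strand, "MXE",
                    anchor_left=b_end, anchor_right=e_start,
                    inclusion_exons=(inc,),
                    exclusion_exons=(exc,),
                ))
    return out


# -- interval arithmetic on closed integer intervals ------------------------

def _merge(ivs: Iterable[Interval]) -> list[Interval]:
    ivs = sorted(ivs)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(ivs: Sequence[Interval], minus: Sequence[Interval]) -> list[Interval]:
    out = []
    for s, e in ivs:
        pieces = [(s, e)]
        for ms, me in minus:
            nxt = []
            for ps, pe in pieces:
                if me < ps or ms > pe:
                    nxt.append((ps, pe))
                    continue
                if ps < ms:
                    nxt.append((ps, ms - 1))
                if pe > me:
                    nxt.append((me + 1, pe))
            pieces = nxt
        out.extend(pieces)
    return [iv for iv in out if iv[0] <= iv[1]]


def _clip(ivs: Sequence[Interval], lo: int, hi: int) -> list[Interval]:
    return [(max(s, lo), min(e, hi)) for s, e in ivs if e >= lo and s <= hi]


def _complex_events(tx_a: Transcript, tx_b: Transcript, gene_id: str,
                    found: Sequence[SpliceEvent]) -> list[SpliceEvent]:
    """Unexplained structural differences inside the common span -> `complex`."""
    lo = max(tx_a.start, tx_b.start)
    hi = min(tx_a.end, tx_b.end)
    if lo > hi:
        return []
    ex_a = _clip(tx_a.exon_chain, lo, hi)
    ex_b = _clip(tx_b.exon_chain, lo, hi)
    diff = _merge(_subtract(ex_a, ex_b) + _subtract(ex_b, ex_a))
    covered = [(ev.anchor_left, ev.anchor_right) for ev in found]
    remaining = _subtract(diff, _merge(covered)) if covered else diff
    if not remaining:
        return []
    # group residual difference intervals: a fully shared exon strictly
    # between two intervals separates them into distinct regions
    shared = sorted(set(tx_a.exon_chain) & set(tx_b.exon_chain))
    groups: list[list[Interval]] = [[remaining[0]]]
    for prev, cur in itertools.pairwise(remaining):
        gap = (prev[1] + 1, cur[0] - 1)
        separated = any(gap[0] <= s and e <= gap[1] for s, e in shared)
        if separated:
            groups.append([cur])
        else:
            groups[-1].append(cur)
    out = []
    for grp in groups:
        rs, re = grp[0][0], grp[-1][1]
        fa = tuple(_clip(tx_a.exon_chain, rs, re))
        fb = tuple(_clip(tx_b.exon_chain, rs, re))

        def size(form):
            return sum(e - s + 1 for s, e in form)

        inc, exc = (fa, fb) if (size(fa), fa) >= (size(fb), fb) else (fb, fa)
        out.append(SpliceEvent(
            gene_id, tx_a.chrom, tx_a.strand, COMPLEX,
            anchor_left=rs - 1, anchor_right=re + 1,
            inclusion_exons=inc,
            exclusion_exons=exc,
        ))
    return out


def classify_pair(tx_a: Transcript, tx_b: Transcript,
                  gene_id: str = "", with_complex: bool = True) -> list[SpliceEvent]:
    """All local splicing events distinguishing two isoforms of one gene.

    Symmetric: ``classify_pair(a, b)`` and ``classify_pair(b, a)`` return the
    same canonical events.
    """
    if tx_a.chrom != tx_b.chrom or tx_a.strand != tx_b.strand:
        raise ValueError(
            f"transcripts {tx_a.id} and {tx_b.id} are on different "
            "chromosomes or strands"
        )
    if tx_a.exon_chain == tx_b.exon_chain:
        return []
    events: dict[tuple, SpliceEvent] = {}
    for ev in (
        _ri_events(tx_a, tx_b, gene_id) + _ri_events(tx_b, tx_a, gene_id)
        + _se_events(tx_a, tx_b, gene_id) + _se_events(tx_b, tx_a, gene_id)
        + _alt_site_events(tx_a, tx_b, gene_id)
        + _mxe_events(tx_a, tx_b, gene_id)
    ):
        events.setdefault(ev.signature, ev)
    found = list(events.values())
    if with_complex:
        found += _complex_events(tx_a, tx_b, gene_id, found)
    found.sort(key=_sort_key)
    return found


def _sort_key(ev: SpliceEvent):
    return (_TYPE_ORDER[ev.etype], ev.anchor_left, ev.anchor_right, ev.event_id)


def detect_events(gene: GeneModel, with_complex: bool = True) -> list[SpliceEvent]:
    """Deduplicated union of :func:`classify_pair` over all transcript pairs."""
    # duplicate exon chains contribute nothing new
    unique: dict[tuple, Transcript] = {}
    for t in gene.transcripts:
        unique.setdefault(t.exon_chain, t)
    events: dict[str, SpliceEvent] = {}
    for ta, tb in itertools.combinations(unique.values(), 2):
        for ev in classify_pair(ta, tb, gene.gene_id, with_complex=with_complex):
            events.setdefault(ev.event_id, ev)
    return sorted(events.values(), key=_sort_key)


def event_catalog(genes: Iterable[GeneModel],
                  with_complex: bool = True) -> pd.DataFrame:
    """Genome-wide event table, deduplicated, with per-type counts in ``.attrs``."""
    rows = []
    for gene in genes:
        for ev in detect_events(gene, with_complex=with_complex):
            rows.append(_event_to_row(ev))
    df = pd.DataFrame(rows, columns=_CATALOG_COLUMNS).drop_duplicates("event_id")
    df = df.reset_index(drop=True)
    counts = {t: int((df["etype"] == t).sum()) for t in (*EVENT_TYPES, COMPLEX)}
    df.attrs["type_counts"] = counts
    return df


_CATALOG_COLUMNS = [
    "event_id", "gene_id", "etype", "chrom", "strand",
    "anchor_left", "anchor_right", "inclusion_exons", "exclusion_exons",
]


def _fmt_form(form: tuple[Interval, ...]) -> str:
    return ",".join(f"{s}-{e}" for s, e in form) or "."


def _parse_form(text: str) -> tuple[Interval, ...]:
    if text == ".":
        return ()
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def _event_to_row(ev: SpliceEvent) -> dict:
    return {
        "event_id": ev.event_id,
        "gene_id": ev.gene_id,
        "etype": ev.etype,
        "chrom": ev.chrom,
        "strand": ev.strand,
        "anchor_left": ev.anchor_left,
        "anchor_right": ev.anchor_right,
        "inclusion_exons": _fmt_form(ev.inclusion_exons),
        "exclusion_exons": _fmt_form(ev.exclusion_exons),
    }


def events_to_table(events: Iterable[SpliceEvent]) -> pd.DataFrame:
    return pd.DataFrame([_event_to_row(ev) for ev in events],
                        columns=_CATALOG_COLUMNS)


def events_from_table(df: pd.DataFrame) -> list[SpliceEvent]:
    out = []
    for row in df.itertuples(index=False):
        out.append(SpliceEvent(
            gene_id=row.gene_id, chrom=row.chrom, strand=row.strand,
            etype=row.etype, anchor_left=int(row.anchor_left),
            anchor_right=int(row.anchor_right),
            inclusion_exons=_parse_form(row.inclusion_exons),
            exclusion_exons=_parse_form(row.exclusion_exons),
        ))
    return out
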