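"""Gene/transcript/exon domain types and GTF I/O.

Coordinates are 1-based inclusive genomic positions throughout, matching the
GTF convention.  A transcript is an ordered chain of non-overlapping exons on
one chromosome and strand; the gaps between consecutive exons are its introns.
Only ``exon`` features are read from GTF; both the GTF ``key "value";`` and the
bare ``key=value`` attribute dialects are accepted on input, and canonical GTF
attributes are written on output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from gffutils.feature import feature_from_line

log = logging.getLogger(__name__)

Interval = tuple[int, int]


class GtfParseError(ValueError):
    """A line of a GTF file could not be interpreted."""


class ValidationError(ValueError):
    """A gene/transcript/exon violates a structural invariant."""


@dataclass(frozen=True, order=True)
class Exon:
    """A single exon as a closed genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValidationError(f"exon coordinates must be positive: {self}")
        if self.start > self.end:
            raise ValidationError(f"exon start > end: {self}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Transcript:
    """An ordered exon chain on one chromosome and strand.

    Exons are sorted by ascending start, non-overlapping, and separated by
    gaps (introns) of length >= 1.  Adjacent exons (zero-length gap) are
    merged on construction with a warning, since the junction between them
    carries no splice site.
    """

    id: str
    exons: tuple[Exon, ...]
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"transcript {self.id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"transcript {self.id}: no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValidationError(
                f"transcript {self.id} spans multiple chromosomes: {sorted(chroms)}"
            )
        exons = sorted(self.exons)
        merged: list[Exon] = []
        for e in exons:
            if merged and e.start <= merged[-1].end:
                raise ValidationError(
                    f"transcript {self.id}: overlapping exons "
                    f"{merged[-1]} and {e}"
                )
            if merged and e.start == merged[-1].end + 1:
                log.warning(
                    "transcript %s: merging adjacent exons %s and %s "
                    "(zero-length intron)", self.id, merged[-1], e,
                )
                merged[-1] = Exon(e.chrom, merged[-1].start, e.end)
            else:
                merged.append(e)
        object.__setattr__(self, "exons", tuple(merged))

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def exon_chain(self) -> tuple[Interval, ...]:
        """Exon intervals as plain (start, end) tuples."""
        return tuple((e.start, e.end) for e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """A gene: one or more transcript isoforms sharing strand and chromosome."""

    gene_id: str
    transcripts: tuple[Transcript, ...]
    strand: str
    chrom: str

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id}: no transcripts")
        ids = [t.id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"gene {self.gene_id}: duplicate transcript ids")
        for t in self.transcripts:
            if t.strand != self.strand:
                raise ValidationError(
                    f"gene {self.gene_id}: transcript {t.id} strand {t.strand} "
                    f"!= gene strand {self.strand}"
                )
            if t.chrom != self.chrom:
                raise ValidationError(
                    f"gene {self.gene_id}: transcript {t.id} on {t.chrom}, "
                    f"gene on {self.chrom}"
                )

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


def introns_of(t: Transcript) -> list[Interval]:
    """Introns of a transcript as closed intervals between consecutive exons.

    For consecutive exons [a, b], [c, d] the intron is [b + 1, c - 1]; a
    single-exon transcript has none.
    """
    return [
        (t.exons[i].end + 1, t.exons[i + 1].start - 1)
        for i in range(len(t.exons) - 1)
    ]


def has_intron(gene: GeneModel) -> bool:
    """True if any transcript of the gene has >= 2 exons."""
    return any(len(t.exons) > 1 for t in gene.transcripts)


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read exon features from a GTF/GFF file into gene models.

    Non-exon features are ignored.  Exon lines must carry ``gene_id`` and
    ``transcript_id`` attributes.  Output is sorted by
    (chromosome, gene start, gene_id) and is insensitive to input line order.
    """
    path = Path(path)
    # (gene_id) -> (transcript_id) -> list of Exon; plus strand bookkeeping
    tx_exons: dict[str, dict[str, list[Exon]]] = {}
    tx_strands: dict[tuple[str, str], set[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}, line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            try:
                feature = feature_from_line(line)
            except Exception as exc:  # malformed coordinates, attributes, ...
                raise GtfParseError(f"{path}, line {lineno}: {exc}") from exc
            if feature.start > feature.end:
                raise GtfParseError(
                    f"{path}, line {lineno}: start {feature.start} > end {feature.end}"
                )
            attrs = feature.attributes
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(
                    f"{path}, line {lineno}: exon feature lacks gene_id or "
                    "transcript_id attribute"
                )
            gid = attrs["gene_id"][0]
            tid = attrs["transcript_id"][0]
            try:
                exon = Exon(feature.seqid, feature.start, feature.end)
            except ValidationError as exc:
                raise GtfParseError(f"{path}, line {lineno}: {exc}") from exc
            tx_exons.setdefault(gid, {}).setdefault(tid, []).append(exon)
            tx_strands.setdefault((gid, tid), set()).add(feature.strand)

    genes: list[GeneModel] = []
    for gid, txs in tx_exons.items():
        transcripts = []
        for tid, exons in sorted(txs.items()):
            strands = tx_strands[(gid, tid)]
            if len(strands) > 1:
                raise ValidationError(
                    f"transcript {tid} has exons on multiple strands: "
                    f"{sorted(strands)}"
                )
            transcripts.append(Transcript(tid, tuple(exons), strands.pop()))
        chroms = {t.chrom for t in transcripts}
        if len(chroms) > 1:
            raise ValidationError(
                f"gene {gid} spans multiple chromosomes: {sorted(chroms)}"
            )
        gstrands = {t.strand for t in transcripts}
        if len(gstrands) > 1:
            raise ValidationError(
                f"gene {gid} has transcripts on both strands"
            )
        genes.append(
            GeneModel(gid, tuple(transcripts), transcripts[0].strand,
                      transcripts[0].chrom)
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gtf(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as an exon-feature GTF, re-readable by :func:`read_gtf`."""
    rows: list[tuple[str, int, int, str, str, str]] = []
    for gene in models:
        for t in gene.transcripts:
            for e in t.exons:
                rows.append((e.chrom, e.start, e.end, t.strand, gene.gene_id, t.id))
    rows.sort(key=lambda r: (r[0], r[1], r[4], r[5], r[2]))
    with Path(path).open("w") as fh:
        for chrom, start, end, strand, gid, tid in rows:
            fh.write(
                f"{chrom}\tspliceshift\texon\t{start}\t{end}\t.\t{strand}\t.\t"
                f'gene_id "{gid}"; transcript_id "{tid}";\n'
            )


def mirror_gene(gene: GeneModel, pivot: int | None = None,
                flip_strand: bool = True) -> GeneModel:
    """Reflect a gene's coordinates, optionally flipping its strand.

    Every exon [s, e] maps to [pivot - e, pivot - s].  With the strand
    flipped as well (default) the result is the same gene read in the other
    direction, so all event labels must be preserved; mirroring while
    *keeping* the strand must swap every A5 label with A3 and preserve
    RI/SE/MXE.  Both make useful consistency probes for event detection.
    """
    if pivot is None:
        pivot = gene.end + gene.start  # keeps coordinates positive
    flip = {"+": "-", "-": "+"}[gene.strand] if flip_strand else gene.strand
    txs = tuple(
        Transcript(
            t.id,
            tuple(Exon(e.chrom, pivot - e.end, pivot - e.start) for e in t.exons),
            flip,
        )
        for t in gene.transcripts
    )
    return GeneModel(gene.gene_id, txs, flip, gene.chrom)
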