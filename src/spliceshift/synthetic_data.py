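"""Ground-truthed synthetic genomes, counts and reads for pipeline testing.

The generator emulates the statistical skeleton of a two-condition,
two-replicate alternative-splicing study: a set of genes each carrying one
planted splicing event of a known class (RI/SE/A5/A3/MXE), a true inclusion
fraction per condition (a configurable fraction of events gets a true PSI
shift of ``delta_psi``), binomial isoform-specific read counts at a
Poisson-distributed depth per replicate, and gene labels (splicing-related
yes/no, term annotations) for the enrichment statistics.

Reads are simulated at the block/junction level only (no sequence, no error
model): each emitted read is positioned to be isoform-specific under the
counting rules of :mod:`spliceshift.psi_quant`, so read-level and count-level
simulation agree exactly at the same seed.

Randomness: each stage draws from its own ``numpy`` Generator seeded with
(stage index, seed), so stages are individually reproducible and
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .event_detection import EVENT_TYPES, SpliceEvent
from .gene_models import Exon, GeneModel, Transcript
from .psi_quant import ReadSupport

_GENE_SPACING = 10_000
_STAGE_GENOME, _STAGE_COUNTS, _STAGE_READS = 0, 1, 2


@dataclass(frozen=True)
class SimulationSpec:
    """Study-design parameters of one synthetic dataset."""

    n_genes: int = 100
    events_per_type: Mapping[str, int] = field(
        default_factory=lambda: {t: 10 for t in EVENT_TYPES})
    replicates_per_condition: int = 2
    depth: float = 100.0                  # mean informative reads/event/replicate
    psi_low: float = 0.2                  # base PSI ~ Uniform(psi_low, psi_high)
    psi_high: float = 0.8
    differential_fraction: float = 0.2
    delta_psi: float = 0.3
    splicing_gene_fraction: float = 0.1
    splicing_enrichment_factor: float = 1.0   # >1 plants shifts preferentially
    n_terms: int = 20
    genes_per_term: int = 15
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("differential_fraction", "splicing_gene_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]: {v}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0.0 <= self.psi_low <= self.psi_high <= 1.0):
            raise ValueError("PSI base range must satisfy 0 <= low <= high <= 1")
        if self.replicates_per_condition < 1:
            raise ValueError("need at least one replicate per condition")
        unknown = set(self.events_per_type) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event types: {sorted(unknown)}")

    @property
    def n_events(self) -> int:
        return sum(self.events_per_type.values())

    @property
    def conditions(self) -> tuple[str, str]:
        return ("c1", "c2")


@dataclass
class TruthTable:
    """Planted ground truth: per-event PSI/labels and per-gene annotations."""

    events: pd.DataFrame   # event_id, gene_id, etype, psi_c1, psi_c2, differential
    genes: pd.DataFrame    # gene_id, splicing_related, terms, has_intron
    event_objects: dict[str, SpliceEvent]

    @property
    def differential_ids(self) -> set[str]:
        return set(self.events.loc[self.events["differential"], "event_id"])


# Template transcript pairs (gene-local 1-based coordinates) by structural
# class.  "A5-like" varies the donor side in + orientation; on a - strand
# gene the same structure reads as an A3, so templates for A5/A3 swap there.
_TEMPLATES: dict[str, tuple[tuple, tuple, dict]] = {
    "RI": (
        ((1, 100), (201, 300)), ((1, 300),),
        dict(anchor_left=100, anchor_right=201,
             inclusion_exons=((101, 200),), exclusion_exons=()),
    ),
    "SE": (
        ((1, 100), (201, 300), (401, 500)), ((1, 100), (401, 500)),
        dict(anchor_left=100, anchor_right=401,
             inclusion_exons=((201, 300),), exclusion_exons=()),
    ),
    "A5": (  # donor-side variation (genomic left edge of the intron)
        ((1, 200), (301, 400)), ((1, 100), (301, 400)),
        dict(anchor_left=1, anchor_right=301,
             inclusion_exons=((1, 200),), exclusion_exons=((1, 100),)),
    ),
    "A3": (  # acceptor-side variation (genomic right edge of the intron)
        ((1, 100), (201, 400)), ((1, 100), (301, 400)),
        dict(anchor_left=100, anchor_right=400,
             inclusion_exons=((201, 400),), exclusion_exons=((301, 400),)),
    ),
    "MXE": (
        ((1, 100), (201, 300), (501, 600)), ((1, 100), (351, 450), (501, 600)),
        dict(anchor_left=100, anchor_right=501,
             inclusion_exons=((201, 300),), exclusion_exons=((351, 450),)),
    ),
}


def _shift(form: tuple, offset: int) -> tuple:
    return tuple((s + offset, e + offset) for s, e in form)


def _planted_gene(gene_id: str, chrom: str, strand: str, etype: str,
                  offset: int) -> tuple[GeneModel, SpliceEvent]:
    # mirrored strand-relative labels: an A5 on "-" has the A3-like structure
    structure = etype
    if strand == "-" and etype in ("A5", "A3"):
        structure = "A3" if etype == "A5" else "A5"
    t1, t2, ev_kw = _TEMPLATES[structure]
    transcripts = tuple(
        Transcript(f"{gene_id}.{i + 1}",
                   tuple(Exon(chrom, s + offset, e + offset) for s, e in chain),
                   strand)
        for i, chain in enumerate((t1, t2))
    )
    event = SpliceEvent(
        gene_id=gene_id, chrom=chrom, strand=strand, etype=etype,
        anchor_left=ev_kw["anchor_left"] + offset,
        anchor_right=ev_kw["anchor_right"] + offset,
        inclusion_exons=_shift(ev_kw["inclusion_exons"], offset),
        exclusion_exons=_shift(ev_kw["exclusion_exons"], offset),
    )
    return GeneModel(gene_id, transcripts, strand, chrom), event


def generate_genome(spec: SimulationSpec) -> tuple[list[GeneModel], TruthTable]:
    """Build a synthetic genome with one planted event per event gene.

    Deterministic under ``spec.seed``.  Genes beyond the planted-event genes
    are constitutive two-exon single-isoform genes, so the genome also
    provides intron-containing non-differential genes for enrichment
    universes.
    """
    if spec.n_events > spec.n_genes:
        raise ValueError(
            f"spec plants {spec.n_events} events but has only "
            f"{spec.n_genes} genes"
        )
    rng = np.random.default_rng([_STAGE_GENOME, spec.seed])
    etypes = [t for t in EVENT_TYPES for _ in range(spec.events_per_type.get(t, 0))]

    genes: list[GeneModel] = []
    event_objects: dict[str, SpliceEvent] = {}
    event_rows = []
    for i in range(spec.n_genes):
        gene_id = f"G{i + 1:05d}"
        strand = "+" if i % 2 == 0 else "-"
        offset = i * _GENE_SPACING
        if i < len(etypes):
            gene, event = _planted_gene(gene_id, "chr1", strand, etypes[i], offset)
            event_objects[event.event_id] = event
            event_rows.append({"event_id": event.event_id, "gene_id": gene_id,
                               "etype": event.etype})
        else:
            exons = tuple(Exon("chr1", s + offset, e + offset)
                          for s, e in ((1, 100), (201, 300)))
            gene = GeneModel(gene_id, (Transcript(f"{gene_id}.1", exons, strand),),
                             strand, "chr1")
        genes.append(gene)

    gene_ids = [g.gene_id for g in genes]
    splicing_related = rng.random(spec.n_genes) < spec.splicing_gene_fraction
    splicing_by_gene = dict(zip(gene_ids, splicing_related))

    events = pd.DataFrame(event_rows,
                          columns=["event_id", "gene_id", "etype"])
    n_events = len(events)
    psi1 = rng.uniform(spec.psi_low, spec.psi_high, size=n_events)
    n_diff = int(round(spec.differential_fraction * n_events))
    weights = np.array([
        spec.splicing_enrichment_factor if splicing_by_gene[g] else 1.0
        for g in events["gene_id"]
    ])
    differential = np.zeros(n_events, dtype=bool)
    if n_diff > 0 and n_events > 0:
        chosen = rng.choice(n_events, size=min(n_diff, n_events),
                            replace=False, p=weights / weights.sum())
        differential[chosen] = True
    psi2 = psi1.copy()
    for idx in np.flatnonzero(differential):
        up_ok = psi1[idx] + spec.delta_psi <= 1.0
        down_ok = psi1[idx] - spec.delta_psi >= 0.0
        if up_ok and down_ok:
            sign = 1.0 if rng.random() < 0.5 else -1.0
        elif up_ok:
            sign = 1.0
        elif down_ok:
            sign = -1.0
        else:
            raise ValueError(
                f"delta_psi {spec.delta_psi} infeasible for base PSI {psi1[idx]}")
        psi2[idx] = psi1[idx] + sign * spec.delta_psi
    events["psi_c1"] = psi1
    events["psi_c2"] = psi2
    events["differential"] = differential

    term_ids = [f"TERM{j + 1:04d}" for j in range(spec.n_terms)]
    terms_by_gene: dict[str, list[str]] = {g: [] for g in gene_ids}
    for term in term_ids:
        size = min(spec.genes_per_term, spec.n_genes)
        for g in rng.choice(gene_ids, size=size, replace=False):
            terms_by_gene[g].append(term)
    genes_df = pd.DataFrame({
        "gene_id": gene_ids,
        "splicing_related": splicing_related,
        "terms": [";".join(terms_by_gene[g]) for g in gene_ids],
        "has_intron": True,
    })
    return genes, TruthTable(events, genes_df, event_objects)


def _draw_counts(truth: TruthTable, spec: SimulationSpec) -> pd.DataFrame:
    rng = np.random.default_rng([_STAGE_COUNTS, spec.seed])
    rows = []
    for ev in truth.events.itertuples(index=False):
        for ci, cond in enumerate(spec.conditions):
            psi = ev.psi_c1 if ci == 0 else ev.psi_c2
            for rep in range(1, spec.replicates_per_condition + 1):
                n = max(1, int(rng.poisson(spec.depth)))
                inc = int(rng.binomial(n, psi))
                rows.append({
                    "event_id": ev.event_id, "gene_id": ev.gene_id,
                    "sample_id": f"{cond}_r{rep}", "condition": cond,
                    "replicate": rep, "inclusion": inc, "exclusion": n - inc,
                })
    return pd.DataFrame(rows, columns=[
        "event_id", "gene_id", "sample_id", "condition", "replicate",
        "inclusion", "exclusion"])


def simulate_counts(truth: TruthTable, spec: SimulationSpec) -> pd.DataFrame:
    """Isoform-specific count table: Binomial(Poisson depth, true PSI) per replicate."""
    return _draw_counts(truth, spec)


def _junction_read(junction, flank: int):
    (d, a) = junction
    return ((d - flank + 1, d), (a, a + flank - 1))


def _read_for(event: SpliceEvent, side: str, k: int,
              read_length: int) -> tuple:
    """Block layout for the k-th read supporting one form of an event."""
    flank = read_length // 2
    juncs = (event.inclusion_junctions() if side == "inclusion"
             else event.exclusion_junctions())
    if juncs:
        return _junction_read(juncs[k % len(juncs)], flank)
    # junction-free form (RI inclusion): a body read inside the retained intron
    body = event.inclusion_exons[0]
    return ((body[0], min(body[0] + read_length - 1, body[1])),)


def simulate_reads(truth: TruthTable, spec: SimulationSpec) -> pd.DataFrame:
    """Block-level reads whose isoform-specific assignment equals the count draw.

    Uses the same count-stage random stream as :func:`simulate_counts`, so at
    a given seed ``assign_reads`` over the output recovers exactly the counts
    that :func:`simulate_counts` returns.
    """
    counts = _draw_counts(truth, spec)
    rows = []
    for rec in counts.itertuples(index=False):
        event = truth.event_objects[rec.event_id]
        for side, n in (("inclusion", rec.inclusion),
                        ("exclusion", rec.exclusion)):
            for k in range(n):
                blocks = _read_for(event, side, k, spec.read_length)
                rows.append({
                    "read_id": f"{rec.event_id}|{rec.sample_id}|{side[0]}{k}",
                    "sample_id": rec.sample_id,
                    "chrom": event.chrom,
                    "blocks": ",".join(f"{s}-{e}" for s, e in blocks),
                })
    return pd.DataFrame(rows, columns=["read_id", "sample_id", "chrom", "blocks"])


def reads_from_table(df: pd.DataFrame) -> dict[str, list[ReadSupport]]:
    """Group a reads table into per-sample ReadSupport lists."""
    out: dict[str, list[ReadSupport]] = {}
    for rec in df.itertuples(index=False):
        blocks = tuple(
            (int(s), int(e))
            for s, e in (part.split("-") for part in rec.blocks.split(","))
        )
        out.setdefault(rec.sample_id, []).append(
            ReadSupport(rec.read_id, blocks))
    return out


def random_gene(rng: np.random.Generator, gene_id: str = "rand",
                max_exons: int = 6, max_transcripts: int = 4) -> GeneModel:
    """A random small gene drawing exon boundaries from a shared position pool.

    Transcripts sample their exon boundaries from one pool of spaced
    positions, so isoforms frequently share splice sites and realise all
    five event classes (plus complex regions) across random draws.
    """
    pool = np.sort(rng.choice(np.arange(1, 400), size=4 * max_exons,
                              replace=False)) * 10
    strand = "+" if rng.random() < 0.5 else "-"
    n_tx = int(rng.integers(2, max_transcripts + 1))
    transcripts = []
    for t in range(n_tx):
        n_exons = int(rng.integers(1, max_exons + 1))
        positions = np.sort(rng.choice(pool, size=2 * n_exons, replace=False))
        exons = tuple(
            Exon("chrS", int(positions[2 * i]), int(positions[2 * i + 1]))
            for i in range(n_exons)
        )
        transcripts.append(Transcript(f"{gene_id}.{t + 1}", exons, strand))
    return GeneModel(gene_id, tuple(transcripts), strand, "chrS")
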