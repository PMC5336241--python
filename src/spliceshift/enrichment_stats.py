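"""Downstream statistics: distribution-shift tests, enrichment, qPCR ratios.

Covers four independent analyses that follow a differential-splicing run:

* Pearson chi-square on 2x2 tables, used both for the per-event-type
  distribution shift (differential events vs the total catalog) and for the
  enrichment of a curated splicing-related gene list among differentially
  spliced genes.
* Term (GO-style) overrepresentation with an upper-tail hypergeometric test
  against a custom reference universe and Benjamini-Hochberg correction,
  with optional annotation propagation to ancestor terms along an acyclic
  child -> parent edge list.
* The Pfaffl relative-quantification ratio for qPCR validation, normalising
  an event-specific amplicon to an all-isoform internal control amplicon:
  ratio = E_t ** dCt_t / E_ref ** dCt_ref.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .event_detection import EVENT_TYPES


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows = group, columns = category."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")


@dataclass(frozen=True)
class TermEnrichmentResult:
    term_id: str
    study_hits: int
    study_size: int
    ref_hits: int
    ref_size: int
    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")
        if self.q < self.p - 1e-12:
            raise ValueError("BH-adjusted q below raw p")
        if self.study_hits > min(self.study_size, self.ref_hits):
            raise ValueError("study hits exceed study size or term size")


@dataclass(frozen=True)
class QpcrMeasurement:
    """Pfaffl inputs: amplification efficiencies and Ct shifts (control - treatment)."""

    target_efficiency: float
    ref_efficiency: float
    dct_target: float
    dct_ref: float

    def __post_init__(self) -> None:
        for name in ("target_efficiency", "ref_efficiency"):
            e = getattr(self, name)
            if not (1.0 < e <= 2.0):
                raise ValueError(
                    f"{name} must lie in (1, 2] (2 = perfect doubling): {e}"
                )


def chi_square_2x2(table: ContingencyTable2x2,
                   yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value (df = 1) for a 2x2 table.

    A zero row or column marginal makes the test degenerate; the function
    then returns (0, 1) with a warning.
    """
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero marginal); returning p = 1")
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(obs, correction=yates)
    return float(stat), float(p)


def event_type_distribution_test(
    differential_events: pd.DataFrame,
    all_events: pd.DataFrame,
    mode: str = "differential_vs_total",
) -> pd.DataFrame:
    """Per-type frequency shift of differential events against the catalog.

    For each of the five event classes, a 2x2 table of (this type, other
    types) x (differential set, comparison set) is tested with Pearson
    chi-square.  The default comparison set is the *total* catalog, of which
    the differential events are a subset; ``mode="differential_vs_rest"``
    uses the complement instead (disjoint strata).
    """
    if mode not in ("differential_vs_total", "differential_vs_rest"):
        raise ValueError(f"unknown mode: {mode}")
    diff_ids = set(differential_events["event_id"])
    all_ids = set(all_events["event_id"])
    if not diff_ids <= all_ids:
        raise ValueError("differential events must be a subset of all events")
    comparison = all_events
    if mode == "differential_vs_rest":
        comparison = all_events[~all_events["event_id"].isin(diff_ids)]
    diff_counts = differential_events["etype"].value_counts()
    comp_counts = comparison["etype"].value_counts()
    n_diff = len(differential_events)
    n_comp = len(comparison)
    rows = []
    for etype in EVENT_TYPES:
        a = int(diff_counts.get(etype, 0))
        c = int(comp_counts.get(etype, 0))
        if n_diff == 0 or n_comp == 0:
            stat, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = chi_square_2x2(
                    ContingencyTable2x2(a, n_diff - a, c, n_comp - c)
                )
        frac_diff = a / n_diff if n_diff else 0.0
        frac_comp = c / n_comp if n_comp else 0.0
        direction = "enriched" if frac_diff > frac_comp else (
            "depleted" if frac_diff < frac_comp else "unchanged")
        rows.append({
            "etype": etype, "n_differential": a, "n_comparison": c,
            "frac_differential": frac_diff, "frac_comparison": frac_comp,
            "statistic": stat, "p": p, "direction": direction,
        })
    return pd.DataFrame(rows)


def splicing_gene_enrichment(
    diff_genes: Iterable[str],
    splicing_genes: Iterable[str],
    reference: Iterable[str],
) -> tuple[float, float, float]:
    """Enrichment of a curated splicing-gene list among differential genes.

    Returns (fraction of differential genes that are splicing-related,
    chi-square statistic, p).  The splicing list is intersected with the
    reference universe before testing; differential genes must be a subset of
    the universe.
    """
    universe = set(reference)
    diff = set(diff_genes)
    if not diff <= universe:
        missing = sorted(diff - universe)[:5]
        raise ValueError(f"differential genes outside the reference: {missing}")
    splicing = set(splicing_genes) & universe
    if not diff:
        return float("nan"), 0.0, 1.0
    a = len(diff & splicing)
    b = len(diff - splicing)
    c = len((universe - diff) & splicing)
    d = len((universe - diff) - splicing)
    stat, p = chi_square_2x2(ContingencyTable2x2(a, b, c, d))
    return a / len(diff), stat, p


def propagate_annotations(
    annotations: Mapping[str, Iterable[str]],
    parent_edges: Iterable[tuple[str, str]],
) -> dict[str, set[str]]:
    """Copy every gene's term annotations to all ancestor terms.

    ``parent_edges`` is an acyclic (child, parent) list; a cycle is an error.
    """
    dag = nx.DiGraph()
    dag.add_edges_from(parent_edges)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("term parent graph contains a cycle")
    out: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        full = set(terms)
        for term in list(full):
            if term in dag:
                full |= nx.descendants(dag, term)  # ancestors along child->parent
        out[gene] = full
    return out


def term_enrichment(
    annotations: Mapping[str, Iterable[str]],
    study: Iterable[str],
    reference: Iterable[str],
    propagate: bool = True,
    parent_edges: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric term overrepresentation with BH correction.

    The universe is the supplied reference gene list; per term, the p-value is
    P(X >= study_hits) for study_size draws from ref_size genes of which
    ref_hits carry the term.  Terms absent from the reference are skipped.
    """
    universe = set(reference)
    study_set = set(study)
    for gene in sorted(study_set):
        if gene not in universe:
            raise ValueError(f"study gene {gene} absent from the reference universe")
    if propagate:
        annotations = propagate_annotations(
            annotations, parent_edges if parent_edges is not None else [])
    gene_terms = {g: set(ts) for g, ts in annotations.items() if g in universe}
    term_genes: dict[str, set[str]] = {}
    for gene, terms in gene_terms.items():
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)
    ref_size = len(universe)
    study_size = len(study_set)
    rows = []
    for term in sorted(term_genes):
        ref_hits = len(term_genes[term])
        if ref_hits == 0:
            continue
        study_hits = len(term_genes[term] & study_set)
        p = float(stats.hypergeom.sf(study_hits - 1, ref_size, ref_hits,
                                     study_size))
        rows.append({
            "term_id": term, "study_hits": study_hits,
            "study_size": study_size, "ref_hits": ref_hits,
            "ref_size": ref_size, "p": min(p, 1.0),
        })
    df = pd.DataFrame(rows, columns=["term_id", "study_hits", "study_size",
                                     "ref_hits", "ref_size", "p"])
    if len(df):
        _, q, _, _ = multipletests(df["p"], method="fdr_bh")
        df["q"] = np.maximum(q, df["p"])  # guard rounding below raw p
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def build_reference_universe(
    genes,
    expression: Mapping[str, float],
    exclude: Iterable[str] = (),
) -> set[str]:
    """Custom enrichment universe: intron-containing genes with >= 1 read.

    ``genes`` is a GeneModel collection; ``expression`` maps gene ids to read
    counts; ``exclude`` removes e.g. organellar or cryptic-intron-only genes.
    """
    from .gene_models import has_intron

    excluded = set(exclude)
    return {
        g.gene_id for g in genes
        if has_intron(g)
        and expression.get(g.gene_id, 0) >= 1
        and g.gene_id not in excluded
    }


def pfaffl_ratio(m: QpcrMeasurement) -> float:
    """Pfaffl relative expression ratio E_t**dCt_t / E_ref**dCt_ref."""
    return (m.target_efficiency ** m.dct_target
            / m.ref_efficiency ** m.dct_ref)


def pfaffl_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Vectorised Pfaffl ratios for a qPCR table.

    Expects columns sample, target_efficiency, dct_target, ref_efficiency,
    dct_ref; returns the table with a ``ratio`` column appended.
    """
    out = measurements.copy()
    out["ratio"] = [
        pfaffl_ratio(QpcrMeasurement(
            target_efficiency=float(r.target_efficiency),
            ref_efficiency=float(r.ref_efficiency),
            dct_target=float(r.dct_target),
            dct_ref=float(r.dct_ref),
        ))
        for r in measurements.itertuples(index=False)
    ]
    return out
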